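_:c14n0 <http://purl.org/net/exergame/ns#metricName> <http://purl.org/net/exergame/metric#Success> .
_:c14n0 <http://purl.org/net/exergame/ns#metricValue> _:c14n7 .
_:c14n1 <http://purl.org/net/exergame/ns#endDateTime> "2014-09-22T18:09:39+02:00"^^<http://www.w3.org/2001/XMLSchema#dateTime> .
_:c14n1 <http://purl.org/net/exergame/ns#game> <http://www.fitforall.gr/resources/SideRaisesGame> .
_:c14n1 <http://purl.org/net/exergame/ns#player> <http://www.fitforall.gr/resources/player162> .
_:c14n1 <http://purl.org/net/exergame/ns#result> _:c14n6 .
_:c14n1 <http://purl.org/net/exergame/ns#site> <http://www.fitforall.gr/resources/MedicalPhysicsLaboratoryAuth> .
_:c14n1 <http://purl.org/net/exergame/ns#startDateTime> "2014-09-22T18:09:39+02:00"^^<http://www.w3.org/2001/XMLSchema#dateTime> .
_:c14n1 <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <http://purl.org/net/exergame/ns#GameSession> .
_:c14n2 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_1> "1.2"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n2 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_2> "0.9"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n2 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_3> "1.5"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n2 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_4> "1.1"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n2 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_5> "1.4"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n2 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_6> "1.0"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n2 <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <http://www.w3.org/1999/02/22-rdf-syntax-ns#Seq> .
_:c14n3 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_1> "4.1"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n3 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_2> "3.8"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n3 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_3> "5.0"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n3 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_4> "4.4"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n3 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_5> "4.9"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n3 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_6> "4.2"^^<http://www.w3.org/2001/XMLSchema#decimal> .
_:c14n3 <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <http://www.w3.org/1999/02/22-rdf-syntax-ns#Seq> .
_:c14n4 <http://purl.org/net/exergame/ns#metricName> <http://purl.org/net/exergame/metric#GoalTime> .
_:c14n4 <http://purl.org/net/exergame/ns#metricUnit> <http://qudt.org/vocab/unit#SecondTime> .
_:c14n4 <http://purl.org/net/exergame/ns#metricValue> _:c14n3 .
_:c14n5 <http://purl.org/net/exergame/ns#metricName> <http://purl.org/net/exergame/metric#ReactionTime> .
_:c14n5 <http://purl.org/net/exergame/ns#metricUnit> <http://qudt.org/vocab/unit#SecondTime> .
_:c14n5 <http://purl.org/net/exergame/ns#metricValue> _:c14n2 .
_:c14n6 <http://purl.org/net/exergame/ns#metricRelation> _:c14n0 .
_:c14n6 <http://purl.org/net/exergame/ns#metricRelation> _:c14n4 .
_:c14n6 <http://purl.org/net/exergame/ns#metricRelation> _:c14n5 .
_:c14n6 <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <http://purl.org/net/exergame/ns#Result> .
_:c14n7 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_1> "true"^^<http://www.w3.org/2001/XMLSchema#boolean> .
_:c14n7 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_2> "true"^^<http://www.w3.org/2001/XMLSchema#boolean> .
_:c14n7 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_3> "false"^^<http://www.w3.org/2001/XMLSchema#boolean> .
_:c14n7 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_4> "true"^^<http://www.w3.org/2001/XMLSchema#boolean> .
_:c14n7 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_5> "false"^^<http://www.w3.org/2001/XMLSchema#boolean> .
_:c14n7 <http://www.w3.org/1999/02/22-rdf-syntax-ns#_6> "true"^^<http://www.w3.org/2001/XMLSchema#boolean> .
_:c14n7 <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <http://www.w3.org/1999/02/22-rdf-syntax-ns#Seq> .
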