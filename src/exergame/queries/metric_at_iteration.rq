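# All values of one metric at one iteration, with the player and start
# date of each game session.  The published query text for this request
# was not preserved; this is a reconstruction from the described triple
# structure (session -> result -> metricRelation -> metricName /
# metricValue -> rdf:_n).  Placeholders: $metric (metric IRI),
# $member (rdf:_n membership property IRI), $direct (extra UNION branch
# for the single-iteration direct-literal encoding; empty otherwise).
PREFIX exergame: <http://purl.org/net/exergame/ns#>
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>

SELECT ?player ?startDateTime ?value
WHERE {
  ?session exergame:player ?player ;
           exergame:startDateTime ?startDateTime ;
           exergame:result ?result .
  ?result exergame:metricRelation ?relation .
  ?relation exergame:metricName <$metric> .
  {
    ?relation exergame:metricValue ?seq .
    ?seq rdf:type rdf:Seq ;
         <$member> ?value .
  }
  $direct
}
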