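"""Ontology term registry for the exergame vocabulary.

The exergame ontology (published at ``http://purl.org/net/exergame/ns#``)
describes exergames -- serious games combining gameplay with physical
exercise -- and the telemetry produced while elderly players play them.
This module holds the IRIs of its classes and properties together with the
namespaces of the companion vocabularies it reuses (FOAF for players, OPE
for exercises, NCIt for muscles, QUDT for units, vCard for site addresses,
SKOS for the shared concept vocabulary).

A handful of linkage properties (``gameMetric``, ``gameController``,
``presentationHardware``, ``gameExercise``, ``metricUnit``,
``involvesMuscle``, ``equipment``, ``benefit``, ``gameGoal``,
``exerciseGoal``) are minted by this package in the exergame namespace:
the published documentation never names the properties that attach a
game's components to the game instance.  They live in the same registry
so that a corrected official term list can be dropped in via
:meth:`OntologyTerms.replace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Mapping
from urllib.parse import urlparse

__all__ = [
    "Iri",
    "OntologyTerms",
    "default_terms",
    "normalize_iri",
    "EXERGAME_NS",
    "METRIC_NS",
    "CONTROLLER_NS",
    "CONCEPT_NS",
    "SITETYPE_NS",
    "INVENTED_PROPERTIES",
]

EXERGAME_NS = "http://purl.org/net/exergame/ns#"
METRIC_NS = "http://purl.org/net/exergame/metric#"
CONTROLLER_NS = "http://purl.org/net/exergame/controller#"
CONCEPT_NS = "http://purl.org/net/exergame/concept#"
SITETYPE_NS = "http://purl.org/net/exergame/sitetype#"

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
FOAF_NS = "http://xmlns.com/foaf/0.1/"
SKOS_NS = "http://www.w3.org/2004/02/skos/core#"
OPE_NS = "http://www.semanticweb.org/ontologies/2013/2/OPE.owl#"
NCI_NS = "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#"
QUDT_NS = "http://qudt.org/schema/qudt#"
QUDT_UNIT_NS = "http://qudt.org/vocab/unit#"
VCARD_NS = "http://www.w3.org/2006/vcard/ns#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"

# Some published excerpts print the exergame namespaces under the host
# ``purl.com`` while every canonical mention uses ``purl.org``; the former is
# accepted on input and normalized to the latter.
_PURL_COM_ALIAS = "http://purl.com/net/exergame/"
_PURL_ORG = "http://purl.org/net/exergame/"


class Iri(str):
    """An absolute IRI.

    A thin ``str`` subclass that rejects empty strings, strings containing
    whitespace, and relative references (no scheme).
    """

    __slots__ = ()

    def __new__(cls, value: str) -> "Iri":
        if not isinstance(value, str) or not value:
            raise ValueError("IRI must be a non-empty string")
        if any(c.isspace() for c in value):
            raise ValueError(f"IRI may not contain whitespace: {value!r}")
        if not urlparse(value).scheme:
            raise ValueError(f"IRI must be absolute (missing scheme): {value!r}")
        return super().__new__(cls, value)

    @property
    def local_name(self) -> str:
        """Fragment after ``#``, else the last path segment."""
        if "#" in self:
            return self.rsplit("#", 1)[1]
        return self.rstrip("/").rsplit("/", 1)[1]


def normalize_iri(value: str) -> Iri:
    """Return *value* as an :class:`Iri`, folding the ``purl.com`` alias."""
    if value.startswith(_PURL_COM_ALIAS):
        value = _PURL_ORG + value[len(_PURL_COM_ALIAS):]
    return Iri(value)


_CLASS_NAMES = (
    "Game",
    "GameSession",
    "Result",
    "MetricRelation",
    "GoalMetric",
    "Unit",
    "GameController",
    "PresentationHardware",
    "Exercise",
    "SiteType",
    "Player",
)

_PUBLISHED_PROPERTIES = (
    "result",
    "site",
    "startDateTime",
    "endDateTime",
    "player",
    "game",
    "metricRelation",
    "metricName",
    "metricValue",
    "siteAddress",
    "concept",
)

#: Linkage properties minted by this package (see module docstring).
INVENTED_PROPERTIES = (
    "gameMetric",
    "gameController",
    "presentationHardware",
    "gameExercise",
    "metricUnit",
    "involvesMuscle",
    "equipment",
    "benefit",
    "gameGoal",
    "exerciseGoal",
)


@dataclass(frozen=True)
class OntologyTerms:
    """Registry of class IRIs, property IRIs and namespace prefixes.

    Invariants checked at construction: every class/property IRI starts
    with one of the registered namespaces, and the prefix map is bijective.
    """

    classes: Mapping[str, Iri] = field(default_factory=dict)
    properties: Mapping[str, Iri] = field(default_factory=dict)
    prefixes: Mapping[str, Iri] = field(default_factory=dict)

    def __post_init__(self) -> None:
        namespaces = tuple(self.prefixes.values())
        if len(set(namespaces)) != len(namespaces):
            raise ValueError("prefix map is not bijective")
        for kind, table in (("class", self.classes), ("property", self.properties)):
            for name, iri in table.items():
                if not any(iri.startswith(ns) for ns in namespaces):
                    raise ValueError(
                        f"{kind} {name!r} IRI {iri} is outside every registered namespace"
                    )

    def cls(self, name: str) -> Iri:
        return self.classes[name]

    def prop(self, name: str) -> Iri:
        return self.properties[name]

    def replace(self, **changes: Mapping[str, Iri]) -> "OntologyTerms":
        """Return a registry with some tables swapped (e.g. corrected
        official property IRIs)."""
        return _dc_replace(self, **changes)

    @property
    def exergame_ns(self) -> Iri:
        return self.prefixes["exergame"]


def default_terms() -> OntologyTerms:
    """The complete default registry for the published ontology."""
    classes = {name: Iri(EXERGAME_NS + name) for name in _CLASS_NAMES}
    properties = {
        name: Iri(EXERGAME_NS + name)
        for name in _PUBLISHED_PROPERTIES + INVENTED_PROPERTIES
    }
    prefixes = {
        "exergame": Iri(EXERGAME_NS),
        "exergame-metric": Iri(METRIC_NS),
        "exergame-controller": Iri(CONTROLLER_NS),
        "exergame-concept": Iri(CONCEPT_NS),
        "exergame-sitetype": Iri(SITETYPE_NS),
        "rdf": Iri(RDF_NS),
        "rdfs": Iri(RDFS_NS),
        "owl": Iri(OWL_NS),
        "foaf": Iri(FOAF_NS),
        "skos": Iri(SKOS_NS),
        "ope": Iri(OPE_NS),
        "nci": Iri(NCI_NS),
        "qudt": Iri(QUDT_NS),
        "vcard": Iri(VCARD_NS),
        "xsd": Iri(XSD_NS),
    }
    return OntologyTerms(classes=classes, properties=properties, prefixes=prefixes)
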