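"""Graph vocabulary: concepts, triples, rule axioms, knowledge graphs.

Five ontology namespaces stand in for the source vocabularies — DO
(diseases), COPE (childhood-obesity prevention / SDoH causal concepts),
GISO (geography), HIO (health-indicator metrics), ACESO (risk factors) —
plus a UPHO namespace for entities (patients, populations, tracts) that
none of them define.  The concept scheme is a plain isA DAG; no OWL, no
description logic.

Triples carry provenance (asserted | data | ml | inferred), an optional
weight (data values, ml confidences), and for inferred triples a
derivation record (rule id + antecedent triple ids) that powers the
explanation layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "PREFIXES",
    "Concept",
    "ConceptScheme",
    "Literal",
    "Triple",
    "Derivation",
    "RuleAxiom",
    "TriplePattern",
    "Guard",
    "KnowledgeGraph",
    "SchemeError",
    "default_scheme",
    "is_subtype",
    "FEATURE_METRICS",
    "METRIC_FACTORS",
    "OUTCOME_METRIC",
]

PREFIXES = {
    "DO": "disease concepts",
    "COPE": "obesity-prevention / SDoH causal concepts",
    "GISO": "geographic regions",
    "HIO": "health-indicator metrics",
    "ACESO": "risk-factor hierarchy",
    "UPHO": "observatory entities (individuals, populations, tracts)",
}

#: Canonical metric concept for each tract-table column.
FEATURE_METRICS = {
    "obesity_prev": "HIO:%ObesityPrevalence",
    "lack_physical_activity": "HIO:%PopWLackOfPhysicalActivity",
    "poverty": "HIO:%UnderPovertyLine",
    "no_hs_diploma": "HIO:%PopNoHighSchoolDiploma",
    "unemployment": "HIO:%Unemployed",
    "pct_black": "HIO:%BlackPopulation",
    "lack_insurance": "HIO:%NoHealthInsurance",
    "low_access_supermarket": "HIO:LowAccessToSupermarketCount",
    "crime_rate": "HIO:CrimeRatePer1000",
}

OUTCOME_METRIC = FEATURE_METRICS["obesity_prev"]

#: Which risk-factor / physical-characteristic concept each metric measures.
#: Metrics without a causal concept in the scheme (race, insurance, crime)
#: are deliberately absent.
METRIC_FACTORS = {
    "HIO:%PopWLackOfPhysicalActivity": "COPE:LackOfPhysicalActivity",
    "HIO:%UnderPovertyLine": "COPE:Poverty",
    "HIO:%PopNoHighSchoolDiploma": "COPE:LowEducation",
    "HIO:%Unemployed": "COPE:Unemployment",
    "HIO:LowAccessToSupermarketCount": "COPE:FoodDesert",
}


class SchemeError(ValueError):
    """Invalid concept scheme, unknown curie, or graph invariant violation."""


@dataclass(frozen=True)
class Concept:
    curie: str
    label: str = ""
    parents: tuple[str, ...] = ()

    def __post_init__(self):
        prefix = self.curie.split(":", 1)[0]
        if ":" not in self.curie or prefix not in PREFIXES:
            raise SchemeError(
                f"curie {self.curie!r} must be PREFIX:LocalName with "
                f"PREFIX in {sorted(PREFIXES)}"
            )


class ConceptScheme:
    """An acyclic isA hierarchy of namespaced concepts."""

    def __init__(self, concepts: list[Concept] | None = None):
        self._concepts: dict[str, Concept] = {}
        for c in concepts or []:
            self.add(c, _validate=False)
        self.validate()

    def add(self, concept: Concept, _validate: bool = True) -> None:
        self._concepts[concept.curie] = concept
        if _validate:
            self.validate()

    def __contains__(self, curie: str) -> bool:
        return curie in self._concepts

    def __getitem__(self, curie: str) -> Concept:
        try:
            return self._concepts[curie]
        except KeyError:
            raise SchemeError(f"unknown concept {curie!r}") from None

    @property
    def concepts(self) -> dict[str, Concept]:
        return dict(self._concepts)

    def validate(self) -> None:
        """Closure under parent references and acyclicity of isA."""
        for c in self._concepts.values():
            for p in c.parents:
                if p not in self._concepts:
                    raise SchemeError(
                        f"{c.curie} has unresolved parent {p!r}"
                    )
        # cycle detection by iterative DFS with colors
        color = {k: 0 for k in self._concepts}  # 0 white, 1 gray, 2 black
        for start in self._concepts:
            if color[start]:
                continue
            stack = [(start, iter(self._concepts[start].parents))]
            color[start] = 1
            while stack:
                node, it = stack[-1]
                for p in it:
                    if color[p] == 1:
                        raise SchemeError(
                            f"isA cycle through {p!r}"
                        )
                    if color[p] == 0:
                        color[p] = 1
                        stack.append((p, iter(self._concepts[p].parents)))
                        break
                else:
                    color[node] = 2
                    stack.pop()


@dataclass(frozen=True)
class Literal:
    """A typed numeric literal: a value tagged with the metric concept it
    instantiates, so rules can match metrics by type."""

    value: float
    metric: str  # metric concept curie, e.g. HIO:%UnderPovertyLine

    def __str__(self) -> str:
        v = self.value
        s = f"{v:g}"
        return f'"{s}"^^{self.metric}'

    @classmethod
    def parse(cls, text: str) -> "Literal":
        if not (text.startswith('"') and "^^" in text):
            raise SchemeError(f"not a typed literal: {text!r}")
        val, metric = text.rsplit("^^", 1)
        return cls(value=float(val.strip('"')), metric=metric)


Term = "str | Literal"


@dataclass(frozen=True)
class Derivation:
    rule_id: str
    antecedents: tuple[str, ...]  # triple ids


@dataclass(frozen=True)
class Triple:
    subject: str
    predicate: str
    object: object  # curie, entity id, or Literal
    provenance: str = "asserted"
    weight: float | None = None
    derivation: Derivation | None = None

    def __post_init__(self):
        if self.provenance not in {"asserted", "data", "ml", "inferred"}:
            raise SchemeError(f"bad provenance {self.provenance!r}")
        if (self.provenance == "inferred") != (self.derivation is not None):
            raise SchemeError(
                "derivation must be present exactly when provenance=inferred"
            )
        if self.weight is not None and self.provenance not in {"ml", "data"}:
            raise SchemeError("weight only allowed for ml/data triples")

    @property
    def key(self) -> tuple:
        return (self.subject, self.predicate, str(self.object))

    @property
    def id(self) -> str:
        return f"{self.subject}|{self.predicate}|{self.object}"

    def to_line(self) -> str:
        parts = [self.subject, self.predicate, str(self.object),
                 self.provenance]
        if self.weight is not None:
            parts.append(repr(float(self.weight)))
        return " ".join(parts)

    @classmethod
    def from_line(cls, line: str) -> "Triple":
        parts = line.split()
        if len(parts) not in (4, 5):
            raise SchemeError(f"cannot parse triple line: {line!r}")
        s, p, o, prov = parts[:4]
        obj: object = o
        if o.startswith('"'):
            obj = Literal.parse(o)
        w = float(parts[4]) if len(parts) == 5 else None
        # inferred triples lose their derivation on a text round-trip;
        # re-tag as asserted to keep invariants honest
        if prov == "inferred":
            prov, w = "asserted", None
        return cls(s, p, obj, prov, w)


@dataclass(frozen=True)
class Guard:
    """Numeric comparison on a variable bound to a typed literal."""

    variable: str
    op: str  # one of >=, <=, >, <
    threshold: float

    _OPS = {
        ">=": lambda a, b: a >= b,
        "<=": lambda a, b: a <= b,
        ">": lambda a, b: a > b,
        "<": lambda a, b: a < b,
    }

    def holds(self, value: float) -> bool:
        return self._OPS[self.op](value, self.threshold)


@dataclass(frozen=True)
class TriplePattern:
    """Antecedent/consequent pattern; terms starting with '?' are variables.

    An object term of the form ``?v^^?m`` (or ``?v^^HIO:X``) matches a typed
    literal, binding ``?v`` to its value and the type slot to its metric
    concept.
    """

    subject: str
    predicate: str
    object: str

    def variables(self) -> set[str]:
        out = set()
        for t in (self.subject, self.predicate, *self.object_parts()):
            if t.startswith("?"):
                out.add(t)
        return out

    def object_parts(self) -> tuple[str, ...]:
        if "^^" in self.object:
            v, m = self.object.split("^^", 1)
            return (v, m)
        return (self.object,)

    def __str__(self) -> str:
        return f"{self.subject} {self.predicate} {self.object}"


@dataclass(frozen=True)
class RuleAxiom:
    """If-then rule: conjunctive antecedent patterns (optionally guarded)
    entailing one consequent pattern.  Range-restricted and negation-free."""

    id: str
    antecedents: tuple[TriplePattern, ...]
    consequent: TriplePattern
    guards: tuple[Guard, ...] = ()

    def __post_init__(self):
        bound = set()
        for pat in self.antecedents:
            bound |= pat.variables()
        free = self.consequent.variables() - bound
        if free:
            raise SchemeError(
                f"rule {self.id}: consequent variables {sorted(free)} "
                "not bound in any antecedent (range restriction)"
            )
        for g in self.guards:
            if g.variable not in bound:
                raise SchemeError(
                    f"rule {self.id}: guard variable {g.variable} unbound"
                )


class KnowledgeGraph:
    """A set of triples over a concept scheme.

    Set semantics on (subject, predicate, object): adding a triple whose
    key is already present is a no-op, so provenance partitions are
    disjoint and re-running enrichment is idempotent.
    """

    def __init__(self, scheme: ConceptScheme,
                 triples: list[Triple] | None = None):
        self.scheme = scheme
        self._triples: dict[tuple, Triple] = {}
        for t in triples or []:
            self.add(t)

    def add(self, triple: Triple) -> bool:
        """Add a triple; returns True if it was new."""
        if triple.key in self._triples:
            return False
        self._triples[triple.key] = triple
        return True

    def __contains__(self, key) -> bool:
        if isinstance(key, Triple):
            key = key.key
        return key in self._triples

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self):
        return iter(self._triples.values())

    @property
    def triples(self) -> list[Triple]:
        return list(self._triples.values())

    def get(self, subject=None, predicate=None, object=None) -> list[Triple]:
        """Triples matching the given constant slots (None = wildcard)."""
        out = []
        for t in self._triples.values():
            if subject is not None and t.subject != subject:
                continue
            if predicate is not None and t.predicate != predicate:
                continue
            if object is not None and str(t.object) != str(object):
                continue
            out.append(t)
        return out

    def by_id(self, triple_id: str) -> Triple:
        for t in self._triples.values():
            if t.id == triple_id:
                return t
        raise SchemeError(f"no triple with id {triple_id!r}")

    def copy(self) -> "KnowledgeGraph":
        kg = KnowledgeGraph(self.scheme)
        kg._triples = dict(self._triples)
        return kg

    # --- serialization -------------------------------------------------

    def to_lines(self) -> str:
        return "\n".join(
            t.to_line() for t in sorted(self._triples.values(),
                                        key=lambda t: t.key)
        )

    @classmethod
    def from_lines(cls, text: str, scheme: ConceptScheme) -> "KnowledgeGraph":
        triples = [Triple.from_line(ln) for ln in text.splitlines()
                   if ln.strip()]
        return cls(scheme, triples)

    def to_node_link(self) -> dict:
        """Deterministic node-link JSON (nodes sorted by id)."""
        nodes = {}
        for t in self._triples.values():
            for term in (t.subject, t.object):
                nid = str(term)
                if nid not in nodes:
                    kind = "literal" if isinstance(term, Literal) else (
                        "concept" if (":" in nid and
                                      nid.split(":")[0] in PREFIXES)
                        else "entity")
                    label = (self.scheme[nid].label
                             if kind == "concept" and nid in self.scheme
                             else nid)
                    nodes[nid] = {"id": nid, "kind": kind, "label": label}
        links = []
        for t in sorted(self._triples.values(), key=lambda t: t.key):
            link = {
                "source": t.subject,
                "target": str(t.object),
                "predicate": t.predicate,
                "provenance": t.provenance,
            }
            if t.weight is not None:
                link["weight"] = float(t.weight)
            if t.derivation is not None:
                link["derivation"] = {
                    "rule": t.derivation.rule_id,
                    "antecedents": list(t.derivation.antecedents),
                }
            links.append(link)
        return {
            "directed": True,
            "multigraph": True,
            "nodes": [nodes[k] for k in sorted(nodes)],
            "links": links,
        }

    @classmethod
    def from_node_link(cls, doc: dict, scheme: ConceptScheme) -> "KnowledgeGraph":
        kg = cls(scheme)
        for link in doc["links"]:
            obj: object = link["target"]
            if isinstance(obj, str) and obj.startswith('"'):
                obj = Literal.parse(obj)
            deriv = None
            prov = link["provenance"]
            if "derivation" in link:
                deriv = Derivation(
                    link["derivation"]["rule"],
                    tuple(link["derivation"]["antecedents"]),
                )
            kg.add(Triple(link["source"], link["predicate"], obj, prov,
                          link.get("weight"), deriv))
        return kg

    def to_json(self) -> str:
        return json.dumps(self.to_node_link(), indent=1, sort_keys=True)


def default_scheme() -> ConceptScheme:
    """The minimal concept hierarchy the observatory uses.

    Diseases under DO:Disease; SDoH concepts under ACESO:RiskFactor;
    lack of physical activity as a physical characteristic (itself a risk
    factor); one HIO metric concept per tract-table column; geographic
    region kinds; and UPHO entity kinds.
    """
    def c(curie, label, *parents):
        return Concept(curie, label, tuple(parents))

    concepts = [
        c("DO:Disease", "disease"),
        c("DO:Obesity", "obesity", "DO:Disease"),
        c("DO:Diabetes", "diabetes", "DO:Disease"),
        c("ACESO:RiskFactor", "risk factor"),
        c("COPE:SDoH", "social determinant of health", "ACESO:RiskFactor"),
        c("COPE:LackOfTransportation", "lack of transportation", "COPE:SDoH"),
        c("COPE:FoodDesert", "food desert", "COPE:SDoH"),
        c("COPE:Income", "income", "COPE:SDoH"),
        c("COPE:Poverty", "poverty", "COPE:SDoH"),
        c("COPE:Unemployment", "unemployment", "COPE:SDoH"),
        c("COPE:LowEducation", "low education", "COPE:SDoH"),
        c("COPE:PhysicalCharacteristic", "physical characteristic",
          "ACESO:RiskFactor"),
        c("COPE:LackOfPhysicalActivity", "lack of physical activity",
          "COPE:PhysicalCharacteristic"),
        c("HIO:Metric", "health-indicator metric"),
        c("GISO:GeographicRegion", "geographic region"),
        c("GISO:ZipCode", "zip code", "GISO:GeographicRegion"),
        c("GISO:CensusTract", "census tract", "GISO:GeographicRegion"),
        c("GISO:Neighborhood", "neighborhood", "GISO:GeographicRegion"),
        c("UPHO:Individual", "individual"),
        c("UPHO:Population", "population"),
    ]
    labels = {
        "HIO:%ObesityPrevalence": "% obesity prevalence",
        "HIO:%PopWLackOfPhysicalActivity": "% population lacking physical activity",
        "HIO:%UnderPovertyLine": "% population below poverty line",
        "HIO:%PopNoHighSchoolDiploma": "% population without high-school diploma",
        "HIO:%Unemployed": "% population unemployed",
        "HIO:%BlackPopulation": "% Black population",
        "HIO:%NoHealthInsurance": "% population without health insurance",
        "HIO:LowAccessToSupermarketCount": "low-income population far from supermarket",
        "HIO:CrimeRatePer1000": "crime rate per 1000",
    }
    for curie in FEATURE_METRICS.values():
        concepts.append(c(curie, labels[curie], "HIO:Metric"))
    return ConceptScheme(concepts)


def is_subtype(scheme: ConceptScheme, a: str, b: str) -> bool:
    """Reflexive-transitive isA reachability: is a a subtype of b?"""
    scheme[a], scheme[b]  # raise on unknown curies
    seen = set()
    stack = [a]
    while stack:
        cur = stack.pop()
        if cur == b:
            return True
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(scheme[cur].parents)
    return False
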