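"""Population knowledge-graph construction and enrichment.

``build_graph`` lays down the semantic skeleton (concept hierarchy, domain
axioms, metric links) and populates it with tract-level evidence (typed
literal metric values, residence edges).  Two enrichment passes follow:
``enrich_with_inference`` runs the forward-chaining reasoner to a stable
state, and ``enrich_with_ml`` adds isPredictorOf edges for the top-ranked
features of a fitted analytics model, weighted by scaled importance.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

from upho.analytics import ImportanceResult
from upho.reasoner import RuleLibrary, forward_chain
from upho.semantics import (
    FEATURE_METRICS,
    METRIC_FACTORS,
    OUTCOME_METRIC,
    ConceptScheme,
    KnowledgeGraph,
    Literal,
    SchemeError,
    Triple,
    is_subtype,
)

__all__ = [
    "build_graph",
    "enrich_with_ml",
    "enrich_with_inference",
    "neighborhood_id",
    "to_graphml",
]

#: Domain axioms asserted into every built graph (also derivable from the
#: shipped antecedent-free rules; set semantics dedupes).
DOMAIN_AXIOMS = (
    ("COPE:LackOfPhysicalActivity", "leadsTo", "DO:Obesity"),
    ("HIO:%ObesityPrevalence", "isHealthIndicatorFor", "DO:Obesity"),
    ("DO:Obesity", "isRiskFactorOf", "DO:Diabetes"),
)


def neighborhood_id(geoid: str) -> str:
    return f"nbhd-{geoid}"


def build_graph(scheme: ConceptScheme, table: pd.DataFrame,
                focus: dict | None = None) -> KnowledgeGraph:
    """Construct the population knowledge graph from tract data.

    Adds: the scheme's isA edges; per-tract nodes typed GISO:CensusTract
    with a one-per-tract Neighborhood; a ``has`` edge per feature value
    (typed literal, provenance ``data``, weight = value); metric→factor
    ``isMetricOf`` links; the domain causal axioms; and, if ``focus`` is
    given, an individual (``{"individual": id, "geoid": g}``) or
    population (``{"population": id, "geoids": [...]}``) with livesIn
    edges.
    """
    kg = KnowledgeGraph(scheme)
    for concept in scheme.concepts.values():
        for parent in concept.parents:
            kg.add(Triple(concept.curie, "isA", parent))
    for metric, factor in METRIC_FACTORS.items():
        if metric in scheme and factor in scheme:
            kg.add(Triple(metric, "isMetricOf", factor))
    for s, p, o in DOMAIN_AXIOMS:
        kg.add(Triple(s, p, o))

    geoids = [str(g) for g in table["geoid"]] if len(table) else []
    feature_cols = [c for c in table.columns if c in FEATURE_METRICS]
    for _, row in table.iterrows():
        geoid = str(row["geoid"])
        nbhd = neighborhood_id(geoid)
        kg.add(Triple(geoid, "isA", "GISO:CensusTract"))
        kg.add(Triple(geoid, "representsA", nbhd))
        kg.add(Triple(nbhd, "isA", "GISO:Neighborhood"))
        for col in feature_cols:
            metric = FEATURE_METRICS[col]
            value = float(row[col])
            kg.add(Triple(geoid, "has", Literal(value, metric),
                          "data", weight=value))
            factor = METRIC_FACTORS.get(metric)
            if factor is not None and is_subtype(
                    scheme, factor, "COPE:PhysicalCharacteristic"):
                kg.add(Triple(nbhd, "hasPhysicalCharacteristic", factor,
                              "data"))

    if focus:
        if "individual" in focus:
            geoid = str(focus["geoid"])
            if geoid not in geoids:
                raise SchemeError(f"focus geoid {geoid!r} not in table")
            kg.add(Triple(focus["individual"], "isA", "UPHO:Individual"))
            kg.add(Triple(focus["individual"], "livesIn", geoid))
        elif "population" in focus:
            pop = focus["population"]
            kg.add(Triple(pop, "isA", "UPHO:Population"))
            for geoid in focus.get("geoids", geoids):
                geoid = str(geoid)
                if geoid not in geoids:
                    raise SchemeError(
                        f"focus geoid {geoid!r} not in table"
                    )
                kg.add(Triple(pop, "livesIn", geoid))
        else:
            raise SchemeError(
                "focus must name an 'individual' or a 'population'"
            )
    return kg


def enrich_with_ml(kg: KnowledgeGraph, importance: ImportanceResult,
                   top_k: int = 5) -> KnowledgeGraph:
    """Add ml-provenance isPredictorOf edges for the top_k most important
    features, weight = scaled importance / 100 (in [0, 1])."""
    out = kg.copy()
    ranking = [f for f in importance.ranking() if f in FEATURE_METRICS
               and FEATURE_METRICS[f] != OUTCOME_METRIC]
    if top_k > len(ranking):
        warnings.warn(
            f"top_k={top_k} exceeds {len(ranking)} available features; "
            "clamping", stacklevel=2,
        )
        top_k = len(ranking)
    for f in ranking[:max(top_k, 0)]:
        out.add(Triple(
            FEATURE_METRICS[f], "isPredictorOf", OUTCOME_METRIC,
            "ml", weight=importance.scaled[f] / 100.0,
        ))
    return out


def enrich_with_inference(kg: KnowledgeGraph, rules: RuleLibrary,
                          max_passes: int = 10,
                          hooks=()) -> KnowledgeGraph:
    """Alternate forward chaining and re-derivation hooks until a pass
    adds nothing (the stable state of the graph)."""
    current = kg
    for _ in range(max_passes):
        before = len(current)
        current = forward_chain(current, rules)
        for hook in hooks:
            current = hook(current)
        if len(current) == before:
            return current
    raise RuntimeError(
        f"graph did not stabilize within {max_passes} passes"
    )


def to_graphml(kg: KnowledgeGraph, path) -> None:
    """Write the graph as GraphML (deterministic node ordering)."""
    g = nx.MultiDiGraph()
    doc = kg.to_node_link()
    for node in doc["nodes"]:
        g.add_node(node["id"], kind=node["kind"], label=node["label"])
    for link in doc["links"]:
        attrs = {"predicate": link["predicate"],
                 "provenance": link["provenance"]}
        if "weight" in link:
            attrs["weight"] = float(link["weight"])
        if "derivation" in link:
            attrs["rule"] = link["derivation"]["rule"]
        g.add_edge(link["source"], link["target"], **attrs)
    nx.write_graphml(g, path)
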