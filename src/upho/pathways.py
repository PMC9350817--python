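"""Causal-pathway tracing, hover-style explanations, recommendations.

Pathways are metapath-constrained walks on the enriched knowledge graph
from an individual/population to a disease.  Two templates are
registered by default: the semantic route
(livesIn → representsA → hasPhysicalCharacteristic → leadsTo) and the
statistical route (livesIn → has → isPredictorOf → isHealthIndicatorFor).
A pathway's score is the product of its edge weights (semantic edges
count 1), so scores live in [0, 1] when ml weights do.

Chaining convention: consecutive edges chain on node identity, except
that a typed-literal object (a tract's metric value) chains to the
metric concept it instantiates — that is how a tract-level observation
hands over to a population-level predictor edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from upho.semantics import (
    FEATURE_METRICS,
    KnowledgeGraph,
    Literal,
    SchemeError,
    Triple,
)

__all__ = [
    "METAPATHS",
    "Pathway",
    "Explanation",
    "trace_pathways",
    "explain",
    "summarize_recommendations",
]

#: Registered metapath templates (predicate sequences).
METAPATHS = (
    ("livesIn", "representsA", "hasPhysicalCharacteristic", "leadsTo"),
    ("livesIn", "has", "isPredictorOf", "isHealthIndicatorFor"),
)

_METRIC_FEATURES = {v: k for k, v in FEATURE_METRICS.items()}


def _chain_targets(obj) -> list[str]:
    """Node ids an edge object can hand over to."""
    if isinstance(obj, Literal):
        return [str(obj), obj.metric]
    return [str(obj)]


@dataclass(frozen=True)
class Pathway:
    edges: tuple[Triple, ...]
    score: float
    evidence: str  # semantic | statistical | both

    @property
    def node_sequence(self) -> tuple[str, ...]:
        nodes = [self.edges[0].subject]
        for e in self.edges:
            nodes.append(str(e.object))
        return tuple(nodes)

    def validate(self, kg: KnowledgeGraph) -> None:
        for e in self.edges:
            if e.key not in kg:
                raise SchemeError(f"pathway edge not in graph: {e.key}")
        for a, b in zip(self.edges, self.edges[1:]):
            if b.subject not in _chain_targets(a.object):
                raise SchemeError(
                    f"pathway does not chain at {a.object} -> {b.subject}"
                )


@dataclass(frozen=True)
class Explanation:
    target: str
    text: str
    values: dict = field(default_factory=dict)


def trace_pathways(kg: KnowledgeGraph, source: str, outcome: str,
                   max_len: int = 6,
                   templates=METAPATHS) -> list[Pathway]:
    """Enumerate metapath-constrained pathways from ``source`` to the
    disease ``outcome``, scored by the product of edge weights and sorted
    by score descending (ties by lexicographic node-id sequence)."""
    if not any(t.subject == source for t in kg):
        raise SchemeError(f"unknown source {source!r}")
    by_subject: dict[str, list[Triple]] = {}
    for t in kg:
        by_subject.setdefault(t.subject, []).append(t)

    found: list[Pathway] = []

    def dfs(template, step, frontier, edges):
        if step == len(template):
            if str(edges[-1].object) == outcome:
                score = 1.0
                for e in edges:
                    if e.provenance == "ml" and e.weight is not None:
                        score *= float(e.weight)
                provs = {e.provenance for e in edges}
                if provs <= {"ml"}:
                    evidence = "statistical"
                elif "ml" in provs:
                    evidence = "both"
                else:
                    evidence = "semantic"
                found.append(Pathway(tuple(edges), score, evidence))
            return
        for node in frontier:
            for t in by_subject.get(node, []):
                if t.predicate != template[step]:
                    continue
                dfs(template, step + 1, _chain_targets(t.object),
                    edges + [t])

    for template in templates:
        if len(template) <= max_len:
            dfs(tuple(template), 0, [source], [])
    found.sort(key=lambda p: (-p.score, p.node_sequence))
    return found


def _fmt(x: float) -> str:
    return f"{x:.1f}"


def explain(kg: KnowledgeGraph, target: str,
            reference_table: pd.DataFrame | None = None,
            region: str = "city") -> Explanation:
    """Hover-style explanation of a node or edge.

    Metric-value nodes compare the stored tract value with the reference
    table's average; ml edges cite the scaled importance behind the
    predictor link; inferred edges replay their stored derivation;
    asserted edges get definitional text.  Numbers are rendered to one
    decimal and echoed in ``values``.
    """
    # edge by triple id
    for t in kg:
        if t.id == target:
            return _explain_edge(kg, t)
    # literal metric node
    for t in kg:
        if isinstance(t.object, Literal) and str(t.object) == target:
            lit = t.object
            label = (kg.scheme[lit.metric].label
                     if lit.metric in kg.scheme else lit.metric)
            values = {"tract_value": float(f"{lit.value:.1f}")}
            if reference_table is not None:
                col = _METRIC_FEATURES.get(lit.metric)
                if col is not None and col in reference_table.columns:
                    mean = float(reference_table[col].mean())
                    values["reference_average"] = float(f"{mean:.1f}")
                    text = (
                        f"In this neighborhood, {_fmt(lit.value)} "
                        f"({label}) — compared to the {region} average "
                        f"of {_fmt(mean)}."
                    )
                    return Explanation(target, text, values)
            text = f"In this neighborhood, {label} is {_fmt(lit.value)}."
            return Explanation(target, text, values)
    # plain node
    for t in kg:
        if t.subject == target or str(t.object) == target:
            label = (kg.scheme[target].label
                     if target in kg.scheme else target)
            return Explanation(
                target, f"{label}: a node of the population knowledge "
                        f"graph.", {},
            )
    raise SchemeError(f"unknown explanation target {target!r}")


def _explain_edge(kg: KnowledgeGraph, t: Triple) -> Explanation:
    def label(curie):
        return kg.scheme[curie].label if curie in kg.scheme else str(curie)

    if t.provenance == "ml":
        score = float(f"{(t.weight or 0.0) * 100:.1f}")
        text = (
            f"{label(t.subject)} predicts {label(str(t.object))} with a "
            f"scaled model importance of {_fmt(score)} (0-100)."
        )
        return Explanation(t.id, text, {"scaled_importance": score})
    if t.provenance == "inferred":
        d = t.derivation
        ante = ", ".join(d.antecedents) if d.antecedents else "no premises"
        text = (
            f"Inferred by rule {d.rule_id} from: {ante}."
        )
        return Explanation(t.id, text,
                           {})
    if t.predicate == "isA":
        return Explanation(
            t.id,
            f"{label(t.subject)} is a kind of {label(str(t.object))}.",
            {},
        )
    if isinstance(t.object, Literal):
        v = float(f"{t.object.value:.1f}")
        return Explanation(
            t.id,
            f"Tract {t.subject}: {label(t.object.metric)} = {_fmt(v)}.",
            {"tract_value": v},
        )
    return Explanation(
        t.id,
        f"{label(t.subject)} {t.predicate} {label(str(t.object))} "
        f"(domain knowledge).",
        {},
    )


def summarize_recommendations(kg: KnowledgeGraph,
                              pathways: list[Pathway]) -> list[str]:
    """One screening recommendation per inferred shouldBeScreenedFor
    triple, plus one intervention recommendation per traced pathway
    (framed on its risk factor), deduplicated, score-descending order."""
    def label(curie):
        return kg.scheme[curie].label if curie in kg.scheme else str(curie)

    recs: list[str] = []
    for t in sorted(kg.get(predicate="shouldBeScreenedFor"),
                    key=lambda t: t.key):
        recs.append(
            f"{t.subject} should be screened for {label(str(t.object))}."
        )
    for p in pathways:  # already score-descending
        factor = None
        for e in p.edges:
            if e.predicate in ("hasPhysicalCharacteristic", "isExposedTo"):
                factor = str(e.object)
            elif e.predicate == "isPredictorOf":
                factor = e.subject
        if factor is not None:
            recs.append(
                f"Consider interventions addressing {label(factor)}, a "
                f"leading factor on a traced pathway to "
                f"{label(str(p.edges[-1].object))}."
            )
    seen, out = set(), []
    for r in recs:
        if r not in seen:
            seen.add(r)
            out.append(r)
    return out
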