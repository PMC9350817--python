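"""Datalog-style forward chaining over a knowledge graph.

Negation-free, retraction-free rules with set semantics guarantee a unique
least fixpoint, so the inferred triple set is independent of rule order.
Every inferred triple records the rule and the antecedent triples that
produced it; replaying those records bottoms out in asserted/data/ml
triples (or in antecedent-free domain axioms), which is what the
explanation layer renders.

Rules live in a line-oriented text format::

    RULE RB2: ?p isExposedTo ?rf & ?rf leadsTo ?d => ?p atRiskOf ?d

Antecedent conjuncts are triple patterns (``?x`` terms are variables; an
object ``?v^^?m`` matches a typed literal, binding value and metric
concept) or numeric guards like ``?v >= 50``.  A rule with no antecedents
is a domain axiom that simply asserts its consequent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from upho.semantics import (
    Derivation,
    Guard,
    KnowledgeGraph,
    Literal,
    RuleAxiom,
    SchemeError,
    Triple,
    TriplePattern,
)

__all__ = [
    "Binding",
    "RuleLibrary",
    "NonterminationError",
    "match",
    "check_guards",
    "forward_chain",
    "parse_rule",
    "parse_rules",
    "load_rules",
    "default_rules",
]

Binding = dict  # variable name -> constant term


class NonterminationError(RuntimeError):
    """Fixpoint not reached within the allotted rounds."""


_GUARD_RE = re.compile(r"^(\?\w+)\s*(>=|<=|>|<)\s*([-+0-9.eE]+)$")


def _unify_term(pat_term: str, value, binding: Binding) -> Binding | None:
    """Unify one pattern term with a concrete term under a binding."""
    if pat_term.startswith("?"):
        if pat_term in binding:
            if _same(binding[pat_term], value):
                return binding
            return None
        out = dict(binding)
        out[pat_term] = value
        return out
    return binding if _same(pat_term, value) else None


def _same(a, b) -> bool:
    if isinstance(a, Literal) or isinstance(b, Literal):
        return str(a) == str(b)
    return a == b


def match(pattern: TriplePattern, triple: Triple,
          binding: Binding | None = None) -> Binding | None:
    """Extend ``binding`` so that ``pattern`` grounds to ``triple``.

    Returns the extended binding, or None on failure.  A typed-literal
    object pattern ``?v^^?m`` requires the triple's object to be a
    :class:`~upho.semantics.Literal`; ``?v`` binds to its numeric value and
    the type slot to its metric concept curie.
    """
    b = dict(binding) if binding else {}
    b2 = _unify_term(pattern.subject, triple.subject, b)
    if b2 is None:
        return None
    b2 = _unify_term(pattern.predicate, triple.predicate, b2)
    if b2 is None:
        return None
    parts = pattern.object_parts()
    if len(parts) == 2:  # typed-literal pattern
        if not isinstance(triple.object, Literal):
            return None
        val_pat, metric_pat = parts
        b2 = _unify_term(val_pat, triple.object.value, b2)
        if b2 is None:
            return None
        b2 = _unify_term(metric_pat, triple.object.metric, b2)
        return b2
    return _unify_term(parts[0], triple.object, b2)


def check_guards(guards: tuple[Guard, ...], binding: Binding) -> bool:
    """Evaluate numeric guards against bound (literal) values."""
    for g in guards:
        v = binding[g.variable]
        if isinstance(v, Literal):
            v = v.value
        if not isinstance(v, (int, float)):
            return False
        if not g.holds(float(v)):
            return False
    return True


def _instantiate(pattern: TriplePattern, binding: Binding):
    def sub(term):
        return binding[term] if term.startswith("?") else term

    parts = pattern.object_parts()
    if len(parts) == 2:
        obj: object = Literal(float(sub(parts[0])), str(sub(parts[1])))
    else:
        obj = sub(parts[0])
    return sub(pattern.subject), sub(pattern.predicate), obj


@dataclass
class RuleLibrary:
    """An ordered list of rule axioms (order affects only which derivation
    is recorded for a triple derivable in several ways, never the result
    set)."""

    rules: list[RuleAxiom] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)


def _join(rule: RuleAxiom, triples: list[Triple],
          delta_keys: set | None) -> list[tuple[Binding, tuple[Triple, ...]]]:
    """All antecedent matches; if delta_keys is given, keep only matches
    using at least one delta triple (semi-naive restriction)."""
    results: list[tuple[Binding, tuple[Triple, ...], bool]] = [({}, (), False)]
    for pat in rule.antecedents:
        nxt = []
        for binding, used, touched in results:
            for t in triples:
                b2 = match(pat, t, binding)
                if b2 is not None:
                    nxt.append(
                        (b2, used + (t,),
                         touched or delta_keys is None
                         or t.key in delta_keys)
                    )
        results = nxt
        if not results:
            return []
    out = []
    for binding, used, touched in results:
        if delta_keys is not None and not touched:
            continue
        if check_guards(rule.guards, binding):
            out.append((binding, used))
    return out


def forward_chain(kg: KnowledgeGraph, rules: RuleLibrary,
                  max_rounds: int = 100) -> KnowledgeGraph:
    """Compute the least fixpoint of ``rules`` over ``kg``.

    Monotone: all input triples are preserved.  Inferred triples get
    provenance ``inferred`` and a derivation naming the rule and the
    antecedent triple ids; when a triple is derivable several ways, the
    first derivation under (round, rule order, triple insertion order)
    is kept.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    out = kg.copy()
    delta_keys: set | None = None  # None = first round, use everything
    for _ in range(max_rounds):
        new: list[Triple] = []
        snapshot = out.triples
        for rule in rules:
            for binding, used in _join(rule, snapshot, delta_keys):
                s, p, o = _instantiate(rule.consequent, binding)
                cand = Triple(
                    str(s), str(p), o, "inferred",
                    derivation=Derivation(rule.id,
                                          tuple(t.id for t in used)),
                )
                if cand.key not in out and all(
                        cand.key != n.key for n in new):
                    new.append(cand)
        if not new:
            return out
        for t in new:
            out.add(t)
        delta_keys = {t.key for t in new}
    raise NonterminationError(
        f"fixpoint not reached within {max_rounds} rounds"
    )


# --- rule text format --------------------------------------------------

def parse_rule(line: str) -> RuleAxiom:
    m = re.match(r"^RULE\s+([\w-]+)\s*:\s*(.*?)\s*=>\s*(.+)$", line.strip())
    if not m:
        raise SchemeError(f"cannot parse rule line: {line!r}")
    rid, body, head = m.groups()
    antecedents: list[TriplePattern] = []
    guards: list[Guard] = []
    if body.strip():
        for conjunct in body.split("&"):
            conjunct = conjunct.strip()
            gm = _GUARD_RE.match(conjunct)
            if gm:
                guards.append(Guard(gm.group(1), gm.group(2),
                                    float(gm.group(3))))
                continue
            toks = conjunct.split()
            if len(toks) != 3:
                raise SchemeError(
                    f"rule {rid}: bad conjunct {conjunct!r}"
                )
            antecedents.append(TriplePattern(*toks))
    toks = head.strip().split()
    if len(toks) != 3:
        raise SchemeError(f"rule {rid}: bad consequent {head!r}")
    return RuleAxiom(rid, tuple(antecedents), TriplePattern(*toks),
                     tuple(guards))


def parse_rules(text: str) -> RuleLibrary:
    rules = [
        parse_rule(ln)
        for ln in text.splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    return RuleLibrary(rules)


def load_rules(path) -> RuleLibrary:
    with open(path, encoding="utf-8") as fh:
        return parse_rules(fh.read())


def default_rules() -> RuleLibrary:
    """The shipped domain axioms (R1–R3) and bridging rules (RB1–RB3)."""
    text = resources.files("upho").joinpath("rules/default.rules").read_text(
        encoding="utf-8"
    )
    return parse_rules(text)
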