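"""The worked patient scenario: a single tract's facts plus the domain
axioms, encoded as a small knowledge graph.

An adult patient lives in census tract 10300; the tract's records show
49% of its population lacking physical activity, 21% without a
high-school diploma, 60% below the poverty line, and an obesity
prevalence of 46%.  The analytics layer has flagged lack of physical
activity as a predictor of obesity prevalence.  Forward chaining over
the shipped rules then derives the patient's exposure to lack of
physical activity and a diabetes-screening recommendation.

This module is the canonical fixture for the reasoner and pathway
layers; the numbers are the scenario's, not outputs of any model run.
"""

from __future__ import annotations

from upho.reasoner import RuleLibrary, default_rules
from upho.semantics import (
    ConceptScheme,
    KnowledgeGraph,
    Literal,
    Triple,
    default_scheme,
)

__all__ = ["PATIENT", "TRACT", "scenario_graph", "scenario_rules"]

PATIENT = "patient-1"
TRACT = "10300"

_METRICS = {
    "lack_physical_activity": ("HIO:%PopWLackOfPhysicalActivity", 49.0),
    "no_hs_diploma": ("HIO:%PopNoHighSchoolDiploma", 21.0),
    "poverty": ("HIO:%UnderPovertyLine", 60.0),
    "obesity_prev": ("HIO:%ObesityPrevalence", 46.0),
}


def scenario_graph(scheme: ConceptScheme | None = None,
                   with_predictor: bool = True) -> KnowledgeGraph:
    """Encode the scenario's initial facts.

    Facts: the patient's residence; the tract's four metric values; the
    ml-derived predictor edge (``with_predictor``); the domain axioms
    (lack of physical activity leads to obesity; obesity-prevalence is a
    health indicator for obesity; obesity is a risk factor for
    diabetes); and the single metric-link axiom the exposure rule needs.
    Only the physical-activity metric carries a link here, so inference
    derives exactly the scenario's printed conclusions.
    """
    scheme = scheme or default_scheme()
    kg = KnowledgeGraph(scheme)
    kg.add(Triple(PATIENT, "isA", "UPHO:Individual"))
    kg.add(Triple(TRACT, "isA", "GISO:CensusTract"))
    kg.add(Triple(PATIENT, "livesIn", TRACT))                      # F1
    # neighborhood view of the tract, carrying its physical characteristic
    kg.add(Triple(TRACT, "representsA", f"nbhd-{TRACT}"))
    kg.add(Triple(f"nbhd-{TRACT}", "isA", "GISO:Neighborhood"))
    kg.add(Triple(f"nbhd-{TRACT}", "hasPhysicalCharacteristic",
                  "COPE:LackOfPhysicalActivity", "data"))
    for col in ("lack_physical_activity", "no_hs_diploma",
                "poverty", "obesity_prev"):                        # F2-F5
        metric, value = _METRICS[col]
        kg.add(Triple(TRACT, "has", Literal(value, metric), "data",
                      weight=value))
    if with_predictor:                                             # F6
        kg.add(Triple("HIO:%PopWLackOfPhysicalActivity", "isPredictorOf",
                      "HIO:%ObesityPrevalence", "ml", weight=1.0))
    # domain axioms (R1-R3) and the metric link RB1 resolves
    kg.add(Triple("COPE:LackOfPhysicalActivity", "leadsTo", "DO:Obesity"))
    kg.add(Triple("HIO:%ObesityPrevalence", "isHealthIndicatorFor",
                  "DO:Obesity"))
    kg.add(Triple("DO:Obesity", "isRiskFactorOf", "DO:Diabetes"))
    kg.add(Triple("HIO:%PopWLackOfPhysicalActivity", "isMetricOf",
                  "COPE:LackOfPhysicalActivity"))
    return kg


def scenario_rules() -> RuleLibrary:
    """The bridging rules only: the scenario graph already asserts the
    domain axioms as ground facts, so the antecedent-free axiom rules
    are redundant (kept out to keep derivations minimal)."""
    lib = default_rules()
    return RuleLibrary([r for r in lib if r.id.startswith("RB")])
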