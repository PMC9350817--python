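# Domain axioms: causal and indicator knowledge.
RULE R1: => COPE:LackOfPhysicalActivity leadsTo DO:Obesity
RULE R2: => HIO:%ObesityPrevalence isHealthIndicatorFor DO:Obesity
RULE R3: => DO:Obesity isRiskFactorOf DO:Diabetes
# Bridging rules: residence-based exposure, causal risk, screening.
RULE RB1: ?p livesIn ?t & ?t has ?v^^?m & ?m isMetricOf ?rf => ?p isExposedTo ?rf
RULE RB2: ?p isExposedTo ?rf & ?rf leadsTo ?d => ?p atRiskOf ?d
RULE RB3: ?p atRiskOf ?d & ?d isRiskFactorOf ?d2 => ?p shouldBeScreenedFor ?d2
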