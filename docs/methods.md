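# Methods

This note documents the models, procedures and numerical choices behind
`upho`, in the order data flows through the package.

## Problem setting

The package models neighborhood-level drivers of chronic-disease
prevalence. The unit of analysis is the US census tract (11-digit FIPS
code). Each tract carries a crude disease-prevalence outcome (percent of
adults, as published in BRFSS-style small-area estimates) and a set of
social-determinant and behavioral features: percent of adults lacking
physical activity, percent below the federal poverty line, percent of
adults 25+ without a high-school diploma, percent unemployed, percent
Black population, percent without health insurance, a count of
low-income population far from a supermarket, and a crime rate per 1000.
Two deliberately coupled representations are built from the same table:
a predictive model with per-feature attribution, and an ontology-backed
knowledge graph over which rules infer individual-level exposure and
screening advice and through which "causal pathways" — chains from a
person or population through neighborhood exposures to a disease — are
traced and explained.

## Synthetic tract generator

The generator (`upho.tracts`) emulates the joint structure of a
178-tract urban county. Defaults are the marginal means/SDs of the
Memphis-style study table (obesity 37.50 (7.84); lack of physical
activity 36.16 (9.80); poverty 28.65 (16.28); no-HS-diploma 10.38
(6.59); unemployment 15.73 (9.31); % Black 63.17 (32.70); lack of
insurance 20.21 (6.78); low supermarket access 1382.20 (108.37); crime
350.20 (126.26) per 1000) and per-feature Spearman targets with the
outcome (0.92, 0.83, 0.81, 0.73, 0.77, 0.37, 0.37; insurance is not part
of that screen and defaults to 0.40 here).

Mechanism: a latent Gaussian copula. Feature ``j`` loads on a single
common factor with loading equal to its configured outcome correlation,
giving the feature–feature correlation matrix ``C`` with
``C[i,j] = rho_i * rho_j`` (repaired to the nearest positive-definite
correlation matrix by eigenvalue clipping when a user supplies an
inconsistent target). Margins are rescaled to their target mean/SD and
clipped to their valid range (percents to [0, 100], counts/rates to
≥ 0). The outcome is then a linear model,
``y = b0 + Σ w_j x_j + N(0, σ)``, clipped to [0, 100].

Choices worth knowing:

- **Clipping after noise.** Guarantees every generated record satisfies
  the field invariants, at the cost of a small bias in extreme margins
  (a mean-37.5/SD-16 percent margin loses a few percent of its lower
  tail). Tests that require clipping to be inactive shrink the SDs.
- **Rank-correlation targets are approximate.** They are imposed on the
  latent Gaussian; after marginal transform and clipping the empirical
  Spearman is within about ±0.05 of target at n = 10000 (a Gaussian
  copula maps Pearson ρ to Spearman ≈ (6/π)·asin(ρ/2), slightly below
  ρ).
- **Default outcome weights** are solved from the correlation system
  ``C a = rho`` so the noiseless latent outcome reproduces the
  configured correlations, then the magnitudes are permuted so the
  implied importance ordering matches the canonical ordering (physical
  activity > poverty > education > unemployment > race > insurance >
  food access > crime); the permutation swaps only nearly equal
  magnitudes, so correlations move little. The default noise SD makes
  the latent outcome unit-variance, i.e. the systematic share of
  outcome variance follows from the correlation targets themselves.
- **The crime marginal is internally inconsistent** in the source
  summary table (the full-sample and training-subset rows disagree
  wildly); the full-sample column is used as-is.
- Geoids are synthesized as the Shelby County, TN prefix ``47157`` plus
  a 6-digit sequence.

What the generator does **not** emulate: spatial autocorrelation between
neighboring tracts, non-Gaussian margins (real prevalence estimates are
skewed and heteroscedastic), measurement error in the published
estimates, and any nonlinearity in the outcome model. Passing tests on
this generator therefore demonstrate correctness of the pipeline's
mechanics and recoverability of a linear signal under realistic
collinearity — not that the fitted importances would be unbiased on real
data.

## Analytics pipeline

`upho.analytics` exposes a statsmodels-style pair: ``SdohSvr`` (model)
and ``SdohSvrResults`` (fit artifacts with ``summary()``). ``fit()``
runs, in order:

1. **Spearman screen.** Each candidate feature's Spearman rank
   correlation with the outcome (midranks for ties; p-value from the
   t approximation on n−2 df). Features with p > α are dropped
   (default α = 0.05, configurable — the screen threshold is a
   convention, not derived).
2. **VIF filter.** ``VIF_j = 1/(1−R²_j)`` from least squares of feature
   j on the remaining features plus intercept; exact collinearity is
   reported as +∞. Features with VIF > 10 are removed (single pass;
   default threshold 10).
3. **Split and standardize.** Seeded random 85/15 train/test split
   (train count = round-half-up of n·0.85, so 178 → 151/27).
   Features are centred and scaled by *training* mean and population SD
   and the same transform is applied to the test portion. The outcome
   is left in percent units so predictions and attributions stay
   interpretable.
4. **Grid-search CV.** Linear-kernel ε-SVR
   (minimize ½‖w‖² + C·Σ max(0, |y−w·x−b|−ε)) over a small default grid
   C ∈ {0.25, 0.5, 1, 2, 4}, ε ∈ {0.01, 0.1, 0.2, 0.5}, spanning
   under- to over-regularization on standardized features. Folds:
   shuffle indices with the seed, cut into contiguous blocks, remainder
   rows one per leading fold. The winner minimizes mean CV RMSE; ties
   break toward smaller C, then smaller ε.
5. **Final fit and evaluation.** RMSE and R² (about the sample mean)
   on both splits.
6. **Importance.** Raw importance is |standardized coefficient| —
   model-faithful for a linear kernel and exactly reproducible — min-max
   scaled to [0, 100]. If all magnitudes are equal the scaled scores
   are set to 0 with a warning. This is a deliberate, documented
   definition: black-box permutation or wrapper importances would not
   be more faithful for an affine model and are harder to verify.
7. **Attribution.** For a focus tract, closed-form interventional
   Shapley values of the linear model against the full table as
   background: ``phi_j = w'_j (x_j − mean(bg_j))`` with ``w'`` the
   weights mapped back to raw units. Efficiency
   (Σφ = prediction − baseline) holds to machine precision, and the
   closed form equals exhaustive coalition enumeration for any p
   (verified to 1e-9 for p = 8 in tests). The full-table background is
   a choice; a city- or county-restricted background would shift the
   baseline but not the pairwise comparisons.

Numerical notes: the SVR dual solver occasionally stalls near its
optimum at tight tolerances on strongly collinear designs, so fits run
at tol 1e-5 and escalate to 1e-4/1e-3 before a non-convergence error is
raised; the residual optimality gap is orders of magnitude below any
quantity interpreted downstream. Degenerate inputs (constant features,
zero-variance outcome, empty test split, fewer than two surviving
features) raise typed errors rather than propagating NaNs.

## Concept scheme, knowledge graph, reasoner

The graph vocabulary (`upho.semantics`) uses five namespaces standing in
for the source ontologies — DO (diseases), COPE (SDoH/obesity-prevention
causal concepts), GISO (geography), HIO (indicator metrics), ACESO
(risk-factor hierarchy) — plus UPHO for entities none of them define
(patients, populations, tracts). The scheme is a plain acyclic ``isA``
DAG containing exactly the concepts the pipeline uses; there is no OWL
parsing and no description logic, and ``is_subtype`` is
reflexive-transitive reachability. Tract metric values are *typed
literals* — a number tagged with the metric concept it instantiates — so
rules can match metrics by type.

Triples carry provenance (``asserted`` scheme/axiom knowledge, ``data``
tract evidence, ``ml`` model-derived edges, ``inferred``), an optional
weight, and for inferred triples a derivation (rule id + antecedent
triple ids). The graph has set semantics on (subject, predicate,
object), so re-running any enrichment is idempotent.

The reasoner (`upho.reasoner`) is negation-free forward chaining with
semi-naive evaluation, which guarantees a unique least fixpoint — the
inferred triple *set* is independent of rule order (a property the tests
exercise by permuting the rule list). When a triple is derivable several
ways, the first derivation under (round, rule order, triple insertion
order) is recorded and alternates discarded, keeping output stable. The
shipped rule file contains three antecedent-free domain axioms (lack of
physical activity leads to obesity; obesity prevalence is a health
indicator for obesity; obesity is a risk factor for diabetes) and three
bridging rules:

    RB1: ?p livesIn ?t & ?t has ?v^^?m & ?m isMetricOf ?rf => ?p isExposedTo ?rf
    RB2: ?p isExposedTo ?rf & ?rf leadsTo ?d => ?p atRiskOf ?d
    RB3: ?p atRiskOf ?d & ?d isRiskFactorOf ?d2 => ?p shouldBeScreenedFor ?d2

RB1 derives exposure from the mere presence of a metric in the tract;
numeric guards (e.g. ``?v >= 50``) are supported in the rule language
for users who want exposure only above a threshold, but default off
since the domain supplies no cutoff.

``build_graph`` (`upho.kg_builder`) lays down the scheme's isA edges,
one node per tract (typed census tract, with a one-per-tract
neighborhood node so the canonical metapath is traceable), a ``has``
edge per feature value (data provenance, weight = value, literal keyed
by (tract, metric) so equal values in different tracts do not collide),
metric→factor ``isMetricOf`` links, and the domain axioms.
``enrich_with_inference`` iterates forward chaining (plus optional
re-derivation hooks) to a stable state; ``enrich_with_ml`` adds
``isPredictorOf`` edges from the top-k most important features' metric
concepts to the outcome metric concept (default k = 5), weighted by
scaled importance / 100. Predictor edges sit at the concept level, not
per tract, matching the population-level meaning of the model.

## Pathways and explanations

`upho.pathways` enumerates walks whose predicate sequence matches a
registered metapath template:

- semantic route: livesIn → representsA → hasPhysicalCharacteristic →
  leadsTo;
- statistical route: livesIn → has → isPredictorOf →
  isHealthIndicatorFor.

Chaining is on node identity, with one convention: a typed-literal
object (a tract's metric value) chains to the metric concept it
instantiates, which is how a tract-level observation hands over to a
population-level predictor edge. A pathway's score is the product of
its edge weights with semantic edges counting 1 — the minimal way to
combine rule-based and model-based evidence into one number; no
probabilistic semantics is claimed for it. Results sort by score
descending, ties by lexicographic node sequence; evidence is labelled
``semantic``, ``statistical``, or ``both``. The default maximum pathway
length is 6 edges, enough for both templates.

Explanations render stored values only (no recomputation): metric nodes
compare the tract's literal against the reference-table average, both to
one decimal; ml edges cite the scaled importance; inferred edges replay
their recorded derivation (rule id and antecedent triple ids). "Risk
level" output is deliberately presented as tract-vs-reference
comparisons plus pathway scores, labelled as such — no composite risk
index is defined. Recommendations are one per inferred screening fact
plus one per traced pathway (framed on the pathway's risk factor),
deduplicated, in score order. Patient-level analysis is
neighborhood-proxy analysis by design: the individual inherits
tract-level exposures, which overstates certainty about any one person.

## Driver

`upho.cli` exposes the dashboard-style selections as JSON config / CLI
flags (outcome; analytics aim, of which only causal-pathway analysis is
implemented; patient/population level with location; census-tract
granularity; optional feature-subset filter) and writes the full bundle:
tracts.csv, analytics.json, graph.json (node-link), graph.graphml,
pathways.json, report.md, run.log. All randomness flows from two seeds
(generator, split/CV), and identical configuration reproduces
byte-identical JSON artifacts.

## Verification experiments and their sizes

The test suite and `scripts/acceptance.py` recompute, from scratch:
the scenario knowledge base's forward-chaining conclusions and their
derivation chains; the VIF screen on the published values (7 features
retained, max retained VIF 8.82); the 0–100 importance-scaling contract
on freshly fitted models; closed-form Shapley vs exhaustive coalition
enumeration (p = 8, all 256 coalitions, agreement to 1e-9) and
efficiency on every background row; Datalog properties (monotonicity,
idempotence, order independence, equality with a naive closure) on
random 50-triple graphs; and metapath enumeration vs brute-force path
search.

The ranking-recovery experiment deserves detail. It generates 100
replicate tables at the default n = 178 with a strictly ordered weight
profile (`recovery_weights()`) and outcome noise SD 0.5, runs the full
pipeline on each, and asks how often the scaled-importance ranking
equals the generating (standardized-space) ranking. The weight profile
was designed against an independent full-data OLS oracle: adjacent
standardized-magnitude gaps were widened until the generating ranking is
statistically identifiable at this sample size and correlation structure
(the oracle recovers it in ≥ 99% of replicates) — with narrower gaps the
experiment tests sampling noise, not the pipeline. Under these
conditions the pipeline recovers the full 8-feature ordering in
effectively all replicates with test R² above 0.99.

## Known limitations

- The importance definition is coefficient-based and linear-model
  specific; it is not comparable to permutation importances from
  nonlinear models.
- Pathway scores are heuristic products of edge confidences; they order
  pathways sensibly but have no calibrated probabilistic meaning.
- The reasoner is propositional-over-ground-facts Datalog: no negation,
  no retraction, no uncertainty, and subsumption is only the explicit
  isA DAG.
- The generator's single-factor dependence structure cannot represent
  features that correlate with each other more than their outcome
  correlations imply.
- All individual-level conclusions are neighborhood proxies; the
  package never sees person-level data.
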