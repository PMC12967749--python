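# Methods

## Experimental design model

An NDS deployment is a factorial set of enrichment treatments. The 2022
variant has 11 treatments plus control: N, P, Fe, Zn singles; N+P, N+Fe,
P+Fe pairs; N+P+Fe, N+Fe+Zn, P+Fe+Mo, P+Fe+Ni triples. The 2021 variant
supplies Zn as Zn+Co (the two metals substitute in carbonic anhydrase, so
Co is treated as a passenger riding in the Zn "slot") and lacks the N+Fe
arm, leaving 10 treatments plus control. Treatments are identified by
element set; labels are canonical ("Fe+N" parses to "N+Fe"). The replicate
target defaults to 5 cups per treatment, configurable; the value is an
inference from deployments of five loaded bars per stream.

A stream × response variable is analysable when the control and every
present treatment carry at least 2 replicates and at least 70% of the
design's cups were recovered. Four response variables are carried
independently: lab-extracted chlorophyll *a* and the three field-fluorometry
pigment groups (diatom, cyanobacteria, chlorophyte). No cross-taxon
reconciliation is attempted; chlorophyll *a* governs stream-level
presence/absence exports, with the first available fluorometry variable
standing in when chlorophyll *a* is missing.

## Effect sizes

Ratios are computed from arithmetic means of replicates, RR = ln(Ȳ_T/Ȳ_C),
not from means of per-replicate logs: the interaction contrast needs an
additive expectation on the arithmetic-mean scale, and the additive
expectation used is *response-above-control* additivity, Ȳ_A + Ȳ_B − Ȳ_C.
That expectation is the central interpretive choice of the package (the
standard reading of comparing a combination to the "additive" single
responses); the IRR denominators are the only place it enters, so swapping
in another expectation only requires replacing `interaction_rr_pair`.

Each design yields a contrast registry. Pairwise contrasts need both single
arms (2022: N×P, N×Fe, P×Fe; 2021 lacks N×Fe). A three-element treatment is
decomposed as (block of first two elements) × (remaining element): N+P+Fe →
(N+P)×Fe and N+Fe+Zn → (N+Fe)×Zn. When the added element has no single arm
(Mo, Ni), the contrast is the added-element form ln(Ȳ_ABX/Ȳ_AB) over the
base pair. When the block arm does not exist — N+Fe+Zn under the 2021
design — no additive expectation can be formed and the contrast is omitted;
Zn evidence in 2021 comes from its single (Zn+Co) arm. The registry
therefore has 7 interaction entries for 2022 and 5 for 2021.

Degenerate cases are carried as explicit markers, never silently dropped: a
zero treatment mean with positive control is a "collapse" (conceptually
RR = −∞, compared as −∞ against thresholds, classified as a negative
response); a non-positive additive expectation marks the contrast's IRR
"degenerate" and its interaction class not-applicable; a non-positive
control mean makes the whole stream × response variable unclassifiable with
an audit reason.

## Classification taxonomy

Thresholds: θ_single = 0.326 on RRs (a +38.5% biomass increase) and
θ_interaction = 0.385 on IRRs, both applied as strict inequalities
(RR = 0.326 exactly is *not* stimulation). For a contrast with axes A, B
and S_X := RR_X > θ_single:

* S_A ∧ S_B → independent co-limitation;
* exactly one stimulated and RR_combined − RR_responding > θ_single →
  serial limitation (primary = responding axis); the serial "additional
  response" cut-off reuses θ_single — no separate serial threshold is
  published, so this is a documented, configurable choice;
* exactly one stimulated, no extra combined response → single limitation;
* neither stimulated, RR_combined > θ_single → simultaneous co-limitation;
* neither stimulated and any of RR_A, RR_B, RR_combined < −θ_single →
  negative response; otherwise no response.

Interaction class: super-additive above θ_interaction, sub-additive below
−θ_interaction, else additive; not-applicable when the IRR is degenerate.

Element-level roll-up: an element is limited-or-co-limited when it appears
in a single-limitation label, in an independent/simultaneous co-limitation
label (a triple contrast classified as co-limitation contributes all three
elements, e.g. an N-P-Fe label), as the primary of a serial label, through
an added-element contrast (added RR > θ_single while the base combination
also responded), or when its own single-supply RR clears θ_single (this
last route is what carries Zn in the 2021 design, where Zn enters no
pairwise contrast). Serial *secondaries* are recorded separately and never
counted as co-limited. Negative status (single-arm RR < −θ_single) never
erases a limited status earned in another contrast; priority is
limited > serial-secondary > negative > none.

One property the taxonomy does **not** have: raising θ_single is not
monotone in the number of limited elements. A combined-only response is
reclassified from single limitation (one element) to simultaneous
co-limitation (two elements) when the responding single drops below a
raised threshold. The property suite asserts monotonicity for the
stimulation-driven categories only and documents this exclusion.

Cohort summaries report, per element, limited counts/percentages, single-
supply stimulation counts, and the median single-arm RR over streams where
the element is limited (elements with no single arm report no median);
plus co-limited combination counts and the interaction-class mix among
co-limitation labels. Ties are reported jointly, not broken.

## Synthetic generator

Scenarios are multiplicative: each limiting element has a factor f > 1 and
treatment means are μ_C · Π f over supplied limiting elements —
single (one factor), serial (secondary factor applies only when the primary
is also supplied), independent (product, times an interaction multiplier g
when all limiting elements are present), simultaneous (a joint factor that
applies only when the full set is supplied), negative (f < 1). Defaults
echo the magnitude contrast between macronutrients and metals:
f = e^0.89 ≈ 2.44 for N and P, f = e^0.60 ≈ 1.82 for metals, joint factor
e^0.89, negative factor e^−0.60, baseline control mean 3 µg/cm².

Replicate noise is mean-one lognormal: replicate = mean ×
exp(N(−σ²/2, σ²)), so arithmetic means are unbiased and the mean of
replicate logs converges to ln(mean) − σ²/2. Default σ = 0.2 with 5
replicates. Seeding is hierarchical (`default_rng([cohort_seed, index])`),
so extending a cohort never perturbs existing streams.

Note that the multiplicative model makes an independent co-limitation
scenario with g = 1 mildly super-additive on the IRR scale (the product of
factors exceeds the additive expectation); exactly-additive surfaces exist
only as directly constructed mean tables, which the tests use for the
IRR = 0 identity.

"Exact recovery" of a planted scenario means the element-status map matches
ground truth *and* the contrast carrying the planted elements reproduces
the planted category. Recovery is evaluated at the contrast level because
the taxonomy deliberately propagates co-limitation to supersets (a stream
truly independent in N and Fe also earns an N-P-Fe label through the
(N+P)×Fe contrast — a property of the published decision procedure, not an
error); the canonical recovery cohorts plant element sets for which ground
truth and taxonomy coincide. Recovery is exact at σ = 0 for every category
under both design variants, ≈95% at the study noise level (σ = 0.2, n = 5)
and degrades monotonically with σ.

Synthetic covariates are study-sized (27 water-quality, 52 landscape, 21
soil-metal-decile variables). Two named drivers carry signal: DRP
(lognormal, median 6 µg/L) and N_DEP (uniform 0.5–8 kg N/ha/yr);
presence/absence labels follow conjunctions of threshold clauses (the
default Fe rule is DRP > 5.6 ∧ N_DEP < 3.6 with 5% label flips), and all
other variables are independent of labels by construction. Missingness is
injected completely at random into the water-quality block only (imputation
in the source context concerned water-quality data), at rate 0.015.

What the generator does *not* emulate — and what passing tests therefore do
not show about field data: replicate noise is homoscedastic on the log
scale with no cup-position or deployment-time effects; covariates are
mutually independent apart from the planted rules, unlike real water
chemistry; missingness is never informative; and taxa responses are
generated from the same surface rather than diverging by phylum.

## Predictor stage

Predictive mean matching: for each incomplete variable, OLS on the fully
observed variables (intercept included, solved by least squares) predicts
the variable for all rows; a missing cell receives the *observed* value of
one of k = 5 donors with nearest predictions, chosen uniformly (seeded).
PMM therefore never fabricates values. Variables with fewer than k + 1
observed values fall back to the observed median with a warning, as does a
table with no complete regression basis.

Random forests: one presence/absence model per element, stratified 80/20
train/test split (stratification keeps the no-information rate meaningful
at n ≈ 40). The grid searches the three tuned parameters — variables per
split ∈ {√p, p/3, p/10}, maximum leaf nodes ∈ {4, 8, 16, unlimited}, trees
∈ {250, 500, 1000} — selecting by out-of-bag score on the training split.
The reported training misclassification rate is the out-of-bag error: the
in-sample error of a random forest is ~0 by construction, so a meaningful
training rate (one that can fail a < 30% gate) must be OOB-style.
Held-out accuracy is single-holdout, not k-fold. The performance gate is
well_performing ⇔ (OOB misclassification < 0.30 ∧ test accuracy > NIR),
where NIR is the majority-class share of the test set. Importance is mean
impurity decrease by default; permutation importance is available behind a
flag.

Partial dependence sweeps 50 even grid points between the 2.5th and 97.5th
percentiles of a feature (avoiding tail artefacts), overwriting the feature
for every stream and averaging predicted presence probabilities. Threshold
detection returns the midpoint of the grid interval with the maximum
absolute first difference plus its direction; a flat curve yields no
threshold. Planted thresholds are recovered within one grid step in both
directions on rule-labelled cohorts of 200 streams.

## Problem sizes and numerical choices

The test and acceptance workloads use cohorts of 100–500 streams per
condition, 120,000 sampled tuples for the decision-table equivalence check,
and 200-stream covariate cohorts for the predictor stage — sizes at which
every Monte-Carlo margin in the assertions is comfortably wide. CSV outputs
from the CLI fix floats at 6 significant digits for byte-stable runs;
biomass round-trip files use `%.17g` with round-trip float parsing, which
is bit-exact. All randomness flows from explicit integer seeds.

## Known limitations

* The additive-expectation form and the serial cut-off are interpretive
  choices (documented above); alternative forms change classifications
  near thresholds.
* The 2021 N+Fe+Zn arm is generated but unused by any contrast, mirroring
  the missing N+Fe arm rather than inventing a decomposition.
* No replicate-variance weighting, confidence intervals, or tests of
  frequency differences: classification is by point effect sizes against
  fixed thresholds.
* The predictor stage does not reproduce any particular R random-forest or
  imputation RNG stream; equivalence is at the level of reported rates and
  recovered thresholds.
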