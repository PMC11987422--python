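# Methods

## Problem setting

Administrative inpatient claims databases record essentially everything
billed — diagnoses, drugs, procedures, supplies — but rarely the clinical
severity measures (ejection fraction, vital signs, functional scores) that
confound treatment choice in observational comparative effectiveness
studies. `claimsvec` implements a proxy-adjustment strategy: compress the
very high-dimensional space of claims codes into dense *distributed
representations*, sum each patient's admission-day code vectors into one
fixed-length covariate, and feed that covariate into a propensity-score
model. Because first-day treatment decisions are driven by (unrecorded)
severity, the code-derived vector acts as a severity proxy and absorbs part
of the otherwise unmeasured confounding.

## Code embeddings

Codes are embedded with skip-gram and negative sampling (SGNS). A
*document* is the multiset of codes billed during one admission (an
admission-day grouping is available). Codes have no natural order, so token
order within each document is re-randomised every epoch and the sliding
window of radius `window` (default 8) simply pairs each code with random
co-occurring codes. For each observed pair `(w, c)` and `negative` noise
codes `n_i` drawn from the unigram^0.75 distribution, SGD ascends

    log σ(v_w · u_c) + Σ_i log σ(−v_w · u_{n_i})

with a learning rate decaying linearly from `alpha = 0.025` to
`min_alpha = 1e-4`. Defaults: `k = 200` (the dimensionality of the released
weight-table format this package emulates), `negative = 5`, `epochs = 5`,
`min_count = 5`, frequent-token subsampling threshold `t = 1e-3` (the
common word2vec code default; keep probability `sqrt(t/f) + t/f`).
Training is single-threaded sequential SGD (a numba kernel), so the weight
table is bit-reproducible given `(corpus, config, seed)`. Only the input
matrix is released; the context matrix stays in memory for objective
evaluation and is discarded on save.

Two numerical notes. First, negatives that collide with the positive
context are skipped, matching the reference SGNS implementations. Second,
input-vector cosine similarity in SGNS reflects *shared contexts*
(second-order co-occurrence): two tokens that only ever co-occur with each
other are driven toward anti-aligned input vectors, because each is the
other's most frequent negative. The trainer's alignment tests therefore
plant co-occurrence *clusters*, the regime the synthetic generator also
emulates and the regime in which embedding sums carry severity signal.

## Patient vectors

A patient's covariate vector is the plain sum (with multiplicity) of the
weight vectors of their day-1 codes; codes missing from the table
contribute nothing and are counted. No normalisation is applied — the
estimand is a sum, not an average — though `dedupe=True` and `mode="mean"`
exist for sensitivity analyses. Patients with no matched day-1 code get
the zero vector and a logged warning.

## Risk-adjustment models and matching

* Model 1: no adjustment (crude risk difference).
* Model 2: propensity-score matching on named measured confounders
  (in simulations, the complete/true model including latent severity).
* Model 3: matching on age, sex and the k embedding components, entered as
  k separate main-effect terms.
* Model 4: the union of Models 2 and 3.

Propensity scores come from an unpenalised maximum-likelihood logistic fit
(internally standardised for conditioning; coefficients reported on the raw
scale). Perfect separation — detected as AUC of the linear predictor
exactly 1 — triggers an L2 ridge refit (`C = 1`) with a logged warning, or
an error if the fallback is disabled.

Matching is greedy 1:1 nearest-neighbour without replacement: treated
units in seeded random order, each paired to the closest unmatched control
within a caliper of `0.01 × SD(PS)`. The caliper is interpreted on the
probability scale by default; a logit-scale mode is provided because the
"1% of the standardised deviation" convention is stated ambiguously in the
literature this design follows. Equidistant controls tie-break to the
lowest patient id, which makes the pairing deterministic.

Balance is assessed with the standardised mean difference
(`|Δmean| / sqrt((s_t² + s_c²)/2)`, `p(1−p)` variance for binaries) and
with the matched c-statistic: the AUC of a treatment model (Model 4's
covariate set by convention) refit *within* the matched cohort — 0.5 under
full balance. Effect estimates are treated-minus-control differences
(risk difference for binary outcomes, mean difference for length of stay)
with percentile-bootstrap 95% CIs; matched analyses resample pairs,
unmatched analyses resample patients within arms.

## Bias-injection simulation

The simulation validates that embedding-sum adjustment removes injected
confounding when the truth is null:

1. A Bernoulli(0.5) treatment indicator is drawn independently of
   everything, so the true risk difference is exactly 0.
2. A prognostic logistic model for the composite outcome (death or ADL
   dependency at discharge) is fit once on the full cohort using the
   Model-2 covariates, and patients are split into quartiles Q1–Q4 of
   predicted risk (ties to the lower bin).
3. Each replicate samples, without replacement, `n_control` controls
   equally across quartiles and `n_treated` treated units with
   scenario-specific quartile weights, running linearly from
   (0.4, 0.3, 0.2, 0.1) to (0.1, 0.2, 0.3, 0.4) across the scenario grid
   (largest-remainder apportionment keeps counts exact).
4. Models 1–4 are applied to each sampled cohort; medians, 2.5/97.5
   percentile bands, coverage of 0, SMD summaries and matched
   c-statistics are aggregated over replicates.

The random indicator is redrawn every replicate (the repeated process
includes the assignment step); fitting it once would let a single chance
treatment–outcome association propagate identically into all replicates
and bias even the true model's median. `n_treated` defaults to
`n_control = 10 000`; per-replicate CIs use a reduced bootstrap
(`n_boot = 200`) since only the point estimates' distribution across
replicates is summarised. Seeds for sampling, matching and bootstrap are
spawned per (scenario, replicate, model) from the master seed, so any
replicate is reproducible in isolation.

## Subsample-bootstrap comparison

For application-style analyses, `bootstrap_compare` draws a fraction
(default 20%) of the cohort without replacement per iteration, runs all
models end-to-end, and summarises per-iteration differences of estimates
and CI widths against Model 4 (mean plus 2.5/97.5 percentile interval of
the difference distribution). The 20% fraction follows the methods
convention of the design this emulates; the same source elsewhere
describes the subsample as 5% of the population, a conflict we surface
here rather than resolve. Iterations with zero matched pairs are flagged,
excluded and counted.

## Synthetic data-generating process

One latent severity `s ~ N(0,1)` per patient drives:

* **codes** — each admission emits ~Poisson(12) day-1 codes (minimum 2)
  and ~Poisson(3) later-day codes; a code's cluster is chosen with
  probability ∝ `exp(−(s − μ_j)²/(2·0.8²))` for 10 cluster centres evenly
  spaced on [−2, 2], then a token uniformly within the cluster (500-token
  vocabulary). Severity thus enters through co-occurrence structure, not
  marginal token frequency — the regime where embeddings, rather than
  high-dimensional indicator covariates, are the natural compression;
* **measured confounders** — age, coma-scale flag, admission ADL
  dependency, systolic blood pressure, CKD, all loaded on severity; sex is
  independent;
* **treatment** — early rehabilitation (start day ≤ 2) with
  `logit P(T=1) = −0.4 + γs`; `γ` is the confounding dial (`γ = 0` is
  randomised; the default study condition is `γ = 1`);
* **outcomes** — death, ADL dependency, 90-day readmission (logistic in
  s) and log-normal length of stay, all conditionally independent of
  treatment given severity, so the true effect is 0 by construction.
  Default coefficients give a ~27% composite rate and a strongly
  discriminative prognostic model (apparent c-statistic ≈ 0.83).

The truth record (severity, true model probabilities) supports oracle
checks: stratifying on true severity must remove the naive bias.

What the generator does **not** emulate: real fee-schedule code semantics
and frequency skew, hospital-level clustering, seasonal admission
patterns, code–outcome edges not mediated by severity, informative missing
data. Passing tests therefore demonstrate the method's internal validity
under a single-confounder mechanism with relational code signal, not its
performance on any real claims database.

## Problem sizes

Test and acceptance runs use desk-scale versions of the study conditions,
chosen as the smallest sizes at which the Monte-Carlo error is well below
the assertion margins: a 20 000-patient cohort (γ = 1), k = 200 embeddings
for the complete-model balance check, k = 50 embeddings for the
scenario-grid runs, a 5-point grid with 20 replicates at
`n_control = n_treated = 2 000`, and 200-draw per-replicate bootstraps.

## Known limitations

* Greedy (not optimal) matching; no IPW, full matching or HDPS-style
  covariate prioritisation.
* The embedding dimension is a free parameter; nothing here establishes
  that k = 200 is optimal (it is config everywhere).
* Percentile bootstrap CIs, not BCa; pair resampling treats the matched
  set as fixed and ignores matching uncertainty.
* The matched c-statistic refit inflates slightly above 0.5 in finite
  samples in proportion to covariate count over matched size (a ~0.05
  apparent-AUC overfit at 200 covariates per ~12 000 matched patients),
  which is why balance conclusions use orderings and bands rather than
  equality with 0.5.
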