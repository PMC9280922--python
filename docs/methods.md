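# Methods

## The model

`dbnpsy` analyses two-wave panels of binary mental-health indicators with a
discrete dynamic Bayesian network (DBN): a directed acyclic graph whose
nodes are wave-tagged items (`item@W1`, `item@W2`, plus an untagged static
twin/non-twin covariate) and whose arcs are conditional dependencies
pointing forward in time. Three structural constraints are imposed as a
blacklist during search: no arcs within wave 1, no arcs within wave 2, and
no arcs backward from wave 2. The permitted candidate space is therefore
exactly (wave-1 ∪ static) × wave-2, every candidate graph is acyclic by
construction, and arc direction is never ambiguous.

### Scoring

Structures are scored with the Bayesian information criterion in the
larger-is-better convention, using natural logarithms throughout:

    score(G) = Σ_nodes [ loglik(node | parents) − (d/2)·log N ],
    d = (r − 1)·q,   r = child states (2),   q = 2^|parents|.

The log-likelihood of a family is the maximized multinomial likelihood
Σ_jk n_jk log(n_jk / n_j) with 0·log 0 ≡ 0. Parent configurations never
observed contribute zero likelihood but still count toward q; this keeps
the penalty a deterministic function of the parent-set size. The score
decomposes over families, which the search exploits (per-family caching,
vectorized evaluation of all single-parent additions for one child).

### Search

Hill climbing starts from the empty graph (no prior structure is forced by
default) and repeatedly applies the best single-arc addition or deletion
whose gain exceeds a tolerance of 1e-10 (guarding against floating-point
ping-pong); arc reversal is never a legal move under the temporal
blacklist. It then runs 10 restart rounds, each applying 10 random arc
toggles (uniformly chosen candidate arc; added if absent, deleted if
present) to the incumbent best network before re-ascending; the best
structure seen is returned. Equal-gain moves break ties by lexicographic
(parent, child) order, making the search deterministic given its seed.
Because the constrained score decomposes over wave-2 families, an
exhaustive oracle (`exhaustive_best`) computes the exact global optimum by
per-child parent-set enumeration whenever the candidate space holds at
most 20 arcs; the heuristic is tested against it.

### Model averaging

Arc strength is the fraction of B nonparametric bootstrap resamples
(resample size m = n) whose learned network contains the arc. Since
direction is fixed by the constraints, no separate direction confidence
exists. The consensus network keeps arcs with strength ≥ 0.50 (inclusive),
following the a-priori threshold used in this literature; the data-driven
alternative is the significance threshold of Scutari & Nagarajan (2013):
treat the ideal strength vector as 0/1 and choose the cutoff minimizing
the L1 distance between the empirical strength CDF and the induced step
CDF. Candidate cutoffs are the observed strengths plus midpoints between
consecutive distinct values; among ties the largest candidate is returned
so the cutoff falls between the noise and signal clusters. Per-bootstrap
RNG streams are spawned from the master seed (`numpy` seed sequences), so
results are reproducible and independent of participant row order (rows
are canonicalized by participant id before resampling).

### Parameters and prediction

Conditional probability tables are Dirichlet posterior means with
imaginary sample size `iss` (default 1) spread uniformly over the table:
cell = (n_jk + iss/(r·q)) / (n_j + iss/q). Unseen parent configurations
fall back to uniform and every probability is strictly interior, so
constant training columns in a cross-validation fold never break
prediction. The posterior classification error of a wave-2 node is the 0-1
loss of predicting its posterior mode given the participant's wave-1
values, estimated by k-fold cross-validation (k = 10, 10 runs by default):
each run shuffles participants with a seeded permutation, splits them into
k folds (remainders spread one per fold), relearns the structure on each
training portion (avoiding information leakage; a fixed-structure mode is
available), and averages fold losses; the report carries the mean and
standard deviation over runs. Prediction ties break toward 0.

### Cohort rules

Items are binary. Substance use follows the ASSIST screening ladder:
tobacco and alcohol count as recent use only at daily (or almost daily)
frequency, cannabis already at weekly. Any day out of role (or in bed)
counts as impairment. Social support is stored in the risk direction
(1 = lacks a confidante). Subthreshold syndromes: depression-like (≥3 of
6 somatic or ≥2 of 6 anxious-depressive items), hypomanic-like (all 5
hypomanic items), psychotic-like (≥2 of 6 psychotic-like items). The
primary cohort keeps participants complete at both waves with no
full-threshold diagnostic-interview flag at wave 1; the progression cohort
additionally drops anyone with a wave-1 subthreshold syndrome. Missing
data are not imputed — incomplete participants are excluded with reason
codes in the eligibility roster. The packaged 30-item catalog uses
semantic placeholder identifiers because exact questionnaire wordings are
not part of the public record for this battery.

## The synthetic cohort generator

The generator is the test bed: wave-1 and static items are independent
Bernoulli draws, and each wave-2 item follows a logistic model in its
planted parents, probability = expit(intercept + Σ log-odds · parent).
The logistic parameterization gives controllable odds-ratio effect sizes
while inducing exact CPTs; intercepts are solved by root finding (Brent)
so each wave-2 node hits its target marginal given the parent
distribution (verified to within 0.02 at n = 10,000).

Scenarios:

* **persistence** — 11 within-item arcs (tobacco, lack of a confidante,
  impaired sleep quality, cannabis, impaired concentration, alcohol,
  pressured speech, increased activity, feeling elated, thoughts not your
  own, hypersomnia), log-odds log 8.
* **cross_lag** — 7 cross-item arcs (elation→self-esteem,
  anergia→somatic pain, concentration→stress, fatigue→days out of role,
  sleep quality→feeling overwhelmed, pressured speech→heard voices,
  activity→self-esteem), log-odds log 6.
* **persistence_cross_lag** — the union (18 arcs), used for structure-
  recovery benchmarks.
* **progression** — arcs from wave-1 symptoms into the three wave-2
  syndrome indicator nodes, generated directly as nodes to isolate the
  second-analysis inference path (an item-level route would convolve it
  with the syndrome derivation).
* **null** — no cross-wave dependence; see sizing below.

Default wave-1 prevalences for the item scenarios lie on a 0.45 → 0.05
gradient over the 29 dynamic items (an approximate symptom-frequency
gradient); the static twin indicator has prevalence 0.68. Effect sizes
(odds ratios 8 within-item, 6 cross-item) are strong enough for reliable
desk-scale recovery at n ≈ 600–2000; they are design choices, not
estimates of the real cohort's effects.

The **progression scenario** uses its own per-domain marginals (somatic
0.15, anxious-depressive 0.10, hypomanic 0.25, psychotic 0.05). With
independent wave-1 items, the 0.45–0.05 gradient would put the wave-1
any-syndrome rate at ~86%, destroying the progression cohort that the
second analysis is defined on; the chosen rates put it at ~19%
analytically (P(psych count ≥ 2) + P(soma count ≥ 3) ≈ 0.16, P(psychotic
count ≥ 2) ≈ 0.03), matching the roughly one-in-five rate typical of such
cohorts, so ~80% of simulated participants survive the progression
filter. Target wave-2 syndrome marginals are the progression rates
43/538, 61/538 and 13/538.

### Sizing the null calibration scenario

The null scenario exists to verify that bootstrap averaging at threshold
0.50 is calibrated: under independence the consensus should be empty. This
property constrains the scenario's size. Under independence, a candidate
arc's G-statistic is asymptotically χ²₁ and the arc enters a single
learned network only if G > log n (probability ≈ 0.009 per arc at
n = 1000). A full 30-node candidate space (870 arcs) therefore yields one
or two spurious consensus arcs in nearly every replicate — no
implementation can make a fixed-threshold consensus empty there — so the
null calibration scenario is a compact four-item subnetwork (16 candidate
arcs), which also keeps it inside the exhaustive oracle's 20-arc
enumeration cap so that null-scenario searches are verified exactly.

A calibration experiment (50 replicates per size, n = 1000, B = 200,
verified against the exhaustive oracle on every resample) measured
empty-consensus rates of 0.94, 0.90 and 0.94 for 2-, 3- and 4-item nulls:
statistically indistinguishable, i.e. the residual spurious rate does not
scale down with the candidate space. The mechanism is that once a
borderline spurious arc's sample G-statistic approaches log n, its
bootstrap selection frequency concentrates near 0.5, so a few percent of
replicates produce one arc just above the 0.50 cut in any nondegenerate
null. The per-replicate empty-consensus probability of this procedure at
n = 1000 is therefore ~0.93–0.97, not a quantity that can be pushed
arbitrarily close to 1 by design; calibration checks over a finite
replicate batch should expect occasional single-arc consensus sets.

### What the generator does not emulate

Wave-1 items are independent; real symptom items are strongly positively
correlated within wave, which is why real cohorts can combine high item
prevalences with moderate syndrome rates. No twin-pair correlation or
heritability structure is simulated (participants are exchangeable
singletons, as in the analysis the package reimplements), and no
missing-data mechanism is generated. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the stated
generative model, not robustness to within-wave dependence, relatedness,
or informative attrition.

## Numerical choices

* Natural logarithms everywhere; affects score magnitudes, never argmax.
* Improvement tolerance 1e-10; CPT rows sum to 1 within 1e-12.
* Tie-breaks: lexicographic (parent, child) for search moves and arc
  rankings; fewer arcs, then lexicographic, for the exhaustive oracle;
  state 0 for prediction ties; largest tied candidate for the automatic
  threshold.
* Odds ratios use the Haldane–Anscombe correction (0.5 to every cell) only
  when a cell is empty, with a flag; CIs are Woolf intervals
  exp(log OR ± 1.96·SE), SE = √(Σ 1/cell).
* The scoring code is written for general child cardinality r but only
  r = 2 is exercised; all study variables are binary.
* Seeds: every public entry point takes one seed; internal streams are
  spawned via `numpy.random.SeedSequence`, and derived seeds stay below
  2³¹.

## Problem sizes used in the shipped checks

Structure recovery runs the combined 18-arc scenario at n = 2000 with
B = 200 bootstraps over 5 master seeds (tests) or 3 (acceptance script);
null calibration uses 20 (tests) or 10 (script) replicates at n = 1000,
B = 200; oracle-equivalence sweeps use twenty 4 + 4-node datasets at
n = 500; cross-validation sanity uses n = 2000 with k = 10 and 10 runs.
These sizes give stable statistics at desk scale; B = 1000, as used for
real analyses, only sharpens the strength estimates.

## Known limitations

* The consensus/threshold machinery assumes the temporally constrained
  arc space; general-purpose Bayesian-network features (arc reversal,
  CPDAG equivalence classes, hybrid nodes, missing-data likelihoods,
  alternative scores beyond BIC) are out of scope.
* The automatic threshold is reported for comparison; on weak-signal
  strength vectors it can sit below meaningful confidence levels, which
  is why exploratory top-k tables are flagged rather than filtered.
* With B bootstraps, strengths are multiples of 1/B; very small B makes
  the automatic threshold coarse.
* Eligibility requires complete data after binarization; the package does
  not adjudicate whether completeness should be assessed on raw scales.
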