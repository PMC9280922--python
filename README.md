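# dbnpsy

Dynamic Bayesian network analysis of two-wave binary psychiatric cohort
data: which self-rated symptoms, functioning problems, substance-use habits
and social-support deficits at one assessment wave predict themselves
(persistence), other items (cross-lag), or progression to a subthreshold
syndrome at the next wave, roughly five years later.

The package is aimed at researchers working with longitudinal
psychopathology panels (for example twin-registry follow-up cohorts of
emerging adults) who want a reproducible, fully seeded implementation of
the temporal-network workflow: item binarization and eligibility filtering,
temporally constrained structure learning, bootstrap model averaging, and
cross-validated predictive evaluation — plus a synthetic cohort generator
with planted ground truth so every stage can be validated end to end
without access to restricted cohort data.

## The model

Nodes are wave-tagged binary items (`item@W1`, `item@W2`, plus a static
twin/non-twin covariate). A blacklist forbids arcs within wave 1, within
wave 2, and backward in time, so the candidate space is exactly
(W1 ∪ static) → W2 and every candidate graph is acyclic. Structures are
learned by hill climbing with 10 random restarts and 10 perturbing
operations under the BIC score (natural logs, larger is better),

    score(G) = Σ_v [ loglik(v | pa(v)) − (d_v / 2)·log N ],   d_v = 2^|pa(v)|,

and summarized by nonparametric bootstrap model averaging: the strength of
an arc is the fraction of B resampled cohorts whose learned network
contains it, and the consensus network keeps arcs with strength ≥ 0.50
(the data-driven L1 "significance threshold" on the strength CDF is
reported alongside). Conditional probability tables are Dirichlet
posterior means (imaginary sample size 1), and each wave-2 node's
posterior classification error — the 0-1 loss of predicting its posterior
mode from a participant's wave-1 values — is estimated by 10×10-fold
cross-validation. Subthreshold syndromes follow item-count rules:
depression-like (≥3 of 6 somatic or ≥2 of 6 anxious-depressive items),
hypomanic-like (all 5 hypomanic items), psychotic-like (≥2 of 6
psychotic-like items). See `docs/methods.md` for assumptions, parameter
defaults, and numerical conventions.

## Worked example

Simulate a cohort of 2,000 participants from the persistence scenario
(eleven items whose wave-1 endorsement raises the odds of re-endorsement
at wave 2 by a factor of 8), estimate arc strengths from 200 bootstraps,
and score recovery of the planted structure:

```python
import dbnpsy as d

gt = d.build_scenario("persistence")
panel_w1, panel_w2 = d.sample_cohort(gt, n=2000, seed=7)
joint = d.join_waves(panel_w1, panel_w2)
constraints = d.temporal_constraints_for(list(joint.columns))

table = d.bootstrap_strengths(joint, constraints, B=200, master_seed=7)
consensus = d.averaged_network(table, threshold=0.50)
print("automatic threshold:", round(d.automatic_threshold(table), 3))
print(d.classify_arcs(consensus).head(6).to_string(index=False))
rep = d.recovery_metrics(gt.true_arcs, consensus.arc_set)
print("recall", rep.recall, "precision", round(rep.precision, 3), "shd", rep.shd)
```

which prints:

```
automatic threshold: 0.693
                   parent                     child  strength       class
               alcohol@W1                alcohol@W2       1.0 within_item
              cannabis@W1               cannabis@W2       1.0 within_item
        feeling_elated@W1         feeling_elated@W2       1.0 within_item
           hypersomnia@W1            hypersomnia@W2       1.0 within_item
impaired_concentration@W1 impaired_concentration@W2       1.0 within_item
impaired_sleep_quality@W1 impaired_sleep_quality@W2       1.0 within_item
recall 1.0 precision 0.917 shd 1
```

All 11 planted persistence arcs are recovered (recall 1.0), each labeled
`within_item` with its bootstrap strength; one borderline spurious arc
slips past the 0.50 cut (precision 0.917, structural Hamming distance 1),
and the automatic threshold (0.693) sits above the noise floor.

The same workflow is available from the shell:

```sh
dbnpsy simulate --scenario persistence --n 2000 --seed 7 --out-prefix cohort
dbnpsy average  --input cohort.csv --b 200 --seed 7 --out-dir results/
dbnpsy cv       --input cohort.csv --k 10 --runs 10 --seed 7
dbnpsy run      --config config.yaml     # full pipeline, writes report.json
```

`dbnpsy run` drives the two end-to-end analyses (`primary_dbn` over all
item nodes; `progression_dbn` into the three wave-2 syndrome indicator
nodes, which always reports the top-5 most certain arcs flagged against
the automatic threshold, even when nothing clears 0.50).

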