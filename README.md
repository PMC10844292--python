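# flarekit

Paired longitudinal single-cell analysis of rheumatoid-arthritis **flare
versus drug-free remission** after DMARD withdrawal.

When patients in deep remission stop their disease-modifying drugs, some
flare within weeks and some stay well. Given paired blood samples (baseline
on drug, follow-up at flare onset or month 6 of remission), cluster labels
for every cell, an expression matrix, and V(D)J chain records, this package
answers three questions the way the originating cohort study (BioRRA)
framed them:

1. **Which cell populations move?** Per-cluster differential abundance
   across four group/visit contrasts, in two modes: an overdispersed
   logistic-binomial mixed model with a per-patient random intercept
   (pairing) and an observation-level random intercept (overdispersion),
   Laplace-fitted and Wald-tested — or the Wilcoxon rank-sum test on
   per-sample percentages. BH correction within each contrast, and a
   selection rule that calls a cluster *flare-associated* iff it changes
   significantly at flare onset in flare patients while staying flat in
   remission patients.
2. **Which markers distinguish the groups within a population?**
   Per-cluster rank-sum tests on single-cell expression with Bonferroni
   correction within (cluster, contrast) and a ±1.5 fold-change gate.
3. **Do individual clones expand?** Clonotypes are cells sharing both
   paired CDR3 nucleotide junctions within one patient (≥2 cells); on top
   of that partition: clonal fractions, Shannon-entropy diversity with
   Hutcheson t comparisons, and two-sided Fisher exact tests of per-clone
   abundance shifts between visits, BH-corrected within patient.

A ground-truth-bearing synthetic-study generator emulates the full paired
two-arm design (Dirichlet–multinomial compositions shared across a
patient's visits, negative-binomial/log-normal markers, zeta-law clone
sizes), so every statistical layer is testable end to end without any data
download. `docs/methods.md` has the models and their assumptions.

## Worked example

```python
from flarekit.config import SimConfig, AbundanceEffect
from flarekit.simulate import simulate_counts
from flarekit.abundance import test_abundance_glmm, call_flare_associated

cfg = SimConfig(  # 20 flare + 16 remission patients, 31 clusters
    planted_abundance_effects=[AbundanceEffect("GDT_3", "flare", 0.8)],
    seed=1,
)
meta, counts = simulate_counts(cfg)
flare = test_abundance_glmm(counts, meta, "FlareV_vs_FlareB")
rem = test_abundance_glmm(counts, meta, "RemV_vs_RemB")
print(flare.loc[flare.cluster_id == "GDT_3",
                ["effect", "p_adj", "median_pct_1", "median_pct_2"]])
calls = call_flare_associated(flare, rem, "increase")
print(sorted(calls.loc[calls.associated, "cluster_id"]))
```

prints (seed 1):

```
      effect         p_adj  median_pct_1  median_pct_2
27  0.804475  1.049886e-50      2.632888      1.259001
['GDT_3']
```

The planted +0.8 log-odds follow-up shift on the γδ T-cell cluster is
estimated at 0.80, survives BH, roughly doubles the median percentage, and
is the only cluster passing the flare-association rule.

The numbered drivers under `analysis/` run the full narrative on a
simulated cohort — `01_simulate_study.py` (study + ground truth),
`02_cluster_abundance.py` (both engines + flare calls),
`03_marker_expression.py`, `04_repertoire.py`,
`05_published_numbers.py`, `06_calibration.py` — writing their tables
under `results/`. The same pipeline is scriptable via the `flarekit`
CLI (`simulate`, `abundance`, `express`, `repertoire`, `all`).

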