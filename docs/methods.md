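# Methods

## The analysis problem

Patients with rheumatoid arthritis in deep remission can attempt withdrawal
of their disease-modifying drugs (DMARDs); some then flare within months
while others remain in drug-free remission (DFR). The analysis this package
implements asks which circulating immune-cell populations, and which T/B
cell clones, separate those outcomes in a paired longitudinal design: every
patient contributes a baseline sample (on drug, in remission) and one
follow-up sample (at flare onset, or at month 6 for DFR patients). Four
group/visit contrasts organise everything:

| name | arm 1 | arm 2 | paired |
|---|---|---|---|
| FlareV_vs_FlareB | flare patients, flare onset | flare patients, baseline | yes |
| RemV_vs_RemB | DFR patients, month 6 | DFR patients, baseline | yes |
| FlareB_vs_RemB | flare baseline | DFR baseline | no |
| FlareV_vs_RemV | flare onset | DFR month 6 | no |

The pipeline consumes cluster labels (it never clusters), an expression
matrix, and AIRR-schema chain records, and produces per-contrast abundance
tables, per-cluster differential-marker tables, and repertoire statistics.

## Differential cluster abundance

### Mixed-model engine

For cluster $k$ with $y_i$ of $m_i$ cells in sample $i$:

$$y_i \sim \mathrm{Bin}(m_i, p_i), \qquad
\mathrm{logit}\, p_i = \beta_0 + \beta_1 x_i + u_{pat(i)} + e_i$$

with $x_i$ the arm-1 indicator, $u \sim N(0, \sigma_u^2)$ a patient random
intercept (sample pairing) and $e \sim N(0, \sigma_e^2)$ an
observation-level random intercept (extra-binomial overdispersion). The two
random terms collapse to one per-observation effect whose prior covariance
is block-diagonal with at most 2×2 patient blocks, so the Laplace
approximation is evaluated exactly in O(n): for fixed variances, the joint
mode over (random effects, β) is found by damped Newton with a 2×2 Schur
complement for β (penalised IRLS, as in lme4), and the profiled marginal
likelihood is maximised over $(\log\sigma_u^2, \log\sigma_e^2)$ by
Nelder–Mead from three deterministic starts. On a reference paired dataset
the fixed effect and its standard error agree with lme4's `glmer` (binomial
family, same random-effects structure) to four significant figures.

Inference is a two-sided Wald z test on $\beta_1$, conditional on the
estimated variances; p-values are Benjamini–Hochberg adjusted across
clusters within each contrast. Under the null design (both visits share a
patient's latent composition; 20+16 patients; 31 clusters) the simulated
type-I error at 0.05 is ≈0.04 — mildly conservative, never inflated. The
conservatism is a boundary effect: the generator puts no visit-level noise
beyond counting under the null, so $\hat\sigma_e^2$ piles up at zero and
inflates the standard error in half the fits. A likelihood-ratio variant
was measured at ≈0.034 and not adopted.

Failure handling: empty or saturated clusters return effect 0, p = 1; if
the Laplace fit cannot produce a usable curvature the cluster falls back to
a beta-binomial fixed-effects fit and is flagged in the output, never
aborting the run.

### Rank-based engine

The scRNAseq-mode test is the two-sided Wilcoxon rank-sum test on
per-sample percentage abundances, with BH adjustment across clusters within
each contrast. The rank-sum (not signed-rank) form is applied to the paired
visit contrasts as well, reproducing the procedure as stated; this discards
the pairing and costs power, which is visible in the analysis drivers
(the rank engine detects none of the rare planted subsets that the mixed
model finds at n = 20+16). The exact null distribution is used when both
arms have ≤10 samples and the data are tie-free; otherwise the normal
approximation with mid-ranks and tie correction.

### Flare-association rule

A cluster is *flare-associated (increase)* iff its BH-adjusted p < 0.05
with a positive effect in FlareV_vs_FlareB **and** its adjusted p ≥ 0.05 in
RemV_vs_RemB; *decrease* analogously. Applied to the published per-contrast
summaries of the BioRRA cohort this yields exactly {CD4_1, BC_1, GDT_3}
increased and {DC_2} decreased. Clusters absent from a published contrast
table are coded p_adj = 1, since only significant rows were published.

## Differential marker expression

Within one cluster and contrast, each feature is compared between the two
arms' cells (pooled across samples) by the rank-sum test. Features with
nonzero expression in <5% of the cluster's cells in both arms are excluded
before testing and do not inflate the Bonferroni m. Significance is the
conjunction

significant ⇔ Bonferroni-adjusted p < 0.05 **and** (FC > 1.5 or FC < 1/1.5),

with FC = (mean₁ + 0.1)/(mean₂ + 0.1). The additive pseudocount makes the
all-zero feature well-defined (FC = 1, p = 1) and the definition satisfies
FC(a,b)·FC(b,a) = 1. Cell-level pooling is a deliberate choice (per-sample
means are one flag away): it matches volcano-plot p-value magnitudes but is
pseudoreplicated — p-values overstate evidence when patients differ
systematically, a known limitation. Clusters with fewer than 100 cells in
total are excluded from all downstream analysis (strict threshold: exactly
100 is kept); arms with fewer than 10 cells of a cluster are not tested.

## Clonal repertoire

**Clonotypes.** A cell's identity key is the locus-ordered concatenation of
its two productive CDR3 nucleotide junctions (TRA|TRB for T compartments,
IGH|light for B), joined by a separator outside the nucleotide alphabet so
keys cannot collide by concatenation. Keys are grouped within (patient,
compartment), pooling both visits; groups of ≥2 cells are clonotypes.
Multiple productive chains at one locus — and the IGK/IGL ambiguity — are
resolved by most supporting reads, ties by lexicographically smallest
junction, and always counted in the run log. Cells without a complete
productive pair are excluded from repertoire statistics and logged.

**Diversity.** Shannon entropy in nats over all distinct keys of one
(patient, visit, compartment) repertoire, singletons included, with
Hutcheson's variance
$\mathrm{var}\,H = [\sum p_i \ln^2 p_i - (\sum p_i \ln p_i)^2]/N + (S-1)/(2N^2)$.
Baseline and follow-up are compared by Hutcheson's t with Welch-type
degrees of freedom; BH across patients within a compartment. The test's
null is multinomial resampling of a *fixed* community: on simulated
same-community pairs it rejects at ≈0.05, whereas pairs drawn from freshly
re-drawn clone pools reject far above nominal because the latent entropy
itself varies — a caveat for interpreting longitudinal entropy changes as
biology rather than community turnover.

**Per-clone shifts.** Each clone's visit-1 versus visit-2 abundance is a
2×2 table [[a, n1−a], [b, n2−b]] tested by the two-sided Fisher exact test
(probability-mass two-siding), BH-adjusted within patient (whole-compartment
scope) or within (patient, cluster) (subset scope). Direction is expansion
iff b/n2 > a/n1. The implementation is verified against full hypergeometric
enumeration on all tables with totals ≤ 24 and random tables with totals
≤ 200.

**Clonal fraction** is 100 × clonal cells / complete-pair cells, one
decimal. The published compartment counts reproduce 11.3% (CD4), 34.7%
(CD8) and 4.0% (B).

## The synthetic-study generator

The generator is the package's test bed and emulates the paired two-arm
design end to end:

- **Composition.** Per patient one composition is drawn from
  Dirichlet(α) and shared by both visits — this single draw produces both
  the pairing and the between-patient overdispersion. Defaults: 20 flare +
  16 DFR patients; 31 clusters with mean abundances ∝ k^(−0.7) (≈8% down
  to ≈1%) and total concentration 50 (realistic patient-to-patient
  compositional spread); totals per sample gamma–Poisson with mean 3000,
  shape 8. Planted composition effects multiply a cluster's relative
  weight by exp(log-odds) at the follow-up visit of one arm, then
  renormalise; under the null there is deliberately no visit-level noise
  beyond multinomial counting.
- **Markers.** 320 transcripts (negative binomial, cluster-specific means,
  dispersion 2) and 34 surface proteins (log-normal around cluster means,
  σ = 0.5), matching the immune-panel scale of the sequencing assay.
  Planted differential markers multiply the targeted (cluster, arm) mean
  by 2^log2FC.
- **Repertoire.** Per (patient, compartment), clone weights follow a zeta
  law (exponent 2.5, truncated at the cell count) carrying a clonal
  fraction of 11.3% (CD4), 34.7% (CD8), 4.0% (B) — the published
  compartment fractions. Junctions are stop-free random codon strings of
  30–60 nt, unique within patient; every T cell carries exactly one
  productive TRA and TRB, B cells IGH plus one light chain. A planted
  expansion multiplies one clone's follow-up weight, adding clonal mass
  rather than displacing sibling clones.

What the generator does **not** emulate: V/J gene usage, somatic
hypermutation, doublets, batch effects, cluster-specific marker biology, or
any dependence of repertoire structure on the composition effects. Passing
tests therefore certify the statistical machinery under the stated
sampling laws, not robustness to real-data artefacts.

## Validation studies

`flarekit.validation` re-runs the calibration and recovery experiments from
scratch (no stored fixtures): mixed-model type-I error (500 replicates of
the 36-patient null design; the binomial reference CI uses the replicate
count as n because clusters within a replicate share one composition
draw), power/FDR against +0.7 log-odds shifts planted on 3 of 30 clusters
(200 replicates; discovery is direction-aware — BH-significant *and*
positive — because compositional closure makes the unplanted clusters truly
decrease), Hutcheson calibration (1000 same-community pairs of 1000
cells), and recovery of an 8-fold clonal expansion in a ~3000-cell
compartment (200 replicates, including exact clonotype-set recovery).
Problem sizes are the cohort's own; replicate counts were chosen so the
full suite runs comfortably on one CPU.

## Numerical and policy choices

- α = 0.05 on adjusted p-values defines "significant" throughout.
- BH is NaN-aware: NaN p-values (failed fits) propagate and do not count
  toward m.
- All TSV outputs carry a header comment with tool version, seed and a
  config hash; floats print at 6 significant digits; identical
  (config, seed) reruns are byte-identical.
- Random streams are per-stage children of the study seed, so each
  generator stage is independently reproducible.
- Entropy uses natural log; the base cancels in the Hutcheson statistic.

## Known limitations

- The rank-sum form on paired contrasts ignores pairing (kept for fidelity
  to the stated procedure); the mixed model is the powered engine.
- Cell-level DE is pseudoreplicated (see above).
- The mixed-model Wald test is mildly conservative under boundary
  overdispersion; reported p-values near 0.05 are slightly too large.
- Compositional closure means planted (or real) increases in some clusters
  necessarily depress the rest; abundance results are statements about
  relative, not absolute, cell counts.
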