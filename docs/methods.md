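# Methods

This note documents the statistical models implemented in `bftx`, the
synthetic-data generator that the tests exercise them on, and the
numerical and design choices made where the design was genuinely open.

## Clinical-stage models

All clinical analyses reduce to ordinary least squares with listwise
deletion (the used n is reported per model) and two-sided t tests; the
t-tail kernel `t_tail_p` is the single source of every p-value, so a
reported (statistic, df, p) triple is internally consistent by
construction.

* **Case-control microstructure**: metric ~ diagnosis + age + sex + CAST +
  smoking, per region (Ch1-3, left NBM, right NBM, in that fixed order),
  with an optional intracranial-volume covariate as a sensitivity
  analysis. Levene's test (Brown–Forsythe median centring by default,
  mean centring available) accompanies each comparison.
* **Structure–MRS coupling**: Pearson correlation between dACC choline
  and each region's metric within one diagnostic group, plus a
  covariate-adjusted variant implemented as the t test of the region
  coefficient in choline ~ region + age + sex + CAST. "Adjusted
  correlation" is thus a coefficient test, which is what fluctuating
  published degrees of freedom imply.
* **Decoupling**: the diagnosis-by-metric interaction in
  choline ~ metric + diagnosis + metric:diagnosis + age + sex. Smoking
  and cannabis are excluded from the interaction model by design — the
  control group contains essentially no smokers and the groups differ
  strongly in cannabis use — and the output records that reason string.
* **Multiple testing**: Bonferroni families are explicit objects: 3 tests
  for region families (threshold 0.05/3 ≈ 0.017), 8 for clinical
  correlations (6.25·10⁻³), 12 for cognitive correlations (4.17·10⁻³).

Two-sidedness everywhere: published p-values are consistent with
two-sided tests, and no analysis pre-registers a direction at the kernel
level.

## Structural covariance

For a BF seed region, per-subject seed qT1 is correlated with every
vertex across the pooled HC+FEP sample (a group-stratified mode exists
but is off by default; pooling matches how such maps are usually built
and maximises n). FDR (BH) is computed **within each structure** —
cortex-L, cortex-R, hippocampus, amygdala, striatum, thalamus, globus
pallidum — because discovery families are anatomically scoped; the test
suite asserts per-structure q equals BH applied to that structure alone.
Vertices missing in > 20% of subjects (configurable) or constant across
subjects are excluded and counted. No spatial smoothing is applied to r
maps, and covariates are not regressed out by default (a residualise
mode exists); both follow the principle of making the raw map the
default object.

## Expression preprocessing

* **Probe collapsing**: among QC-passing probes, one probe per gene by
  highest probe-to-RNA-seq correlation; ties break deterministically by
  probe id; genes with no passing probe are dropped and logged.
* **Sample QC** is declarative: a label allow-list, per-label bounding
  spheres (the BF labels use 15 mm spheres around the nominal nucleus
  centres), and an explicit exclusion list. Unknown exclusion ids warn
  rather than fail.
* **Sample-to-vertex matching**: nearest vertex by Euclidean distance
  (k-d tree, verified against an all-pairs oracle), left cortex only by
  default since only a minority of donors sample the right hemisphere.
  Samples farther than 10 mm are removed **before** vertex deduplication
  (the order is a flag; both orders are implemented); where several
  samples share a vertex the closest is retained. Exact distance ties
  break by lowest vertex id, then lowest sample id, so matching is a
  deterministic one-to-one map. Raising the cutoff never removes a
  previously retained sample (tested).

## Region-specific expression and moderated t

Per gene, expression is regressed on donor indicator variables (fixed
effects — the donors are the blocking structure, and a fixed-effect
block matches the reference implementation's behaviour for this design)
plus an indicator of the target region versus all other sampled regions
pooled (a pairwise-contrast mode exists). Samples are restricted to
donors that sampled both BF regions. Because the design is shared by all
genes, the scan is a single matrix solve.

Empirical-Bayes moderation fits a scaled-F model to the ensemble of
residual variances by the method of moments on log variances: with
z_g = log s²_g and e_g = z_g − ψ(d_g/2) + log(d_g/2), the excess of
Var(e) over the expected sampling variance mean ψ′(d_g/2) identifies d₀
through the inverse trigamma, and the mean identifies s₀². When the
observed variance does not exceed the sampling variance, d₀ = ∞ and s₀²
is the pooled (arithmetic) mean of the variances — the natural estimator
in that regime, and the one the reference R implementation uses. The
implementation is cross-checked against that reference (via Rscript) to
1e-6 on a shared fixture. Moderated t uses the posterior variance
(d₀s₀² + d_g s²_g)/(d₀+d_g) at d_g + d₀ degrees of freedom (continuous t
for fractional df; normal tail at d₀ = ∞). Genes with numerically zero
residual variance are flagged degenerate, excluded from hyperparameter
estimation and reported NA. Ranking uses −log₁₀(p)·sign(t); FDR-passing
lists are emitted at q < 0.10, 0.05, 0.01. Each BF contrast refits its
own hyperparameters (the alternative — one shared fit — would couple the
two contrasts through their variance ensembles).

## Imaging-transcriptomics mixed model

Per gene, vertex-level covariance r at the matched vertices is modelled
as r = α + β·expression + u_donor + ε with u ~ N(0, σ²_u),
ε ~ N(0, σ²_e), fit by REML profiling the variance ratio λ = σ²_u/σ²_e
in one dimension (block-diagonal algebra; bounded scalar minimisation
with an explicit λ = 0 boundary comparison). The slope is tested by a
Wald t with df = n − 2; a likelihood-ratio option (ML, χ²₁) exists.
Singular fits (λ at the zero boundary) fall back to OLS and are flagged
but kept in the ranking — dropping them would bias the deciles, and for
null genes a zero donor variance is the expected outcome because the
response carries no donor structure of its own. The fit is verified
against a grid-search oracle over λ (step 10⁻³) and against an
independent mixed-model implementation. Expression is used as-is by
default; a within-donor z-scoring flag exists and is covered by a test.
Genes are ranked by t; the top and bottom deciles (⌊0.10·n⌋ each,
boundary ties broken by gene id) feed cell-type enrichment.

## Enrichment

Disease-set overlap uses the hypergeometric upper tail against a
configurable universe — by default all genes surviving probe selection,
since any external tool's internal background is not recoverable — with
BH FDR across sets and deterministic tie-breaks. Exact agreement with
combinatorial enumeration is asserted for all small universes.

The pSI (specificity index probability) of gene g for cell type c is a
permutation-calibrated upper-tail probability of the margin
x_gc − max_{c′≠c} x_gc′, with the null built by shuffling each gene's
row and pooling across genes and permutations (cell types are
exchangeable under the null; 200 permutations by default). Constant rows
get pSI = 1. Marker sets at thresholds 0.05/0.01/0.001/10⁻⁴ are nested
by construction. One consequence of the pooled null: planted markers
contaminate it, flooring their own pSI near the marker fraction, so at
small gene counts the strictest thresholds can have empty marker sets —
reported as NA cells, not errors. Cell-type enrichment applies the
hypergeometric test per (cell type × threshold) with FDR taken jointly
across the grid (per-threshold FDR available).

## Synthetic-data generator

The generator's defaults are the study conditions, chosen once:

* **Cohort**: 56 FEP / 29 HC; age ≈ 22 ± 4 years; predominantly male;
  smoking 30% in patients vs none in controls; CAST ~ Poisson(1.3) vs
  Poisson(0.3), calibrated so the expected group-difference t ≈ 5.6
  matches the published demographic contrast; ICV ≈ 1.5·10⁶ mm³ with a
  sex offset.
* **Microstructure**: per region, metrics share a latent demyelination
  factor (ρ = 0.5) so qT1/AxD/RD co-perturb; standardized case-control
  effects 0.62 (qT1), 0.65 (AxD), 0.50 (RD) in Ch1-3 — sized so the
  expected unadjusted t matches the published effects — and 0 in NBM.
  Physical scales: qT1 1650 ± 60 ms, AxD 1.05 ± 0.06, RD
  0.70 ± 0.05 (10⁻³ mm²/s).
* **MRS**: choline 1.60 ± 0.25 with correlation −0.5 to left-NBM qT1 in
  controls and 0 in patients; CRLB ≈ 1.88 ± 0.52%. YMRS couples to
  left-NBM qT1 (r = 0.45) and PANSS-negative to left-NBM AxD (r = 0.36)
  within patients. Trail-making is missing for 18 patients / 4 controls
  and DSST for 1 patient, mirroring available-case sizes.
* **Surfaces**: spherical-shell point clouds (2000 vertices/hemisphere
  by default; 100 per subcortical structure) in a shared mm frame; a
  smooth projection field (positive frontal lobe, weaker negative
  occipital lobe, Gaussian bumps of 30 mm scale, normalised to max 1);
  per-vertex qT1 = 2000 ms + subject offset (sd 8 ms) + 12 ms ×
  field × subject BF latent + spatially correlated noise (Gaussian
  kernel, 20 mm bandwidth, sd 10 ms), giving peak seed-vertex
  correlations ≈ 0.6.
* **Expression**: 6 donors (donor intercept sd 0.5 log₂ units), 60
  left-cortical samples per donor, right-hemisphere samples from only
  the last 2 donors, and BF samples from 4 donors (9 NBM, 9 Ch1-3 of
  which one is planted mislabelled/misplaced, leaving 8 after QC); 2000
  genes by default (a speed knob, not a claim about transcriptome size);
  30 BF-enriched genes at +1 log₂ in BF samples; 30 field-coupled genes
  whose cortical expression tracks the projection field; ~30% of genes
  get a weaker second probe and 10% of probes fail QC; one left-cortical
  sample is displaced > 10 mm from every vertex (the matching QC case).
* **Cell profiles and disease sets**: five cell types; the planted BF
  genes are cholinergic-neuron markers and half the field-coupled genes
  are oligodendrocyte markers; a schizophrenia-like set shares 20 genes
  with the planted BF set, plus control sets with no overlap.

What the generator does **not** emulate: MRI physics and real mesh
topology, microarray normalisation pipelines (expression is log-normal
with additive donor intercepts), spatial autocorrelation of expression
beyond the planted field, hemispheric asymmetries, and realistic
linkage between gene sets. Passing recovery tests therefore show that
the statistical machinery detects the planted structure at realistic
sizes and noise — not that the pipeline is robust to every artefact of
real acquisition.

## Power and what "recovery" means

With the planted covariate-group correlations (cannabis, smoking), the
covariate-adjusted case-control model has ~0.5–0.6 power for the 0.62-SD
Ch1-3 effect at n = 56/29 — variance inflation from group-correlated
covariates is a real feature of such designs. Parameter recovery for the
group effect is therefore defined as sign recovery (observed rate ≈
0.98), matching the generator's stated invariant. The control coupling
(R = −0.5 at n = 29) has ≈ 0.85 power, asserted as ≥ 80% significance
recovery over 500 replicates; "decoupling" is asserted as the patient
side staying non-significant (rate ≈ 0.94). The diagnosis-by-qT1
interaction at planted slopes −0.5 vs 0 and n = 85 has only ≈ 0.6 power,
so interaction power is demonstrated in a direct simulation with noise
sd matched to the effect (power > 0.8), and the end-to-end decoupling
claim rests on the two per-group criteria above. The unadjusted MRS
group comparison at a planted 0.8-SD shift has ≈ 0.93 power; the
covariate-adjusted variant ≈ 0.7 for the same reason as above.

## Numerical choices

* Exact distance ties in matching: lowest vertex id, then lowest sample
  id. Decile boundary ties: gene id order.
* REML λ search on log₁₀ λ ∈ [−8, 4] with an explicit boundary
  comparison at λ = 0; singular threshold λ < 10⁻⁶.
* Inverse trigamma by Newton iteration with asymptotic starts (the
  classical scheme); moderation requires ≥ 10 positive variances.
* Degenerate residual variance: s² ≤ 10⁻¹² × mean-square signal.
* Canonical output formatting: TSV, 6 significant digits, '\n' line
  ends — manifest hashes are reproducible bit for bit under a fixed
  seed.
* Permutation p-values (pSI) are add-one corrected so they lie in (0, 1].

## Test and acceptance problem sizes

The validation suites run on scaled-down generator configs — 400
vertices/hemisphere, 50 per subcortical structure, 500 genes, 40
cortical samples/donor — which preserve every structural feature (donor
layout, planted QC cases, field geometry) at lower resolution; cohort
sizes and effect sizes are never scaled. Replicate counts: 500 for
cheap cohort-level recovery and null-calibration rates, 200 for
covariate-adjusted sign recovery, 5–10 for the expression-stage suites
where each replicate is a full dataset.

## Known limitations

* The mixed-model Wald test uses residual df = n − 2; Satterthwaite-type
  df are not implemented (the LRT option is the alternative).
* pSI depth is bounded by the pooled-null contamination described above;
  with few genes the 10⁻⁴ marker sets may be empty.
* The covariance stage offers no spatial cluster inference or
  autocorrelation-preserving (spin) nulls; per-vertex FDR only.
* Group comparisons from summary statistics offer pooled and Welch
  variants; analyses default to pooled.
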