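# Methods

## The screening statistic

The screen rests on three per-gene quantities.

**Stroma:epithelium log ratio `L`.** Paired micro-dissected epithelium and
stroma matrices are taken to linear scale (values declared log2 are
un-logged), a pseudocount is added, and the ratio is aggregated across
specimens. Two aggregations are provided because the source data's
convention is genuinely ambiguous: `ratio_of_means` (default) takes
log2(mean stroma / mean epithelium) and is robust to single-specimen
dropouts; `mean_of_ratios` averages per-pair log2 ratios and weights every
specimen equally. The pseudocount (default 1.0 on the linear scale) guards
against zeros; genes with zero expression in both compartments at
pseudocount 0 come back as missing, not as an error.

**Correlation profile `r_g`.** Pearson correlation of the target gene with
every gene across bulk samples. Genes constant across samples have no
defined correlation and are flagged and dropped from all downstream
correlation work. Bulk input on a linear scale is log2(x+1)-transformed
before any correlation; expression correlations on the raw scale are
dominated by the handful of highest-expressed genes.

**Mesenchymal score `MS(g) = corr_x(r_g(x), L(x))`.** Computed for all
genes at once as a standardized-matrix product in gene blocks, then a
closed-form Pearson against `L` with per-row self-exclusion — numerically
identical (to ~1e-15) to the per-gene double loop, which the test suite
keeps as an oracle. The degenerate self pair `(r_g(g)=1, L(g))` is excluded
by default (`exclude_self=True`); the flag exists because the convention is
a judgment call, not a mathematical necessity. A defined score requires at
least three genes shared between the bulk matrix and `L` (at least two
usable pairs after self-exclusion); pairs with a missing member are deleted
pairwise.

**Prognostic z.** One univariable Cox proportional-hazards fit per gene on
the (transformed) expression; `z = beta/se`, positive meaning adverse. The
default covariate transform is log2(x+1) for linear-scale input and `raw`
for input already on the log2 scale (the model front door switches
automatically). z is invariant to affine rescaling of the covariate, so the
`zscore` transform changes beta but not the screen's decisions.

**Selection rule.** `MS > 0.3`, `L < 0`, `z > 1.96`, all strict; boundary
genes are excluded, and genes missing any metric are excluded and counted
in the report. No multiple-testing adjustment is applied by default — the
rule is a deliberate reproduction of a raw-threshold screen — but a
Benjamini–Hochberg mode (`fdr=`) replaces the z criterion for users who
want FDR control.

## Survival estimators

The Cox fitter maximizes the Efron-corrected partial likelihood by
Newton–Raphson with step halving. Efron rather than Breslow because the
synthetic integer-valued times produce heavy ties, where Breslow's
approximation biases beta toward zero. Convergence is declared at
max |score| < 1e-8 or step < 1e-10; the likelihood, gradient and
information are vectorized over event-time groups so a 2000-gene screen
refits in under a second. A fit whose standardized coefficient passes
|beta|·sd(x) > 10 is aborted as a monotone likelihood (perfect
separation) — on such plateaus the gradient can fall below tolerance and
fake convergence at a meaningless optimum. Confidence intervals are
Wald-style on the log scale, `exp(beta ± 1.96·se)`.

One consequence of Efron ties worth knowing: duplicating every subject
changes the estimate slightly (duplication creates ties where there were
none), exactly as reference implementations behave; the invariance that
does hold, and is tested, is to any strictly increasing transform of the
time axis.

Kaplan–Meier uses the product-limit estimator with the standard convention
that censorings at a time follow the events at that time. The log-rank test
is the multi-group O−E statistic with hypergeometric variance and a
pseudo-inverse for the (G−1)-dimensional quadratic form. Group
dichotomization supports splitting at the mean and at the median, and the
rule is a required argument — both conventions are in active use and a
silent default would hide a consequential choice.

## Clinical statistics

The chi-square test of independence defaults to the likelihood-ratio form
(G-test), `2·Σ O·ln(O/E)` with `0·ln 0 = 0`, no continuity correction; the
Pearson form is available. The default was fixed by recomputing a published
patient-characteristics table from its printed counts: the likelihood-ratio
form reproduces the printed p-values (0.043, 0.060 — a zero-cell case —
0.041, 0.953, 0.842) where Pearson does not (0.047, 0.143). Two printed
entries resist exact reproduction and are documented rather than forced:
one (0.238) sits on a rounding boundary of the computed 0.23747, and one
(0.005) falls between the likelihood-ratio (0.0045) and Pearson (0.0058)
values, so neither form matches it after rounding.

Mann–Whitney U uses midrank ties, an exact p when the group-size product is
at most 400 and the pooled data is tie-free, and otherwise the
tie-corrected normal approximation without continuity correction (chosen
for closer exact/asymptotic agreement at moderate n). Table-one percentages
are half-up rounded to one decimal and p-values to three, matching clinical
reporting conventions.

## Clustering

Cell lines are clustered agglomeratively on a gene subset; defaults are
correlation distance (1 − Pearson between sample profiles) with average
linkage, both exposed. Per-gene preprocessing defaults to **centering
only**. Full z-scoring is available but is not the default for a reason
worked out during design: scaling each gene to unit variance makes the
effective group loading `l_g/sd_g`, and for marker genes whose variance is
dominated by the very program that separates the groups this ratio is
nearly constant across genes — the group structure becomes a constant
offset of every standardized sample profile, which correlation distance
cannot see. Centering removes baseline expression without erasing loading
heterogeneity. The EMT-prone cluster is the one maximizing mean
standardized marker expression; exact ties go to the lowest cluster ID and
are flagged. Trees export to Newick with merge-height branch lengths.

## The synthetic cohort

The generator produces every input the screen consumes, with ground truth,
under one seeded configuration. Its default parameters are the study
conditions assumed throughout the tests: 2000 genes, 200 bulk samples, 13
micro-dissection pairs, 150 stromal-archetype genes, 60 planted mediators,
30 cell lines of which 10 EMT-prone.

- **Admixture.** Per-sample stromal fraction `f ~ Beta(2, 3)` (mean 0.4 —
  bounded, right-spread purity; the Beta shapes are free parameters, since
  no canonical purity distribution exists for this setting). Bulk
  expression mixes the epithelial and stromal archetype profiles **in
  linear space** and reports log2, because admixture of cell populations is
  additive in transcript counts: `bulk = log2((1−f)·2^E + f·2^S)` plus
  noise. A consequence of this model worth knowing: an archetype gene's
  bulk expression is exactly monotone in `f` but curved in log space, so
  its Pearson correlation with `f` saturates near 0.97, not 1, even
  noiselessly.
- **Gene roles.** Stromal archetypes are elevated in the stromal profile by
  3 log2 units, planted mediators in the epithelial profile by 1 log2 unit,
  both scaled by per-gene effect weights ~ U(0.5, 1.5) — real signatures
  are not uniform shifts. Mediators additionally gain
  `mediator_coupling·f` (default 2.0 log2 per unit stromal fraction) in
  bulk: they co-vary with stromal content, the screen's central premise,
  while staying epithelium-enriched in the micro-dissection. The coupling
  must out-run the convex-mixture dilution of an epithelium-enriched gene,
  which is why its default exceeds the epithelial offset.
- **Survival.** Per-sample EMT activity is the mediators' shared coupling
  signal `mediator_coupling·f`; event times are exponential with hazard
  `0.1·exp(hazard_coef·activity)` per time unit and an independent
  exponential censoring clock tuned to an expected censored fraction of
  0.25. `hazard_coef` defaults to 2.0, which puts the hazard ratio across
  the activity interquartile range near 5 — the magnitude of the
  univariable clinical hazard ratios this kind of screen is meant to
  explain. (An earlier draft used 1.5 from a signal-to-noise estimate that
  neglected censoring and mixture attenuation; the corrected calculation is
  the current default.)
- **Cell-line panel.** Pure tumor cells, no admixture. The EMT program is
  modelled as a rank-two continuum (two partial-EMT axes with per-gene
  loadings and continuous per-line activity, strong in EMT-prone lines,
  near zero elsewhere) plus gene-specific biological variability across
  lines ~ U(0.3, 1.2) log2. Both ingredients matter: a rank-one uniform
  offset is provably invisible to correlation distance after per-gene
  standardization, and without program-independent variability each marker
  gene's variance is its own loading, which normalizes the structure away.
- **Clinical table.** Binary marker (prevalence 0.3), a binary covariate
  whose prevalence follows a logistic model in the marker with configurable
  odds ratio (default 2.0), an independent site factor and age, and
  survival in which the marker carries hazard ratio 2.0.

What the generator does **not** emulate: read-level count noise (negative
binomial overdispersion), batch effects, probe-level microarray artifacts,
gene-gene co-expression beyond the planted structure in bulk, and partial
EMT states in the bulk compartment. Passing recovery tests therefore shows
the pipeline is correct and well-calibrated under its own assumptions, not
that it would achieve the same sensitivity on real tumors, where the
stromal signature is noisier and mediator coupling far weaker.

Determinism: every generator draws from a stream keyed by (seed, stream-id),
so cohort, micro-dissection, survival, panel and clinical table are
individually reproducible and mutually independent given the seed.

## Problem sizes in the tests

The default-condition suites run at the generator's native scale (2000
genes × 200 samples; ten matched null cohorts for calibration); oracle
comparisons run on 5–12-gene fixtures where brute force is exact. The
acceptance script repeats the full default screen, its ten-seed null, a
2000-replicate G-test calibration and a 20-seed Cox recovery, all seeded
from its `--seed`.

## Known limitations

- Gene identifiers match by exact string; no symbol aliasing or probe
  mapping.
- No time-varying covariates, stratified Cox, or interval censoring.
- The log-rank implementation recomputes risk sets per event time; it is
  comfortable at cohort scale but not optimized for biobank-scale inputs.
- `MS` depends on the bulk cohort's composition: scores from cohorts with
  different purity distributions are not directly comparable.
- The selection thresholds are reproduction choices, not optimized
  operating points; the BH-FDR mode exists precisely because raw `z > 1.96`
  over 20k genes has no error-rate guarantee.
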