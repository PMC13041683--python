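# Methods

## Data model

All analyses start from a gene × sample `ExpressionMatrix` holding raw
integer read counts and/or TPM, a `GroupDesign` mapping samples to groups
with a designated control, and optionally a `MarkerReference` of cell-type
marker genes. Genes are rows and samples are columns in every file dialect
(TSV and Matrix Market + ID sidecars). Gene identifiers are opaque strings;
no symbol or Ensembl mapping is attempted. TPM is validated to sum to 10⁶
per sample (relative tolerance 1e-6) and can be derived from counts as
`TPMᵢ = 10⁶ · (cᵢ/ℓᵢ) / Σⱼ(cⱼ/ℓⱼ)` when gene lengths are available; an
all-zero sample column is rejected wherever a normalization or a diversity
index would be undefined.

## α-diversity indices

Six per-sample indices are computed on **raw integer counts**: Menhinick
`S/√N`, Brillouin `(ln N! − Σ ln nᵢ!)/N` (evaluated through the log-gamma
function; refuses non-integer input, since it is defined on individuals),
Shannon entropy in nats, Pielou equitability `J = H/ln S`, evenness
`e^H/S`, and Simpson dominance `D = Σ pᵢ²`. Natural logarithms are used
here, matching the conventions of classic ecology software; the per-gene
entropy machinery below deliberately uses log base 2, and both are exposed.
Proportion-based indices are tolerated on TPM input with a warning;
Menhinick and Brillouin are then reported as missing rather than silently
mis-scaled.

Edge cases follow the analytic limits: a single-expressed-gene library has
entropy 0, evenness 1, dominance 1, and equitability undefined (stored as
missing with a warning, since `ln S = 0`).

Group comparison uses one-way ANOVA with Tukey's HSD post hoc at family
α = 0.05. Two degenerate layouts are flagged rather than passed to the
F distribution: all values identical (F = 0, p = 1) and zero within-group
variance with distinct means (p = 0, flagged). The ANOVA's type-I error is
verified by simulation in the test suite (1,000 null three-group datasets;
rejection rate within 0.05 ± 0.02).

## PSE and the DSD statistic

For one library, gene proportions are `pᵢ = TPMᵢ/Σⱼ TPMⱼ` over **all**
genes of the sample (zeros contribute nothing, so the definition does not
depend on whether unexpressed genes are counted), the library's diversity
is the log2 Shannon entropy `H = −Σ pᵢ log₂ pᵢ` with `0·log 0 ≡ 0`, and
`G` is recorded as the number of expressed genes, bounding `H ≤ log₂ G`.
Each gene's percentage Shannon entropy `PSEᵢ = (−pᵢ log₂ pᵢ)/H` is its
fractional contribution to that entropy: 0 for unexpressed genes, summing
to 1 per sample (asserted to 1e-9), undefined when H = 0 (single-gene
library — rejected with an explicit error).

For a case/control contrast, per-gene PSE is averaged within groups
(arithmetic mean, group-mean-then-ratio), and

- `DSD = log₂((PSE̅_case + ε)/(PSE̅_control + ε))`
- `DEG = log₂((TPM̅_case + ε)/(TPM̅_control + ε))`

The pseudocount ε defaults to half the smallest positive value of the
relevant quantity across the whole dataset (configurable to any positive
number). Genes with a zero group mean are flagged (`case_absent`,
`control_absent`, `absent_in_both` — the last forced to 0) rather than
reported as silently extreme ratios; ratios at flagged genes are
ε-dominated and should be read as "appeared/disappeared", not as measured
fold changes.

Both arms are tested per gene with a two-sided Wilcoxon rank-sum
(Mann–Whitney U) test — on per-sample PSE for DSD, on TPM for DEG, the
identical machinery so the two metrics stay comparable. Exact enumeration
is used when both groups have ≤ 8 samples and the gene's values are
tie-free; otherwise the normal approximation with tie-corrected variance
and continuity correction. Genes constant across both groups get p = 1.
Significance calls use the raw-p thresholds |log₂FC| ≥ 1 and
−log₁₀ p ≥ 1.3; BH-adjusted q-values are always carried alongside but do
not drive the default calls. Genes significant in opposite directions by
the two metrics go to an explicit `discordant` Venn bucket.

Sample pairing is never assumed: the contrast groups may differ in size,
so the rank-sum (not signed-rank) formulation is the only coherent choice.

## Rank-abundance and binning

Whittaker curves are computed from group-mean TPM (one curve per group,
not per-sample curves averaged): shares sorted descending, rank 1 = most
abundant, ties broken by gene id for determinism. Spearman rank
correlation (average ranks on ties) compares group abundance profiles and
equals the textbook `1 − 6Σd²/(n(n²−1))` on tie-free input. Abundance bins
are tertiles of grand-mean TPM across all samples — low/medium/high — with
boundary ties resolved by gene-id order; tertiles are a declared package
convention, chosen for symmetry with three-way group designs, not an
externally fixed threshold. The percent coefficient of variation is
`100·sd/mean` with the sample (n−1) standard deviation; a zero mean yields
a flagged missing value.

## Marker-mean deconvolution

Cell-type composition is estimated by a deliberately transparent
reference-based score: a type's score in a sample is the arithmetic mean
TPM of its marker genes present in the matrix, and proportions are scores
normalized to 100 % per sample. Marker coverage (fraction of the
reference's markers found) is always reported; a cell type with no matched
markers is an error, not a silent zero. Group statistics per cell type:
mean ± SEM, one-way ANOVA across groups, Welch's two-sided unequal-variance
t-test of each non-control group against the control, and the signed
percent change of group means `100·(case − control)/control`.

This estimator recovers Dirichlet mixing proportions with Pearson r > 0.99
in the package's simulation when marker sets are disjoint and strongly
type-specific (the regime the recovery test pins at r ≥ 0.9); overlapping
or weakly specific signatures bias scores toward shared expression and
degrade recovery. No regression, NNLS, or signature learning is attempted —
proportions are a normalized score, and absolute values should be
interpreted relative to the marker panel supplied.

## Synthetic cohort generator

The generator emulates a three-group bulk RNA-seq study. Defaults: 10,000
genes; groups HC/ASH/AH with 10/11/18 samples; per-gene expected relative
abundances drawn log-normal(meanlog 0, sdlog 2) and normalized — a few
dominant transcripts over a long low-abundance tail, as in real bulk
transcriptomes; sequencing depth 2·10⁶–5·10⁶ reads per sample (default
5·10⁶); negative-binomial counts parameterized by a size parameter *k*
(variance `μ + μ²/k`, default k = 10, `inf` = Poisson), sampled
gamma-Poisson. Gene lengths default to 1 kb so TPM is proportional to
counts unless lengths are overridden. All randomness flows from one
integer seed; reruns are byte-identical.

Two disease mechanisms perturb the expected abundances before counts are
drawn, scaled by a per-group severity ladder (control = 0, so the control
arm is exactly the unperturbed baseline):

- **low_loss** — genes below abundance-rank quantile `q_low` are silenced
  with probability `min(π·severity, 1)`; survivors are attenuated by
  `δ^severity`. Defaults `q_low = 0.9, π = 0.15, δ = 0.4`.
- **high_gain** — genes above `q_high` are amplified by `γ^severity`.
  Defaults `q_high = 0.9, γ = 1.5`.

The low_loss defaults are attenuation-dominated by design. A
silencing-dominated regime removes rare genes outright, which cuts
richness S much faster than entropy H and therefore *raises* Pielou J and
evenness — the opposite of the progressive-unevenness phenotype the
mechanism is meant to model. Progressive attenuation of a broad
low-abundance band instead drains entropy continuously while the band
stays (partially) detected, so Shannon, equitability, and evenness fall
and dominance rises monotonically along the ladder; the depth and γ
defaults keep high_gain's renormalization from pushing tail genes below
the detection limit, so its signature — dominance up, richness preserved —
stays distinct from low_loss. These orderings were verified on expected
proportions analytically and on realized counts across several seeds
before being frozen.

What the generator does **not** emulate: empirical abundance spectra of
any real tissue, batch or library-preparation effects, gene–gene
correlation, length-dependent detection bias, or isoform structure.
Passing tests on synthetic cohorts therefore demonstrate that the
statistics respond correctly to the modeled mechanisms, not that any
particular real cohort's absolute index values are reproduced.

A separate mixture mode draws per-sample cell-type proportions from a
Dirichlet and mixes per-type expression signatures, returning the ground
truth for deconvolution recovery tests; `make_disjoint_signatures` builds
the disjoint-marker regime (shared log-normal background plus exclusive
markers at 50× mean background).

## Numerical and interface choices

- Brillouin uses `gammaln`, never factorials, so N ~ 10⁷ is safe.
- Proportion sums are checked at 1e-6 before entropy; PSE sums asserted at
  1e-9 after.
- Tie-breaks (rank curves, abundance bins) are lexicographic by gene id,
  making every output deterministic for a fixed input.
- CLI outputs are plain-text TSV/JSON only, with commented metadata
  headers (tool version, parameters) and SHA-256 manifests; input paths
  are recorded as basenames so identical reruns into different directories
  hash identically.
- Problem sizes in the test suite (e.g., 1,000-gene differential
  recovery, 40-replicate null calibration, 2,000 null genes for rank-test
  size) are chosen as the smallest sizes at which the checked properties
  are statistically stable.

## Known limitations

- The DSD ε-policy makes fold changes at zero group means
  policy-dependent; flags mark them, but downstream consumers must decide
  how to treat appeared/disappeared genes.
- Brillouin's integer requirement means TPM-only datasets get no
  Menhinick/Brillouin values.
- The deconvolution is a marker-mean score, not a deconvolution in the
  regression sense; proportions are panel-relative.
- Wilcoxon p-values at the default cohort sizes use the normal
  approximation; exact p-values are only computed for ≤ 8 samples per
  group without ties.
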