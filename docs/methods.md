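# Methods

This note documents the statistical model behind `hypervar`, the choices
made where the design was genuinely open, what the synthetic cohort does
and does not emulate, and the package's known limitations.

## Variability measures

For a feature (gene or CpG) within one cell type, the package computes
the unbiased variance *s²* (df = n − 1), the per-donor absolute
deviations from the group **mean** *dᵢ = |yᵢ − ȳ|*, and their median
(MAD). The deviations are taken from the mean, not the median: the
downstream test operates on the *dᵢ* themselves, and the mean-based form
makes the test statistic sensitive to both spread and asymmetry changes.

Raw variance and MAD are strongly mean-dependent (in log-scale RNA-seq
data, low-expressed genes have the largest spread), so cross-feature and
cross-cell-type comparisons require a mean correction. The expected
variance function *f(μ)* is estimated by LOWESS of log(*s²* + ε) on the
mean with span 0.3, three robustifying iterations, and ε = 1e-8;
the smoothed curve is linearly interpolated on a 512-point grid,
constant-extrapolated beyond the fitted mean range, and floored at a
small positive constant. The mean-corrected score is the variance ratio

EV = *s²* / *f(μ)*,

computed per cell type on that cell type's own fit (each cell type has
its own mean-variance regime). On trend-bearing null data the residual
|Spearman ρ(EV, mean)| is below 0.02 while ρ(variance, mean) ≈ −0.95.
EV is scale-equivariant through the variance (multiplying a feature by c
multiplies *s²* by c²) and responds to the mean only through *f*.

Methylation is analyzed on the M-value scale, M = log2(β/(1−β)), with β
values clamped to [1e-6, 1 − 1e-6] before conversion; β is used for
display only. The same machinery produces the methylation score MV.

## Paired moderated differential-variability test

All cell types come from the same donors, so contrasts are paired:
donor-wise differences of absolute deviations
*zᵢ = d⁽ᴬ⁾ᵢ − d⁽ᴮ⁾ᵢ* (complete pairs only; donors missing either sample
are dropped) enter a one-sample moderated t-test,

t̃ = z̄ / (s̃/√n),  s̃² = (d₀s₀² + df·s²) / (d₀ + df),  df = n − 1,

with p-values from the t distribution on d₀ + df degrees of freedom.
The prior (d₀, s₀²) is fitted by the log-variance moment method: with
*e_g* = log *s²_g* − ψ(df/2) + log(df/2), solve
ψ′(d₀/2) = var(*e*) − ψ′(df/2) by Newton inversion of the trigamma
function and set s₀² = exp(mean(*e*) + ψ(d₀/2) − log(d₀/2)). When the
observed spread of log variances does not exceed the sampling spread,
d₀ = ∞ and all variances shrink to s₀². The implementation agrees with
Bioconductor limma's `fitFDist`/`squeezeVar` to ten decimal places on a
frozen fixture, and with the classical paired t-test exactly when
moderation is disabled (d₀ = 0). Features with s̃² = 0 and z̄ = 0 are
reported as t = 0, p = 1.

## Combined call, classification, common list

A feature is called hypervariable in A versus B when all three hold:

1. BH-adjusted p < α (default 0.05);
2. EV_A − EV_B ≥ δ, where δ = 0.10 × (max − min) of the EV values pooled
   over both cell types of the contrast, computed on the analyzed
   (post-filter) feature set;
3. the deviation difference z̄ has the same sign (the two statistics of
   the combined rule may not disagree silently).

Labels over the three contrasts are mutually exclusive by construction:
`specific:X` requires an up-call in both of X's contrasts and is
evaluated first; `shared:X+Y` requires up-calls of X and Y each against
the third cell type and is only assigned to features not already
specific; everything else is `none`. The specific-before-shared
precedence resolves the corner where all three contrasts are significant.

The "common to all cell types" list is a separate rank-based selection,
not a classification label: features are ranked from most to least
variable by MAD and by EV within each cell type (six rankings, average
ranks on ties); a feature's score is its worst rank, and the n
best-scoring features are selected (ties broken by mean rank, then
feature id). n defaults to the rounded mean size of the nonempty
specific/shared lists and is configurable (`PipelineConfig.n_common`),
since the precise averaging set behind the published list sizes is not
recoverable. Because raw MAD is mean-dependent, high-mean features with
genuinely inflated variance can rank modestly on the MAD rankings; the
rank list therefore recovers injected "common" features only partially
(well above chance), which is a property of the rank-based rule itself.

## Filters

Genes are kept when expressed (raw count ≥ 1, i.e. log2(count+1) ≥ 1;
threshold configurable) in at least 50% of samples of **every** cell type
and annotated protein-coding. Probes are dropped when any of six criteria
fires: detection p ≥ 0.01 in ≥ 1 sample (strict single-sample reading);
bead count < 3 in ≥ 5% of samples; sex chromosome; ambiguous mapping;
non-CG probe; SNP with MAF ≥ 0.05 within 2 bp. Filters are idempotent
and report per-criterion drop counts. Annotation coordinates are 1-based
inclusive; BED exports would be 0-based half-open.

## Associations, enrichment, networks

Spearman correlation screens (features × donor traits; CpG methylation ×
expression of the mapped gene) use average ranks, the large-sample t
approximation for p, and BH correction within a declared family — per
(cell type, trait) for the trait screen, per region class (promoter =
TSS1500/TSS200/5′UTR/first exon; body = body/3′UTR) for the
methylation-expression link. Daily weather series are interpolated
linearly (edge gaps take the nearest observed value) and joined to donors
by collection date. Gene-level MV for the MV-vs-EV binned profiles is the
mean MV over the gene's promoter (or body) CpGs; the binning sorts
ascending by the ordering metric (stable, ties by feature id) into
consecutive bins of 100.

Enrichment of an HVP set in an annotation category is tested against the
background of all QC-passing probes, exactly (hypergeometric upper/lower
tail) and empirically by drawing `n_resamples` (default 1000) random
probe subsets of the set's size; the empirical p uses add-one smoothing,
(1 + #{k\* ≥ k}) / (n + 1), so it is never zero. Chromatin states over
≥ 5 biological replicates collapse to the modal state when seen in ≥ 80%
of replicates, else "variable" (modal ties are "variable" by definition).

Co-expression networks connect genes at Pearson r > 0.6 (strict);
unconnected genes are removed. Modules come from an agglomerative scheme
over the edge clustering coefficient ECC(u,v) = (t_uv + 1)/min(deg_u − 1,
deg_v − 1) (t_uv + 1 when a degree is ≤ 1): edges are processed in
descending ECC (ties by edge id, so runs are deterministic), merging
endpoint clusters unless both already satisfy the module condition
2·(internal edges) > (outgoing edge ends); clusters below `min_size`
(default 5) are discarded. This is a documented approximation of the
FAG-EC family of agglomerative edge-clustering algorithms, whose exact
stopping rule is not published with the method's citation; a plain
connected-components fallback is selectable.

## Synthetic cohort

The generator emulates the statistical structure the analysis relies on,
at the study's dimensions (125 donors, three cell types, paired design):

- expression baseline: per-feature mean ~ U(0, 12) on the log2 scale
  (features carrying injected or covariate effects are drawn from
  U(2, 12) so they survive the expression filter); expected variance
  v(μ) = 2·exp(−0.4·μ) + 0.05, times a lognormal per-feature dispersion
  (log-sd 0.25) shared across cell types — sharing makes null variances
  exchangeable across cell types, so paired F-type ratios have median 1;
- methylation baseline: β ~ 0.45·Beta(1,10) + 0.45·Beta(10,1) +
  0.10·Beta(2,2) converted to M; M-scale noise variance
  0.6·exp(−0.3·|M|) + 0.02 times the same kind of dispersion;
- injected hypervariability: designated features have their noise
  variance multiplied by the configured inflation (default ×4) in the
  designated cell type(s); a configurable fraction (default 0.5,
  mirroring the reported ~55–64% of hypervariable features with cis
  genetic associations) is realized instead as an additive Hardy-Weinberg
  genotype effect (default MAF 0.3) whose allele effect is calibrated so
  the across-donor variance matches the same inflation — variability
  then *emerges* from genetic heterogeneity rather than wider noise;
- covariates: donor sex (46% male), age ~ N(55, 12²) clipped to [20, 75],
  collection dates over two years; optional sex log-fold-changes,
  seasonal sinusoids, age slopes on CpGs, target-ρ trait couplings and
  methylation-expression couplings, each recorded in the truth table;
- annotations: gene biotypes (10% non-coding among effect-free genes),
  CpG genomic features / gene elements / CpG-to-gene map, probe QC
  columns with a 2% failure rate, and per-replicate chromatin-state
  calls in which injected HVPs preferentially sit in enhancer states and
  open-sea features (bias 0.6) so the enrichment stage has signal to
  find, as observed for neutrophil HVPs;
- an optional donor random effect (default off) induces the
  cross-cell-type correlation that the paired design removes; a dropout
  option removes samples to exercise complete-pair handling.

Everything is deterministic under the configured seed (bit-identical
serialization). What the generator does **not** emulate: count-level
noise and library-size effects (data enter post-normalization, on the
log2/M scales), batch effects, probe-type chemistry differences,
realistic linkage or allele-frequency spectra, correlated co-expression
blocks among null genes, and real effect-size distributions of
hypervariable features — the defaults are plausibility choices for power
evaluation, not estimates of any particular cohort. Passing recovery
tests therefore demonstrate correctness of the inference machinery under
the stated model, not performance on real data.

## Numerical and scale choices

- Simulated log-expression values are continuous Gaussians around the
  feature mean; small negative values can occur at low-mean features and
  are tolerated (the scale is idealized post-normalization data).
- LOWESS evaluation uses the `delta` aggregation speed-up only above
  5000 features; fits are reproducible either way.
- Resampling enrichment draws subsets via random keys and argpartition in
  chunks capped at 2×10⁷ elements, keeping memory flat at any background
  size.
- The pipeline manifest records the package version, seed, and every
  analysis parameter, but not wall-clock timings, so reruns are
  byte-identical. The default test/validation problem sizes (2,000
  features for calibration, 5,000 for recovery, 11,980 genes + 50,000
  CpGs for the full-scale run) were chosen so the whole validation suite
  completes in about a minute on a single CPU.

## Limitations

- The EV trend fit is a documented stand-in for the original
  mean-correction algorithm it emulates; only the contract (smooth,
  positive, mean-free ratio) is guaranteed.
- The moderated test assumes approximately normal donor-wise deviation
  differences; with n = 125 the t reference is accurate, but for very
  small cohorts (n < 10 pairs) calibration degrades.
- The combined rule's δ depends on the observed EV range and is therefore
  dataset-relative; extreme EV outliers widen δ and make calls more
  conservative.
- Module detection approximates an agglomerative edge-clustering method
  from its published description; module boundaries on graphs without
  clear density structure are tie-break-dependent (though deterministic).
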