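# hypervar

Differential **variability** analysis of gene expression and DNA
methylation across paired cell types.

Most differential analyses ask whether the *mean* level of a gene or CpG
site differs between conditions. `hypervar` asks a different question:
in which cell type does a feature *vary more between individuals*?
Inter-individual variability of expression and methylation is a proxy for
phenotypic plasticity — immune cell types that must respond rapidly to
environmental challenges (canonically neutrophils, compared with
monocytes and naive T cells) carry genes and CpG sites with systematically
elevated variability. The package is aimed at analysts of paired
multi-cell-type population cohorts (the same donors profiled in every
cell type) who want to find, classify, and interpret these hypervariable
genes (HVGs) and hypervariable CpG positions (HVPs).

## Method

For each feature *g* within a cell type with values *y₁ … yₙ* across *n*
donors:

- **Deviation statistics.** Absolute deviations from the group mean,
  *dᵢ = |yᵢ − ȳ|*, and their median (MAD).
- **Mean-corrected variability score.** Raw variance and MAD correlate
  strongly and negatively with mean expression, which would confound any
  cross-cell-type comparison. The expected variance at a feature's mean,
  *f(μ)*, is fitted by a robust LOWESS of log-variance on mean, and

  EV*g* = *s²g* / *f(μg)*

  (EV for expression, MV for methylation M values) is approximately
  independent of the mean.
- **Paired moderated test.** For each cell-type pair (A, B), donor-wise
  differences *zᵢ = d⁽ᴬ⁾ᵢ − d⁽ᴮ⁾ᵢ* are reduced to a one-sample moderated
  t-statistic *t̃ = z̄ / (s̃/√n)*, where the posterior variance
  *s̃² = (d₀s₀² + df·s²)/(d₀ + df)* shrinks each feature's variance toward
  an empirical-Bayes prior (d₀, s₀²) fitted by moment-matching on the log
  variances; *t̃* has *d₀ + n − 1* degrees of freedom.
- **Combined call.** A feature is hypervariable in A versus B only when
  its Benjamini–Hochberg adjusted p is below α = 0.05 **and** its EV
  exceeds B's by at least 10% of the observed pooled EV range, with both
  statistics agreeing in direction.
- **Classification.** Calls from the three pairwise contrasts fold into
  mutually exclusive labels: `specific:X` (up in X against both others),
  `shared:X+Y` (each up against the third), else `none` — no feature can
  appear in more than one list. Features variable in *all three* cell
  types are selected separately by a rank-based rule (worst rank across
  the six MAD/EV rankings).

Downstream stages correlate hypervariable features with donor traits and
daily weather (Spearman), link CpG methylation to expression of the
mapped gene at promoters and gene bodies, test annotation enrichment of
HVP sets (hypergeometric and repeated random sampling against the
QC-passing background), call consensus/"variable" chromatin states over
biological replicates, and build thresholded co-expression networks
(Pearson r > 0.6) with ECC-based module detection.

Because cohort data of this kind are controlled-access, the package ships
a synthetic cohort generator (`hypervar.synthetic`) that reproduces the
statistical structure — paired donors across three cell types, a negative
mean-variance trend, bimodal methylation, injected cell-type-specific /
shared / common hypervariability, cis-genotype-driven variance, and sex /
age / season / trait covariate effects — with a ground-truth table for
recovery scoring.

## Worked example

```python
import hypervar as hv

genes = [f"gene_{i:05d}" for i in range(40)]
config = hv.SimConfig(
    n_donors=125, n_genes=1000, n_cpgs=10, seed=42,
    injected_sets=(
        hv.InjectedSet(genes[:25], "specific:neutrophil", 4.0),
        hv.InjectedSet(genes[25:40], "shared:monocyte+neutrophil", 4.0),
    ),
)
cohort = hv.simulate_cohort(config)

var_tables, absdevs, contrasts, classification, common = hv.analyze_assay(
    cohort.expression, cohort.design, config.cell_types
)
print(hv.summarize_counts(classification, n_common=len(common)).to_string(index=False))
print(hv.truth_eval(classification, cohort.truth).round(3).to_string(index=False))
```

Output:

```
                     label   n
                    common  20
                      none 960
shared:monocyte+neutrophil  15
       specific:neutrophil  25

                     label  n_injected  n_recovered  sensitivity  precision  label_accuracy
shared:monocyte+neutrophil          15           15          1.0        1.0             1.0
       specific:neutrophil          25           25          1.0        1.0             1.0
                   overall          40           40          1.0        1.0             1.0
```

All 25 genes injected with 4-fold variance inflation in neutrophils are
recovered as `specific:neutrophil`, the 15 genes inflated in both myeloid
cell types as `shared:monocyte+neutrophil`, with no false calls among the
960 null genes; the `common` row is the size of the separate rank-based
common list.

The same analysis is available from a shell:

```bash
hypervar simulate --config sim.yaml --out cohort/ --seed 42
hypervar run --config pipeline.yaml
hypervar variability --matrix expr.tsv --design samples.tsv --cell-type neutrophil --out var.tsv
```

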