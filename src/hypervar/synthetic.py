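"""Synthetic paired multi-cell-type cohort generator.

Emulates the statistical structure of a population cohort profiled for
gene expression (log2 scale) and DNA methylation (M-value scale) in three
immune cell types from the same donors:

* a strong negative mean-variance trend for expression (variance is a
  decreasing function of the mean, times a lognormal per-feature
  dispersion shared across cell types, so variances are exchangeable
  across cell types under the null);
* bimodal methylation (a low/high beta mixture converted to M values)
  with its own mean-variance regime on the M scale;
* injected hypervariable features — cell-type-specific, shared between
  two cell types, or common to all three — realized either as pure noise
  inflation or as an additive cis-genotype effect (Hardy-Weinberg
  genotypes, additive mean shift per alternate allele calibrated so the
  across-donor variance matches the requested inflation);
* donor covariates (sex, age, collection date) with optional sex, age,
  seasonal and quantitative-trait effects on designated features;
* annotation tables (gene biotype, CpG genomic feature / gene element /
  CpG-to-gene map, per-replicate chromatin-state calls, probe QC) so the
  full pipeline, including filtering and enrichment, runs end to end.

Everything is deterministic under a fixed seed, and every injected effect
is recorded in a ground-truth table for recovery scoring.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CHROMATIN_STATES,
    GENE_ELEMENTS,
    GENOMIC_FEATURES,
    CohortDesign,
    CpGAnnotation,
    OmicsMatrix,
    Scale,
)

__all__ = [
    "InjectedSet",
    "SimConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_traits",
    "simulate_weather",
    "truth_eval",
]

TRAIT_NAMES = (
    "age",
    "bmi",
    "alcohol",
    "neutrophil_percentage",
    "neutrophil_granularity",
    "cell_count",
)


@dataclass
class InjectedSet:
    """A set of features with inflated variance in designated cell types.

    ``label`` is ``"specific:<cell>"``, ``"shared:<cellA>+<cellB>"`` or
    ``"common"``; ``assay`` selects expression or methylation features.
    """

    feature_ids: tuple
    label: str
    variance_inflation: float = 4.0
    assay: str = "expression"

    def __post_init__(self):
        self.feature_ids = tuple(self.feature_ids)
        if self.variance_inflation < 1:
            raise ValueError("variance_inflation must be >= 1")
        if self.assay not in ("expression", "methylation"):
            raise ValueError("assay must be 'expression' or 'methylation'")

    def target_cells(self, cell_types) -> list[str]:
        if self.label == "common":
            return list(cell_types)
        kind, _, spec = self.label.partition(":")
        if kind == "specific":
            if spec not in cell_types:
                raise ValueError(f"unknown cell type in label {self.label!r}")
            return [spec]
        if kind == "shared":
            cells = spec.split("+")
            if len(cells) != 2 or any(c not in cell_types for c in cells):
                raise ValueError(f"bad shared label {self.label!r}")
            return cells
        raise ValueError(f"unknown injected-set label {self.label!r}")


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Expression baseline: per-feature mean ~ U(0, 12) on the log2 scale
    (injected/special features are kept above 2 so they survive the
    expression filter); expected variance v(mu) = a*exp(-b*mu) + c with a
    lognormal per-feature dispersion shared across cell types.
    Methylation baseline: beta ~ 0.45 Beta(1,10) + 0.45 Beta(10,1)
    + 0.10 Beta(2,2) converted to M; noise variance decays with |M|.
    """

    n_donors: int = 125
    n_genes: int = 2000
    n_cpgs: int = 2000
    cell_types: tuple = ("monocyte", "neutrophil", "naive_T")
    # expression mean-variance trend v(mu) = a * exp(-b * mu) + c
    mean_variance_slope: float = 0.4
    trend_amplitude: float = 2.0
    trend_floor: float = 0.05
    feature_dispersion_sd: float = 0.25
    # methylation noise trend on the M scale: v(M) = a_m * exp(-b_m*|M|) + c_m
    m_trend_amplitude: float = 0.6
    m_trend_slope: float = 0.3
    m_trend_floor: float = 0.02
    donor_effect_sd: float = 0.0
    injected_sets: tuple = ()
    genetic_fraction: float = 0.5
    genetic_maf: float = 0.3
    sex_effect_genes: tuple = ()  # of (feature_id, logfc)
    trait_effect_features: tuple = ()  # of (feature_id, trait, target_rho)
    seasonal_features: tuple = ()  # of (feature_id, amplitude)
    age_effect_cpgs: tuple = ()  # of (feature_id, slope_per_year)
    coupled_cpgs: tuple = ()  # of (cpg_id, gene_id, target_rho)
    noncoding_fraction: float = 0.1
    qc_fail_fraction: float = 0.02
    hvp_enhancer_bias: float = 0.6
    variable_state_fraction: float = 0.1
    n_state_replicates: int = 6
    dropout_rate: float = 0.0
    weather_missing_fraction: float = 0.05
    male_fraction: float = 0.46
    seed: int = 0

    def __post_init__(self):
        if self.n_donors < 4:
            raise ValueError("need at least 4 donors")
        if len(self.cell_types) != 3:
            raise ValueError("exactly three cell types are required")
        if not (0 < self.genetic_maf <= 0.5):
            raise ValueError("MAF must lie in (0, 0.5]")
        self.injected_sets = tuple(
            s if isinstance(s, InjectedSet) else InjectedSet(**s) for s in self.injected_sets
        )
        ids = {"expression": self._gene_ids(), "methylation": self._cpg_ids()}
        for s in self.injected_sets:
            s.target_cells(self.cell_types)  # validates the label
            unknown = set(s.feature_ids) - set(ids[s.assay])
            if unknown:
                raise ValueError(f"injected ids outside the feature range: {sorted(unknown)[:3]}")

    def _gene_ids(self) -> pd.Index:
        return pd.Index([f"gene_{i:05d}" for i in range(self.n_genes)])

    def _cpg_ids(self) -> pd.Index:
        return pd.Index([f"cg{i:07d}" for i in range(self.n_cpgs)])

    def expected_variance(self, mu: np.ndarray) -> np.ndarray:
        return self.trend_amplitude * np.exp(-self.mean_variance_slope * mu) + self.trend_floor

    def expected_m_variance(self, m: np.ndarray) -> np.ndarray:
        return self.m_trend_amplitude * np.exp(-self.m_trend_slope * np.abs(m)) + self.m_trend_floor


@dataclass
class SyntheticCohort:
    """Generated cohort: matrices, design, traits, annotations and truth."""

    expression: dict
    methylation: dict
    design: CohortDesign
    traits: pd.DataFrame
    weather: pd.DataFrame
    gene_annotation: pd.DataFrame
    cpg_annotation: CpGAnnotation
    truth: pd.DataFrame
    config: SimConfig


def _special_gene_ids(config: SimConfig) -> set:
    special = set()
    for s in config.injected_sets:
        if s.assay == "expression":
            special |= set(s.feature_ids)
    special |= {g for g, _ in config.sex_effect_genes}
    special |= {g for g, _, _ in config.trait_effect_features}
    special |= {g for g, _ in config.seasonal_features}
    special |= {g for _, g, _ in config.coupled_cpgs}
    return special


def _special_cpg_ids(config: SimConfig) -> set:
    special = set()
    for s in config.injected_sets:
        if s.assay == "methylation":
            special |= set(s.feature_ids)
    special |= {c for c, _ in config.age_effect_cpgs}
    special |= {c for c, _, _ in config.coupled_cpgs}
    return special


def _make_design(config: SimConfig, rng: np.random.Generator) -> CohortDesign:
    donors = [f"D{i:04d}" for i in range(config.n_donors)]
    sex = np.where(rng.random(config.n_donors) < config.male_fraction, "M", "F")
    age = np.clip(rng.normal(55.0, 12.0, config.n_donors), 20.0, 75.0).round(1)
    start = datetime.date(2012, 1, 1)
    offsets = rng.integers(0, 730, config.n_donors)
    dates = [start + datetime.timedelta(days=int(o)) for o in offsets]
    rows = []
    for d, s, a, dt in zip(donors, sex, age, dates):
        for ct in config.cell_types:
            rows.append((f"{d}:{ct}", d, ct, s, a, dt.isoformat()))
    table = pd.DataFrame(
        rows, columns=["sample_id", "donor_id", "cell_type", "sex", "age", "collection_date"]
    )
    if config.dropout_rate > 0:
        drop = rng.random(len(table)) < config.dropout_rate
        table = table[~drop].reset_index(drop=True)
    return CohortDesign(table)


def _truth_rows(config: SimConfig):
    """One truth row per injected feature, with genetic flags assigned."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    rows = []
    for s in config.injected_sets:
        ids = list(s.feature_ids)
        genetic = rng.random(len(ids)) < config.genetic_fraction
        for fid, g in zip(ids, genetic):
            rows.append(
                {
                    "feature_id": fid,
                    "assay": s.assay,
                    "label": s.label,
                    "variance_inflation": s.variance_inflation,
                    "genetic": bool(g),
                    "maf": config.genetic_maf if g else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "assay", "label", "variance_inflation", "genetic", "maf"],
    )


def _seasonal_phase(dates: pd.Series) -> np.ndarray:
    doy = pd.to_datetime(dates).dt.dayofyear.to_numpy(dtype=float)
    return np.sin(2.0 * np.pi * (doy - 80.0) / 365.25)


def _simulate_assay(
    config: SimConfig,
    design: CohortDesign,
    rng: np.random.Generator,
    assay: str,
) -> tuple[dict, pd.DataFrame, np.ndarray, np.ndarray]:
    """Generate the per-cell-type matrices for one assay.

    Returns (matrices, truth, baseline_mean, noise_sd_matrix).
    """
    truth = _truth_rows(config)
    truth = truth[truth["assay"] == assay].set_index("feature_id")
    if assay == "expression":
        ids = config._gene_ids()
        special = _special_gene_ids(config)
        mu = rng.uniform(0.0, 12.0, config.n_genes)
        is_special = ids.isin(special)
        mu[is_special] = rng.uniform(2.0, 12.0, int(is_special.sum()))
        base_var = config.expected_variance(mu)
        scale = Scale.log2_expression
    else:
        ids = config._cpg_ids()
        comp = rng.choice(3, size=config.n_cpgs, p=[0.45, 0.45, 0.10])
        beta = np.empty(config.n_cpgs)
        beta[comp == 0] = rng.beta(1, 10, (comp == 0).sum())
        beta[comp == 1] = rng.beta(10, 1, (comp == 1).sum())
        beta[comp == 2] = rng.beta(2, 2, (comp == 2).sum())
        beta = np.clip(beta, 1e-4, 1 - 1e-4)
        mu = np.log2(beta / (1.0 - beta))
        base_var = config.expected_m_variance(mu)
        scale = Scale.m_value
    dispersion = np.exp(rng.normal(0.0, config.feature_dispersion_sd, len(ids)))
    var0 = base_var * dispersion  # shared across cell types under the null

    pos = pd.Index(ids).get_indexer
    donors = design.donors
    n_donors = len(donors)
    donor_idx = {d: i for i, d in enumerate(donors)}

    # per-feature, per-cell-type variance multiplier from injected sets
    inflation = {ct: np.ones(len(ids)) for ct in config.cell_types}
    genetic_shift = {ct: None for ct in config.cell_types}
    geno = {}
    for s in (x for x in config.injected_sets if x.assay == assay):
        cells = s.target_cells(config.cell_types)
        idx = pos(pd.Index(s.feature_ids))
        for j, fid in zip(idx, s.feature_ids):
            row = truth.loc[fid]
            if row["genetic"]:
                maf = config.genetic_maf
                g = rng.binomial(2, maf, n_donors).astype(float)
                geno_var = 2.0 * maf * (1.0 - maf)
                effect = np.sqrt((s.variance_inflation - 1.0) * var0[j] / geno_var)
                shift = effect * (g - 2.0 * maf)  # centered additive genotype effect
                geno[fid] = g
                for ct in cells:
                    if genetic_shift[ct] is None:
                        genetic_shift[ct] = np.zeros((len(ids), n_donors))
                    genetic_shift[ct][j] = shift
            else:
                for ct in cells:
                    inflation[ct][j] *= s.variance_inflation

    donor_effect = (
        rng.normal(0.0, config.donor_effect_sd, (len(ids), n_donors))
        if config.donor_effect_sd > 0
        else None
    )
    sex = design.donor_attr("sex").reindex(donors)
    age = design.donor_attr("age").reindex(donors).to_numpy(dtype=float)
    dates = design.donor_attr("collection_date").reindex(donors)
    season = _seasonal_phase(dates)

    matrices = {}
    for ct in config.cell_types:
        ct_samples = design.samples(ct)
        cols = ct_samples["sample_id"].tolist()
        d_of_sample = [donor_idx[d] for d in ct_samples["donor_id"]]
        sd = np.sqrt(var0 * inflation[ct])
        vals = mu[:, None] + rng.normal(0.0, 1.0, (len(ids), n_donors)) * sd[:, None]
        if genetic_shift[ct] is not None:
            vals += genetic_shift[ct]
        if donor_effect is not None:
            vals += donor_effect
        if assay == "expression":
            male = (sex == "M").to_numpy()
            for fid, lfc in config.sex_effect_genes:
                vals[pos(pd.Index([fid]))[0], male] += lfc
            for fid, amp in config.seasonal_features:
                vals[pos(pd.Index([fid]))[0]] += amp * season
        else:
            for fid, slope in config.age_effect_cpgs:
                vals[pos(pd.Index([fid]))[0]] += slope * (age - age.mean())
        matrices[ct] = OmicsMatrix(
            pd.DataFrame(vals[:, d_of_sample], index=ids, columns=cols), scale
        )
    noise_sd = {ct: np.sqrt(var0 * inflation[ct]) for ct in config.cell_types}
    return matrices, truth.reset_index(), mu, noise_sd


def _couple_cpgs(config, expression, methylation, rng):
    """Mix standardized gene expression into designated CpG M values to
    realize a target methylation-expression correlation."""
    for cpg, gene, rho in config.coupled_cpgs:
        for ct in config.cell_types:
            meth = methylation[ct].values
            expr = expression[ct].values
            if gene not in expr.index or cpg not in meth.index:
                raise ValueError(f"coupled pair ({cpg}, {gene}) outside the feature range")
            donors_e = expr.columns.str.split(":").str[0]
            donors_m = meth.columns.str.split(":").str[0]
            e = expr.loc[gene].to_numpy()
            z = (e - e.mean()) / (e.std() or 1.0)
            m_row = meth.loc[cpg].to_numpy()
            sd = m_row.std() or 1.0
            mean = m_row.mean()
            resid = (m_row - mean) / sd
            aligned = pd.Series(z, index=donors_e).reindex(donors_m).to_numpy()
            mixed = rho * aligned + np.sqrt(max(0.0, 1 - rho**2)) * resid
            meth.loc[cpg] = mean + sd * mixed


def _gene_annotation(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = config._gene_ids()
    special = _special_gene_ids(config)
    biotype = np.where(
        rng.random(config.n_genes) < config.noncoding_fraction, "lincRNA", "protein_coding"
    )
    biotype[ids.isin(special)] = "protein_coding"
    chrom = rng.choice([f"chr{i}" for i in range(1, 23)], config.n_genes)
    return pd.DataFrame({"feature_id": ids, "biotype": biotype, "chromosome": chrom})


def _cpg_annotation(
    config: SimConfig, design: CohortDesign, rng: np.random.Generator
) -> CpGAnnotation:
    ids = config._cpg_ids()
    n = config.n_cpgs
    special = pd.Index(ids).isin(_special_cpg_ids(config))
    chrom = rng.choice([f"chr{i}" for i in range(1, 23)], n).astype(object)
    sexchrom = (rng.random(n) < 0.02) & ~special
    chrom[sexchrom] = "chrX"

    feat = rng.choice(GENOMIC_FEATURES, n, p=[0.30, 0.25, 0.10, 0.35]).astype(object)
    # injected HVPs preferentially fall in open sea (away from islands)
    feat[special] = rng.choice(GENOMIC_FEATURES, int(special.sum()), p=[0.10, 0.20, 0.10, 0.60])

    element = rng.choice(GENE_ELEMENTS, n, p=[0.12, 0.10, 0.08, 0.05, 0.20, 0.05, 0.40]).astype(
        object
    )
    gene_ids = config._gene_ids()
    gene = np.where(
        element == "intergenic", None, rng.choice(gene_ids, n)
    ).astype(object)
    for cpg, g, _ in config.coupled_cpgs:
        i = pd.Index(ids).get_loc(cpg)
        gene[i] = g
        if element[i] == "intergenic":
            element[i] = "TSS200"

    ambiguous = (rng.random(n) < 0.005) & ~special
    non_cg = (rng.random(n) < 0.005) & ~special
    snp_maf = np.where((rng.random(n) < 0.01) & ~special, rng.uniform(0.05, 0.5, n), np.nan)

    table = pd.DataFrame(
        {
            "feature_id": ids,
            "chromosome": chrom,
            "genomic_feature": feat,
            "gene_element": element,
            "gene_id": gene,
            "ambiguous_mapping": ambiguous,
            "non_cg": non_cg,
            "snp_maf": snp_maf,
        }
    )

    samples = design.table["sample_id"].tolist()
    det = rng.uniform(0.0, 0.005, (n, len(samples)))
    fail = (rng.random(n) < config.qc_fail_fraction) & ~special
    det[fail, 0] = 0.02
    beads = rng.poisson(15, (n, len(samples))).astype(float) + 3.0
    detection_p = pd.DataFrame(det, index=ids, columns=samples)
    bead_count = pd.DataFrame(beads, index=ids, columns=samples)

    # chromatin-state calls per cell type: base state per region, replicate
    # calls concordant unless the region is designated variable
    state_calls = {}
    reps = [f"rep{i + 1}" for i in range(config.n_state_replicates)]
    for ct in config.cell_types:
        base = rng.choice(CHROMATIN_STATES, n, p=[0.15, 0.20, 0.25, 0.15, 0.25]).astype(object)
        bias = special & (rng.random(n) < config.hvp_enhancer_bias)
        base[bias] = "enhancer"
        variable = rng.random(n) < config.variable_state_fraction
        calls = np.tile(base[:, None], (1, len(reps))).astype(object)
        alt = rng.choice(CHROMATIN_STATES, n)
        n_flip = len(reps) // 2
        flip_cols = rng.integers(0, len(reps), (n, n_flip))
        rows_var = np.where(variable)[0]
        for i in rows_var:
            calls[i, flip_cols[i]] = alt[i]
        long = pd.DataFrame(
            {
                "region_id": np.repeat(ids, len(reps)),
                "replicate_id": np.tile(reps, n),
                "state": calls.ravel(),
            }
        )
        state_calls[ct] = long
    return CpGAnnotation(
        table=table, detection_p=detection_p, bead_count=bead_count, state_calls=state_calls
    )


def simulate_weather(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily weather series over the collection window.

    Sinusoidal seasonal cycle plus noise for minimum/maximum temperature
    and daylight hours, with a configurable fraction of missing days in
    the temperature series.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    dates = pd.date_range("2012-01-01", "2013-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    phase = np.sin(2.0 * np.pi * (doy - 105.0) / 365.25)
    tmin = 6.0 + 7.0 * phase + rng.normal(0, 2.0, len(dates))
    tmax = tmin + 6.0 + rng.normal(0, 1.5, len(dates))
    daylight = 12.2 + 4.5 * np.sin(2.0 * np.pi * (doy - 80.0) / 365.25)
    out = pd.DataFrame(
        {"date": dates, "tmin": tmin, "tmax": tmax, "daylight_hours": daylight}
    )
    if config.weather_missing_fraction > 0:
        miss = rng.random(len(dates)) < config.weather_missing_fraction
        out.loc[miss, ["tmin", "tmax"]] = np.nan
    return out


def simulate_traits(
    design: CohortDesign,
    config: SimConfig,
    expression: dict | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-donor quantitative traits (donor x trait, wide).

    Baseline traits are drawn from plausible marginal distributions; for
    each configured (feature, trait, rho) effect the trait is rebuilt as a
    mixture of the standardized feature values (first cell type) and
    noise so the realized Spearman correlation approximates the target.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    donors = design.donors
    n = len(donors)
    traits = pd.DataFrame(
        {
            "age": design.donor_attr("age").reindex(donors).to_numpy(dtype=float),
            "bmi": rng.normal(26.0, 4.0, n),
            "alcohol": rng.gamma(2.0, 4.0, n),
            "neutrophil_percentage": rng.normal(55.0, 8.0, n),
            "neutrophil_granularity": rng.normal(150.0, 10.0, n),
            "cell_count": rng.lognormal(1.6, 0.3, n),
        },
        index=pd.Index(donors, name="donor_id"),
    )
    for fid, trait, rho in config.trait_effect_features:
        if trait not in traits.columns:
            raise ValueError(f"unknown trait name {trait!r}")
        if expression is None:
            raise ValueError("trait effects require the expression matrices")
        ct = config.cell_types[0]
        expr = expression[ct].values
        if fid not in expr.index:
            raise ValueError(f"trait-effect feature {fid!r} outside the feature range")
        sample_donors = expr.columns.str.split(":").str[0]
        z = pd.Series(expr.loc[fid].to_numpy(), index=sample_donors).reindex(donors)
        z = (z - z.mean()) / (z.std() or 1.0)
        base = traits[trait]
        noise = rng.normal(0.0, 1.0, n)
        mixed = rho * z.to_numpy() + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
        traits[trait] = base.mean() + base.std() * mixed
    return traits


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort from a configuration.

    Deterministic under the configured seed: repeated calls with the same
    config produce identical outputs.
    """
    root = np.random.SeedSequence(config.seed)
    rng_design, rng_expr, rng_meth, rng_annot = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    design = _make_design(config, rng_design)
    expression, truth_e, _, _ = _simulate_assay(config, design, rng_expr, "expression")
    methylation, truth_m, _, _ = _simulate_assay(config, design, rng_meth, "methylation")
    _couple_cpgs(config, expression, methylation, np.random.default_rng(root.spawn(1)[0]))
    gene_annot = _gene_annotation(config, rng_annot)
    cpg_annot = _cpg_annotation(config, design, rng_annot)
    traits = simulate_traits(design, config, expression)
    weather = simulate_weather(config)
    truth = pd.concat([truth_e, truth_m], ignore_index=True)
    return SyntheticCohort(
        expression=expression,
        methylation=methylation,
        design=design,
        traits=traits,
        weather=weather,
        gene_annotation=gene_annot,
        cpg_annotation=cpg_annot,
        truth=truth,
        config=config,
    )


def truth_eval(
    classification: pd.DataFrame,
    truth: pd.DataFrame,
    assay: str = "expression",
    common_list=None,
) -> pd.DataFrame:
    """Score a classification against the injected ground truth.

    For each injected class (and pooled over classes, row ``overall``):

    * sensitivity — fraction of injected features receiving any
      hypervariability label;
    * precision — fraction of labelled features that were injected
      (pooled row only; per-class rows restrict to features whose call
      matches the class);
    * label_accuracy — among recovered injected features, the fraction
      whose label matches the injected class.

    Injected features of class ``common`` are variable in every cell type,
    so the disjoint specific/shared labels cannot recover them; when
    ``common_list`` (the rank-based selection) is given, their labels are
    taken from membership in that list instead.
    """
    cls = classification.set_index("feature_id")["label"].copy()
    tr = truth[truth["assay"] == assay]
    tr = tr[tr["label"] != "none"]
    if common_list is not None:
        in_common = cls.index.isin(pd.Index(common_list))
        cls[in_common & (cls == "none")] = "common"
    called = cls[cls != "none"]
    rows = []
    for label, sub in tr.groupby("label"):
        ids = pd.Index(sub["feature_id"])
        recovered = cls.reindex(ids).fillna("none")
        hit = recovered != "none"
        correct = recovered == label
        n_called_label = int((called == label).sum())
        tp_label = int(correct.sum())
        rows.append(
            {
                "label": label,
                "n_injected": len(ids),
                "n_recovered": int(hit.sum()),
                "sensitivity": float(hit.mean()) if len(ids) else np.nan,
                "precision": tp_label / n_called_label if n_called_label else np.nan,
                "label_accuracy": float((correct[hit]).mean()) if hit.any() else np.nan,
            }
        )
    ids_all = pd.Index(tr["feature_id"])
    recovered = cls.reindex(ids_all).fillna("none")
    hit = recovered != "none"
    n_called = len(called)
    tp = int(called.index.isin(ids_all).sum())
    correct = recovered.to_numpy() == tr.set_index("feature_id").reindex(ids_all)["label"].to_numpy()
    rows.append(
        {
            "label": "overall",
            "n_injected": len(ids_all),
            "n_recovered": int(hit.sum()),
            "sensitivity": float(hit.mean()) if len(ids_all) else np.nan,
            "precision": tp / n_called if n_called else np.nan,
            "label_accuracy": float(correct[hit.to_numpy()].mean()) if hit.any() else np.nan,
        }
    )
    return pd.DataFrame(rows)
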