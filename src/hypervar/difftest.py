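"""Moderated differential-variability testing and hypervariability calls.

The pipeline tests, for every feature and every pair of cell types, whether
the per-sample absolute deviations from the group mean differ between the
two cell types. Because all cell types come from the same donors, the test
is paired: donor-wise differences of absolute deviations are reduced to a
one-sample moderated t-statistic. Variance moderation follows the
empirical-Bayes scheme of limma-style linear models: per-feature variances
are shrunk toward a prior (d0, s0^2) fitted by moment-matching a scaled-F
model on the log variances, and the t-statistic gains d0 extra degrees of
freedom.

A feature is called hypervariable in a cell type only under the combined
rule: BH-corrected p below alpha AND a mean-corrected variability (EV/MV)
difference of at least ``rel_delta`` of the observed pooled EV range, with
both statistics agreeing in direction. Calls from the three pairwise
contrasts are then folded into mutually exclusive labels (cell-type
specific, shared between two cell types) plus a separate rank-based list of
features variable in all three cell types.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import CohortDesign, OmicsMatrix

__all__ = [
    "ModerationParams",
    "estimate_moderation",
    "posterior_variance",
    "paired_diffvar_test",
    "bh_adjust",
    "combined_decision",
    "classify_features",
    "rank_common",
    "sex_diff_expression",
]

MIN_MODERATION_FEATURES = 50
MIN_PAIRS = 4


@dataclass
class ModerationParams:
    """Empirical-Bayes prior for variance moderation.

    d0 is the prior degrees of freedom (may be ``inf`` for complete
    shrinkage), s0_sq the prior variance, df_residual the residual degrees
    of freedom of the per-feature variances the prior was fitted on.
    """

    d0: float
    s0_sq: float
    df_residual: float

    @classmethod
    def none(cls, df_residual: float) -> "ModerationParams":
        """No moderation: d0 = 0 reproduces the classical t-test."""
        return cls(d0=0.0, s0_sq=1.0, df_residual=df_residual)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_moderation(s2, df) -> ModerationParams:
    """Fit (d0, s0^2) by the log-variance moment method.

    With s2_g ~ s0^2 * F(df, d0) the log variances satisfy
    e_g = log s2_g - psi(df/2) + log(df/2), whose mean and excess variance
    identify the prior: trigamma(d0/2) = var(e) - trigamma(df/2) and
    s0^2 = exp(mean(e) + psi(d0/2) - log(d0/2)). When the observed spread
    is no larger than the sampling spread, d0 = inf (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    df = float(df)
    if df <= 0:
        raise ValueError("df must be positive")
    pos = s2[np.isfinite(s2) & (s2 > 0)]
    if pos.size == 0:
        raise ValueError("all variances are zero; cannot fit a variance prior")
    if pos.size < MIN_MODERATION_FEATURES:
        raise ValueError(
            f"need at least {MIN_MODERATION_FEATURES} positive variances, got {pos.size}"
        )
    e = np.log(pos) - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return ModerationParams(d0=math.inf, s0_sq=math.exp(emean), df_residual=df)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return ModerationParams(d0=d0, s0_sq=s0_sq, df_residual=df)


def posterior_variance(s2, params: ModerationParams) -> np.ndarray:
    """Shrink per-feature variances toward the prior.

    s~^2 = (d0*s0^2 + df*s^2) / (d0 + df); with d0 = 0 this is the sample
    variance, with d0 = inf the prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(params.d0):
        return np.full_like(s2, params.s0_sq)
    df = params.df_residual
    return (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)


def _moderated_pvalues(t: np.ndarray, df_total: float) -> np.ndarray:
    if math.isinf(df_total):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df_total)


def paired_diffvar_test(
    absdev_a: pd.DataFrame,
    absdev_b: pd.DataFrame,
    pairing: pd.DataFrame | None = None,
    moderation: ModerationParams | str = "fit",
) -> pd.DataFrame:
    """Paired moderated t-test on donor-wise absolute-deviation differences.

    Parameters
    ----------
    absdev_a, absdev_b
        Feature x sample matrices of absolute deviations (from
        :func:`hypervar.variability.group_stats`), on the same feature set.
    pairing
        Frame with columns ``sample_a, sample_b`` mapping paired samples
        (e.g. from :meth:`CohortDesign.paired_samples`). When omitted the
        columns are assumed aligned positionally.
    moderation
        ``"fit"`` to estimate the prior from these data, or explicit
        :class:`ModerationParams` (use ``ModerationParams.none(df)`` for
        the classical paired t-test).

    Returns a frame with columns ``feature_id, n_pairs, mean_absdev_diff,
    t, df_total, p``.
    """
    if not absdev_a.index.equals(absdev_b.index):
        raise ValueError("absdev matrices must share the same feature index")
    if pairing is not None:
        a = absdev_a.loc[:, pairing["sample_a"]].to_numpy(dtype=float)
        b = absdev_b.loc[:, pairing["sample_b"]].to_numpy(dtype=float)
    else:
        if absdev_a.shape[1] != absdev_b.shape[1]:
            raise ValueError("unpaired matrices of different widths; give a pairing")
        a = absdev_a.to_numpy(dtype=float)
        b = absdev_b.to_numpy(dtype=float)
    n = a.shape[1]
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} complete donor pairs, got {n}")
    z = a - b
    mean_diff = z.mean(axis=1)
    s2 = z.var(axis=1, ddof=1)
    df = n - 1
    if isinstance(moderation, str):
        if moderation != "fit":
            raise ValueError("moderation must be 'fit' or ModerationParams")
        params = estimate_moderation(s2, df)
    else:
        params = moderation
    s2_post = posterior_variance(s2, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / np.sqrt(s2_post / n)
    # identical deviations in both groups: no evidence either way
    degenerate = (s2_post == 0) & (mean_diff == 0)
    t[degenerate] = 0.0
    df_total = params.d0 + df
    p = _moderated_pvalues(t, df_total)
    p[degenerate] = 1.0
    return pd.DataFrame(
        {
            "feature_id": absdev_a.index,
            "n_pairs": n,
            "mean_absdev_diff": mean_diff,
            "t": t,
            "df_total": df_total,
            "p": p,
        }
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are excluded from the family size and propagated unchanged.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def combined_decision(
    q,
    ev_a,
    ev_b,
    mean_absdev_diff,
    cell_a: str = "A",
    cell_b: str = "B",
    alpha: float = 0.05,
    rel_delta: float = 0.10,
) -> pd.Series:
    """Combined hypervariability call for one pairwise contrast.

    A feature is called up in cell A when its BH-adjusted p is below
    ``alpha``, its EV exceeds cell B's by at least ``rel_delta`` of the
    observed pooled EV range of the two cell types, and the deviation
    statistic points the same way; symmetrically for cell B; otherwise
    'none'. Returns a Series of calls taking values ``{cell_a, cell_b,
    'none'}``.
    """
    q = np.asarray(q, dtype=float)
    ev_a = np.asarray(ev_a, dtype=float)
    ev_b = np.asarray(ev_b, dtype=float)
    mad_diff = np.asarray(mean_absdev_diff, dtype=float)
    pooled = np.concatenate([ev_a, ev_b])
    ev_range = float(np.nanmax(pooled) - np.nanmin(pooled))
    if ev_range == 0:
        warnings.warn("degenerate pooled EV range (max == min); delta set to 0")
    delta = rel_delta * ev_range
    ev_diff = ev_a - ev_b
    sig = q < alpha
    call = np.full(q.shape, "none", dtype=object)
    call[sig & (ev_diff >= delta) & (mad_diff > 0)] = cell_a
    call[sig & (-ev_diff >= delta) & (mad_diff < 0)] = cell_b
    return pd.Series(call)


def classify_features(
    calls: Mapping[tuple[str, str], pd.Series],
    cell_types: Sequence[str],
) -> pd.DataFrame:
    """Fold the three pairwise contrasts into mutually exclusive labels.

    ``calls`` maps each unordered cell-type pair (keyed in ``cell_types``
    order) to a per-feature Series of combined-decision calls indexed by
    feature id. A feature is ``specific:X`` when called up in X in both of
    X's contrasts; otherwise ``shared:X+Y`` when called up in X versus the
    third cell type Z and up in Y versus Z; otherwise ``none``. Specific
    labels take precedence, so no feature can appear in more than one list.
    """
    if len(cell_types) != 3:
        raise ValueError("classification requires exactly three cell types")
    a, b, c = cell_types
    expected = [(a, b), (a, c), (b, c)]
    for pair in expected:
        if pair not in calls:
            raise ValueError(f"missing contrast {pair}")
    index = calls[expected[0]].index
    for pair in expected[1:]:
        if not calls[pair].index.equals(index):
            raise ValueError("contrasts must cover the same feature universe")

    def up(x: str, other: str) -> np.ndarray:
        pair = (x, other) if (x, other) in calls else (other, x)
        return (calls[pair] == x).to_numpy()

    label = np.full(len(index), "none", dtype=object)
    # cell-type-specific: up against both other cell types
    for x in (a, b, c):
        others = [t for t in (a, b, c) if t != x]
        mask = up(x, others[0]) & up(x, others[1]) & (label == "none")
        label[mask] = f"specific:{x}"
    # shared between two: each up against the third
    for x, y in ((a, b), (a, c), (b, c)):
        z = next(t for t in (a, b, c) if t not in (x, y))
        mask = up(x, z) & up(y, z) & (label == "none")
        label[mask] = f"shared:{x}+{y}"
    return pd.DataFrame({"feature_id": index, "label": label})


def rank_common(
    var_tables: Mapping[str, pd.DataFrame],
    n: int,
) -> pd.Index:
    """Rank-based list of features variable in all cell types.

    Features are ranked from most to least variable, separately by MAD and
    by EV within each cell type (average ranks on ties). A feature's score
    is its WORST (largest) rank over the six rankings; the ``n`` features
    with the smallest score are returned, breaking ties by mean rank and
    then feature id.
    """
    tables = list(var_tables.values())
    index = pd.Index(tables[0]["feature_id"])
    rank_cols = []
    for tab in tables:
        if not pd.Index(tab["feature_id"]).equals(index):
            raise ValueError("variability tables must share the same feature order")
        for col in ("mad", "ev"):
            rank_cols.append(stats.rankdata(-tab[col].to_numpy(), method="average"))
    if n > len(index):
        raise ValueError(f"n={n} exceeds the {len(index)} available features")
    ranks = np.column_stack(rank_cols)
    score = ranks.max(axis=1)
    mean_rank = ranks.mean(axis=1)
    order = np.lexsort((index.to_numpy(), mean_rank, score))
    return index[order[:n]]


def sex_diff_expression(
    expr: OmicsMatrix,
    design: CohortDesign,
    cell_type: str,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    moderation: ModerationParams | str = "fit",
    max_age: float | None = None,
) -> pd.DataFrame:
    """Two-sample moderated t-test of mean expression between sexes.

    logFC is the male-minus-female mean difference on the log2 scale. A
    gene is significant when its BH-adjusted p is below ``alpha`` and
    |logFC| >= ``lfc_min`` (use 0 for the no-threshold screen). ``max_age``
    restricts to donors strictly younger than the given age (the
    menopause-status sensitivity analysis).
    """
    samples = design.samples(cell_type)
    if max_age is not None:
        samples = samples[samples["age"] < max_age]
    sexes = samples["sex"].unique()
    if len(sexes) < 2:
        raise ValueError("both sexes are required for differential expression")
    males = samples.loc[samples["sex"] == "M", "sample_id"]
    females = samples.loc[samples["sex"] == "F", "sample_id"]
    if len(males) < 3 or len(females) < 3:
        raise ValueError("need at least 3 samples per sex")
    xm = expr.values.loc[:, males].to_numpy(dtype=float)
    xf = expr.values.loc[:, females].to_numpy(dtype=float)
    n1, n2 = xm.shape[1], xf.shape[1]
    logfc = xm.mean(axis=1) - xf.mean(axis=1)
    s2 = ((n1 - 1) * xm.var(axis=1, ddof=1) + (n2 - 1) * xf.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    df = n1 + n2 - 2
    if isinstance(moderation, str):
        if moderation != "fit":
            raise ValueError("moderation must be 'fit' or ModerationParams")
        params = estimate_moderation(s2, df)
    else:
        params = moderation
    s2_post = posterior_variance(s2, params)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    degenerate = (s2_post == 0) & (logfc == 0)
    t[degenerate] = 0.0
    p = _moderated_pvalues(t, params.d0 + df)
    p[degenerate] = 1.0
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "cell_type": cell_type,
            "n_male": n1,
            "n_female": n2,
            "logfc": logfc,
            "t": t,
            "p": p,
            "q": q,
            "significant": (q < alpha) & (np.abs(logfc) >= lfc_min),
        }
    )
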