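"""Per-feature, per-cell-type variability measures.

Two complementary statistics are computed for every feature within a cell
type:

* deviation statistics — the per-sample absolute deviations from the group
  mean, |y_i - mean|, and their median (MAD). These feed the downstream
  paired moderated test.
* the mean-corrected variability score EV (expression) / MV (methylation):
  the observed unbiased variance divided by the variance expected at the
  feature's mean. The expected-variance function is fitted by a robust
  LOWESS of log-variance on the mean, so the score is approximately
  independent of mean level — essential because raw variance (and MAD)
  correlate strongly and negatively with mean expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .containers import CohortDesign, OmicsMatrix

__all__ = [
    "GroupStats",
    "MeanVarianceFit",
    "group_stats",
    "fit_mean_variance",
    "compute_ev",
    "variability_table",
]

MIN_GROUP_SIZE = 4


@dataclass
class GroupStats:
    """Per-feature summary statistics for one cell type.

    ``stats`` has columns ``feature_id, cell_type, mean, variance, mad``;
    ``absdev`` is the feature x sample matrix of absolute deviations from
    the group mean.
    """

    stats: pd.DataFrame
    absdev: pd.DataFrame
    cell_type: str


def group_stats(
    matrix: OmicsMatrix,
    design: CohortDesign | None = None,
    cell_type: str | None = None,
) -> GroupStats:
    """Mean, unbiased variance, absolute deviations and MAD per feature.

    When a design is given, the matrix is restricted to the samples of
    ``cell_type`` first. The MAD here is the median of absolute deviations
    from the group MEAN (not the median) — the deviation statistic of the
    moderated variability test.
    """
    if design is not None:
        if cell_type is None:
            raise ValueError("cell_type required when a design is given")
        samples = design.samples(cell_type)["sample_id"]
        matrix = matrix.subset(samples=samples)
    label = cell_type if cell_type is not None else "all"
    vals = matrix.values.to_numpy(dtype=float)
    n = vals.shape[1]
    if n < MIN_GROUP_SIZE:
        raise ValueError(f"need at least {MIN_GROUP_SIZE} samples per group, got {n}")
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    absdev = np.abs(vals - mean[:, None])
    mad = np.median(absdev, axis=1)
    stats = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "cell_type": label,
            "mean": mean,
            "variance": var,
            "mad": mad,
        }
    )
    absdev_df = pd.DataFrame(absdev, index=matrix.feature_ids, columns=matrix.sample_ids)
    return GroupStats(stats=stats, absdev=absdev_df, cell_type=label)


@dataclass
class MeanVarianceFit:
    """Expected-variance function fitted on (mean, variance) pairs.

    Evaluation interpolates linearly on a fixed grid of the smoothed
    log-variance curve and extrapolates by the boundary constants outside
    the fitted mean range. Values are floored at a small positive constant
    so the EV ratio is always defined.
    """

    grid_mu: np.ndarray
    grid_logvar: np.ndarray
    floor: float

    def __call__(self, mu) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        logv = np.interp(mu, self.grid_mu, self.grid_logvar)
        return np.maximum(np.exp(logv), self.floor)


def fit_mean_variance(
    mu,
    var,
    span: float = 0.3,
    iterations: int = 3,
    eps: float = 1e-8,
    grid_size: int = 512,
    floor: float = 1e-10,
) -> MeanVarianceFit:
    """Fit the mean-variance trend by robust LOWESS of log(var + eps) on mean.

    Parameters
    ----------
    span
        LOWESS smoothing fraction.
    iterations
        Robustifying reweighting iterations.
    eps
        Offset guarding the log against zero variances.
    grid_size
        Number of points of the evaluation grid spanning the fitted means.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if mu.shape != var.shape or mu.ndim != 1:
        raise ValueError("mu and var must be 1-D arrays of equal length")
    ok = np.isfinite(mu) & np.isfinite(var)
    mu, var = mu[ok], var[ok]
    if np.unique(mu).size < 2:
        raise ValueError("need at least 2 distinct mean values to fit a trend")
    if np.all(var == 0):
        raise ValueError("all variances are zero; no trend to fit")
    logv = np.log(var + eps)
    span_x = float(mu.max() - mu.min())
    # delta collapses near-duplicate x values inside LOWESS; pure speed knob
    delta = 0.01 * span_x if mu.size > 5000 else 0.0
    smoothed = sm_lowess(
        logv, mu, frac=span, it=iterations, delta=delta, return_sorted=True
    )
    xs, ys = smoothed[:, 0], smoothed[:, 1]
    xs, uniq_idx = np.unique(xs, return_index=True)
    ys = ys[uniq_idx]
    grid_mu = np.linspace(xs[0], xs[-1], grid_size)
    grid_logvar = np.interp(grid_mu, xs, ys)
    return MeanVarianceFit(grid_mu=grid_mu, grid_logvar=grid_logvar, floor=floor)


def compute_ev(var, fit: MeanVarianceFit, mu) -> np.ndarray:
    """Mean-corrected variability score: observed / expected variance."""
    var = np.asarray(var, dtype=float)
    expected = fit(mu)
    return var / expected


def variability_table(
    matrix: OmicsMatrix,
    design: CohortDesign,
    cell_type: str,
    fit: MeanVarianceFit | None = None,
    **fit_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full variability table for one cell type.

    Returns ``(table, absdev)`` where the table has columns ``feature_id,
    cell_type, mean, variance, expected_variance, ev, mad``. Each cell type
    is fitted on its own mean-variance trend unless a prefitted ``fit`` is
    passed.
    """
    gs = group_stats(matrix, design, cell_type)
    tab = gs.stats
    if fit is None:
        fit = fit_mean_variance(tab["mean"].to_numpy(), tab["variance"].to_numpy(), **fit_kwargs)
    expected = fit(tab["mean"].to_numpy())
    tab = tab.assign(
        expected_variance=expected,
        ev=tab["variance"].to_numpy() / expected,
    )
    tab = tab[["feature_id", "cell_type", "mean", "variance", "expected_variance", "ev", "mad"]]
    return tab, gs.absdev
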