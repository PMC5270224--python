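"""Associations of hypervariable features with donor traits and with each
other across molecular layers.

All correlation screens use Spearman's rank correlation (average ranks on
ties, p from the large-sample t approximation) with Benjamini-Hochberg
correction within a declared family. Daily weather series are made gap-free
by linear interpolation (edge gaps take the nearest observed value) before
being joined to donors by collection date.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BODY_ELEMENTS, PROMOTER_ELEMENTS, OmicsMatrix
from .difftest import bh_adjust

__all__ = [
    "spearman_rho",
    "spearman_assoc",
    "interpolate_missing",
    "meth_expr_link",
    "binned_profile",
]

MIN_DONORS = 8


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p (t approximation) for one pair."""
    rho, n = _rank_correlation(np.asarray(x, float)[None, :], np.asarray(y, float))
    return float(rho[0]), float(_rho_pvalues(rho, n)[0])


def _rank_correlation(rows: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorized Spearman rho of each matrix row against y (no missing)."""
    n = y.size
    ry = stats.rankdata(y)
    rx = stats.rankdata(rows, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx @ ry) / denom
    return rho, n


def _rho_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    return p


def spearman_assoc(
    features: pd.DataFrame,
    traits: pd.DataFrame,
    cell_type: str = "all",
) -> pd.DataFrame:
    """Correlate each feature with each donor trait.

    Parameters
    ----------
    features
        Feature x donor matrix (rows indexed by feature id, columns by
        donor id) of molecular values within one cell type.
    traits
        Donor x trait table; NaN trait values drop the donor from that
        trait's screen.

    BH correction is applied per (cell type, trait) family across the
    tested features. Constant traits yield NaN rho.
    """
    results = []
    for trait in traits.columns:
        tvals = traits[trait].reindex(features.columns)
        ok = tvals.notna().to_numpy()
        n_used = int(ok.sum())
        if n_used < MIN_DONORS:
            raise ValueError(
                f"trait {trait!r}: need at least {MIN_DONORS} donors with values, got {n_used}"
            )
        y = tvals.to_numpy(dtype=float)[ok]
        rows = features.to_numpy(dtype=float)[:, ok]
        if np.all(y == y[0]):
            rho = np.full(rows.shape[0], np.nan)
            p = np.full(rows.shape[0], np.nan)
        else:
            rho, n = _rank_correlation(rows, y)
            p = _rho_pvalues(rho, n)
        results.append(
            pd.DataFrame(
                {
                    "feature_id": features.index,
                    "cell_type": cell_type,
                    "trait": trait,
                    "rho": rho,
                    "p": p,
                    "q": bh_adjust(p),
                    "n_used": n_used,
                }
            )
        )
    return pd.concat(results, ignore_index=True)


def interpolate_missing(series: pd.Series) -> pd.Series:
    """Fill gaps in a daily series.

    Interior gaps are filled linearly between the flanking observations;
    edge gaps take the nearest observed value. Observed points are
    preserved exactly.
    """
    obs = series.notna().sum()
    if obs == 0:
        raise ValueError("series is entirely missing")
    if obs < 2:
        raise ValueError("need at least 2 observed points to interpolate")
    out = series.astype(float).interpolate(method="linear", limit_area="inside")
    return out.ffill().bfill()


def meth_expr_link(
    meth: OmicsMatrix,
    expr: OmicsMatrix,
    cpg_table: pd.DataFrame,
    region_class: str,
    cpg_ids=None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Correlate CpG methylation with expression of the mapped gene.

    ``region_class`` is 'promoter' (TSS1500/TSS200/5'UTR/first exon) or
    'body' (body/3'UTR). Columns of both matrices must be the same donors.
    Each CpG in the class (optionally restricted to ``cpg_ids``) is
    Spearman-correlated with its gene across donors; BH is applied across
    the CpG set; CpGs are classed positive/negative at q < alpha, else
    none. Returns the per-CpG table and the class proportions.
    """
    elements = {"promoter": PROMOTER_ELEMENTS, "body": BODY_ELEMENTS}.get(region_class)
    if elements is None:
        raise ValueError("region_class must be 'promoter' or 'body'")
    if not meth.sample_ids.equals(expr.sample_ids):
        raise ValueError("methylation and expression must share the same donors")
    tab = cpg_table.set_index("feature_id")
    if cpg_ids is not None:
        tab = tab.loc[tab.index.intersection(pd.Index(cpg_ids))]
    tab = tab[tab["gene_element"].isin(elements)]
    skipped = 0
    rows = []
    for cpg, gene in tab["gene_id"].items():
        if not isinstance(gene, str) or gene not in expr.feature_ids or cpg not in meth.feature_ids:
            skipped += 1
            continue
        rows.append((cpg, gene))
    if not rows:
        return (
            pd.DataFrame(columns=["feature_id", "gene_id", "rho", "p", "q", "link"]),
            {"positive": np.nan, "negative": np.nan, "none": np.nan, "n_skipped": skipped},
        )
    cpgs = [r[0] for r in rows]
    genes = [r[1] for r in rows]
    m = meth.values.loc[cpgs].to_numpy(dtype=float)
    e = expr.values.loc[genes].to_numpy(dtype=float)
    n = m.shape[1]
    rm = stats.rankdata(m, axis=1)
    re = stats.rankdata(e, axis=1)
    rm = rm - rm.mean(axis=1, keepdims=True)
    re = re - re.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rm * re).sum(axis=1) / np.sqrt((rm**2).sum(axis=1) * (re**2).sum(axis=1))
    p = _rho_pvalues(rho, n)
    q = bh_adjust(p)
    link = np.full(len(rows), "none", dtype=object)
    link[(q < alpha) & (rho > 0)] = "positive"
    link[(q < alpha) & (rho < 0)] = "negative"
    out = pd.DataFrame(
        {"feature_id": cpgs, "gene_id": genes, "rho": rho, "p": p, "q": q, "link": link}
    )
    total = len(out)
    props = {
        "positive": float((link == "positive").sum()) / total,
        "negative": float((link == "negative").sum()) / total,
        "none": float((link == "none").sum()) / total,
        "n_skipped": skipped,
    }
    return out, props


def binned_profile(
    order_metric: pd.Series,
    response: pd.Series,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Per-bin means along an ordering metric.

    Features are sorted ascending by ``order_metric`` (stable, ties broken
    by feature id) and grouped into consecutive bins of ``bin_size`` (the
    last bin may be smaller). Returns one row per bin with the bin index,
    size and the means of metric and response.
    """
    if len(order_metric) == 0:
        raise ValueError("empty input")
    if not order_metric.index.equals(response.index):
        response = response.reindex(order_metric.index)
    order = np.lexsort((order_metric.index.to_numpy(), order_metric.to_numpy()))
    metric = order_metric.to_numpy(dtype=float)[order]
    resp = response.to_numpy(dtype=float)[order]
    n = len(metric)
    bins = np.arange(n) // bin_size
    frame = pd.DataFrame({"bin": bins, "metric": metric, "response": resp})
    out = frame.groupby("bin").agg(
        n=("metric", "size"),
        metric_mean=("metric", "mean"),
        response_mean=("response", "mean"),
    )
    return out.reset_index()
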