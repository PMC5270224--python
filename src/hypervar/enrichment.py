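"""Annotation enrichment of CpG sets and consensus chromatin-state calls.

Enrichment of a CpG set in an annotation category is assessed two ways
against the background of all probes that passed quality control: exactly,
with the hypergeometric distribution, and empirically, by repeatedly
drawing random probe subsets of the same size from the background and
counting how often the resampled category count reaches the observed one.

Chromatin states over biological replicates are collapsed to a consensus:
the modal state when it is seen in at least 80% of replicates, otherwise
the region is called "variable" — a marker of dynamic local chromatin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "consensus_state",
    "consensus_states",
    "hypergeom_enrichment",
    "resampling_enrichment",
    "EnrichmentResult",
    "enrichment_by_system",
]

MIN_REPLICATES = 5
CONSENSUS_FRACTION = 0.8
VARIABLE_STATE = "variable"


def consensus_state(states: Sequence[str], min_replicates: int = MIN_REPLICATES) -> str:
    """Consensus chromatin state of one region over replicates.

    Returns the modal state when its replicate frequency is >= 80% and it
    is the unique mode, otherwise ``"variable"``.
    """
    states = list(states)
    if len(states) < min_replicates:
        raise ValueError(
            f"need at least {min_replicates} replicates for a consensus call, got {len(states)}"
        )
    counts = pd.Series(states).value_counts()
    top = counts.iloc[0]
    if (counts == top).sum() > 1:
        return VARIABLE_STATE
    if top / len(states) >= CONSENSUS_FRACTION:
        return str(counts.index[0])
    return VARIABLE_STATE


def consensus_states(calls: pd.DataFrame, min_replicates: int = MIN_REPLICATES) -> pd.Series:
    """Vectorized consensus over a long (region_id, replicate_id, state) frame."""
    counts = pd.crosstab(calls["region_id"], calls["state"])
    total = counts.sum(axis=1)
    if (total < min_replicates).any():
        bad = total[total < min_replicates].index[:3].tolist()
        raise ValueError(f"regions with fewer than {min_replicates} replicates, e.g. {bad}")
    top = counts.max(axis=1)
    arr = counts.to_numpy()
    tied = (arr == top.to_numpy()[:, None]).sum(axis=1) > 1
    modal = counts.idxmax(axis=1).astype(object)
    out = modal.where((top / total >= CONSENSUS_FRACTION) & ~tied, VARIABLE_STATE)
    out.name = "state"
    return out


def hypergeom_enrichment(
    k_set: int, n_set: int, k_bg: int, n_bg: int
) -> tuple[float, float, float]:
    """Exact enrichment/depletion p-values and fold change.

    With X ~ Hypergeometric(population n_bg, successes k_bg, draws n_set):
    p_enrich = P(X >= k_set), p_deplete = P(X <= k_set),
    fold = (k_set/n_set) / (k_bg/n_bg).
    """
    if not (0 <= k_set <= n_set <= n_bg and k_set <= k_bg <= n_bg):
        raise ValueError("inconsistent counts for hypergeometric test")
    if n_set == 0 or k_bg == 0:
        raise ValueError("empty set or empty category in background")
    dist = stats.hypergeom(M=n_bg, n=k_bg, N=n_set)
    p_enrich = float(dist.sf(k_set - 1))
    p_deplete = float(dist.cdf(k_set))
    fold = (k_set / n_set) / (k_bg / n_bg)
    return p_enrich, p_deplete, fold


@dataclass
class EnrichmentResult:
    """Enrichment of a feature set in one annotation category."""

    category: str
    n_set: int
    k_set: int
    n_background: int
    k_background: int
    fold: float
    p_enrich: float
    p_deplete: float
    p_empirical: float
    p_empirical_deplete: float
    n_resamples: int
    seed: int | None


def resampling_enrichment(
    set_ids: Iterable[str],
    background: pd.Series,
    category: str,
    n_resamples: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    _chunk_elems: int = 20_000_000,
) -> EnrichmentResult:
    """Empirical enrichment by repeated random sampling from the background.

    Parameters
    ----------
    set_ids
        The feature set (must be a subset of the background index).
    background
        Series mapping every QC-passing probe id to its category label.
    category
        The category whose overrepresentation is tested.

    Random subsets of size |set| are drawn from the background without
    replacement; the empirical p uses add-one smoothing,
    p = (1 + #{resampled k >= observed k}) / (n_resamples + 1), so it is
    never exactly zero. Fold is observed k over the mean resampled k.
    """
    set_ids = pd.Index(set_ids)
    bg_ids = background.index
    if not set_ids.isin(bg_ids).all():
        raise ValueError("feature set must be a subset of the background")
    cats = background.to_numpy()
    if category not in cats:
        raise ValueError(f"category {category!r} absent from background")
    in_cat = (cats == category).astype(np.int64)
    n_bg = len(bg_ids)
    n_set = len(set_ids)
    k_bg = int(in_cat.sum())
    k_obs = int(in_cat[bg_ids.get_indexer(set_ids)].sum())
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.empty(n_resamples, dtype=np.int64)
    # chunked vectorized sampling: random keys + argpartition give uniform
    # subsets without replacement
    per_chunk = max(1, _chunk_elems // max(n_bg, 1))
    done = 0
    while done < n_resamples:
        m = min(per_chunk, n_resamples - done)
        keys = rng.random((m, n_bg))
        idx = np.argpartition(keys, n_set - 1, axis=1)[:, :n_set]
        counts[done : done + m] = in_cat[idx].sum(axis=1)
        done += m
    p_emp = (1.0 + (counts >= k_obs).sum()) / (n_resamples + 1.0)
    p_emp_dep = (1.0 + (counts <= k_obs).sum()) / (n_resamples + 1.0)
    mean_k = counts.mean()
    fold = k_obs / mean_k if mean_k > 0 else np.nan
    p_enrich, p_deplete, _ = hypergeom_enrichment(k_obs, n_set, k_bg, n_bg)
    return EnrichmentResult(
        category=category,
        n_set=n_set,
        k_set=k_obs,
        n_background=n_bg,
        k_background=k_bg,
        fold=float(fold),
        p_enrich=p_enrich,
        p_deplete=p_deplete,
        p_empirical=float(p_emp),
        p_empirical_deplete=float(p_emp_dep),
        n_resamples=n_resamples,
        seed=seed,
    )


def enrichment_by_system(
    set_ids: Iterable[str],
    background: pd.Series,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run resampling enrichment for every category of one annotation system.

    One test per category; BH correction across the categories of the
    system (columns ``q_enrich``/``q_deplete`` from the hypergeometric p).
    """
    from .difftest import bh_adjust

    rng = np.random.default_rng(seed)
    rows = []
    for category in sorted(pd.unique(background)):
        res = resampling_enrichment(
            set_ids, background, category, n_resamples=n_resamples, rng=rng
        )
        rows.append(vars(res) | {"seed": seed})
    out = pd.DataFrame(rows)
    out["q_enrich"] = bh_adjust(out["p_enrich"])
    out["q_deplete"] = bh_adjust(out["p_deplete"])
    return out
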