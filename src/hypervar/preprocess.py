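"""Value-scale transforms and feature-filtering rules.

Expression matrices enter as exon-based read counts per gene and are
log-transformed as ``log2(x + 1)``. Methylation values move between the
beta scale (proportion methylated, used for display) and the M scale
(log2 ratio of methylated to unmethylated intensity, used for analysis).

Filtering implements two rule sets:

* genes are kept only when robustly expressed (in at least half of the
  samples of *every* cell type) and protein-coding;
* 450K-style probes are dropped when any of six QC criteria fires
  (detection p, bead count, sex chromosome, ambiguous mapping, non-CG
  probe, SNP within 2 bp of the probed CG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CpGAnnotation, OmicsMatrix, Scale

__all__ = [
    "log_transform",
    "beta_to_m",
    "m_to_beta",
    "filter_genes",
    "filter_probes",
    "ProbeFilterReport",
]

#: Beta values of exactly 0/1 are clamped away from the boundary before the
#: logit-like M transform.
BETA_EPS = 1e-6

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


def log_transform(counts: OmicsMatrix) -> OmicsMatrix:
    """log2(x + 1) transform of a count matrix."""
    if counts.scale is not Scale.counts:
        raise ValueError(f"expected a counts matrix, got scale={counts.scale.value}")
    vals = counts.values.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("counts must be nonnegative")
    out = pd.DataFrame(
        np.log2(vals + 1.0), index=counts.feature_ids, columns=counts.sample_ids
    )
    return OmicsMatrix(out, Scale.log2_expression)


def beta_to_m(beta: OmicsMatrix, eps: float = BETA_EPS) -> OmicsMatrix:
    """Convert methylation beta values to M values: M = log2(b / (1 - b))."""
    if beta.scale is not Scale.beta_value:
        raise ValueError(f"expected a beta-value matrix, got scale={beta.scale.value}")
    b = beta.values.to_numpy(dtype=float)
    if np.nanmin(b) < 0 or np.nanmax(b) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    out = pd.DataFrame(m, index=beta.feature_ids, columns=beta.sample_ids)
    return OmicsMatrix(out, Scale.m_value)


def m_to_beta(m: OmicsMatrix) -> OmicsMatrix:
    """Inverse of :func:`beta_to_m`: beta = 2^M / (2^M + 1)."""
    if m.scale is not Scale.m_value:
        raise ValueError(f"expected an M-value matrix, got scale={m.scale.value}")
    vals = m.values.to_numpy(dtype=float)
    # logistic on the log2 scale, computed stably for large |M|
    beta = 1.0 / (1.0 + np.exp2(-vals))
    out = pd.DataFrame(beta, index=m.feature_ids, columns=m.sample_ids)
    return OmicsMatrix(out, Scale.beta_value)


def filter_genes(
    logexpr: Mapping[str, OmicsMatrix],
    annotation: pd.DataFrame,
    min_fraction: float = 0.5,
    expressed_count_min: float = 1.0,
) -> pd.Index:
    """Keep protein-coding genes robustly expressed in every cell type.

    Parameters
    ----------
    logexpr
        Mapping cell type -> log2(count+1) matrix over a shared feature
        universe.
    annotation
        Gene annotation with columns ``feature_id`` and ``biotype``.
    min_fraction
        Fraction of samples per cell type in which the gene must be
        expressed (default one half).
    expressed_count_min
        A gene counts as expressed in a sample when its raw count is at
        least this value, i.e. its log2(count+1) value is at least
        ``log2(expressed_count_min + 1)``.
    """
    if "biotype" not in annotation.columns:
        raise ValueError("gene annotation must have a 'biotype' column")
    if not logexpr:
        raise ValueError("no expression matrices given")
    mats = list(logexpr.values())
    features = mats[0].feature_ids
    for m in mats[1:]:
        if not features.equals(m.feature_ids):
            raise ValueError("cell types must share the same feature universe")
    threshold = np.log2(expressed_count_min + 1.0)
    keep = np.ones(len(features), dtype=bool)
    for m in mats:
        frac = (m.values.to_numpy() >= threshold).mean(axis=1)
        keep &= frac >= min_fraction
    biotype = annotation.set_index("feature_id")["biotype"].reindex(features)
    keep &= (biotype == "protein_coding").to_numpy()
    return features[keep]


@dataclass
class ProbeFilterReport:
    """Probe ids kept plus per-criterion drop counts.

    ``dropped_by`` counts every criterion a probe fails (a probe can fail
    several), while ``n_dropped`` counts unique dropped probes.
    """

    kept: pd.Index
    dropped_by: dict
    n_input: int

    @property
    def n_dropped(self) -> int:
        return self.n_input - len(self.kept)


def filter_probes(
    meth: OmicsMatrix,
    annotation: CpGAnnotation,
    detection_p_max: float = 0.01,
    bead_count_min: int = 3,
    bead_fail_fraction: float = 0.05,
    snp_maf_min: float = 0.05,
) -> ProbeFilterReport:
    """Apply the six probe-level QC exclusion criteria.

    A probe is dropped if ANY of the following holds:

    1. detection p >= ``detection_p_max`` in at least one sample;
    2. bead count below ``bead_count_min`` in at least
       ``bead_fail_fraction`` of samples;
    3. the probe maps to a sex chromosome;
    4. the probe has an ambiguous genomic mapping;
    5. the probe is a non-CG probe;
    6. a SNP with MAF >= ``snp_maf_min`` lies within 2 bp of the probed CG.
    """
    tab = annotation.table.set_index("feature_id").reindex(meth.feature_ids)
    if annotation.detection_p is None or annotation.bead_count is None:
        raise ValueError("probe QC requires detection_p and bead_count matrices")
    det = annotation.detection_p.reindex(index=meth.feature_ids, columns=meth.sample_ids)
    beads = annotation.bead_count.reindex(index=meth.feature_ids, columns=meth.sample_ids)
    if det.isna().any().any() or beads.isna().any().any():
        raise ValueError("QC matrices must cover every probe and sample")

    fails = {
        "detection_p": (det.to_numpy() >= detection_p_max).any(axis=1),
        "bead_count": (beads.to_numpy() < bead_count_min).mean(axis=1) >= bead_fail_fraction,
        "sex_chromosome": tab["chromosome"].isin(SEX_CHROMOSOMES).to_numpy(),
        "ambiguous_mapping": tab.get("ambiguous_mapping", pd.Series(False, index=tab.index))
        .fillna(False)
        .astype(bool)
        .to_numpy(),
        "non_cg": tab.get("non_cg", pd.Series(False, index=tab.index))
        .fillna(False)
        .astype(bool)
        .to_numpy(),
        "snp_within_2bp": (tab.get("snp_maf", pd.Series(np.nan, index=tab.index)).to_numpy() >= snp_maf_min),
    }
    any_fail = np.zeros(len(meth.feature_ids), dtype=bool)
    counts = {}
    for name, mask in fails.items():
        counts[name] = int(mask.sum())
        any_fail |= mask
    return ProbeFilterReport(
        kept=meth.feature_ids[~any_fail], dropped_by=counts, n_input=len(meth.feature_ids)
    )
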