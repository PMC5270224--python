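"""Core in-memory containers shared across the analysis stages.

The package works on feature-by-sample matrices (log2 expression or
methylation M values), a cohort design table that records how samples from
the same donor pair up across cell types, and small annotation tables.
All containers are thin wrappers over pandas objects so that they can be
round-tripped through TSV without loss.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "OmicsMatrix",
    "CohortDesign",
    "CpGAnnotation",
    "PROMOTER_ELEMENTS",
    "BODY_ELEMENTS",
    "GENOMIC_FEATURES",
    "GENE_ELEMENTS",
    "CHROMATIN_STATES",
]

#: Gene elements counted as promoter-proximal when linking CpGs to genes
#: (manifest categories TSS1500, TSS200, 5'UTR and first exon).
PROMOTER_ELEMENTS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})

#: Gene elements counted as gene body (body and 3'UTR).
BODY_ELEMENTS = frozenset({"Body", "3UTR"})

#: Closed vocabulary of CpG genomic-feature categories.
GENOMIC_FEATURES = ("island", "shore", "shelf", "open_sea")

#: Closed vocabulary of gene-element categories.
GENE_ELEMENTS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "intergenic")

#: Closed five-state chromatin vocabulary used for consensus calling.
CHROMATIN_STATES = ("promoter", "enhancer", "elongation", "polycomb", "heterochromatin")


class Scale(str, enum.Enum):
    """Value scale of an omics matrix."""

    counts = "counts"
    log2_expression = "log2_expression"
    m_value = "m_value"
    beta_value = "beta_value"


@dataclass
class OmicsMatrix:
    """A feature x sample numeric matrix with an explicit value scale.

    Parameters
    ----------
    values
        DataFrame with feature ids as the index and sample ids as columns.
    scale
        One of :class:`Scale`. Beta-value matrices are checked to lie in
        ``[0, 1]``.
    """

    values: pd.DataFrame
    scale: Scale

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("matrix values must be numeric")
        if self.scale is Scale.beta_value:
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("beta values must lie in [0, 1]")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, features=None, samples=None) -> "OmicsMatrix":
        """Return a new matrix restricted to the given features/samples."""
        vals = self.values
        if features is not None:
            vals = vals.loc[list(features)]
        if samples is not None:
            vals = vals.loc[:, list(samples)]
        return OmicsMatrix(vals, self.scale)


@dataclass
class CohortDesign:
    """Sample sheet: one row per (donor, cell type) sample.

    Columns: ``sample_id, donor_id, cell_type, sex, age, collection_date``.
    (donor, cell type) is unique; this is what makes paired contrasts
    across cell types possible.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "donor_id", "cell_type", "sex", "age", "collection_date")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        if self.table.duplicated(subset=["donor_id", "cell_type"]).any():
            raise ValueError("(donor_id, cell_type) must be unique")

    @property
    def cell_types(self) -> list[str]:
        return list(pd.unique(self.table["cell_type"]))

    @property
    def donors(self) -> list[str]:
        return list(pd.unique(self.table["donor_id"]))

    def samples(self, cell_type: str) -> pd.DataFrame:
        """Rows for one cell type, ordered by donor id."""
        sub = self.table[self.table["cell_type"] == cell_type]
        if sub.empty:
            raise KeyError(f"no samples for cell type {cell_type!r}")
        return sub.sort_values("donor_id").reset_index(drop=True)

    def paired_samples(self, cell_a: str, cell_b: str) -> pd.DataFrame:
        """Complete donor pairs across two cell types.

        Returns a frame with columns ``donor_id, sample_a, sample_b``;
        donors missing either sample are dropped.
        """
        a = self.samples(cell_a)[["donor_id", "sample_id"]].rename(
            columns={"sample_id": "sample_a"}
        )
        b = self.samples(cell_b)[["donor_id", "sample_id"]].rename(
            columns={"sample_id": "sample_b"}
        )
        return a.merge(b, on="donor_id", how="inner").sort_values("donor_id").reset_index(drop=True)

    def donor_attr(self, column: str) -> pd.Series:
        """Per-donor value of a donor-level column (sex, age, date)."""
        sub = self.table.drop_duplicates("donor_id").set_index("donor_id")
        return sub[column]


@dataclass
class CpGAnnotation:
    """Annotation bundle for methylation probes.

    ``table`` has one row per probe with columns: ``feature_id, chromosome,
    genomic_feature, gene_element, gene_id, ambiguous_mapping, non_cg,
    snp_maf`` (NaN when no SNP within 2 bp). ``detection_p`` and
    ``bead_count`` are probe x sample QC matrices. ``state_calls`` maps each
    cell type to a long frame (region_id, replicate_id, state) of
    chromatin-state calls over biological replicates.
    """

    table: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    bead_count: pd.DataFrame | None = None
    state_calls: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ("feature_id", "chromosome", "genomic_feature", "gene_element")
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"CpG annotation missing columns: {missing}")
        if self.table["feature_id"].duplicated().any():
            raise ValueError("duplicate probe ids in annotation")
        bad = set(self.table["genomic_feature"]) - set(GENOMIC_FEATURES)
        if bad:
            raise ValueError(f"unknown genomic features: {sorted(bad)}")
        bad = set(self.table["gene_element"]) - set(GENE_ELEMENTS)
        if bad:
            raise ValueError(f"unknown gene elements: {sorted(bad)}")
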