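"""TSV/YAML serialization of cohorts, tables and configs.

Matrices are written features-in-rows with the sample ids as header; the
sample sheet, truth table and all result tables are plain TSV; configs are
YAML. Writing is deterministic (fixed column order, fixed float format) so
identical cohorts serialize to identical bytes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .containers import OmicsMatrix, Scale
from .synthetic import SimConfig, SyntheticCohort

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_table",
    "read_table",
    "write_config",
    "read_config",
    "write_cohort",
]

FLOAT_FORMAT = "%.10g"


def write_matrix(matrix: OmicsMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path, scale: Scale | str) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return OmicsMatrix(df, Scale(scale))


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_config(config: SimConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["injected_sets"] = [dataclasses.asdict(s) for s in config.injected_sets]
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(data), fh, sort_keys=True)


def _plain(obj):
    """Recursively convert tuples/numpy scalars to YAML-friendly types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def read_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimConfig(**data)


def write_cohort(cohort: SyntheticCohort, outdir) -> list[Path]:
    """Serialize a synthetic cohort to a directory of TSV/YAML files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(fn, name):
        path = outdir / name
        fn(path)
        written.append(path)

    for ct, mat in cohort.expression.items():
        _w(lambda p, m=mat: write_matrix(m, p), f"expression_{ct}.tsv")
    for ct, mat in cohort.methylation.items():
        _w(lambda p, m=mat: write_matrix(m, p), f"methylation_{ct}.tsv")
    _w(lambda p: write_table(cohort.design.table, p), "samples.tsv")
    _w(lambda p: write_table(cohort.traits.reset_index(), p), "traits.tsv")
    _w(lambda p: cohort.weather.to_csv(p, index=False, float_format=FLOAT_FORMAT), "weather.csv")
    _w(lambda p: write_table(cohort.gene_annotation, p), "gene_annotation.tsv")
    _w(lambda p: write_table(cohort.cpg_annotation.table, p), "cpg_annotation.tsv")
    _w(lambda p: write_table(cohort.truth, p), "truth.tsv")
    _w(lambda p: write_config(cohort.config, p), "config.yaml")
    return written
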