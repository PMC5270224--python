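"""End-to-end orchestration of the differential-variability analysis.

A single configuration drives either a simulated cohort or file inputs
through: preprocessing/filtering -> per-cell-type variability tables ->
paired moderated differential-variability tests on all three cell-type
pairs -> combined hypervariability calls and mutually exclusive
classification -> rank-based common list -> sex-specific differential
expression -> trait/weather associations -> CpG annotation enrichment ->
co-expression network modules. Every stage writes its result table to the
output directory and the manifest records all parameters and the seed, so
a rerun with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import binned_profile, interpolate_missing, meth_expr_link, spearman_assoc
from .containers import CohortDesign, OmicsMatrix, Scale
from .difftest import (
    bh_adjust,
    classify_features,
    combined_decision,
    paired_diffvar_test,
    rank_common,
    sex_diff_expression,
)
from .enrichment import consensus_states, enrichment_by_system
from .io import write_table
from .netmod import build_network, detect_modules
from .preprocess import filter_genes, filter_probes
from .synthetic import SimConfig, simulate_cohort, truth_eval
from .variability import variability_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "summarize_counts", "analyze_assay"]

log = logging.getLogger("hypervar.pipeline")


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run."""

    simulate: SimConfig | None = None
    outdir: str = "hypervar_out"
    alpha: float = 0.05
    rel_delta: float = 0.10
    lfc_min: float = 1.0
    r_threshold: float = 0.6
    min_module_size: int = 5
    bin_size: int = 100
    n_resamples: int = 1000
    n_common: int | None = None
    expressed_count_min: float = 1.0
    stages: tuple = (
        "preprocess",
        "variability",
        "difftest",
        "sex_de",
        "associate",
        "enrich",
        "network",
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        sim = data.pop("simulate", None)
        cfg = cls(**data)
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            cfg.simulate = SimConfig(**sim)
        return cfg


@dataclass
class PipelineResult:
    """In-memory bundle of the main result tables."""

    var_tables: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    common: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    sex_de: dict = field(default_factory=dict)
    associations: pd.DataFrame | None = None
    meth_expr: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    modules: list = field(default_factory=list)
    recovery: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def summarize_counts(classification: pd.DataFrame, n_common: int | None = None) -> pd.DataFrame:
    """Per-label counts of a classification table (plus the common-list size).

    Counts over all labels including ``none`` sum to the feature total.
    """
    counts = classification["label"].value_counts().rename_axis("label").reset_index(name="n")
    if n_common is not None:
        counts = pd.concat(
            [counts, pd.DataFrame([{"label": "common", "n": n_common}])], ignore_index=True
        )
    return counts.sort_values("label").reset_index(drop=True)


def analyze_assay(
    matrices: dict,
    design: CohortDesign,
    cell_types,
    alpha: float = 0.05,
    rel_delta: float = 0.10,
    n_common: int | None = None,
):
    """Variability tables, three paired contrasts, classification and the
    rank-based common list for one assay.

    Returns ``(var_tables, absdevs, contrasts, classification, common)``
    where ``contrasts`` maps each cell-type pair to its full result table.
    """
    cell_types = list(cell_types)
    var_tables, absdevs = {}, {}
    for ct in cell_types:
        tab, absdev = variability_table(matrices[ct], design, ct)
        var_tables[ct] = tab
        absdevs[ct] = absdev
    contrasts = {}
    calls = {}
    a, b, c = cell_types
    for ct_a, ct_b in ((a, b), (a, c), (b, c)):
        pairing = design.paired_samples(ct_a, ct_b)
        res = paired_diffvar_test(absdevs[ct_a], absdevs[ct_b], pairing)
        res["q"] = bh_adjust(res["p"])
        ev_a = var_tables[ct_a]["ev"].to_numpy()
        ev_b = var_tables[ct_b]["ev"].to_numpy()
        call = combined_decision(
            res["q"], ev_a, ev_b, res["mean_absdev_diff"], ct_a, ct_b, alpha, rel_delta
        )
        res = res.assign(
            cell_a=ct_a, cell_b=ct_b, ev_a=ev_a, ev_b=ev_b, ev_diff=ev_a - ev_b, call=call
        )
        contrasts[(ct_a, ct_b)] = res
        calls[(ct_a, ct_b)] = pd.Series(call.to_numpy(), index=pd.Index(res["feature_id"]))
    classification = classify_features(calls, cell_types)
    if n_common is None:
        sizes = classification.loc[classification["label"] != "none", "label"].value_counts()
        n_common = int(round(sizes.mean())) if len(sizes) else 0
    n_common = min(n_common, len(classification))
    ranked = {ct: var_tables[ct] for ct in cell_types}
    common = rank_common(ranked, n_common) if n_common > 0 else pd.Index([])
    return var_tables, absdevs, contrasts, classification, common


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all configured stages and write results to ``config.outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    if config.simulate is None:
        raise ValueError("pipeline requires a simulate block (file-input mode: load "
                         "matrices yourself and call analyze_assay)")

    def stage(name):
        enabled = name in config.stages
        if enabled:
            log.info("stage %s ...", name)
        return enabled

    sim = config.simulate
    cohort = simulate_cohort(sim)
    cell_types = list(sim.cell_types)
    timings = {}

    # ---- preprocess: feature filters -------------------------------------
    t = time.time()
    expr = cohort.expression
    meth = cohort.methylation
    if stage("preprocess"):
        kept_genes = filter_genes(
            expr, cohort.gene_annotation, expressed_count_min=config.expressed_count_min
        )
        probe_report = filter_probes(meth[cell_types[0]], cohort.cpg_annotation)
        kept_probes = probe_report.kept
        expr = {ct: m.subset(features=kept_genes) for ct, m in expr.items()}
        meth = {ct: m.subset(features=kept_probes) for ct, m in meth.items()}
        result.manifest["n_genes_kept"] = len(kept_genes)
        result.manifest["n_probes_kept"] = len(kept_probes)
        result.manifest["probe_drop_counts"] = probe_report.dropped_by
    timings["preprocess"] = time.time() - t

    # ---- variability + difftest per assay --------------------------------
    t = time.time()
    for assay, mats in (("expression", expr), ("methylation", meth)):
        if not stage("variability") and not stage("difftest"):
            continue
        var_tables, absdevs, contrasts, classification, common = analyze_assay(
            mats,
            cohort.design,
            cell_types,
            alpha=config.alpha,
            rel_delta=config.rel_delta,
            n_common=config.n_common,
        )
        result.var_tables[assay] = var_tables
        result.contrasts[assay] = contrasts
        result.classification[assay] = classification
        result.common[assay] = common
        counts = summarize_counts(classification, n_common=len(common))
        result.counts[assay] = counts
        result.recovery[assay] = truth_eval(
            classification, cohort.truth, assay, common_list=common
        )
        write_table(pd.concat(var_tables.values()), outdir / f"variability_{assay}.tsv")
        write_table(
            pd.concat(contrasts.values(), ignore_index=True), outdir / f"contrasts_{assay}.tsv"
        )
        write_table(classification, outdir / f"classification_{assay}.tsv")
        write_table(counts, outdir / f"counts_{assay}.tsv")
        pd.Series(common, name="feature_id").to_csv(
            outdir / f"common_{assay}.tsv", sep="\t", index=False
        )
    timings["difftest"] = time.time() - t

    # ---- sex-specific differential expression ----------------------------
    t = time.time()
    if stage("sex_de"):
        for ct in cell_types:
            de = sex_diff_expression(
                expr[ct], cohort.design, ct, lfc_min=config.lfc_min, alpha=config.alpha
            )
            result.sex_de[ct] = de
        write_table(pd.concat(result.sex_de.values(), ignore_index=True), outdir / "sex_de.tsv")
    timings["sex_de"] = time.time() - t

    # ---- trait and seasonal associations ---------------------------------
    t = time.time()
    if stage("associate") and "expression" in result.classification:
        cls = result.classification["expression"]
        assoc_frames = []
        weather = cohort.weather.set_index("date")
        filled = pd.DataFrame(
            {c: interpolate_missing(weather[c]) for c in ("tmin", "tmax", "daylight_hours")}
        )
        donor_dates = pd.to_datetime(cohort.design.donor_attr("collection_date"))
        weather_traits = filled.reindex(donor_dates.to_numpy()).set_axis(donor_dates.index)
        traits = cohort.traits.join(weather_traits)
        for ct in cell_types:
            hv = cls.loc[cls["label"].str.contains(ct, regex=False), "feature_id"]
            if hv.empty:
                continue
            sample_map = cohort.design.samples(ct).set_index("sample_id")["donor_id"]
            feats = expr[ct].values.loc[hv]
            feats = feats.rename(columns=sample_map)
            assoc_frames.append(spearman_assoc(feats, traits, cell_type=ct))
        if assoc_frames:
            result.associations = pd.concat(assoc_frames, ignore_index=True)
            write_table(result.associations, outdir / "trait_associations.tsv")
    if stage("associate") and "methylation" in result.classification:
        cls_m = result.classification["methylation"]
        ct = cell_types[1]  # the cell type with injected hypervariability by convention
        hv = cls_m.loc[cls_m["label"] != "none", "feature_id"]
        sample_map = cohort.design.samples(ct).set_index("sample_id")["donor_id"]
        meth_d = meth[ct].subset(samples=sample_map.index)
        meth_d = OmicsMatrix(meth_d.values.rename(columns=sample_map), Scale.m_value)
        expr_d = expr[ct].subset(samples=sample_map.index)
        expr_d = OmicsMatrix(expr_d.values.rename(columns=sample_map), Scale.log2_expression)
        for region in ("promoter", "body"):
            table, props = meth_expr_link(
                meth_d,
                expr_d,
                cohort.cpg_annotation.table,
                region,
                cpg_ids=hv if len(hv) else None,
                alpha=config.alpha,
            )
            result.meth_expr[region] = {"table": table, "proportions": props}
            if len(table):
                write_table(table, outdir / f"meth_expr_{region}.tsv")
        # MV-vs-EV binned profile at promoters (gene-level MV = mean over
        # the gene's promoter CpGs)
        ann = cohort.cpg_annotation.table
        mv = result.var_tables["methylation"][ct].set_index("feature_id")["ev"]
        ev = result.var_tables["expression"][ct].set_index("feature_id")["ev"]
        prom = ann[ann["gene_element"].isin(("TSS1500", "TSS200", "5UTR", "1stExon"))]
        prom = prom[prom["gene_id"].notna() & prom["feature_id"].isin(mv.index)]
        gene_mv = mv.reindex(prom["feature_id"]).groupby(prom["gene_id"].to_numpy()).mean()
        shared = gene_mv.index.intersection(ev.index)
        if len(shared) >= config.bin_size:
            profile = binned_profile(gene_mv.loc[shared], ev.loc[shared], config.bin_size)
            result.meth_expr["mv_ev_profile"] = profile
            write_table(profile, outdir / "mv_ev_profile.tsv")
    timings["associate"] = time.time() - t

    # ---- CpG annotation enrichment ---------------------------------------
    t = time.time()
    if stage("enrich") and "methylation" in result.classification:
        cls_m = result.classification["methylation"]
        ct = cell_types[1]
        hvp = cls_m.loc[cls_m["label"] == f"specific:{ct}", "feature_id"]
        if hvp.empty:
            hvp = cls_m.loc[cls_m["label"] != "none", "feature_id"]
        if not hvp.empty:
            ann = cohort.cpg_annotation.table.set_index("feature_id")
            kept = meth[ct].feature_ids
            ann = ann.reindex(kept)
            systems = {
                "genomic_feature": ann["genomic_feature"],
                "gene_element": ann["gene_element"],
            }
            calls = cohort.cpg_annotation.state_calls.get(ct)
            if calls is not None:
                states = consensus_states(calls[calls["region_id"].isin(kept)])
                systems["chromatin_state"] = states.reindex(kept)
            for system, background in systems.items():
                res = enrichment_by_system(
                    hvp, background, n_resamples=config.n_resamples, seed=config.seed
                )
                result.enrichment[system] = res
                write_table(res, outdir / f"enrichment_{system}.tsv")
    timings["enrich"] = time.time() - t

    # ---- co-expression network -------------------------------------------
    t = time.time()
    if stage("network") and "expression" in result.classification:
        cls = result.classification["expression"]
        ct = cell_types[1]
        genes = cls.loc[cls["label"] == f"specific:{ct}", "feature_id"]
        if len(genes) >= 3:
            ev = result.var_tables["expression"][ct].set_index("feature_id")["ev"]
            samples = cohort.design.samples(ct)["sample_id"]
            net = build_network(
                expr[ct].values.loc[genes, samples], config.r_threshold, ev=ev
            )
            result.modules = detect_modules(net, min_size=config.min_module_size)
            edges = pd.DataFrame(
                [(u, v, d["r"]) for u, v, d in net.edges(data=True)],
                columns=["gene_a", "gene_b", "r"],
            )
            write_table(edges, outdir / "network_edges.tsv")
            membership = pd.DataFrame(
                [
                    (g, i)
                    for i, mod in enumerate(result.modules)
                    for g in sorted(mod)
                ],
                columns=["feature_id", "module"],
            )
            write_table(membership, outdir / "network_modules.tsv")
    timings["network"] = time.time() - t

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": _manifest_params(config),
        "stages": list(config.stages),
    }
    result.manifest.update(manifest)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
    # timings are logged, never written: the manifest must be reproducible
    result.manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    result.manifest["total_s"] = round(time.time() - t0, 3)
    for name, dt in timings.items():
        log.info("stage %s took %.2fs", name, dt)
    return result


def _manifest_params(config: PipelineConfig) -> dict:
    data = dataclasses.asdict(config)
    data.pop("outdir", None)  # output location, not an analysis parameter
    if config.simulate is not None:
        sim = dataclasses.asdict(config.simulate)
        sim["injected_sets"] = [dataclasses.asdict(s) for s in config.simulate.injected_sets]
        data["simulate"] = sim
    return data
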