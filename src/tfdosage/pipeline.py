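"""End-to-end pipeline: simulate -> preprocess -> effects -> dose-response
-> downstream, with one global seed, stage toggles and a machine-readable
run report whose cell counts reconcile across stage boundaries.

The global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``, so stages are individually
reproducible.  All tabular outputs are TSV; identical (config, seed)
yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import downstream as ds
from . import effects as fx
from . import io as dio
from . import preprocess as pp
from . import simdata as sd
from .doseresponse import DEFAULT_GRID, DEFAULT_RESTRICTED_BOUNDS, \
    fit_network, network_predictions

__version__ = "0.1.0"

STAGES = ("simulate", "preprocess", "effects", "doseresponse", "downstream")


@dataclass
class PipelineConfig:
    """All pipeline thresholds with their conventional defaults."""

    stages: tuple = STAGES
    seed: int = 0
    input_dir: str | None = None     # read a dataset instead of simulating
    # QC
    min_umi: int = 500               # strict "less than" minimum
    min_genes: int = 50
    top_umi_fraction: float = 0.01
    scale_factor: float = 10_000.0
    modality_trim_fraction: float = 0.05
    # effects
    ntc_fdr_cutoff: float = 0.05
    epsilon: float = 1e-9
    # dose response
    folds: int = 10
    range_threshold: float = 0.05
    responsive_fdr_cutoff: float = 0.05
    loess_span: float = 0.75
    loess_degree: int = 2
    nonmono_quantile: float = 0.95
    nonmono_prominence: float = 0.05
    grid_min: float = DEFAULT_GRID[0]
    grid_max: float = DEFAULT_GRID[1]
    grid_points: int = DEFAULT_GRID[2]
    restricted_bounds: tuple = DEFAULT_RESTRICTED_BOUNDS
    # downstream
    n_clusters: int = 6
    enrichment_delta_aic: float = 0.0
    celltype_fdr_cutoff: float = 0.10
    summary_fdr_cutoff: float = 0.05
    simulation: sd.SimulationConfig = field(default_factory=sd.SimulationConfig)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["restricted_bounds"] = list(d["restricted_bounds"])
        d["simulation"]["modality_set"] = list(d["simulation"]["modality_set"])
        d["simulation"]["baseline_mean_range"] = list(
            d["simulation"]["baseline_mean_range"])
        if d["simulation"]["ntc_offtarget_spec"] is not None:
            s = d["simulation"]["ntc_offtarget_spec"]
            d["simulation"]["ntc_offtarget_spec"] = [
                s[0], list(s[1]), s[2], s[3]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("simulation", {})
        sim["modality_set"] = tuple(sim.get("modality_set", sd.MODALITIES))
        sim["baseline_mean_range"] = tuple(
            sim.get("baseline_mean_range", (1.0, 30.0)))
        if sim.get("ntc_offtarget_spec") is not None:
            s = sim["ntc_offtarget_spec"]
            sim["ntc_offtarget_spec"] = (s[0], tuple(s[1]), s[2], s[3])
        d["stages"] = tuple(d.get("stages", STAGES))
        d["restricted_bounds"] = tuple(
            d.get("restricted_bounds", DEFAULT_RESTRICTED_BOUNDS))
        return cls(simulation=sd.SimulationConfig(**sim), **d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Check every config invariant; violations are data, not exceptions."""
    v = []
    for s in config.stages:
        if s not in STAGES:
            v.append(f"unknown stage {s!r}")
    if config.folds < 2:
        v.append(f"folds={config.folds}: folds >= 2 required")
    if config.grid_min > config.grid_max:
        v.append(f"grid_min={config.grid_min} > grid_max={config.grid_max}")
    if config.grid_points < 2:
        v.append("grid_points >= 2 required")
    if not 0 < config.scale_factor:
        v.append("scale_factor must be > 0")
    for name in ("top_umi_fraction", "modality_trim_fraction",
                 "ntc_fdr_cutoff", "responsive_fdr_cutoff",
                 "celltype_fdr_cutoff", "summary_fdr_cutoff"):
        val = getattr(config, name)
        if not 0 <= val <= 1:
            v.append(f"{name}={val} outside [0, 1]")
    if not 0 < config.loess_span <= 1:
        v.append("loess_span must be in (0, 1]")
    if config.loess_degree not in (1, 2):
        v.append("loess_degree must be 1 or 2")
    if config.n_clusters < 1:
        v.append("n_clusters >= 1 required")
    if config.restricted_bounds[0] >= config.restricted_bounds[1]:
        v.append("restricted_bounds must be increasing")
    v.extend(config.simulation.validate())
    return v


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % 2**31)
            for s, c in zip(STAGES, children)}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the enabled stages; returns the run report dict.

    Stage outputs land under ``out_dir/<stage>/``; the report (stage
    record counts, attrition, wall time, seed, config hash) is written to
    ``out_dir/report.json``.  On a stage failure, partial outputs are
    retained and the report marks the failure point.
    """
    problems = validate_config(config)
    if problems:
        raise sd.ConfigurationError("; ".join(problems))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report = {"seed": config.seed, "config_hash": config.config_hash(),
              "version": __version__, "stages": {}, "failed_stage": None}
    state: dict = {}
    t0 = time.time()
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            t_stage = time.time()
            rec = _run_stage(stage, config, seeds[stage], out_dir, state)
            rec["wall_time_s"] = round(time.time() - t_stage, 3)
            report["stages"][stage] = rec
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = f"{type(exc).__name__}: {exc}"
        _dump_report(report, out_dir, t0)
        raise
    _dump_report(report, out_dir, t0)
    return report


def _dump_report(report, out_dir, t0):
    report["total_wall_time_s"] = round(time.time() - t0, 3)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)


def _run_stage(stage, config, seed, out_dir, state):
    if stage == "simulate":
        return _stage_simulate(config, seed, out_dir, state)
    if stage == "preprocess":
        return _stage_preprocess(config, seed, out_dir, state)
    if stage == "effects":
        return _stage_effects(config, out_dir, state)
    if stage == "doseresponse":
        return _stage_doseresponse(config, seed, out_dir, state)
    return _stage_downstream(config, seed, out_dir, state)


def _stage_simulate(config, seed, out_dir, state):
    sim = dataclasses.replace(config.simulation, seed=seed)
    dataset = sd.simulate_dataset(sim)
    dio.write_dataset(dataset, out_dir / "simulated")
    state["dataset"] = dataset
    state["sim_config"] = sim
    return {"cells_out": dataset.n_cells(),
            "genes": len(dataset.gene_ids),
            "guides": len(dataset.guide_meta)}


def _stage_preprocess(config, seed, out_dir, state):
    if "dataset" not in state:
        if config.input_dir is None:
            raise sd.ConfigurationError(
                "preprocess needs a simulated dataset or input_dir")
        state["dataset"] = dio.read_dataset(config.input_dir)
    data = state["dataset"]
    cells_in = data.n_cells()

    counts, kept_ids, qc_report = pp.qc_filter_cells(
        data.counts, data.cell_ids, min_umi=config.min_umi,
        min_genes=config.min_genes, top_fraction=config.top_umi_fraction)
    pos = {c: i for i, c in enumerate(data.cell_ids)}
    kept_idx = [pos[c] for c in kept_ids]
    guide_counts = data.guide_counts[:, kept_idx]

    calls = pp.call_guides_gmm(
        guide_counts, list(data.guide_meta["guide_id"]), kept_ids,
        random_state=seed)
    single = pp.filter_single_guide(calls, kept_ids)

    norm, norm_ids = pp.normalize_log1p(counts, kept_ids,
                                        scale_factor=config.scale_factor)
    marker_ids = dict(sd.MARKER_GENES)
    modality = pp.assign_modality(
        norm, data.gene_ids, norm_ids, marker_ids,
        trim_fraction=config.modality_trim_fraction)

    cells = (single.merge(modality, on="cell_id", how="inner")
             .set_index("cell_id"))
    keep = ((cells["status"] == "kept")
            & (~cells["modality_trimmed"])).reindex(norm_ids).fillna(False)
    final_ids = [c for c in norm_ids if keep[c]]
    col = {c: i for i, c in enumerate(norm_ids)}
    final_pos = [col[c] for c in final_ids]
    state["norm"] = norm[:, final_pos]
    state["gene_ids"] = data.gene_ids
    cell_table = cells.loc[final_ids].reset_index()[
        ["cell_id", "guide_id", "modality"]].reset_index(drop=True)
    state["cells"] = cell_table

    qc_out = qc_report.merge(
        single[["cell_id", "status", "n_guides"]], on="cell_id", how="left")
    qc_out = qc_out.merge(
        modality[["cell_id", "modality", "modality_trimmed"]],
        on="cell_id", how="left")
    qc_out["final_kept"] = qc_out["cell_id"].isin(set(final_ids))
    _write_tsv(qc_out, out_dir / "preprocess" / "cell_qc.tsv")
    # attrition counted sequentially over disjoint reasons so that
    # cells_in - sum(attrition) == cells_out exactly
    in_norm = cells  # indexed by cell_id, one row per normalized cell
    attrition = {
        "qc_min_umi": int((qc_report["removal_reason"] == "min_umi").sum()),
        "qc_min_genes": int((qc_report["removal_reason"] == "min_genes").sum()),
        "qc_top_umi": int((qc_report["removal_reason"] == "top_umi").sum()),
        "zero_total": len(kept_ids) - len(norm_ids),
        "no_guide": int((in_norm["status"] == "no_guide").sum()),
        "multi_guide": int((in_norm["status"] == "multi_guide").sum()),
        "modality_trim": int(
            in_norm.loc[in_norm["status"] == "kept",
                        "modality_trimmed"].sum()),
    }
    return {"cells_in": cells_in, "cells_out": len(final_ids),
            "attrition": attrition}


def _stage_effects(config, out_dir, state):
    data = state["dataset"]
    cells = state["cells"]
    kept_ntc, ntc_report = fx.filter_ntc_offtargets(
        state["norm"], state["gene_ids"], cells, data.guide_meta,
        fdr_cutoff=config.ntc_fdr_cutoff)
    effects = fx.compute_fold_changes(
        state["norm"], state["gene_ids"], cells, kept_ntc, data.guide_meta,
        epsilon=config.epsilon)
    state["effects"] = effects
    state["kept_ntc"] = kept_ntc
    _write_tsv(effects, out_dir / "effects" / "effects.tsv")
    with open(out_dir / "effects" / "ntc_report.json", "w") as fh:
        json.dump(ntc_report, fh, indent=1, default=str)
    return {"cells_in": len(cells), "cells_out": len(cells),
            "n_tests": len(effects),
            "kept_ntc": {m: list(v) for m, v in kept_ntc.items()}}


def _network_cis_genes(config, state):
    sim = state.get("sim_config", config.simulation)
    cis = sim.cis_gene_ids()
    present = set(state["dataset"].guide_meta["target_cis_gene"].dropna())
    cis = [g for g in cis if g in present]
    if sim.control_cis_gene and len(cis) > 1:
        cis = cis[:-1]     # drop the negative-control network
    return cis


def _stage_doseresponse(config, seed, out_dir, state):
    effects = state["effects"]
    sim = state.get("sim_config", config.simulation)
    trans_genes = sim.trans_gene_ids()
    grid = np.linspace(config.grid_min, config.grid_max, config.grid_points)
    tables, preds = [], []
    ss = np.random.SeedSequence(seed)
    cis_list = _network_cis_genes(config, state)
    child = {c: int(s.generate_state(1)[0] % 2**31)
             for c, s in zip(cis_list, ss.spawn(len(cis_list)))}
    state["fits"] = {}
    for cis_gene in cis_list:
        table, fits = fit_network(
            effects, cis_gene, trans_genes, folds=config.folds,
            rng_seed=child[cis_gene],
            range_threshold=config.range_threshold,
            fdr_cutoff=config.responsive_fdr_cutoff,
            loess_span=config.loess_span, loess_degree=config.loess_degree,
            nonmono_quantile=config.nonmono_quantile,
            nonmono_prominence=config.nonmono_prominence)
        tables.append(table)
        state["fits"][cis_gene] = (table, fits)
        pred = network_predictions(table, fits, grid)
        pred.insert(0, "cis_gene", cis_gene)
        preds.append(pred.reset_index())
    fit_table = pd.concat(tables, ignore_index=True)
    state["fit_table"] = fit_table
    pred_table = pd.concat(preds, ignore_index=True)
    state["predictions"] = pred_table
    _write_tsv(fit_table, out_dir / "doseresponse" / "fits.tsv")
    _write_tsv(pred_table, out_dir / "doseresponse" / "predictions.tsv")
    return {"cells_in": len(state["cells"]),
            "networks": len(cis_list),
            "genes_fit": int(fit_table["fittable"].sum())}


def _stage_downstream(config, seed, out_dir, state):
    fit_table = state["fit_table"]
    pred = state["predictions"]
    data = state["dataset"]
    ss = np.random.SeedSequence(seed)
    s_ann, s_prof = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2)]

    # prediction matrix: genes x (cis gene grids concatenated)
    wide = pred.set_index(["trans_gene", "cis_gene"]).unstack("cis_gene")
    wide = wide.dropna(axis=0)
    _, _, labels = ds.cluster_responses(wide, k=config.n_clusters)
    cluster_table = labels.reset_index().rename(columns={0: "cluster"})
    _write_tsv(cluster_table, out_dir / "downstream" / "cluster_assignments.tsv")

    annotations = sd.simulate_annotations(data.truth, s_ann)
    prop = ds.test_qualitative_properties(fit_table, annotations)
    quant = ds.correlate_quantitative_properties(fit_table, annotations)
    _write_tsv(prop, out_dir / "downstream" / "property_tests.tsv")
    _write_tsv(quant, out_dir / "downstream" / "quantitative_correlations.tsv")

    gene_sets = {
        "disease": annotations.loc[annotations["disease_linked"], "gene_id"],
        "gwas_wbc": annotations.loc[annotations["gwas_wbc"], "gene_id"],
        "gwas_platelet": annotations.loc[
            annotations["gwas_platelet"], "gene_id"],
        "gwas_rbc": annotations.loc[annotations["gwas_rbc"], "gene_id"],
        "gwas_reticulocyte": annotations.loc[
            annotations["gwas_reticulocyte"], "gene_id"],
    }
    families = {"disease": "disease", "gwas_wbc": "gwas",
                "gwas_platelet": "gwas", "gwas_rbc": "gwas",
                "gwas_reticulocyte": "gwas"}
    enr = ds.enrichment_nonlinear(
        fit_table, gene_sets, families,
        delta_aic_threshold=config.enrichment_delta_aic)
    _write_tsv(enr, out_dir / "downstream" / "enrichment.tsv")

    cis_list = _network_cis_genes(config, state)
    profiles = ds.zscale_profiles(
        sd.simulate_celltype_profiles(state["effects"], cis_list[0], s_prof))
    ct = ds.correlate_celltypes(state["effects"], profiles, cis_list,
                                fdr_cutoff=config.celltype_fdr_cutoff)
    _write_tsv(ct, out_dir / "downstream" / "celltype_correlations.tsv")

    trend, overlap = ds.cis_feature_analysis(
        state["effects"], data.guide_meta, loess_span=config.loess_span)
    _write_tsv(trend, out_dir / "downstream" / "cis_features.tsv")
    if len(overlap):
        _write_tsv(overlap, out_dir / "downstream" / "cis_peak_overlap.tsv")

    sim = state.get("sim_config", config.simulation)
    summaries = pd.concat([
        ds.summarize_global_response(
            state["effects"], cg, sim.trans_gene_ids(),
            fdr_cutoff=config.summary_fdr_cutoff).assign(cis_gene=cg)
        for cg in cis_list], ignore_index=True)
    _write_tsv(summaries, out_dir / "downstream" / "global_summary.tsv")
    return {"cells_in": len(state["cells"]),
            "clusters": int(labels.nunique()),
            "genes_clustered": int(len(wide))}


def check_reconciliation(report: dict) -> list[str]:
    """Verify that cell counts reconcile across stage boundaries."""
    problems = []
    stages = report["stages"]
    chain = [s for s in STAGES if s in stages]
    for up, down in zip(chain, chain[1:]):
        out_n = stages[up].get("cells_out")
        in_n = stages[down].get("cells_in")
        if out_n is not None and in_n is not None and out_n != in_n:
            problems.append(f"{up}.cells_out={out_n} != {down}.cells_in={in_n}")
    pre = stages.get("preprocess")
    if pre is not None:
        att = pre["attrition"]
        expected = pre["cells_in"] - sum(att.values())
        if expected != pre["cells_out"]:
            problems.append(
                f"preprocess attrition does not reconcile: "
                f"{pre['cells_in']} - {sum(att.values())} != {pre['cells_out']}")
    return problems
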