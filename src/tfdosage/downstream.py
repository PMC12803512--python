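"""Downstream analyses of dose-response properties.

Clusters predicted responses across cis-gene networks, relates sigmoid
parameters to qualitative gene flags (Wilcoxon) and quantitative metrics
(Pearson), tests enrichment of nonlinear responses in disease/GWAS gene
sets (Fisher exact), correlates perturbation profiles with cell-type
expression states, and analyses cis determinants of guide efficacy
(distance-to-TSS trend, peak-overlap contrasts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from ._stats import bh_fdr, fisher_exact_with_log_odds, rank_sum_test
from .doseresponse import DELTA_AIC_ENRICHMENT, _loess_predict

SIGMOID_PARAMS = ("a", "b", "c", "d", "range")


def cluster_responses(predictions: pd.DataFrame, k: int = 6,
                      method: str = "complete", metric: str = "euclidean"):
    """Hierarchically cluster genes by their predicted response vectors.

    ``predictions`` is genes x grid points (per-cis-gene grids
    concatenated column-wise; no missing values).  Returns
    ``(leaf_order, linkage_matrix, labels)`` with k-cluster labels from a
    complete-linkage Euclidean dendrogram by default.
    """
    values = predictions.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("predictions contain missing values")
    link = hierarchy.linkage(values, method=method, metric=metric)
    order = [predictions.index[i] for i in hierarchy.leaves_list(link)]
    labels = pd.Series(hierarchy.fcluster(link, t=k, criterion="maxclust"),
                       index=predictions.index, name="cluster")
    return order, link, labels


def _exclusion_mask(fit_table: pd.DataFrame) -> pd.Series:
    """Genes retained for property tests: responsive and monotonic only."""
    keep = fit_table["fittable"].astype(bool)
    keep &= fit_table["responsive"].fillna(False).astype(bool)
    keep &= ~fit_table["nonmonotonic"].fillna(False).astype(bool)
    return keep


def _param_values(fit_table: pd.DataFrame, param: str) -> pd.Series:
    if param == "range":
        vals = fit_table["d"] - fit_table["c"]
    else:
        vals = fit_table[param]
    return pd.Series(vals.to_numpy(), index=fit_table["trans_gene"])


def test_qualitative_properties(fit_table: pd.DataFrame,
                                annotations: pd.DataFrame,
                                flags=None, min_group: int = 3,
                                ) -> pd.DataFrame:
    """Wilcoxon contrasts of sigmoid parameters between flagged gene groups.

    Per network (the fit table's cis gene) and parameter (a, b, c, d and
    the derived range d - c), a two-sided rank-sum test compares flag=yes
    against flag=no genes; non-responsive and non-monotonic genes are
    excluded first.  BH-FDR is applied per network family.
    """
    if flags is None:
        flags = [c for c in annotations.columns
                 if annotations[c].dtype == bool]
    ann = annotations.set_index("gene_id")
    out = []
    for cis_gene, tab in fit_table.groupby("cis_gene"):
        tab = tab[_exclusion_mask(tab)]
        genes = [g for g in tab["trans_gene"] if g in ann.index]
        for param in SIGMOID_PARAMS:
            vals = _param_values(tab, param).loc[genes]
            for flag in flags:
                grp = ann.loc[genes, flag].astype(bool)
                yes = vals[grp.to_numpy()]
                no = vals[~grp.to_numpy()]
                if len(yes) < min_group or len(no) < min_group:
                    out.append({"cis_gene": cis_gene, "parameter": param,
                                "property": flag, "n_yes": len(yes),
                                "n_no": len(no), "mean_diff": np.nan,
                                "p_value": np.nan, "skipped": True})
                    continue
                _, p = rank_sum_test(yes.to_numpy(), no.to_numpy())
                out.append({"cis_gene": cis_gene, "parameter": param,
                            "property": flag, "n_yes": len(yes),
                            "n_no": len(no),
                            "mean_diff": float(yes.mean() - no.mean()),
                            "p_value": p, "skipped": False})
    table = pd.DataFrame(out)
    if len(table):
        table["fdr"] = np.nan
        for cis_gene in table["cis_gene"].unique():
            m = table["cis_gene"] == cis_gene
            table.loc[m, "fdr"] = bh_fdr(table.loc[m, "p_value"].to_numpy())
    return table


def correlate_quantitative_properties(fit_table: pd.DataFrame,
                                      annotations: pd.DataFrame,
                                      metrics=None, min_pairs: int = 5,
                                      ) -> pd.DataFrame:
    """Pearson correlations of sigmoid parameters with gene metrics.

    Pairwise-complete observations; t-distribution p-values; BH-FDR per
    network family; same exclusions as the qualitative tests.
    """
    if metrics is None:
        metrics = [c for c in annotations.columns
                   if annotations[c].dtype != bool and c != "gene_id"]
    ann = annotations.set_index("gene_id")
    out = []
    for cis_gene, tab in fit_table.groupby("cis_gene"):
        tab = tab[_exclusion_mask(tab)]
        genes = [g for g in tab["trans_gene"] if g in ann.index]
        for param in SIGMOID_PARAMS:
            vals = _param_values(tab, param).loc[genes]
            for metric in metrics:
                mv = pd.to_numeric(ann.loc[genes, metric], errors="coerce")
                ok = vals.notna().to_numpy() & mv.notna().to_numpy()
                row = {"cis_gene": cis_gene, "parameter": param,
                       "metric": metric, "n": int(ok.sum())}
                x = vals.to_numpy()[ok]
                y = mv.to_numpy(dtype=float)[ok]
                if ok.sum() < min_pairs or np.std(x) == 0 or np.std(y) == 0:
                    row.update(r=np.nan, p_value=np.nan, skipped=True)
                else:
                    r, p = stats.pearsonr(x, y)
                    row.update(r=float(r), p_value=float(p), skipped=False)
                out.append(row)
    table = pd.DataFrame(out)
    if len(table):
        table["fdr"] = np.nan
        for cis_gene in table["cis_gene"].unique():
            m = table["cis_gene"] == cis_gene
            table.loc[m, "fdr"] = bh_fdr(table.loc[m, "p_value"].to_numpy())
    return table


def enrichment_nonlinear(fit_table: pd.DataFrame, gene_sets: dict,
                         families: dict | None = None,
                         delta_aic_threshold: float = DELTA_AIC_ENRICHMENT,
                         ) -> pd.DataFrame:
    """Fisher enrichment of nonlinear responses in gene sets.

    Per network x gene set: 2x2 table of (dAIC > threshold vs. <=) by
    (in set vs. not) over fittable genes with a defined dAIC; two-sided
    Fisher exact p; log-odds (Haldane +0.5 when a cell is zero, flagged).
    ``families`` maps set name -> family label; BH-FDR runs across sets
    within each (network, family).
    """
    if families is None:
        families = {name: "default" for name in gene_sets}
    out = []
    for cis_gene, tab in fit_table.groupby("cis_gene"):
        tab = tab[tab["fittable"].astype(bool)
                  & np.isfinite(tab["delta_aic"])]
        genes = set(tab["trans_gene"])
        nonlinear = set(
            tab.loc[tab["delta_aic"] > delta_aic_threshold, "trans_gene"])
        for name, members in gene_sets.items():
            members = set(members) & genes
            if not members:
                out.append({"cis_gene": cis_gene, "gene_set": name,
                            "family": families.get(name, "default"),
                            "skipped": True, "p_value": np.nan,
                            "log_odds": np.nan})
                continue
            a = len(nonlinear & members)
            b = len(nonlinear - members)
            c = len(members - nonlinear)
            d = len(genes - nonlinear - members)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                out.append({"cis_gene": cis_gene, "gene_set": name,
                            "family": families.get(name, "default"),
                            "n11": a, "n12": b, "n21": c, "n22": d,
                            "skipped": True, "p_value": np.nan,
                            "log_odds": np.nan})
                continue
            lo, p, corr = fisher_exact_with_log_odds([[a, b], [c, d]])
            out.append({"cis_gene": cis_gene, "gene_set": name,
                        "family": families.get(name, "default"),
                        "n11": a, "n12": b, "n21": c, "n22": d,
                        "log_odds": lo, "p_value": p,
                        "haldane_corrected": corr, "skipped": False})
    table = pd.DataFrame(out)
    if len(table):
        table["fdr"] = np.nan
        for (cis_gene, fam), grp in table.groupby(["cis_gene", "family"]):
            m = (table["cis_gene"] == cis_gene) & (table["family"] == fam)
            table.loc[m, "fdr"] = bh_fdr(table.loc[m, "p_value"].to_numpy())
    return table


def zscale_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-scale cell-type profiles per gene across cell types.

    Genes with zero SD across cell types are left at 0.
    """
    vals = profiles.to_numpy(dtype=float)
    mean = vals.mean(axis=0, keepdims=True)
    sd = vals.std(axis=0, ddof=0, keepdims=True)
    z = np.where(sd > 0, (vals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


def correlate_celltypes(effects: pd.DataFrame, profiles: pd.DataFrame,
                        cis_genes, fdr_cutoff: float = 0.10,
                        min_shared: int = 10) -> pd.DataFrame:
    """Correlate perturbation fold-change vectors with cell-type profiles.

    ``profiles`` is cell types x genes (z-scaled across cell types).  For
    every (guide, modality) perturbation and cell type, the Pearson
    correlation over shared trans genes (cis genes excluded); BH-FDR
    across all pairs at 10% by default.
    """
    shared = [g for g in profiles.columns
              if g in set(effects["gene_id"]) and g not in set(cis_genes)]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared genes (need >= {min_shared})")
    wide = effects.pivot_table(index=["guide_id", "modality"],
                               columns="gene_id", values="log2fc")[shared]
    out = []
    for (guide_id, modality), vec in wide.iterrows():
        v = vec.to_numpy(dtype=float)
        for ct in profiles.index:
            p_vec = profiles.loc[ct, shared].to_numpy(dtype=float)
            ok = np.isfinite(v) & np.isfinite(p_vec)
            if ok.sum() < min_shared or np.std(v[ok]) == 0 \
                    or np.std(p_vec[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(v[ok], p_vec[ok])
            out.append({"guide_id": guide_id, "modality": modality,
                        "cell_type": ct, "r": float(r),
                        "p_value": float(p), "n_genes": int(ok.sum())})
    table = pd.DataFrame(out)
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table["significant"] = table["fdr"] < fdr_cutoff
    return table


def read_bed_intervals(path) -> list[tuple[int, int]]:
    """Read 0-based half-open intervals from a BED file (first 3 columns)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [(int(s), int(e)) for s, e in zip(bed[1], bed[2])]


def cis_feature_analysis(effects: pd.DataFrame, guide_meta: pd.DataFrame,
                         intervals: dict | None = None,
                         loess_span: float = 0.75,
                         trend_classes=("tiling", "TSS"),
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cis determinants of guide efficacy.

    Per modality: a LOESS trend of cis log2FC against TSS offset over
    tiling + TSS guides (attenuated, enhancer and NTC excluded), with the
    trend's extremum offset; and, when ``intervals`` (annotation name ->
    0-based half-open interval list, guide overlap = TSS offset inside an
    interval) is given, a rank-sum contrast of cis log2FC for overlapping
    vs. non-overlapping guides per annotation.

    Returns ``(trend_table, overlap_table)``.
    """
    cis_rows = effects[effects["gene_id"] == effects["target_cis_gene"]]
    merged = cis_rows.merge(
        guide_meta[["guide_id", "guide_class", "tss_offset_bp"]], on="guide_id")
    trends = []
    for modality, grp in merged.groupby("modality"):
        sub = grp[grp["guide_class"].isin(trend_classes)
                  & np.isfinite(grp["tss_offset_bp"])]
        if len(sub) < 5:
            continue
        x = sub["tss_offset_bp"].to_numpy(dtype=float)
        y = sub["log2fc"].to_numpy(dtype=float)
        grid = np.linspace(x.min(), x.max(), 201)
        trend = _loess_predict(x, y, grid, loess_span, 2)
        ext = int(np.argmax(np.abs(trend)))
        trends.append({"modality": modality, "n_guides": len(sub),
                       "extremum_offset_bp": float(grid[ext]),
                       "extremum_log2fc": float(trend[ext])})
    trend_table = pd.DataFrame(trends)

    overlap_rows = []
    if intervals:
        for name, ivals in intervals.items():
            for modality, grp in merged.groupby("modality"):
                sub = grp[np.isfinite(grp["tss_offset_bp"])]
                pos = sub["tss_offset_bp"].to_numpy()
                inside = np.zeros(len(sub), dtype=bool)
                for s, e in ivals:
                    inside |= (pos >= s) & (pos < e)
                if inside.sum() == 0 or inside.sum() == len(sub):
                    overlap_rows.append({
                        "annotation": name, "modality": modality,
                        "n_in": int(inside.sum()),
                        "n_out": int(len(sub) - inside.sum()),
                        "p_value": np.nan, "skipped": True})
                    continue
                y = sub["log2fc"].to_numpy()
                _, p = rank_sum_test(y[inside], y[~inside])
                overlap_rows.append({
                    "annotation": name, "modality": modality,
                    "n_in": int(inside.sum()),
                    "n_out": int(len(sub) - inside.sum()),
                    "mean_diff": float(y[inside].mean() - y[~inside].mean()),
                    "p_value": p, "skipped": False})
    return trend_table, pd.DataFrame(overlap_rows)


def summarize_global_response(effects: pd.DataFrame, cis_gene: str,
                              trans_genes, fdr_cutoff: float = 0.05,
                              ) -> pd.DataFrame:
    """Per-guide global trans-response summary for one cis gene.

    For each targeting guide: its cis log2FC, the mean absolute trans
    log2FC over measured trans genes, and the number of trans genes
    significant at ``fdr_cutoff``.
    """
    sub = effects[effects["target_cis_gene"] == cis_gene]
    trans_set = set(trans_genes)
    out = []
    for (guide_id, modality), grp in sub.groupby(["guide_id", "modality"]):
        cis_fc = grp.loc[grp["gene_id"] == cis_gene, "log2fc"]
        trans = grp[grp["gene_id"].isin(trans_set)]
        out.append({
            "guide_id": guide_id, "modality": modality,
            "cis_log2fc": float(cis_fc.iloc[0]) if len(cis_fc) else np.nan,
            "mean_abs_trans_log2fc": float(trans["log2fc"].abs().mean()),
            "n_significant_trans": int((trans["fdr"] <= fdr_cutoff).sum()),
            "n_trans_measured": len(trans),
        })
    return pd.DataFrame(out)
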