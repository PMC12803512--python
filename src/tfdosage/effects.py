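"""Pseudo-bulk fold changes versus non-targeting controls.

The effect of each (guide, modality) perturbation on each measured gene is
summarised as the natural-log ratio of mean normalized expression between
the guide's cells and the pooled cells of the kept NTC guides of the same
modality:

    logfc = ln(mean(group 1) + eps) - ln(mean(NTC pool) + eps)

where the group mean is taken on the depth-normalized linear scale
(back-transformed from the log1p values, as the reference single-cell
implementation of this fold change does -- averaging the log values
instead would compress every fold change toward zero), with a two-sided
Wilcoxon rank-sum p-value per gene and Benjamini-Hochberg
FDR computed jointly across all guide x gene x modality tests.  Before
that, NTC guides with apparent off-target activity are screened out by
all-pairs differential testing among the NTCs of each modality.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr, rank_sum_test_matrix

LN2 = float(np.log(2.0))
DEFAULT_EPSILON = 1e-9


def _cells_of(cells: pd.DataFrame, guide_id: str, modality: str) -> np.ndarray:
    mask = (cells["guide_id"] == guide_id) & (cells["modality"] == modality)
    return cells.index[mask].to_numpy()


def filter_ntc_offtargets(norm: np.ndarray, gene_ids, cells: pd.DataFrame,
                          guide_meta: pd.DataFrame,
                          fdr_cutoff: float = 0.05,
                          ) -> tuple[dict, dict]:
    """Screen NTC guides for off-target behaviour, per modality.

    ``cells`` must be indexed by column position into ``norm`` (one row per
    column, with guide_id and modality columns).  For every unordered pair
    of NTC guides within a modality, each gene is rank-sum tested with
    BH-FDR across genes within the pair.  An NTC is discarded when it
    shows more than one gene at FDR < ``fdr_cutoff`` in more than one of
    its pairwise comparisons, with per-gene sign agreement (oriented to
    the guide) across the flagged comparisons.

    Returns ``(kept, report)``: per modality the surviving NTC guide list,
    and a JSON-serialisable report of all comparisons and decisions.
    """
    ntc_ids = list(guide_meta.loc[guide_meta["guide_class"] == "NTC",
                                  "guide_id"])
    kept: dict[str, list] = {}
    report: dict[str, dict] = {}
    for modality in sorted(cells["modality"].unique()):
        present = [g for g in ntc_ids
                   if len(_cells_of(cells, g, modality)) > 0]
        if len(present) < 2:
            warnings.warn(
                f"<2 NTC guides with cells in {modality}; filter skipped",
                stacklevel=2)
            kept[modality] = present
            report[modality] = {"skipped": True, "kept": present}
            continue
        comparisons = []
        # per guide: list of (other, {gene: sign}) for flagged comparisons
        flagged: dict[str, list] = {g: [] for g in present}
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                g1, g2 = present[i], present[j]
                c1 = _cells_of(cells, g1, modality)
                c2 = _cells_of(cells, g2, modality)
                p = rank_sum_test_matrix(norm[:, c1], norm[:, c2])
                fdr = bh_fdr(p)
                de = np.flatnonzero(fdr < fdr_cutoff)
                diff = norm[:, c1].mean(axis=1) - norm[:, c2].mean(axis=1)
                de_genes = {gene_ids[k]: float(np.sign(diff[k])) for k in de}
                comparisons.append({
                    "pair": [g1, g2], "n_de": len(de),
                    "de_genes": {g: s for g, s in de_genes.items()},
                })
                if len(de) > 1:
                    flagged[g1].append(de_genes)
                    flagged[g2].append({g: -s for g, s in de_genes.items()})
        decisions = {}
        for g in present:
            comps = flagged[g]
            discard = False
            if len(comps) > 1:
                consistent = True
                union = set().union(*[set(c) for c in comps])
                for gene in union:
                    signs = {c[gene] for c in comps if gene in c}
                    if len(signs) > 1:
                        consistent = False
                discard = consistent
            decisions[g] = {
                "n_flagged_comparisons": len(comps),
                "discarded": discard,
            }
        kept[modality] = [g for g in present if not decisions[g]["discarded"]]
        report[modality] = {
            "skipped": False, "comparisons": comparisons,
            "decisions": decisions, "kept": kept[modality],
        }
    return kept, report


def compute_fold_changes(norm: np.ndarray, gene_ids, cells: pd.DataFrame,
                         kept_ntc: dict, guide_meta: pd.DataFrame,
                         epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Pseudo-bulk fold changes of every targeting guide vs. pooled NTCs.

    One row per (guide, modality, gene).  ``logfc_natural`` follows the
    mean-ratio formula with pseudocount ``epsilon`` added to both group
    means; ``log2fc = logfc_natural / ln 2``.  Genes with zero counts in
    both groups get logfc 0 and p 1 (flagged in ``both_zero``).  BH-FDR is
    joint across all rows.
    """
    target_by_guide = guide_meta.set_index("guide_id")["target_cis_gene"]
    targeting = guide_meta.loc[
        guide_meta["guide_class"] != "NTC", "guide_id"]
    frames = []
    for modality in sorted(cells["modality"].unique()):
        ntc_cells = np.concatenate([
            _cells_of(cells, g, modality) for g in kept_ntc.get(modality, [])
        ]) if kept_ntc.get(modality) else np.array([], dtype=int)
        if len(ntc_cells) == 0:
            raise ValueError(f"no kept NTC cells for modality {modality!r}")
        ntc_block = norm[:, ntc_cells]
        ntc_mean = np.expm1(ntc_block).mean(axis=1)
        for guide_id in targeting:
            gcells = _cells_of(cells, guide_id, modality)
            n1 = len(gcells)
            if n1 == 0:
                frames.append(pd.DataFrame({
                    "guide_id": guide_id, "modality": modality,
                    "target_cis_gene": target_by_guide[guide_id],
                    "gene_id": list(gene_ids),
                    "log2fc": np.nan, "logfc_natural": np.nan,
                    "p_value": np.nan, "n_cells_guide": 0,
                    "n_cells_ntc": len(ntc_cells), "both_zero": False,
                    "undefined": True,
                }))
                continue
            block = norm[:, gcells]
            gmean = np.expm1(block).mean(axis=1)
            logfc = np.log(gmean + epsilon) - np.log(ntc_mean + epsilon)
            pvals = rank_sum_test_matrix(block, ntc_block)
            both_zero = (gmean == 0) & (ntc_mean == 0)
            logfc[both_zero] = 0.0
            pvals[both_zero] = 1.0
            frames.append(pd.DataFrame({
                "guide_id": guide_id, "modality": modality,
                "target_cis_gene": target_by_guide[guide_id],
                "gene_id": list(gene_ids),
                "log2fc": logfc / LN2, "logfc_natural": logfc,
                "p_value": pvals, "n_cells_guide": n1,
                "n_cells_ntc": len(ntc_cells), "both_zero": both_zero,
                "undefined": False,
            }))
    out = pd.concat(frames, ignore_index=True)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out


def split_consistency_diagnostic(norm: np.ndarray, gene_ids,
                                 cells: pd.DataFrame, kept_ntc: dict,
                                 cis_gene: str, guide_id: str,
                                 modality: str,
                                 epsilon: float = DEFAULT_EPSILON):
    """Fold changes computed separately for cis-zero vs. cis-positive cells.

    Splits the cells of one guide by whether the cis gene has zero or
    positive normalized expression, computes transcriptome-wide fold
    changes for each stratum against the pooled NTC cells, and reports the
    Pearson correlation of the two fold-change vectors across genes
    (excluding the cis gene itself, which defines the split).

    Returns ``(table, r)`` or ``(None, note)`` when a stratum is empty.
    """
    gi = {g: i for i, g in enumerate(gene_ids)}
    gcells = _cells_of(cells, guide_id, modality)
    cis_expr = norm[gi[cis_gene], gcells]
    zero = gcells[cis_expr == 0]
    pos = gcells[cis_expr > 0]
    if len(zero) == 0 or len(pos) == 0:
        return None, (f"stratum empty for {guide_id}/{modality}: "
                      f"{len(zero)} zero, {len(pos)} positive cells")
    ntc_cells = np.concatenate(
        [_cells_of(cells, g, modality) for g in kept_ntc[modality]])
    ntc_mean = np.expm1(norm[:, ntc_cells]).mean(axis=1)

    def fc(idx):
        return (np.log(np.expm1(norm[:, idx]).mean(axis=1) + epsilon)
                - np.log(ntc_mean + epsilon)) / LN2

    table = pd.DataFrame({
        "gene_id": list(gene_ids),
        "log2fc_cis_zero": fc(zero),
        "log2fc_cis_positive": fc(pos),
        "n_cells_zero": len(zero), "n_cells_positive": len(pos),
    })
    mask = [g != cis_gene for g in gene_ids]
    r = float(stats.pearsonr(table.loc[mask, "log2fc_cis_zero"],
                             table.loc[mask, "log2fc_cis_positive"])[0])
    return table, r
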