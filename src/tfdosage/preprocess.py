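"""Cell QC, guide calling, modality assignment and normalization.

Mirrors the processing of a targeted multimodal single-cell screen at the
matrix level: cells with fewer than 500 UMIs or fewer than 50 detected
genes are discarded, then the top 1% of surviving cells by UMI content;
guides are called per cell from guide capture counts with a two-component
Gaussian mixture; cells with other than exactly one guide are discarded;
modality is assigned from the two dCas9 marker transcripts with 5% trims;
expression is log1p normalized (ln(1 + count * scale / cell total)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.mixture import GaussianMixture

from .simdata import ConfigurationError

DEFAULT_MIN_UMI = 500
DEFAULT_MIN_GENES = 50
DEFAULT_TOP_FRACTION = 0.01
DEFAULT_SCALE_FACTOR = 10_000.0
MODALITY_TRIM_FRACTION = 0.05


def qc_filter_cells(counts: sparse.spmatrix, cell_ids,
                    min_umi: int = DEFAULT_MIN_UMI,
                    min_genes: int = DEFAULT_MIN_GENES,
                    top_fraction: float = DEFAULT_TOP_FRACTION,
                    ) -> tuple[sparse.csr_matrix, list, pd.DataFrame]:
    """Remove low-quality cells, then the top fraction by UMI content.

    Thresholds are strict ("less than"): a cell with exactly ``min_umi``
    UMIs or ``min_genes`` detected genes is retained.  The top-fraction
    rule is applied after the two minimum filters, on the survivors, using
    nearest-rank counting (``floor(n * top_fraction)`` cells removed) with
    ties broken by stable input order.

    Returns (filtered counts, kept cell ids, per-cell QC report).
    """
    counts = sparse.csr_matrix(counts)
    if counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    totals = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()

    reason = np.array([""] * counts.shape[1], dtype=object)
    reason[totals < min_umi] = "min_umi"
    keep_min = totals >= min_umi
    low_genes = (n_genes < min_genes) & keep_min
    reason[low_genes] = "min_genes"
    keep_min &= ~low_genes

    survivors = np.flatnonzero(keep_min)
    n_top = int(np.floor(len(survivors) * top_fraction))
    if n_top > 0:
        # stable: sort by (-total, position); take the deepest n_top
        order = survivors[np.lexsort((survivors, -totals[survivors]))]
        top = order[:n_top]
        reason[top] = "top_umi"
        keep_min[top] = False

    report = pd.DataFrame({
        "cell_id": list(cell_ids),
        "total_umi": totals.astype(int),
        "n_genes_detected": n_genes.astype(int),
        "qc_pass": keep_min,
        "removal_reason": reason,
    })
    kept = np.flatnonzero(keep_min)
    if len(kept) == 0:
        warnings.warn("QC removed every cell", stacklevel=2)
    kept_ids = [cell_ids[i] for i in kept]
    return counts[:, kept], kept_ids, report


def call_guides_gmm(guide_counts: sparse.spmatrix, guide_ids, cell_ids,
                    min_separation: float = 2.0,
                    random_state: int = 0) -> pd.DataFrame:
    """Call guides per cell with per-guide two-component Gaussian mixtures.

    For each guide a univariate GMM is fitted on log2(count + 1) across
    the cells with a positive count (fitting across all cells lets the
    mixture collapse onto the zero spike and split zero from nonzero
    instead of ambient background from true carriers); a positive-count
    cell carries the guide when the posterior probability of the
    high-mean component exceeds 0.5.  Guides whose two component means
    are separated by less than ``min_separation`` log2 units -- ambient
    background versus carrier capture is several units -- yield no calls,
    as do all-zero and single-valued guides.

    Returns a long table (cell_id, guide_id) of calls.
    """
    gm = sparse.csr_matrix(guide_counts)
    rows = []
    for i, gid in enumerate(guide_ids):
        counts_i = np.asarray(gm[i].todense()).ravel()
        pos = np.flatnonzero(counts_i > 0)
        y = np.log2(counts_i[pos] + 1.0)
        if len(pos) < 2 or np.ptp(y) == 0:
            continue
        # covariance floor keeps a component from collapsing onto a single
        # discrete log2 count value (counts are integers, so the fitted
        # data are point masses)
        model = GaussianMixture(
            n_components=2, n_init=5, tol=1e-6, max_iter=500,
            reg_covar=0.05, random_state=random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(y.reshape(-1, 1))
        means = model.means_.ravel()
        hi = int(np.argmax(means))
        if abs(means[hi] - means[1 - hi]) < min_separation:
            continue
        post = model.predict_proba(y.reshape(-1, 1))[:, hi]
        for j in pos[post > 0.5]:
            rows.append({"cell_id": cell_ids[j], "guide_id": gid})
    return pd.DataFrame(rows, columns=["cell_id", "guide_id"])


def filter_single_guide(calls: pd.DataFrame, cell_ids) -> pd.DataFrame:
    """Retain cells with exactly one called guide.

    Returns a per-cell table (cell_id, guide_id, n_guides, status) where
    status is "kept", "no_guide" or "multi_guide".
    """
    counts = calls.groupby("cell_id")["guide_id"].agg(list) if len(calls) \
        else pd.Series(dtype=object)
    rows = []
    for cid in cell_ids:
        g = counts.get(cid, [])
        if len(g) == 1:
            rows.append({"cell_id": cid, "guide_id": g[0], "n_guides": 1,
                         "status": "kept"})
        elif len(g) == 0:
            rows.append({"cell_id": cid, "guide_id": None, "n_guides": 0,
                         "status": "no_guide"})
        else:
            rows.append({"cell_id": cid, "guide_id": None, "n_guides": len(g),
                         "status": "multi_guide"})
    return pd.DataFrame(rows)


def assign_modality(norm_values: np.ndarray, gene_ids, cell_ids,
                    marker_gene_ids: dict,
                    trim_fraction: float = MODALITY_TRIM_FRACTION,
                    ) -> pd.DataFrame:
    """Assign each cell a modality from marker transcripts, with trims.

    Cells are labelled by the marker with the greater normalized
    expression.  Then, within interference-labelled cells, the bottom
    ``trim_fraction`` by interference-marker expression are discarded; and
    within activation-labelled cells, the top ``trim_fraction`` by
    interference-marker expression are discarded.  Trim counts use
    ``floor(n * trim_fraction)``, ties broken by stable cell order.
    """
    for m, g in marker_gene_ids.items():
        if g not in gene_ids:
            raise ConfigurationError(f"marker feature {g!r} for {m} missing")
    gi = {g: i for i, g in enumerate(gene_ids)}
    i_mark = norm_values[gi[marker_gene_ids["interference"]]]
    a_mark = norm_values[gi[marker_gene_ids["activation"]]]
    modality = np.where(i_mark >= a_mark, "interference", "activation")
    trimmed = np.zeros(len(cell_ids), dtype=bool)

    for label, take_low in (("interference", True), ("activation", False)):
        idx = np.flatnonzero(modality == label)
        n_trim = int(np.floor(len(idx) * trim_fraction))
        if n_trim == 0:
            continue
        key = i_mark[idx]
        order = idx[np.lexsort((idx, key if take_low else -key))]
        trimmed[order[:n_trim]] = True

    return pd.DataFrame({
        "cell_id": list(cell_ids),
        "modality": modality,
        "interference_marker": i_mark,
        "activation_marker": a_mark,
        "modality_trimmed": trimmed,
    })


def normalize_log1p(counts: sparse.spmatrix, cell_ids,
                    scale_factor: float = DEFAULT_SCALE_FACTOR,
                    ) -> tuple[np.ndarray, list]:
    """log1p library-size normalization: ln(1 + count * scale / cell total).

    Cells with zero total counts are dropped with a warning.  Returns a
    dense (genes x cells) array and the kept cell ids; zero counts map to
    exactly 0.
    """
    if scale_factor <= 0:
        raise ConfigurationError("scale_factor must be > 0")
    counts = sparse.csr_matrix(counts)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-count cells",
                      stacklevel=2)
    if not keep.any():
        raise ValueError("no cell has nonzero counts")
    sub = counts[:, keep].toarray().astype(float)
    sub *= scale_factor / totals[keep]
    out = np.log1p(sub)
    kept_ids = [c for c, k in zip(cell_ids, keep) if k]
    return out, kept_ids
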