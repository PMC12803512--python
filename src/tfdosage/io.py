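"""Reading and writing the on-disk dataset layout.

Counts are stored as MatrixMarket sparse matrices in the 10x-triplet
dialect (matrix.mtx + features.tsv + barcodes.tsv, 1-based MatrixMarket
indices); metadata and ground truth are plain TSV.  A write followed by a
read reproduces the in-memory dataset exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simdata import SimulatedDataset

COUNTS = ("matrix.mtx", "features.tsv", "barcodes.tsv")
GUIDE_COUNTS = ("guide_matrix.mtx", "guide_features.tsv")


def _write_mtx(path: Path, mat: sparse.spmatrix) -> None:
    spio.mmwrite(str(path), sparse.coo_matrix(mat), field="integer")
    # mmwrite appends .mtx only when missing; path already carries it


def _write_ids(path: Path, ids) -> None:
    with open(path, "w") as fh:
        for x in ids:
            fh.write(f"{x}\n")


def _read_ids(path: Path) -> list:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh]


def write_dataset(dataset: SimulatedDataset, directory) -> list[str]:
    """Write the dataset file set; returns the file names written."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to {directory}: {exc}") from exc

    _write_mtx(directory / "matrix.mtx", dataset.counts)
    _write_ids(directory / "features.tsv", dataset.gene_ids)
    _write_ids(directory / "barcodes.tsv", dataset.cell_ids)
    _write_mtx(directory / "guide_matrix.mtx", dataset.guide_counts)
    _write_ids(directory / "guide_features.tsv",
               list(dataset.guide_meta["guide_id"]))
    dataset.cell_meta.to_csv(directory / "cell_meta.tsv", sep="\t", index=False)
    dataset.guide_meta.to_csv(directory / "guide_meta.tsv", sep="\t", index=False)
    dataset.truth.to_csv(directory / "truth_curves.tsv", sep="\t", index=False)
    return sorted(os.listdir(directory))


def read_dataset(directory) -> SimulatedDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    directory = Path(directory)
    counts = sparse.csr_matrix(spio.mmread(str(directory / "matrix.mtx")))
    counts = counts.astype("int64")
    gene_ids = _read_ids(directory / "features.tsv")
    cell_ids = _read_ids(directory / "barcodes.tsv")
    guide_counts = sparse.csr_matrix(
        spio.mmread(str(directory / "guide_matrix.mtx"))).astype("int64")
    cell_meta = pd.read_csv(directory / "cell_meta.tsv", sep="\t")
    if cell_meta.empty:
        cell_meta = cell_meta.astype(
            {c: object for c in cell_meta.columns if c != "lib_factor"})
    guide_meta = pd.read_csv(directory / "guide_meta.tsv", sep="\t")
    truth = pd.read_csv(directory / "truth_curves.tsv", sep="\t")
    return SimulatedDataset(
        counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
        guide_counts=guide_counts, cell_meta=cell_meta,
        guide_meta=guide_meta, truth=truth,
    )
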