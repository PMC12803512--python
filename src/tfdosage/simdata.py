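"""Synthetic graded CRISPRi/CRISPRa Perturb-seq datasets with ground truth.

Emulates a targeted single-cell screen in which a 96-guide library
(TSS-tiling, TSS, mismatch-attenuated, enhancer and non-targeting guides)
gradually modulates the dosage of a handful of cis transcription factors in
two modalities (interference and activation), and a panel of trans genes
responds along linear, sigmoid, non-monotonic or flat ground-truth curves.

Counts follow a negative-binomial model with lognormal library-size
factors; guide capture counts and two modality marker transcripts are
simulated so that guide calling and modality assignment can be exercised
end to end.  Everything is seeded and ground truth is exported, so every
downstream estimator can be tested against the generating model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

MODALITIES = ("interference", "activation")
GUIDE_CLASSES = ("tiling", "TSS", "attenuated", "enhancer", "NTC")
CURVE_TYPES = ("linear", "sigmoid", "nonmonotonic", "unresponsive")

#: offset (bp from TSS) of peak efficacy, per modality
EFFICACY_MODE_BP = {"interference": 238.0, "activation": -99.0}
#: width (bp) of the Gaussian efficacy profile
EFFICACY_WIDTH_BP = 500.0
#: peak |log2FC| magnitude of the efficacy profile, per modality
EFFICACY_PEAK = {"interference": 1.8, "activation": 0.8}

MARKER_GENES = {"interference": "dCas9-KRAB", "activation": "dCas9-VPR"}
ZERO_CONTROL_GENE = "CTRL_ZERO"
HIGH_CONTROL_GENE = "CTRL_HIGH"


class ConfigurationError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic screen.

    Defaults mirror the experimental design being emulated: a 96-guide
    library (51 tiling / 8 TSS / 20 attenuated / 12 enhancer / 5 NTC) over
    four cis genes, ~80 cells per guide per modality, and cis effects
    spanning roughly -1.8 to +0.8 log2 units.
    """

    n_cis_genes: int = 4
    n_trans_genes: int = 86
    guide_counts_by_class: dict = field(
        default_factory=lambda: {
            "tiling": 51, "TSS": 8, "attenuated": 20, "enhancer": 12, "NTC": 5,
        }
    )
    cells_per_guide_mean: float = 80.0
    modality_set: tuple = MODALITIES
    baseline_mean_range: tuple = (1.0, 30.0)
    dispersion: float = 10.0
    poisson_mode: bool = False
    library_size_lognormal_sigma: float = 0.35
    dropout_extra: float = 0.0
    multi_guide_fraction: float = 0.05
    marker_mean: float = 8.0
    marker_contamination: float = 0.02
    #: (ntc guide_id, tuple of gene ids, log2 effect, modality) or None
    ntc_offtarget_spec: tuple | None = None
    curve_type_proportions: dict = field(
        default_factory=lambda: {
            "linear": 0.30, "sigmoid": 0.45, "nonmonotonic": 0.05,
            "unresponsive": 0.20,
        }
    )
    #: last cis gene gets an all-unresponsive trans network (negative control)
    control_cis_gene: bool = True
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if self.n_cis_genes < 1:
            problems.append("n_cis_genes must be >= 1")
        if self.n_trans_genes < 0:
            problems.append("n_trans_genes must be >= 0")
        if self.guide_counts_by_class.get("NTC", 0) < 1:
            problems.append("at least one NTC guide is required")
        for cls, n in self.guide_counts_by_class.items():
            if cls not in GUIDE_CLASSES:
                problems.append(f"unknown guide class {cls!r}")
            if n < 0:
                problems.append(f"guide count for {cls!r} must be >= 0")
        if self.cells_per_guide_mean <= 0:
            problems.append("cells_per_guide_mean must be > 0")
        if not (self.baseline_mean_range[0] > 0
                and self.baseline_mean_range[1] >= self.baseline_mean_range[0]):
            problems.append("baseline_mean_range must be a positive interval")
        if self.dispersion <= 0:
            problems.append("dispersion must be > 0")
        if not 0 <= self.dropout_extra <= 1:
            problems.append("dropout_extra must be in [0, 1]")
        if not 0 <= self.multi_guide_fraction <= 1:
            problems.append("multi_guide_fraction must be in [0, 1]")
        total = sum(self.curve_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            problems.append(
                f"curve_type_proportions sums to {total}, expected 1")
        for ct in self.curve_type_proportions:
            if ct not in CURVE_TYPES:
                problems.append(f"unknown curve type {ct!r}")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ConfigurationError("; ".join(problems))

    def cis_gene_ids(self) -> list[str]:
        return [f"CIS{i + 1}" for i in range(self.n_cis_genes)]

    def trans_gene_ids(self) -> list[str]:
        return [f"TRANS{i + 1:03d}" for i in range(self.n_trans_genes)]

    def all_gene_ids(self) -> list[str]:
        return (self.cis_gene_ids() + self.trans_gene_ids()
                + [ZERO_CONTROL_GENE, HIGH_CONTROL_GENE]
                + [MARKER_GENES[m] for m in MODALITIES])


def _efficacy(offset_bp: float, modality: str) -> float:
    """Gaussian-in-offset efficacy profile, in |log2FC| units."""
    mode = EFFICACY_MODE_BP[modality]
    return EFFICACY_PEAK[modality] * float(
        np.exp(-0.5 * ((offset_bp - mode) / EFFICACY_WIDTH_BP) ** 2))


def _signed(magnitude: float, modality: str) -> float:
    return -magnitude if modality == "interference" else magnitude


def build_guide_library(config: SimulationConfig, rng_seed: int) -> pd.DataFrame:
    """Construct the guide library with designed cis effects per modality.

    Tiling guides are spaced evenly over +/-1000 bp from the TSS; their
    efficacy follows a smooth unimodal profile of offset peaking at +238 bp
    (interference) and -99 bp (activation).  Attenuated guides weaken
    monotonically with the mismatch distance from the PAM; enhancer guides
    draw mid-magnitude effects; NTC guides have zero designed effect.
    """
    config.require_valid()
    rng = np.random.default_rng(rng_seed)
    counts = config.guide_counts_by_class
    cis = config.cis_gene_ids()

    rows = []
    for cls in GUIDE_CLASSES:
        n = counts.get(cls, 0)
        if cls == "tiling" and n > 0:
            offsets = np.linspace(-1000, 1000, n)
        for i in range(n):
            guide_id = f"{cls}_{i + 1}"
            target = None if cls == "NTC" else cis[i % len(cis)]
            offset = np.nan
            mismatch = np.nan
            eff = {m: 0.0 for m in MODALITIES}
            if cls == "tiling":
                offset = float(np.round(offsets[i]))
                for m in MODALITIES:
                    mag = _efficacy(offset, m) * rng.uniform(0.6, 1.0)
                    eff[m] = _signed(mag, m)
            elif cls == "TSS":
                offset = 0.0
                for m in MODALITIES:
                    mag = _efficacy(0.0, m) * rng.uniform(0.7, 1.0)
                    eff[m] = _signed(mag, m)
            elif cls == "attenuated":
                mismatch = float(1 + (i % 10) * 2)
                for m in MODALITIES:
                    mag = (_efficacy(0.0, m) * np.exp(-mismatch / 8.0)
                           * rng.uniform(0.8, 1.0))
                    eff[m] = _signed(mag, m)
            elif cls == "enhancer":
                for m in MODALITIES:
                    mag = rng.uniform(0.2, 0.6)
                    eff[m] = _signed(mag, m)
            rows.append({
                "guide_id": guide_id,
                "target_cis_gene": target,
                "guide_class": cls,
                "tss_offset_bp": offset,
                "mismatch_pam_distance": mismatch,
                "log2fc_interference": eff["interference"],
                "log2fc_activation": eff["activation"],
            })
    guides = pd.DataFrame(rows)
    spec = config.ntc_offtarget_spec
    if spec is not None:
        ntc_id = spec[0]
        if ntc_id not in set(guides["guide_id"]):
            raise ConfigurationError(f"off-target NTC {ntc_id!r} not in library")
    return guides


def designed_effect(guides: pd.DataFrame, guide_id: str, modality: str) -> float:
    row = guides.loc[guides["guide_id"] == guide_id].iloc[0]
    return float(row[f"log2fc_{modality}"])


# ---------------------------------------------------------------------------
# ground-truth response curves


def evaluate_curve(curve: pd.Series | dict, x) -> np.ndarray:
    """Evaluate a ground-truth trans response at cis log2FC ``x``.

    All curve types are anchored so that the response at x = 0 (no cis
    dosage change) is exactly 0, because observed responses are fold
    changes relative to the NTC reference.
    """
    x = np.asarray(x, dtype=float)
    ct = curve["curve_type"]
    if ct == "unresponsive":
        return np.zeros_like(x)
    if ct == "linear":
        return curve["slope"] * x
    if ct == "sigmoid":
        a, b, c, d = curve["a"], curve["b"], curve["c"], curve["d"]
        raw = c + (d - c) / (1.0 + np.exp(np.clip(b * (x - a), -500, 500)))
        at0 = c + (d - c) / (1.0 + np.exp(np.clip(b * (0.0 - a), -500, 500)))
        return raw - at0
    if ct == "nonmonotonic":
        p, h, w = curve["peak_x"], curve["peak_height"], curve["width"]
        raw = h * np.exp(-0.5 * ((x - p) / w) ** 2)
        at0 = h * np.exp(-0.5 * (p / w) ** 2)
        return raw - at0
    raise ValueError(f"unknown curve type {ct!r}")


def sample_truth_curves(config: SimulationConfig, guides: pd.DataFrame,
                        rng_seed: int) -> pd.DataFrame:
    """Draw one ground-truth curve per (trans gene, cis gene) pair.

    Curve types follow ``curve_type_proportions``; sigmoid parameters come
    from documented default ranges (|d-c| in [0.2, 2.0], |b| in [2, 10],
    a in [-0.5, 0.5]).  When ``control_cis_gene`` is set the last cis gene
    receives an all-unresponsive network.
    """
    config.require_valid()
    if config.n_trans_genes < 1:
        raise ConfigurationError("n_trans_genes must be >= 1")
    rng = np.random.default_rng(rng_seed)
    types = list(config.curve_type_proportions)
    probs = np.array([config.curve_type_proportions[t] for t in types])
    cis = config.cis_gene_ids()
    control = cis[-1] if (config.control_cis_gene and len(cis) > 1) else None

    rows = []
    for trans in config.trans_gene_ids():
        for cg in cis:
            if cg == control:
                ct = "unresponsive"
            else:
                ct = types[rng.choice(len(types), p=probs)]
            row = {"trans_gene": trans, "cis_gene": cg, "curve_type": ct,
                   "slope": np.nan, "a": np.nan, "b": np.nan, "c": np.nan,
                   "d": np.nan, "peak_x": np.nan, "peak_height": np.nan,
                   "width": np.nan}
            if ct == "linear":
                row["slope"] = rng.uniform(0.2, 1.0) * rng.choice([-1, 1])
            elif ct == "sigmoid":
                rng_dc = rng.uniform(0.2, 2.0)
                c = rng.uniform(-0.5, 0.0)
                row.update(
                    a=rng.uniform(-0.5, 0.5),
                    b=rng.uniform(2.0, 10.0) * rng.choice([-1, 1]),
                    c=c, d=c + rng_dc,
                )
            elif ct == "nonmonotonic":
                row.update(
                    peak_x=rng.uniform(-1.0, 0.2),
                    peak_height=rng.uniform(0.3, 1.0) * rng.choice([-1, 1]),
                    width=rng.uniform(0.3, 0.6),
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# count simulation


@dataclass
class SimulatedDataset:
    """In-memory synthetic dataset: counts, guide counts and metadata."""

    counts: sparse.csr_matrix           # genes x cells, integer UMIs
    gene_ids: list
    cell_ids: list
    guide_counts: sparse.csr_matrix     # guides x cells, integer UMIs
    cell_meta: pd.DataFrame
    guide_meta: pd.DataFrame
    truth: pd.DataFrame

    def n_cells(self) -> int:
        return self.counts.shape[1]


def _nb_draw(rng, mu: np.ndarray, dispersion: float, poisson: bool) -> np.ndarray:
    mu = np.maximum(mu, 0.0)
    if poisson:
        return rng.poisson(mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        p = dispersion / (dispersion + mu[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def simulate_counts(config: SimulationConfig, guides: pd.DataFrame,
                    truths: pd.DataFrame, rng_seed: int) -> SimulatedDataset:
    """Simulate the UMI count matrix and guide capture counts.

    Per cell: a modality and guide are assigned (a ``multi_guide_fraction``
    of cells carry a second guide); a lognormal library factor scales all
    genes; each gene's expected count is baseline x libfactor x 2^effect,
    where the effect is the designed cis log2FC for the guide's target and
    the ground-truth curve evaluated at that cis log2FC for trans genes.
    Counts are negative-binomial (or Poisson in ``poisson_mode``).
    """
    config.require_valid()
    rng = np.random.default_rng(rng_seed)
    gene_ids = config.all_gene_ids()
    cis_ids = config.cis_gene_ids()
    trans_ids = config.trans_gene_ids()
    n_genes = len(gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    baseline = np.exp(rng.uniform(np.log(config.baseline_mean_range[0]),
                                  np.log(config.baseline_mean_range[1]),
                                  n_genes))
    baseline[gene_index[ZERO_CONTROL_GENE]] = 0.0
    baseline[gene_index[HIGH_CONTROL_GENE]] = 4.0 * config.baseline_mean_range[1]
    for m in MODALITIES:
        baseline[gene_index[MARKER_GENES[m]]] = config.marker_mean

    # truth lookup: (trans, cis) -> curve row
    truth_by_pair = {(r["trans_gene"], r["cis_gene"]): r
                     for r in truths.to_dict("records")}
    guide_rows = {r["guide_id"]: r for r in guides.to_dict("records")}
    guide_ids = list(guides["guide_id"])

    spec = config.ntc_offtarget_spec

    # log2-effect vector over all genes for each (guide, modality)
    effect_cache: dict[tuple[str, str], np.ndarray] = {}

    def effects_for(guide_id: str, modality: str) -> np.ndarray:
        key = (guide_id, modality)
        if key in effect_cache:
            return effect_cache[key]
        eff = np.zeros(n_genes)
        g = guide_rows[guide_id]
        target = g["target_cis_gene"]
        if target is not None and not (isinstance(target, float) and np.isnan(target)):
            cis_fc = float(g[f"log2fc_{modality}"])
            eff[gene_index[target]] = cis_fc
            for t in trans_ids:
                curve = truth_by_pair.get((t, target))
                if curve is not None:
                    eff[gene_index[t]] = float(evaluate_curve(curve, cis_fc))
        elif spec is not None and guide_id == spec[0] and modality == spec[3]:
            for gene in spec[1]:
                eff[gene_index[gene]] = float(spec[2])
        effect_cache[key] = eff
        return eff

    cells = []
    for modality in config.modality_set:
        for guide_id in guide_ids:
            n_cells = rng.poisson(config.cells_per_guide_mean)
            for _ in range(n_cells):
                cells.append((modality, guide_id))

    n_total = len(cells)
    second = rng.random(n_total) < config.multi_guide_fraction
    libfac = rng.lognormal(mean=0.0, sigma=config.library_size_lognormal_sigma,
                           size=n_total)

    counts = np.zeros((n_genes, n_total), dtype=np.int64)
    n_guides = len(guide_ids)
    gidx = {g: i for i, g in enumerate(guide_ids)}
    # guide capture: background Poisson(0.3) everywhere, carrier NB(mean 50)
    gdo = rng.poisson(0.3, size=(n_guides, n_total))

    meta_rows = []
    for j, (modality, guide_id) in enumerate(cells):
        guide_list = [guide_id]
        if second[j]:
            other = guide_ids[rng.integers(n_guides)]
            if other != guide_id:
                guide_list.append(other)
        mu = baseline * libfac[j] * np.exp2(effects_for(guide_id, modality))
        # modality markers: expressed in-modality, contamination otherwise
        for m in MODALITIES:
            mi = gene_index[MARKER_GENES[m]]
            if m != modality:
                mu[mi] *= config.marker_contamination
        counts[:, j] = _nb_draw(rng, mu, config.dispersion, config.poisson_mode)
        for gl in guide_list:
            gdo[gidx[gl], j] += _nb_draw(
                rng, np.array([50.0 * libfac[j]]), config.dispersion,
                config.poisson_mode)[0]
        meta_rows.append({
            "cell_id": f"cell_{j + 1:06d}",
            "modality": modality,
            "guide_ids": ";".join(guide_list),
            "hash_label": f"hash_{modality[:3]}_{j % 4 + 1}",
            "lib_factor": libfac[j],
        })

    if config.dropout_extra > 0:
        drop = rng.random(counts.shape) < config.dropout_extra
        counts[drop] = 0

    cell_meta = pd.DataFrame(meta_rows)
    guide_meta = guides.copy()
    return SimulatedDataset(
        counts=sparse.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=list(cell_meta["cell_id"]),
        guide_counts=sparse.csr_matrix(gdo),
        cell_meta=cell_meta,
        guide_meta=guide_meta,
        truth=truths.copy(),
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run guide design, truth sampling and count simulation from one seed."""
    ss = np.random.SeedSequence(config.seed)
    s_guides, s_truth, s_counts = [
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
    guides = build_guide_library(config, s_guides)
    truths = sample_truth_curves(config, guides, s_truth)
    return simulate_counts(config, guides, truths, s_counts)


# ---------------------------------------------------------------------------
# planted annotation tables and cell-type profiles


def simulate_annotations(truths: pd.DataFrame, rng_seed: int,
                         n_cell_types: int = 6) -> pd.DataFrame:
    """Synthetic per-gene annotation table with planted structure.

    Planted relations (per trans gene, aggregated over its response
    curves): housekeeping genes are drawn preferentially among genes with
    small response ranges; pLI/pHaplo are negatively related to the
    response range plus noise; disease and GWAS sets are enriched among
    genes with nonlinear (sigmoid or non-monotonic) true responses.
    Quantitative metrics contain some missing values, as real annotation
    tables do.
    """
    rng = np.random.default_rng(rng_seed)

    def true_range(r):
        if r["curve_type"] == "sigmoid":
            return abs(r["d"] - r["c"])
        if r["curve_type"] == "linear":
            return abs(r["slope"]) * 1.5
        if r["curve_type"] == "nonmonotonic":
            return abs(r["peak_height"])
        return 0.0

    per_gene = truths.assign(rng_=truths.apply(true_range, axis=1)).groupby(
        "trans_gene")["rng_"].max()
    nonlin = truths.groupby("trans_gene")["curve_type"].apply(
        lambda s: bool(s.isin(["sigmoid", "nonmonotonic"]).any()))
    genes = list(per_gene.index)
    rg = per_gene.to_numpy()
    rg_norm = rg / (rg.max() if rg.max() > 0 else 1.0)

    housekeeping = rng.random(len(genes)) < 0.15 + 0.35 * (1 - rg_norm)
    disease = rng.random(len(genes)) < np.where(nonlin[genes], 0.45, 0.15)
    rows = []
    for i, g in enumerate(genes):
        rows.append({
            "gene_id": g,
            "housekeeping": bool(housekeeping[i]),
            "transcription_factor": bool(rng.random() < 0.25),
            "disease_linked": bool(disease[i]),
            "gwas_wbc": bool(rng.random() < (0.4 if nonlin[g] else 0.12)),
            "gwas_platelet": bool(rng.random() < 0.2),
            "gwas_rbc": bool(rng.random() < 0.2),
            "gwas_reticulocyte": bool(rng.random() < (0.35 if nonlin[g] else 0.1)),
            "pLI": float(np.clip(1 - rg_norm[i] + rng.normal(0, 0.2), 0, 1)),
            "pHaplo": float(np.clip(1 - rg_norm[i] + rng.normal(0, 0.15), 0, 1)),
            "missense_z": float(rng.normal(1.0 - rg_norm[i], 1.0)),
            "n_chip_peaks": int(rng.poisson(3)),
            "n_ppi": int(rng.poisson(30)),
        })
    ann = pd.DataFrame(rows)
    # missing values, as in real annotation tables
    for col in ("pLI", "pHaplo", "missense_z"):
        miss = rng.random(len(ann)) < 0.05
        ann.loc[miss, col] = np.nan
    for k in range(n_cell_types):
        ann[f"celltype_{k + 1}_mean"] = rng.lognormal(0, 1, len(ann))
    return ann


def simulate_celltype_profiles(effects: pd.DataFrame, cis_gene: str,
                               rng_seed: int, n_other: int = 4) -> pd.DataFrame:
    """Synthetic cell-type mean-expression profiles (cell types x genes).

    One "maturation" profile is constructed to align with the trans
    response to positive dosage of ``cis_gene``; the remaining profiles
    are noise.  Returned unscaled; z-scale across cell types before
    correlating.
    """
    rng = np.random.default_rng(rng_seed)
    sub = effects[(effects["target_cis_gene"] == cis_gene)]
    if sub.empty:
        raise ValueError(f"no effects for cis gene {cis_gene!r}")
    # trans response at the strongest positive cis dosage sets the axis
    cis_rows = sub[sub["gene_id"] == cis_gene]
    best = cis_rows.loc[cis_rows["log2fc"].idxmax()]
    vec = sub[(sub["guide_id"] == best["guide_id"])
              & (sub["modality"] == best["modality"])]
    vec = vec.set_index("gene_id")["log2fc"]
    genes = list(vec.index)
    base = rng.lognormal(1.0, 0.5, len(genes))
    rows = {"maturation": base * np.exp2(2.0 * vec.to_numpy())}
    for k in range(n_other):
        rows[f"celltype_{k + 1}"] = base * rng.lognormal(0, 0.8, len(genes))
    prof = pd.DataFrame(rows, index=genes).T
    prof.index.name = "cell_type"
    return prof
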