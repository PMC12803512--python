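import numpy as np
import pandas as pd
import pytest

from tfdosage import simdata as sd


SMALL_GUIDES = {"tiling": 12, "TSS": 4, "attenuated": 4, "enhancer": 4,
                "NTC": 4}


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(
        n_trans_genes=12, cells_per_guide_mean=40,
        guide_counts_by_class=dict(SMALL_GUIDES), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sd.simulate_dataset(small_config)


def make_sigmoid_points(a, b, c, d, n=90, noise_sd=0.1, seed=0,
                        x_lo=-1.8, x_hi=0.8):
    """Dose points from a known 4PL curve with Gaussian noise."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_lo, x_hi, n)
    from tfdosage.doseresponse import sigmoid
    y = sigmoid(x, a, b, c, d) + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"x": x, "y": y})


@pytest.fixture(scope="session")
def truth_cells_effects(small_dataset):
    """Fold-change table computed with ground-truth guide/modality labels.

    Bypasses GMM calling so that estimator behaviour can be tested in
    isolation from guide-assignment noise.
    """
    from tfdosage import effects as fx
    from tfdosage import preprocess as pp
    d = small_dataset
    norm, ids = pp.normalize_log1p(d.counts, d.cell_ids)
    cm = d.cell_meta.set_index("cell_id").loc[ids]
    single = ~cm["guide_ids"].str.contains(";")
    norm = norm[:, single.to_numpy()]
    cm = cm[single]
    cells = pd.DataFrame({"guide_id": cm["guide_ids"].to_numpy(),
                          "modality": cm["modality"].to_numpy()})
    kept, _ = fx.filter_ntc_offtargets(norm, d.gene_ids, cells, d.guide_meta)
    eff = fx.compute_fold_changes(norm, d.gene_ids, cells, kept, d.guide_meta)
    return d, norm, cells, kept, eff
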