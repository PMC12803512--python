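"""Clustering, property tests, enrichment, cell-type and cis analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfdosage import downstream as ds
from tfdosage import simdata as sd


def _fit_table(genes, params, cis_gene="CIS1", responsive=True,
               nonmono=False, delta_aic=None):
    n = len(genes)
    tab = pd.DataFrame({
        "cis_gene": cis_gene, "trans_gene": genes, "fittable": True,
        "responsive": responsive if np.ndim(responsive) else
        [responsive] * n,
        "nonmonotonic": nonmono if np.ndim(nonmono) else [nonmono] * n,
        "delta_aic": delta_aic if delta_aic is not None else 1.0,
    })
    for p in ("a", "b", "c", "d"):
        tab[p] = params[p]
    return tab


class TestClustering:
    def test_identical_rows_merge_at_zero_height(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]] * 2 + [[9.0, 9.0, 9.0]],
                         index=["g1", "g2", "g3"])
        order, link, labels = ds.cluster_responses(m, k=2)
        assert link[0, 2] == pytest.approx(0.0)
        assert labels["g1"] == labels["g2"] != labels["g3"]

    def test_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(0)
        grid = np.linspace(-1.8, 0.5, 50)
        arch = [np.tanh(3 * grid), -np.tanh(3 * grid),
                np.exp(-(grid + 0.5) ** 2)]
        rows, truth = [], []
        for k, base in enumerate(arch):
            for i in range(30):
                rows.append(base + rng.normal(0, 0.02, len(grid)))
                truth.append(k)
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(90)])
        _, _, labels = ds.cluster_responses(m, k=3)
        assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.9

    def test_partition_invariant_under_row_permutation(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(20, 10)),
                         index=[f"g{i}" for i in range(20)])
        _, _, lab1 = ds.cluster_responses(m, k=4)
        perm = m.sample(frac=1.0, random_state=2)
        _, _, lab2 = ds.cluster_responses(perm, k=4)
        # same partition up to label renaming
        from sklearn.metrics import adjusted_rand_score
        common = list(m.index)
        assert adjusted_rand_score(lab1[common], lab2[common]) == 1.0

    def test_missing_values_rejected(self):
        m = pd.DataFrame([[1.0, np.nan]], index=["g"])
        with pytest.raises(ValueError):
            ds.cluster_responses(m)


class TestQualitativeProperties:
    def _ann(self, genes, flag):
        return pd.DataFrame({"gene_id": genes, "flagged": flag})

    def test_identical_groups_give_p_one(self):
        genes = [f"g{i}" for i in range(12)]
        params = {"a": 0.0, "b": -4.0, "c": 0.0, "d": 1.0}
        tab = _fit_table(genes, params)
        ann = self._ann(genes, [True] * 6 + [False] * 6)
        out = ds.test_qualitative_properties(tab, ann, flags=["flagged"])
        done = out[~out["skipped"]]
        assert (done["p_value"] == 1.0).all()

    def test_planted_range_difference_detected(self):
        # "housekeeping" genes generated with halved response range
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            genes = [f"g{i}" for i in range(80)]
            flag = [True] * 40 + [False] * 40
            d = np.where(flag, 0.4, 0.8) + rng.normal(0, 0.08, 80)
            tab = _fit_table(genes, {"a": 0.0, "b": -4.0, "c": 0.0, "d": d})
            ann = self._ann(genes, flag)
            out = ds.test_qualitative_properties(tab, ann, flags=["flagged"])
            row = out[(out["parameter"] == "range")].iloc[0]
            if row["fdr"] < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_small_groups_skipped(self):
        genes = [f"g{i}" for i in range(5)]
        tab = _fit_table(genes, {"a": 0, "b": -4, "c": 0, "d": 1})
        ann = self._ann(genes, [True] + [False] * 4)
        out = ds.test_qualitative_properties(tab, ann, flags=["flagged"])
        assert out["skipped"].all()

    def test_exclusions_remove_nonresponsive_and_nonmonotonic(self):
        genes = [f"g{i}" for i in range(12)]
        tab = _fit_table(genes, {"a": 0, "b": -4, "c": 0, "d": 1},
                         responsive=[True] * 10 + [False] * 2,
                         nonmono=[True] * 2 + [False] * 10)
        ann = self._ann(genes, [True] * 6 + [False] * 6)
        out = ds.test_qualitative_properties(tab, ann, flags=["flagged"])
        assert (out["n_yes"] + out["n_no"]).max() == 8


class TestQuantitativeProperties:
    def test_metric_equal_to_parameter_gives_r_one(self):
        genes = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(4)
        b = rng.normal(-4, 1, 20)
        tab = _fit_table(genes, {"a": 0.0, "b": b, "c": 0.0, "d": 1.0})
        ann = pd.DataFrame({"gene_id": genes, "metric": b})
        out = ds.correlate_quantitative_properties(tab, ann,
                                                   metrics=["metric"])
        row = out[out["parameter"] == "b"].iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_covariance_ratio_on_five_points(self):
        genes = list("abcde")
        vals = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        metric = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        tab = _fit_table(genes, {"a": vals, "b": -4.0, "c": 0.0, "d": 1.0})
        ann = pd.DataFrame({"gene_id": genes, "m": metric})
        out = ds.correlate_quantitative_properties(tab, ann, metrics=["m"])
        row = out[out["parameter"] == "a"].iloc[0]
        cov = np.mean((vals - vals.mean()) * (metric - metric.mean()))
        expected = cov / (vals.std() * metric.std())
        assert row["r"] == pytest.approx(expected, abs=1e-12)

    def test_planted_negative_phaplo_correlation(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(60)]
        rng_d = rng.uniform(0.2, 1.5, 60)
        phaplo = np.clip(1 - 0.6 * rng_d + rng.normal(0, 0.1, 60), 0, 1)
        tab = _fit_table(genes, {"a": 0.0, "b": -4.0, "c": 0.0, "d": rng_d})
        ann = pd.DataFrame({"gene_id": genes, "pHaplo": phaplo})
        out = ds.correlate_quantitative_properties(tab, ann,
                                                   metrics=["pHaplo"])
        row = out[out["parameter"] == "range"].iloc[0]
        assert row["r"] < 0 and row["fdr"] < 0.05

    def test_zero_variance_metric_skipped(self):
        genes = [f"g{i}" for i in range(10)]
        tab = _fit_table(genes, {"a": 0.0, "b": -4.0, "c": 0.0, "d": 1.0})
        ann = pd.DataFrame({"gene_id": genes, "m": 1.0})
        out = ds.correlate_quantitative_properties(tab, ann, metrics=["m"])
        assert out["skipped"].all()


class TestEnrichment:
    def test_known_table_odds_ratio_and_p(self):
        # build a network realizing the 2x2 table [[10,5],[5,10]]
        genes = [f"g{i}" for i in range(30)]
        delta = [1.0] * 15 + [-1.0] * 15          # 15 nonlinear, 15 not
        in_set = genes[:10] + genes[15:20]        # 10 nonlinear, 5 not
        tab = _fit_table(genes, {"a": 0, "b": -4, "c": 0, "d": 1},
                         delta_aic=delta)
        out = ds.enrichment_nonlinear(tab, {"s": in_set})
        row = out.iloc[0]
        assert [row["n11"], row["n12"], row["n21"], row["n22"]] == \
            [10, 5, 5, 10]
        assert row["log_odds"] == pytest.approx(np.log(4.0), abs=1e-12)
        assert row["p_value"] == pytest.approx(
            stats.fisher_exact([[10, 5], [5, 10]])[1], abs=1e-12)

    def test_null_simulation_controls_fdr(self):
        rng = np.random.default_rng(6)
        n_rep, hits, tests = 500, 0, 0
        genes = [f"g{i}" for i in range(40)]
        for rep in range(n_rep):
            delta = rng.choice([1.0, -1.0], 40)
            in_set = list(np.array(genes)[rng.random(40) < 0.4])
            tab = _fit_table(genes, {"a": 0, "b": -4, "c": 0, "d": 1},
                             delta_aic=delta)
            out = ds.enrichment_nonlinear(tab, {"s": in_set})
            row = out.iloc[0]
            if not row["skipped"]:
                tests += 1
                if row["fdr"] < 0.05:
                    hits += 1
        se = np.sqrt(0.05 * 0.95 / tests)
        assert hits / tests <= 0.05 + 3 * se

    def test_zero_cell_uses_haldane_and_flags(self):
        genes = [f"g{i}" for i in range(20)]
        delta = [1.0] * 10 + [-1.0] * 10
        in_set = genes[:5]     # all in-set genes nonlinear -> zero cell
        tab = _fit_table(genes, {"a": 0, "b": -4, "c": 0, "d": 1},
                         delta_aic=delta)
        out = ds.enrichment_nonlinear(tab, {"s": in_set})
        row = out.iloc[0]
        assert row["haldane_corrected"]
        assert np.isfinite(row["log_odds"])


class TestCellTypes:
    def _effects(self, vec, genes, guide="g1", modality="interference"):
        return pd.DataFrame({
            "guide_id": guide, "modality": modality, "gene_id": genes,
            "log2fc": vec, "target_cis_gene": "CIS1"})

    def test_matching_profile_correlates_perfectly(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(20)]
        vec = rng.normal(size=20)
        eff = self._effects(vec, genes)
        profiles = pd.DataFrame([vec, -vec], index=["same", "neg"],
                                columns=genes)
        out = ds.correlate_celltypes(eff, profiles, ["CIS1"]).set_index(
            "cell_type")
        assert out.loc["same", "r"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["neg", "r"] == pytest.approx(-1.0, abs=1e-12)

    def test_zscaling_mean_zero_sd_one(self):
        rng = np.random.default_rng(8)
        prof = pd.DataFrame(rng.lognormal(0, 1, size=(5, 30)),
                            index=[f"ct{i}" for i in range(5)],
                            columns=[f"G{i}" for i in range(30)])
        z = ds.zscale_profiles(prof)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_alignment_increases_with_designed_dosage(self):
        # profile built to align with the positive-dosage trans response:
        # guides with larger designed dosage correlate more strongly
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(30)]
        slopes = rng.normal(0, 0.6, 30)            # per-gene response/dosage
        dosages = np.linspace(-1.5, 0.8, 12)       # per-guide cis dosage
        frames = []
        for j, x in enumerate(dosages):
            frames.append(self._effects(
                slopes * x + rng.normal(0, 0.05, 30), genes,
                guide=f"g{j}"))
        eff = pd.concat(frames, ignore_index=True)
        profile = pd.DataFrame([slopes], index=["maturation"], columns=genes)
        out = ds.correlate_celltypes(eff, profile, ["CIS1"])
        out["dosage"] = [dosages[int(g[1:])] for g in out["guide_id"]]
        rho = stats.spearmanr(out["dosage"], out["r"])[0]
        assert rho >= 0.8

    def test_insufficient_shared_genes_raises(self):
        eff = self._effects([0.1], ["G0"])
        profiles = pd.DataFrame([[1.0]], index=["ct"], columns=["G0"])
        with pytest.raises(ValueError, match="shared genes"):
            ds.correlate_celltypes(eff, profiles, [])


class TestCisFeatures:
    def _effects_from_guides(self, guides, noise_sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for _, g in guides.iterrows():
            if g["guide_class"] == "NTC":
                continue
            for mod in ("interference", "activation"):
                rows.append({
                    "guide_id": g["guide_id"], "modality": mod,
                    "gene_id": g["target_cis_gene"],
                    "target_cis_gene": g["target_cis_gene"],
                    "log2fc": g[f"log2fc_{mod}"] + rng.normal(0, noise_sd),
                })
        return pd.DataFrame(rows)

    def test_trend_extremum_near_designed_efficacy_peak(self):
        guides = sd.build_guide_library(sd.SimulationConfig(), 11)
        eff = self._effects_from_guides(guides, noise_sd=0.05, seed=1)
        trend, _ = ds.cis_feature_analysis(eff, guides)
        t = trend.set_index("modality")
        assert abs(t.loc["interference", "extremum_offset_bp"] - 238) <= 100
        assert abs(t.loc["activation", "extremum_offset_bp"] - (-99)) <= 150

    def test_empty_annotation_skipped(self):
        guides = sd.build_guide_library(sd.SimulationConfig(), 11)
        eff = self._effects_from_guides(guides)
        _, overlap = ds.cis_feature_analysis(
            eff, guides, intervals={"far_peak": [(5000, 6000)]})
        assert overlap["skipped"].all()

    def test_null_overlap_p_is_large_when_distributions_match(self):
        # effects drawn independently of offset: being inside a peak
        # carries no information, so p-values should be well above 0.05
        # in the vast majority of replicates
        guides = sd.build_guide_library(sd.SimulationConfig(), 11)
        big = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            null = guides.copy()
            null["log2fc_interference"] = rng.normal(0, 0.5, len(null))
            null["log2fc_activation"] = rng.normal(0, 0.5, len(null))
            eff = self._effects_from_guides(null, noise_sd=0.0,
                                            seed=200 + rep)
            lo = rng.uniform(-1000, 0)
            _, overlap = ds.cis_feature_analysis(
                eff, null, intervals={"peak": [(lo, lo + 700)]})
            merged = overlap[~overlap["skipped"]]
            if len(merged) and (merged["p_value"] >= 0.05).all():
                big += 1
        assert big >= int(0.75 * n_rep)

    def test_summarize_global_response_zero_and_full_counts(self):
        genes = ["CIS1"] + [f"G{i}" for i in range(5)]
        eff = pd.DataFrame({
            "guide_id": "g1", "modality": "interference",
            "gene_id": genes, "target_cis_gene": "CIS1",
            "log2fc": 0.0, "fdr": 0.5})
        out = ds.summarize_global_response(eff, "CIS1",
                                           [f"G{i}" for i in range(5)])
        assert out.iloc[0]["mean_abs_trans_log2fc"] == 0.0
        assert out.iloc[0]["n_significant_trans"] == 0
        out_full = ds.summarize_global_response(
            eff, "CIS1", [f"G{i}" for i in range(5)], fdr_cutoff=1.0)
        assert out_full.iloc[0]["n_significant_trans"] == 5

    def test_control_network_summary_is_flat(self):
        # a cis gene with no true trans responses: mean |log2fc| does not
        # trend with dosage
        rng = np.random.default_rng(12)
        rows = []
        dosages = np.linspace(-1.5, 0.5, 20)
        for j, x in enumerate(dosages):
            rows.append({"guide_id": f"g{j}", "modality": "interference",
                         "gene_id": "CIS1", "target_cis_gene": "CIS1",
                         "log2fc": x, "fdr": 0.001})
            for i in range(30):
                rows.append({"guide_id": f"g{j}",
                             "modality": "interference",
                             "gene_id": f"G{i}", "target_cis_gene": "CIS1",
                             "log2fc": rng.normal(0, 0.02), "fdr": 0.9})
        eff = pd.DataFrame(rows)
        out = ds.summarize_global_response(
            eff, "CIS1", [f"G{i}" for i in range(30)])
        slope = stats.linregress(out["cis_log2fc"],
                                 out["mean_abs_trans_log2fc"])[0]
        assert abs(slope) < 0.02
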