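"""Statistics and classifier tests on synthetic feature tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphomi import (
    OMI_FEATURES,
    coefficient_of_variation,
    glass_delta,
    group_comparison,
    sample_cell_parameters,
    train_activation_classifier,
    train_phasor_classifier,
    umap_embed,
    zscore_cluster,
)
from lymphomi.simulate import default_activated, default_quiescent
from lymphomi.statsml import PHASOR_FEATURES


@pytest.fixture(scope="module")
def param_table():
    """Cell-parameter table with the default activated/quiescent contrast."""
    q = sample_cell_parameters(default_quiescent(), 300, "control", rng=11)
    a = sample_cell_parameters(default_activated(), 300, "stimulated", rng=22)
    table = pd.concat([q, a], ignore_index=True)
    table = table[table.activation != "unlabeled"].reset_index(drop=True)
    # ground-truth parameters stand in directly for fitted features
    table["orr_norm"] = table["orr"] / q["orr"].mean()
    table["nadh_a1"] = table["nadh_a1"] * 100
    table["fad_a1"] = table["fad_a1"] * 100
    return table


class TestGlassDelta:
    def test_identical_groups_give_zero(self):
        x = np.arange(10.0)
        assert glass_delta(x, x).delta == 0.0

    def test_formula(self, rng):
        control = rng.normal(10, 2, 20000)
        test = rng.normal(4, 5, 1000)
        es = glass_delta(control, test)
        assert es.delta == pytest.approx(3.0, abs=0.1)
        assert es.delta == (es.mu_control - es.mu_test) / es.sigma_control
        assert es.magnitude == "large"

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            glass_delta(np.ones(5), np.arange(5.0))

    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_equivariance(self, shift, scale):
        rng = np.random.default_rng(0)
        c = rng.normal(0, 1, 50)
        t = rng.normal(1, 1, 50)
        base = glass_delta(c, t).delta
        moved = glass_delta(c * scale + shift, t * scale + shift).delta
        assert moved == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestCV:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation(np.full(5, 3.0)) == 0.0

    def test_two_point_example(self):
        assert coefficient_of_variation(np.array([1.0, 3.0])) == pytest.approx(
            np.sqrt(2) / 2, rel=1e-12
        )

    def test_lognormal_monte_carlo(self, rng):
        cv_true = 0.3
        sigma = np.sqrt(np.log(1 + cv_true**2))
        x = rng.lognormal(0.0, sigma, 10_000)
        se = cv_true * np.sqrt((0.5 + cv_true**2) / 10_000)
        assert coefficient_of_variation(x) == pytest.approx(cv_true, abs=3 * se)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(np.array([-1.0, 1.0]))


class TestZscoreCluster:
    def test_zscores_are_standardized(self, param_table):
        res = zscore_cluster(param_table, OMI_FEATURES)
        np.testing.assert_allclose(res.zscores.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(res.zscores.std(ddof=0), 1.0, atol=1e-9)

    def test_two_cluster_cut_recovers_well_separated_groups(self):
        """Ward clustering on z-scores recovers two clearly separated
        populations (shifts of several control SDs on multiple features)."""
        from dataclasses import replace

        from lymphomi.simulate import ChannelPopulation

        q_pop = default_quiescent()
        a_pop = replace(
            default_activated(),
            nadh=ChannelPopulation(0.35, 0.05, 2.3, 0.15, 0.80, 0.025),
            orr_mean=0.62,
        )
        q = sample_cell_parameters(q_pop, 250, "control", rng=1)
        a = sample_cell_parameters(a_pop, 250, "stimulated", rng=2)
        t = pd.concat([q, a], ignore_index=True)
        t = t[t.activation != "unlabeled"].reset_index(drop=True)
        t["orr_norm"] = t["orr"] / q["orr"].mean()
        res = zscore_cluster(t, OMI_FEATURES)
        labels = t["activation"].to_numpy()
        cl = res.cluster_labels
        agree = max(
            np.mean((cl == 1) == (labels == "activated")),
            np.mean((cl == 2) == (labels == "activated")),
        )
        assert agree >= 0.95

    def test_duplicated_rows_merge_first_at_zero_distance(self, param_table):
        t = pd.concat([param_table.iloc[[0]], param_table.iloc[:20]], ignore_index=True)
        res = zscore_cluster(t, OMI_FEATURES)
        assert res.linkage_matrix[0, 2] == 0.0

    def test_constant_feature_error_names_it(self, param_table):
        t = param_table.copy()
        t["fad_tm"] = 1.0
        with pytest.raises(ValueError, match="fad_tm"):
            zscore_cluster(t, OMI_FEATURES)


class TestUMAP:
    def test_deterministic_and_separates_groups(self, param_table):
        emb1 = umap_embed(param_table, OMI_FEATURES, seed=5)
        emb2 = umap_embed(param_table, OMI_FEATURES, seed=5)
        np.testing.assert_array_equal(emb1, emb2)
        from sklearn.metrics import silhouette_score

        labels = param_table["activation"].to_numpy()
        assert silhouette_score(emb1, labels) > 0.25

    def test_scaling_preserves_cluster_structure(self, param_table):
        from sklearn.cluster import KMeans

        scaled = param_table.copy()
        scaled[OMI_FEATURES] = scaled[OMI_FEATURES] * 7.0
        e1 = umap_embed(param_table, OMI_FEATURES, seed=3)
        e2 = umap_embed(scaled, OMI_FEATURES, seed=3)
        k1 = KMeans(2, n_init=10, random_state=0).fit_predict(e1)
        k2 = KMeans(2, n_init=10, random_state=0).fit_predict(e2)
        agree = max(np.mean(k1 == k2), np.mean(k1 != k2))
        assert agree >= 0.9

    def test_too_few_cells_rejected(self, param_table):
        with pytest.raises(ValueError):
            umap_embed(param_table.iloc[:10], OMI_FEATURES)


class TestActivationClassifier:
    def test_separable_populations_classify_well(self, param_table):
        rep = train_activation_classifier(param_table, seed=0)
        assert rep.accuracy >= 0.90
        assert rep.confusion.sum() == rep.test_size
        assert rep.importances.sum() == pytest.approx(100.0, abs=1e-6)

    def test_reproducible_for_fixed_seed(self, param_table):
        r1 = train_activation_classifier(param_table, seed=7)
        r2 = train_activation_classifier(param_table, seed=7)
        assert r1.accuracy == r2.accuracy and r1.auc == r2.auc
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        pd.testing.assert_series_equal(r1.importances, r2.importances)

    def test_perfectly_separable_feature_dominates(self, param_table):
        t = param_table.copy()
        t["oracle"] = (t["activation"] == "activated").astype(float)
        rep = train_activation_classifier(t, features=OMI_FEATURES + ["oracle"], seed=1)
        assert rep.accuracy == 1.0
        assert rep.importances["oracle"] == rep.importances.max()

    def test_single_class_rejected(self, param_table):
        sub = param_table[param_table.activation == "activated"]
        with pytest.raises(ValueError):
            train_activation_classifier(sub)

    def test_best_named_subset_bounds_all_subsets(self, param_table):
        """No named feature subset beats the best one found by exhaustive
        search over the named subsets (monotonicity is not assumed)."""
        rep_all = train_activation_classifier(param_table, seed=0)
        top4 = list(rep_all.importances.sort_values(ascending=False).index[:4])
        subsets = {
            "all": OMI_FEATURES,
            "nadh": ["nadh_tm", "nadh_tau1", "nadh_tau2", "nadh_a1"],
            "top4": top4,
            "single": [rep_all.importances.idxmax()],
        }
        aucs = {
            name: train_activation_classifier(
                param_table, features=f, feature_set=name, seed=0
            ).auc
            for name, f in subsets.items()
        }
        best = max(aucs.values())
        assert all(a <= best for a in aucs.values())


@pytest.fixture(scope="module")
def phasor_table():
    rng = np.random.default_rng(4)
    n = 300
    rows = []
    for label, (g_shift, s_shift) in (("quiescent", (0, 0)), ("activated", (0.06, 0.02))):
        base = {
            "nadh_g1": 0.55 + g_shift, "nadh_s1": 0.40 + s_shift,
            "nadh_g2": 0.35 + g_shift, "nadh_s2": 0.38 + s_shift,
            "fad_g1": 0.60, "fad_s1": 0.38, "fad_g2": 0.40, "fad_s2": 0.36,
        }
        block = pd.DataFrame(
            {k: rng.normal(v, 0.02, n) for k, v in base.items()}
        )
        block["activation"] = label
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


class TestPhasorClassifier:
    @pytest.mark.parametrize("model", ["random_forest", "logistic"])
    def test_separated_chord_classifies(self, phasor_table, model):
        rep = train_phasor_classifier(phasor_table, model=model, seed=0)
        assert rep.accuracy >= 0.85
        assert rep.importances.sum() == pytest.approx(100.0, abs=1e-6)

    def test_duplicate_features_still_run(self, phasor_table):
        t = phasor_table.copy()
        for ch in ("g1", "s1", "g2", "s2"):
            t[f"fad_{ch}"] = t[f"nadh_{ch}"]
        rep = train_phasor_classifier(t, seed=0)
        assert 0.0 <= rep.accuracy <= 1.0

    def test_both_harmonics_at_least_match_single(self, phasor_table):
        single = [f for f in PHASOR_FEATURES if f.endswith("1")]
        rep_single = train_phasor_classifier(phasor_table, features=single, seed=0)
        rep_both = train_phasor_classifier(phasor_table, seed=0)
        assert rep_both.auc >= rep_single.auc - 0.02


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        x = np.arange(20.0)
        res = group_comparison({"a": x, "b": x.copy()})
        assert res.method == "t-test"
        assert res.pvalue == pytest.approx(1.0)

    def test_shifted_normals_detected(self, rng):
        res = group_comparison(
            {"a": rng.normal(0, 1, 200), "b": rng.normal(2, 1, 200)}
        )
        assert res.pvalue < 1e-10

    def test_three_groups_dispatch_to_kruskal_with_posthoc(self, rng):
        groups = {
            "a": rng.normal(0, 1, 50),
            "b": rng.normal(0, 1, 50),
            "c": rng.normal(3, 1, 50),
        }
        res = group_comparison(groups)
        assert res.method == "kruskal-wallis"
        ph = res.posthoc.set_index(["group_a", "group_b"])
        assert ph.loc[("a", "c"), "pvalue_holm"] < 0.001
        assert ph.loc[("a", "b"), "pvalue_holm"] > 0.05
        assert (ph["pvalue_holm"] >= ph["pvalue"] - 1e-12).all()
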