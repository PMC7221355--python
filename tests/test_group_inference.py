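import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportions_ztest

import topoconnect as tc
from topoconnect.group_inference import _clusters_of
from tests.conftest import random_connectivity


def null_feature_phenotypes(n0=50, n1=50, seed=0):
    """Features independent of group, with realistic covariates."""
    rng = np.random.default_rng(seed)
    n = n0 + n1
    g = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    phen = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": g,
            "sex": rng.integers(0, 2, n),
            "age": rng.normal(11, 3, n).clip(5),
            "motion": np.abs(rng.normal(0.07, 0.05, n)),
        }
    )
    feats = pd.DataFrame(rng.standard_normal((n, 3)), columns=["auc", "slope", "kurtosis"])
    feats.insert(0, "subject_id", phen.subject_id)
    return feats, phen


class TestZScore:
    def test_simple_column(self):
        df = pd.DataFrame({"age": [1.0, 2.0, 3.0]})
        out = tc.zscore_features(df, columns=["age"])
        assert np.allclose(out["age"], [-1, 0, 1])

    def test_idempotent_and_standardized(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 2)), columns=["auc", "motion"])
        once = tc.zscore_features(df)
        twice = tc.zscore_features(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)
        assert np.allclose(once.mean(), 0, atol=1e-12)
        assert np.allclose(once.std(ddof=1), 1, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            tc.zscore_features(pd.DataFrame({"auc": [1.0, 1.0, 1.0]}))


class TestGroupModel:
    def test_null_features_cover_one(self):
        feats, phen = null_feature_phenotypes(60, 60, seed=3)
        model = tc.fit_group_model(feats, phen)
        assert model.converged_
        lo, hi = model.conf_int_.loc["auc"]
        assert lo < 1 < hi
        assert model.n_cases_ == 60 and model.n_controls_ == 60

    def test_or_equals_exp_beta(self):
        feats, phen = null_feature_phenotypes(40, 40, seed=4)
        model = tc.fit_group_model(feats, phen)
        assert np.allclose(
            model.odds_ratios_.to_numpy(), np.exp(model.params_.to_numpy()), atol=1e-12
        )
        sf = model.summary_frame()
        assert list(sf.columns) == ["term", "beta", "or", "ci_low", "ci_high", "p"]

    def test_group_recode_inverts_or(self):
        feats, phen = null_feature_phenotypes(45, 55, seed=5)
        m1 = tc.fit_group_model(feats, phen)
        flipped = phen.assign(group=1 - phen.group)
        m2 = tc.fit_group_model(feats, flipped)
        assert m2.odds_ratios_["auc"] == pytest.approx(
            1 / m1.odds_ratios_["auc"], rel=1e-6
        )
        assert m2.pvalues_["auc"] == pytest.approx(m1.pvalues_["auc"], rel=1e-6)

    def test_separation_is_flagged_not_raised(self):
        feats, phen = null_feature_phenotypes(25, 25, seed=6)
        feats = feats.assign(auc=phen.group * 10.0 - 5.0)  # perfect separator
        model = tc.fit_group_model(feats, phen)
        assert model.converged_ is False

    def test_validation_errors(self):
        feats, phen = null_feature_phenotypes(30, 30, seed=7)
        with pytest.raises(ValueError, match="motion"):
            tc.fit_group_model(feats, phen.drop(columns=["motion"]))
        with pytest.raises(ValueError, match="at least 20"):
            tc.fit_group_model(feats.head(10), phen.head(10))
        renamed = feats.assign(subject_id=feats.subject_id + "_x")
        with pytest.raises(ValueError, match="mismatch"):
            tc.fit_group_model(renamed, phen)


class TestSubnetworkScan:
    def test_whole_brain_equals_single_label_scan(self, small_cohort):
        cms, phen, part = small_cohort
        whole = tc.Partition(part.node_ids, ["all"] * len(part.node_ids))
        scan = tc.subnetwork_scan(cms, whole, phen)
        feats = tc.features_table(cms, phen.subject_id)
        model = tc.fit_group_model(feats, phen)
        cell = scan.cells_.iloc[0]
        assert cell["or_auc"] == pytest.approx(model.odds_ratios_["auc"], abs=1e-10)
        assert cell["p_auc"] == pytest.approx(model.pvalues_["auc"], abs=1e-10)

    def test_cell_grid_shape(self, small_cohort):
        cms, phen, part = small_cohort
        scan = tc.subnetwork_scan(cms, part, phen)
        k = part.k
        assert len(scan.cells_) == k * (k + 1) // 2
        assert scan.cells_["evaluable"].all()

    def test_small_networks_marked_unevaluable(self, small_cohort):
        cms, phen, _ = small_cohort
        n = cms[0].n
        labels = ["tiny"] * 3 + ["rest"] * (n - 3)
        part = tc.Partition(list(cms[0].node_ids), labels)
        scan = tc.subnetwork_scan(cms, part, phen)
        cells = scan.cells_.set_index("cell")
        assert not cells.loc["tiny", "evaluable"]
        assert cells.loc["rest", "evaluable"]

    def test_fwe_p_lower_bound_and_reproducibility(self, small_cohort):
        cms, phen, part = small_cohort
        a = tc.subnetwork_scan(cms, part, phen, n_perm=50, seed=8)
        b = tc.subnetwork_scan(cms, part, phen, n_perm=50, seed=8)
        assert np.array_equal(a.null_max_, b.null_max_)
        for p in a.p_fwe_:
            assert p >= 1 / 51

    def test_fwe_correct_on_completed_scan(self, small_cohort):
        cms, phen, part = small_cohort
        scan = tc.subnetwork_scan(cms, part, phen)
        assert scan.p_fwe_ == []
        tc.fwe_correct(scan, phen, n_perm=100, seed=3)
        assert len(scan.p_fwe_) == len(scan.clusters_)
        redo = tc.subnetwork_scan(cms, part, phen, n_perm=100, seed=3)
        assert scan.p_fwe_ == redo.p_fwe_
        with pytest.raises(ValueError, match="n_perm"):
            tc.fwe_correct(scan, phen, n_perm=10)


class TestClusterRule:
    def test_no_significant_cells(self):
        assert _clusters_of([]) == []

    def test_full_grid_single_cluster(self):
        nets = ["a", "b", "c", "d"]
        cells = [(x,) for x in nets] + [
            (x, y) for i, x in enumerate(nets) for y in nets[i + 1 :]
        ]
        clusters = _clusters_of(cells)
        assert len(clusters) == 1
        assert len(clusters[0]) == 10  # k(k+1)/2 with k=4

    def test_disjoint_components(self):
        clusters = _clusters_of([("a",), ("a", "b"), ("c", "d")])
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [1, 2]

    def test_self_loop_only(self):
        clusters = _clusters_of([("a",)])
        assert clusters == [[("a",)]]


class TestEdgeProportions:
    def test_known_counts_match_z_oracle(self):
        # 9/10 cases vs 2/10 controls present: pooled z about 3.15
        d_case = [np.full((2, 2), 0.1) for _ in range(9)] + [np.full((2, 2), 1.5)]
        d_ctrl = [np.full((2, 2), 0.1) for _ in range(2)] + [np.full((2, 2), 1.5)] * 8
        for m in d_case + d_ctrl:
            np.fill_diagonal(m, 0.0)
        groups = [1] * 10 + [0] * 10
        res = tc.edge_proportion_test(d_case + d_ctrl, groups, eps=0.5)
        row = res.iloc[0]
        assert row.prop_case == pytest.approx(0.9)
        assert row.prop_control == pytest.approx(0.2)
        stat, p = proportions_ztest([9, 2], [10, 10])
        assert row.p == pytest.approx(p, abs=1e-12)
        assert abs(stat) == pytest.approx(3.15, abs=0.01)
        assert bool(row["mask"]) is True

    def test_identical_groups_no_mask(self, rng):
        dms = [tc.to_distance(random_connectivity(6, rng)) for _ in range(8)]
        both = dms + [tc.DistanceMatrix(list(d.node_ids), d.d.copy()) for d in dms]
        res = tc.edge_proportion_test(both, [0] * 8 + [1] * 8, eps=0.6)
        assert np.allclose(res["diff"], 0)
        assert not res["mask"].any()

    def test_saturated_threshold(self, rng):
        dms = [tc.to_distance(random_connectivity(5, rng)) for _ in range(10)]
        res = tc.edge_proportion_test(dms, [0] * 5 + [1] * 5, eps=2.0)
        assert (res.prop_case == 1).all() and (res.prop_control == 1).all()
        assert (res.p == 1).all()
        assert not res["mask"].any()

    def test_label_swap_flips_diff(self, rng):
        dms = [tc.to_distance(random_connectivity(7, rng)) for _ in range(12)]
        g = [0] * 5 + [1] * 7
        a = tc.edge_proportion_test(dms, g, eps=0.8)
        b = tc.edge_proportion_test(dms, [1 - x for x in g], eps=0.8)
        assert np.allclose(a["diff"], -b["diff"])
        assert np.allclose(a["p"], b["p"])

    def test_errors(self, rng):
        dms = [tc.to_distance(random_connectivity(4, rng))]
        with pytest.raises(ValueError, match="non-empty"):
            tc.edge_proportion_test(dms, [0], eps=0.5)
        with pytest.raises(ValueError, match="eps"):
            tc.edge_proportion_test(dms, [0], eps=3.0)

    def test_scan_stacks_thresholds(self, rng):
        cms = [random_connectivity(5, rng) for _ in range(6)]
        res = tc.edge_proportion_scan(cms, [0, 0, 0, 1, 1, 1], eps_list=(0.5, 1.0))
        assert sorted(res.eps.unique()) == [0.5, 1.0]
        assert len(res) == 2 * 10  # two thresholds x C(5,2) edges


class TestEffectSizes:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((12.26, 3.07, 96, 10.5, 2.48, 81), 0.63),
            ((111.27, 13.92, 96, 108.22, 13.69, 81), 0.22),
        ],
    )
    def test_cohens_d_summaries(self, args, expected):
        assert round(tc.cohens_d_summary(*args), 2) == expected

    def test_cohens_d_equal_means(self):
        assert tc.cohens_d_summary(5, 1, 10, 5, 2, 10) == 0.0

    def test_cohens_d_invalid(self):
        with pytest.raises(ValueError):
            tc.cohens_d_summary(1, 0, 10, 2, 1, 10)
        with pytest.raises(ValueError):
            tc.cohens_d_summary(1, 1, 1, 2, 1, 10)

    def test_odds_ratio_basic(self):
        assert tc.odds_ratio_2x2(1, 1, 1, 1) == 1.0
        assert tc.odds_ratio_2x2(51, 45, 22, 59) == pytest.approx(3.0394, abs=1e-4)

    def test_odds_ratio_haldane_correction(self):
        val = tc.odds_ratio_2x2(0, 5, 5, 5)
        assert np.isfinite(val) and val > 0
        assert val == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    def test_odds_ratio_undefined(self):
        with pytest.raises(ValueError):
            tc.odds_ratio_2x2(0, 0, 3, 4)
        with pytest.raises(ValueError):
            tc.odds_ratio_2x2(0, 3, 0, 4)
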