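import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphnet.cohort import load_reported_edge_changes
from morphnet.io import zscore_features
from morphnet.network import ConnMatrix, build_network
from morphnet.stats import (
    bh_fdr,
    classify_edge_change,
    consensus_from_fractions,
    consensus_hubs,
    edgewise_comparison,
    exclude_outliers,
    ks_normality,
    mmse_screen,
    rank_transform,
    screening_thresholds,
    spearman,
    two_sample_test,
)


class TestRankTransform:
    def test_mean_rank_ties(self):
        np.testing.assert_allclose(rank_transform([3, 1, 4, 1]), [3, 1.5, 4, 1.5])

    def test_strictly_increasing(self):
        np.testing.assert_allclose(rank_transform([0.1, 0.5, 0.6, 2.0]), [1, 2, 3, 4])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_rank_sum_conservation(self, values):
        n = len(values)
        assert rank_transform(values).sum() == pytest.approx(n * (n + 1) / 2)

    def test_order_preserving(self, rng):
        x = rng.normal(size=30)
        r = rank_transform(x)
        assert np.all(np.argsort(r, kind="stable") == np.argsort(x, kind="stable"))


class TestKSNormality:
    def test_normal_samples_rarely_reject_hard(self):
        rng = np.random.default_rng(0)
        pvals = [ks_normality(rng.standard_normal(200)) for _ in range(300)]
        # Lilliefors table p-values are clipped, so assert tail behavior only
        assert np.mean(np.asarray(pvals) < 0.01) <= 0.05

    def test_lognormal_samples_mostly_reject(self):
        rng = np.random.default_rng(1)
        pvals = [ks_normality(np.exp(rng.standard_normal(200))) for _ in range(100)]
        assert np.mean(np.asarray(pvals) < 0.05) >= 0.9

    def test_shifted_symmetric_behaves_as_normal(self):
        rng = np.random.default_rng(2)
        pvals = [ks_normality(100.0 + 0.1 * rng.standard_normal(200)) for _ in range(100)]
        assert np.mean(np.asarray(pvals) < 0.01) <= 0.05

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            ks_normality(np.array([1.0, 2.0]))


class TestTwoSampleTest:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_test(a, list(a), tails="two")
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_swap_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        r1 = two_sample_test(a, b, tails="two")
        r2 = two_sample_test(b, a, tails="two")
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_pooled_t_textbook_oracle(self):
        a = [1.2, 2.3, 0.9, 1.8, 2.0, 1.5]
        b = [2.1, 2.9, 3.3, 2.4, 2.8, 3.0]
        # independent oracle: explicit pooled-variance formula
        na, nb = len(a), len(b)
        va = np.var(a, ddof=1)
        vb = np.var(b, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t_expected = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        res = two_sample_test(a, b, tails="two")
        assert not res.welch
        assert res.t == pytest.approx(t_expected, abs=1e-12)

    def test_levene_gate_selects_welch(self, rng):
        from scipy import stats as sps

        a = rng.normal(0, 0.05, 30)
        b = rng.normal(0.5, 5.0, 30)
        res = two_sample_test(a, b, tails="two")
        assert res.welch
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_one_tailed_observed_halves_p(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(2, 1, 10)
        two = two_sample_test(a, b, tails="two")
        one = two_sample_test(a, b, tails="one", direction="observed")
        assert one.p == pytest.approx(two.p / 2)

    def test_fixed_direction(self, rng):
        a, b = rng.normal(2, 1, 10), rng.normal(0, 1, 10)  # a > b
        with_dir = two_sample_test(a, b, tails="one", direction=+1.0)
        against = two_sample_test(a, b, tails="one", direction=-1.0)
        assert with_dir.p < 0.05 < against.p

    def test_degenerate_variance_both_groups(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_sample_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


def bh_stepup_oracle(p, alpha):
    """Literal step-up rule: reject all p <= largest p(k) with p(k) <= k*alpha/m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    thresh = 0.0
    for k in range(m, 0, -1):
        if p[order[k - 1]] <= k * alpha / m:
            thresh = p[order[k - 1]]
            break
    return p <= thresh if thresh > 0 else np.zeros(m, bool)


class TestBHFDR:
    def test_all_ones_no_rejections(self):
        q, reject = bh_fdr([1.0] * 5)
        assert not reject.any()

    def test_stepup_enumeration_example(self):
        # k=4 passes since 0.04 <= 4*0.05/4, so everything is rejected
        q, reject = bh_fdr([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert reject.all()

    def test_matches_stepup_oracle_on_random_p(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 1, 40) ** 2
            q, reject = bh_fdr(p, alpha=0.05)
            np.testing.assert_array_equal(reject, bh_stepup_oracle(p, 0.05))

    def test_alpha_monotonicity(self, rng):
        p = rng.uniform(0, 0.2, 30)
        _, strict = bh_fdr(p, alpha=0.01)
        _, loose = bh_fdr(p, alpha=0.05)
        assert np.all(loose[strict])  # strict rejections subset of loose

    def test_q_at_least_p(self, rng):
        p = rng.uniform(0, 1, 50)
        q, _ = bh_fdr(p)
        assert np.all(q >= p - 1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestClassifyEdgeChange:
    @pytest.mark.parametrize(
        "nc,ad,expected",
        [
            (0.80, 0.42, "decrease-positive"),
            (-0.15, 0.05, "decrease-negative"),
            (0.06, -0.29, "increase-negative"),
            (-0.15, 0.15, "increase-positive"),  # boundary |ad| == |nc|
            (0.25, 0.58, "increase-positive"),
            (-0.97, -0.80, "decrease-negative"),
            (-0.75, -0.79, "increase-negative"),
        ],
    )
    def test_known_pairs(self, nc, ad, expected):
        assert classify_edge_change(nc, ad) == expected

    def test_reproduces_all_52_reference_rows(self):
        df = load_reported_edge_changes()
        assert len(df) == 52
        predicted = [classify_edge_change(r.r_nc, r.r_ad) for r in df.itertuples()]
        assert predicted == list(df["reported_class"])
        counts = pd.Series(predicted).value_counts()
        assert counts["decrease-positive"] == 17
        assert counts["decrease-negative"] == 17
        assert counts["increase-positive"] == 9
        assert counts["increase-negative"] == 9


class TestExcludeOutliers:
    def test_iqr_fence_oracle(self):
        values = [1.0, 2.0, 3.0, 100.0]
        q1, q3 = np.percentile(values, [25, 75])
        fence_hi = q3 + 1.5 * (q3 - q1)
        assert 100.0 > fence_hi  # oracle: 100 lies beyond the fence
        keep, log = exclude_outliers(values, rule="iqr")
        assert keep.tolist() == [True, True, True, False]
        assert log["n_excluded"] == 1

    def test_clean_sample_untouched(self, rng):
        values = rng.uniform(0, 1, 50)
        keep, _ = exclude_outliers(values, rule="iqr")
        assert keep.all()

    def test_rule_off(self):
        keep, log = exclude_outliers([1.0, 2.0, 1000.0], rule="off")
        assert keep.all() and log["rule"] == "off"

    def test_zscore_rule(self, rng):
        values = np.concatenate([rng.normal(0, 1, 100), [50.0]])
        keep, _ = exclude_outliers(values, rule="zscore")
        assert not keep[-1]

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            exclude_outliers([1.0, 2.0, 3.0, 4.0], rule="grubbs")


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman([1, 2, 3, 4], [10, 20, 25, 100]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman([1, 2, 3, 4], [9, 7, 3, 1]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 5.0]
        rx, ry = rank_transform(x), rank_transform(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_missing(self):
        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def _networks_from_tensors(atlas, rng, n, perturb=None):
    """Small helper: random standardized cohorts -> ConnMatrix list."""
    from morphnet.io import DEFAULT_FEATURES, FeatureTensor

    nets = []
    for i in range(n):
        values = rng.normal(0, 1, size=(1, 68, 5))
        if perturb is not None:
            values = perturb(values)
        t = FeatureTensor(
            values=values, subjects=(f"s{i}",), features=DEFAULT_FEATURES, atlas=atlas
        )
        nets.append(build_network(zscore_features(t), f"s{i}"))
    return nets


class TestEdgewiseComparison:
    def test_output_contract(self, atlas, rng):
        nc = _networks_from_tensors(atlas, rng, 4)
        ad = _networks_from_tensors(atlas, rng, 4)
        df = edgewise_comparison(nc, ad, tails="two", outlier_rule="off")
        assert len(df) == 2278
        assert np.all(df["q"] >= df["p"] - 1e-12)
        assert np.all(df.loc[df["significant"], "q"] <= 0.05)
        assert set(df.loc[~df["significant"], "change_class"]) <= {"none"}
        sig = df["significant"]
        assert (df.loc[sig, "change_class"] != "none").all()

    def test_monotone_transform_invariance(self, atlas, rng):
        # rank transform makes t and p invariant to r -> r^3
        nc = _networks_from_tensors(atlas, rng, 5)
        ad = _networks_from_tensors(atlas, rng, 5)
        df1 = edgewise_comparison(nc, ad, tails="two", outlier_rule="off")

        def cube(conns):
            return [
                ConnMatrix(r=np.sign(c.r) * np.abs(c.r) ** 3, subject=c.subject, atlas=atlas)
                for c in conns
            ]

        df2 = edgewise_comparison(cube(nc), cube(ad), tails="two", outlier_rule="off")
        np.testing.assert_allclose(df1["t"], df2["t"], atol=1e-9)
        np.testing.assert_allclose(df1["p"], df2["p"], atol=1e-9)

    def test_outlier_exclusion_recorded(self, atlas, rng):
        nc = _networks_from_tensors(atlas, rng, 6)
        ad = _networks_from_tensors(atlas, rng, 6)
        df = edgewise_comparison(nc, ad, outlier_rule="iqr", tails="two")
        assert (df["n_excluded_nc"] >= 0).all()
        assert len(df) == 2278

    def test_needs_two_subjects(self, atlas, rng):
        nets = _networks_from_tensors(atlas, rng, 2)
        with pytest.raises(ValueError):
            edgewise_comparison(nets[:1], nets)


class TestConsensusHubs:
    def test_worked_fraction_example(self):
        flags = consensus_from_fractions([0.45, 0.30, 0.25], threshold=0.30)
        assert flags.tolist() == [True, True, False]

    def test_threshold_zero_boundary(self, atlas):
        hub_sets = [{"ENT_L"}, set(), set()]
        df = consensus_hubs(hub_sets, atlas, threshold=0.0)
        assert df["is_hub"].all()  # every region has fraction >= 0

    def test_empty_hub_sets(self, atlas):
        df = consensus_hubs([set(), set()], atlas, threshold=0.30)
        assert not df["is_hub"].any()
        assert (df["fraction"] == 0).all()

    def test_subject_permutation_invariance(self, atlas, rng):
        sets = [
            {"ENT_L", "PC_L"},
            {"ENT_L"},
            {"LOCC_R", "ENT_L"},
            set(),
        ]
        df1 = consensus_hubs(sets, atlas)
        df2 = consensus_hubs(sets[::-1], atlas)
        pd.testing.assert_frame_equal(df1, df2)

    def test_fraction_arithmetic(self, atlas):
        sets = [{"ENT_L"}] * 7 + [set()] * 13  # 7/20 = 0.35
        df = consensus_hubs(sets, atlas, threshold=0.30).set_index("region")
        assert df.loc["ENT_L", "fraction"] == pytest.approx(0.35)
        assert bool(df.loc["ENT_L", "is_hub"])
        assert df["is_hub"].sum() == 1


class TestMMSEScreen:
    def _table(self):
        return pd.DataFrame(
            {
                "subject": ["a", "b", "c", "d"],
                "group": ["NC", "NC", "AD", "AD"],
                "mmse": [29, 30, 25, 29],
                "e_global": [0.60, 0.62, 0.40, 0.41],
                "m_e_local": [0.70, 0.72, 0.50, 0.51],
                "m_bc": [20.0, 21.0, 35.0, 34.0],
            }
        )

    def test_low_zone_always_ad(self):
        out = mmse_screen(self._table())
        assert out.set_index("subject").loc["c", "predicted"] == "AD"
        assert out.set_index("subject").loc["c", "zone"] == "low"

    def test_high_zone_uses_properties(self):
        out = mmse_screen(self._table(), voting="majority").set_index("subject")
        assert out.loc["a", "predicted"] == "NC"  # well above thresholds
        assert out.loc["d", "predicted"] == "AD"  # in zone but AD-like properties

    def test_high_e_global_majority_is_nc(self):
        table = self._table()
        thresholds = screening_thresholds(table)
        row = pd.DataFrame(
            {
                "subject": ["x"],
                "mmse": [29],
                "e_global": [thresholds["e_global"] + 1.0],
                "m_e_local": [thresholds["m_e_local"] + 1.0],
                "m_bc": [thresholds["m_bc"] - 5.0],
            }
        )
        out = mmse_screen(row, thresholds=thresholds, voting="majority")
        assert out["predicted"].iloc[0] == "NC"

    def test_missing_mmse_fatal(self):
        bad = self._table()
        bad.loc[0, "mmse"] = np.nan
        with pytest.raises(ValueError, match="MMSE"):
            mmse_screen(bad)
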