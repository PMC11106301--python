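import numpy as np
import pandas as pd
import pytest

from mblfp import interbrain as ib
from mblfp.spectral import HlrSeries

from conftest import calibration_config, make_annotations


def series(values, subject="m1", cohort="c01", condition="group", valid=None):
    values = np.asarray(values, dtype=float)
    return HlrSeries(
        subject_id=subject, cohort_id=cohort, condition=condition,
        values=values,
        valid=np.ones(len(values), bool) if valid is None else np.asarray(valid, bool),
    )


def iid_pool(rng, n_cohorts=3, n_subjects=4, n=500, condition="group"):
    return [
        series(rng.normal(size=n), subject=f"m{j+1}", cohort=f"c{i+1:02d}",
               condition=condition)
        for i in range(n_cohorts)
        for j in range(n_subjects)
    ]


class TestPairCorrelation:
    def test_identical_series_correlate_fully(self, rng):
        x = rng.normal(size=100)
        pc = ib.pair_correlation(series(x, "m1"), series(x, "m2"))
        assert pc.r == pytest.approx(1.0)

    def test_negated_series_anticorrelate(self, rng):
        x = rng.normal(size=100)
        pc = ib.pair_correlation(series(x, "m1"), series(-x, "m2"))
        assert pc.r == pytest.approx(-1.0)

    def test_symmetry(self, rng):
        a = series(rng.normal(size=200), "m1")
        b = series(rng.normal(size=200), "m2")
        assert ib.pair_correlation(a, b).r == ib.pair_correlation(b, a).r

    def test_constant_series_flagged_undefined(self):
        pc = ib.pair_correlation(series(np.ones(50), "m1"),
                                 series(np.arange(50.0), "m2"))
        assert np.isnan(pc.r)

    def test_lag_scan_peaks_at_planted_lead(self, rng):
        x = rng.normal(size=500)
        a = series(x, "m1")
        b = series(np.concatenate([[0.0], x[:-1]]), "m2")  # m1 leads by 1 s
        scan = ib.lagged_correlation(a, b, max_lag_s=3).set_index("lag_s")
        assert scan["r"].idxmax() == 1
        assert scan.loc[1, "r"] > 0.99

    def test_invalid_seconds_dropped_pairwise(self, rng):
        x = rng.normal(size=100)
        va = np.ones(100, bool); va[:10] = False
        a = series(x, "m1", valid=va)
        b = series(x, "m2")
        pc = ib.pair_correlation(a, b)
        assert pc.n == 90 and pc.r == pytest.approx(1.0)


class TestCombinations:
    def test_group_class_combinatorics(self, rng):
        pool = iid_pool(rng, n_cohorts=3, n_subjects=4)
        pairs = ib.build_combinations(pool, "group")
        assert len(pairs) == 3 * 6  # 3 cohorts x C(4,2)
        assert all(a.cohort_id == b.cohort_id for a, b in pairs)

    def test_group_shuffled_excludes_same_cohort(self, rng):
        pool = iid_pool(rng, n_cohorts=3, n_subjects=4)
        pairs = ib.build_combinations(pool, "group_shuffled")
        assert pairs and all(a.cohort_id != b.cohort_id for a, b in pairs)

    def test_group_single_shuffled_mixes_conditions(self, rng):
        pool = iid_pool(rng, 2, 2, condition="group") + iid_pool(
            rng, 2, 2, condition="single"
        )
        pairs = ib.build_combinations(pool, "group_single_shuffled")
        assert pairs
        for a, b in pairs:
            assert a.cohort_id == b.cohort_id
            assert {a.condition, b.condition} == {"group", "single"}

    def test_no_self_pairs(self, rng):
        pool = iid_pool(rng)
        for cls in ("group", "group_shuffled"):
            for a, b in ib.build_combinations(pool, cls):
                assert a.key != b.key

    def test_unsatisfiable_class_rejected(self, rng):
        pool = iid_pool(rng, n_cohorts=1)
        with pytest.raises(ValueError):
            ib.build_combinations(pool, "group_shuffled")


class TestPermutationNull:
    def test_same_seed_identical_draws(self, rng):
        pool = iid_pool(rng)
        n1 = ib.permutation_null(pool, n_draws=1500, seed=42)
        n2 = ib.permutation_null(pool, n_draws=1500, seed=42)
        np.testing.assert_array_equal(n1.draws, n2.draws)

    def test_pool_order_exchangeability(self, rng):
        pool = iid_pool(rng, n=2000)
        shuffled = list(pool)
        np.random.default_rng(1).shuffle(shuffled)
        n1 = ib.permutation_null(pool, n_draws=4000, seed=0)
        n2 = ib.permutation_null(shuffled, n_draws=4000, seed=0)
        assert abs(n1.mean - n2.mean) < 0.005
        assert abs(n1.sd - n2.sd) < 0.005

    def test_band_is_ordered_and_centred(self, rng):
        pool = iid_pool(rng)
        null = ib.permutation_null(pool, n_draws=2000, seed=0)
        lo, hi = null.band
        assert lo < null.mean < hi

    def test_small_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            ib.permutation_null(iid_pool(rng)[:3], n_draws=1000)

    def test_few_draws_warn(self, rng):
        with pytest.warns(UserWarning):
            ib.permutation_null(iid_pool(rng), n_draws=500, seed=0)

    def test_percentile_of(self, rng):
        null = ib.permutation_null(iid_pool(rng), n_draws=2000, seed=0)
        assert null.percentile_of(1.0) == 100.0
        assert null.percentile_of(-1.0) == 0.0


class TestResidualCorrelation:
    def _session(self, rng, n=1800, condition="group", hlr_equals_states=True):
        states = {
            f"m{j+1}": rng.choice(
                ["inactive", "active_still", "active"], size=n
            ).tolist()
            for j in range(3)
        }
        table = make_annotations(states, condition=condition)
        enc = {"inactive": 0.0, "active_still": 1.0, "active": 2.0}
        out = []
        for sid, st in states.items():
            vals = np.array([enc[s] for s in st]) + 1.0
            if not hlr_equals_states:
                vals = rng.normal(size=n) + 5.0
            out.append(series(vals, sid, condition=condition))
        return out, table

    def test_exactly_linear_relation_gives_zero_residuals(self, rng):
        sess = self._session(rng)
        res = ib.residual_correlation([sess], segment_min=15)
        np.testing.assert_allclose(res.segments["residual"], 0.0, atol=1e-10)

    def test_pooled_residuals_sum_to_zero(self, rng):
        g = self._session(rng, condition="group", hlr_equals_states=False)
        s = self._session(rng, condition="single", hlr_equals_states=False)
        res = ib.residual_correlation([g, s], segment_min=15, scope="pooled")
        assert abs(res.segments["residual"].mean()) < 1e-10

    def test_per_condition_residuals_centre_each_condition(self, rng):
        g = self._session(rng, condition="group", hlr_equals_states=False)
        s = self._session(rng, condition="single", hlr_equals_states=False)
        res = ib.residual_correlation([g, s], segment_min=15, scope="per_condition")
        for _, sub in res.segments.groupby("condition"):
            assert abs(sub["residual"].mean()) < 1e-10

    def test_onehot_encoding_supported(self, rng):
        sess = self._session(rng)
        res = ib.residual_correlation([sess], segment_min=15, encoding="onehot")
        assert len(res.segments) == 6
        assert np.isfinite(res.segments["r_loc"]).all()

    def test_segment_count(self, rng):
        sess = self._session(rng, n=2 * 900)
        res = ib.residual_correlation([sess], segment_min=15)
        # 3 pairs x 2 segments
        assert len(res.segments) == 6


class TestGranger:
    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.tsa.stattools import grangercausalitytests

        for _ in range(5):
            x = rng.normal(size=400)
            y = np.roll(x, 1) * 0.4 + rng.normal(size=400)
            p_own = ib.granger_pvalue(x, y, lag=1)
            res = grangercausalitytests(
                np.column_stack([y, x]), maxlag=1, verbose=False
            )
            p_sm = res[1][0]["ssr_ftest"][1]
            assert p_own == pytest.approx(p_sm, rel=1e-6)

    def test_planted_coupling_detected(self, rng):
        n = 2000
        x = rng.normal(size=n)
        eps = rng.normal(size=n)
        y = 0.6 * np.roll(x, 1) + eps
        assert ib.granger_pvalue(x, y) < 1e-6
        assert ib.granger_pvalue(y, x) > 0.01

    def test_deterministic_lead(self, rng):
        x = rng.normal(size=500)
        y = np.roll(x, 1)
        x, y = x[1:], y[1:]
        assert ib.granger_pvalue(x, y) < 1e-12
        assert ib.granger_pvalue(y, x) > 0.001

    def test_power_monotone_in_coupling(self, rng):
        """Detection rate rises with planted lag-1 coupling strength."""
        n, reps = 2000, 60
        rates = []
        for w in (0.0, 0.05, 0.15):
            hits = 0
            for _ in range(reps):
                x = rng.normal(size=n)
                y = w * np.concatenate([[0.0], x[:-1]]) + rng.normal(size=n)
                hits += ib.granger_pvalue(x, y) < 0.05
            rates.append(hits / reps)
        assert rates[0] < rates[1] < rates[2]
        assert rates[0] < 0.15 and rates[2] > 0.9

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            ib.granger_pvalue(np.arange(10.0), np.arange(10.0))

    def test_matrix_layout(self, rng):
        pool = [series(rng.normal(size=300), f"m{j}") for j in range(1, 5)]
        p = ib.granger_matrix(pool)
        assert list(p.index) == ["m1", "m2", "m3", "m4"]
        assert np.isnan(np.diag(p)).all()
        off = p.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.isfinite(off).all()

    def test_gap_bridging_and_longest_run(self, rng):
        x = rng.normal(size=300)
        valid = np.ones(300, bool)
        valid[100:102] = False  # short gap: bridged
        valid[200:250] = False  # long gap: splits
        a = series(x, "m1", valid=valid)
        b = series(rng.normal(size=300), "m2")
        xa, xb = ib._contiguous_valid(a, b)
        assert len(xa) == 200  # 0..199 after bridging the 2-s gap


class TestDirectionality:
    def _pmat(self, p_ab, p_ba):
        return pd.DataFrame(
            [[np.nan, p_ab], [p_ba, np.nan]], index=["a", "b"], columns=["a", "b"]
        )

    @pytest.mark.parametrize(
        "p_ab,p_ba,expected",
        [
            (0.01, 0.40, "unidirectional"),
            (0.01, 0.01, "bidirectional"),
            (0.40, 0.40, "none"),
        ],
    )
    def test_classification_rule(self, p_ab, p_ba, expected):
        g = ib.classify_directionality(self._pmat(p_ab, p_ba))
        assert g.pair_classes.loc[0, "class"] == expected

    def test_degrees_and_edges(self):
        g = ib.classify_directionality(self._pmat(0.01, 0.40))
        assert g.edges == [("a", "b")]
        deg = g.degrees.set_index("subject_id")
        assert deg.loc["a", "out_degree"] == 1
        assert deg.loc["b", "in_degree"] == 1

    def test_multiple_testing_corrections(self):
        # raw p=0.03 is significant uncorrected, not after Bonferroni (m=2)
        g_raw = ib.classify_directionality(self._pmat(0.03, 0.40))
        g_bon = ib.classify_directionality(self._pmat(0.03, 0.40), correction="bonferroni")
        assert g_raw.pair_classes.loc[0, "class"] == "unidirectional"
        assert g_bon.pair_classes.loc[0, "class"] == "none"
        g_bh = ib.classify_directionality(self._pmat(0.01, 0.012), correction="bh")
        assert g_bh.pair_classes.loc[0, "class"] == "bidirectional"

    def test_missing_pvalue_rejected(self):
        with pytest.raises(ValueError):
            ib.classify_directionality(self._pmat(np.nan, 0.4))


class TestModelInterface:
    def test_fit_produces_full_results(self, rng):
        from mblfp.synthetic import simulate_hlr_series
        from mblfp.io_formats import AnnotationTable

        sessions = []
        for i in range(2):
            cfg = calibration_config(cohort_id=f"c{i+1:02d}", duration_s=900, seed=i)
            s, gt = simulate_hlr_series(cfg)
            table = AnnotationTable(df=gt.states, condition="group")
            sessions.append((s, table))
        cfg_s = calibration_config(
            cohort_id="c01", condition="single", duration_s=900, seed=10
        )
        s_single, gt_s = simulate_hlr_series(cfg_s)
        sessions.append(
            (s_single, AnnotationTable(df=gt_s.states, condition="single"))
        )
        res = ib.InterbrainModel(sessions).fit(n_draws=1500, seed=0)
        assert set(res.class_means()) >= {"group", "group_shuffled"}
        assert res.null.draws.size == 1500
        assert set(res.granger) == {"c01", "c02"}
        text = res.summary()
        assert "permutation null" in text and "Granger" in text
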