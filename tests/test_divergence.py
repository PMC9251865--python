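import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolscan import divergence
from tests._oracles import fisher_exact_enumeration, pair_stats_bruteforce

POOLS = ["A", "B", "LB", "HV"]


class TestFstEstimators:
    def test_identical_pools_give_zero_nei(self):
        assert divergence.window_fst_nei([30], [30], [30], [30]) == pytest.approx(0.0)

    def test_fixed_alternate_alleles_give_one(self):
        assert divergence.window_fst_nei([60], [0], [0], [60]) == pytest.approx(1.0)
        assert divergence.window_fst_karlsson([60], [0], [0], [60]) == pytest.approx(1.0)

    def test_nei_hand_value(self):
        # f = 0.8 vs 0.2: h_T = 0.5, h_W = 0.32
        assert divergence.window_fst_nei([48], [12], [12], [48]) == pytest.approx(
            0.36, abs=1e-12
        )

    def test_karlsson_identical_pools_slightly_negative(self):
        # h = 900/3540; N = -2h/60; D = N + 2h
        h = 900 / 3540
        expected = (-2 * h / 60) / (-2 * h / 60 + 2 * h)
        got = divergence.window_fst_karlsson([30], [30], [30], [30])
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(-0.016949, abs=1e-6)

    def test_karlsson_hand_value(self):
        got = divergence.window_fst_karlsson([48], [12], [12], [48])
        assert got == pytest.approx(0.354576 / 0.68, abs=1e-6)

    def test_identical_pools_near_zero_at_depth_60(self, rng):
        maj = rng.integers(10, 50, size=200)
        mn = 60 - maj
        assert abs(divergence.window_fst_nei(maj, mn, maj, mn)) < 0.02
        assert abs(divergence.window_fst_karlsson(maj, mn, maj, mn)) < 0.02

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(*[st.integers(min_value=0, max_value=120)] * 4),
            min_size=1,
            max_size=20,
        )
    )
    def test_estimators_symmetric_in_pool_order(self, counts):
        ma, na, mb, nb = (np.array(x) for x in zip(*counts))
        for fst in (divergence.window_fst_nei, divergence.window_fst_karlsson):
            ab, ba = fst(ma, na, mb, nb), fst(mb, nb, ma, na)
            assert (np.isnan(ab) and np.isnan(ba)) or ab == pytest.approx(ba, abs=1e-12)
        d_ab = divergence.snp_delta_af(ma, na, mb, nb)
        d_ba = divergence.snp_delta_af(mb, nb, ma, na)
        np.testing.assert_allclose(d_ab, d_ba, atol=1e-12)

    def test_undefined_when_no_usable_snps(self):
        assert np.isnan(divergence.window_fst_nei([0], [0], [30], [30]))
        assert np.isnan(divergence.window_fst_karlsson([1], [0], [30], [30]))


class TestDeltaAF:
    def test_identical_frequencies_zero(self):
        np.testing.assert_allclose(divergence.snp_delta_af([30], [30], [15], [15]), [0.0])

    def test_fixed_difference_one(self):
        np.testing.assert_allclose(divergence.snp_delta_af([60], [0], [0], [60]), [1.0])

    def test_hand_value(self):
        np.testing.assert_allclose(
            divergence.snp_delta_af([54], [6], [12], [48]), [0.7], atol=1e-12
        )

    def test_zero_depth_snp_skipped(self):
        d = divergence.snp_delta_af([0], [0], [30], [30])
        assert np.isnan(d[0])


class TestFisher:
    def test_identical_tables_p_one(self):
        assert divergence.snp_fisher_test(30, 30, 30, 30) == 1.0

    def test_small_fixed_table_matches_enumeration(self):
        # (5,0 / 0,5): the two extreme tables, p = 2/C(10,5)
        assert divergence.snp_fisher_test(5, 0, 0, 5) == pytest.approx(
            2 / 252, rel=1e-9
        )

    def test_deep_fixed_table_beats_bonferroni_threshold(self):
        assert divergence.snp_fisher_test(60, 0, 0, 60) < 2.5e-11

    def test_zero_margin_convention(self):
        assert divergence.snp_fisher_test(0, 0, 30, 30) == 1.0
        assert divergence.snp_fisher_test(30, 0, 30, 0) == 1.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(min_value=0, max_value=25)] * 4))
    def test_matches_exhaustive_enumeration(self, table):
        a, b, c, d = table
        ours = divergence.snp_fisher_test(a, b, c, d)
        assert ours == pytest.approx(fisher_exact_enumeration(a, b, c, d), rel=1e-9)


class TestTreemixExport:
    def test_format_definition(self, small_snps):
        one = small_snps.iloc[:1]
        buf = io.StringIO()
        divergence.treemix_export(one, POOLS, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "A B LB HV"
        r = one.iloc[0]
        assert lines[1] == " ".join(
            f"{r[f'{p}_maj']},{r[f'{p}_min']}" for p in POOLS
        )

    def test_zero_snps_header_only(self, small_snps):
        buf = io.StringIO()
        divergence.treemix_export(small_snps.iloc[0:0], POOLS, buf)
        assert buf.getvalue() == "A B LB HV\n"

    def test_round_trip_counts(self, small_snps):
        sub = small_snps.iloc[:50]
        buf = io.StringIO()
        divergence.treemix_export(sub, POOLS, buf)
        names, maj, mn = divergence.read_treemix(buf.getvalue().splitlines())
        assert names == POOLS
        for i, p in enumerate(POOLS):
            np.testing.assert_array_equal(maj[:, i], sub[f"{p}_maj"].to_numpy())
            np.testing.assert_array_equal(mn[:, i], sub[f"{p}_min"].to_numpy())


class TestWindowPairTableAgainstBruteForce:
    def test_oracle_equivalence_on_simulated_fixture(self, small_snps):
        fixture = small_snps.iloc[:1000]
        win = divergence.divergence_windows(fixture, "A", "B")
        oracle = pair_stats_bruteforce(fixture.to_dict("records"), "A", "B")
        assert len(win) == len(oracle)
        for r in win.itertuples(index=False):
            exp = oracle[(r.chrom, r.start)]
            for col, key in (
                ("fst_nei", "fst_nei"),
                ("fst_karlsson", "fst_karlsson"),
                ("delta_af_mean", "delta_af_mean"),
            ):
                got = getattr(r, col)
                if exp[key] is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(exp[key], abs=1e-12)


class TestDistributionComparison:
    def test_identical_samples(self):
        res = divergence.compare_window_distributions([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert res["t_p"] == pytest.approx(1.0)
        assert res["W"] == pytest.approx(8.0)  # null mid-value n1*n2/2

    def test_large_shift_detected(self, rng):
        x = rng.normal(0, 1, 100)
        res = divergence.compare_window_distributions(x, x + 50)
        assert res["t_p"] < 1e-6
        assert res["wilcoxon_p"] < 1e-6

    def test_equal_constant_samples_w_at_null_midvalue(self):
        res = divergence.compare_window_distributions([2.0] * 6, [2.0] * 5)
        assert res["W"] == pytest.approx(15.0)  # 6*5/2

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            divergence.compare_window_distributions([1.0], [1, 2.0])
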