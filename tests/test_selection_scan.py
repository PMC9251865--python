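import numpy as np
import pandas as pd
import pytest

from poolscan import diversity, divergence, selection_scan as ss
from poolscan.io_sync import GeneInterval

INTRODUCED = ["A", "B"]
ESTABLISHED = ["LB", "HV"]


def _zhp_frame(z_by_pool: dict) -> pd.DataFrame:
    """One-window long table from {'A': 0.5, ...}."""
    return pd.DataFrame(
        [
            {"pool": p, "chrom": "chr1", "start": 0, "z_h_p": z}
            for p, z in z_by_pool.items()
        ]
    )


class TestZhpContrastScan:
    @pytest.mark.parametrize(
        "z, mode, expected",
        [
            ({"A": 0.5, "B": 0.3, "LB": -2.5, "HV": -2.1}, "directional", 1),
            ({"A": -4.2, "B": -4.5, "LB": 0.2, "HV": 0.1}, "relaxed", 1),
            ({"A": 0.5, "B": -0.1, "LB": -2.5, "HV": -2.2}, "directional", 0),
            ({"A": 0.5, "B": 0.3, "LB": -2.5, "HV": -1.9}, "directional", 0),
            ({"A": -4.2, "B": -3.9, "LB": 0.2, "HV": 0.1}, "relaxed", 0),
        ],
    )
    def test_conjunction_of_thresholds(self, z, mode, expected):
        scan = ss.directional_scan if mode == "directional" else ss.relaxed_scan
        out = scan(_zhp_frame(z), INTRODUCED, ESTABLISHED)
        assert len(out) == expected

    def test_missing_pool_window_skipped_and_audited(self):
        frame = _zhp_frame({"A": 0.5, "B": 0.3, "LB": -2.5, "HV": -2.1})
        extra = pd.DataFrame(
            [
                {"pool": p, "chrom": "chr1", "start": 5000,
                 "z_h_p": np.nan if p == "HV" else -3.0 if p in ESTABLISHED else 1.0}
                for p in INTRODUCED + ESTABLISHED
            ]
        )
        audit: list = []
        out = ss.directional_scan(
            pd.concat([frame, extra]), INTRODUCED, ESTABLISHED, audit=audit
        )
        assert list(out["start"]) == [0]
        assert audit == [("chr1", 5000)]

    def test_candidates_satisfy_inequalities_on_recheck(self, small_snps):
        div = diversity.diversity_windows(small_snps, INTRODUCED + ESTABLISHED, min_snps=20)
        for scan, low, high in (
            (ss.directional_scan, ESTABLISHED, INTRODUCED),
            (ss.relaxed_scan, INTRODUCED, ESTABLISHED),
        ):
            out = scan(div, INTRODUCED, ESTABLISHED)
            assert ss.audit_candidates(out, low_group=low, high_group=high) == 0


class TestWindowDivergenceScan:
    @staticmethod
    def _windows(n=100, seed=5):
        rng = np.random.default_rng(seed)
        fst = rng.uniform(0.0, 0.3, n)
        pi_a = rng.uniform(1e-3, 5e-3, n)
        pi_b = rng.uniform(1e-3, 5e-3, n)
        # plant exactly one joint outlier
        k = min(17, n - 1)
        fst[k], pi_a[k], pi_b[k] = 0.9, 1e-6, 1e-6
        chrom = ["chr1"] * n
        start = np.arange(n) * 5000
        return (
            pd.DataFrame({"chrom": chrom, "start": start, "fst_nei": fst}),
            pd.DataFrame({"chrom": chrom, "start": start, "pi": pi_a}),
            pd.DataFrame({"chrom": chrom, "start": start, "pi": pi_b}),
        )

    def test_joint_outlier_is_the_single_candidate(self):
        fst, pa, pb = self._windows()
        out, cuts = ss.window_divergence_scan(fst, pa, pb)
        assert list(out["start"]) == [17 * 5000]
        assert cuts["fst"] < 0.9 and cuts["pi_a"] > 1e-6

    def test_all_identical_fst_yields_nothing(self):
        fst, pa, pb = self._windows()
        fst["fst_nei"] = 0.2
        out, _ = ss.window_divergence_scan(fst, pa, pb)
        assert len(out) == 0  # nothing strictly above the 95th percentile

    def test_pi_failure_in_one_pool_excludes(self):
        fst, pa, pb = self._windows()
        pb.loc[17, "pi"] = 5e-3
        out, _ = ss.window_divergence_scan(fst, pa, pb)
        assert len(out) == 0

    def test_too_few_windows_rejected(self):
        fst, pa, pb = self._windows(n=10)
        with pytest.raises(ValueError, match="percentile"):
            ss.window_divergence_scan(fst, pa, pb)


class TestSnpDivergenceScan:
    @staticmethod
    def _table():
        n = 200
        rng = np.random.default_rng(2)
        tab = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, n + 1),
                "delta_af": rng.uniform(0, 0.5, n),
                "fisher_p": rng.uniform(0.1, 1.0, n),
            }
        )
        tab.loc[0, ["delta_af", "fisher_p"]] = (0.99, 1e-20)
        ann = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, n + 1),
                "category": "intergenic",
                "gene_id": None,
            }
        )
        ann.loc[0, "category"] = "non_synonymous"
        ann.loc[0, "gene_id"] = "geneX"
        return tab, ann

    def test_qualifying_snp_returned(self):
        tab, ann = self._table()
        out, cutoff = ss.snp_divergence_scan(tab, ann)
        assert list(out["pos"]) == [1]
        assert cutoff <= 0.99

    def test_synonymous_annotation_excludes(self):
        tab, ann = self._table()
        ann.loc[0, "category"] = "synonymous"
        out, _ = ss.snp_divergence_scan(tab, ann)
        assert len(out) == 0

    def test_no_annotated_snps_warns_and_returns_empty(self):
        tab, ann = self._table()
        with pytest.warns(UserWarning, match="no annotated"):
            out, _ = ss.snp_divergence_scan(tab, ann.iloc[0:0])
        assert len(out) == 0


class TestAssignGenes:
    @staticmethod
    def _inputs(fisher_p=1e-20, category="non_synonymous"):
        cand = pd.DataFrame({"chrom": ["chr1"], "start": [0]})
        snps = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "delta_af": [0.9], "fisher_p": [fisher_p]}
        )
        ann = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "category": [category], "gene_id": ["geneX"]}
        )
        return cand, snps, ann

    def test_qualifying_snp_assigns_gene(self):
        cand, snps, ann = self._inputs()
        out = ss.assign_genes(cand, snps, ann)
        assert out["gene_ids"].iloc[0] == ["geneX"]

    def test_fisher_failure_leaves_window_geneless(self):
        cand, snps, ann = self._inputs(fisher_p=0.5)
        out = ss.assign_genes(cand, snps, ann)
        assert out["gene_ids"].iloc[0] == []

    def test_two_snps_same_gene_listed_once(self):
        cand, snps, ann = self._inputs()
        snps = pd.concat([snps, snps.assign(pos=200)], ignore_index=True)
        ann = pd.concat([ann, ann.assign(pos=200)], ignore_index=True)
        out = ss.assign_genes(cand, snps, ann)
        assert out["gene_ids"].iloc[0] == ["geneX"]

    def test_gene_intervals_supplement_annotation(self):
        cand, snps, ann = self._inputs()
        ann["gene_id"] = None
        genes = [GeneInterval("chr1", 50, 150, "geneY")]
        out = ss.assign_genes(cand, snps, ann, gene_intervals=genes)
        assert out["gene_ids"].iloc[0] == ["geneY"]


class TestCoverageBias:
    @staticmethod
    def _windows(seed=0, n=500):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 5000,
                "mean_depth": rng.normal(80, 5, n),
            }
        )

    def test_fold_change_hand_value(self):
        # mean depths 74 vs 63 give fold change log2(74/63) ~ 0.232
        assert np.log2(74 / 63) == pytest.approx(0.232, abs=5e-4)

    def test_random_candidates_show_no_bias(self):
        wins = self._windows()
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            cand = wins.iloc[rng.choice(len(wins), 25, replace=False)]
            res = ss.coverage_bias_check(cand, wins, seed=seed)
            if abs(res["fold_change_m"]) < 0.1 and res["paired_t_p"] > 0.05:
                ok += 1
        assert ok >= 9

    def test_top_depth_decile_flagged(self):
        wins = self._windows(seed=3)
        cand = wins.nlargest(50, "mean_depth")
        res = ss.coverage_bias_check(cand, wins, seed=1)
        assert res["fold_change_m"] > 0
        assert res["paired_t_p"] < 0.05

    def test_empty_candidate_set_rejected(self):
        wins = self._windows()
        with pytest.raises(ValueError, match="empty"):
            ss.coverage_bias_check(wins.iloc[0:0], wins)


def test_window_mean_depth_matches_direct_average(small_snps):
    pools = INTRODUCED + ESTABLISHED
    depths = ss.window_mean_depth(small_snps, pools)
    one = depths.iloc[0]
    sel = small_snps[
        (small_snps["chrom"] == one["chrom"])
        & ((small_snps["pos"] - 1) // 5000 * 5000 == one["start"])
    ]
    manual = np.mean(
        [
            (sel[f"{p}_maj"] + sel[f"{p}_min"]).to_numpy(float)
            for p in pools
        ]
    )
    assert one["mean_depth"] == pytest.approx(manual)
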