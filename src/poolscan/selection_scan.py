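"""Candidate-detection procedures and coverage QC.

Three scans are implemented:

* snp_divergence_scan — non-synonymous SNPs whose pairwise dAF reaches the
  empirical 95th percentile and whose Fisher exact p beats the genome-size
  Bonferroni threshold (alpha/genome_size);
* window_divergence_scan — windows whose pair F_ST lies strictly above the
  empirical 95th percentile while within-pool pi lies strictly below the
  5th percentile in BOTH pools (divergence plus reduced diversity, to avoid
  confounding selection with drift);
* zhp_contrast_scan — windows where the Z-scored pooled heterozygosity is
  below a cutoff in every pool of a "low" group while above 0 in every pool
  of a "high" group.  Directional mode: low = established descendants,
  cutoff -2 (fixation after introduction, variation retained in sources);
  relaxed mode: low = introduced sources, cutoff -4 (constraint in the
  native environment, variation restored after release).

Percentile cutoffs are always computed from the data at run time (linear
interpolation between order statistics); realized cutoffs are reported with
the candidates.  All thresholds are strict inequalities.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_sync import GeneInterval


def snp_divergence_scan(
    snp_table: pd.DataFrame,
    annotation: pd.DataFrame,
    q_delta: float = 95.0,
    alpha: float = 0.05,
    genome_size: float = 2e9,
) -> tuple:
    """Candidate SNPs for adaptive divergence between a pool pair.

    ``snp_table`` needs chrom, pos, delta_af, fisher_p; ``annotation`` needs
    chrom, pos, category and optionally gene_id.  Returns (candidates,
    realized_cutoff): SNPs with delta_af >= the empirical q_delta-th
    percentile, fisher_p < alpha/genome_size and category non_synonymous.
    """
    daf = snp_table["delta_af"].to_numpy(float)
    defined = daf[~np.isnan(daf)]
    if defined.size == 0:
        return snp_table.iloc[0:0].copy(), float("nan")
    cutoff = float(np.percentile(defined, q_delta))
    p_thresh = alpha / genome_size
    merged = snp_table.merge(annotation, on=["chrom", "pos"], how="inner")
    if len(merged) == 0:
        import warnings

        warnings.warn("no annotated SNPs; snp divergence scan is empty")
        out = merged
    else:
        mask = (
            (merged["delta_af"] >= cutoff)
            & (merged["fisher_p"] < p_thresh)
            & (merged["category"] == "non_synonymous")
        )
        out = merged[mask.fillna(False)].reset_index(drop=True)
    out = out.copy()
    out["scan_type"] = "snp_divergence"
    return out, cutoff


def window_divergence_scan(
    fst_windows: pd.DataFrame,
    pi_windows_a: pd.DataFrame,
    pi_windows_b: pd.DataFrame,
    q_fst: float = 95.0,
    q_pi: float = 5.0,
) -> tuple:
    """Windows of high pair F_ST and low pi in both pools.

    Inputs are window tables keyed by (chrom, start) with columns
    ``fst_nei`` resp. ``pi``.  Returns (candidates, cutoffs dict with the
    realized fst and per-pool pi percentiles).  Raises when fewer than 20
    defined F_ST windows exist (percentiles unstable).
    """
    fst = fst_windows.dropna(subset=["fst_nei"])
    if len(fst) < 20:
        raise ValueError("fewer than 20 defined windows; percentile cutoffs unstable")
    fst_cut = float(np.percentile(fst["fst_nei"].to_numpy(float), q_fst))
    pa = pi_windows_a.dropna(subset=["pi"])
    pb = pi_windows_b.dropna(subset=["pi"])
    pi_cut_a = float(np.percentile(pa["pi"].to_numpy(float), q_pi))
    pi_cut_b = float(np.percentile(pb["pi"].to_numpy(float), q_pi))
    merged = fst.merge(
        pa[["chrom", "start", "pi"]].rename(columns={"pi": "pi_a"}),
        on=["chrom", "start"],
    ).merge(
        pb[["chrom", "start", "pi"]].rename(columns={"pi": "pi_b"}),
        on=["chrom", "start"],
    )
    mask = (
        (merged["fst_nei"] > fst_cut)
        & (merged["pi_a"] < pi_cut_a)
        & (merged["pi_b"] < pi_cut_b)
    )
    out = merged[mask].reset_index(drop=True).copy()
    out["scan_type"] = "window_divergence"
    cutoffs = {"fst": fst_cut, "pi_a": pi_cut_a, "pi_b": pi_cut_b}
    return out, cutoffs


def zhp_contrast_scan(
    zhp: pd.DataFrame,
    high_group: Sequence[str],
    low_group: Sequence[str],
    low_cutoff: float,
    audit: Optional[list] = None,
) -> pd.DataFrame:
    """Windows with z_h_p < low_cutoff in every low-group pool and > 0 in
    every high-group pool.

    ``zhp`` is a long diversity table (pool, chrom, start, z_h_p); windows
    missing z_h_p for any pool in either group are skipped (and recorded in
    ``audit`` when given).  The returned frame carries one column
    ``zhp_{pool}`` per pool plus scan bookkeeping.
    """
    pools = list(high_group) + list(low_group)
    wide = zhp.pivot_table(index=["chrom", "start"], columns="pool", values="z_h_p")
    missing_pools = [p for p in pools if p not in wide.columns]
    if missing_pools:
        raise ValueError(f"z_h_p missing entirely for pools {missing_pools}")
    wide = wide[pools]
    complete = wide.notna().all(axis=1)
    if audit is not None:
        audit.extend([tuple(ix) for ix in wide.index[~complete]])
    wide = wide[complete]
    mask = np.ones(len(wide), dtype=bool)
    for p in low_group:
        mask &= (wide[p] < low_cutoff).to_numpy()
    for p in high_group:
        mask &= (wide[p] > 0.0).to_numpy()
    out = wide[mask].reset_index()
    out.columns = ["chrom", "start"] + [f"zhp_{p}" for p in pools]
    out["low_cutoff"] = low_cutoff
    return out


def directional_scan(
    zhp: pd.DataFrame,
    introduced: Sequence[str],
    established: Sequence[str],
    cutoff: float = -2.0,
    audit: Optional[list] = None,
) -> pd.DataFrame:
    """Directional-selection candidates: fixation in the established pools
    (z < cutoff in each) with variation retained in the introduced (z > 0)."""
    out = zhp_contrast_scan(zhp, high_group=introduced, low_group=established,
                            low_cutoff=cutoff, audit=audit)
    out["scan_type"] = "directional"
    return out


def relaxed_scan(
    zhp: pd.DataFrame,
    introduced: Sequence[str],
    established: Sequence[str],
    cutoff: float = -4.0,
    audit: Optional[list] = None,
) -> pd.DataFrame:
    """Relaxed-selection candidates: strong fixation in the introduced pools
    (z < cutoff in each) with variation restored in the established (z > 0)."""
    out = zhp_contrast_scan(zhp, high_group=established, low_group=introduced,
                            low_cutoff=cutoff, audit=audit)
    out["scan_type"] = "relaxed"
    return out


def assign_genes(
    candidates: pd.DataFrame,
    snp_table: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_intervals: Optional[Sequence[GeneInterval]] = None,
    window_size: int = 5000,
    alpha: float = 0.05,
    genome_size: float = 2e9,
) -> pd.DataFrame:
    """Attach gene_ids to window candidates.

    A gene is listed for a candidate window when it contains at least one
    non-synonymous SNP inside the window that also passes the Fisher
    threshold.  Gene identity comes from the annotation's gene_id, plus any
    provided 1-based-inclusive gene intervals containing the SNP.  Without a
    gene table, annotation gene_ids alone are used (with a warning when
    neither source exists).
    """
    p_thresh = alpha / genome_size
    merged = snp_table.merge(annotation, on=["chrom", "pos"], how="inner")
    qualifying = merged[
        (merged["category"] == "non_synonymous")
        & (merged["fisher_p"] < p_thresh)
    ]
    if gene_intervals is None and ("gene_id" not in annotation.columns):
        import warnings

        warnings.warn("no gene information available; gene_ids left empty")
    out = candidates.copy()
    gene_lists = []
    for row in out.itertuples(index=False):
        start, end = int(row.start), int(row.start) + window_size
        in_win = qualifying[
            (qualifying["chrom"] == row.chrom)
            & (qualifying["pos"] > start)
            & (qualifying["pos"] <= end)
        ]
        genes: set = set()
        if "gene_id" in in_win.columns:
            genes.update(g for g in in_win["gene_id"] if g is not None and not pd.isna(g))
        if gene_intervals is not None:
            for snp in in_win.itertuples(index=False):
                for gi in gene_intervals:
                    if gi.chrom == snp.chrom and gi.start <= snp.pos <= gi.end:
                        genes.add(gi.gene_id)
        gene_lists.append(sorted(genes))
    out["gene_ids"] = gene_lists
    return out


def window_mean_depth(
    snps: pd.DataFrame, pool_names: Sequence[str], window_size: int = 5000
) -> pd.DataFrame:
    """Mean per-SNP read depth (major+minor, averaged over pools) per window."""
    from .diversity import assign_windows

    depth = np.zeros(len(snps))
    for nm in pool_names:
        depth += snps[f"{nm}_maj"].to_numpy(float) + snps[f"{nm}_min"].to_numpy(float)
    depth /= len(pool_names)
    work = pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "start": assign_windows(snps["pos"].to_numpy(), window_size),
            "depth": depth,
        }
    )
    out = work.groupby(["chrom", "start"], sort=True)["depth"].mean().reset_index()
    return out.rename(columns={"depth": "mean_depth"})


def coverage_bias_check(
    candidate_windows: pd.DataFrame,
    all_windows: pd.DataFrame,
    n_random: Optional[int] = None,
    seed: int = 0,
) -> dict:
    """Read-depth QC: are candidate windows unusually covered?

    Draws a size-matched random sample of windows (seeded) and returns both
    mean depths, the fold change M = log2(candidate/random) and the paired
    t-test p-value.  Both inputs are keyed (chrom, start) with a
    ``mean_depth`` column.
    """
    if len(candidate_windows) == 0:
        raise ValueError("candidate set is empty")
    cand = candidate_windows.merge(
        all_windows[["chrom", "start", "mean_depth"]], on=["chrom", "start"]
    ) if "mean_depth" not in candidate_windows.columns else candidate_windows
    n = len(cand) if n_random is None else n_random
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(all_windows), size=n, replace=False)
    rand_depth = all_windows["mean_depth"].to_numpy(float)[idx]
    cand_depth = cand["mean_depth"].to_numpy(float)
    if len(cand_depth) != len(rand_depth):
        raise ValueError("size-matched sample requires n_random == len(candidates)")
    mean_c, mean_r = float(np.mean(cand_depth)), float(np.mean(rand_depth))
    m = float(np.log2(mean_c / mean_r))
    t = stats.ttest_rel(cand_depth, rand_depth)
    return {
        "mean_depth_candidates": mean_c,
        "mean_depth_random": mean_r,
        "fold_change_m": m,
        "paired_t_p": float(t.pvalue),
    }


def audit_candidates(
    candidates: pd.DataFrame, low_group: Sequence[str], high_group: Sequence[str]
) -> int:
    """Self-consistency check for ZH_P scans: number of emitted candidates
    violating their defining inequalities when re-read from stored stats."""
    bad = 0
    for row in candidates.itertuples(index=False):
        cut = row.low_cutoff
        ok = all(getattr(row, f"zhp_{p}") < cut for p in low_group) and all(
            getattr(row, f"zhp_{p}") > 0 for p in high_group
        )
        bad += 0 if ok else 1
    return bad
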