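"""Pairwise divergence between pools.

Two windowed F_ST estimators are provided:

* Nei-style: per SNP, within-pool heterozygosity h_i = 1 - f_i^2 - (1-f_i)^2
  averaged over the two pools, total heterozygosity from the frequency of
  the pooled read counts; the window value is
  (sum h_T - sum h_W) / sum h_T over SNPs.  Heterozygosities here are the
  uncorrected 1 - sum f^2, so identical pools give exactly 0 and fixed
  alternate alleles exactly 1.
* Karlsson-style (ratio of sums): per SNP with major count a_i, depth n_i,
  h_i = a_i(n_i - a_i)/(n_i(n_i - 1)); N = (a1/n1 - a2/n2)^2 - h1/n1 - h2/n2;
  D = N + h1 + h2; window F_ST = sum N / sum D.  This form corrects for read
  sampling and tracks estimates from individually genotyped SNPs.

dAF is the absolute difference in the frequency of the globally defined
(cross-pool) major allele; per-SNP allele-frequency differences are tested
with Fisher's exact test on the 2x2 read-count table.  Negative window F_ST
values are reported as computed (not clamped) to preserve distribution shape
for percentile thresholds.  Fisher p-values treat reads as independent
draws, as Pool-seq read-count tests conventionally do; this pseudo-
replication caveat is recorded in output metadata by callers.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import assign_windows


# ------------------------------------------------------------- per-SNP core


def _uncorrected_h(f: np.ndarray) -> np.ndarray:
    return 1.0 - f * f - (1.0 - f) ** 2


def window_fst_nei(
    maj_a: np.ndarray, min_a: np.ndarray, maj_b: np.ndarray, min_b: np.ndarray
) -> float:
    """Nei-style window F_ST from per-SNP read counts of one pool pair."""
    maj_a = np.asarray(maj_a, float)
    min_a = np.asarray(min_a, float)
    maj_b = np.asarray(maj_b, float)
    min_b = np.asarray(min_b, float)
    da, db = maj_a + min_a, maj_b + min_b
    ok = (da > 0) & (db > 0)
    if not np.any(ok):
        return float("nan")
    fa, fb = maj_a[ok] / da[ok], maj_b[ok] / db[ok]
    ft = (maj_a[ok] + maj_b[ok]) / (da[ok] + db[ok])
    h_within = 0.5 * (_uncorrected_h(fa) + _uncorrected_h(fb))
    h_total = _uncorrected_h(ft)
    denom = float(np.sum(h_total))
    if denom == 0.0:
        return float("nan")
    return float((np.sum(h_total) - np.sum(h_within)) / denom)


def window_fst_karlsson(
    maj_a: np.ndarray, min_a: np.ndarray, maj_b: np.ndarray, min_b: np.ndarray
) -> float:
    """Karlsson-style (ratio of sums) window F_ST from per-SNP read counts."""
    maj_a = np.asarray(maj_a, float)
    min_a = np.asarray(min_a, float)
    maj_b = np.asarray(maj_b, float)
    min_b = np.asarray(min_b, float)
    na, nb = maj_a + min_a, maj_b + min_b
    ok = (na >= 2) & (nb >= 2)
    if not np.any(ok):
        return float("nan")
    a1, n1 = maj_a[ok], na[ok]
    a2, n2 = maj_b[ok], nb[ok]
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1.0))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1.0))
    num = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    den = num + h1 + h2
    d = float(np.sum(den))
    if d == 0.0:
        return float("nan")
    return float(np.sum(num) / d)


def snp_delta_af(
    maj_a: np.ndarray, min_a: np.ndarray, maj_b: np.ndarray, min_b: np.ndarray
) -> np.ndarray:
    """|f_maj,a - f_maj,b| per SNP (NaN where either pool has zero depth)."""
    maj_a = np.asarray(maj_a, float)
    min_a = np.asarray(min_a, float)
    maj_b = np.asarray(maj_b, float)
    min_b = np.asarray(min_b, float)
    da, db = maj_a + min_a, maj_b + min_b
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(maj_a / da - maj_b / db)
    d[(da == 0) | (db == 0)] = np.nan
    return d


def snp_fisher_test(n_maj_a: int, n_min_a: int, n_maj_b: int, n_min_b: int) -> float:
    """Two-sided Fisher exact p for the 2x2 read-count table.

    A zero margin (monomorphic table or empty pool) returns p = 1 by
    convention.
    """
    table = np.array([[n_maj_a, n_min_a], [n_maj_b, n_min_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fisher_tests(
    maj_a: np.ndarray,
    min_a: np.ndarray,
    maj_b: np.ndarray,
    min_b: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-SNP Fisher exact p-values; entries outside ``mask`` are NaN."""
    n = len(maj_a)
    out = np.full(n, np.nan)
    idx = range(n) if mask is None else np.flatnonzero(mask)
    for i in idx:
        out[i] = snp_fisher_test(int(maj_a[i]), int(min_a[i]), int(maj_b[i]), int(min_b[i]))
    return out


# --------------------------------------------------------------- pipelines


def divergence_windows(
    snps: pd.DataFrame,
    pool_a: str,
    pool_b: str,
    window_size: int = 5000,
    chrom_lengths: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-window pairwise table: fst_nei, fst_karlsson, delta_af_mean."""
    starts = assign_windows(snps["pos"].to_numpy(), window_size)
    ma = snps[f"{pool_a}_maj"].to_numpy(np.int64)
    na = snps[f"{pool_a}_min"].to_numpy(np.int64)
    mb = snps[f"{pool_b}_maj"].to_numpy(np.int64)
    nb = snps[f"{pool_b}_min"].to_numpy(np.int64)
    daf = snp_delta_af(ma, na, mb, nb)
    work = pd.DataFrame(
        {"chrom": snps["chrom"], "start": starts, "ma": ma, "na": na, "mb": mb, "nb": nb, "daf": daf}
    )
    rows = []
    for (chrom, start), g in work.groupby(["chrom", "start"], sort=True):
        if chrom_lengths is not None and start + window_size > chrom_lengths.get(chrom, np.inf):
            continue
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(start) + window_size,
                "pair": f"{pool_a}:{pool_b}",
                "n_snps": len(g),
                "fst_nei": window_fst_nei(g["ma"], g["na"], g["mb"], g["nb"]),
                "fst_karlsson": window_fst_karlsson(g["ma"], g["na"], g["mb"], g["nb"]),
                "delta_af_mean": float(np.nanmean(g["daf"].to_numpy()))
                if np.any(~np.isnan(g["daf"].to_numpy()))
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def snp_divergence_table(
    snps: pd.DataFrame,
    pool_a: str,
    pool_b: str,
    fisher_min_delta_af: Optional[float] = None,
) -> pd.DataFrame:
    """Per-SNP pair table with delta_af and fisher_p.

    When ``fisher_min_delta_af`` is given, Fisher p-values are computed only
    for SNPs with delta_af at or above it (others NaN) — the scans only use
    p-values in the upper dAF tail.
    """
    ma = snps[f"{pool_a}_maj"].to_numpy(np.int64)
    na = snps[f"{pool_a}_min"].to_numpy(np.int64)
    mb = snps[f"{pool_b}_maj"].to_numpy(np.int64)
    nb = snps[f"{pool_b}_min"].to_numpy(np.int64)
    daf = snp_delta_af(ma, na, mb, nb)
    mask = None if fisher_min_delta_af is None else (daf >= fisher_min_delta_af)
    p = fisher_tests(ma, na, mb, nb, mask=mask)
    return pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "pos": snps["pos"],
            "pair": f"{pool_a}:{pool_b}",
            "delta_af": daf,
            "fisher_p": p,
        }
    )


def treemix_export(
    snps: pd.DataFrame, pool_names: Sequence[str], stream: TextIO
) -> None:
    """TreeMix allele-count export: pool-name header, then per SNP one line
    of space-separated ``n_maj,n_min`` per pool (gzip-compatible plain text)."""
    stream.write(" ".join(pool_names) + "\n")
    cols = [(snps[f"{nm}_maj"].to_numpy(), snps[f"{nm}_min"].to_numpy()) for nm in pool_names]
    for i in range(len(snps)):
        stream.write(" ".join(f"{c[0][i]},{c[1][i]}" for c in cols) + "\n")


def read_treemix(stream: Iterable[str]) -> tuple:
    """Parse a TreeMix export back to (pool_names, n_maj, n_min) arrays."""
    it = iter(stream)
    names = next(it).split()
    maj_rows, min_rows = [], []
    for line in it:
        if not line.strip():
            continue
        pairs = [tok.split(",") for tok in line.split()]
        maj_rows.append([int(a) for a, _ in pairs])
        min_rows.append([int(b) for _, b in pairs])
    return names, np.asarray(maj_rows, np.int64), np.asarray(min_rows, np.int64)


def frequency_distance_matrix(snps: pd.DataFrame, pool_names: Sequence[str]) -> pd.DataFrame:
    """Euclidean distance between pools in major-allele frequency space
    (a simple dendrogram-free summary of between-pool relationships)."""
    freqs = {}
    for nm in pool_names:
        ma = snps[f"{nm}_maj"].to_numpy(float)
        mi = snps[f"{nm}_min"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs[nm] = ma / (ma + mi)
    mat = np.zeros((len(pool_names), len(pool_names)))
    for i, a in enumerate(pool_names):
        for j, b in enumerate(pool_names):
            d = freqs[a] - freqs[b]
            mat[i, j] = float(np.sqrt(np.nanmean(d * d)))
    return pd.DataFrame(mat, index=list(pool_names), columns=list(pool_names))


def compare_window_distributions(x: Sequence[float], y: Sequence[float]) -> dict:
    """Welch two-sample t and Wilcoxon rank-sum comparison of two window-
    statistic samples; returns {'t_p', 'wilcoxon_p', 'W'} (W is the
    Mann-Whitney U, identical to R wilcox.test's W)."""
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    y = np.asarray(y, float)
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 defined values")
    t_res = stats.ttest_ind(x, y, equal_var=False)
    u_res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return {
        "t_p": float(t_res.pvalue),
        "wilcoxon_p": float(u_res.pvalue),
        "W": float(u_res.statistic),
    }
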