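"""Per-site and windowed diversity statistics for population pools.

For each pool the pipeline reports, in fixed non-overlapping windows
(default 5 kb):

* pi — expected pairwise nucleotide diversity per covered site, summing the
  finite-depth-corrected site heterozygosity (M/(M-1))*(1 - f_maj^2 - f_min^2)
  over SNPs (M = major+minor read depth);
* theta_w — Watterson's estimate S/a1 per covered site;
* tajima_d — classic Tajima's D, (Pi - theta_W)/sqrt(e1*S + e2*S*(S-1)),
  with sample size n equal to the haploid pool size (2 x diploids);
* h_p — pooled heterozygosity, 2*n_maj*n_min/(n_maj+n_min)^2 per site,
  windowed as the mean over sites (a ratio-of-window-sums variant is
  available via ``hp_mode``), retained only for windows with at least
  ``min_snps`` variant sites (default 33);
* z_h_p — the within-pool Z-score of h_p over retained windows, so that
  each pool's distribution has mean 0 and standard deviation 1.

Window coordinates are 0-based half-open [start, start + size).
"""

from __future__ import annotations

import math
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd


class Window(NamedTuple):
    chrom: str
    start: int  # 0-based
    end: int  # half-open


def assign_windows(pos: np.ndarray, window_size: int) -> np.ndarray:
    """Window start (0-based) for each 1-based position."""
    return ((np.asarray(pos, dtype=np.int64) - 1) // window_size) * window_size


# ---------------------------------------------------------------- site level


def site_pi(n_maj: float, n_min: float) -> float:
    """Finite-depth-corrected site heterozygosity (M/(M-1))(1 - f^2 - (1-f)^2).

    Undefined (ValueError) when total depth M < 2.
    """
    m = n_maj + n_min
    if m < 2:
        raise ValueError("site_pi requires read depth >= 2")
    f = n_maj / m
    return (m / (m - 1.0)) * (1.0 - f * f - (1.0 - f) * (1.0 - f))


def site_hp(n_maj: float, n_min: float) -> float:
    """Pooled heterozygosity 2*n_maj*n_min/(n_maj+n_min)^2 (max 0.5)."""
    m = n_maj + n_min
    if m < 1:
        raise ValueError("site_hp requires read depth >= 1")
    return 2.0 * n_maj * n_min / (m * m)


def _site_pi_vec(n_maj: np.ndarray, n_min: np.ndarray) -> np.ndarray:
    m = (n_maj + n_min).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = n_maj / m
        pi = (m / (m - 1.0)) * (1.0 - f * f - (1.0 - f) ** 2)
    pi[m < 2] = np.nan
    return pi


def _site_hp_vec(n_maj: np.ndarray, n_min: np.ndarray) -> np.ndarray:
    m = (n_maj + n_min).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hp = 2.0 * n_maj * n_min / (m * m)
    hp[m < 1] = np.nan
    return hp


# ------------------------------------------------------------- window level


def tajima_constants(n: int) -> dict:
    """Tajima's (1989) normalization constants for sample size n chromosomes."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def window_pi(
    site_pis: Sequence[float], covered_positions: int, min_covered_fraction: float = 0.0,
    window_size: Optional[int] = None,
) -> Optional[float]:
    """Sum of site pi over covered length; None when coverage is too thin."""
    if window_size is not None and covered_positions / window_size < min_covered_fraction:
        return None
    if covered_positions <= 0:
        return None
    return float(np.nansum(np.asarray(site_pis, dtype=float))) / covered_positions


def window_tajima_d(site_pis: Sequence[float], haploid_n: int) -> Optional[float]:
    """Classic Tajima's D from a window's per-site pi values (S = len)."""
    s = len(site_pis)
    if s == 0:
        return None
    k = tajima_constants(haploid_n)
    big_pi = float(np.nansum(np.asarray(site_pis, dtype=float)))
    theta_w = s / k["a1"]
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return None
    return (big_pi - theta_w) / math.sqrt(var)


def window_hp(site_hps: Sequence[float], min_snps: int = 33) -> Optional[float]:
    """Mean of per-site H_P; None when the window has fewer than min_snps."""
    if len(site_hps) < min_snps:
        return None
    return float(np.nanmean(np.asarray(site_hps, dtype=float)))


def zscore_hp(window_hps: Sequence[float]) -> np.ndarray:
    """Z-normalize a pool's window H_P values (sample sd, ddof=1)."""
    x = np.asarray(window_hps, dtype=float)
    if x.size < 2:
        raise ValueError("zscore_hp requires >= 2 defined windows")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or np.ptp(x) == 0.0:
        raise ValueError("degenerate H_P distribution (zero variance)")
    return (x - float(np.mean(x))) / sd


# ---------------------------------------------------------------- pipeline


def diversity_windows(
    snps: pd.DataFrame,
    pool_names: Sequence[str],
    window_size: int = 5000,
    min_snps: int = 33,
    min_covered_fraction: float = 0.5,
    coverage: Optional[dict] = None,
    haploid_n: int = 100,
    hp_mode: str = "mean",
    chrom_lengths: Optional[dict] = None,
) -> pd.DataFrame:
    """Windowed diversity table, one row per (pool, window).

    ``coverage`` optionally maps (chrom, window_start) -> number of positions
    passing depth filters; when absent every window is treated as fully
    covered (appropriate when invariant covered positions are not carried in
    the input).  With ``chrom_lengths`` given, trailing partial windows are
    not emitted.  Columns: pool, chrom, start, end, n_snps, covered_fraction,
    pi, theta_w, tajima_d, h_p, z_h_p (NaN where undefined).
    """
    if hp_mode not in ("mean", "ratio_of_sums"):
        raise ValueError(f"unknown hp_mode {hp_mode!r}")
    k = tajima_constants(haploid_n)
    starts = assign_windows(snps["pos"].to_numpy(), window_size) if len(snps) else np.array([], int)
    work = snps[["chrom", "pos"]].copy()
    work["start"] = starts
    rows = []
    for nm in pool_names:
        n_maj = snps[f"{nm}_maj"].to_numpy(np.int64)
        n_min = snps[f"{nm}_min"].to_numpy(np.int64)
        pi_s = _site_pi_vec(n_maj, n_min)
        hp_s = _site_hp_vec(n_maj, n_min)
        grp = work.assign(pi=pi_s, hp=hp_s, nmaj=n_maj, nmin=n_min).groupby(
            ["chrom", "start"], sort=True
        )
        agg = grp.agg(
            n_snps=("pi", "size"),
            pi_sum=("pi", lambda v: np.nansum(v.to_numpy())),
            s_seg=("pi", lambda v: int(np.sum(~np.isnan(v.to_numpy())))),
            hp_mean=("hp", lambda v: np.nanmean(v.to_numpy()) if len(v) else np.nan),
            maj_sum=("nmaj", "sum"),
            min_sum=("nmin", "sum"),
        ).reset_index()
        if chrom_lengths is not None:
            keep = agg.apply(
                lambda r: r["start"] + window_size <= chrom_lengths.get(r["chrom"], np.inf),
                axis=1,
            )
            agg = agg[keep].reset_index(drop=True)
        cov = np.empty(len(agg))
        for i, (c, st) in enumerate(zip(agg["chrom"], agg["start"])):
            covered = window_size if coverage is None else coverage.get((c, int(st)), 0)
            cov[i] = covered / window_size
        s = agg["s_seg"].to_numpy(float)
        pi_sum = agg["pi_sum"].to_numpy(float)
        covered_n = cov * window_size
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = np.where(covered_n > 0, pi_sum / covered_n, np.nan)
            theta = np.where(covered_n > 0, (s / k["a1"]) / covered_n, np.nan)
            var = k["e1"] * s + k["e2"] * s * (s - 1)
            taj = np.where(
                (s > 0) & (var > 0), (pi_sum - s / k["a1"]) / np.sqrt(var), np.nan
            )
        thin = cov < min_covered_fraction
        pi[thin] = np.nan
        theta[thin] = np.nan
        taj[thin] = np.nan
        if hp_mode == "mean":
            hp = agg["hp_mean"].to_numpy(float)
        else:
            ms, ns = agg["maj_sum"].to_numpy(float), agg["min_sum"].to_numpy(float)
            tot = ms + ns
            with np.errstate(divide="ignore", invalid="ignore"):
                hp = 2.0 * ms * ns / (tot * tot)
        hp = np.where(agg["n_snps"].to_numpy() >= min_snps, hp, np.nan)
        out = pd.DataFrame(
            {
                "pool": nm,
                "chrom": agg["chrom"],
                "start": agg["start"].astype(np.int64),
                "end": agg["start"].astype(np.int64) + window_size,
                "n_snps": agg["n_snps"].astype(np.int64),
                "covered_fraction": cov,
                "pi": pi,
                "theta_w": theta,
                "tajima_d": taj,
                "h_p": hp,
            }
        )
        defined = out["h_p"].notna()
        z = np.full(len(out), np.nan)
        if defined.sum() >= 2:
            z[defined.to_numpy()] = zscore_hp(out.loc[defined, "h_p"].to_numpy())
        out["z_h_p"] = z
        rows.append(out)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def write_diversity_tsv(div: pd.DataFrame, stream, header: Optional[str] = None) -> None:
    """Per-pool window TSV with 'na' for undefined values."""
    if header is not None:
        stream.write(f"# {header}\n")
    div.to_csv(stream, sep="\t", index=False, na_rep="na", float_format="%.10g")
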