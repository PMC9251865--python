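"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as slow, per-site scalar arithmetic
(math/fractions only, no shared code with the package's vectorized paths)
so it can serve as a second route for the window statistics, Tajima's
constants and Fisher's exact test.
"""

from __future__ import annotations

import math
from fractions import Fraction


def tajima_d_bruteforce(big_pi: float, s: int, n: int) -> float:
    """Tajima's D with constants accumulated exactly in rationals."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = float(e1) * s + float(e2) * s * (s - 1)
    theta_w = s / float(a1)
    return (big_pi - theta_w) / math.sqrt(var)


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n1, n2 = a + b, c + d
    k_col = a + c
    n = n1 + n2
    if n1 == 0 or n2 == 0 or k_col == 0 or k_col == n:
        return 1.0
    denom = math.comb(n, k_col)
    kmin, kmax = max(0, k_col - n2), min(k_col, n1)
    probs = [
        math.comb(n1, k) * math.comb(n2, k_col - k) / denom
        for k in range(kmin, kmax + 1)
    ]
    p_obs = probs[a - kmin]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-9)))


def window_stats_bruteforce(
    snp_rows: list, pool: str, window_size: int = 5000, min_snps: int = 33,
    haploid_n: int = 100,
) -> dict:
    """Per-window pi-sum/S/H_P for one pool by a plain per-site loop.

    ``snp_rows`` are dicts with chrom, pos and {pool}_maj/{pool}_min.
    Returns {(chrom, start): {'pi', 'theta_w', 'tajima_d', 'h_p', 'n_snps'}}
    with window-length-normalized pi/theta (full coverage assumed) and None
    for undefined values.
    """
    groups: dict = {}
    for r in snp_rows:
        start = ((r["pos"] - 1) // window_size) * window_size
        groups.setdefault((r["chrom"], start), []).append(r)
    a1 = sum(1.0 / i for i in range(1, haploid_n))
    out = {}
    for key, rows in groups.items():
        pis, hps = [], []
        for r in rows:
            nm, nn = r[f"{pool}_maj"], r[f"{pool}_min"]
            m = nm + nn
            if m >= 1:
                hps.append(2.0 * nm * nn / (m * m))
            if m >= 2:
                f = nm / m
                pis.append((m / (m - 1.0)) * (1.0 - f * f - (1.0 - f) * (1.0 - f)))
        s = len(pis)
        big_pi = sum(pis)
        taj = tajima_d_bruteforce(big_pi, s, haploid_n) if s > 0 else None
        out[key] = {
            "pi": big_pi / window_size,
            "theta_w": (s / a1) / window_size,
            "tajima_d": taj,
            "h_p": (sum(hps) / len(hps)) if len(hps) >= min_snps else None,
            "n_snps": len(rows),
        }
    return out


def pair_stats_bruteforce(
    snp_rows: list, pool_a: str, pool_b: str, window_size: int = 5000
) -> dict:
    """Per-window Nei/Karlsson F_ST and mean dAF by a plain per-site loop."""
    groups: dict = {}
    for r in snp_rows:
        start = ((r["pos"] - 1) // window_size) * window_size
        groups.setdefault((r["chrom"], start), []).append(r)
    out = {}
    for key, rows in groups.items():
        ht_sum = hw_sum = 0.0
        num_sum = den_sum = 0.0
        dafs = []
        for r in rows:
            ma, na = r[f"{pool_a}_maj"], r[f"{pool_a}_min"]
            mb, nb = r[f"{pool_b}_maj"], r[f"{pool_b}_min"]
            da, db = ma + na, mb + nb
            if da > 0 and db > 0:
                fa, fb = ma / da, mb / db
                ft = (ma + mb) / (da + db)
                hw_sum += 0.5 * ((1 - fa * fa - (1 - fa) ** 2) + (1 - fb * fb - (1 - fb) ** 2))
                ht_sum += 1 - ft * ft - (1 - ft) ** 2
                dafs.append(abs(fa - fb))
            if da >= 2 and db >= 2:
                h1 = ma * (da - ma) / (da * (da - 1.0))
                h2 = mb * (db - mb) / (db * (db - 1.0))
                n = (ma / da - mb / db) ** 2 - h1 / da - h2 / db
                num_sum += n
                den_sum += n + h1 + h2
        out[key] = {
            "fst_nei": (ht_sum - hw_sum) / ht_sum if ht_sum != 0 else None,
            "fst_karlsson": num_sum / den_sum if den_sum != 0 else None,
            "delta_af_mean": sum(dafs) / len(dafs) if dafs else None,
        }
    return out
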