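"""Functional enrichment of allele-frequency differences.

SNPs annotated with a functional category (non-synonymous, synonymous, UTR,
5 kb upstream/downstream, intragenic, intergenic) are binned by pairwise
dAF into 10 equal bins (0-0.1, 0.1-0.2, ..., last bin right-closed).  Under
no association between function and divergence, the expected count for a
(category, bin) cell is row_total * column_total / grand_total; the
reported effect size is the M-value log2(observed/expected) and
significance comes from a df=1 chi-square on the cell's 2x2 collapse
(cell vs rest-of-row vs rest-of-column vs remainder), without continuity
correction.  A cell is called enriched when M exceeds ``m_min`` and p beats
the genome-size Bonferroni threshold alpha/genome_size (0.05 / 2e9 =
2.5e-11 by default).

dAF = 0 SNPs (monomorphic between the pair but variant elsewhere) fall in
bin 0: the grand total is all annotated SNPs.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_sync import ANNOTATION_CATEGORIES

N_BINS = 10

#: display order of categories in output tables
CATEGORY_ORDER = (
    "non_synonymous",
    "synonymous",
    "UTR",
    "upstream_5kb",
    "downstream_5kb",
    "intragenic",
    "intergenic",
)


def bin_delta_af(delta_af: float) -> int:
    """Bin index 0-9 for a dAF value; bins are [0,0.1), ..., [0.9,1.0]."""
    if not (0.0 <= delta_af <= 1.0) or math.isnan(delta_af):
        raise ValueError(f"delta_af out of range [0, 1]: {delta_af!r}")
    return min(int(delta_af * N_BINS), N_BINS - 1)


def bin_delta_af_vec(delta_af: np.ndarray) -> np.ndarray:
    d = np.asarray(delta_af, float)
    if np.any(np.isnan(d)) or np.any((d < 0) | (d > 1)):
        raise ValueError("delta_af values must lie in [0, 1] and be defined")
    return np.minimum((d * N_BINS).astype(int), N_BINS - 1)


def _cell_chi2(obs: float, row: float, col: float, total: float) -> float:
    """df=1 chi-square of the 2x2 collapse of one cell (no continuity corr.)."""
    a = obs
    b = row - obs
    c = col - obs
    d = total - row - col + obs
    denom = row * (total - row) * col * (total - col)
    if denom == 0:
        return 0.0
    return total * (a * d - b * c) ** 2 / denom


def enrichment_table(annotated: pd.DataFrame) -> pd.DataFrame:
    """Observed/expected grid over (category x dAF bin).

    ``annotated`` needs columns ``category`` and ``delta_af`` (one row per
    SNP).  Returns one row per cell with observed, expected, m_value, chi2,
    p and a ``flagged`` column marking cells with expected = 0 but observed
    > 0 (M undefined there).
    """
    bad = set(annotated["category"].unique()) - ANNOTATION_CATEGORIES
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    bins = bin_delta_af_vec(annotated["delta_af"].to_numpy())
    cats = [c for c in CATEGORY_ORDER if c in set(annotated["category"])]
    obs = pd.crosstab(
        pd.Categorical(annotated["category"], categories=cats),
        pd.Categorical(bins, categories=range(N_BINS)),
        dropna=False,
    ).to_numpy(float)
    total = obs.sum()
    row_tot = obs.sum(axis=1, keepdims=True)
    col_tot = obs.sum(axis=0, keepdims=True)
    expected = row_tot @ col_tot / total
    rows = []
    for i, cat in enumerate(cats):
        for b in range(N_BINS):
            o, e = obs[i, b], expected[i, b]
            flagged = e == 0.0 and o > 0
            if o > 0 and e > 0:
                m = math.log2(o / e)
            elif o == 0 and e > 0:
                m = -math.inf
            else:
                m = math.nan
            chi2 = _cell_chi2(o, float(row_tot[i, 0]), float(col_tot[0, b]), total)
            p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
            rows.append(
                {
                    "category": cat,
                    "bin": b,
                    "observed": int(o),
                    "expected": e,
                    "m_value": m,
                    "chi2": chi2,
                    "p": p,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


def significant_cells(
    grid: pd.DataFrame,
    m_min: float = 0.05,
    alpha: float = 0.05,
    genome_size: float = 2e9,
) -> pd.DataFrame:
    """Cells with m_value > m_min and p < alpha/genome_size."""
    thresh = alpha / genome_size
    mask = (grid["m_value"] > m_min) & (grid["p"] < thresh) & ~grid["flagged"]
    return grid[mask].reset_index(drop=True)


def write_enrichment_tsv(grid: pd.DataFrame, stream, header: Optional[str] = None,
                         m_min: float = 0.05, alpha: float = 0.05,
                         genome_size: float = 2e9) -> None:
    if header is not None:
        stream.write(f"# {header}\n")
    out = grid.copy()
    out["significant"] = (
        (out["m_value"] > m_min) & (out["p"] < alpha / genome_size) & ~out["flagged"]
    )
    out.to_csv(stream, sep="\t", index=False, na_rep="na", float_format="%.10g")
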