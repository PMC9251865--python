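"""Site-level filtering: indel-region masking, depth-window subsampling and
biallelic SNP calling.

The filters mirror standard Pool-seq practice for large, partially polyploid
genomes: positions within a flank of any indel are removed (alignment around
indels is error-prone), per-pool countable depth must fall inside a fixed
window (low depth means few individuals represented; high depth flags
collapsed paralogs), and over-covered sites are thinned to the maximum depth
by drawing reads without replacement.  A site failing any per-pool filter is
dropped for all pools so that every downstream pairwise statistic sees an
aligned site set.

The SNP table produced by :func:`call_snps` is a pandas DataFrame with one
row per biallelic site and columns ``chrom, pos, major, minor`` plus
``{pool}_maj``/``{pool}_min`` read counts per pool; the major allele is
defined on counts pooled over all populations (ties broken A<C<G<T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

import numpy as np
import pandas as pd

from .io_sync import SYNC_BASES, SyncSite

#: countable bases in sync order and their alphabetical tie-break rank
_BASE_LETTERS = ("A", "T", "C", "G")
_TIE_RANK = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PoolConfig:
    """Per-run pool declaration and filter parameters.

    diploid_pool_size is the number of diploid individuals per pool (50 in
    the study design this pipeline targets); min/max depth bound the
    countable per-pool depth window (20-150x); min_minor_count is the pooled
    minor-allele read count needed to call a SNP; indel_flank the masked
    distance (bp) around each indel.
    """

    pool_names: Sequence[str]
    diploid_pool_size: int = 50
    min_depth: int = 20
    max_depth: int = 150
    min_minor_count: int = 2
    indel_flank: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_depth <= self.max_depth):
            raise ValueError("require 0 < min_depth <= max_depth")
        if self.indel_flank < 0:
            raise ValueError("indel_flank must be >= 0")
        if self.diploid_pool_size < 1:
            raise ValueError("diploid_pool_size must be >= 1")

    @property
    def n_pools(self) -> int:
        return len(self.pool_names)

    @property
    def haploid_n(self) -> int:
        return 2 * self.diploid_pool_size


@dataclass
class AuditLog:
    """Drop reasons per site, writable as a TSV (chrom, pos, reason)."""

    rows: list = field(default_factory=list)

    def drop(self, chrom: str, pos: int, reason: str) -> None:
        self.rows.append((chrom, pos, reason))

    def counts(self) -> dict:
        out: dict = {}
        for _, _, reason in self.rows:
            out[reason] = out.get(reason, 0) + 1
        return out

    def write(self, stream: TextIO) -> None:
        stream.write("chrom\tpos\treason\n")
        for chrom, pos, reason in self.rows:
            stream.write(f"{chrom}\t{pos}\t{reason}\n")


def mask_indel_regions(
    sites: Iterable[SyncSite],
    indel_positions: set,
    flank: int = 5,
    audit: Optional[AuditLog] = None,
) -> list:
    """Drop every site within ``flank`` bp of an indel on the same chromosome.

    The masked interval around an indel at position p is the closed
    [p - flank, p + flank]; all other sites pass unchanged in order.
    """
    if not indel_positions:
        return list(sites)
    by_chrom: dict = {}
    for chrom, pos in indel_positions:
        by_chrom.setdefault(chrom, []).append(pos)
    masks = {c: np.sort(np.asarray(ps)) for c, ps in by_chrom.items()}
    out = []
    for s in sites:
        ps = masks.get(s.chrom)
        if ps is not None:
            i = np.searchsorted(ps, s.pos)
            near = (i < len(ps) and ps[i] - s.pos <= flank) or (
                i > 0 and s.pos - ps[i - 1] <= flank
            )
            if near:
                if audit is not None:
                    audit.drop(s.chrom, s.pos, "indel_mask")
                continue
        out.append(s)
    return out


def depth_mode(sites: Sequence[SyncSite], pool: int) -> int:
    """Mode of the countable read-depth histogram for one pool (QC only)."""
    depths = np.array([s.depth(pool) for s in sites], dtype=int)
    if depths.size == 0:
        return 0
    return int(np.bincount(depths).argmax())


def subsample_site(
    site: SyncSite, cfg: PoolConfig, rng: np.random.Generator
) -> Optional[SyncSite]:
    """Apply the depth window to one site; None means dropped (all pools).

    Pools with countable depth above ``cfg.max_depth`` are thinned to exactly
    max_depth by a multivariate hypergeometric draw on the four base counts
    (reads are physical observations, so sampling is without replacement);
    any pool below ``cfg.min_depth`` drops the whole site.  N/del counts pass
    through untouched.
    """
    new_counts = []
    for pool in range(site.n_pools):
        c = site.counts[pool]
        d = c[0] + c[1] + c[2] + c[3]
        if d < cfg.min_depth:
            return None
        if d > cfg.max_depth:
            kept = rng.multivariate_hypergeometric(list(c[:4]), cfg.max_depth)
            new_counts.append((int(kept[0]), int(kept[1]), int(kept[2]), int(kept[3]), c[4], c[5]))
        else:
            new_counts.append(c)
    return site._replace(counts=tuple(new_counts))


def subsample_depth(
    sites: Iterable[SyncSite],
    cfg: PoolConfig,
    seed: Optional[int] = None,
    audit: Optional[AuditLog] = None,
) -> list:
    """Depth-window filter over a site stream; deterministic for fixed seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = []
    for s in sites:
        r = subsample_site(s, cfg, rng)
        if r is None:
            if audit is not None:
                audit.drop(s.chrom, s.pos, "low_depth")
            continue
        out.append(r)
    return out


def call_snps(
    sites: Sequence[SyncSite],
    cfg: PoolConfig,
    audit: Optional[AuditLog] = None,
) -> pd.DataFrame:
    """Call biallelic SNPs from masked, subsampled sites.

    A base qualifies when its count pooled over all pools is at least
    ``cfg.min_minor_count``; a site with exactly two qualifying bases becomes
    a SNP.  The major allele is the qualifying base with the larger pooled
    count (ties broken by A<C<G<T order).  Idempotent on its own output
    re-expressed as sites.
    """
    names = list(cfg.pool_names)
    cols: dict = {"chrom": [], "pos": [], "major": [], "minor": []}
    for nm in names:
        cols[f"{nm}_maj"] = []
        cols[f"{nm}_min"] = []
    for s in sites:
        arr = np.asarray(s.counts, dtype=np.int64)[:, :4]  # pools x ACGT(sync order)
        pooled = arr.sum(axis=0)
        qual = np.flatnonzero(pooled >= cfg.min_minor_count)
        if len(qual) != 2:
            if audit is not None:
                audit.drop(s.chrom, s.pos, "non_biallelic")
            continue
        i, j = int(qual[0]), int(qual[1])
        bi, bj = _BASE_LETTERS[i], _BASE_LETTERS[j]
        if pooled[i] > pooled[j]:
            mi, mj = i, j
        elif pooled[j] > pooled[i]:
            mi, mj = j, i
        else:
            mi, mj = (i, j) if _TIE_RANK[bi] < _TIE_RANK[bj] else (j, i)
        cols["chrom"].append(s.chrom)
        cols["pos"].append(s.pos)
        cols["major"].append(_BASE_LETTERS[mi])
        cols["minor"].append(_BASE_LETTERS[mj])
        for p, nm in enumerate(names):
            cols[f"{nm}_maj"].append(int(arr[p, mi]))
            cols[f"{nm}_min"].append(int(arr[p, mj]))
    df = pd.DataFrame(cols)
    df["pos"] = df["pos"].astype(np.int64) if len(df) else df["pos"]
    return df


def snps_to_sites(snps: pd.DataFrame, pool_names: Sequence[str]) -> list:
    """Re-express a SNP table as SyncSites (used for idempotence checks)."""
    sites = []
    sync_idx = {b: i for i, b in enumerate(SYNC_BASES)}
    for row in snps.itertuples(index=False):
        counts = []
        for nm in pool_names:
            c = [0, 0, 0, 0, 0, 0]
            c[sync_idx[row.major]] = int(getattr(row, f"{nm}_maj"))
            c[sync_idx[row.minor]] = int(getattr(row, f"{nm}_min"))
            counts.append(tuple(c))
        sites.append(SyncSite(row.chrom, int(row.pos), row.major, tuple(counts)))
    return sites


def pool_count_arrays(snps: pd.DataFrame, pool_names: Sequence[str]):
    """(n_maj, n_min) integer arrays of shape (n_snps, n_pools)."""
    n_maj = np.column_stack([snps[f"{nm}_maj"].to_numpy(np.int64) for nm in pool_names])
    n_min = np.column_stack([snps[f"{nm}_min"].to_numpy(np.int64) for nm in pool_names])
    return n_maj, n_min
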