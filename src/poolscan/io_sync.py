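"""Readers and writers for the text formats the pipeline touches.

Supported formats: SAMtools mpileup (read-only), the tab-separated sync
allele-count format (``chrom  pos  ref  A:T:C:G:N:del`` per pool), the SNP
functional-annotation TSV, gene intervals from GFF3, and the TreeMix
allele-count export consumed elsewhere.

Counts are carried in the fixed sync base order A:T:C:G:N:del.  N and
deletion counts are parsed and stored but never enter coverage or allele
frequencies downstream (the pipeline analyses biallelic substitutions).
Quality encoding is fixed to Phred+33.
"""

from __future__ import annotations

from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, TextIO

# Fixed sync column order for count vectors.
SYNC_BASES = ("A", "T", "C", "G", "N", "del")
#: index into a count vector for each countable base
BASE_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4}
#: closed vocabulary of functional-annotation categories
ANNOTATION_CATEGORIES = frozenset(
    {
        "non_synonymous",
        "synonymous",
        "UTR",
        "upstream_5kb",
        "downstream_5kb",
        "intragenic",
        "intergenic",
    }
)

PHRED_OFFSET = 33


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class SyncSite(NamedTuple):
    """One genomic position with per-pool base counts.

    ``counts`` is a tuple of per-pool 6-tuples in A:T:C:G:N:del order.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    counts: tuple

    @property
    def n_pools(self) -> int:
        return len(self.counts)

    def depth(self, pool: int) -> int:
        """Countable depth (A+T+C+G) for one pool; N/del excluded."""
        c = self.counts[pool]
        return c[0] + c[1] + c[2] + c[3]


class AnnotationRecord(NamedTuple):
    chrom: str
    pos: int  # 1-based
    category: str
    gene_id: Optional[str]


class GeneInterval(NamedTuple):
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    gene_id: str


def _parse_mpileup_pool(
    ref: str, bases: str, quals: str, min_base_quality: int, lineno: int
) -> tuple[list, bool]:
    """Resolve one pool's base/quality strings to counts.

    Returns (counts[6], saw_indel).  ``^``/``$`` read markers are stripped,
    indel insertions/deletions (``+N...``/``-N...``) are consumed but not
    counted, ``*`` is a deleted base, ``>``/``<`` reference skips consume a
    quality character but count toward nothing.
    """
    counts = [0, 0, 0, 0, 0, 0]
    saw_indel = False
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # '^' plus mapping-quality char
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            saw_indel = True
            i += 1
            num = 0
            while i < n and bases[i].isdigit():
                num = num * 10 + int(bases[i])
                i += 1
            i += num  # inserted/deleted sequence, not a base call
            continue
        if qi >= len(quals):
            raise FormatError(f"line {lineno}: quality string shorter than base string")
        q = ord(quals[qi]) - PHRED_OFFSET
        qi += 1
        i += 1
        if ch in ".,":
            base = ref
        elif ch in "ACGTNacgtn":
            base = ch.upper()
        elif ch in "*#":
            saw_indel = True
            if q >= min_base_quality:
                counts[5] += 1
            continue
        elif ch in "><":
            continue  # reference skip
        else:
            raise FormatError(f"line {lineno}: unknown base symbol {ch!r}")
        if q >= min_base_quality:
            counts[BASE_INDEX[base]] += 1
    return counts, saw_indel


def read_mpileup(
    stream: Iterable[str],
    n_pools: int,
    min_base_quality: int = 20,
    indel_positions: Optional[set] = None,
) -> Iterator[SyncSite]:
    """Parse a SAMtools mpileup stream into SyncSites.

    Bases with quality below ``min_base_quality`` (Phred+33) are excluded
    from the counts.  If ``indel_positions`` is a set it is filled with
    ``(chrom, pos)`` of every site showing indel evidence in any pool, for
    use by :func:`poolscan.preprocess.mask_indel_regions`.
    """
    expected = 3 + 3 * n_pools
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split()
        if len(fields) != expected:
            raise FormatError(
                f"line {lineno}: expected {expected} columns for {n_pools} pools, "
                f"got {len(fields)}"
            )
        chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
        pos = int(pos_s)
        pool_counts = []
        saw_indel = False
        for p in range(n_pools):
            depth_s, bases, quals = fields[3 + 3 * p : 6 + 3 * p]
            counts, indel = _parse_mpileup_pool(ref, bases, quals, min_base_quality, lineno)
            saw_indel = saw_indel or indel
            if sum(counts[:4]) + counts[4] + counts[5] > int(depth_s):
                raise FormatError(
                    f"line {lineno}: counted bases exceed depth column in pool {p}"
                )
            pool_counts.append(tuple(counts))
        if saw_indel and indel_positions is not None:
            indel_positions.add((chrom, pos))
        yield SyncSite(chrom, pos, ref, tuple(pool_counts))


def read_sync(stream: Iterable[str]) -> Iterator[SyncSite]:
    """Parse a sync stream (``chrom pos ref`` then ``A:T:C:G:N:del`` per pool)."""
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"line {lineno}: sync needs >= 4 tab-separated columns")
        chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
        counts = []
        for tok in fields[3:]:
            parts = tok.split(":")
            if len(parts) != 6:
                raise FormatError(f"line {lineno}: count token {tok!r} is not 6 fields")
            try:
                counts.append(tuple(int(x) for x in parts))
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer count in {tok!r}") from None
        yield SyncSite(chrom, int(pos_s), ref, tuple(counts))


def write_sync(
    sites: Iterable[SyncSite], stream: TextIO, header: Optional[str] = None
) -> None:
    """Write sites in sync format; ``header`` (no leading ``#``) is emitted
    as a comment line recording provenance (tool version, config hash, seed)."""
    if header is not None:
        stream.write(f"# {header}\n")
    for s in sites:
        cols = [s.chrom, str(s.pos), s.ref]
        cols.extend(":".join(str(c) for c in pool) for pool in s.counts)
        stream.write("\t".join(cols) + "\n")


def read_annotation_table(stream: Iterable[str]) -> list:
    """Read the SNP annotation TSV (header: chrom, pos, category, gene_id).

    Categories are validated against the closed vocabulary; records are
    returned sorted by (chrom, pos).  gene_id may be empty/'.' -> None.
    """
    it = iter(stream)
    try:
        header = next(it).rstrip("\n").split("\t")
    except StopIteration:
        raise FormatError("empty annotation file (missing header)") from None
    if header[:3] != ["chrom", "pos", "category"]:
        raise FormatError(f"unexpected annotation header: {header!r}")
    records = []
    for lineno, line in enumerate(it, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        chrom, pos_s, category = fields[0], fields[1], fields[2]
        if category not in ANNOTATION_CATEGORIES:
            raise FormatError(
                f"line {lineno}: unknown annotation category {category!r}; "
                f"expected one of {sorted(ANNOTATION_CATEGORIES)}"
            )
        gene = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else None
        records.append(AnnotationRecord(chrom, int(pos_s), category, gene))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_annotation_table(records: Sequence[AnnotationRecord], stream: TextIO) -> None:
    stream.write("chrom\tpos\tcategory\tgene_id\n")
    for r in records:
        stream.write(f"{r.chrom}\t{r.pos}\t{r.category}\t{r.gene_id or '.'}\n")


def read_gene_intervals(stream: Iterable[str]) -> list:
    """Extract gene intervals (1-based inclusive) from a GFF3 stream.

    Only ``gene`` features are kept; the gene identifier is the ``ID=``
    attribute (falling back to ``gene_id=`` or ``Name=``).
    """
    genes = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"line {lineno}: GFF3 needs 9 columns, got {len(fields)}")
        if fields[2] != "gene":
            continue
        attrs = {}
        for item in fields[8].split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                attrs[k.strip()] = v.strip()
        gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
        if gid is None:
            raise FormatError(f"line {lineno}: gene feature without ID attribute")
        genes.append(GeneInterval(fields[0], int(fields[3]), int(fields[4]), gid))
    return genes
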