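"""Ground-truthed translocation simulator.

The generator emulates the study design the pipeline targets: two source
populations ("A", migratory; "B", resident) diverged at a genome-wide
F_ST target (default 0.16, Balding-Nichols model), simultaneously released
into a new lake system, and two descendant populations ("LB", "HV") formed
by admixture of the sources — LB biased toward B (default weight 0.75 on
B), HV biased toward A (default weight 0.30 on B) — followed by a few
generations of Wright-Fisher drift (default 5 generations at Ne = 200).
Each population is then pooled-sequenced: 50 diploids per pool, binomial
chromosome sampling, negative-binomial read depth around 80x (overdispersed,
as real coverage is), and a small per-read error rate that can relocate a
read to any other base.

Planted regions make selection signals available for scan validation:

* ``established_sweep`` — a directional-selection signal: the ancestral
  frequency is drawn from a narrow intermediate band so the variant
  segregates in both sources (standing variation), and after drift both
  descendant pools are pushed to near-fixation (1 - eps);
* ``source_divergence`` — near-fixed alternate alleles in the two sources
  before mixing (high dAF / F_ST with low within-source diversity).

Loci are unlinked; sweep "regions" are realized as runs of adjacent loci so
that 5 kb windows reach the >= 33-SNP retention threshold.  Identical
SimConfig (including seed) gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_sync import SyncSite, AnnotationRecord
from .enrichment import CATEGORY_ORDER

SWEEP_EPS = 0.02

#: baseline probabilities of functional categories (order = CATEGORY_ORDER);
#: roughly the genomic proportions of a compact annotated vertebrate genome
DEFAULT_CATEGORY_PROBS = {
    "non_synonymous": 0.05,
    "synonymous": 0.07,
    "UTR": 0.05,
    "upstream_5kb": 0.09,
    "downstream_5kb": 0.09,
    "intragenic": 0.30,
    "intergenic": 0.35,
}


@dataclass
class SweepRegion:
    chrom: str
    start: int  # 0-based half-open, window-aligned by convention
    end: int
    mode: str  # established_sweep | source_divergence

    def __post_init__(self) -> None:
        if self.mode not in ("established_sweep", "source_divergence"):
            raise ValueError(f"unknown sweep mode {self.mode!r}")


@dataclass
class SimConfig:
    """Study-design parameters of the simulated translocation."""

    n_chrom: int = 5
    chrom_length: int = 1_000_000
    n_loci: int = 50_000
    fst_target: float = 0.16
    ancestral_freq_range: tuple = (0.05, 0.95)
    admix_alpha_lb: float = 0.75  # weight on source B in LB
    admix_alpha_hv: float = 0.30  # weight on source B in HV
    drift_generations: int = 5
    ne: int = 200
    diploid_pool_size: int = 50
    mean_depth: float = 80.0
    depth_dispersion: float = 8.0
    error_rate: float = 0.002
    sweep_regions: Sequence[SweepRegion] = field(default_factory=tuple)
    seed: int = 0
    pool_names: tuple = ("A", "B", "LB", "HV")

    def __post_init__(self) -> None:
        if not (0.0 < self.fst_target < 1.0):
            raise ValueError("fst_target must be in (0, 1)")
        for a in (self.admix_alpha_lb, self.admix_alpha_hv):
            if not (0.0 <= a <= 1.0):
                raise ValueError("admixture weights must be in [0, 1]")
        if min(self.n_chrom, self.chrom_length, self.n_loci, self.ne,
               self.diploid_pool_size) < 1:
            raise ValueError("all sizes must be positive")


@dataclass
class SimTruth:
    """Ground truth: per-locus frequencies, planted regions, realized seed."""

    loci: pd.DataFrame  # chrom,pos,p_anc,f_A,f_B,f_LB,f_HV,sweep_mode
    regions: pd.DataFrame
    seed: int
    window_fst_ab: pd.DataFrame  # chrom,start,true_fst (Nei-style on truth)


def default_sweep_regions(
    cfg: SimConfig, n_regions: int = 10, mode: str = "established_sweep",
    region_size: int = 5000,
) -> list:
    """Evenly spaced window-aligned planted regions across the chromosomes."""
    regions = []
    per_chrom = int(np.ceil(n_regions / cfg.n_chrom))
    placed = 0
    for c in range(cfg.n_chrom):
        for r in range(per_chrom):
            if placed >= n_regions:
                break
            start = ((r + 1) * cfg.chrom_length // (per_chrom + 1) // region_size) * region_size
            regions.append(SweepRegion(f"chr{c + 1}", start, start + region_size, mode))
            placed += 1
    return regions


def _place_loci(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Distinct 1-based positions, spread over chromosomes proportionally."""
    per = np.full(cfg.n_chrom, cfg.n_loci // cfg.n_chrom, dtype=int)
    per[: cfg.n_loci % cfg.n_chrom] += 1
    frames = []
    for c in range(cfg.n_chrom):
        pos = rng.choice(cfg.chrom_length, size=per[c], replace=False) + 1
        pos.sort()
        frames.append(pd.DataFrame({"chrom": f"chr{c + 1}", "pos": pos}))
    return pd.concat(frames, ignore_index=True)


def _sweep_mode_per_locus(loci: pd.DataFrame, regions: Sequence[SweepRegion]) -> np.ndarray:
    mode = np.array([""] * len(loci), dtype=object)
    pos0 = loci["pos"].to_numpy() - 1
    for r in regions:
        hit = (loci["chrom"].to_numpy() == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)
        mode[hit] = r.mode
    return mode


def simulate_source_freqs(cfg: SimConfig, rng: np.random.Generator,
                          loci: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Ancestral and source-population frequencies per locus.

    The ancestral frequency p is uniform on ``ancestral_freq_range`` (narrow
    intermediate band 0.40-0.60 inside established_sweep regions, so the
    planted variant is standing variation in both sources); f_A and f_B are
    independent Balding-Nichols draws Beta(p(1-F)/F, (1-p)(1-F)/F).
    source_divergence regions then pin f_A = 1-eps, f_B = eps.
    """
    if loci is None:
        loci = _place_loci(cfg, rng)
    n = len(loci)
    mode = (
        loci["sweep_mode"].to_numpy()
        if "sweep_mode" in loci.columns
        else _sweep_mode_per_locus(loci, cfg.sweep_regions)
    )
    lo, hi = cfg.ancestral_freq_range
    p = rng.uniform(lo, hi, size=n)
    est = mode == "established_sweep"
    p[est] = rng.uniform(0.40, 0.60, size=int(est.sum()))
    f = cfg.fst_target
    scale = (1.0 - f) / f
    f_a = rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1 - p) * scale, 1e-12))
    f_b = rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1 - p) * scale, 1e-12))
    div = mode == "source_divergence"
    f_a[div] = 1.0 - SWEEP_EPS
    f_b[div] = SWEEP_EPS
    out = loci.copy()
    out["sweep_mode"] = mode
    out["p_anc"] = p
    out["f_A"] = f_a
    out["f_B"] = f_b
    return out


def simulate_established_freqs(
    freqs: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Descendant-population frequencies: admixture, drift, planted sweeps.

    Each descendant starts at f0 = alpha*f_B + (1-alpha)*f_A, undergoes
    ``drift_generations`` rounds of binomial Wright-Fisher drift at size
    2*Ne, and established_sweep regions are then overridden to 1 - eps.
    """
    out = freqs.copy()
    two_ne = 2 * cfg.ne
    for name, alpha in (("LB", cfg.admix_alpha_lb), ("HV", cfg.admix_alpha_hv)):
        f = alpha * out["f_B"].to_numpy() + (1.0 - alpha) * out["f_A"].to_numpy()
        for _ in range(cfg.drift_generations):
            f = rng.binomial(two_ne, f) / two_ne
        est = (out["sweep_mode"] == "established_sweep").to_numpy()
        f = np.where(est, 1.0 - SWEEP_EPS, f)
        out[f"f_{name}"] = f
    return out


_OTHER_BASES = {
    "A": ("T", "C", "G"),
    "T": ("A", "C", "G"),
    "C": ("A", "T", "G"),
    "G": ("A", "T", "C"),
}
_SYNC_IDX = {"A": 0, "T": 1, "C": 2, "G": 3}


def sample_pool_sync(
    freqs: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> tuple:
    """Pooled sequencing of the four populations; returns (sites, pool_freqs).

    Per pool and locus: k ~ Binomial(2*pool_size, f) chromosomes carry the
    reference ("allele 1") base, giving pool frequency q; read depth
    d ~ NegBin(mean=mean_depth, dispersion=depth_dispersion); reads fall on
    the four bases with probabilities q(1-e)+ (1-q)e/3 for the reference
    base, (1-q)(1-e) + q e/3 for the alternate, and e/3 for each other base.
    """
    n = len(freqs)
    names = list(cfg.pool_names)
    two_n = 2 * cfg.diploid_pool_size
    # reference/alternate bases per locus
    ref_idx = rng.integers(0, 4, size=n)
    alt_off = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_off) % 4
    bases = np.array(["A", "T", "C", "G"])
    ref = bases[ref_idx]
    alt = bases[alt_idx]
    k = cfg.depth_dispersion
    p_nb = k / (k + cfg.mean_depth)
    e = cfg.error_rate
    counts = np.zeros((n, len(names), 6), dtype=np.int64)
    pool_q = {}
    for pi, nm in enumerate(names):
        f = freqs[f"f_{nm}"].to_numpy()
        q = rng.binomial(two_n, f) / two_n
        pool_q[nm] = q
        d = rng.negative_binomial(k, p_nb, size=n)
        probs = np.zeros((n, 4))
        rows = np.arange(n)
        probs[rows, ref_idx] += q * (1 - e) + (1 - q) * e / 3
        probs[rows, alt_idx] += (1 - q) * (1 - e) + q * e / 3
        other = probs == 0.0
        probs[other] = e / 3
        probs /= probs.sum(axis=1, keepdims=True)
        draws = rng.multinomial(d, probs)
        # map base index (A,T,C,G order used here) to sync order (same order)
        counts[:, pi, :4] = draws
    sites = []
    for i in range(n):
        sites.append(
            SyncSite(
                freqs["chrom"].iat[i],
                int(freqs["pos"].iat[i]),
                str(ref[i]),
                tuple(tuple(int(x) for x in counts[i, pi]) for pi in range(len(names))),
            )
        )
    return sites, pool_q


def true_window_fst(freqs: pd.DataFrame, window_size: int = 5000) -> pd.DataFrame:
    """Nei-style F_ST between sources A and B from true frequencies."""
    from .diversity import assign_windows

    fa = freqs["f_A"].to_numpy()
    fb = freqs["f_B"].to_numpy()
    hw = 0.5 * ((1 - fa**2 - (1 - fa) ** 2) + (1 - fb**2 - (1 - fb) ** 2))
    fm = 0.5 * (fa + fb)
    ht = 1 - fm**2 - (1 - fm) ** 2
    work = pd.DataFrame(
        {
            "chrom": freqs["chrom"],
            "start": assign_windows(freqs["pos"].to_numpy(), window_size),
            "hw": hw,
            "ht": ht,
        }
    )
    agg = work.groupby(["chrom", "start"], sort=True).sum(numeric_only=True).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["true_fst"] = (agg["ht"] - agg["hw"]) / agg["ht"]
    return agg[["chrom", "start", "true_fst"]]


def simulate(cfg: SimConfig) -> tuple:
    """Full simulation: returns (sites, SimTruth)."""
    rng = np.random.default_rng(cfg.seed)
    loci = _place_loci(cfg, rng)
    loci["sweep_mode"] = _sweep_mode_per_locus(loci, cfg.sweep_regions)
    freqs = simulate_source_freqs(cfg, rng, loci)
    freqs = simulate_established_freqs(freqs, cfg, rng)
    sites, _ = sample_pool_sync(freqs, cfg, rng)
    regions = pd.DataFrame(
        [
            {"chrom": r.chrom, "start": r.start, "end": r.end, "mode": r.mode}
            for r in cfg.sweep_regions
        ]
    )
    truth = SimTruth(
        loci=freqs[
            ["chrom", "pos", "p_anc", "f_A", "f_B", "f_LB", "f_HV", "sweep_mode"]
        ].copy(),
        regions=regions,
        seed=cfg.seed,
        window_fst_ab=true_window_fst(freqs),
    )
    return sites, truth


def simulate_annotation(
    loci: pd.DataFrame,
    rng: np.random.Generator,
    category_probs: Optional[dict] = None,
    planted: Optional[dict] = None,
    delta_af: Optional[np.ndarray] = None,
) -> list:
    """Assign functional categories to loci, independent of frequency by
    default (null).  ``planted`` optionally enriches one category in a dAF
    range: {'category', 'min_delta_af', 'factor'} multiplies that category's
    probability by ``factor`` for SNPs whose ``delta_af`` is at/above the
    threshold (then renormalizes).  Genic categories receive a synthetic
    gene_id derived from position (50 kb gene grid).
    """
    probs = dict(DEFAULT_CATEGORY_PROBS if category_probs is None else category_probs)
    cats = [c for c in CATEGORY_ORDER if c in probs]
    base_p = np.array([probs[c] for c in cats], dtype=float)
    base_p /= base_p.sum()
    n = len(loci)
    p_matrix = np.tile(base_p, (n, 1))
    if planted is not None:
        if delta_af is None:
            raise ValueError("planted enrichment needs delta_af values")
        ci = cats.index(planted["category"])
        hit = np.asarray(delta_af) >= planted["min_delta_af"]
        p_matrix[hit, ci] *= planted["factor"]
        p_matrix /= p_matrix.sum(axis=1, keepdims=True)
    cum = np.cumsum(p_matrix, axis=1)
    u = rng.uniform(size=n)
    choice = (u[:, None] > cum).sum(axis=1)
    genic = {"non_synonymous", "synonymous", "UTR", "intragenic"}
    records = []
    for i in range(n):
        cat = cats[int(choice[i])]
        chrom = loci["chrom"].iat[i]
        pos = int(loci["pos"].iat[i])
        gene = f"gene_{chrom}_{pos // 50_000}" if cat in genic else None
        records.append(AnnotationRecord(chrom, pos, cat, gene))
    return records


def config_echo(cfg: SimConfig) -> dict:
    """YAML-serializable echo of the resolved configuration."""
    d = asdict(cfg)
    d["sweep_regions"] = [asdict(r) if not isinstance(r, dict) else r for r in cfg.sweep_regions]
    d["ancestral_freq_range"] = list(cfg.ancestral_freq_range)
    d["pool_names"] = list(cfg.pool_names)
    return d
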