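# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducibility.

## Input model and filtering

The atomic record is a genomic position with per-pool base counts in the
fixed order A:T:C:G:N:del. Counts come either from a sync file or from
SAMtools mpileup parsed directly (Phred+33 only — no encoding
autodetection, since all modern Illumina data use it; bases below the
quality floor, default Q20, are excluded). N and deletion counts are stored
but never enter coverage or allele frequencies: all statistics concern
biallelic substitutions.

Three filters produce the analysis-ready SNP table:

* **Indel masking.** Any site within a closed ±5 bp interval of an indel
  is removed; alignment around indels is error-prone. Only positions are
  masked, not whole reads — read-level information is gone by the time
  counts exist.
* **Depth window.** Per pool, countable depth (A+T+C+G) must lie in
  [20, 150]. Below 20× a pool-seq frequency reflects too few individuals;
  far above the mode, coverage in a partially tetraploid genome flags
  collapsed paralogs. Sites above 150× are thinned to exactly 150 reads by
  a multivariate hypergeometric draw on the four base counts — without
  replacement, because reads are physical observations and resampling with
  replacement would inflate variance. The per-pool depth-histogram mode is
  computed and logged for QC, but the subsampling bounds are the fixed
  configured window for all pools. A site failing in any pool is dropped in
  all pools, so every pairwise statistic sees one aligned site set.
* **SNP calling.** Counts are pooled over all populations per base; a base
  qualifies with pooled count ≥ 2 (a config value — the conventional
  pool-seq minimum to exclude singleton sequencing errors); exactly two
  qualifying bases make a biallelic SNP. The major allele is the larger
  pooled count, ties broken in A<C<G<T order so the choice is
  deterministic. The major/minor identity is global (cross-pool), which is
  what makes ΔAF well-defined as a between-pool comparison of the same
  allele.

## Window statistics

Windows are 0-based half-open, fixed width (default 5 kb), non-overlapping.
Trailing partial windows are emitted only when chromosome lengths are
unknown; when lengths are available (always true for simulated data) they
are trimmed, since a fractional window's per-length statistics are not
comparable.

Per site with major/minor read depths (n_MAJ, n_MIN), M = n_MAJ + n_MIN:

* π site value: (M/(M−1))·(1 − f² − (1−f)²), the finite-depth-corrected
  heterozygosity. This closed form differs from the combinatorial
  min-count correction used by some pooled-analysis tools; the difference
  is second-order at ≥ 20× and the closed form is exactly reproducible.
  Window π divides the site sum by covered length; when invariant-site
  coverage is not carried in the input every position is treated as
  covered, which only rescales all windows by a common factor. Windows
  under 50% coverage (when coverage is tracked) are undefined.
* Tajima's D uses the classic 1989 constants with sample size equal to the
  haploid pool size (n = 100 chromosomes for 50 diploids), not a pooled
  re-derivation. Downstream use is sign and ranking only, which this
  preserves; absolute values should not be compared across studies.
* H_P = 2·n_MAJ·n_MIN/M², bounded by 0.5; window value is the mean over
  sites, retained only with ≥ 33 variant sites (the genome-wide average
  sites-per-window in the motivating dataset, and the point below which the
  window mean becomes noisy). A ratio-of-window-sums variant
  (2·Σn_MAJ·Σn_MIN/(Σn_MAJ+Σn_MIN)²) is available behind
  `hp_mode="ratio_of_sums"`; the mean-of-sites form is the default because
  H_P is defined per variant site and windowing is a smoothing step.
  ZH_P standardizes window H_P within each pool with the sample standard
  deviation (ddof = 1); the pool-wide mean is 0 and sd 1 to 1e-9 by
  construction, which is what makes cross-pool contrasts of "below/above
  average heterozygosity" meaningful.

## Divergence

The Nei-style window F_ST uses the uncorrected heterozygosity 1 − Σf²
within and between pools, so identical pools give exactly 0 and fixed
alternate alleles exactly 1 — the depth correction is deliberately reserved
for diversity reporting. The Karlsson-style estimator is a ratio of sums of
per-SNP numerators (a₁/n₁ − a₂/n₂)² − h₁/n₁ − h₂/n₂ over denominators
N + h₁ + h₂ with h = a(n−a)/(n(n−1)); it corrects for read sampling and, on
Balding–Nichols simulations at the default design (50,000 loci, pools of
50, 80×), recovers the simulation parameter F = 0.16 within ±0.01 — the
small residual upward bias (~(1−F)/2N_pool) comes from pool sampling, which
no read-level correction can remove. Negative window values are reported as
computed, never clamped: the selection scans threshold on empirical
percentiles and clamping would distort the distribution's lower tail.

Fisher's exact test treats reads as independent draws from each pool. Reads
from the same individual are not independent, so these p-values are
anticonservative in absolute terms (the standard pool-seq caveat, recorded
in output metadata); the pipeline only uses them against the very stringent
genome-size Bonferroni threshold α/G = 0.05/2×10⁹ = 2.5×10⁻¹¹, and the
per-SNP table computes them only at or above the ΔAF percentile cutoff,
where they are actually consumed.

The Wilcoxon statistic reported by the distribution-comparison utility is
the Mann–Whitney U (identical to R `wilcox.test`'s W).

## Enrichment

ΔAF bins are left-closed/right-open except the last ([0.9, 1.0]), giving a
total non-overlapping partition; ΔAF = 0 SNPs belong to bin 0 since the
grand total is all annotated SNPs. Expected cell counts are the usual
independence product; the df = 1 test is the 2×2 collapse of each cell
against the rest of its row and column, without continuity correction
(recorded in output metadata). M = log2(obs/exp) is 0 exactly at
independence and antisymmetric under swapping observed and expected. Cells
with zero expectation but nonzero observation are flagged rather than
given an M value.

## Selection scans

All percentile cutoffs (95th ΔAF, 95th F_ST, 5th π) are computed from the
data at run time by linear interpolation between order statistics and
logged; printed cutoff values from any particular dataset are realizations
of the rule, not constants. All thresholds are strict inequalities. The
window-divergence scan refuses to run below 20 defined windows, where
empirical 5%/95% percentiles are meaningless. The ZH_P scans use no
p-values at all: the directional rule is ZH_P < −2 in every established
(descendant) pool with ZH_P > 0 in every introduced (source) pool, and the
relaxed rule ZH_P < −4 in every introduced pool with ZH_P > 0 in every
established pool. Requiring the event jointly in two pools is itself the
drift control — drift fixes different regions in different populations.
No upper cutoff beyond > 0 is applied to the high group: the contrast's
purpose is only to certify that variation was present there.

Candidate gene assignment lists a gene when a candidate window contains a
non-synonymous SNP passing the Fisher threshold, using annotation gene ids
and any supplied gene intervals (1-based inclusive). The coverage QC draws
a seeded size-matched random window sample and reports both mean depths,
the fold change M = log2(candidate/random) and a paired t-test; pairing is
positional (i-th candidate vs i-th sampled window), which under the null of
no depth bias is an arbitrary but valid pairing.

## Synthetic data

The generator reproduces the study design, not the study genome:

* Source divergence is Balding–Nichols: ancestral frequency p uniform on
  (0.05, 0.95), each source frequency an independent
  Beta(p(1−F)/F, (1−p)(1−F)/F) draw with F = 0.16.
* Descendants start at α·f_B + (1−α)·f_A (α = 0.75 for LB, 0.30 for HV —
  one descendant biased toward each source) and drift for 5 binomial
  Wright–Fisher generations at Ne = 200, matching the ~5 generations and
  small effective sizes of the motivating system.
* Pooled sequencing draws 2×50 chromosomes binomially, then reads at
  negative-binomial depth (mean 80, dispersion 8, i.e. sd ≈ 30 — chosen so
  the coverage tails that motivate the 20–150× filter actually occur) with
  a 0.002 per-read error relocating the read to a uniform other base.
* Planted `established_sweep` regions model directional selection from
  standing variation: the ancestral frequency is drawn from 0.40–0.60 so
  the variant segregates in both sources, and both descendant frequencies
  are set to 1 − 0.02 after drift. Both pieces are required for the signal
  to be a directional-selection signal at all (low descendant H_P **and**
  retained source variation). `source_divergence` regions instead pin the
  sources at 0.98/0.02 before mixing.
* Defaults: 5 chromosomes × 1 Mb, 50,000 loci (~50 variant sites per 5 kb
  window, comfortably above the 33-site retention threshold and matching
  the motivating data's density).

What it does not emulate: linkage (loci are independent; sweep "regions"
are runs of adjacent loci, so window statistics behave correctly but no LD
structure exists), recombination, paralogy/structural variation, mapping
artefacts, and indels (simulated data exercise the indel masker only
through explicit position sets). Passing tests therefore demonstrate
estimator correctness and scan calibration under the sampling model, not
robustness to alignment pathology or LD-driven false positives.

## Determinism and problem sizes

Every random step flows from numpy `default_rng` seeded from a single
configured seed; the CLI derives per-stage seeds by a fixed affine map so
stages can be rerun in isolation, and identical configs give byte-identical
outputs (output headers carry the tool version, a config hash and the
seed; timestamps appear only in the log).

The validation suite runs the full study-scale design (50,000 loci, four
pools of 50, 80×) for the estimator-recovery, scan-calibration and
enrichment-null checks — 5–20 seeds each — and uses 1,000-site fixtures for
the machine-precision oracle comparisons; these sizes give stable
percentiles and sub-minute runtimes per check on a single core. The Fisher
exactness check enumerates one representative per symmetry orbit of all
2×2 tables with row sums ≤ 30 after verifying the implementation's
invariance under those symmetries.
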