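# Methods

## 5′-end counting

A cleavage event tagged and sequenced from a DNA end places the R1 read's
5′ terminus at the break: the leftmost aligned reference base for a
forward-strand read, the rightmost aligned base (`reference_end − 1`) for
a reverse-strand read. Both strands accumulate into one per-contig array,
since a blunt or near-blunt double-strand break yields ends on both
strands at (nearly) the same coordinate. Retained reads are primary,
mapped, non-duplicate, non-QC-fail R1 records whose alignment consumes at
least 40 reference bases; "aligned length" is measured in reference space
because the 5′-end coordinate is a reference-space quantity (a
query-space mode exists for comparison). No mapping-quality cutoff is
applied by default. All filters live in `FilterConfig`.

## Normalization, smoothing, fold change

Each replicate is scaled to counts per million using its whole-library
retained-read total (not per-contig totals), replicate CPM tracks are
summed per condition, and the aggregate is smoothed with a centered
moving average of width w = 5 bp. Edges are zero-padded with a constant
divisor w, which damps rather than inflates edge values; a shrink-window
alternative would instead up-weight the first two bases of every contig.
Enrichment is `log2((T+pc)/(M+pc))` with pc = 0.1 CPM. The pseudocount
only needs to be small relative to the 1.0 CPM summit floor so that it
cannot manufacture threshold-passing signal at empty positions; its value
is recorded in output metadata and is CLI-overridable.

## Summit calling

Candidate summits are local maxima of the smoothed treated profile
passing three inclusive criteria at the summit position: smoothed treated
signal ≥ 1.0 CPM, log2FC ≥ 2, and pseudocounted treated/mock ratio ≥ 1.2
(the ratio uses smoothed CPM with the same pseudocount as the fold
change, keeping all three criteria on one scale). A local maximum is a
run of equal values that is ≥ both flanking values and > at least one;
the run reports its **center** (left-of-center for even runs). The center
is deliberate: a symmetric moving average of an isolated single-base
spike is an exactly flat w-wide plateau whose center is the spike, so any
other tie-break systematically displaces the summit. Because summing CPM
tracks and convolving leaves ~1e-13 relative jitter on plateaus that are
flat in exact arithmetic, run equality is judged at a relative tolerance
of 1e-9 (absolute 1e-12) — far below any biologically meaningful signal
difference and far above accumulated rounding error.

Replicate consistency is enforced on raw counts: at least 2 treated
replicates must each reach a raw 5′-end count ≥ 5 somewhere in the ±1 bp
window around the candidate summit (window clipped at contig edges,
comparison inclusive). Surviving summits are clustered transitively —
consecutive same-contig summits ≤ 3 bp apart join one cluster — and the
member with the highest smoothed treated signal (leftmost on exact ties)
becomes the final summit. Peaks are emitted as 3-bp half-open intervals
centered on the summit, clipped at contig boundaries; the BED score is
round(100 × log2FC) capped at 1000. A separate strict `log2FC > 2` export
filter reproduces figure-style filtered tables and is intentionally
distinct from the inclusive calling threshold.

## Motif windows and scanning

Windows span summit ± 20 bp (length 41); windows crossing a contig
boundary are skipped and counted. De novo discovery is delegated to
external MEME (ZOOPS, ≤ 5 motifs, widths 5–15, both strands; the exact
command is emitted alongside the FASTA). The built-in scanner matches
IUPAC-degenerate patterns position-by-position: a motif code matches a
base when the base is in the code's set, sequence `N` is matched only by
motif `N`, and minus-strand hits are found by scanning the reverse
complement and reporting plus-strand offsets. Counting "motif-bearing
windows" means ≥ 1 hit on either strand.

## Neighborhood statistics

For each genome the proximal region is the focal gene body ± 1000 bp,
clipped at the genome ends (clipped length is also the density
denominator). A tRNA gene is proximal if it overlaps the region by ≥ 1
bp; with ~76-bp tRNA genes and 1000-bp flanks, the overlap-versus-
containment choice moves densities by at most one gene in rare boundary
cases, and both a flanks-only mode and the overlap rule are exposed as
flags. Proximal density is paired with the genome-wide density
(tRNA count / genome length).

The one-sided paired Wilcoxon signed-rank test drops zero differences,
midranks tied absolute differences, and takes W as the sum of the ranks
of positive differences — the convention under which n all-positive pairs
give the analytic maximum n(n+1)/2 (43956 at n = 296). For n ≤ 25 without
ties the p-value is exact, by dynamic-programming enumeration of all 2^n
sign assignments; otherwise a normal approximation with tie-corrected
variance and a 0.5 continuity correction is used. The exact path is
cross-checked against an independent library implementation in the test
suite.

The bootstrap draws, in each of 10,000 iterations, an independent
with-replacement resample of each group at its own size and records the
difference in medians; the 95% CI is the 2.5th/97.5th percentile of that
distribution (linear-interpolation quantile rule). Resampling the groups
independently ignores the pairing — this is implemented as specified for
the analysis it reproduces, and a paired-bootstrap mode is available for
comparison. Groups are sorted before index resampling so the CI is
invariant to input order at a fixed seed.

## tRF cleavage mapping

Within a tRNA locus the 5′ base of each uniquely aligned read is counted
per position. Uniqueness defaults to "primary alignment of a read with no
secondary records anywhere in the file" (two passes over the file); a
MAPQ ≥ 1 rule is available where aligners encode uniqueness in mapping
quality. The condition ratio adds a 1-count pseudocount to each vector
*before* scaling by its genome-wide retained-read total — added after
per-million scaling the pseudocount would be negligible and empty
background positions would dominate the ratio. The cleavage call is the
set of argmax positions of the ratio track, reported only when the
maximum reaches 2.0 (no threshold is prescribed by the procedure this
reproduces; 2.0 marks a doubling of relative coverage). Swapping
conditions yields the elementwise reciprocal track.

## Synthetic data

`simulate_site_seq` emulates the SITE-seq signal structure: every
replicate receives background reads whose 5′ ends are uniform over the
contig (total ~ Poisson(rate × length), strands random), and treated
replicates add Poisson-distributed forward-strand reads at each planted
site. Planted 5′ ends carry ±1 bp end-repair jitter (P(−1, 0, +1) =
0.15, 0.7, 0.15): end repair and dA-tailing blunt a minority of tagged
ends by one base, and a signal confined to a single base is both
unrealistic and pathological for summit calling — its smoothed profile
is an exactly flat plateau whose argmax is decided by whichever stray
background read lands nearby, displacing summits by up to (w−1)/2.
Defaults follow the study conditions the package is exercised under:
50-kb genome, 12 sites ≥ 500 bp apart, expected excess 20 reads per
treated replicate per site, background 0.02 ends/bp/replicate, 3 + 3
replicates, 100-bp reads. Every record is a primary, mapped, R1-flagged
alignment written as sorted, indexed BAM; extraction on simulated files
reproduces the simulator's internal tally exactly (a writer/reader
round-trip the tests enforce).

`simulate_neighborhood` places tRNA start points by an inhomogeneous
Poisson process: intensity = background rate outside the proximal region
and background × enrichment inside it. Defaults are study-scale: 296
genomes of 30–180 kb, background 1e-4 genes/bp (a handful of tRNAs per
phage-sized genome), 600-bp focal gene, 50-fold proximal enrichment —
strong co-localization, under which essentially every paired difference
is positive and W hits its analytic maximum. `simulate_trf` draws a
shared per-position Poisson background (mean 5) for both conditions and
adds a Poisson spike (mean 200) at the cleavage position (default 48 of
an 85-nt locus) in the defense-present condition only.

What the generators deliberately do not model: sequencing errors and base
qualities, adapter artifacts, GC or mappability bias, overdispersed
(negative-binomial) backgrounds beyond an optional flag, covalent base
modifications, and real tRNA gene structure. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
signal under idealized noise — not robustness to every artifact of real
libraries.

## Problem sizes and numerical choices

Simulated screens use 50-kb single-contig genomes with ~1,000 background
reads per replicate, sizes at which a full six-replicate simulate + call
cycle takes well under a second; oracle comparisons use 100 random
length-1000 profiles and 1000 random 100-mers; bootstrap calibration uses
200 replications of 10,000 iterations at n = 50 per group. Degenerate
inputs fail loudly: empty replicates cannot be CPM-scaled, an all-zero
difference vector refuses the Wilcoxon test, fewer than two usable pairs
refuse the neighborhood summary with a message rather than an exception,
and empty alignment files yield zero tracks with a logged warning.

## Known limitations

- Strand-collapsed counting cannot separate staggered-cut end pairs; a
  staggered simulation mode exists but per-strand calling does not.
- The peak caller is threshold-based, as in the procedure it implements;
  it provides no FDR or significance model.
- The exact Wilcoxon path requires tie-free absolute differences; tied
  data at small n fall back to the normal approximation.
- `primary_no_secondary` uniqueness trusts the aligner to emit secondary
  records for multimappers; aligners configured to suppress them should
  use the MAPQ rule.
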