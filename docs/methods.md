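# Methods

## Coordinate model

The mitochondrial genome is circular; `mitodel` works on a *rotated*
linearization re-origined at the Cas9 cut site. With rotation offset `o`
(default 1547 bp, human) and genome length `L` (default 16,569 bp), rotated
position `r` maps to standard position `r + o` for `r ≤ L − o` and
`r − (L − o)` otherwise; the map is its own inverse's mirror and is tested
exhaustively over all positions. Internally every interval is 0-based
half-open; reported breakpoints are 1-based, with the deletion written as
`[start, end)` — `start` is the first deleted base, `end` the first retained
base after it. In the standard frame a deletion that crosses the
conventional origin is reported with `end_std < start_std`, the usual way
origin-spanning mtDNA deletions appear in databases.

The minor arc defaults to standard 408–5746 and the major arc to its
complement (5747–407, wrapping the origin). Because nCATS molecules are
linearized at the cut site, a deletion never wraps in the rotated frame, and
arc classification is a containment test against the rotated arc intervals;
it is validated against a per-base brute-force classification. Both the
genome length and arc boundaries are configuration, so synthetic test
genomes of any size work.

## Deletion callers

All thresholds live in one `CallerParams` object (defaults: minimum
deletion 100 bp strict, merge window 300 bp, minimum segment 200 bp,
maximum query gap 300 bp, maximum overlap 50 bp strict, realign trigger
500 bp, minimum reference gap 100 bp, minimum alignment score 100).

**Primary CIGAR.** `D` runs longer than the minimum are candidates at their
reference intervals; candidates on one read separated by at most the merge
window are combined into a single event spanning from the first start to
the last end. Merged size is therefore span-based (it includes retained
bases between the runs): the merged call represents one junction-spanning
event, which is what per-read frequency counts measure.

**Chimeric.** Segments of a read (primary + supplementaries) are ordered
along the query in original read orientation — reverse-strand SAM records
are re-oriented using their clip lengths, and hard clips are counted when
reconstructing read length. Each query-adjacent pair must satisfy: both
segments cover > 200 read bases; same strand (opposite-strand splits are
inversions, out of scope); query gap in (−50, 300] bp (small overlaps
tolerated, contiguity bounded); reference overlap < 50 bp; reference gap
> 100 bp ("distant on the reference" — tied to the deletion size floor so
chimeric calls obey the same minimum as CIGAR calls). The call is the
reference interval between the reference-ordered segments. Reads with
several supplementaries are chained pairwise, one call per compatible
junction, which reduces to the single-pair rule for the common
primary+supplementary case. The implementation is checked against an
independent brute-force enumeration of the pair predicate on thousands of
randomized bundles.

**Realignment.** Reads whose length and primary aligned span disagree by
more than 500 bp are locally realigned to the rotated reference with an
affine-gap local aligner (match 2, mismatch −3, gap open −5, extend −2;
both orientations tried, best score kept; hits under score 100 discarded).
Two candidate sources are combined: (i) reference gaps bridged *inside* the
best local alignment — an affine aligner bridges a deletion whose gap cost
is below the flanking match score, so mid-sized deletions appear as one
gapped alignment; (ii) a second pass aligning the unaligned query
prefix/suffix, paired with the first hit under the same rules as the
chimeric caller — large deletions, whose gap cost exceeds any bridge. Both
routes feed the same merge step. The aligner is Biopython's
`PairwiseAligner` in local mode; alignment identity is not load-bearing for
breakpoints at the ±300 bp matching tolerance used throughout.

**Combination.** Per read, calls from different callers whose start and end
breakpoints are each within the merge window are collapsed to the widest
extent; the chimeric source is recorded on cross-caller merges since it is
the sensitivity-limiting route for large events. Calls on different reads
never merge — events are single-molecule observations.

**Read filters.** Reads must be strictly > 400 bp (mapping specificity
floor) and < 17,000 bp (longer-than-genome reads suggest nuclear
contamination), and pass mean base quality ≥ 5 when qualities are present.
The filters gate all callers uniformly so every frequency shares one
denominator; they can be disabled.

## Simulator

`simulate` emulates the geometry of Cas9-enriched nanopore reads: each read
starts at the cut site (template position 1 plus ≤ 10 bp jitter), strand is
Bernoulli with 85% forward (adapter ligation favors the strand downstream
of the PAM), lengths are lognormal with median ~8 kbp and σ = 0.4 (most
molecules extend well past mid-genome), and errors are iid per base —
mismatch 5%, insertion 1.5%, deletion 1.5%, ~8% aggregate, the error scale
of the nanopore chemistry this workflow targets. Templates carry one
deletion each, by default starting at rotated bp 4000 with sizes 1–10 kbp in
1 kbp steps, 500 reads per template. Ground truth records whether each
read's span covers the deletion junction; sensitivity denominators count
spanning reads only.

What the simulator does **not** model: homopolymer-conditioned or
signal-level error structure, quality-score variation (a constant Phred is
written), chimeric library artifacts, NUMT-derived reads, and heteroplasmy
mixtures within one template. Passing benchmarks therefore demonstrate
correctness of the calling geometry and thresholds under realistic error
*rates*, not robustness to every nanopore artifact; real-data performance
additionally depends on basecaller and chemistry.

The SAM fixture writer serializes truth reads directly as alignments (one
`D`-run primary, or a soft/hard-clipped primary+supplementary pair split at
the junction), so the callers' geometry is testable without any aligner.

The cohort generator produces per-donor deletion tables whose frequency
above a signal size (2 kbp) follows `log10 f = −5.25 + 0.0354·age` with
0.12 dex donor scatter — the frequency scale and slope of an aging muscle
cohort (~4×10⁻⁵ at age 25 rising ~60-fold by 75) — over 15 donors aged
26–81 with 150,000 mtDNA reads each. Signal deletions sit in the major arc
with sizes uniform in (2000, 2400] bp; an age-independent background
(10⁻³·3 per read) of 0.6–2 kbp deletions sits in the minor arc; 6.5% of
signal events span the arc boundary. Bounding the signal sizes makes the
generating threshold identifiable by construction: sweeping below 2 kbp
picks up the uncorrelated background, sweeping above it loses the signal
entirely. This mirrors the qualitative structure of aged-tissue cohorts
(age-responsive large major-arc deletions over an age-flat small-deletion
background) rather than any particular dataset.

## Statistics

*Frequency* is `#{size > s} / n_mt_reads`; it is non-increasing in `s` by
construction. *Regressions* are ordinary least squares of log10 frequency on
the covariate (age, or log10 ddPCR frequency); donors with zero qualifying
events are excluded from that threshold — no pseudocounts — matching the
observation that large-threshold correlations degrade for lack of events.
At least three usable donors are required; sweeps report thresholds that
fail this as missing, and `best_threshold` is the smallest argmax of R².

*Welch's t* compares group frequencies on the log10 scale by default
(frequencies are right-skewed across donors); zero-variance degenerate
groups return t = 0, p = 1 when equal.

*Density comparison* estimates each group's breakpoint density with a
Gaussian kernel of fixed bandwidth h = 50 bp on a 512-point grid over
[1, L] (linear, no circular wrap-around) and uses
`T = Σ (f̂_a − f̂_b)² Δx` with a label-permutation null preserving group
sizes: `p = (1 + #{T* ≥ T}) / (1 + n_perm)`, default 1,000 permutations.
Permuted assignments always fill the smaller group from a canonically
ordered pooled sample, so swapping the group labels leaves both T and p
exactly unchanged; identical inputs give T = 0 and p = 1 exactly. By
default both endpoints of every call are pooled as "breakpoints"
(configurable to starts or ends only). Type-I calibration is verified by
simulation (null rejection rate at α = 0.05 over 500 replicates with 199
permutations each).

## Benchmark alignment regime

The sensitivity benchmark aligns simulated reads with minimap2 (`map-ont`)
with long-gap rechaining capped at 3 kbp (`-r 500,3000`). Recent minimap2
versions will chain deletions of nearly any size into the primary CIGAR,
which hides the split-alignment representation the chimeric caller exists
for; capping the rechaining reproduces the regime in which large deletions
appear as primary+supplementary pairs, while leaving the combined caller's
results essentially unchanged (it recovers the event through whichever
representation the aligner picks). The cap is exposed as `--max-join` on
`mitodel align` and is a property of the benchmark, not of the callers.

## Problem sizes and numerical notes

The default test and acceptance runs use 10 templates × 50 reads for the
alignment benchmark, 2,500 randomized bundles for the oracle comparison,
exhaustive 16,569-position coordinate checks, 500 calibration replicates,
and 100-replicate parameter-recovery loops — all sized to run on one CPU in
well under the time a coffee takes. Realignment tests use a 6 kbp synthetic
genome because local alignment is O(read × genome); behavior is identical
at full scale, only slower. Ties in the threshold sweep resolve to the
smallest threshold; interval merging is single-linkage on sorted
candidates; RNG use is `numpy.random.default_rng` seeded everywhere, and
byte-level determinism of simulator output under a fixed seed is asserted.

## Limitations

- Inversions, duplications, insertions and SNV heteroplasmy are out of
  scope; opposite-strand chimeric pairs are deliberately dropped.
- Arc classification of a deletion uses containment of its breakpoint
  interval; events of one or two bases at an arc boundary are classified by
  their inclusive interval.
- The permutation p-value floor is `1/(n_perm + 1)`; raise `n_permutations`
  for smaller floors.
- Realignment is the slowest path (seconds per read at full genome scale)
  and is opt-in via `--fastq`; the primary+chimeric combination covers the
  size spectrum in the benchmark without it.
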