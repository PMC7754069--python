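# Methods

`dmrecon` reconstructs co-existing circular double-minute (DM / ecDNA)
species from copy-number, junction-read, FISH and SNP evidence, and ships a
synthetic-data generator that emits every one of those observables from a
known ground truth.  This note records the model, the parameters that
matter, the numerical choices, and what the synthetic data does and does
not establish about real data.

## Coordinates and conventions

All coordinates are 0-based, half-open.  A segment's *head* is its
lower-coordinate end (drawn '+'), its *tail* the higher end ('−').  A
junction record stores its two sides in canonical order — sorted by
(digit-aware contig key, position, sign) — so a read and its reverse
complement produce the identical record; orientation classes −/+
(tail-to-head), +/− (head-to-tail), +/+ and −/− are read off the canonical
record.  Contig names sort digit-aware, so an "8" contig precedes a "10"
contig as in genomic convention.

## Synthetic data: the study conditions

The generator's defaults encode the conditions the reconstruction is
designed for, at ~1/1000 genomic scale so everything runs in well under a
second:

| parameter | default | meaning |
|---|---|---|
| contigs | 12 kb + 6 kb | toy stand-ins for the two source chromosomes |
| sub-amplicons | 11 in regions of 2+4+3+2 | H1a…H4b layout, 500–600 bp each |
| populations | 2 circles | 9-segment (5000 bp, 3 junctions) and 6-segment (3500 bp, 6 junctions), sharing one junction |
| mean DM counts | 101, 107 per cell | Poisson-distributed per cell |
| probe spacing | 10 bp | on a half-spacing offset grid |
| log2 noise | sd 0.1 | i.i.d. Gaussian per probe |
| FISH probes | 6 | one BAC analogue per selected sub-amplicon |
| cells | 40 | per FISH experiment |
| SNP sites | 34 | 10 chromosomal vs 1500 DM copies, depth 1000 |
| reads | 3 per junction | flanks 150 bp, alternate reads reverse-complemented |

The eight junctions carry engineered forensic signatures: four simple MMEJ
joins (microhomology 2–5 bp), one blunt join, one four-breakpoint composite
(three 1–2 bp untemplated interior fragments, classified MMEJ via its 2 bp
flank microhomology), and two replication-type (FoSTeS/MMBIR) junctions
with templated insertions of 5–679 bp — one of them with 21 fragments of
which 18 locatable ones derive from non-amplified sequence, two from
amplified regions (one 110 bp from the junction), and one 5 bp fragment
that is inherently unplaceable at this genome size.  Orientation classes
across the eight junctions count 3/1/2/2.

**Copy model.**  Expected total copies at a position are
`2 + Σₚ abundanceₚ × multiplicityₚ`; the diploid chromosomal background
contributes the 2.  Probe log2 ratio is `log2(copies/2)` plus noise.

**Microhomology planting.**  Bases are i.i.d. uniform (repeat-free at this
scale, so exact substring search is a sound aligner; a 20 bp anchor has a
~10⁻⁸ chance collision in an 18 kb genome).  For each junction the
configured homology is written into the reference: the h bases immediately
before the canonically-second breakpoint (outside that segment) are set
equal to the first segment's terminal h bases, and one disagreeing base is
forced beyond the window on both sides, so measured homology equals the
configured value exactly — including 0 for the blunt junction, which would
otherwise pick up ~0.44 expected spurious agreement.  Junctions that share
reference bases near a common boundary are planted iteratively to a
verified fixpoint.  Untemplated insertion bases (and resampled templated
origins) are chosen so that no maximal-match block can slide across an
element boundary; without this, recovered insertion lengths would be
ill-defined by ±1 bp.

**Probe grid.**  Probes sit at spacing/2 + k·spacing.  Amplicon boundaries
fall on multiples of 100, hence midway between two probes, so the
segmentation's midpoint boundary convention recovers true change positions
*exactly* at zero noise — a deliberate alignment of grid and convention,
not a coincidence of rounding.

## Segmentation

Two passes: (1) candidate change points where the absolute difference of
leading/trailing rolling medians (window = `min_probes`, default 5) exceeds
`level_tol` (default 0.3 log2 units), taking the centre of each candidate
plateau; (2) runs shorter than `min_probes` merge into the closer
neighbour, then adjacent segments within `level_tol` merge.  A final local
refinement reassigns probes around each boundary to the nearer segment
median (minimising summed absolute deviation), which at noise sd 0.1 and a
1.0 log2 tier gap recovers boundaries to the probe (misassignment requires
a >5σ noise excursion).  Boundaries are placed midway between flanking
probes; probe spacing bounds resolution.

Tier quantization anchors tier 1 at the lowest amplified segment level;
tier k sits k−1 log2 units higher (tier 2 = twice tier 1's copies).  A
level exactly midway between tiers goes to the *lower* tier; levels above
`max_tier` are flagged, never dropped.  Baseline is the median log2 of
probes outside configured exclusion regions (global median by default —
valid because amplified probes are a minority).  DM-borne copies are
`2·2^log2 − 2`.

Breakpoints are the deduplicated boundaries of all tier ≥ 1 segments, named
J1… in genomic order.  Adjacent same-tier sub-amplicons are invisible to
copy number; their shared boundary is recovered by splitting segments at
junction breakpoint coordinates (the chr10 pair in the default layout),
which is why the J-count rises from 14 to 15 after junction calling.

## Junction calling

Split alignment seeds maximal exact matches ≥ `min_anchor` (20 bp) on both
strands, walking left-to-right across the read; every block is then
extended leftwards to its maximal extent so microhomologous overlaps
between flanks survive.  The first and last blocks are the flanks;
interior aligned blocks and unaligned gaps become ordered insertion
candidates.  Records are canonicalized (reverse-complement invariant) and
the join is placed at the maximal extension of the canonically-first
flank, which by the planting convention lands exactly on segment
boundaries.

Microhomology is measured on the *reference* flanks: the count of
positions the join point can slide in either direction, i.e. valid
placements − 1, capped at `max_scan` (50) with a degenerate flag.  An
exhaustive join-point-slide oracle cross-checks the routine on 1,000
random planted junctions in the test suite.

Insertion origins: unique alignment (from the split aligner), else a
near-exact scan allowing 1 mismatch per 50 bp; zero hits or ties ⇒
*uncertain* (deliberately conservative — results are reported "without
considering uncertain" fragments).  Fragments shorter than 5 bp are always
uncertain: a 5-mer occurs ~17 times by chance in an 18 kb genome, and
correspondingly the real ambiguity this models.  Mechanism: templated
insertion ≥ 5 bp (the smallest reported templated fragment) ⇒
FoSTeS/MMBIR; else microhomology ≥ 1 bp ⇒ MMEJ; else blunt NHEJ.  The MMEJ
cut-off of 1 bp is configurable; no consensus threshold exists.

A junction's *breakpoint count* is 1 + its number of interior fragments.
The four-breakpoint composite junction is modelled with three sub-anchor
untemplated fragments; called from reads these merge into a single 4 bp
insertion (sub-anchor fragments are unresolvable by exact matching), so
the composite's 4-join count is a property of the structure records, not
of re-called reads — a known, documented limit of the toy aligner.

## Assembly

The breakpoint graph has segment-body edges with multiplicity 2^(tier−1),
junction edges, and reference-adjacency edges between abutting amplified
segments.  Junction multiplicity is inferred by node balance: a junction is
promoted to the full segment multiplicity at any endpoint with no other
incident connector — the copy-doubling signature of a junction shared by
two populations.  (A FISH-only flag would over-promote junctions whose
endpoints merely lie on shared segments.)  Adjacency edges absorb the
residual at each node; inconsistent or overloaded nodes are errors.

Decomposition enumerates all edge-consuming alternating cycle sets
(exhaustive, fine at ≤ a dozen segments), filters by FISH constraints
(co-observed segments share a cycle, never co-observed do not), and prefers:
minimal non-negative copy-fit residual, then fewest cycles, then
lexicographic canonical form.  The copy-fit term is load-bearing: with six
probes, the unprobed sub-amplicon can drift between cycles in a way FISH
cannot see, and only the ~6-copy difference between the two population
abundances pins it.  An independent oracle (cycle catalogue + exact cover)
confirms the decomposition on 20 random ≤ 8-segment instances.

Abundances solve `copies(s) ≈ Σₚ aₚ·mₚ(s)` by NNLS; structures identical in
segment content are rejected as unidentifiable.  The shared-to-specific
copy ratio is mean shared copies over the mean of population-specific
copies — exactly 2.0 at the configured counts (208/104).

FISH partition groups DMs by identical probe pattern; all-negative DMs are
reported unassigned; subset-merging of dropout patterns exists but is off
by default (the simulator has no dropout).  "Diploid"-like double-signal
DMs are treated as a whole-cycle doubling, not a distinct topology, and
are not simulated.

## Evolution inference

*Breakpoint clustering*: maximal runs of ≥ `min_bp` (default 5, the lower
bound of the usual 5–10 criterion) breakpoints spanning ≤ 50 kb, by
two-pointer sweep (oracle: all-pairs scan).  On the 1000×-scaled toy
genome the criterion is trivially met; the operation is exercised at
realistic scales in its tests.

*Join randomness*: exact multinomial goodness-of-fit of the four
orientation-class counts against uniform, p = total probability of
outcomes no more probable than the observed one.  Chi-square is invalid at
n = 8; the exact test is conservative (rejection rate ≤ nominal under the
null, verified by simulation).  The observed 3/1/2/2 split gives p ≈ 0.96.
This test is the package's formalization of a criterion usually stated
without a statistic; no printed p-value is being reproduced.

*SNP zygosity*: a site is called homozygous-on-DMs when its minor-allele
fraction is below `minor_fraction_threshold` (default 0.05); the one-sided
Clopper–Pearson 95% upper bound is reported as a per-site confidence flag
rather than gating the call, so the analytic power bound holds: at the
10:1500 mixture (minor fraction 0.0066) and depth ≥ 200, all sites are
called with probability > 0.999.

*Stepwise verdict*: three evidence items — (a) one circle's genomic
footprint on shared contigs nests strictly inside the other's, (b) ≥ 1
junction shared by both circles, (c) DM-borne SNPs homozygous in both
populations.  `stepwise` needs ≥ 2 items (configurable); all items false
with no shared junction gives `independent`; anything else (including
missing zygosity data) is `inconclusive`.

## What the synthetic data does not show

The generator omits read errors and quality scores, real repeat structure,
capture efficiency, FISH probe dropout and imaging noise, and GC/replication
waves in the copy-number track.  Passing the round-trip therefore
demonstrates the *logic* of the reconstruction — segmentation, forensics,
graph decomposition and inference compose correctly and deterministically —
not robustness to alignment ambiguity or platform noise in real libraries.
The split aligner is exact-match and valid only on repeat-free sequence;
real data would need a probabilistic aligner in its place.

## Determinism

One root seed drives fixed-order child seeds for the genome, copy-number,
read, FISH and SNP simulators; re-running any stage with the same
configuration is byte-identical, and the pipeline summary is reproducible
end to end.
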