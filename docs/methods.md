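# Methods

This note documents the models, conventions and numerical choices behind
kappascan, and what its synthetic benchmarks do and do not establish.

## Coordinate and strand conventions

All coordinates are 0-based, half-open; BED is the native annotation dialect
and GFF3 is converted on read. The reference plus strand is fixed so Jκ coding
segments read left to right. Junction positions are *boundaries* (between-base
coordinates at the junction-proximal prey edge). With a Jκ coding-end bait on
the unrearranged reference, junctions to deletional-orientation partners map
to the minus strand and inversional-orientation partners to the plus strand;
this convention is derived mechanically from read orientation (the bait reads
leftward into the junction) and is what makes strand a mechanism readout.

RSS orientation is stored as the direction the heptamer points
(`down`/`up` the coordinate axis); the RAG cleavage point is the
heptamer–coding boundary. A rearrangement keeps the coding side: deletional
joins excise the inter-heptamer interval (the signal side, Cer/Sis included
when within it), inversional joins reverse-complement it in place, which
relocates the joined segments' RSSs into the hybrid joint — the allele map
therefore drops an RSS whose adjacency to its coding segment is broken, and
the joined V and J become landmarks on the allele.

The allele↔reference transform is a list of signed blocks
`(allele_start, allele_end, ref_start, ref_end, ±1)` tiling the allele.
Sign −1 blocks reflect positions within the block and flip strand. Base and
boundary coordinates have separate mapping rules (a shared block edge is a
valid boundary of both neighbours). The transform exports as a chain-like TSV
and can materialize the allele sequence, which the tests hold to exact
equality with direct string surgery.

## RSS information-content model

`rss_scoring` trains a positional log-odds model (bits, log2 against the
background composition; pseudocount 1, uniform background by default; optional
first-order dependencies) from aligned, heptamer-first RSS sequences. Scores
are additive (order 0) and deterministic. The model's job in this package is
to *rank* sites — strong vs weak classification against a configurable
threshold and weighting of simulated capture — not to reproduce any published
score table; published recombination-information-content scores play the same
role and a user can swap in their own training set or threshold via the TSV /
JSON interfaces. Cryptic-site scanning applies a hard `CAC` heptamer-prefix
filter on both strands before thresholding, the usual convention for
biologically meaningful cryptic sites.

## Junction calling and fine structure

The toy caller assumes reads begin with the bait (longest common prefix
defines the realized bait deletion) and anchors the prey with an exact 20-mer
seed taken from the 3' end, stepping one window inward (up to three windows)
when a sequencing mismatch breaks the first; a seed hitting more than one
locus position yields an `ambiguous` record, no hit `unmapped`, and both are
excluded downstream. From the anchor, a gapless extension (+1 match, −1
mismatch) walks toward the bait; the prey start is the *leftmost* maximum of
the cumulative score, so isolated interior mismatches are crossed while
junction-adjacent mismatching bases fall to the insertion. Ties and
microhomology resolve bait-first (left assignment), and the microhomology
length is recorded. This rule set is the package's canonical junction
convention: the read simulator re-expresses its planted truth through the same
rule (a mismatch planted on the junction-proximal prey base is *definitionally*
indistinguishable from an inserted base), so "truth" under noise means the
canonical representation of the realized read. At zero noise the convention is
vacuous and calls must match the planted truth exactly, which the tests
enforce.

P-nucleotides are detected as the maximal k ≤ 4 such that the insertion
prefix (suffix) equals the reverse complement of the terminal k bases of the
untrimmed bait (prey) coding end — trimmed ends carry none, and overlapping
claims resolve bait-first. Effective insertion = insertion length minus both
P lengths. Near-junction mismatches are counted in a 20-bp window anchored at
the junction-proximal prey end; in-window indels are out of scope for the
counter (deletions are carried by the deletion fields). Prey deletions are
measured from the annotated RSS boundary (bona fide) or recorded cryptic-site
boundary; a negative value marks the rare junction placed past the boundary by
the left-assignment rule and is never clamped silently.

## The filtering pipeline

`run_cryptic_pipeline` applies, in fixed order: bona fide removal (prey within
10 bp — tolerant of the ≤ 7 bp allowed prey trimming — of a catalog boundary on
the matching strand; the catalog covers both coding and signal ends of every
annotated RSS plus a user-supplied blacklist of unannotated bona fide sites),
the indel filter (keep bait deletion ≤ 5, prey deletion ≤ 7, effective
insertion ≤ 2), and the mutation filter (keep ≤ 2 mismatches in the 20-bp
window). Boundary values are kept: the thresholds express "greater than" as
removal. The audit log conserves counts exactly, each filter is idempotent,
and because bona fide removal is purely positional the indel filter commutes
with it. `empirical_indel_profile` recomputes the indel/insertion
distributions of bona fide non-productive joins so the thresholds can be
re-derived from data: under the default noise model ~1–2% of joins exceed the
insertion bound and essentially none exceed the deletion bounds, which is the
empirical shape the defaults encode. The filters presuppose TdT-free mouse
pre-B junctions (no N-regions); the pipeline refuses `species="human"`.

## Repertoire statistics

Libraries are weight-normalized to a 500,000-read total (exact by
construction, proportion-preserving to 1e-12, applied at most once). Vκ usage
percentages are computed per replicate over bona-fide-coding junctions only
and summarized as mean ± s.e.m. (sample s.d. over replicates, n−1).
Off-target profiles are strand-split, half-open binned percentages of the
cryptic total (default 10-kb bins at real-locus scale; the analysis scripts
use 2-kb bins on the mini locus), exported as bedGraph. Region × orientation
summaries derive orientation from prey strand under the fixed convention.
`convergent_fraction` unprojects reference-frame junctions into allele
coordinates through the rearrangement transform (convergent = allele minus
strand for a Jκ bait); junctions falling in reference intervals deleted from
the allele are excluded and counted. Productivity of a V→J coding join
requires frame preservation — `(v.frame + len(V retained) + insertion) mod 3`
equal to the trimmed J's codon offset — and no stop codon among the
junction-spanning codons; segments without frame annotation return `n/a`.
Welch's t-test is implemented directly (Satterthwaite df, two-sided p via the
t distribution) and is held to 1e-9 agreement with an independent reference
implementation in the tests; identical samples return t = 0, p = 1 by
convention. No multiple-testing correction is applied by default (single
pre-specified comparisons); Benjamini–Hochberg is available for exploratory
batches.

## The synthetic generator: what it emulates

`make_mini_locus` builds a ~46-kb single-contig miniature of the locus
architecture: 4 distal deletional Vκs, 4 middle inversional Vκs, 4 proximal
Vκs of mixed orientation (most-proximal deletional), Cer and Sis, a
Sis-to-Jκ1 scanning leg carrying convergent-only cryptic sites, Jκ1/2/4/5
(plus a non-functional Jκ3 landmark), iEκ and the 3′ RS. Bona fide 12RSSs
share the consensus heptamer and carry 0–11 deterministic spacer/nonamer
mismatches so the trained model spreads their scores; strong/weak labels
follow the packaged (median) threshold by construction. One cryptic site is
planted mid-gap after each Vκ, alternating strands, so each Vκ region is
strand-balanced. Coding sequences are stop-free in frame 0 with codon-multiple
lengths. Everything is deterministic given (config, seed).

Two mechanisms are simulated:

* **Primary diffusion** (Jκ1 bait, unrearranged locus): bona fide capture
  probability proportional to an RSS-score weight
  `2^((score − max)/4 bits)`, independent of orientation and distance —
  the diffusion platform presents Vκs locus-wide. Cryptic junctions (rate 0.1
  of the library) split evenly between the convergent-only scanning leg,
  strictly confined between Cer/Sis and Jκ (the simulator idealizes
  "scanning terminates at Sis" to strictly), and orientation-symmetric
  diffusional capture of Vκ-region cryptic sites. The symmetric class is what
  makes the diffusion convergent fraction ≈ 0.5 outside the RC window, the
  observable that separates the mechanisms.
* **Secondary linear scanning** (Jκ2 bait, after a primary rearrangement):
  a sequential first-capture competing-hazards walk upstream from the RC in
  allele coordinates — capture probability at site *i* is
  `exp(−d_i/decay) · Π_{j<i}(1 − q_j) · q_i` with `q = 1 − exp(−hazard)`,
  hazard = 0.3 × weight for bona fide sites (× a 3× transcription-impediment
  bonus for transcribed Vκs, × a 0.2 penalty for inversional-orientation
  Vκs) and 0.02 for cryptic sites, decay 30 kb at mini-locus scale. Cryptic
  capture is convergent-only in the allele frame. This reproduces saturation
  on immediately upstream Vκs and the strand-projection signature without any
  polymer physics. Sampling uses the exact first-hit distribution conditioned
  on capture, so identical seeds give identical libraries.

All simulator rates (capture hazards, decay, penalties, cryptic rate, noise
means) are stand-ins chosen once at mini-locus scale to make the mechanism
signatures measurable; they are not estimates of the biology, and nothing
downstream depends on their particular values beyond sign and rough order.

Read emission composes bait (geometric end deletion, mean 1 bp), insertion
(P-nucleotides with probability 0.3 at untrimmed ends, max 2 bp per side;
geometric untemplated insertion, mean 0.3 — mouse pre-B cells lack TdT, so
untemplated bases are rare) and 60 bp of prey with per-base mismatch rate
0.005, then canonicalizes the realized truth as described above.

## What passing tests show — and don't

The benchmarks establish internal correctness: exact coordinate algebra,
oracle-equivalent filters and P-detection, exact zero-noise recovery, ≥ 99.9%
noisy junction-call agreement with canonical truth, Spearman ρ ≥ 0.9 between
end-to-end estimated Vκ usage and true capture weights at 50,000 junctions,
and clean separation of the two mechanisms' orientation signatures at a few
thousand junctions. They do not validate the upstream alignment pipeline of
real HTGTS data (adapter trimming, barcode demultiplexing, genome-scale
multi-mapping), chromatin-level realism (the simulator has no contact maps,
accessibility or transcription dynamics beyond a scalar bonus), or the
biological rates themselves. Real-locus analyses should supply their own
annotation, blacklist and thresholds through the documented interfaces.

## Problem sizes

The packaged analyses run at mini-locus scale: 10,000–50,000 junctions per
library, three replicates where replicate statistics are reported; the full
test suite and the acceptance script each complete in well under a minute on
one CPU.
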