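# Methods

`pirnakit` implements the computational route from raw small-RNA reads to
(1) ovarian somatic piRNA cluster calls and (2) a classification of the
dominant piRNA biogenesis mechanism at those clusters, together with a
generative simulator that produces libraries with known ground truth so
every stage can be validated offline. This note records the models, the
parameters that matter, the numerical conventions, and what the synthetic
data do and do not establish about real libraries.

## Coordinate and weighting conventions

All intervals are 0-based, half-open. For a read aligned to `[start, end)`
on the plus strand, the 5' end is `start` and the 3' end is `end - 1`; on
the minus strand the 5' end is `end - 1` and the 3' end is `start`. Reads
are collapsed to sequence species with counts before mapping, and all
downstream abundances are count-weighted. A read with `n` reported
placements contributes weight `1/n` at each placement, so its total weight
is always 1 ("evenly distribute multimappers"). Operationally, a *piRNA* is
any processed read of at least 23 nt; the processing window keeps reads of
18–40 nt.

## Read processing and the internal mapper

Trimming locates the leftmost occurrence of the 3' adapter (a prefix of at
least 10 nt is accepted at the very end of the read), removes it and
everything after it, then strips the 4-nt randomised UMIs from both ends of
the remainder. Reads without an adapter, or too short to contain both
UMIs, are discarded. Contaminant filtering removes any read placeable on
either strand of a contaminant reference (rRNA/tRNA/snRNA-type sequences)
with at most one mismatch.

The mapper is exact over the full read, with *all-best-stratum* semantics:
all placements at the minimal achievable mismatch count are reported, and
nothing from worse strata. Exact placements are found by hashing 14-nt
read prefixes against a genome index and verifying the full match; the
k-mismatch stratum (k ≤ 3) is reached by pigeonhole anchoring — a placement
with at most k mismatches must contain an exact (k+1)-th part of the read —
followed by full Hamming verification. `N` never matches any base, so a
read with more Ns than the mismatch budget is unmapped. Because the search
is exact over the full read, on repetitive genomes it can report strictly
more multi-placements than seed-based aligners whose seed length truncates
18–40-nt reads; this only redistributes 1/n weights, never drops reads.
A SAM import adapter accepts pre-computed alignments for users with real
data; multiplicity (and hence 1/n weights) is re-derived per read name.

## Mappability, tiles and cluster calling

A genome position is *unique* iff its 25-mer, counted together with its
reverse complement, occurs exactly once across both strands of the whole
genome. Tiles are 500 nt on a fixed grid starting at position 0 of each
contig; a tile is kept iff at least 85% of its positions are unique
(inclusive threshold; trailing partial tiles are discarded; positions past
the last full k-mer of a contig count as non-unique).

Genome-unique piRNA reads are assigned to the tile containing their 5' end
(the paper's assignment rule for boundary-straddling reads is not stated;
the 5' end is unambiguous) and normalised to counts per million
genome-unique piRNA mappers of the library (cpm). Ovary/embryo enrichment
uses a single-read pseudocount: `fold = (ov + eps) / (em + eps)` with
`eps` the cpm one read contributes in the smaller library — a floor is
required for tiles empty in the embryo, which are exactly the interesting
ones. Tiles with fold ≥ 10 and ovary cpm ≥ 5 are merged into cluster calls
when separated by at most 2 failing grid tiles, and runs of fewer than 2
passing tiles are dropped. These merge parameters are defaults exposed in
the config: the original cluster coordinates were curated manually from
scatter plots, so no parameter setting is claimed to reproduce published
coordinates exactly.

## Biogenesis signatures

**z-scores.** Every linkage statistic reports the deviation of the focal
frequency from the mean of its window in units of the window's population
standard deviation, with the focal value included in both mean and sd, and
z = 0 when the window is flat. This convention is applied uniformly because
the published definition does not state whether the focal value is held
out; including it is the conservative choice (it can only shrink |z|).

**Phasing.** For every 3'-end position `t` with abundance `a(t)` and every
signed offset `d` in the 20-nt window `[-9, +10]`, the profile accumulates
`a(t) * b(t+d)` where `b` is the 5'-end abundance map of the same strand
(coordinates run in transcript orientation on the minus strand). `d = +1`
means a 5' end on the very next base after a 3' end. The window is placed
as `[-9, +10]` rather than `[-10, +9]` so the focal +1 bin is interior;
the choice is configurable and does not move the +1 bin. Phasing uses
weighted all-mappers. The companion nucleotide signature is the uridine
frequency at the position immediately 3' of piRNA 3' ends, profiled over an
11-nt window.

**Ping-pong.** With `a+` and `a-` the 5'-end abundance maps of plus- and
minus-strand reads, the overlap score is
`score(s) = sum_i a+(i) * a-(i + s - 1)` for `s` in 1..20, so `s = 10` is
the canonical ping-pong overlap. The published description weighs
"co-occurrence" by abundance without giving a formula; the product is the
default (symmetric, additive over positions) and a `min`-based variant is
available behind a flag for sensitivity checks. Per-tile profiles are
computed for 0.5-kb tiles whose plus- and minus-strand coverage exceed
1000 and 10 cpm of genome-mapped reads respectively, using cluster-unique
mappers. The companion nucleotide signatures are uridine at position 1 of
one strand and adenosine at position 10 of the other.

**In-trans ping-pong.** Genome-mapping piRNA reads are reduced to three
9-mer tables: positions g1–g9, the last 9 nt, and the reverse complement of
g2–g10. Each table is normalised (per-million then rescaled) to sum to
exactly 1000. The linkage is the dot product of the g1g9 and g2g10revComp
tables; last9 x g2g10revComp — two views with no mechanistic relationship —
is the genomic background. The ratio is linkage/background, infinite when
the background is empty but linkage is not, and NaN when both are zero.
Tiles dominated by canonical ping-pong pairs inflate the statistic and can
be blacklisted through an explicit exclusion-interval parameter (mirroring
the manual exclusion applied to a tile on Ae. aegypti chromosome
NC_035109.1 where an abundant canonical pair resides).

## The simulator

The simulator's defaults are the study conditions; they are not free
parameters of the tests.

* Genome: one 60-kb uniform-random contig; a 5-kb uni-stranded somatic
  cluster at 10–15 kb carrying antisense transposon fragments; a 5-kb
  germline cluster near the 3' end of the contig shared by both libraries;
  toy rRNA/tRNA/snRNA contaminant references drawn under the same seed.
* Read lengths: discrete truncated normal on [23, 35] nt, sd 1.5; strand
  means 27.4 nt (plus) and 25.3 nt (minus). The location parameter is
  calibrated so the *realized* (discretised, truncated) mean equals the
  configured value — "mean length" is treated as the observable.
* Phasing mode (`u_bias` 0.85, `phase_prob` 0.7): processing runs walk the
  cluster transcript head-to-tail. The 3' end of each read is drawn among
  window positions followed by uridine with probability `u_bias`; when no
  such position exists within the 23–35-nt window (about 2.4% of reads on
  a uniform genome) the choice is unbiased and the read is flagged
  `u_fallback` in the truth table, so parameter-recovery checks can
  condition on unflagged reads. With probability `phase_prob` the next 5'
  end is the base after the previous 3' end; at a break the run either
  re-initiates within a 50-nt downstream gap window or (with probability
  `walk_restart_prob` = 0.3) detaches and re-enters the cluster uniformly.
  Without the detachment branch every run walks to the cluster's 3' end and
  5' coverage ramps ~100-fold across the cluster, starving the first tiles;
  detachment keeps coverage near-uniform without changing any linkage
  signature.
* Ping-pong mode (`first_u_bias` 0.90): trigger/responder pairs with 5'
  ends overlapping exactly 10 nt on opposite strands; responders sit on the
  plus strand and start with uridine with probability `first_u_bias`, which
  makes position 10 of the trigger adenosine by complementarity.
* Slicing-triggered phasing: the genome carries a 1-kb trigger locus whose
  sequence is the reverse complement of a cluster sub-segment, so trigger
  reads originate from a genuinely distinct locus while responder g1–g9
  equals the reverse complement of trigger g2–g10 in sequence space. Events
  draw from a fixed pool of 40 anchor sites per seed, mimicking the small
  number of dominant trigger/responder species that drive the statistic in
  real libraries; each responder is followed by a phased trail.
* Libraries: ovary = 30% mechanism-derived somatic reads + shared germline
  reads + 5% contaminants; embryo = germline + contaminants only, 20,000
  reads each. Inserts are wrapped as 4-nt UMI + insert + 4-nt UMI + 3'
  adapter and written as 4-line FASTQ with constant "I" qualities
  (qualities are unused downstream). Identical configs give byte-identical
  outputs.

What the simulator does **not** model: sequencing errors, PCR duplicates,
germline dual-strand ping-pong beyond what ping-pong mode provides,
transcription-level coverage structure (peaks, pause sites), or a realistic
embryonic germline composition — the shared uniform germline cluster is a
stand-in, not a claim about real embryos. Consequently, passing tests show
that the statistics recover the generating parameters and mechanisms under
idealised composition and noise-free reads; they do not establish
performance under real-library artefacts.

## Problem sizes and verification

Tests and the acceptance script run at the simulator's default scale:
20,000 reads per library on a 60-kb genome, with seed sweeps of 20 for the
recovery and null invariants — sizes at which every stage completes in
seconds while keeping binomial standard errors far below the tested
tolerances. The mapper is validated against an exhaustive sliding-window
Hamming oracle, the mappability mask against an independent substring-scan
census, feature counting against a quadratic interval scan, and merged
homology regions against hand-computed unions; filter thresholds are pinned
by boundary tests at bit-scores 50/30, region sizes 1500/300 nt, bait count
5, and e-value 1e-10. Positional-shuffle nulls drive all linkage z-scores
below 2 in at least 95% of seeds.

## Known limitations

* The exact-full-read mapper is quadratic in the worst case on highly
  repetitive genomes and is intended for desk-scale genomes (up to a few
  megabases), not chromosome-scale assemblies.
* Cluster-call coordinates depend on the merge defaults; on real data these
  should be tuned against a genome browser, as the original analysis was.
* The in-trans background can be zero on tiny read sets, making the ratio
  infinite; compare linkage values, not ratios, across very small inputs.
* Bait-count filtering of homology regions counts *distinct* baits ("hits
  from five or more baits" read literally); a hit-count interpretation
  would be slightly more permissive.
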