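# Methods

This note documents the models, conventions and numerical choices behind
`virin`, in the order the pipeline runs.

## Read quality filter

`sliding_window_trim` reproduces sliding-window semantics over base
qualities: scanning 5′→3′ with a 4-base window, the read is cut at the first
window whose mean Phred falls below the threshold (default Q30), except that
leading bases inside that window which individually meet the threshold are
kept — this is the behaviour of the standard trimming tool the filter
emulates, and it is what makes "60 bases of Q40 followed by Q2 tails" keep
exactly 60 bases rather than 58.  Reads whose surviving prefix is shorter
than 50 nt are removed; in paired mode the default drops both mates when
either is removed (orphan retention is a switch, since keeping unpaired
mates changes downstream mate-anchor logic).  The threshold is interpreted
as base-call quality: the filter runs before alignment, so a mapping-quality
reading would be incoherent.  Phred+33 is assumed, configurable.

## Candidate extraction

Two populations feed breakpoint calling:

* **flag filter** — a read passes iff `(flag & 4) != 0 and (flag & 264) == 0`:
  unmapped, mate mapped, not secondary.  Of the 4,096 12-bit flag values,
  exactly 2^9 = 512 pass (three bits constrained).
* **soft clips** — terminal `S` operations of length ≥ 20 nt (default) on
  primary mapped records.  The anchor is the junction base: `pos` for a
  leading clip, `pos + reference_span − 1` for a trailing clip.  20 nt is a
  specificity choice at 150 bp read length: shorter clips align to a viral
  panel too promiscuously.  Hard clips carry no sequence and are ignored.
  Anchors (and mapped mates) below MAPQ 20 are dropped to avoid breakpoints
  in ambiguous host regions.

## Viral panel search

The aligner is seed-and-extend: a hash index of all panel 15-mers on both
strands; query seeds are grouped per (virus, strand, diagonal); the
best-supported diagonal per group is refined by banded local dynamic
programming (band ±15) with match +1, mismatch −1, gap open −2, gap extend
−1 (affine: a length-L gap costs 2 + (L−1)).  A hit is accepted at identity
≥ 0.90 over ≥ 30 aligned columns.  Identity is matches over aligned columns
including gap columns.  Each read is assigned to its single best virus
(score, then identity, then lexicographically smallest virus id), so
per-virus counts sum to the number of assigned reads.  The banded score
equals full-matrix local DP whenever the optimal path stays within the band
of the seeded diagonal; with substitution-only divergence that is always the
case, and the test suite verifies score equality against an independent
full-matrix implementation.

The sample-level screen retains viruses with ≥ `min_virus_reads` assigned
reads.  The protocol value is 1,000 for ~billion-read WGS samples; this is
not a property of the method but of that data scale, so desk-scale runs
(simulations, tests) set it explicitly lower (50 in the acceptance run,
documented as scaled down) rather than pretending a 200 kb toy genome is a
30× human genome.

## Assembly and completeness gate

A minimal de Bruijn assembler stands in for a full assembler at viral-genome
scale: canonical k-mers (k = 33, each stored under min(kmer, revcomp)),
edges weighted by occurrence count, unitigs (maximal non-branching paths)
emitted as contigs, contigs < 2k dropped.  Two pruning passes precede
unitig construction:

* absolute: k-mers seen < 2 times (configurable; 1 in error-free tests) are
  sequencing-error singletons;
* relative: at a branch, sibling edges below 0.2× the dominant sibling's
  multiplicity are removed.  This matters because at high aggregate coverage
  (several insertions of one provirus give > 100× over the viral genome)
  identical errors recur and pass any fixed absolute threshold, shattering
  unitigs; the relative prune is the minimal stand-in for the bubble-popping
  and tip-clipping a production assembler performs.  Error-free graphs are
  untouched: equal-multiplicity siblings are never pruned.  The 0.2 ratio
  comes from the error model (recurrent-error edges at multiplicity 2–5 vs
  true edges ≥ 30), not from tuning against any test outcome.

Assembly consumes every panel-hitting primary unmapped read — including
fully-viral pairs whose both mates are unmapped, which never pass the
candidate flag filter but carry most of the proviral sequence — plus soft
clips of length ≥ k.  Completeness is the longest contig assigned to a virus
(by the internal aligner) as a percentage of that viral genome; a virus is
kept strictly above 5%.  A summed-breadth basis is available behind a flag
but longest-contig is the default, matching how "genome completeness" is
conventionally quoted for a largest contig.  No multi-k iteration, bubble
popping proper, or scaffolding: out of scope for desk-scale viral genomes.

## Breakpoint calling and clustering

Junction-base convention: the breakpoint is the host base adjacent to the
first viral base.  Soft-clip evidence is exact; the viral coordinate
adjacent to the junction (`virus_pos`) is `r_end` for a left clip aligned
forward and `r_start` for a right clip, mirrored on the − strand.
Discordant evidence is approximate: `mate_end + 1` (+ strand anchor) or
`mate_pos − 1` (− strand); positions off the genome edge are skipped with a
warning.  Published breakpoint tables rarely state their junction
convention, so a ±1 disagreement with external coordinates is possible and
documented rather than hidden.

Clustering is per sample, per virus, per chromosome, and per junction
orientation (host→virus vs virus→host).  Orientation matters: a clean
insertion produces its two junctions at *adjacent* host bases, and any
positional window ≥ 1 would merge them into one cluster if orientation were
ignored — they are distinct junctions with distinct viral attachment points.
Exact breakpoints cluster by single linkage with gap ≤ 10 bp; approximate
breakpoints attach to the nearest exact cluster within 1,000 bp (one insert
size) or form approximate-only clusters.  The representative position is the
median of exact members (lower-middle for even counts).  Support is the
member count; reporting threshold is ≥ 1, configurable.

## Annotation

Breakpoints are annotated as points (1-based).  DNase-I hypersensitivity is
point-in-interval over the BED track (BED `[start, end)` contains 1-based
`pos` iff `start < pos ≤ end`).  Repeat class maps onto
{LTR, LINE, SINE, Retroposon, Simple_repeat}; overlaps resolve by higher
annotation score, then the fixed priority LTR > LINE > SINE > Retroposon >
Simple_repeat; unknown labels map to `none` with a warning.  Region classes
follow the precedence promoter > 5′UTR > 3′UTR > exon > intron > intergenic.
The promoter is TSS −2,000/+200 in transcription orientation — a
reproducible conventional window, exposed in config, adopted because a
"promoter" category is meaningless without a definition.  UTRs come from
CDS-vs-exon geometry on protein-coding genes; genes without CDS annotate
only exon/intron.  Overlapping genes resolve by class precedence, then
smaller gene span, then name.  Chromosome names are compared after
stripping any `chr` prefix.  GENCODE GTF flavor (basic vs comprehensive) is
the caller's choice; any gene/exon/CDS GTF with `gene_name`/`gene_type`
attributes is accepted.

## Cohort statistics

Mann–Whitney U reports U = min(U_a, U_b) with midrank ties.  The exact
branch enumerates all C(n_a+n_b, n_a) labelings when n_a+n_b ≤ 16 and the
data are tieless; p = P(min(U_a, U_b) ≤ u_obs).  Otherwise a normal
approximation with continuity correction is used, with an Edgeworth
kurtosis term on tieless data: the U null is platykurtic with exact excess
kurtosis g₂ = −(6/5)(m² + n² + mn + m + n)/(mn(m+n+1)), and
P(U ≤ u) ≈ Φ(z) − φ(z)·(g₂/24)(z³ − 3z) at z = (u + ½ − μ)/σ.  Without the
term, the plain normal misses the exact p by up to 0.011 two-sided even at
n = 8 per group; with it, the error is ≤ 0.0006 at n = 8 and ≤ 0.0025 down
to n = 5.  Below n = 5 the discrete distribution's single atoms carry more
than 0.01 probability, so no smooth approximation can track it closer —
irrelevant in practice because the exact branch covers those sizes.  With
ties, the tie-corrected plain normal is used.  The t test is Welch by
default (Student pooled behind a flag) with the degenerate contracts: both
variances zero and equal means → p = 1, different means → p = 0.  All tests
are two-sided; significance is p < 0.05; no multiple-testing correction is
applied across per-chromosome tests by default (a Benjamini–Hochberg option
exists) to match how such per-chromosome scans are conventionally reported.

## Simulator: what it emulates and what it does not

The generator produces: an i.i.d. random host chromosome at configurable GC
(default 0.41, human-like); clean proviral insertions (full-length or
partial ≥ 500 bp, random orientation, sites ≥ 2 kb apart and ≥ 1 kb from
ends) recorded in a truth table as the last host base before the virus and
the first after; paired 2×150 bp reads at Normal(500, 50) insert length,
uniform starts, FR orientation, substitution errors at 0.5% by default; a
truth alignment against the host-only reference in which junction reads are
soft-clipped on the host side with exact anchors and fully-viral reads are
unmapped (with the mate's coordinates when the mate is host-anchored); and
synthetic DNase/repeat/gene tracks with known context at each insertion.
Defaults mirror the sequencing design the pipeline targets (Illumina
2×150 bp WGS at 30×; a ~9.5 kb provirus, the scale of a full-length
HERV-K).

Quality strings are drawn from an Illumina-like distribution (mostly
Q35–41) and are *not* per-base coupled to the planted errors: coupling them
(uniform Q23 at 0.5% error) would make the Q30 sliding-window filter remove
every read, which real data does not do — real miscalls frequently carry
high quality scores.

Deliberately not modelled: target-site duplications (an option exists, off
by default so the coordinate oracle stays exact), indel sequencing errors
(option, off by default), GC bias, PCR duplicates, platform quality
profiles, mismapping in repetitive host sequence, and multiple competing
viral taxa.  A green end-to-end test therefore establishes coordinate
arithmetic, evidence accounting and threshold logic — not robustness to
alignment artifacts in real repetitive genomes, which must be assessed on
real data.

## Determinism and degenerate inputs

All randomness flows through one seeded generator; identical configs give
byte-identical outputs.  Empty alignments, empty graphs, viruses with no
contigs, and samples with zero candidates all produce empty-but-valid
results rather than exceptions; malformed input files raise errors naming
the offending line.  Ties anywhere in ranking (virus assignment, cluster
ordering, contig ordering) break deterministically (identity, then
lexicographic).
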