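# Methods

`codmap` re-implements, as a tested library, the comparative-genomics
workflow used to turn a long-read contig assembly of a 23-chromosome
teleost genome into chromosome sequences, and to characterize what those
chromosomes reveal: large polymorphic inversions, a candidate centromeric
satellite, and sex-specific recombination structure. Every stage can be
exercised against a synthetic genome pair in which all of these structures
are planted with known coordinates.

## Chromosome construction from a linkage map

Markers arrive as flanking-sequence pairs with sex-specific genetic
positions (cM) on 23 linkage groups. Placement searches the concatenation
`flank_left + SNP + flank_right` exactly on both strands of every contig
(the SNP base itself is a wildcard), seeded by the leftmost 31-mer of the
concatenated flank through a sorted 2-bit k-mer index. A unique hit places
the marker; multiple hits mark it ambiguous; zero exact hits fall back to
the same seed with up to 2 mismatches over the flanks, else the marker is
absent. This replaces alignment-based placement with a deterministic,
dependency-free equivalent; users with real data can instead import
precomputed placements.

Contigs take the modal linkage group of their placed markers. A contig
reaching `min_votes` (default 2) markers on two groups is chimeric; a
single discordant marker is treated as placement noise. Chimeras are split
at the floor midpoint between the last marker of the 5' group run and the
first marker of the 3' run, the runs being the best two-segment partition
of marker positions by group; if more than 10% of markers remain
discordant under the best split (interleaved groups), the contig is
dropped from anchoring. The true junction is only known to lie between the
two flanking markers, so each child can retain a sliver (up to half the
local marker spacing) of the other chromosome's sequence; child marker
sets are nevertheless pure by construction.

Within each linkage group, contigs are ordered by mean female-map cM
(denser and longer than the male map; ties broken by mean male cM, then
contig id) and oriented by the sign of Kendall's tau between marker bp and
cM, requiring |tau| >= 0.5; below that, orientation is reported `?` and
emitted as `+` but flagged. Chromosomes are concatenated with 500 N gaps
(configurable; the choice is a convention, not an inference) and described
in AGP v2.1. All in-memory coordinates are 0-based half-open; AGP and
report tables are 1-based.

## Genome comparison and inversion calling

The comparator is MUM-style rather than alignment-based: k-mers (k = 21,
odd so no word is its own reverse complement) that occur exactly once in
each genome, counting both strands, are matched across genomes; maximal
runs of overlapping matches merge into anchors. Anchors are grouped by
(query chromosome, target chromosome, strand) and decomposed into
co-linear chains by repeatedly extracting the exact maximum-weight chain
(weight = anchored bp; gaps on either genome bounded by `max_gap`, default
100 kb) with an O(n^2) dynamic programme. Two corrections keep blocks
non-overlapping on the query: a chain whose internal gap fully contains
another substantial block is split at that gap (a forward chain can
otherwise bridge an inversion shorter than `max_gap`), and sparse leftover
chains lying inside a heavier block's span are suppressed. Chains below
`min_block_bp` (20 kb) or `min_anchors` (5) are discarded. An exhaustive
depth-first oracle verifies the chain optimum on small instances.

A maximal run of reverse-strand blocks flanked by forward blocks is an
inversion. Within a run, blocks whose target intervals descend with query
position are the geometry of a single reversal; two adjacent sub-runs with
mutually ascending target order cannot come from one reversal and are
called a double inversion with three breakpoint intervals (left flank,
internal junction, right flank). Deeper nesting is reported as multiple
singles. Each breakpoint interval spans from the last anchor of the
preceding block to the first anchor of the following block, in query
coordinates, reported 1-based with `size = end - start` (the convention
that reproduces the published interval sizes). Precomputed alignments can
drive the same caller through a PAF import path, with the same gap-merge
and occupied-gap rules.

Anchor ends can slide a few bases past a true junction when the first
rearranged base coincides with the reference by chance; recovery tests
therefore test truth containment with one word (k bp) of slack, while
reported intervals remain strictly anchor-to-anchor.

## Centromere-candidate scanning

The tandem-array detector seeds a candidate period p at positions whose
12-mer recurs at lag p within [`min_period`, `max_period`] (defaults 50,
600), merges seed runs, snaps them to whole copies, and trims/extends
copy-by-copy while identity against the per-column majority consensus
stays >= 0.8. Harmonic calls (e.g. a 516 bp dimer of a 258 bp element) are
folded to the smallest divisor period that still refines cleanly.
Overlapping calls keep the higher copies x period product. This is a
deliberately simple, substitution-tolerant array finder, not a
reimplementation of TRF's statistical model; TRF `.dat` ingestion provides
parity on real data.

Candidates pass the satellite filter — consensus strictly more than 60%
AT and unit strictly longer than 80 bp — then cluster greedily
(largest-score first) into families at >= 95% identity, where identity is
`1 - edit_distance / max(len)` maximized over all cyclic rotations and
both strands (tandem phase is arbitrary). The "present on all
chromosomes" requirement is applied at family level. Genome-wide
occurrences of a consensus are counted by exact 15-mer seeding followed by
semi-global (edlib) scoring of candidate windows, keeping best-first
non-overlapping sites at >= 95% identity; a brute-force all-offsets
dynamic programme provides the independent check on short sequences.

## Recombination profiles and morphology

Windowed recombination rates (cM/Mb, default 100 kb bins) come from
linear interpolation of the marker map; monotonicity violations up to
0.5 cM are clamped as map noise, larger ones rejected as input errors. The
suppressed region is the longest run of windows below 0.2 x the
chromosome-median rate (ties: lower mean). A chromosome is metacentric
when the region midpoint falls in the central band [0.25, 0.75] of its
length. There is no field-standard threshold for "repressed
recombination"; both parameters are conventions exposed as flags.
Co-location asks whether the maximum of the repeat-density track falls
inside the suppressed region (extended by one bin); because inversions
also suppress recombination, co-location is treated as evidence, never as
ground truth.

Sex-specific map totals sum the per-chromosome cM range; the
female-to-male ratio is reported rounded to one decimal.

## The synthetic study

The generator's defaults are the study conditions: 23 chromosomes x 2 Mb
(~46 Mb, so the full pipeline runs in minutes), i.i.d. bases at GC 0.46,
and per chromosome one satellite array of 20 copies of a 258 bp
unit-spacer-unit element (88 + 82 + 88 bp, exactly 70% AT, two identical
units) planted at a configurable position (0.5 = metacentric), each copy
independently mutated at 2% so the 95%-identity clustering is exercised.
Three chromosomes also carry a 120 bp AT-rich decoy family that passes the
composition filter but not the all-chromosome one. The rearranged genome
differs by a serial double inversion on chromosome 1 and singles on
chromosomes 2, 7 and 12 (mirroring the four supergene linkage groups),
plus 0.2% substitution divergence. Contigs are cut at exponentially spaced
points (mean 150 kb), reverse-complemented with probability 0.5; with
probability 0.01 a fragment of at least 100 kb is joined to one from
another chromosome — assembler-style misjoins involve sizeable contigs,
and this floor also gives each chimera arm enough markers (about 10
expected at the default 100 markers/Mb) to be detectable. Chimera
junctions carry no sequence signature.

Marker cM positions integrate a piecewise rate: constant on the arms,
2% of background inside a 300 kb window around the planted centromere
(suppressed, not abolished — also keeps the map strictly increasing so
contig order within the window remains defined), scaled to 54.9 cM per
chromosome for males and 1.3 x that for females. Markers inside planted
inversions carry the cM of the non-inverted reference arrangement, as a
linkage map estimated in the reference orientation would.

What the generator does not emulate: indels, genome-wide repeat
background beyond the planted arrays (an option exists, default off),
read-level errors, genotyping noise in the map, and the map gaps seen at
inversion borders in inversion heterozygotes. Passing tests therefore
demonstrate the correctness of the algorithms under clean, fully
determined conditions — not robustness to every artifact of real
assemblies. The anchoring and morphology test conditions run without
inversions (the builder is scored against the reference marker
arrangement, and the rate profile requires monotone cM); the synteny
condition runs with them.

## Numerical and degenerate-input choices

Non-ACGT IUPAC codes degrade to N with a warning so real assemblies
ingest; windows containing N never seed anchors or arrays. k-mer codes are
2-bit packed uint64; reverse complements are computed bitwise. Degenerate
cases are defined, not special-cased: empty inversion lists are the
identity; a linkage group with no contigs yields an empty build with a
warning; chromosomes with fewer than 2 markers are flagged unanchorable;
an empty density track makes co-location undecided (None) rather than
false. Tie-breaks (contig ordering, chain extraction, clustering order,
suppressed-region ties) are all fixed and documented in the code so every
run is reproducible.

The published breakpoint table contains two internal inconsistencies that
the report writer intentionally does not hide: the second interval on
LG02 prints 4,840 bp where its own coordinates subtract to 4,845, and the
LG02 outer span prints 4.51 Mb where the coordinates give 4.50. The
writer always reports the subtraction.

## Problem sizes

Integration tests and the acceptance script run the full 23 x 2 Mb study:
the test suite over seeds 1-5 per condition, the acceptance script over
three seeds derived from its `--seed` (with the clean-count check on two),
sizes chosen so a complete run stays within a few minutes per replicate on
one CPU.
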