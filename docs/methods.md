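# Methods

## The model: reticulate organellar genome structure

A plant mitogenome assembled from long and short reads rarely reduces to a
single circle. Repeats of a few to tens of kbp recombine actively, so the
most faithful representation is a multigraph: *stable contigs* (unique
sequence, reliably assembled by a repeat-graph assembler) connected at
*junctions* mediated by repeat segments that a De Bruijn graph (DBG)
assembler collapses into single nodes. `mitoweaver` takes both views as
input — stable contigs (FASTA) and the DBG "connection network" (GFA1 with
per-segment depth) — and reconciles them.

A junction joins two contig ends, optionally through a repeat mediator.
A repeat attached to `a` contig ends on its left and `b` on its right
induces all `a x b` cross-pairs as junctions: this is the reticulate
reading, in which every traversal of the repeat is a possible linkage. It
is also the only reading under which the worked type-I example — nine
contigs joined by twelve junctions — is realizable from copy-2 repeats
(three repeats, 2x2 cross-pairs each). Junction signatures are canonical
strings over (contig, end) pairs plus the mediator, invariant under end
swap and global strand flip; the multiset of signatures is the resolved
structure.

## Contig threading

Anchors are k-mers (default k = 31) unique both within the contig and
within a single graph segment. Anchors are grouped per (segment, strand)
on their dominant diagonal (ties toward the leftmost contig position), and
the resulting candidate intervals are chained by a dynamic program that
maximizes total anchor count subject to consecutive intervals being linked
in the graph with consistent orientation. Weak stray claims (e.g. a small
dispersed repeat shared between contigs) are dropped by the DP; a strong
unclaimable interval (at least 20% of the chain's anchors) means the graph
is missing a link the contig implies, which is a hard error naming the
segment pair. k = 31 keeps repeats shorter than k unambiguous anchors
while anything longer is a mediator by construction.

## Copy number and minor conformations

The depth baseline is the median depth of gene-bearing segments: gene-free
segments are exactly the depth outliers (repeats run at copy-fold depth,
minor-conformation contigs below baseline), so they must not contaminate
the baseline. Copy number is round-half-up of
depth/baseline with a floor of 1 (a present segment cannot have copy 0);
segments and contigs below `minor_depth_fraction` (default 0.5) of baseline
are flagged minor. With lognormal depth noise at CV 0.1 and copy-2 repeats,
the error probability per repeat segment is the tail probability of the
noise beyond 25% deviation, about 1%; measured per-segment accuracy over
seeded ensembles is 99.6-99.8%.

## Structural types and collinearity

Types are single-linkage components at Jaccard similarity >= tau on
junction signature sets. tau defaults to 0.7 because an accession sharing
ten of twelve linkages (Jaccard 10/14 ~ 0.714) belongs in the type — the
documented behaviour of a complex-pedigree accession — while anything
structurally distinct falls well below. Collinearity reuses the anchor
machinery: per (target contig, strand, diagonal) anchor runs become
blocks, split only at anchor gaps above 200 bp so isolated SNPs do not
fragment a block; blocks below 5 kbp of query length are filtered (the
standard display threshold). Block identity is the anchored fraction.

## Repeat and SSR scanning

The dispersed-repeat finder enumerates maximal exact pairs >= `min_len`
(default 30 bp — "default parameters" of the classical tool are ambiguous
across versions, so the value is exposed) in four classes: second copy
identical (F), reverse-complemented (P), reversed (R), complemented (C).
Discovery seeds every min_len-mer and extends; a pair is emitted only from
its leftmost seed, which enforces maximality. Same-contig pairs whose
copies would overlap are resolved: F overlaps are tandem periodicities and
are dropped; P/R copies converge and are trimmed to touching arms (so a
perfect palindrome `s + revcomp(s)` is one P hit of |s|); C copies run in
parallel and keep their offset-length core. N matches nothing, including
another N. Only exact repeats are reported — the comparisons of interest
are size-class distributions, not degenerate repeats.

SSRs are maximal perfect tandem runs of primitive 1-6 bp units meeting the
MISA minima (10, 6, 5, 5, 5, 5 repeats for unit lengths 1-6). Runs are
found by unit-shifted equality arrays; the reported interval is the full
maximal stretch (possibly ending in a partial unit) and the count is the
number of complete units. Motif classes are canonical over rotation and
strand (sorted union of rotations of the motif and its reverse
complement: `A/T`, `AT/TA`, `C/G`). Shorter-unit hits fully contained in a
longer-unit hit are suppressed, mirroring MISA's reporting.

## CDS SNPs and accession grouping

Spliced CDSs concatenate exons in genomic order (reverse-complemented for
minus strand) and assemble multi-contig genes in the declared
`part_order`. Equal-length ortholog sets are compared column-wise; unequal
lengths are aligned to a modal-length reference by banded global alignment
(match +1, mismatch -1, gap -2, deterministic diagonal-then-up tie-break).
Genes whose lengths differ by more than 10% are reported length-discordant
and excluded — orthologs this divergent signal annotation error, not
biology. Gaps are not alleles; columns gapped in more than half the
accessions are skipped. Grouping takes the majority bipartition across
sites; per-accession concordance is the fraction of sites carrying the
group's majority allele, and anything below 1.0 is an intermediate. Ties
between bipartitions break lexicographically and are flagged ambiguous.

## Transfer scanning (NUMTs/NUPTs)

Detection is seeded local alignment: unique 15-mer seeds over the
organelle, grouped per (contig, diagonal) into cores (split at seed gaps
above 50 bp, because the true alignment may excurse to another diagonal
and return), chained across gaps up to 2 kbp with the unseeded window
between cores re-scored exactly (base comparison when gap lengths agree,
banded global alignment otherwise). Bridges longer than 120 columns must
align at >= 0.62 identity — a gapped global alignment of unrelated DNA
reaches about 0.5, so this floor separates true low-identity homology
(>= 0.8 minus noise) from junk. Chain ends are extended by a banded
X-drop DP (match +1, mismatch -1, gap -2, X = 20). Finally each chain is
re-measured on the optimal (minimum-edit) alignment of its span and
trimmed to the maximum-scoring run window, so heuristic extension can
neither inflate nor dilute the reported span and identity.

Filters follow the stated thresholds, read inclusively (identity >= 80.0%,
nuclear span >= 100 bp) so the printed 80-89% and 100-199 bp bins are
non-empty; identity bins are [80, 90) and [90, 100], length bins 100-199
... 900-999 and 1000+. Overlapping hits from the same organelle interval
to the same nuclear locus keep the higher-identity span; region-deposition
percentages union hit intervals before dividing by region length, while
bin counts keep every retained event. The nuclear region index tiles each
chromosome into exon, intron and intergenic (intron = mRNA minus exon,
intergenic = chromosome minus mRNA) and additionally reports mRNA as its
own class. Flank GC windows cover the bases at distance 100-499, 500-1000
and 1001-2000 from each insert boundary (the open-ended ">1000" class is
capped at 2 kbp), clipped at chromosome ends.

## The synthetic-data generator

`synthio` emulates the study conditions: ~400-450 kbp reticulate
mitogenomes over 6-9 unique contigs (type presets I/II/III at 9/6/6
contigs with 12/8/12 junctions and the named 12.4/3.6/4/33 kbp repeats at
copy 2), mean depth 83x with mean-1 lognormal noise at CV 0.1, GC 0.437,
two gene-free minor contigs at 0.375x depth in the type-I preset, and
planted genes (about one per 12 kbp, 1-3 exons, both strands, 10% tRNA).
Unique segments may fragment into up to two colinear graph pieces, as a
DBG fragments unique sequence, so threading is genuinely exercised. Random
wiring guarantees connectivity (m copy-2 repeats supply 4m attachment
slots; the ensemble draws 2-3 repeats for 6-9 contigs accordingly). Small
dispersed repeats and SSR runs are written into contig sequences with a
registry, so the scanners have planted truth too.

Nuclear genomes are random background (GC 0.37) with evenly spaced
multi-exon genes and planted organellar insertions: each insert is copied
from a random organellar interval, optionally reverse-complemented,
mutated with 90% substitutions / 10% single-base indels until its identity
is within +/-0.5 points of target (subject to 1/length granularity), and
placed strictly inside a feature of the requested region class, which is
stretched around it. Realized identity is recorded from the optimal
(minimum-edit) alignment of the mutated copy against its source — adjacent
random edits occasionally compress, and the optimal path is what any
aligner will see. All generator randomness is namespaced per generator
(`SeedSequence([seed, tag])`), so the same integer seed can never make the
nuclear background replicate the organelle stream.

What the generator does *not* emulate: read-level errors and coverage
waviness, transposon-rich nuclear repeat landscapes, heteroplasmy
gradients, GC heterogeneity along the genome, or degenerate (mismatched)
dispersed repeats. Passing tests therefore demonstrate correctness of the
graph/threading/scanning logic under clean planted truth, not robustness
to assembler artefacts in real data.

## Problem sizes and numerical choices

Recovery ensembles use 6-12 kbp unique segments and 2-4 kbp repeats (100
structures in ~40 s); the demo pipeline scales preset lengths by 0.12.
These sizes keep counts, copy numbers, depths and noise at study
conditions while staying desk-sized; the structural logic is
length-invariant above the anchor size. Ties everywhere are deterministic
(leftmost anchor, diagonal-then-up alignment tie-break, lexicographic
bipartitions and labels); all randomness flows through seeded NumPy
generators, and reruns are byte-identical.

One testing subtlety: the transfer scanner is cross-checked against an
iterative best-local-alignment-and-mask oracle (Smith-Waterman). A single
optimal local alignment can legitimately merge two insertions whose
organellar spacing matches their nuclear spacing — the bridge then costs
less than the flanking score — where an HSP-style scanner reports two
separate hits. Oracle-comparison fixtures therefore exclude such
colinear-compatible insert pairs, so that the two methods have the same
well-defined answer; sensitivity measurements use unrestricted fixtures.

Known limitations: transfer detection requires at least one intact unique
15-mer seed, so ~15% of 150 bp inserts at 80-85% identity are undetectable
by construction (ensemble sensitivity still measures ~97% against a >= 95%
requirement); junction recovery assumes the DBG collapses each repeat into
one segment (mediator chains of two or more repeat segments are not
paired across); and the SSR scanner reports perfect repeats only, no
compound or interrupted SSRs.
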