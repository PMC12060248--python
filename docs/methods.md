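# Methods

## The problem

Two reference-quality assemblies of closely related genomes — here
modelled on the *Aegilops tauschii* AL8/78 assembly and the D subgenome of
Chinese Spring wheat — disagree in the orientation and location of some
sequence segments.  Each disagreement is either a *real* structural
variant (an inversion or a segmental-duplication-derived relocation that
happened in one lineage) or an *assembly error* (a scaffold placed or
oriented wrongly in one of the assemblies).  `cgnkit` implements a
collinearity-based orthology classification between the two gene
complements, derives the structural-difference taxonomy from it, and
discriminates errors from real variants using BLAST sequence identity —
no sequencing reads or optical molecules required.  A separate component
covers the pseudomolecule-construction conventions (genetic-map
anchoring, AGP gap rules, in-silico DLE-1 digestion to CMAP) used to
build and validate such assemblies.

## Orthology from conserved gene neighborhoods

A *conserved gene neighborhood* (CGN) is a pair of genomic segments whose
genes appear in a similar collinear order in both genomes.  The operating
definition is: a query gene and its top BLAST hit in a collinear order
inside a CGN are putative orthologues; a non-collinear top hit is a
putative paralogue (the product of a duplication/deletion history); a
query without any hit is undetected.  "Putative" is deliberate — a tandem
duplication followed by reciprocal losses makes an out-paralogous pair
look perfectly collinear, and a transposition makes a true orthologue
look paralogous — so the classes describe what collinearity can support,
not certain descent.

Per query chromosome the classifier:

1. takes the rank-1 hit of every query (hits ranked per query by
   bitscore, ties by identity then target id; only the top 3 kept),
2. finds the *dominant* target chromosome (plurality of rank-1 targets),
3. chains the *backbone*: the maximum-cardinality ascending subsequence
   of target ranks (a longest-increasing-subsequence computation)
   restricted so consecutive members are within `max_query_gap` and
   `max_target_gap` ranks (both default 5),
4. groups the remaining pairs into monotone (ascending or descending)
   runs under the same gap limits; runs of two or more genes are
   collinear blocks, the rest are singletons (paralogues).

Step 4 is solved exactly for small independent groups: leftovers are
split at query-rank gaps no chain can span, and each component of at most
12 pairs is partitioned by an exhaustive bitmask search maximizing the
number of genes placed in blocks (ties: fewest blocks).  Larger
components fall back to a greedy left-to-right scan.  For dominant-
chromosome inputs of at most 12 pairs the backbone choice itself is
exact: every maximum ascending chain is tried and the one admitting the
best leftover coverage wins.  The decomposition therefore agrees with a
brute-force enumeration of backbone-first monotone-chain decompositions
on all permutations up to n = 8 (verified exhaustively in the tests).
Note the objective is deliberately *backbone-first*: a plain
maximum-coverage partition would split the neighborhood backbone into
two ascending chains in the classic seven-gene example (order A B D E F
C G) and call C orthologous, which contradicts the method's definition.

### Backbone refinement

Gap-capped chaining has three systematic artifacts on realistic input,
where roughly a third of queries (mostly low-confidence genes) interrupt
the backbone with paralogous or undetected entries:

* the backbone fragments wherever interleaving opens a rank gap beyond
  the cap, so placement calls and flank extraction lose their frame;
* genuinely collinear genes stranded between fragments fall out as
  singletons and would be misclassified paralogous;
* the ascending backbone absorbs the edge genes of an inverted segment
  (and always absorbs one member of a 2-gene flip), shrinking or erasing
  orientation differences.

A refinement pass repairs all three after chaining: in-place ascending
blocks and singletons are merged into the backbone when their insertion
keeps it strictly increasing in both query and target rank (larger
fragments first, so a relocated segment cannot occupy a backbone hole
before the true fragment reclaims it); descending blocks reclaim
adjacent backbone members that extend their run monotonically; and a
leftover singleton forming a strict *local swap* with an adjacent
backbone member becomes a 2-gene descending block — the smallest
orientation-difference class.  The local-swap test (both target ranks
strictly between the surrounding backbone targets) is what keeps the
seven-gene example's C a paralogue: its target rank lies far outside its
local window.  The chaining primitive itself is left untouched, so the
oracle equivalence above is preserved.

### Shared-target adjudication

When juxtaposed duplicated queries (within 2 query ranks, configurable)
hit the same target, the identity threshold T = 97.0 % decides: if
exactly one query reaches T it remains the orthologue candidate and the
others are paralogous; if all or none reach it, no decision is made and
the queries are excluded from chaining as *uncertain*.  T is a configured
constant.  The one-sided quantile construction mu − z(1−alpha)·sigma over
the orthologue identity distribution (mu = 99.4, sigma = 1.65,
alpha = 0.01) is exposed as `derive_identity_threshold` and yields
95.56 %, not 97.0; because the printed constant governs the published
classification, the constant wins and the derivation is informational.

## Structural differences and their verdicts

Non-backbone blocks become the difference taxonomy: a descending block
sitting in place on the homologous chromosome is an *orientation*
difference (binned 2 / 3 / >3 by gene-pair count); a displaced block of
at least 3 pairs is an *intrachromosomal location* difference; a block of
at least 3 pairs on a non-dominant chromosome is *interchromosomal*.  A
moved-and-flipped block is tallied once, as a location difference with
its orientation recorded.  In-place ascending off-backbone blocks that
survive refinement are chaining artifacts and are not differences.

**Location differences.** If the relocation is real, the segments derive
from a segmental duplication and the gene pairs are paralogous, so their
identity falls well below the genome-wide orthologue distribution; if it
is an assembly error, an orthologous segment merely sits in the wrong
place and identity is unremarkable.  The verdict is a one-sided z-test of
the segment mean against Normal(mean, sd/sqrt(n)) fitted to all
classified orthologous pairs: p ≤ alpha_loc (default 0.01) means *real*,
otherwise *assembly_error*; segments under 3 pairs are undetermined.  A
fixed identity cut would not work: published real-relocation means reach
97.1 % while error means start at 98.6 %, so only the test against the
fitted distribution separates them.

**Orientation differences.** A real inversion segregates as a
heterozygous polymorphism for a long time; heterozygosity suppresses
recombination and shields the segment from purifying selection, so genes
inside diverge faster than genes flanking it.  The verdict compares the
segment against both flanking runs of backbone pairs (capped at 15 per
side) with one-sided Welch tests (segment < flank), significance
inclusive at alpha_inv = 0.05 because a published case at P = 0.05 is
treated as supporting a real inversion: significant against both flanks
⇒ real; against neither ⇒ assembly_error; mixed evidence, a missing
flank, or a segment under 3 pairs ⇒ undetermined (2-gene orientation
differences are therefore always undetermined).  Welch statistics use
Satterthwaite degrees of freedom; both-constant groups are handled
explicitly (equal means ⇒ p = 1).

## Pseudomolecule construction and optical-map conventions

Marker placements are filtered at 99 % identity and e-value ≤ 1e-5 (the
strong-hit filter; the threshold direction is configurable).  Scaffolds
take the chromosome hit by the plurality of their markers, are ordered by
mean cM (ties: min cM, then id), and oriented by the sign of the Spearman
correlation between cM and scaffold bp; under two usable markers a
scaffold is unoriented and written "+".  Conflicts (scaffold with markers
on several chromosomes, marker present in several scaffolds) are flagged
for inspection, not resolved automatically.

Junction gaps of known length k are written as k Ns with an AGP "N" row;
unknown junctions get exactly 100 Ns and an AGP "U 100" row (gap_type
scaffold, linkage yes, evidence map), AGP v2.1 with 1-based inclusive
coordinates.  Assembly statistics satisfy
effective_length = total_length − gap_length by construction, and gap
counts equal the number of N-runs.

In-silico digestion reports one label per motif occurrence (DLE-1's
CTTAAG by default — its own reverse complement) at the motif's first
base, case-insensitive, overlaps included; windows containing non-ACGT
never match, so gaps carry no labels.  Label positions are written as
CMAP v0.2.  `align_cmaps` is an interval-matching dynamic program (LCS
over consecutive inter-label intervals, matching within a relative
tolerance of 0.1, both orientations tried) that supports the
concordance-screen use case — finding discordant label runs between two
maps — and is not a likelihood-based replacement for a vendor aligner.

## The synthetic genome pair

The generator emulates the study conditions: 4 chromosomes × 500 genes
(2,000 query genes), 52.2 % low-confidence; undetected fractions 1.7 %
(HC) and 15.5 % (LC); scattered-paralogue fractions 8.4 % (HC) and
47.3 % (LC); orthologue identity Normal(99.4, 1.65), paralogue identity
Normal(93.3, 6.7) for HC and Normal(95.2, 4.5) for LC, real-inversion
identity Normal(94, 2), all limited to (50, 100].  Identities are
*ceiling-censored* at 100 % with the underlying location calibrated so
the censored mean equals the configured mean — published mean identities
are measured on ceiling-limited values, and naive clipping would bias
the orthologue mean to 99.0.  Scattered-paralogue targets are uniform
but redrawn if the draw would itself be collinear (landing in the gene's
own slot or continuing a monotone run with a nearby scattered
assignment), since the paralogue label asserts non-collinearity.

Default events per genome: real inversions of 4/5/6/8 collinear pairs
(flip + identity redraw), error inversions of 2/3/4/6/10 pairs (flip
only), segmental duplications of 4/5 (intra) and 4 (inter) pairs
(relocation + paralogue identities), error relocations of 3/4/5 (intra)
and 3/4 (inter) pairs (relocation only), 5 transpositions, 8 tandem
dup/loss genes, 4 shared-target duplications (half decidable by the
threshold, half not).  Event sites are disjoint windows of collinear-fate
genes with margins from chromosome ends and from each other; relocations
move at least 15 ranks.  Decoy rank-2/3 hits (30 % of queries) carry
paralogue-level identities and bitscores strictly below the true
partner's.  Truth labels record the *putative* class each gene should
receive (a tandem-duplication survivor is collinear, hence labelled
orthologous; a transposed gene is labelled paralogous) plus each event's
member genes and expected verdict.  The same seed yields byte-identical
output files.

What the generator does **not** model: nucleotide-level evolution,
autocorrelated divergence along chromosomes (identities are independent
per pair), repeat families, annotation errors beyond the HC/LC split,
and any linkage between gene density and rearrangement breakpoints.
Passing recovery tests therefore shows the pipeline recovers the
declared signal under the declared noise, not that it is robust to every
property of real annotations.

The scaffold-set generator plants known counts of digestion motifs into
otherwise motif-free random sequence, fragments chromosomes into 50
scaffolds with a mix of known (23–5,000 bp) and unknown gaps, stores 40 %
of scaffolds reverse-complemented, and emits markers whose cM positions
are linear in chromosome bp but reported in scaffold-local coordinates —
so anchoring must recover order and orientation, and the truth AGP and
pseudomolecule are exact reference outputs.

## Numerical and scale choices

* Chaining gap limits default to 5 ranks (tolerating paralogue/LC
  interleaving without chaining across rearrangements); "juxtaposed"
  means within 2 query ranks; both configurable.
* Exhaustive search limits: leftover components and backbone-candidate
  enumeration switch to greedy/single-LIS above 12 pairs; the bound keeps
  the bitmask searches trivial while covering every case the brute-force
  oracle can itself afford to verify.
* Significance is inclusive (p ≤ alpha) throughout the discriminator.
* The test and acceptance workloads use ten seeds of the 2,000-gene
  default configuration and the 50-scaffold fixture; these sizes give
  ~130 scored events and stable fraction estimates while a full run
  stays under a minute.
* Event recovery is scored member-wise: an event whose pairs are split
  over adjacent detected blocks of the correct kind and verdict counts
  as recovered when most members are covered.

## Known limitations

* The CLI `detect`/`discriminate` subcommands rebuild blocks from the
  ortholog table, recomputing ranks over the genes present in it; rank
  distances are compressed relative to the full target annotation, which
  can in principle shift a borderline placement call (the `all`
  subcommand avoids this by staying in memory).
* Orientation verdicts need both flanks; differences at chromosome ends
  are undetermined.
* The interval-matching CMAP comparison has no stretch model, no
  false-label model, and a single global tolerance; it is a concordance
  screen only.
* With heavy interleaving the backbone occasionally retains a single
  mis-slotted member in a refinement hole; the effect measured on the
  default simulation is below 0.3 % of classifications.
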