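# cgnkit

Collinearity-based orthology classification and assembly-error
discrimination between two closely related annotated genome assemblies,
with the pseudomolecule-construction and optical-map (CMAP) conventions
used to build chromosome-scale assemblies.

## Who this is for

When a new assembly of a genome (or of a close relative, such as
*Aegilops tauschii* versus the wheat D subgenome) disagrees with a
reference about the orientation or location of a sequence segment, the
disagreement is either a real rearrangement or a mistake in one of the
assemblies.  `cgnkit` decides which, using nothing but the two gene
annotations and a gene-to-gene BLAST hit table.

## The method

**Orthology from conserved gene neighborhoods (CGN).**  A query gene and
its top BLAST hit in a collinear order within a CGN are putative
orthologues; a non-collinear top hit is a putative paralogue.  Per query
chromosome the classifier finds the dominant target chromosome, chains a
backbone — the maximum ascending run of target ranks (a gap-constrained
LIS) — and groups the remaining pairs into monotone runs; runs of ≥ 2
pairs are collinear blocks.  Juxtaposed duplicated queries sharing one
target are adjudicated by an identity threshold (T = 97.0 %): exactly one
query above T keeps the orthologue call, otherwise no decision is made.

**Structural differences.**  Descending in-place blocks are orientation
differences (classes of 2 / 3 / >3 gene pairs); displaced blocks of ≥ 3
pairs are intra- or interchromosomal location differences.

**Error vs real.**  For a location difference, real means segmental
duplication, hence paralogue-level identity: the segment mean is tested
(one-sided z, α = 0.01) against the genome-wide orthologue identity
distribution N(μ̂, σ̂/√n).  For an orientation difference, a real
inversion suppresses recombination while polymorphic and its genes
diverge faster than the flanks: the segment is Welch-tested (one-sided,
α = 0.05, Satterthwaite df) against both flanking backbone runs —
significant against both ⇒ real, against neither ⇒ assembly error.

A seeded simulator generates paired genomes with the identity models
N(99.4, 1.65) for orthologues, N(93.3, 6.7)/N(95.2, 4.5) for HC/LC
paralogues, configurable inversion/relocation/transposition events, and
truth labels — every claim in the test suite is checked against it or
against brute-force oracles.

## Worked example

```
$ cgnkit simulate --seed 1 --out demo/
wrote genome pair (2000 query genes) to demo

$ cgnkit all --genes-a demo/genes_a.gff3 --genes-b demo/genes_b.gff3 \
             --hits demo/hits.tsv --out demo/run
real vs error segment means: t=-4.081 df=2.1 P=0.0498
wrote orthologs/differences/summary to demo/run
```

`demo/run/orthologs.tsv` classifies all 2,000 query genes — here 1,214
orthologous, 591 paralogous, 191 undetected, 4 uncertain — matching the
configured undetected/paralogue rates.  `demo/run/summary.tsv` is the
per-chromosome difference matrix:

```
chromosome  orient_2  orient_3  orient_gt3  intra_location  inter_location
A01         1         0         2           1               1
A02         1         0         1           2               0
A03         1         0         2           2               0
A04         0         0         2           0               2
Total       3         0         7           5               3
```

and `demo/run/differences.tsv` carries one row per difference with its
verdict, e.g.

```
diff_id  kind            size  mean_pident  verdict         p_value
SD0001   orientation     4     94.510       real            2.383e-03
SD0009   orientation     6     99.785       assembly_error  9.330e-01
SD0014   intra_location  5     91.178       real            1.028e-31
SD0015   intra_location  5     99.844       assembly_error  8.194e-01
```

A real inversion shows depressed identity (94.5 % vs ~99.4 % flanks); a
relocated segment at orthologue-level identity is an assembly error.
The closing line of `cgnkit all` is the two-sided Welch comparison of
segment mean identities between the real and error verdict groups.

Other subcommands: `classify`, `detect`, `discriminate` (the same
pipeline stepwise, driven from TSVs), `simulate --kind scaffolds`,
`build-pseudo` (genetic-map anchoring → FASTA + AGP; unknown junctions
get exactly 100 Ns with AGP `U` rows), `digest` (in-silico DLE-1
digestion to CMAP v0.2), `cmap-align` (interval-matching concordance
screen), and `compare-assemblies` (per-chromosome statistics
differences with recomputed paired t-tests).

See `docs/methods.md` for the model, its assumptions, and the
limitations of the simulator.

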