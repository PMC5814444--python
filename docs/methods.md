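# Methods

## Co-occurrence model

For a genome group of `M` aligned sequences, a position `i` is a
*variable site* when at least two distinct valid nucleotides (A, C, G,
T) occur among the samples. For states `x` at `i` and `y` at `j`, with
`N(x_i)` the number of genomes carrying `x` at `i` and `N(x_i y_j)` the
number carrying both, the co-occurrence score is

    CO_ij = f(x_i y_j)² / (f(x_i) f(y_j)) = N(x_i y_j)² / (N(x_i) N(y_j)),

the frequencies `f = N/M` cancelling `M`. The score lies in (0, 1] for
co-observed pairs and equals 1 **iff** the two carrier sets are
identical — perfection is therefore tested on integers
(`N(xy)² == N(x) N(y)`), never on floats, and is found efficiently by
hashing carrier sets rather than scanning all pairs.

Each genome gets its own network: edge `(i, j)` is present in genome
`g`'s network iff some perfect state pair `(x, y)` satisfies `g[i] = x`
and `g[j] = y`. Since a perfect pair's states share one carrier set, a
genome carries both states or neither; a group of `M` genomes yields
`M` networks whose union of edges projects exactly onto the perfect
pairs. Nodes are edge endpoints only; isolated variable sites are not
nodes.

### Filters and conventions

* **Variant-only filter** (default on): perfect pairs are restricted to
  non-consensus states at both positions, so the networks describe
  co-occurring *mutations*. Without it, any two columns with the same
  carrier partition would also connect their consensus states and flood
  the graph. `include_consensus_states` restores the unfiltered rule.
* **`min_carriers`** (default 1 = off) can discard singleton–singleton
  perfect pairs, which are trivially perfect.
* **Missing data**: non-ACGT symbols contribute to neither pair nor
  single-state counts while `M` stays the full sample count, so a
  heavily missing column can never reach `CO = 1`. A column whose only
  second "state" is a gap or `N` is not variable; the
  `count_gaps_as_state` switch makes `-` a fifth allele.
* **Consensus ties** break by fixed symbol order A < C < G < T (then
  `-`), for determinism.
* Coordinates are 1-based inclusive alignment columns everywhere.

## Codon labeling

Positions in protein-coding genes get labels 1, 2, 3 cycling from the
gene's start along its reading direction (minus-strand genes are walked
from their 3′-most reference coordinate); all other positions get 0.
Conventions for cases the rule leaves open, chosen once:

* overlapping CDS (rCRS ATP8/ATP6, ND4L/ND4): the earlier-starting gene
  labels shared positions; conflicting frames are reported in a sidecar
  table (54 positions for the packaged rCRS map);
* incomplete terminal codons (polyadenylation-completed stops, flagged
  in the feature table) continue the 1-2-3 cycle to the gene end;
* if the alignment is longer than the reference, a two-column projection
  table maps alignment columns to reference positions; insertion
  columns get label 0 / segment Misc.

The packaged rCRS (NC_012920) map carries 13 CDS, 22 tRNAs, 2 rRNAs,
the split control region and the light-strand origin, in both TSV and
GFF3 form.

## Motifs

* **ThNM** = triangle (3-clique), typed by the unordered label triple;
  triangles nested in larger cliques are each counted (a k-clique
  contributes C(k,3)), and this choice is recorded in output metadata.
* **TNM** = edge of the subgraph induced after *removing every node in
  any triangle*, typed by the label pair. A pendant edge touching a
  triangle node is therefore not a TNM; `tnm_rule=edge_subtraction`
  offers the milder alternative (drop only triangle edges).
* Type keys sort labels ascending ("1-3", "0-1-3"); there are
  C(5,2) = 10 two-node and C(6,3) = 20 three-node types over the four
  labels.

## Null model

Each group's ensemble uses `N = round(⟨N_Co⟩)` nodes and edge
probability `p = ⟨k⟩/N`, with the group mean degree defined as
`⟨k⟩ = 2⟨E⟩/⟨N_Co⟩` over all `M` networks (empty networks included).
`p = ⟨k⟩/N` is kept as stated even though the mean degree of `G(N, p)`
is `p(N−1)`; the ~1/N bias is accepted for fidelity. Node labels are
drawn i.i.d. from the group's pooled empirical node-label distribution
per realization (default) or by permuting one fixed multiset
(`labels=fixed_multiset`); the in-use mode is recorded in outputs, since
no principled choice exists between them. Default `R = 10,000`
realizations; enrichment is the empirical one-sided tail probability
`(b + 1)/(R + 1)` (add-one correction avoids zero p-values) with a
z-score when the null sd is positive. No multiple-testing correction is
applied across motif types.

## Synthetic data

The generator emulates what the pipeline assumes about real aligned
genome groups: a uniform-ACGT reference with a tiled gene map (D-Loop,
alternating-strand CDS, tRNAs, rRNAs, one ORIL, Misc gaps), groups of
`M` reference copies modified by

* **planted blocks** — position sets sharing one carrier set per group
  (carrier count `⌈fraction·M⌉`, substitution = the next base in
  A→C→G→T→A order), so every within-block pair is a perfect pair and
  every triple a triangle;
* **noise sites** — independent variants with minor-allele frequencies
  drawn from a configured range;
* **missing symbols** — `N`s at a configured rate, placed only in
  invariant columns by default (a missing observation inside a planted
  block would break `CO = 1` under the full-`M` denominator; a flag
  allows it to exercise that documented behaviour).

Carrier sets are collision-checked: a new set equal to — or the
complement of — any already-used set is redrawn, so ground truth is
exact whatever the variant frequencies (when a size class is exhausted
at small `M`, the size escalates to the nearest feasible one and the
realized count is what enters the ground truth). The recorded truth
stores the *minor* state per position, which is what the variant-only
filter recovers, also when the planted fraction exceeds ½ and the
reference state becomes the minor one.

What the generator does **not** emulate: phylogenetic (haplogroup)
structure, mutation-rate heterogeneity along the genome,
transition/transversion bias, recurrent mutation and indel processes.
Passing tests therefore demonstrate correctness of the computations
under the stated model, not robustness to real mtDNA complications such
as homoplasy or alignment artefacts.

### Continental-scale study conditions

`continental_spec(scale)` builds five groups named AF, AM, AS, EU, OC
with `M = round(scale × (2323, 1692, 5715, 7142, 1539))` and alignment
length `max(2000, round(scale × 16881))`. Its planted structure — eight
private 3-blocks per group, shared blocks spanning two to five groups,
one 4-block, one 2-block pair, carrier fractions uniform in (0.1, 0.4),
40 noise sites per group, missing rate 0.01 — was chosen so that
per-genome networks are sparse and triangle-dominated, giving group mean
degrees near 2, and so that cross-group analyses (variome overlap,
predominant pairs) have known expected winners. The analyses and the
acceptance script run at `scale = 0.01` (M = 23, 17, 57, 71, 15; L =
2,000), a size at which the whole pipeline completes in seconds while
leaving dozens of planted pairs and triangles per group to recover.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; identical seeds reproduce FASTA output byte-for-byte and
  null ensembles bit-for-bit. Per-group null seeds derive from the run
  seed plus a CRC of the group name.
* Triangle enumeration uses ordered neighbor intersection (each
  triangle reported once); it is validated against an exhaustive
  C(n,3) oracle in the tests.
* Degenerate inputs: an all-conserved group yields an empty variome
  (valid); genomes carrying no perfect-pair state yield empty networks
  that still enter group means; groups whose mean network size rounds
  below 2 skip the null ensemble with a log note.
* The segment-pair edge matrix is reported at feature-kind granularity
  (CDS, tRNA, rRNA, D-Loop, ORIL, Misc) or per-gene; tRNAs may be
  collapsed into one segment.
* Known limitation: with the variant-only filter off, columns sharing a
  carrier *partition* connect on both state sides; with it on, exactly
  one side survives. Which convention matches any given external
  dataset's published node counts cannot be decided from counts alone,
  which is why both are exposed as configuration.
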