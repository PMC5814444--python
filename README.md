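# conet-mito

Codon-labeled nucleotide co-occurrence networks for groups of aligned
genomes, with motif censuses and Erdős–Rényi null comparison.

## The problem

In a collection of aligned genomes from one population, some pairs of
variable positions mutate *together*: exactly the same genomes carry the
variant state at both positions. Such perfectly co-segregating pairs are
candidates for co-evolving sites. Given several genome groups (e.g.
continental human mtDNA collections aligned to the rCRS reference), this
package:

1. extracts each group's **variome** — the set of variable positions;
2. scores every state pair with the co-occurrence statistic
   `CO_ij = f(x_i y_j)² / (f(x_i) f(y_j))`, where `f` are occurrence
   frequencies over the group's `M` genomes; `CO = 1` exactly when the
   carriers of the two states are the same genomes;
3. builds one network per genome (`A_ij = 1` iff `CO_ij = 1` and the
   genome carries both states), so a group of `M` genomes yields `M`
   networks;
4. relabels nodes by **codon position** — 1, 2, 3 inside protein-coding
   genes by each gene's own reading frame, 0 elsewhere — and counts
   **TNMs** (edges outside any triangle; 10 label types) and **ThNMs**
   (triangles; 20 label types);
5. compares motif counts against matched Erdős–Rényi ensembles
   `G(N, p)` with `N = round(⟨N_Co⟩)`, `p = ⟨k⟩/N`, via empirical tail
   probabilities.

A packaged rCRS (NC_012920) feature table provides the human mtDNA gene
map; a synthetic generator plants co-segregation blocks with exact
ground truth so that every stage is testable without external data.

## Worked example

```python
from conet_mito import (
    continental_spec, generate, extract_variome, build_pair_table,
    build_genome_networks, group_network_summary, codon_labels,
)

spec = continental_spec(scale=0.01, seed=2018)   # five groups, M = 23..71
data = generate(spec)
labeling = codon_labels(data.annotation)

g = data.groups["AF"]
v = extract_variome(g)
table = build_pair_table(g, v)                    # variant-only CO pairs
networks = build_genome_networks(g, table, labeling)
print(v.n_sites, len(table.perfect_pairs), group_network_summary(networks))
```

prints

```
72 31 {'n_networks': 23, 'n_co_mean': 8.956521739130435, 'n_co_sd': 4.154392760205653,
'e_mean': 8.782608695652174, 'e_sd': 4.053517224628405, 'k_mean': 1.9611650485436891}
```

— the AF group has 72 variable sites, of which 31 state pairs
co-segregate perfectly (exactly the planted ground truth), and the 23
per-genome networks average ~9 nodes and ~9 edges, i.e. a group mean
degree `2⟨E⟩/⟨N_Co⟩ ≈ 2`, the signature of triangle-dominated sparse
networks.

The same flow is available as numbered analysis scripts
(`analysis/01_simulate.py` … `analysis/05_null_comparison.py`, writing
tables under `results/`) and as a CLI:

```bash
conet-mito simulate --scale 0.01 --seed 2018 --out scratch/synthetic
conet-mito run --manifest scratch/synthetic/groups.tsv \
    --annotation scratch/synthetic/features.tsv \
    --out scratch/run --seed 17 --null-reps 1000
```

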