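"""NJ phylogeny with bootstrap support from the 14-gene supermatrix."""

from mitocomp import (PHYLO_PCGS, SimulationConfig, bootstrap, codon_align,
                      concatenate, rf_distance, simulate)
from mitocomp.io_formats import parse_newick

cfg = SimulationConfig(seed=3, n_species=7, per_branch_sub_rate=0.03)
genomes, truth = simulate(cfg)

per_gene = [(gene, codon_align({g.species_id: g.cds(gene) for g in genomes}))
            for gene in PHYLO_PCGS]
supermatrix, boundaries = concatenate(per_gene)
print(f"supermatrix: {len(supermatrix)} species x {boundaries[-1]} columns "
      f"({len(boundaries)} genes)")

support_tree = bootstrap(supermatrix, n_reps=200, seed=1)
print(support_tree.newick().strip())
rf = rf_distance(support_tree.tree, parse_newick(truth.tree_newick))
print(f"Robinson-Foulds distance to the true tree: {rf}")
print()
print("Internal node labels are bootstrap percentages over 200 column-")
print("resampled NJ replicates; RF = 0 means the topology was recovered.")
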