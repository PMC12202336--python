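# mitocomp

Comparative analysis of fungal mitochondrial genomes, built for the kind of
study done on entomopathogenic *Cordyceps* species: a handful of circular,
AT-rich mitogenomes (~30–52 kb) that share a fixed gene complement — 15 core
protein-coding genes (PCGs), two rRNAs (*rns*, *rnl*), 25–27 tRNAs — but
differ enormously in size because mobile group-I introns are gained and lost
over short evolutionary timescales. `mitocomp` implements the full desk-side
analysis stack for such a dataset, plus a synthetic-mitogenome generator with
complete ground truth so that every stage can be validated end to end without
downloading anything.

## What it computes

**Composition.** Genome- and gene-level base composition with strand skews
AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C); a region partition that
assigns every nucleotide to exactly one of {PCG exon, rRNA, tRNA, intron,
free ORF, intergenic}; codon usage (counts, frequency per thousand, RSCU)
under the mold mitochondrial genetic code (translation table 4, where UGA
encodes tryptophan); a six-frame ORF census; and the intron-count vs
genome-size correlation (Pearson and Spearman with t-approximation p-values).

**Evolutionary rates.** Per-gene pairwise Kimura two-parameter distances,
d = −½·ln(1−2P−Q) − ¼·ln(1−2Q) with P/Q the transition/transversion
proportions, on codon-filtered alignments; and Nei–Gojobori (1986) Ka/Ks
with Jukes–Cantor correction under code 4, with multiple-hit codons resolved
by averaging over all stop-avoiding substitution pathways.

**Repeats.** MISA-style microsatellites (minimum copies: mono 10, di 5,
tri 4, tetra/penta/hexa 3); REPuter-style maximal dispersed repeats, forward
and palindromic, with Hamming distance ≤ 3 and length 30–5,000 nt; a
simplified tandem-array detector; and per-region repeat localization.

**Intron positional classes (Pcls).** Each intron is labelled by its
insertion coordinate in an intronless reference CDS ("P212" = inserted after
reference nucleotide 212), transferred through a global alignment of the
host-species CDS to the reference. Co-positional introns are clustered into
orthology groups by sequence identity; the resulting species × Pcl
presence/absence matrix feeds Dollo or Fitch parsimony reconstruction of
gain and loss events on a species tree.

**Phylogeny.** Codon-filtered alignments of the 14 core PCGs (all but
*rps3*) concatenated into a supermatrix; K2P distance matrix;
neighbor-joining with deterministic tie-breaks; nonparametric bootstrap;
Robinson–Foulds topology comparison.

**Synthetic data.** `simulate()` builds annotated circular genomes from a
configurable catalog of intron insertion sites, evolves them along a species
tree (per-branch K2P-style substitutions, purifying selection on PCGs,
internal-stop repair), plants repeats at recorded coordinates, and emits
GenBank files together with a `GroundTruth` record (true tree, Pcl matrix,
per-branch events, repeat coordinates, reference CDS set).

## Worked example

```bash
python examples/01_simulate_and_overview.py
```

prints, for a seven-species simulation at the default study conditions:

```
         length_bp gc_pct  at_skew  n_introns  intron_nt intron_pct
species
sp01         37682  29.14  -0.0156          7       6980      18.52
sp02         37712  27.75  -0.0192          7       7010      18.59
sp03         38822  28.98  -0.0168          8       8120      20.92
sp04         39147  28.76  -0.0181          9       8445      21.57
sp05         35962  28.88  -0.0172          6       5260      14.63
sp06         37702  28.49  -0.0131          7       7000      18.57
sp07         32582  27.30  -0.0139          2       1880       5.77
```

Genome length tracks the intron count: `intron_pct` is the fraction of the
circular genome occupied by group-I introns, the dominant driver of
mitogenome size variation in these fungi. The other examples cover codon
usage and rates (`02`), the repeat landscape (`03`), Pcl mapping with Dollo
gain/loss reconstruction (`04`), and the bootstrap phylogeny (`05`) — e.g.
`05` ends with

```
Robinson-Foulds distance to the true tree: 0
```

meaning the NJ tree from the 14-gene supermatrix exactly recovers the
simulated topology, with every internal edge at 100% bootstrap support.

A thin CLI wraps the same functions:
`mitocomp simulate|stats|codon|rates|repeats|introns|phylo|run` (see
`mitocomp --help`).

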