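# Methods

This note documents the models and procedures implemented in `mitocomp`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and coordinates

A `Mitogenome` is an annotated, usually circular DNA molecule linearized at
its deposited origin. Internal coordinates are 0-based half-open on the
forward strand; all reports and GenBank output are 1-based inclusive.
Features carry ascending-sorted interval parts; a feature crossing the
origin is stored as a two-part join with `wraps_origin=True`, written in the
GenBank `join(x..L,1..y)` dialect, and its coding sequence is assembled in
transcription order. Minus-strand feature sequence is the reverse complement
of the ascending-order part concatenation. Unknown bases (N) are excluded
from every composition denominator, which keeps skews well defined.

GenBank reading accepts introns encoded either as explicit `intron` features
or implicitly as gaps between CDS `join` parts; when both are present the
explicit feature (which can carry a group label) wins and any disagreement
about the parent gene is logged rather than silently resolved.

## Composition statistics

Skews follow the strand-asymmetry definitions AT-skew = (A−T)/(A+T),
GC-skew = (G−C)/(G+C) on integer base counts; a zero denominator raises
instead of returning NaN. The region partition assigns every position to
exactly one class with precedence PCG exon > rRNA > tRNA > intron > free ORF
> intergenic, so class totals always sum to the genome length exactly — the
conservation identity the simulator's own bookkeeping is checked against.
One consequence worth noting: nucleotides of an intron-borne ORF count as
*intron*, not free ORF.

Codon usage is counted on the coding strand including stop codons, under
translation table 4 (TGA = Trp; stops TAA/TAG), reported in the RNA
alphabet. RSCU for a codon is its count divided by the mean count of its
synonymous family; the two-codon stop family is included for completeness.
Frequency per thousand is the primary output; RSCU is a standard free extra.

The ORF census scans both strands in all three frames for ATG-initiated
open reading frames ending at TAA/TAG, keeps those of at least `min_nt`
(default 300 nt) that do not overlap any core-PCG exon, and flags ORFs fully
contained in introns. Within a frame segment only the 5'-most ATG opens an
ORF (later in-frame ATGs are shadowed).

Intron-count vs genome-size correlation: Pearson on raw values and Spearman
on mid-ranks, both with the two-sided t approximation at n−2 degrees of
freedom. With the seven-ish genomes typical of such studies the t
approximation is the honest choice; an exact permutation test would add
little at n = 7.

## Evolutionary rates

`codon_align` translates each CDS under code 4 (internal stops are a
per-gene error), globally aligns proteins with affine gaps and BLOSUM62
scoring (open −11, extend −1), and back-threads codons. For more than two
species an anchor projection is used: every species is aligned pairwise to a
deterministic anchor (longest protein, ties by species id) and only anchor
codon columns aligned gaplessly in every species are kept. This is a
deliberate simplification of a progressive MSA: it is deterministic,
oracle-testable against a full dynamic-programming score computation, and
adequate for the low-divergence, length-conserved core genes it is applied
to. Its known limitation is that columns inserted relative to the anchor are
invisible, which only discards data, never fabricates homology.

K2P distances use d = −½·ln(1−2P−Q) − ¼·ln(1−2Q); arguments of the
logarithms at or below zero raise a saturation error, and saturated pairs
are dropped from per-gene means (with the count of dropped pairs retained)
rather than imputed.

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous site fractions
(mutations to stop codons count as nonsynonymous, so S + N = 3 × codons
exactly), site counts averaged over both sequences, observed differences for
multiple-hit codons averaged over all minimal substitution pathways that
avoid stop codons (falling back to all pathways in the degenerate case where
every pathway is blocked), and Jukes–Cantor correction
K = −¾·ln(1 − 4p/3), undefined at p ≥ 3/4. Codon pairs containing a stop
codon (terminal TAA/TAG) are excluded from both site and difference
counting. NG86 was chosen over model-averaging Ka/Ks estimators because it
is fully deterministic and admits an independent brute-force oracle
(explicit pathway enumeration), which the test suite exercises; this is a
method substitution relative to likelihood-based dN/dS and is flagged as
such.

## Repeat detection

All three scanners run on the doubled sequence for circular genomes with
calls constrained to start in the first copy, which makes SSR output
invariant under rotation of the origin and prevents origin-split misses;
coordinates are reported modulo genome length.

**SSRs.** Maximal runs of a primitive 1–6 nt motif meeting the per-class
copy thresholds (mono 10, di 5, tri 4, tetra/penta/hexa 3). The reported
interval is the whole-copy prefix of the maximal run; the canonical motif is
the lexicographically smallest rotation. Compound (interrupted) repeats are
not merged, and overlapping SSRs of different motif classes are all
reported.

**Dispersed repeats.** Maximal repeated pairs — forward (sequence vs itself)
and palindromic (sequence vs its reverse complement) — with at most 3
mismatches and length 30–5,000 nt. Maximality means the pair can be extended
in neither direction without exceeding the mismatch budget; reported
intervals are additionally trimmed to start and end on matching positions,
so an exactly duplicated segment fenced by dense mismatches is reported with
0 mismatches. The scanner is seed-and-extend: every qualifying window must
contain an exact 7-mer match (pigeonhole: ⌈(30−3)/4⌉ = 7), so 7-mer seed
pairs grouped by diagonal, extended to the 4th mismatch on each side, and
enumerated via a sentinel window formula find exactly the maximal windows;
equivalence with a full quadratic diagonal-scan oracle is asserted on random
sequences. Windows longer than 5,000 nt are not reported (the "maximum
repeat size" filter); symmetric duplicates are removed by interval ordering
and identical-interval self-matches are excluded. The self-BLAST stage of
repeat discovery is folded into this detector — the length/mismatch bounds
replace an E-value cutoff for the same biological object.

**Tandem arrays.** A transparent simplification of Tandem Repeats Finder:
for each period p in [2, 100], exact self-matches at lag p seed candidate
arrays, which are extended position-by-position while running identity stays
≥ 0.85; calls need ≥ 1.9 copies. Two choices were made where the procedure
was underdetermined. First, a seed must be an exact run of at least
max(p, 14) matching comparisons: without a minimum seed, any chance "ATAT"
in a random sequence would qualify as a 2-copy dimer, and the detector would
be pure noise; 14 keeps the false-call rate on multi-kilobase random
sequences negligible while still detecting arrays of ≥ 2 perfect copies for
p ≤ 14. The practical consequence is that very short arrays (total length
below ~16 nt) are invisible to this detector. Second, candidate arrays whose
column-majority consensus is non-primitive (e.g. period 4 "ATAT") are
dropped, because the same array is detected at its true smaller period;
otherwise chance extension can let a composed period win the overlap
resolution. Overlapping calls are resolved greedily by highest
copies × period, ties by smaller period, then leftmost.

Repeat localization assigns each repeat (dispersed: its first interval) to
the region class holding the majority of its nucleotides, ties toward the
partition precedence order.

## Intron positional classes and gain/loss

The species CDS (exon concatenation) is globally aligned to the intronless
reference CDS with affine gaps (match +2, mismatch −3, open −5, extend −2);
identity below 0.3 over aligned columns marks the gene unalignable and all
its introns undetermined ("*"). The Pcl position is the 1-based reference
coordinate of the last aligned exon nucleotide 5' of the insertion point.
This convention is fixed and documented rather than inferred: published
Pcl labels never state their absolute convention, so labels here are
internally consistent but may differ from any particular publication's by
±1. If the flanking species coordinate falls in a reference gap, the nearest
aligned column 5' of it is used and the assignment is marked non-confident;
confidence additionally requires `min_flank` (default 15) aligned columns on
each side of the insertion.

Within each (gene, position) group, introns are single-linkage clustered at
pairwise global-alignment identity ≥ 0.7 computed over the shorter intron;
groups that split get suffixed labels (P100a, P100b). The matrix cell is
presence only for confident assignments; undetermined assignments are shown
as "*" and excluded from gain/loss input rather than treated as absence.
Pcls observed in a single species are visible directly in the matrix as
single-presence columns; no cross-dataset search for horizontal transfer is
attempted.

Gain/loss reconstruction offers two modes. Dollo: one gain on the branch
above the MRCA of all presence tips, plus one loss on the root branch of
every maximal presence-free subtree below it. Fitch: two-pass parsimony with
ties resolved toward absence (loss preferred over parallel gain); when the
root resolves to "present" the gain is recorded on the root stem. Both
satisfy the replay identity — applying the reconstructed events along the
tree reproduces the tip pattern exactly — which is property-tested on random
matrices. Undetermined tips are treated as unconstrained (they never force a
loss and never count as presence).

## Phylogeny stage

The phylogeny uses the 14 core PCGs (rps3, the fast-evolving ribosomal
protein gene, is excluded from the tree but kept in the rate tables,
matching the two different gene lists such studies use). Codon-filtered
per-gene alignments are concatenated; pairwise K2P distances feed classic
neighbor-joining with the Q criterion, deterministic lexicographic
tie-breaks, and negative branch lengths clamped to zero with the subtracted
amount moved to the sibling edge. The final agglomeration attaches the last
node to the internal survivor, so for three taxa the pendant branch lengths
solve the three-point equations exactly. Bootstrap support is the percentage
of column-resampled NJ replicates containing each bipartition; replicates
with a saturated (undefined) distance are dropped and counted. ML and
Bayesian inference are intentionally out of scope: NJ + bootstrap is the
desk-scale, deterministic, oracle-testable stand-in, and no convergence
diagnostics apply to it. Robinson–Foulds distance is the symmetric
difference of non-trivial unrooted bipartitions.

## Synthetic-genome generator

The generator's defaults are the study conditions: seven species, 74% AT,
15 PCGs with realistic lengths (atp8 147 nt … nad5 1,980 nt), rnl/rns, 25
tRNAs of 71–85 nt, geometric intergenic spacers of mean 200 nt (exposed in
config — real spacer length distributions are not characterized well enough
to claim more), and a 23-entry intron catalog concentrated on cox1 and cob
with two rnl introns and one rns intron, groups drawn from {IA, IB, IC1,
IC2, ID}. With the default random Dollo-consistent histories (gain branch
uniform, per-branch loss probability 0.22) species carry roughly 2–12
introns and genomes span ~30–42 kb; pushing `loss_rate` to 0 and widening
spacers reaches the ~52 kb end of the size range.

Evolution along the tree applies per-branch substitutions at
`per_branch_sub_rate` (default 0.02 substitutions/site per branch; branch
lengths shape the topology only), with transitions favored
kappa/(kappa+2) : 2/(kappa+2), kappa = 2. PCGs keep their start/stop codons
fixed; internal stops created by mutation are repaired by resampling the
affected codon, and amino-acid-changing codons are retained with probability
`nonsyn_acceptance` (default 0.3), a crude but effective purifying-selection
filter that yields Ka/Ks < 1 for every gene — the qualitative signature of
core mitochondrial PCGs. Introns are created at their gain branch as AT-rich
random sequence, optionally (probability 0.5, length permitting) carrying a
≥ 300 nt LAGLIDADG-like or GIY-YIG-like homing-endonuclease ORF, and then
evolve like any other sequence (intron ORFs are not stop-repaired, so at
high divergence they can decay — as real homing endonucleases do). Planted
repeats are written into spacer or intron sequences at tip assembly, after
mutation, so their recorded coordinates and content are exact.

What the generator does not emulate: codon-usage bias fitted to real
genomes, realistic intron secondary structure, recombination, gene-order
rearrangement, or sequencing error. Tests passing on this synthetic data
therefore validate the algorithms' correctness and calibration under the
stated model, not robustness to annotation noise or assembly artifacts in
real submissions.

All randomness flows from the single config seed through named
`SeedSequence` streams (ancestor, tree, history, evolution), so identical
configs give byte-identical GenBank bundles across runs; the full report
pipeline is likewise byte-deterministic under a fixed seed.

## Numerical and formatting conventions

Percentages in reports are rounded half-up to 2 decimals, skews to 4;
statistics are kept at full double precision in memory. Correlation and rate
computations use exact integer counts before any division. Problem sizes in
the acceptance script (10 Pcl-recovery simulations of 7 species, 200 Dollo
replays, 20 NJ recoveries, 200 bootstrap replicates on 9 taxa) were chosen
as the smallest sets at which the recovery rates are stable to re-seeding.

## Known limitations

- Anchor-projection codon alignment discards columns absent from the anchor.
- The tandem detector cannot see arrays shorter than its exact seed
  (~16 nt total), and its identity model is running identity, not an
  alignment score.
- Pcl transfer assumes length-conserved, alignable exons; genes with heavy
  indel turnover near insertion sites will yield non-confident assignments.
- The origin-wrap representation supports two-part joins (one wrap point);
  wrap joins with additional introns are not modeled.
- Dollo reconstruction treats undetermined ("*") states as unconstrained,
  which is the conservative choice but can underestimate losses.
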