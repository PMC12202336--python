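"""Per-gene pairwise evolutionary rates.

Kimura two-parameter (K2P) distances separate transition (P) and transversion
(Q) proportions: d = −½·ln(1−2P−Q) − ¼·ln(1−2Q). Nonsynonymous/synonymous
rates use the Nei–Gojobori (1986) counting method with Jukes–Cantor
correction under genetic code 4: site fractions per codon position, observed
differences averaged over all minimal substitution pathways that avoid stop
codons, then K = −¾·ln(1 − 4p/3).

Multi-species codon alignments are built by anchor projection: every species'
protein (code 4) is globally aligned to a deterministic anchor with affine
gaps and BLOSUM62 scoring, and only anchor codon columns aligned gaplessly in
all species are kept, back-threaded to nucleotides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .model import CORE_PCGS, GENETIC_CODE_4, STOP_CODONS_4, Mitogenome, translate_code4

log = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Observed divergence exceeds the model's valid domain."""


class GeneAlignmentError(ValueError):
    """A gene cannot be codon-aligned (e.g. internal stop codon)."""


@dataclass(frozen=True)
class DistancePair:
    gene: str
    species_a: str
    species_b: str
    sites: int
    P: float
    Q: float
    k2p: float


@dataclass(frozen=True)
class KaKsPair:
    gene: str
    species_a: str
    species_b: str
    codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    Ka: float | None
    Ks: float | None
    ka_ks: float | None


# ---------------------------------------------------------------------------
# Codon alignment


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _codons(cds: str) -> list[str]:
    if len(cds) % 3:
        raise GeneAlignmentError(f"CDS length {len(cds)} not a multiple of 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def codon_align(gene_cds_by_species: dict[str, str]) -> dict[str, str]:
    """Gapless codon-aligned nucleotide matrix across species.

    Raises GeneAlignmentError if any CDS carries an internal stop codon.
    Columns where any species has a gap relative to the anchor are dropped,
    so all returned rows have equal length (a multiple of 3) and no gaps.
    """
    if len(gene_cds_by_species) < 2:
        raise ValueError("need at least two species")
    codons = {sp: _codons(cds) for sp, cds in gene_cds_by_species.items()}
    prots = {}
    for sp, cods in codons.items():
        aa = "".join(GENETIC_CODE_4[c] for c in cods)
        if "*" in aa[:-1]:
            raise GeneAlignmentError(f"{sp}: internal stop codon")
        prots[sp] = aa
    # deterministic anchor: longest protein, ties by species id
    anchor = min(prots, key=lambda sp: (-len(prots[sp]), sp))
    aligner = _protein_aligner()
    maps: dict[str, dict[int, int]] = {}
    for sp, aa in prots.items():
        if sp == anchor:
            maps[sp] = {i: i for i in range(len(aa))}
            continue
        aln = aligner.align(prots[anchor], aa)[0]
        m: dict[int, int] = {}
        for (ts, te), (qs, qe) in zip(*aln.aligned):
            for k in range(te - ts):
                m[ts + k] = qs + k
        maps[sp] = m
    kept = [i for i in range(len(prots[anchor]))
            if all(i in m for m in maps.values())]
    return {sp: "".join(codons[sp][maps[sp][i]] for i in kept)
            for sp in gene_cds_by_species}


# ---------------------------------------------------------------------------
# K2P

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p(seq_a: str, seq_b: str, gene: str = "", species_a: str = "a",
        species_b: str = "b") -> DistancePair:
    """Kimura two-parameter distance between equal-length gapless sequences.

    Sites containing N in either sequence are excluded. Raises
    SaturationError when 1−2P−Q ≤ 0 or 1−2Q ≤ 0.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if not seq_a:
        raise ValueError("empty sequences")
    sites = ts = tv = 0
    for x, y in zip(seq_a, seq_b):
        if x == "N" or y == "N":
            continue
        sites += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / sites, tv / sites
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"{gene} {species_a}/{species_b}: K2P undefined (P={P:.3f}, Q={Q:.3f})")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistancePair(gene=gene, species_a=species_a, species_b=species_b,
                        sites=sites, P=P, Q=Q, k2p=d)


# ---------------------------------------------------------------------------
# NG86

_BASES = "ACGT"


def _syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3), code 4.

    Mutations producing a stop codon count as nonsynonymous, so the
    synonymous + nonsynonymous site totals of a codon sum to exactly 3.
    """
    aa = GENETIC_CODE_4[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE_4[alt] == aa:
                syn += 1
    return syn / 3.0


_SYN_SITES = {c: _syn_fraction(c) for c in GENETIC_CODE_4 if c not in STOP_CODONS_4}


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts between two codons
    over all minimal substitution pathways, excluding pathways that pass
    through a stop codon (all-pathway average if every pathway is blocked)."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    results: list[tuple[int, int, bool]] = []  # (sd, nd, passes_stop)
    for order in permutations(diff):
        cur, sd, nd, blocked = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS_4 and nxt != cb:
                blocked = True
            if GENETIC_CODE_4[nxt] == GENETIC_CODE_4[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, blocked))
    valid = [(s, n) for s, n, b in results if not b]
    if not valid:
        valid = [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4.0 * p / 3.0)


def ng86(codon_aln_a: str, codon_aln_b: str, gene: str = "",
         species_a: str = "a", species_b: str = "b") -> KaKsPair:
    """Nei–Gojobori (1986) Ka/Ks between two gapless codon-aligned sequences.

    Codon pairs where either codon is a stop (terminal TAA/TAG) are excluded
    from site and difference counting. Site counts are averaged over both
    sequences; undefined Jukes–Cantor corrections yield None.
    """
    if len(codon_aln_a) != len(codon_aln_b) or len(codon_aln_a) % 3:
        raise ValueError("inputs must be equal-length codon alignments")
    S = N = Sd = Nd = 0.0
    ncod = 0
    for i in range(0, len(codon_aln_a), 3):
        ca, cb = codon_aln_a[i:i + 3], codon_aln_b[i:i + 3]
        if ca in STOP_CODONS_4 or cb in STOP_CODONS_4:
            continue
        if "N" in ca or "N" in cb:
            continue
        ncod += 1
        s = (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0
        S += s
        N += 3.0 - s
        if ca != cb:
            sd, nd = _pathway_counts(ca, cb)
            Sd += sd
            Nd += nd
    if ncod == 0:
        raise ValueError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jc_correct(pS)
    Ka = _jc_correct(pN)
    if Ka is None or Ks is None:
        log.warning("%s %s/%s: JC correction undefined (pN=%.3f pS=%.3f)",
                    gene, species_a, species_b, pN, pS)
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsPair(gene=gene, species_a=species_a, species_b=species_b,
                    codons=ncod, S=S, N=N, Sd=Sd, Nd=Nd, Ka=Ka, Ks=Ks,
                    ka_ks=ratio)


# ---------------------------------------------------------------------------
# Per-gene aggregation


def aggregate_rates(k2p_pairs: list[DistancePair], kaks_pairs: list[KaKsPair],
                    gene_order: tuple[str, ...] = CORE_PCGS) -> pd.DataFrame:
    """Per-gene means of K2P / Ka / Ks / Ka-Ks over all defined species pairs.

    Means are taken over defined pairs only; the number of contributing pairs
    is recorded per statistic. Genes without any defined pair get NaN rows.
    """
    rows = []
    for gene in gene_order:
        ks = [p.k2p for p in k2p_pairs if p.gene == gene]
        ka_vals = [p.Ka for p in kaks_pairs if p.gene == gene and p.Ka is not None]
        ks_vals = [p.Ks for p in kaks_pairs if p.gene == gene and p.Ks is not None]
        ratios = [p.ka_ks for p in kaks_pairs if p.gene == gene and p.ka_ks is not None]
        rows.append({
            "gene": gene,
            "mean_k2p": float(np.mean(ks)) if ks else np.nan,
            "n_k2p_pairs": len(ks),
            "mean_ka": float(np.mean(ka_vals)) if ka_vals else np.nan,
            "mean_ks": float(np.mean(ks_vals)) if ks_vals else np.nan,
            "mean_ka_ks": float(np.mean(ratios)) if ratios else np.nan,
            "n_kaks_pairs": len(ratios),
        })
    return pd.DataFrame(rows).set_index("gene")


def gene_rates(genomes: list[Mitogenome],
               genes: tuple[str, ...] = CORE_PCGS,
               ) -> tuple[list[DistancePair], list[KaKsPair], pd.DataFrame]:
    """Codon-align each gene across all genomes and compute all pairwise
    K2P and NG86 statistics plus the per-gene aggregate table.

    Genes that fail codon alignment and species pairs at saturation are
    dropped (logged), never imputed.
    """
    d_pairs: list[DistancePair] = []
    k_pairs: list[KaKsPair] = []
    for gene in genes:
        cds_map = {}
        for g in genomes:
            try:
                cds_map[g.species_id] = g.cds(gene)
            except KeyError:
                log.warning("%s: gene %s missing", g.species_id, gene)
        if len(cds_map) < 2:
            continue
        try:
            aln = codon_align(cds_map)
        except GeneAlignmentError as exc:
            log.warning("gene %s excluded: %s", gene, exc)
            continue
        for a, b in combinations(sorted(aln), 2):
            try:
                d_pairs.append(k2p(aln[a], aln[b], gene, a, b))
            except SaturationError as exc:
                log.warning("%s", exc)
            k_pairs.append(ng86(aln[a], aln[b], gene, a, b))
    return d_pairs, k_pairs, aggregate_rates(d_pairs, k_pairs, genes)
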