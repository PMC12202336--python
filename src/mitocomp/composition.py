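"""Nucleotide composition, skews, region partition, codon usage, ORF census,
and the intron-count vs genome-size correlation.

Skews follow the strand-asymmetry definitions AT-skew = (A−T)/(A+T) and
GC-skew = (G−C)/(G+C) computed on base counts; unknown bases (N) are excluded
from every denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import (CORE_PCGS, GENETIC_CODE_4, STOP_CODONS_4, Feature,
                    Mitogenome, revcomp)

REGION_CLASSES = ("PCG_exon", "rRNA", "tRNA", "intron", "free_orf", "intergenic")
# precedence when intervals overlap: earlier class wins
_REGION_PRECEDENCE = ("PCG_exon", "rRNA", "tRNA", "intron", "free_orf")


class DomainError(ValueError):
    """A statistic is undefined for the given input (e.g. zero denominator)."""


@dataclass(frozen=True)
class SkewStats:
    """Base counts of a sequence; skews raise (never NaN) when undefined."""

    length: int
    a: int
    c: int
    g: int
    t: int

    @property
    def gc_fraction(self) -> float:
        total = self.a + self.c + self.g + self.t
        if total == 0:
            raise DomainError("composition undefined: no unambiguous bases")
        return (self.g + self.c) / total

    @property
    def at_skew(self) -> float:
        if self.a + self.t == 0:
            raise DomainError("AT-skew undefined: A + T = 0")
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float:
        if self.g + self.c == 0:
            raise DomainError("GC-skew undefined: G + C = 0")
        return (self.g - self.c) / (self.g + self.c)


def skew_stats(sequence: str) -> SkewStats:
    """Composition statistics of a DNA string (N excluded from denominators)."""
    if not sequence:
        raise DomainError("empty sequence")
    counts = Counter(sequence.upper())
    return SkewStats(length=len(sequence), a=counts["A"], c=counts["C"],
                     g=counts["G"], t=counts["T"])


def region_partition(genome: Mitogenome) -> dict[str, int]:
    """Assign every genome position to exactly one region class.

    Precedence on overlap: PCG_exon > rRNA > tRNA > intron > free_orf >
    intergenic. Totals sum exactly to genome length.
    """
    n = len(genome.sequence)
    codes = np.full(n, len(REGION_CLASSES) - 1, dtype=np.int8)  # intergenic
    kind_to_class = {"PCG": "PCG_exon", "rRNA": "rRNA", "tRNA": "tRNA",
                     "intron": "intron", "orf": "free_orf"}
    # paint lowest precedence first so higher classes overwrite
    for cls in reversed(_REGION_PRECEDENCE):
        idx = REGION_CLASSES.index(cls)
        for f in genome.features:
            if kind_to_class[f.kind] != cls:
                continue
            for s, e in f.parts:
                codes[s:e] = idx
    counts = np.bincount(codes, minlength=len(REGION_CLASSES))
    return {cls: int(counts[i]) for i, cls in enumerate(REGION_CLASSES)}


def region_class_array(genome: Mitogenome) -> np.ndarray:
    """Per-position region class indices (into REGION_CLASSES)."""
    n = len(genome.sequence)
    codes = np.full(n, len(REGION_CLASSES) - 1, dtype=np.int8)
    kind_to_class = {"PCG": "PCG_exon", "rRNA": "rRNA", "tRNA": "tRNA",
                     "intron": "intron", "orf": "free_orf"}
    for cls in reversed(_REGION_PRECEDENCE):
        idx = REGION_CLASSES.index(cls)
        for f in genome.features:
            if kind_to_class[f.kind] != cls:
                continue
            for s, e in f.parts:
                codes[s:e] = idx
    return codes


# ---------------------------------------------------------------------------
# Codon usage (genetic code 4)

ALL_CODONS = tuple(a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG")
_FAMILY: dict[str, list[str]] = {}
for _cod in ALL_CODONS:
    _FAMILY.setdefault(GENETIC_CODE_4[_cod], []).append(_cod)


def _rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass
class CodonUsageTable:
    """Codon counts, per-thousand frequencies and RSCU under genetic code 4.

    Codons are reported in the RNA alphabet. RSCU for a codon is its count
    divided by the mean count of its synonymous family (1.0 for every member
    of an equally used family).
    """

    counts: dict[str, int]
    freq_per_thousand: dict[str, float]
    rscu: dict[str, float]
    start_codons: dict[tuple[str, str], str] = field(default_factory=dict)
    stop_codons: dict[tuple[str, str], str] = field(default_factory=dict)
    skipped_genes: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


def codon_usage(genomes: list[Mitogenome], genes: tuple[str, ...] | None = None
                ) -> CodonUsageTable:
    """Codon usage over the protein-coding genes of one or more genomes.

    Codons are counted on the coding strand 5'->3', stop codons included.
    Genes whose CDS length is not a multiple of 3 are skipped and recorded.
    """
    counts: Counter[str] = Counter()
    starts: dict[tuple[str, str], str] = {}
    stops: dict[tuple[str, str], str] = {}
    skipped: list[tuple[str, str]] = []
    for g in genomes:
        for f in g.features_of_kind("PCG"):
            if genes is not None and f.name not in genes:
                continue
            cds = g.feature_sequence(f)
            if len(cds) % 3:
                skipped.append((g.species_id, f.name))
                continue
            codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
            counts.update(codons)
            starts[(g.species_id, f.name)] = _rna(codons[0])
            stops[(g.species_id, f.name)] = _rna(codons[-1])
    table = {c: counts.get(c, 0) for c in ALL_CODONS}
    total = sum(table.values())
    freq = {_rna(c): (1000.0 * n / total if total else 0.0) for c, n in table.items()}
    rscu: dict[str, float] = {}
    for fam in _FAMILY.values():
        fam_total = sum(table[c] for c in fam)
        for c in fam:
            rscu[_rna(c)] = (len(fam) * table[c] / fam_total) if fam_total else 0.0
    return CodonUsageTable(
        counts={_rna(c): n for c, n in table.items()},
        freq_per_thousand=freq, rscu=rscu,
        start_codons=starts, stop_codons=stops, skipped_genes=skipped)


# ---------------------------------------------------------------------------
# ORF census


@dataclass(frozen=True)
class OrfRecord:
    start: int          # forward-strand genome coordinates, half-open
    end: int
    strand: str
    length: int
    intronic: bool


def _frame_orfs(seq: str, min_nt: int) -> list[tuple[int, int]]:
    """ATG..stop spans (half-open, in `seq` coordinates), code 4, per frame."""
    out = []
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i:i + 3] == "ATG":
                j = i + 3
                while j + 3 <= n and seq[j:j + 3] not in STOP_CODONS_4:
                    j += 3
                if j + 3 <= n:  # found a stop
                    if j + 3 - i >= min_nt:
                        out.append((i, j + 3))
                    i = j + 3
                    continue
                else:
                    break
            i += 3
    return out


def orf_census(genome: Mitogenome, min_nt: int = 300) -> list[OrfRecord]:
    """Scan both strands, all three frames, for ORFs (ATG .. TAA/TAG, code 4)
    of at least `min_nt` nt that do not overlap core-PCG exons; ORFs fully
    inside an intron are flagged intronic."""
    n = len(genome.sequence)
    exon_mask = np.zeros(n, dtype=bool)
    for f in genome.features_of_kind("PCG"):
        for s, e in f.parts:
            exon_mask[s:e] = True
    intron_mask = np.zeros(n, dtype=bool)
    for f in genome.features_of_kind("intron"):
        for s, e in f.parts:
            intron_mask[s:e] = True

    records: list[OrfRecord] = []
    for strand in "+-":
        seq = genome.sequence if strand == "+" else revcomp(genome.sequence)
        for s, e in _frame_orfs(seq, min_nt):
            gs, ge = (s, e) if strand == "+" else (n - e, n - s)
            if exon_mask[gs:ge].any():
                continue
            records.append(OrfRecord(start=gs, end=ge, strand=strand,
                                     length=e - s,
                                     intronic=bool(intron_mask[gs:ge].all())))
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return records


# ---------------------------------------------------------------------------
# Intron count vs genome size correlation


def intron_size_correlation(points: list[tuple[int, int]]
                            ) -> tuple[float, float, float, float]:
    """Pearson and Spearman correlation between intron count and genome size.

    Returns (pearson_r, pearson_p, spearman_rho, spearman_p). P-values use
    the t approximation with n−2 degrees of freedom; Spearman uses mid-ranks
    (average ranks on ties).
    """
    if len(points) < 3:
        raise DomainError("need at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("zero variance in one coordinate")
    n = len(x)

    def _t_p(r: float) -> float:
        if abs(r) >= 1.0:
            return 0.0
        t = r * np.sqrt((n - 2) / (1 - r * r))
        return float(2 * stats.t.sf(abs(t), df=n - 2))

    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return r, _t_p(r), rho, _t_p(rho)
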