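"""Shared genomic data model for annotated circular mitochondrial genomes.

Internal coordinates are 0-based half-open on the forward strand of the
linearized circle; reports and GenBank output use 1-based inclusive
coordinates. Features crossing the origin are stored as two-part joins and
length computations sum the parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

# The 15 core protein-coding genes of hypocrealean mitogenomes.
CORE_PCGS = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
)
# The 14-gene set used for phylogeny (rps3 excluded).
PHYLO_PCGS = tuple(g for g in CORE_PCGS if g != "rps3")
RRNA_GENES = ("rns", "rnl")
INTRON_GROUPS = ("IA", "IB", "IC1", "IC2", "ID", "II", "unknown")

FEATURE_KINDS = ("PCG", "rRNA", "tRNA", "orf", "intron")

# Mold/protozoan mitochondrial genetic code (transl_table=4): UGA encodes Trp.
_TABLE4 = CodonTable.unambiguous_dna_by_id[4]
GENETIC_CODE_4: dict[str, str] = dict(_TABLE4.forward_table)
STOP_CODONS_4: frozenset[str] = frozenset(_TABLE4.stop_codons)  # {TAA, TAG}
for _stop in STOP_CODONS_4:
    GENETIC_CODE_4[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_code4(cds: str) -> str:
    """Translate a DNA string under genetic code 4 ('*' for TAA/TAG)."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    return "".join(GENETIC_CODE_4[cds[i:i + 3]] for i in range(0, len(cds), 3))


class IntegrityError(ValueError):
    """A genome or feature violates a structural invariant."""


@dataclass
class Feature:
    """A typed annotation on a mitogenome.

    parts are half-open 0-based intervals in ascending coordinate order;
    for minus-strand features the coding sequence is the reverse complement
    of the ascending-order concatenation.
    """

    kind: str
    name: str
    strand: str = "+"
    parts: list[tuple[int, int]] = field(default_factory=list)
    intron_group: str | None = None  # intron kind only
    parent_gene: str | None = None   # intron kind only
    note: str | None = None
    wraps_origin: bool = False       # feature crosses the circular origin

    def transcription_parts(self) -> list[tuple[int, int]]:
        """Parts in 5'->3' template order on the forward strand: ascending,
        except that an origin-crossing feature starts at its last interval."""
        if self.wraps_origin and len(self.parts) > 1:
            return [self.parts[-1]] + self.parts[:-1]
        return list(self.parts)

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def validate(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise IntegrityError(f"{self.name}: unknown feature kind {self.kind!r}")
        if not self.parts:
            raise IntegrityError(f"{self.name}: empty parts")
        if self.strand not in "+-":
            raise IntegrityError(f"{self.name}: bad strand {self.strand!r}")
        for s, e in self.parts:
            if not (0 <= s < e):
                raise IntegrityError(f"{self.name}: bad interval ({s}, {e})")
        for (_, e1), (s2, _) in zip(self.parts, self.parts[1:]):
            if s2 < e1:
                raise IntegrityError(f"{self.name}: overlapping parts")
        if self.intron_group is not None and self.intron_group not in INTRON_GROUPS:
            raise IntegrityError(f"{self.name}: unknown intron group {self.intron_group!r}")


@dataclass
class Mitogenome:
    """An annotated (usually circular) mitochondrial genome."""

    species_id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def sort_features(self) -> None:
        """Sort by start coordinate; ties keep insertion order (stable)."""
        self.features.sort(key=lambda f: f.start)

    def feature_sequence(self, feature: Feature) -> str:
        """Concatenated part sequence (origin-aware), reverse-complemented on
        the minus strand."""
        s = "".join(self.sequence[a:b]
                    for a, b in feature.transcription_parts())
        return revcomp(s) if feature.strand == "-" else s

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def gene(self, name: str, kind: str = "PCG") -> Feature:
        for f in self.features:
            if f.kind == kind and f.name == name:
                return f
        raise KeyError(f"{self.species_id}: no {kind} feature named {name!r}")

    def introns_of(self, gene: str) -> list[Feature]:
        return [f for f in self.features if f.kind == "intron" and f.parent_gene == gene]

    def cds(self, gene: str) -> str:
        """Exon-concatenated coding sequence of a PCG, 5'->3'."""
        return self.feature_sequence(self.gene(gene))

    def validate(self, check_translation: bool = True) -> None:
        n = len(self.sequence)
        if n < 1:
            raise IntegrityError(f"{self.species_id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise IntegrityError(f"{self.species_id}: non-ACGTN characters {sorted(bad)}")
        for f in self.features:
            f.validate()
            if f.end > n:
                raise IntegrityError(
                    f"{self.species_id}/{f.name}: feature extends past sequence end"
                )
        for f1, f2 in zip(self.features, self.features[1:]):
            if f1.start > f2.start:
                raise IntegrityError(f"{self.species_id}: features not sorted by start")
        if check_translation:
            for f in self.features_of_kind("PCG"):
                cds = self.feature_sequence(f)
                if len(cds) % 3:
                    raise IntegrityError(
                        f"{self.species_id}/{f.name}: CDS length {len(cds)} not multiple of 3"
                    )
                aa = translate_code4(cds)
                if "*" in aa[:-1]:
                    raise IntegrityError(
                        f"{self.species_id}/{f.name}: internal stop codon in CDS"
                    )
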