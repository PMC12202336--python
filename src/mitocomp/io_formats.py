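"""Reading and writing the standard formats the pipeline touches.

GenBank flat files (single record, joined CDS locations, transl_table=4),
multi-FASTA, and Newick trees. GenBank coordinates (1-based inclusive) are
converted to/from the internal 0-based half-open convention by Biopython.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import CORE_PCGS, RRNA_GENES, Feature, IntegrityError, Mitogenome

log = logging.getLogger(__name__)

_GB_DATE = "01-JAN-2000"  # fixed so byte output is deterministic


class ParseError(ValueError):
    """A file could not be parsed into the data model."""


# ---------------------------------------------------------------------------
# GenBank


def _feature_kind(ftype: str, name: str, note: str) -> str:
    if ftype == "rRNA":
        return "rRNA"
    if ftype == "tRNA":
        return "tRNA"
    if ftype == "intron":
        return "intron"
    if ftype == "CDS":
        if name in CORE_PCGS and "free-standing" not in note:
            return "PCG"
        return "orf"
    raise ParseError(f"unsupported feature type {ftype!r} for {name!r}")


def _location_parts(loc) -> list[tuple[int, int]]:
    parts = [(int(p.start), int(p.end)) for p in loc.parts]
    parts.sort()
    return parts


def read_genbank(path: str | Path) -> Mitogenome:
    """Read a single-record GenBank flat file into a Mitogenome.

    CDS ``join(...)`` locations become multi-part PCG features; the gaps
    between consecutive CDS parts of the same gene become intron features
    (attached via ``parent_gene``) unless an explicit intron feature already
    covers the same interval, in which case the explicit annotation (which
    may carry a group label) wins and any disagreement is logged, not
    silently resolved.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    seq = str(record.seq).upper()
    circular = record.annotations.get("topology", "linear") == "circular"
    genome = Mitogenome(species_id=record.id, sequence=seq, circular=circular)

    explicit_introns: dict[tuple[int, int], Feature] = {}
    cds_feats: list[Feature] = []
    for sf in record.features:
        if sf.type in ("source", "gene"):
            continue
        quals = sf.qualifiers
        name = (quals.get("gene") or quals.get("label") or [sf.type])[0]
        note = "; ".join(quals.get("note", []))
        try:
            kind = _feature_kind(sf.type, name, note)
        except ParseError:
            continue  # features outside the model (misc_feature etc.)
        strand = "-" if sf.location.strand == -1 else "+"
        raw_starts = [int(p.start) for p in sf.location.parts]
        wraps = strand == "+" and len(raw_starts) > 1 and \
            raw_starts != sorted(raw_starts)
        parts = _location_parts(sf.location)
        feat = Feature(kind=kind, name=name, strand=strand, parts=parts,
                       note=note or None, wraps_origin=wraps)
        if kind == "intron":
            feat.parent_gene = (quals.get("gene") or [None])[0]
            rest = []
            for token in note.split(";"):
                token = token.strip()
                if token.startswith("group="):
                    feat.intron_group = token[len("group="):]
                elif token.startswith("name="):
                    feat.name = token[len("name="):]
                elif token:
                    rest.append(token)
            feat.note = "; ".join(rest) or None
            explicit_introns[(feat.start, feat.end)] = feat
            genome.features.append(feat)
        else:
            if kind in ("PCG", "orf"):
                cds_feats.append(feat)
            genome.features.append(feat)

    # derive introns from CDS joins, reconciling with explicit intron features.
    # Gaps are taken between transcription-consecutive location parts, which
    # skips the wrap point of an origin-crossing join.
    for sf, feat in zip((s for s in record.features if s.type == "CDS"), cds_feats):
        if feat.kind != "PCG":
            continue
        raw = [(int(p.start), int(p.end)) for p in sf.location.parts]
        if feat.strand == "-" and raw and raw[0][0] > raw[-1][0]:
            raw = raw[::-1]
        for (s1, e1), (s2, _) in zip(raw, raw[1:]):
            if s2 < e1:
                continue  # origin wrap, not an intron
            key = (e1, s2)
            if key in explicit_introns:
                ex = explicit_introns[key]
                if ex.parent_gene not in (None, feat.name):
                    log.warning(
                        "%s: intron at %d..%d claims parent %s but lies inside CDS %s",
                        record.id, e1 + 1, s2, ex.parent_gene, feat.name)
                ex.parent_gene = ex.parent_gene or feat.name
            else:
                genome.features.append(Feature(
                    kind="intron", name=f"{feat.name}-intron",
                    strand=feat.strand, parts=[(e1, s2)], parent_gene=feat.name))

    genome.sort_features()
    try:
        genome.validate(check_translation=False)
    except IntegrityError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return genome


def _to_location(feature: Feature) -> SimpleLocation | CompoundLocation:
    st = -1 if feature.strand == "-" else 1
    parts = feature.transcription_parts()
    locs = [SimpleLocation(s, e, strand=st) for s, e in parts]
    if len(locs) == 1:
        return locs[0]
    if feature.strand == "-" and not feature.wraps_origin:
        locs = locs[::-1]
    return CompoundLocation(locs)


def write_genbank(genome: Mitogenome, path: str | Path) -> None:
    """Write a Mitogenome as a standard GenBank flat file (deterministic)."""
    record = SeqRecord(
        Seq(genome.sequence), id=genome.species_id, name=genome.species_id[:16],
        description=f"{genome.species_id} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "data_file_division": "PLN",
            "date": _GB_DATE,
        },
    )
    record.features.append(SeqFeature(
        SimpleLocation(0, len(genome.sequence)), type="source",
        qualifiers={"organism": [genome.species_id]}))
    for f in genome.features:
        loc = _to_location(f)
        quals: dict[str, list[str]] = {"gene": [f.parent_gene or f.name]}
        if f.kind == "PCG":
            quals["transl_table"] = ["4"]
            ftype = "CDS"
        elif f.kind == "orf":
            quals["transl_table"] = ["4"]
            quals["note"] = [f.note or "free-standing ORF"]
            ftype = "CDS"
        elif f.kind == "intron":
            ftype = "intron"
            note = f"name={f.name}"
            if f.intron_group:
                note += f"; group={f.intron_group}"
            if f.note:
                note += f"; {f.note}"
            quals["note"] = [note]
        else:
            ftype = f.kind
        if f.kind not in ("intron", "orf") and f.note:
            quals["note"] = [f.note]
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


# ---------------------------------------------------------------------------
# FASTA

_VALID_NT = set("ACGTNRYSWKMBDHV")  # IUPAC nucleotide codes


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-FASTA file; IDs kept verbatim up to the first whitespace,
    sequences uppercased. An empty file yields an empty list."""
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            for i, ch in enumerate(seq):
                if ch not in _VALID_NT:
                    raise ParseError(
                        f"{path}: record {rec.id!r} has non-IUPAC character "
                        f"{ch!r} at position {i + 1}")
            records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, wrap: int = 70) -> None:
    """Write records as multi-FASTA wrapped at `wrap` columns."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted tree from a Newick file; support values are retained as
    internal node labels. Duplicate leaf labels are rejected."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"{path}: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ParseError(f"{path}: duplicate leaf labels")
    tree.is_rooted = True
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string (same semantics as read_newick)."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ParseError("duplicate leaf labels")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))
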