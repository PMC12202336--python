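"""Group-I intron positional classes (Pcls) and gain/loss reconstruction.

Each intron is mapped to a positional class defined by its insertion
coordinate in an intronless reference coding sequence: the exon-concatenated
CDS of the host species is globally aligned to the reference CDS, and the
insertion point between two exon nucleotides is transferred through the
alignment. The Pcl label is "P" + the 1-based reference coordinate of the
last aligned exon nucleotide 5' of the insertion. Introns sharing a Pcl are
clustered into orthology groups by pairwise sequence identity; the resulting
species × Pcl presence/absence matrix feeds Dollo or Fitch parsimony
reconstruction of gain and loss events on a species tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import pandas as pd
from Bio import Align

from .model import Feature, Mitogenome

log = logging.getLogger(__name__)

UNDETERMINED = "*"


class UnalignableGeneError(ValueError):
    """Species CDS could not be aligned to the reference CDS."""


# ---------------------------------------------------------------------------
# Alignment to the reference CDS


def _nt_aligner(match: float = 2, mismatch: float = -3,
                gap_open: float = -5, gap_extend: float = -2) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass
class AlignmentMap:
    """Bijective map from species-CDS coordinates to reference-CDS
    coordinates (None on gap), with the identity over aligned columns."""

    species_to_ref: dict[int, int]
    identity: float
    score: float
    aligned_columns: int


def align_cds_to_reference(species_cds: str, reference_cds: str,
                           min_identity: float = 0.3,
                           **scores) -> AlignmentMap:
    """Global affine-gap alignment of an intronless species CDS to the
    reference CDS (defaults: match +2, mismatch −3, open −5, extend −2).

    Raises UnalignableGeneError when identity over aligned columns falls
    below `min_identity`.
    """
    if not species_cds or not reference_cds:
        raise ValueError("empty sequence")
    aligner = _nt_aligner(**scores)
    aln = aligner.align(species_cds, reference_cds)[0]
    mapping: dict[int, int] = {}
    matches = cols = 0
    for (ss, se), (rs, re_) in zip(*aln.aligned):
        for k in range(se - ss):
            mapping[ss + k] = rs + k
            cols += 1
            if species_cds[ss + k] == reference_cds[rs + k]:
                matches += 1
    identity = matches / cols if cols else 0.0
    if identity < min_identity:
        raise UnalignableGeneError(
            f"alignment identity {identity:.2f} below {min_identity}")
    return AlignmentMap(species_to_ref=mapping, identity=identity,
                        score=float(aln.score), aligned_columns=cols)


# ---------------------------------------------------------------------------
# Pcl assignment


@dataclass
class PclAssignment:
    species: str
    gene: str
    intron: Feature
    position: int | None          # 1-based reference coordinate, None if undetermined
    label: str                    # "P<pos>" or "*"
    confident: bool
    alignment_identity: float
    intron_sequence: str = ""

    @property
    def pcl(self) -> str:
        return self.label


def _insertion_offsets(genome: Mitogenome, gene_feature: Feature
                       ) -> list[tuple[Feature, int]]:
    """For each intron of a PCG: the number of exon nucleotides 5' of the
    insertion point, in transcription order."""
    introns = sorted(genome.introns_of(gene_feature.name), key=lambda f: f.start)
    parts = list(gene_feature.parts)
    out = []
    for intron in introns:
        upstream = sum(min(e, intron.start) - s
                       for s, e in parts if s < intron.start)
        if gene_feature.strand == "-":
            upstream = gene_feature.length - upstream
        out.append((intron, upstream))
    return out


def assign_pcl(genome: Mitogenome, gene: str, reference_cds: str,
               min_flank: int = 15, min_identity: float = 0.3
               ) -> list[PclAssignment]:
    """Map every intron of `gene` in `genome` to a reference insertion
    coordinate.

    The Pcl position is the 1-based reference coordinate of the last aligned
    exon nucleotide 5' of the insertion; if that species coordinate falls in
    a reference gap the nearest aligned column 5' of it is used and the
    assignment is flagged non-confident. An unalignable gene yields
    undetermined ("*") assignments for all of its introns.
    """
    gene_feature = genome.gene(gene)
    cds = genome.feature_sequence(gene_feature)
    pairs = _insertion_offsets(genome, gene_feature)
    if not pairs:
        return []
    try:
        amap = align_cds_to_reference(cds, reference_cds, min_identity=min_identity)
    except UnalignableGeneError as exc:
        log.warning("%s/%s: %s", genome.species_id, gene, exc)
        return [PclAssignment(species=genome.species_id, gene=gene,
                              intron=intron, position=None, label=UNDETERMINED,
                              confident=False, alignment_identity=0.0,
                              intron_sequence=genome.feature_sequence(intron))
                for intron, _ in pairs]
    out = []
    for intron, offset in pairs:
        # last exon nucleotide 5' of the insertion is species coordinate offset-1
        sp_pos = offset - 1
        confident = True
        while sp_pos >= 0 and sp_pos not in amap.species_to_ref:
            sp_pos -= 1
            confident = False
        if sp_pos < 0:
            out.append(PclAssignment(
                species=genome.species_id, gene=gene, intron=intron,
                position=None, label=UNDETERMINED, confident=False,
                alignment_identity=amap.identity,
                intron_sequence=genome.feature_sequence(intron)))
            continue
        ref_pos = amap.species_to_ref[sp_pos] + 1  # 1-based
        if confident:
            left = sum(1 for p in range(max(0, sp_pos - min_flank + 1), sp_pos + 1)
                       if p in amap.species_to_ref)
            right = sum(1 for p in range(offset, offset + min_flank)
                        if p in amap.species_to_ref)
            confident = left >= min(min_flank, sp_pos + 1) and \
                right >= min(min_flank, len(cds) - offset)
        out.append(PclAssignment(
            species=genome.species_id, gene=gene, intron=intron,
            position=ref_pos, label=f"P{ref_pos}", confident=confident,
            alignment_identity=amap.identity,
            intron_sequence=genome.feature_sequence(intron)))
    return out


# ---------------------------------------------------------------------------
# Orthology clustering and the presence/absence matrix


def _pair_identity(a: str, b: str) -> float:
    """Global-alignment identity over the shorter sequence length."""
    if not a or not b:
        return 0.0
    aligner = _nt_aligner()
    aln = aligner.align(a, b)[0]
    matches = 0
    for (ss, se), (rs, _) in zip(*aln.aligned):
        matches += sum(1 for k in range(se - ss) if a[ss + k] == b[rs + k])
    return matches / min(len(a), len(b))


@dataclass
class PresenceAbsenceMatrix:
    """Species × Pcl boolean table; undetermined cells marked "*"."""

    species: list[str]
    columns: list[str]                       # "gene:P<pos>[suffix]"
    cells: dict[tuple[str, str], str]        # values "1", "0", "*"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame("0", index=self.species, columns=self.columns)
        for (sp, col), v in self.cells.items():
            df.loc[sp, col] = v
        return df

    def presences(self, column: str) -> list[str]:
        return [sp for sp in self.species
                if self.cells.get((sp, column)) == "1"]


def cluster_orthologs(assignments: list[PclAssignment],
                      identity_threshold: float = 0.7,
                      species: list[str] | None = None) -> PresenceAbsenceMatrix:
    """Group co-positional introns into orthology groups by sequence identity.

    Within each (gene, position) group, introns are single-linkage clustered
    at pairwise identity ≥ `identity_threshold` (computed over the shorter
    intron); groups that split get suffixed labels (P100a, P100b, ...).
    Undetermined assignments are marked "*" and never counted as presence.
    """
    if species is None:
        species = sorted({a.species for a in assignments})
    cells: dict[tuple[str, str], str] = {}
    columns: list[str] = []
    groups: dict[tuple[str, int], list[PclAssignment]] = {}
    for a in assignments:
        if a.position is None:
            continue
        groups.setdefault((a.gene, a.position), []).append(a)
    for (gene, pos) in sorted(groups):
        members = sorted(groups[(gene, pos)], key=lambda a: a.species)
        # single-linkage components at identity >= threshold
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in combinations(range(len(members)), 2):
            if _pair_identity(members[i].intron_sequence,
                              members[j].intron_sequence) >= identity_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
        comp: dict[int, list[PclAssignment]] = {}
        for i, m in enumerate(members):
            comp.setdefault(find(i), []).append(m)
        ordered = sorted(comp.values(), key=lambda ms: min(m.species for m in ms))
        multi = len(ordered) > 1
        for ci, ms in enumerate(ordered):
            suffix = chr(ord("a") + ci) if multi else ""
            col = f"{gene}:P{pos}{suffix}"
            columns.append(col)
            for m in ms:
                cells[(m.species, col)] = "1" if m.confident else UNDETERMINED
    # undetermined assignments without a position: flagged per species/gene
    for a in assignments:
        if a.position is None:
            col = f"{a.gene}:{UNDETERMINED}"
            if col not in columns:
                columns.append(col)
            cells[(a.species, col)] = UNDETERMINED
    return PresenceAbsenceMatrix(species=list(species), columns=columns,
                                 cells=cells)


# ---------------------------------------------------------------------------
# Gain/loss reconstruction


@dataclass
class GainLossEvents:
    """Per-branch gained/lost Pcls; branches identified by child-node key
    (leaf label, or sorted tuple of descendant leaf labels)."""

    mode: str
    gains: dict[str, tuple] = field(default_factory=dict)   # pcl -> branch keys
    losses: dict[str, tuple] = field(default_factory=dict)
    tie_rule: str = "absence-at-root"

    def n_events(self) -> int:
        return sum(len(v) for v in self.gains.values()) + \
            sum(len(v) for v in self.losses.values())


def branch_key(node: dendropy.Node) -> tuple:
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return tuple(leaves)


def _replay(tree: dendropy.Tree, gains: tuple, losses: tuple) -> set[str]:
    """Tips carrying a character gained on `gains` branches and lost on
    `losses` branches (events applied on the path from root to tip)."""
    present: set[str] = set()

    def walk(node: dendropy.Node, state: bool) -> None:
        key = branch_key(node)
        if key in gains:
            state = True
        if key in losses:
            state = False
        if node.is_leaf():
            if state:
                present.add(node.taxon.label)
        for ch in node.child_nodes():
            walk(ch, state)

    walk(tree.seed_node, False)
    return present


def gain_loss(matrix: PresenceAbsenceMatrix, tree: dendropy.Tree,
              mode: str = "dollo") -> GainLossEvents:
    """Reconstruct per-branch intron gain and loss events.

    Dollo: a single gain on the branch above the MRCA of all presence tips,
    with the minimal set of losses below it. Fitch: minimum total state
    changes by two-pass parsimony with ties resolved toward absence at the
    root (loss over parallel gain).
    """
    if mode not in ("dollo", "fitch"):
        raise ValueError(f"unknown mode {mode!r}")
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    events = GainLossEvents(mode=mode)
    for col in matrix.columns:
        present = set(matrix.presences(col))
        if not present:
            continue  # columns exist only with >= 1 presence
        missing = present - leaf_labels
        if missing:
            raise ValueError(f"species {sorted(missing)} not in tree")
        # species with undetermined state are excluded from reconstruction
        undet = {sp for sp in matrix.species
                 if matrix.cells.get((sp, col)) == UNDETERMINED}
        if mode == "dollo":
            g, l = _dollo(tree, present, undet)
        else:
            g, l = _fitch(tree, present, undet)
        events.gains[col] = g
        events.losses[col] = l
    return events


def _dollo(tree: dendropy.Tree, present: set[str], undet: set[str]
           ) -> tuple[tuple, tuple]:
    mrca = tree.mrca(taxa=[lf.taxon for lf in tree.leaf_node_iter()
                           if lf.taxon.label in present])
    gains = (branch_key(mrca),)
    losses = []

    def walk(node: dendropy.Node) -> bool:
        """True if any presence tip below; emits one loss per maximal
        presence-free subtree."""
        if node.is_leaf():
            return node.taxon.label in present or node.taxon.label in undet
        any_present = [walk(ch) for ch in node.child_nodes()]
        for ch, ap in zip(node.child_nodes(), any_present):
            if not ap:
                losses.append(branch_key(ch))
        return any(any_present)

    walk(mrca)
    return gains, tuple(sorted(losses))


def _fitch(tree: dendropy.Tree, present: set[str], undet: set[str]
           ) -> tuple[tuple, tuple]:
    state_sets: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            if lbl in undet:
                state_sets[node] = frozenset({0, 1})
            else:
                state_sets[node] = frozenset({1 if lbl in present else 0})
        else:
            kids = [state_sets[ch] for ch in node.child_nodes()]
            inter = frozenset.intersection(*kids)
            state_sets[node] = inter if inter else frozenset.union(*kids)
    gains, losses = [], []
    final: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        ss = state_sets[node]
        if node.parent_node is None:
            final[node] = 0 if 0 in ss else 1  # tie toward absence at root
            if final[node] == 1:
                gains.append(branch_key(node))  # origin on the root stem
        else:
            ps = final[node.parent_node]
            final[node] = ps if ps in ss else min(ss)  # min -> prefers absence
            if final[node] != ps:
                (gains if final[node] == 1 else losses).append(branch_key(node))
    return tuple(sorted(gains)), tuple(sorted(losses))


def replay_events(tree: dendropy.Tree, events: GainLossEvents,
                  column: str) -> set[str]:
    """Tips predicted present for one Pcl by replaying its events."""
    return _replay(tree, events.gains.get(column, ()),
                   events.losses.get(column, ()))


# ---------------------------------------------------------------------------
# Census


def intron_census(genomes: list[Mitogenome]) -> pd.DataFrame:
    """Per-species intron counts and length totals with per-group tallies
    and the split between core-PCG and rRNA hosts."""
    from .model import CORE_PCGS, RRNA_GENES

    rows = []
    for g in genomes:
        introns = g.features_of_kind("intron")
        row: dict[str, object] = {
            "species": g.species_id,
            "n_introns": len(introns),
            "intron_nt": sum(f.length for f in introns),
            "in_core_pcg": 0, "in_rrna": 0, "unassigned": 0,
        }
        for grp in ("IA", "IB", "IC1", "IC2", "ID", "II", "unknown"):
            row[grp] = 0
        for f in introns:
            if f.parent_gene in CORE_PCGS:
                row["in_core_pcg"] += 1
            elif f.parent_gene in RRNA_GENES:
                row["in_rrna"] += 1
            else:
                row["unassigned"] += 1
                if f.parent_gene is None:
                    log.warning("%s: intron %s lacks parent gene",
                                g.species_id, f.name)
            row[f.intron_group or "unknown"] += 1
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")
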