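"""Synthetic annotated mitogenomes with known ground truth.

The generator emulates hypocrealean fungal mitochondrial genomes: circular,
AT-rich (default 74% AT) molecules of roughly 30–52 kb carrying 15 core
protein-coding genes, two rRNAs, 25 tRNAs, a variable complement of group-I
introns (optionally harboring homing-endonuclease-like ORFs), and intergenic
spacers. Introns are gained and lost along a species tree according to a
planted (by default Dollo-consistent) event history; point substitutions
accumulate per branch under a Kimura-style two-parameter kernel with internal
stop codons repaired by codon resampling; repeats of all three scanned
classes can be planted at recorded coordinates. Every stochastic choice is
driven by the single config seed, so identical configs give byte-identical
output bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .introns import branch_key
from .io_formats import write_fasta, write_genbank, write_newick
from .model import (CORE_PCGS, RRNA_GENES, STOP_CODONS_4, Feature, Mitogenome,
                    revcomp)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PclEntry:
    gene: str
    position: int      # 1-based nucleotide coordinate in the reference CDS/rRNA
    length: int        # intron length, nt
    group: str         # IA | IB | IC1 | IC2 | ID

    @property
    def label(self) -> str:
        return f"{self.gene}:P{self.position}"


@dataclass(frozen=True)
class PlantedRepeatSpec:
    rtype: str                 # SSR | tandem | dispersed_forward | dispersed_palindromic
    motif: str = ""            # SSR/tandem unit (dispersed: ignored)
    copies: int = 0            # SSR/tandem copy number
    length: int = 0            # dispersed repeat length, nt
    location_class: str = "intergenic"   # intergenic | intron


# Realistic core-gene lengths (nt, multiples of 3, stop included).
DEFAULT_GENE_LENGTHS = {
    "atp6": 774, "atp8": 147, "atp9": 225, "cob": 1158, "cox1": 1608,
    "cox2": 750, "cox3": 810, "nad1": 1104, "nad2": 1653, "nad3": 423,
    "nad4": 1473, "nad4L": 270, "nad5": 1980, "nad6": 651, "rps3": 1341,
    "rnl": 3150, "rns": 1515,
}

_TRNA_AA = ("A", "R", "N", "D", "C", "Q", "E", "G", "H", "I", "L1", "L2",
            "K", "M", "F", "P", "S1", "S2", "T", "W", "Y", "V", "M1", "R1", "G1")
DEFAULT_TRNAS = tuple(f"trn{aa}" for aa in _TRNA_AA)  # 25 tRNA genes

# Default planted intron catalog: cox1-heavy, a few rRNA-hosted introns,
# mirroring the intron distribution typical of the genus.
DEFAULT_PCL_CATALOG = (
    PclEntry("cox1", 212, 1120, "IB"), PclEntry("cox1", 709, 980, "IA"),
    PclEntry("cox1", 720, 860, "IB"), PclEntry("cox1", 731, 1240, "IB"),
    PclEntry("cox1", 1057, 1005, "ID"), PclEntry("cob", 25, 940, "IA"),
    PclEntry("cob", 392, 1330, "IB"), PclEntry("cob", 823, 890, "IC1"),
    PclEntry("cox2", 6, 1010, "IB"), PclEntry("cox2", 218, 760, "IC1"),
    PclEntry("cox3", 219, 830, "IB"), PclEntry("cox3", 333, 1100, "IC2"),
    PclEntry("nad1", 287, 900, "IB"), PclEntry("nad1", 701, 1150, "IA"),
    PclEntry("nad4", 505, 980, "IB"), PclEntry("nad5", 416, 870, "IC1"),
    PclEntry("nad5", 717, 1200, "IB"), PclEntry("nad5", 1270, 760, "ID"),
    PclEntry("atp6", 572, 920, "IB"), PclEntry("atp9", 128, 690, "IA"),
    PclEntry("rnl", 1410, 1480, "IB"), PclEntry("rnl", 2230, 1020, "IA"),
    PclEntry("rns", 880, 940, "IB"),
)

_MINUS_STRAND = frozenset({"nad6", "trnW", "trnY"})


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species: int = 7
    tree: str = "random"                    # Newick string or "random"
    species_names: tuple[str, ...] | None = None
    genome_at_fraction: float = 0.74
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    trna_names: tuple[str, ...] = DEFAULT_TRNAS
    pcl_catalog: tuple[PclEntry, ...] = DEFAULT_PCL_CATALOG
    gain_loss_events: dict[str, dict] | None = None   # label -> {gain, losses}
    loss_rate: float = 0.22
    per_branch_sub_rate: float = 0.02
    nonsyn_acceptance: float = 0.3   # fraction of amino-acid-changing hits kept
    indel_rate: float = 0.0
    planted_repeats: tuple[PlantedRepeatSpec, ...] = ()
    intergenic_mean: int = 200
    intron_orf_prob: float = 0.5
    n_free_orfs: int = 2
    kappa: float = 2.0

    def validate(self) -> None:
        if not (0.0 <= self.per_branch_sub_rate <= 0.5):
            raise ConfigError("per_branch_sub_rate must be in [0, 0.5]")
        if not (0.0 <= self.indel_rate <= 0.5):
            raise ConfigError("indel_rate must be in [0, 0.5]")
        if not (0.0 <= self.nonsyn_acceptance <= 1.0):
            raise ConfigError("nonsyn_acceptance must be in [0, 1]")
        if not (0.0 < self.genome_at_fraction < 1.0):
            raise ConfigError("genome_at_fraction must be in (0, 1)")
        for e in self.pcl_catalog:
            host_len = self.gene_lengths.get(e.gene)
            if host_len is None:
                raise ConfigError(f"pcl catalog gene {e.gene!r} not in gene set")
            if not (1 <= e.position < host_len - 3):
                raise ConfigError(
                    f"pcl {e.label}: position outside reference CDS")
        if self.species_names is not None and \
                len(self.species_names) != self.n_species:
            raise ConfigError("species_names length != n_species")


@dataclass
class GroundTruth:
    tree_newick: str
    species: list[str]
    matrix: dict[str, dict[str, bool]]           # species -> label -> present
    gains: dict[str, list]                       # label -> [branch keys]
    losses: dict[str, list]
    reference_cds: dict[str, str]
    region_totals: dict[str, dict[str, int]]
    intron_details: dict[str, list[dict]]        # species -> intron records
    repeats: dict[str, list[dict]]               # species -> planted repeats

    def to_json(self) -> str:
        payload = asdict(self)
        payload["gains"] = {k: [list(b) for b in v] for k, v in self.gains.items()}
        payload["losses"] = {k: [list(b) for b in v] for k, v in self.losses.items()}
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Random sequence primitives

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _base_probs(at: float) -> np.ndarray:
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])


def _random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    idx = rng.choice(4, size=n, p=_base_probs(at))
    return _BASES[idx].tobytes().decode()


def _random_cds(rng: np.random.Generator, length: int, at: float) -> str:
    """Random stop-free CDS under code 4: ATG + internal codons + TAA."""
    ncod = length // 3
    body = []
    for _ in range(ncod - 2):
        codon = _random_seq(rng, 3, at)
        while codon in STOP_CODONS_4:
            codon = _random_seq(rng, 3, at)
        body.append(codon)
    return "ATG" + "".join(body) + "TAA"


# ---------------------------------------------------------------------------
# Mutation

_TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T (ASCII)
_TRANSVERSIONS = {65: (67, 84), 71: (67, 84), 67: (65, 71), 84: (65, 71)}


def _mutate(rng: np.random.Generator, seq: str, rate: float, kappa: float,
            window: tuple[int, int] | None = None) -> str:
    """Per-site substitutions: given a hit, transition with probability
    kappa/(kappa+2), otherwise either transversion equiprobably. If `window`
    is given, only positions inside it are mutable."""
    if rate <= 0 or not seq:
        return seq
    arr = bytearray(seq.encode())
    n = len(arr)
    hits = np.flatnonzero(rng.random(n) < rate)
    if window is not None:
        hits = hits[(hits >= window[0]) & (hits < window[1])]
    p_ts = kappa / (kappa + 2.0)
    u = rng.random(hits.size)
    v = rng.random(hits.size)
    for h, uu, vv in zip(hits.tolist(), u.tolist(), v.tolist()):
        b = arr[h]
        if b not in _TRANSITION:
            continue
        if uu < p_ts:
            arr[h] = _TRANSITION[b]
        else:
            tv = _TRANSVERSIONS[b]
            arr[h] = tv[0] if vv < 0.5 else tv[1]
    return arr.decode()


def _mutate_cds(rng: np.random.Generator, cds: str, rate: float, kappa: float,
                nonsyn_acceptance: float = 1.0) -> str:
    """Mutate a CDS keeping start/stop codons fixed.

    Internal stops created by mutation are repaired by resampling the affected
    codon until stop-free; amino-acid-changing codons are then kept only with
    probability `nonsyn_acceptance` (purifying selection), otherwise reverted.
    """
    if rate <= 0:
        return cds
    out = _mutate(rng, cds, rate, kappa, window=(3, len(cds) - 3))
    arr = bytearray(out.encode())
    for i in range(3, len(arr) - 3, 3):
        while bytes(arr[i:i + 3]).decode() in STOP_CODONS_4:
            j = i + int(rng.integers(0, 3))
            arr[j] = int(_BASES[rng.integers(0, 4)])
    if nonsyn_acceptance < 1.0:
        from .model import GENETIC_CODE_4
        for i in range(3, len(arr) - 3, 3):
            new = bytes(arr[i:i + 3]).decode()
            old = cds[i:i + 3]
            if new != old and GENETIC_CODE_4[new] != GENETIC_CODE_4[old]:
                if rng.random() >= nonsyn_acceptance:
                    arr[i:i + 3] = old.encode()
    return arr.decode()


def _apply_indels(rng: np.random.Generator, seq: str, rate: float, at: float) -> str:
    if rate <= 0 or len(seq) < 4:
        return seq
    n_events = rng.poisson(rate * len(seq))
    for _ in range(int(n_events)):
        pos = int(rng.integers(0, len(seq)))
        size = int(rng.geometric(0.35))
        if rng.random() < 0.5 and len(seq) > size + 2:
            seq = seq[:pos] + seq[pos + size:]
        else:
            seq = seq[:pos] + _random_seq(rng, size, at) + seq[pos:]
    return seq


# ---------------------------------------------------------------------------
# Trees and intron histories


def random_yule_tree(rng: np.random.Generator, labels: list[str]) -> dendropy.Tree:
    """Pure-birth topology with unit-exponential branch lengths."""
    taxa = dendropy.TaxonNamespace(labels)
    lineages = []
    for lbl in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lbl)
        node.edge.length = float(rng.exponential(1.0))
        lineages.append(node)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False).tolist())
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(1.0))
        b = lineages.pop(j)
        a = lineages.pop(i)
        parent.add_child(a)
        parent.add_child(b)
        lineages.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = lineages[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def _random_history(rng: np.random.Generator, tree: dendropy.Tree,
                    loss_rate: float) -> tuple[tuple, list[tuple]]:
    """One Dollo-consistent (gain branch, loss branches) history."""
    nodes = list(tree.preorder_node_iter())
    for _ in range(40):
        gain = nodes[int(rng.integers(0, len(nodes)))]
        losses = []

        def walk(node, carried):
            present = set()
            if carried and node is not gain and node.parent_node is not None \
                    and rng.random() < loss_rate and node is not gain:
                losses.append(branch_key(node))
                carried = False
            if node.is_leaf():
                if carried:
                    present.add(node.taxon.label)
            for ch in node.child_nodes():
                present |= walk(ch, carried)
            return present

        losses.clear()
        tips = walk(gain, True)
        if tips:
            return branch_key(gain), losses
    leaf = nodes[-1]
    while not leaf.is_leaf():
        leaf = leaf.child_nodes()[0]
    return branch_key(leaf), []


# ---------------------------------------------------------------------------
# Ancestor


@dataclass
class _Ancestor:
    pcg: dict[str, str]
    rrna: dict[str, str]
    trna: dict[str, str]
    free_orfs: list[str]
    layout: list[tuple[str, str]]   # (kind, name) in genome order
    n_spacers: int


def _default_layout(config: SimulationConfig) -> list[tuple[str, str]]:
    """Deterministic gene order: rnl first, then PCGs with tRNAs interleaved,
    rns and free ORFs mid-genome."""
    pcgs = [g for g in CORE_PCGS if g in config.gene_lengths]
    trnas = list(config.trna_names)
    layout: list[tuple[str, str]] = [("rRNA", "rnl")]
    ti = 0
    for k, gene in enumerate(pcgs):
        layout.append(("PCG", gene))
        for _ in range(2 if k % 2 == 0 else 1):
            if ti < len(trnas):
                layout.append(("tRNA", trnas[ti]))
                ti += 1
        if k == 6:
            layout.append(("rRNA", "rns"))
            for o in range(config.n_free_orfs):
                layout.append(("orf", f"freeorf{o + 1}"))
    while ti < len(trnas):
        layout.append(("tRNA", trnas[ti]))
        ti += 1
    return layout


def _build_ancestor(config: SimulationConfig, rng: np.random.Generator) -> _Ancestor:
    at = config.genome_at_fraction
    pcg = {g: _random_cds(rng, config.gene_lengths[g], at)
           for g in CORE_PCGS if g in config.gene_lengths}
    rrna = {g: _random_seq(rng, config.gene_lengths[g], at)
            for g in RRNA_GENES if g in config.gene_lengths}
    trna = {name: _random_seq(rng, int(rng.integers(71, 86)), at)
            for name in config.trna_names}
    free_orfs = [_random_cds(rng, int(rng.integers(100, 160)) * 3, at)
                 for _ in range(config.n_free_orfs)]
    layout = _default_layout(config)
    return _Ancestor(pcg=pcg, rrna=rrna, trna=trna, free_orfs=free_orfs,
                     layout=layout, n_spacers=len(layout) + 1)


def make_reference_cds(config: SimulationConfig) -> list[tuple[str, str]]:
    """Intronless reference CDS set: the ancestral exon concatenations, the
    coordinate frame for all Pcl labels of the run."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(4)
    anc = _build_ancestor(config, np.random.default_rng(streams[0]))
    return [(g, anc.pcg[g]) for g in CORE_PCGS if g in anc.pcg]


# ---------------------------------------------------------------------------
# Simulation


@dataclass
class _IntronState:
    entry: PclEntry
    seq: str
    orf: tuple[int, int] | None   # (offset, length) within intron, or None
    orf_family: str = ""


def _new_intron(rng: np.random.Generator, entry: PclEntry, at: float,
                orf_prob: float) -> _IntronState:
    orf = None
    family = ""
    if entry.length >= 400 and rng.random() < orf_prob:
        orf_len = int(rng.integers(100, max(101, (entry.length - 60) // 3))) * 3
        orf_len = min(orf_len, ((entry.length - 60) // 3) * 3)
        orf_len = max(orf_len, 300)
        offset = 30
        head = _random_seq(rng, offset, at)
        body = _random_cds(rng, orf_len, at)
        tail = _random_seq(rng, entry.length - offset - orf_len, at)
        family = "LAGLIDADG-like" if rng.random() < 0.5 else "GIY-YIG-like"
        return _IntronState(entry=entry, seq=head + body + tail,
                            orf=(offset, orf_len), orf_family=family)
    return _IntronState(entry=entry, seq=_random_seq(rng, entry.length, at),
                        orf=orf, orf_family=family)


@dataclass
class _NodeState:
    pcg: dict[str, str]
    rrna: dict[str, str]
    trna: dict[str, str]
    free_orfs: list[str]
    spacers: list[str]
    introns: dict[str, _IntronState]   # label -> state

    def copy(self) -> "_NodeState":
        return _NodeState(pcg=dict(self.pcg), rrna=dict(self.rrna),
                          trna=dict(self.trna), free_orfs=list(self.free_orfs),
                          spacers=list(self.spacers),
                          introns=dict(self.introns))


def simulate(config: SimulationConfig
             ) -> tuple[list[Mitogenome], GroundTruth]:
    """Run the generator: returns one annotated Mitogenome per species plus
    the GroundTruth record (true tree, Pcl presence/absence, per-branch
    events, planted repeat coordinates, reference CDS set)."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_anc = np.random.default_rng(streams[0])
    rng_tree = np.random.default_rng(streams[1])
    rng_hist = np.random.default_rng(streams[2])
    rng_evo = np.random.default_rng(streams[3])
    at = config.genome_at_fraction

    ancestor = _build_ancestor(config, rng_anc)

    species = list(config.species_names or
                   (f"sp{i + 1:02d}" for i in range(config.n_species)))
    if config.tree == "random":
        tree = random_yule_tree(rng_tree, species)
    else:
        tree = dendropy.Tree.get(data=config.tree, schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True
        got = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        if got != sorted(species):
            raise ConfigError(f"tree leaves {got} do not match species set")

    # intron gain/loss history per catalog entry
    gains: dict[str, tuple] = {}
    losses: dict[str, list] = {}
    for entry in config.pcl_catalog:
        if config.gain_loss_events and entry.label in config.gain_loss_events:
            ev = config.gain_loss_events[entry.label]
            gains[entry.label] = tuple(ev["gain"])
            losses[entry.label] = [tuple(b) for b in ev.get("losses", [])]
        else:
            g, l = _random_history(rng_hist, tree, config.loss_rate)
            gains[entry.label] = g
            losses[entry.label] = l
    catalog_by_label = {e.label: e for e in config.pcl_catalog}

    # spacer lengths at the root
    root_spacers = [max(20, int(rng_evo.geometric(1.0 / config.intergenic_mean)))
                    for _ in range(ancestor.n_spacers)]
    root_state = _NodeState(
        pcg=dict(ancestor.pcg), rrna=dict(ancestor.rrna),
        trna=dict(ancestor.trna), free_orfs=list(ancestor.free_orfs),
        spacers=[_random_seq(rng_evo, n, at) for n in root_spacers],
        introns={})

    tip_states: dict[str, _NodeState] = {}

    def evolve(node: dendropy.Node, state: _NodeState) -> None:
        state = state.copy()
        key = branch_key(node)
        rate = config.per_branch_sub_rate
        kappa = config.kappa
        if node.parent_node is not None and rate > 0:
            state.pcg = {g: _mutate_cds(rng_evo, s, rate, kappa,
                                        config.nonsyn_acceptance)
                         for g, s in sorted(state.pcg.items())}
            state.rrna = {g: _mutate(rng_evo, s, rate, kappa)
                          for g, s in sorted(state.rrna.items())}
            state.trna = {g: _mutate(rng_evo, s, rate, kappa)
                          for g, s in sorted(state.trna.items())}
            state.free_orfs = [_mutate_cds(rng_evo, s, rate, kappa)
                               for s in state.free_orfs]
            state.spacers = [
                _apply_indels(rng_evo, _mutate(rng_evo, s, rate, kappa),
                              config.indel_rate, at)
                for s in state.spacers]
            state.introns = {
                lbl: _IntronState(entry=st.entry,
                                  seq=_mutate(rng_evo, st.seq, rate, kappa),
                                  orf=st.orf, orf_family=st.orf_family)
                for lbl, st in sorted(state.introns.items())}
        for lbl in sorted(gains):
            if gains[lbl] == key:
                state.introns[lbl] = _new_intron(
                    rng_evo, catalog_by_label[lbl], at, config.intron_orf_prob)
        for lbl in sorted(losses):
            if key in losses[lbl]:
                state.introns.pop(lbl, None)
        if node.is_leaf():
            tip_states[node.taxon.label] = state
        for ch in sorted(node.child_nodes(), key=branch_key):
            evolve(ch, state)

    evolve(tree.seed_node, root_state)

    genomes: list[Mitogenome] = []
    truth_repeats: dict[str, list[dict]] = {}
    region_totals: dict[str, dict[str, int]] = {}
    intron_details: dict[str, list[dict]] = {}
    for sp in species:
        genome, planted, totals, details = _assemble(
            sp, tip_states[sp], config, rng_evo, at)
        genomes.append(genome)
        truth_repeats[sp] = planted
        region_totals[sp] = totals
        intron_details[sp] = details

    matrix = {sp: {lbl: lbl in tip_states[sp].introns for lbl in sorted(gains)}
              for sp in species}
    truth = GroundTruth(
        tree_newick=tree.as_string(schema="newick", suppress_rooting=True).strip(),
        species=species, matrix=matrix,
        gains={lbl: [list(gains[lbl])] for lbl in gains},
        losses={lbl: [list(b) for b in losses[lbl]] for lbl in losses},
        reference_cds={g: ancestor.pcg[g] for g in sorted(ancestor.pcg)},
        region_totals=region_totals, intron_details=intron_details,
        repeats=truth_repeats)
    return genomes, truth


def _intron_region(sp_introns: dict[str, _IntronState], gene: str
                   ) -> list[_IntronState]:
    sts = [st for st in sp_introns.values() if st.entry.gene == gene]
    return sorted(sts, key=lambda st: st.entry.position)


def _assemble(sp: str, state: _NodeState, config: SimulationConfig,
              rng: np.random.Generator, at: float
              ) -> tuple[Mitogenome, list[dict], dict[str, int], list[dict]]:
    """Lay the evolved elements onto a circular sequence, planting repeats
    into spacer/intron sequences and recording all ground-truth coordinates."""
    totals = {k: 0 for k in ("PCG_exon", "intron", "rRNA", "tRNA",
                             "free_orf", "intergenic")}
    details: list[dict] = []
    planted: list[dict] = []

    # plant repeats by rewriting spacer (or intron) strings before layout
    spacers = list(state.spacers)
    intron_plants: dict[str, list[tuple[int, str, dict]]] = {}
    spacer_marks: dict[int, list[tuple[int, str, dict]]] = {}
    next_spacer = 1
    for ri, spec in enumerate(config.planted_repeats):
        if spec.rtype == "SSR":
            text = spec.motif * spec.copies
            pieces = [text]
        elif spec.rtype == "tandem":
            text = spec.motif * spec.copies
            pieces = [text]
        elif spec.rtype in ("dispersed_forward", "dispersed_palindromic"):
            unit = _random_seq(rng, spec.length, at)
            other = unit if spec.rtype == "dispersed_forward" else revcomp(unit)
            pieces = [unit, other]
        else:
            raise ConfigError(f"unknown planted repeat type {spec.rtype!r}")
        for pi, text in enumerate(pieces):
            info = {"rtype": spec.rtype, "index": ri, "copy": pi,
                    "text": text, "location_class": spec.location_class}
            if spec.location_class == "intron" and state.introns:
                lbl = sorted(state.introns)[(ri + pi) % len(state.introns)]
                st = state.introns[lbl]
                off = max(0, len(st.seq) - len(text) - 5)
                st = _IntronState(entry=st.entry,
                                  seq=st.seq[:off] + text + st.seq[off + len(text):],
                                  orf=None, orf_family="")
                state.introns[lbl] = st
                intron_plants.setdefault(lbl, []).append((off, text, info))
            else:
                si = next_spacer % len(spacers)
                next_spacer += 2
                if len(spacers[si]) < len(text) + 10:
                    spacers[si] = spacers[si] + _random_seq(
                        rng, len(text) + 10 - len(spacers[si]), at)
                off = 5
                spacers[si] = (spacers[si][:off] + text +
                               spacers[si][off + len(text):])
                spacer_marks.setdefault(si, []).append((off, text, info))

    chunks: list[str] = []
    features: list[Feature] = []
    pos = 0

    def emit(text: str, cls: str) -> int:
        nonlocal pos
        chunks.append(text)
        start = pos
        pos += len(text)
        totals[cls] += len(text)
        return start

    def add_spacer(si: int) -> None:
        start = emit(spacers[si], "intergenic")
        for off, text, info in spacer_marks.get(si, ()):
            planted.append(dict(info, start=start + off,
                                end=start + off + len(text), species=sp))

    si = 0
    add_spacer(si)
    si += 1
    layout = _default_layout(config)
    for kind, name in layout:
        strand = "-" if name in _MINUS_STRAND else "+"
        if kind == "PCG":
            cds = state.pcg[name]
            intr = _intron_region(state.introns, name)
            pieces: list[tuple[str, str, object]] = []
            prev = 0
            for st in intr:
                p = st.entry.position
                pieces.append(("exon", cds[prev:p], None))
                pieces.append(("intron", st.seq, st))
                prev = p
            pieces.append(("exon", cds[prev:], None))
            if strand == "-":
                pieces = [(k, revcomp(t), m) for k, t, m in pieces[::-1]]
            exon_parts: list[tuple[int, int]] = []
            for pkind, text, meta in pieces:
                if pkind == "exon":
                    start = emit(text, "PCG_exon")
                    exon_parts.append((start, start + len(text)))
                else:
                    start = emit(text, "intron")
                    st = meta
                    features.append(Feature(
                        kind="intron", name=f"{name}-P{st.entry.position}",
                        strand=strand, parts=[(start, start + len(text))],
                        intron_group=st.entry.group, parent_gene=name))
                    details.append({"species": sp, "gene": name,
                                    "position": st.entry.position,
                                    "group": st.entry.group,
                                    "length": len(text),
                                    "start": start, "end": start + len(text)})
                    if st.orf is not None:
                        o_off, o_len = st.orf
                        if strand == "-":
                            o_start = start + len(text) - o_off - o_len
                        else:
                            o_start = start + o_off
                        features.append(Feature(
                            kind="orf", name=f"{name}-orf{o_len // 3 - 1}",
                            strand=strand, parts=[(o_start, o_start + o_len)],
                            note=f"{st.orf_family} homing endonuclease"))
                    lbl = f"{name}:P{st.entry.position}"
                    for off, ptext, info in intron_plants.get(lbl, ()):
                        if strand == "-":
                            p_start = start + len(text) - off - len(ptext)
                        else:
                            p_start = start + off
                        planted.append(dict(info, start=p_start,
                                            end=p_start + len(ptext), species=sp))
            features.append(Feature(kind="PCG", name=name, strand=strand,
                                    parts=exon_parts))
        elif kind == "rRNA":
            seq = state.rrna[name]
            intr = _intron_region(state.introns, name)
            pieces = []
            prev = 0
            for st in intr:
                p = st.entry.position
                pieces.append(("exon", seq[prev:p], None))
                pieces.append(("intron", st.seq, st))
                prev = p
            pieces.append(("exon", seq[prev:], None))
            exon_parts = []
            for pkind, text, meta in pieces:
                if pkind == "exon":
                    start = emit(text, "rRNA")
                    exon_parts.append((start, start + len(text)))
                else:
                    start = emit(text, "intron")
                    st = meta
                    features.append(Feature(
                        kind="intron", name=f"{name}-P{st.entry.position}",
                        strand="+", parts=[(start, start + len(text))],
                        intron_group=st.entry.group, parent_gene=name))
                    details.append({"species": sp, "gene": name,
                                    "position": st.entry.position,
                                    "group": st.entry.group,
                                    "length": len(text),
                                    "start": start, "end": start + len(text)})
            features.append(Feature(kind="rRNA", name=name, strand="+",
                                    parts=exon_parts))
        elif kind == "tRNA":
            seq = state.trna[name]
            if strand == "-":
                seq = revcomp(seq)
            start = emit(seq, "tRNA")
            features.append(Feature(kind="tRNA", name=name, strand=strand,
                                    parts=[(start, start + len(seq))]))
        elif kind == "orf":
            idx = int(name.replace("freeorf", "")) - 1
            seq = state.free_orfs[idx]
            start = emit(seq, "free_orf")
            features.append(Feature(kind="orf", name=name, strand="+",
                                    parts=[(start, start + len(seq))],
                                    note="free-standing ORF"))
        add_spacer(si)
        si += 1

    genome = Mitogenome(species_id=sp, sequence="".join(chunks),
                        circular=True, features=features)
    genome.sort_features()
    return genome, planted, totals, details


# ---------------------------------------------------------------------------
# Bundles


def write_bundle(genomes: list[Mitogenome], truth: GroundTruth,
                 out_dir: str | Path) -> None:
    """Write per-species GenBank, the reference CDS FASTA, the true tree and
    ground_truth.json into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_genbank(g, out / f"{g.species_id}.gbk")
    write_fasta(sorted(truth.reference_cds.items()), out / "reference.fasta")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(truth.tree_newick + "\n")
    with open(out / "ground_truth.json", "w") as fh:
        fh.write(truth.to_json() + "\n")
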