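"""Distance phylogeny: supermatrix concatenation, K2P distance matrix,
neighbor-joining, nonparametric bootstrap, Robinson–Foulds distance.

Neighbor joining follows the classic Q-criterion agglomeration with a
deterministic lexicographic tie-break; negative branch lengths are clamped to
zero with the subtracted amount moved to the sibling edge. Bootstrap support
is the percentage of replicate NJ trees (built from column-resampled
supermatrices) containing each bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np


class MissingDataError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal; NaN = missing

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v - v.T)) > 1e-12:
                raise ValueError("matrix must be symmetric")
        self.values = v

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(len(self.ids), dtype=bool)
        return bool(np.isnan(self.values[off]).any())


# ---------------------------------------------------------------------------
# Supermatrix


def concatenate(per_gene_alignments: list[tuple[str, dict[str, str]]]
                ) -> tuple[dict[str, str], list[int]]:
    """Column-wise concatenation of per-gene gapless alignments.

    Returns (species -> concatenated sequence, partition boundaries), where
    boundaries[i] is the cumulative column count after gene i (the last
    boundary equals the supermatrix width).
    """
    if not per_gene_alignments:
        raise ValueError("no alignments")
    species = sorted(per_gene_alignments[0][1])
    problems = []
    for gene, aln in per_gene_alignments:
        if sorted(aln) != species:
            problems.append((gene, sorted(set(species) ^ set(aln))))
    if problems:
        raise MissingDataError(
            "species sets differ: " +
            "; ".join(f"{g} (offending: {', '.join(sp)})" for g, sp in problems))
    out = {sp: [] for sp in species}
    boundaries = []
    total = 0
    for gene, aln in per_gene_alignments:
        width = {len(s) for s in aln.values()}
        if len(width) != 1:
            raise ValueError(f"{gene}: rows have unequal length")
        total += width.pop()
        boundaries.append(total)
        for sp in species:
            out[sp].append(aln[sp])
    return {sp: "".join(chunks) for sp, chunks in out.items()}, boundaries


_N = ord("N")
_PURINES = (ord("A"), ord("G"))


def _k2p_rows(rows: np.ndarray) -> np.ndarray:
    """Pairwise K2P distances between uint8-encoded equal-length rows
    (NaN at saturation); vectorized for bootstrap throughput."""
    n = rows.shape[0]
    valid_base = rows != _N
    purine = (rows == _PURINES[0]) | (rows == _PURINES[1])
    m = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        valid = valid_base[i] & valid_base[j]
        sites = int(valid.sum())
        if sites == 0:
            m[i, j] = m[j, i] = np.nan
            continue
        diff = valid & (rows[i] != rows[j])
        ts = int((diff & (purine[i] == purine[j])).sum())
        tv = int(diff.sum()) - ts
        P, Q = ts / sites, tv / sites
        w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
        if w1 <= 0 or w2 <= 0:
            m[i, j] = m[j, i] = np.nan
        else:
            m[i, j] = m[j, i] = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return m


def k2p_matrix(supermatrix: dict[str, str]) -> DistanceMatrix:
    """Pairwise K2P distances over a gapless supermatrix (NaN at saturation)."""
    ids = sorted(supermatrix)
    rows = np.array([np.frombuffer(supermatrix[sp].encode(), dtype=np.uint8)
                     for sp in ids])
    return DistanceMatrix(ids=ids, values=_k2p_rows(rows))


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Classic neighbor joining. Requires a complete matrix of ≥ 3 taxa.

    Ties in the Q criterion are broken by the lexicographically smallest
    (label_a, label_b) pair, where an internal node carries the smallest leaf
    label below it; output is therefore deterministic.
    """
    if matrix.has_missing:
        raise MissingDataError("distance matrix has missing entries")
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    taxa = dendropy.TaxonNamespace(matrix.ids)
    nodes: dict[str, dendropy.Node] = {}
    for label in matrix.ids:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes[label] = node
    # active set keyed by sort label (smallest leaf label below the node)
    active: dict[str, dendropy.Node] = dict(nodes)
    dist: dict[frozenset, float] = {}
    for a, b in combinations(matrix.ids, 2):
        i, j = matrix.ids.index(a), matrix.ids.index(b)
        dist[frozenset((a, b))] = float(matrix.values[i, j])

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 2:
        labels = sorted(active)
        r = {a: sum(d(a, b) for b in labels if b != a) for a in labels}
        m = len(labels)
        best = None
        for a, b in combinations(labels, 2):
            q = (m - 2) * d(a, b) - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        dab = d(a, b)
        va = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        vb = dab - va
        # clamp negatives: move the subtracted amount to the sibling edge
        if va < 0:
            vb += -va
            va = 0.0
        if vb < 0:
            va += -vb
            vb = 0.0
        parent = dendropy.Node()
        ca, cb = active.pop(a), active.pop(b)
        ca.edge.length = va
        cb.edge.length = vb
        parent.add_child(ca)
        parent.add_child(cb)
        new_label = min(a, b)
        for c in sorted(active):
            dist[frozenset((new_label, c))] = 0.5 * (d(a, c) + d(b, c) - dab)
        active[new_label] = parent
    # attach the last node to the internal survivor: no degree-2 root, and
    # pendant edge lengths solve the three-point system exactly for n = 3
    (la, na), (lb, nb) = sorted(active.items())
    if nb.is_leaf() and not na.is_leaf():
        na, nb = nb, na
    nb.add_child(na)
    na.edge.length = d(la, lb)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nb
    tree.is_rooted = False
    return tree


def root_at_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the edge leading to the named outgroup taxon."""
    og = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == outgroup:
            og = lf
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    length = og.edge.length or 0.0
    tree.reroot_at_edge(og.edge, length1=length / 2, length2=length / 2,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and Robinson–Foulds


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the smaller/canonical side."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial
        out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Robinson–Foulds symmetric-difference distance (unrooted)."""
    la = {lf.taxon.label for lf in tree_a.leaf_node_iter()}
    lb = {lf.taxon.label for lf in tree_b.leaf_node_iter()}
    if la != lb:
        raise ValueError("trees have different leaf sets")
    return len(_bipartitions(tree_a) ^ _bipartitions(tree_b))


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class SupportTree:
    tree: dendropy.Tree
    supports: dict[frozenset, float]  # bipartition -> percentage
    n_reps: int
    n_dropped: int

    def newick(self) -> str:
        """Newick with integer bootstrap supports as internal node labels."""
        all_leaves = frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
            if key in self.supports:
                node.label = str(int(round(self.supports[key])))
        return self.tree.as_string(schema="newick", suppress_rooting=True)


def bootstrap(supermatrix: dict[str, str], n_reps: int = 1000,
              seed: int = 0) -> SupportTree:
    """Nonparametric bootstrap over supermatrix columns with NJ per replicate.

    Support of an edge is the percentage of (non-dropped) replicate trees
    containing its bipartition; replicates whose distance matrix has a
    saturated (undefined) entry are dropped and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = sorted(supermatrix)
    ncols = len(supermatrix[ids[0]])
    mat = np.array([list(supermatrix[sp].encode()) for sp in ids], dtype=np.uint8)
    main = nj_tree(k2p_matrix(supermatrix))
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(main)}
    rng = np.random.default_rng(seed)
    dropped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        values = _k2p_rows(mat[:, cols])
        if np.isnan(values).any():
            dropped += 1
            continue
        dm = DistanceMatrix(ids=ids, values=values)
        for bp in _bipartitions(nj_tree(dm)):
            if bp in counts:
                counts[bp] += 1
    used = n_reps - dropped
    supports = {bp: (100.0 * c / used if used else 0.0)
                for bp, c in counts.items()}
    return SupportTree(tree=main, supports=supports, n_reps=n_reps,
                       n_dropped=dropped)
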