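"""Repeat landscapes: microsatellites, dispersed repeats, tandem arrays.

Three detectors with the classical tool parameterizations:

* ``find_ssrs`` — MISA-style maximal microsatellite runs with per-class
  minimum copy numbers (mono 10, di 5, tri 4, tetra/penta/hexa 3).
* ``find_dispersed`` — REPuter-style maximal repeated pairs (forward and
  palindromic) with Hamming distance ≤ 3 and length in [30, 5000].
  Maximality: a pair is extendable in neither direction without exceeding
  the mismatch budget; reported intervals are trimmed to start and end on
  matching positions, so the reported mismatch count can be below the budget.
* ``find_tandem`` — a transparent simplification of Tandem Repeats Finder:
  exact k-periodic seed runs extended while running identity stays above a
  threshold, with greedy overlap resolution by array size.

Circular genomes are scanned on the doubled sequence with calls constrained
to start in the first copy, which prevents origin-split misses; coordinates
are reported modulo genome length (intervals may wrap past the origin).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .composition import REGION_CLASSES, region_class_array
from .model import Mitogenome, revcomp

SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
SSR_CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SSRRecord:
    motif: str        # canonical (lexicographically smallest rotation)
    copies: int
    start: int        # 0-based; end may wrap on circular genomes
    end: int
    motif_class: str


@dataclass(frozen=True)
class DispersedRepeat:
    start_a: int
    start_b: int
    length: int
    orientation: str  # "forward" | "palindromic"
    mismatches: int

    @property
    def interval_a(self) -> tuple[int, int]:
        return (self.start_a, self.start_a + self.length)

    @property
    def interval_b(self) -> tuple[int, int]:
        return (self.start_b, self.start_b + self.length)


@dataclass(frozen=True)
class TandemRepeat:
    period: int
    copies: float
    start: int
    end: int
    consensus: str
    identity: float


def _seq_circ(genome) -> tuple[str, bool]:
    if isinstance(genome, Mitogenome):
        return genome.sequence, genome.circular
    return str(genome).upper(), False


# ---------------------------------------------------------------------------
# SSRs


def _is_primitive(unit: str) -> bool:
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def _canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_ssrs(genome) -> list[SSRRecord]:
    """MISA-style microsatellites: maximal runs of a primitive 1–6 nt motif
    meeting the per-class copy threshold. Overlapping SSRs of different motif
    classes are all reported; compound repeats are not merged."""
    seq, circ = _seq_circ(genome)
    L = len(seq)
    s = seq + seq if circ else seq
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    out: list[SSRRecord] = []
    for k in range(1, 7):
        if len(s) <= k:
            continue
        match = arr[:-k] == arr[k:]
        for rs, re_ in _true_runs(match):
            run_len = re_ - rs  # matched comparisons; region length = run_len + k
            region = run_len + k
            start = rs
            if circ:
                if start >= L:
                    continue
                if start == 0 and region < len(s):
                    # continues from before the origin on the circle; its true
                    # start is found in [0, L) on the doubled sequence
                    if seq[L - 1] == seq[(L - 1 + k) % L]:
                        continue
                region = min(region, L)
            copies = region // k
            if copies < SSR_THRESHOLDS[k]:
                continue
            unit = s[start:start + k]
            if not _is_primitive(unit):
                continue
            out.append(SSRRecord(
                motif=_canonical_rotation(unit), copies=copies,
                start=start, end=start + copies * k,
                motif_class=SSR_CLASS_NAMES[k]))
    out.sort(key=lambda r: (r.start, len(r.motif)))
    return out


# ---------------------------------------------------------------------------
# Dispersed repeats (REPuter-style)

_SEED_K = 7  # a ≥30 nt window with ≤3 interior mismatches contains an exact 7-mer


def _seed_index(s: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(s) - k + 1):
        idx[s[i:i + k]].append(i)
    return idx


def _extend_candidate(x: str, y: str, d: int, i: int, budget: int, max_span: int
                      ) -> tuple[int, int, list[int], bool]:
    """Extend from seed start i (x coords) along diagonal d.

    Returns (lo, hi, mismatch_positions, hit_boundary): the maximal span
    [lo, hi) with at most `budget` mismatches on each side beyond the 4th
    bound, i.e. bounded by the (budget+1)-th mismatch or the sequence end.
    """
    nx, ny = len(x), len(y)
    lo_bound = max(0, -d)
    hi_bound = min(nx, ny - d)
    mism: list[int] = []
    hit_boundary = False
    # walk right
    right_m: list[int] = []
    p = i
    while p < hi_bound and (p - i) < max_span:
        if x[p] != y[p + d]:
            right_m.append(p)
            if len(right_m) > budget:
                break
        p += 1
    else:
        hit_boundary = p >= hi_bound
    hi = right_m[-1] if len(right_m) > budget else p
    # walk left
    left_m: list[int] = []
    p = i - 1
    while p >= lo_bound and (i - p) < max_span:
        if x[p] != y[p + d]:
            left_m.append(p)
            if len(left_m) > budget:
                break
        p -= 1
    else:
        hit_boundary = hit_boundary or p < lo_bound
    lo = left_m[-1] + 1 if len(left_m) > budget else p + 1
    mism = left_m[:budget][::-1] + right_m[:budget]
    return lo, hi, sorted(set(mism)), hit_boundary


def _maximal_windows(lo: int, hi: int, mism: list[int], budget: int
                     ) -> list[tuple[int, int, int]]:
    """All maximal ≤budget-mismatch windows within [lo, hi), trimmed so that
    they start and end on matching positions. Returns (start, end, n_mism)."""
    P = [lo - 1] + mism + [hi]
    wins = []
    if len(mism) <= budget:
        wins.append((lo, hi, len(mism)))
    else:
        for j in range(len(P) - budget - 1):
            wins.append((P[j] + 1, P[j + budget + 1], budget))
    out = []
    mset = set(mism)
    for ws, we, _ in wins:
        while ws < we and ws in mset:
            ws += 1
        while we > ws and (we - 1) in mset:
            we -= 1
        nm = sum(1 for m in mism if ws <= m < we)
        if we > ws:
            out.append((ws, we, nm))
    return out


def _scan_pairs(x: str, y: str, pairs_by_diag: dict[int, list[int]],
                min_len: int, max_len: int, max_mismatch: int,
                circular: bool, L: int) -> set[tuple[int, int, int, int]]:
    """Core seed-and-extend scan; returns (x_start, y_start, length, mism).

    Every maximal window of length ≥ min_len with ≤ max_mismatch interior
    mismatches contains an exact run of ≥ ceil((min_len−max_mismatch) /
    (max_mismatch+1)) matches, so 7-mer seeds cannot miss any window at the
    default parameters. Seeds lying in the same exact run as the previous
    seed on a diagonal produce identical extensions and are skipped.
    """
    found: set[tuple[int, int, int, int]] = set()
    cap = min(max_len, L) if circular else max_len
    for d in sorted(pairs_by_diag):
        same_run_until = -1
        for i in sorted(set(pairs_by_diag[d])):
            if i < same_run_until:
                continue  # same exact run as the previous seed
            lo, hi, mism, boundary = _extend_candidate(
                x, y, d, i, max_mismatch, cap + max_mismatch + 1)
            nxt = [m for m in mism if m >= i]
            same_run_until = nxt[0] if nxt else hi
            if hi - lo < min_len:
                continue
            if circular and boundary:
                continue
            for ws, we, nm in _maximal_windows(lo, hi, mism, max_mismatch):
                length = we - ws
                if not (min_len <= length <= cap):
                    continue
                found.add((ws, ws + d, length, nm))
    return found


def find_dispersed(genome, min_len: int = 30, max_len: int = 5000,
                   max_mismatch: int = 3) -> list[DispersedRepeat]:
    """Maximal forward and palindromic repeated pairs with Hamming distance
    ≤ `max_mismatch` and length in [min_len, max_len].

    Symmetric duplicates are removed by ordering the two intervals; the
    whole-sequence self-match is excluded.
    """
    seq, circ = _seq_circ(genome)
    L = len(seq)
    if L < 2 * min_len:
        return []
    records: set[DispersedRepeat] = set()

    def canon(a: int, b: int, length: int, orient: str, nm: int) -> DispersedRepeat:
        if circ:
            a, b = a % L, b % L
        pa, pb = sorted((a, b))
        return DispersedRepeat(start_a=pa, start_b=pb, length=length,
                               orientation=orient, mismatches=nm)

    # forward: sequence vs itself
    x = seq + seq if circ else seq
    idx = _seed_index(x, _SEED_K)
    diag: dict[int, list[int]] = defaultdict(list)
    for positions in idx.values():
        for ai in range(len(positions)):
            if circ and positions[ai] >= L:
                break  # (i, j) with both in the second copy duplicates (i−L, j−L)
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if circ and d % L == 0:
                    continue
                diag[d].append(positions[ai])
    for ws, ys, length, nm in _scan_pairs(x, x, diag, min_len, max_len,
                                          max_mismatch, circ, L):
        if circ and (ws - ys) % L == 0:
            continue
        if not circ and ws == ys:
            continue
        records.add(canon(ws, ys, length, "forward", nm))

    # palindromic: sequence vs its reverse complement
    rc = revcomp(seq)
    y = rc + rc if circ else rc
    idx_y = _seed_index(y, _SEED_K)
    diag = defaultdict(list)
    for kmer, positions in idx.items():
        for j in idx_y.get(kmer, ()):
            for i in positions:
                if circ and i >= L and j >= L:
                    continue  # duplicates the (i−L, j−L) pair
                diag[j - i].append(i)
    n_y = len(y)
    for ws, ys, length, nm in _scan_pairs(x, y, diag, min_len, max_len,
                                          max_mismatch, circ, L):
        # map the reverse-complement interval back to forward-strand coords
        if circ:
            b_start = (L - (ys % L) - length) % L
        else:
            b_start = n_y - (ys + length)
        records.add(canon(ws, b_start, length, "palindromic", nm))

    # identical intervals (e.g. a perfect self-palindrome) are not repeats
    records = {r for r in records if r.start_a != r.start_b}
    return sorted(records, key=lambda r: (r.start_a, r.start_b, r.length,
                                          r.orientation))


# ---------------------------------------------------------------------------
# Tandem repeats


def find_tandem(genome, min_period: int = 2, max_period: int = 100,
                min_identity: float = 0.85, min_copies: float = 1.9,
                min_exact_seed: int = 14) -> list[TandemRepeat]:
    """Simplified tandem-array detector.

    Candidate periods come from exact self-matches at lag p (runs of at least
    max(p, min_exact_seed) matching comparisons); arrays are extended
    position-by-position while the running identity stays at or above
    `min_identity`. Overlapping calls are resolved greedily by highest
    copies × period, ties by smaller period, then leftmost start.
    """
    seq, circ = _seq_circ(genome)
    L = len(seq)
    s = seq + seq if circ else seq
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    candidates: list[TandemRepeat] = []
    seen: set[tuple[int, int, int]] = set()
    for p in range(min_period, min(max_period, len(s) - 1) + 1):
        match = (arr[:-p] == arr[p:])
        m = match.size
        seed_len = max(p, min_exact_seed)
        for rs, re_ in _true_runs(match):
            if re_ - rs < seed_len:
                continue
            a, b = rs, re_
            matches = b - a
            while b < m:
                nm = matches + int(match[b])
                if nm / (b - a + 1) < min_identity:
                    break
                b += 1
                matches = nm
            while a > 0:
                nm = matches + int(match[a - 1])
                if nm / (b - a + 1) < min_identity:
                    break
                a -= 1
                matches = nm
            total = (b - a) + p  # array length in the sequence
            if circ:
                if a >= L:
                    continue
                total = min(total, L)
            copies = total / p
            if copies < min_copies:
                continue
            key = (p, a, b)
            if key in seen:
                continue
            seen.add(key)
            identity = matches / (b - a)
            # column-majority consensus
            cols: list[dict[str, int]] = [dict() for _ in range(p)]
            for pos in range(a, min(a + total, len(s))):
                c = s[pos]
                col = cols[(pos - a) % p]
                col[c] = col.get(c, 0) + 1
            consensus = "".join(
                min(sorted(col), key=lambda c: (-col[c], c)) if col else "N"
                for col in cols)
            if not _is_primitive(consensus):
                continue  # composed motif: the array is reported at its true period
            candidates.append(TandemRepeat(
                period=p, copies=round(copies, 2), start=a, end=a + total,
                consensus=consensus, identity=identity))
    # greedy overlap resolution
    candidates.sort(key=lambda t: (-(t.copies * t.period), t.period, t.start))
    chosen: list[TandemRepeat] = []
    occupied: list[tuple[int, int]] = []
    for t in candidates:
        span = (t.start % L if circ else t.start, t.end)
        if any(span[0] < e and s0 < span[1] for s0, e in occupied):
            continue
        chosen.append(t)
        occupied.append(span)
    chosen.sort(key=lambda t: t.start)
    return chosen


# ---------------------------------------------------------------------------
# Localization


def localize_repeats(genome: Mitogenome, repeats: list) -> dict[str, int]:
    """Assign each repeat to the region class containing the majority of its
    nucleotides (ties broken toward the earlier class in the partition
    precedence). Dispersed repeats are localized by their first interval.
    Returns per-class counts."""
    classes = region_class_array(genome)
    L = len(genome.sequence)
    counts = {cls: 0 for cls in REGION_CLASSES}
    for rec in repeats:
        if isinstance(rec, DispersedRepeat):
            start, end = rec.start_a, rec.start_a + rec.length
        else:
            start, end = rec.start, rec.end
        idx = np.arange(start, end) % L
        tallies = np.bincount(classes[idx], minlength=len(REGION_CLASSES))
        counts[REGION_CLASSES[int(np.argmax(tallies))]] += 1
    return counts


def repeat_region_class(genome: Mitogenome, start: int, end: int) -> str:
    """Majority region class of a single interval (ties toward precedence)."""
    classes = region_class_array(genome)
    idx = np.arange(start, end) % len(genome.sequence)
    tallies = np.bincount(classes[idx], minlength=len(REGION_CLASSES))
    return REGION_CLASSES[int(np.argmax(tallies))]
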