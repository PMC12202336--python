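"""Repeat detectors: threshold boundaries, plant-and-find, and brute-force
oracle equivalence on small random sequences."""

import numpy as np
import pytest

from mitocomp import (Feature, Mitogenome, find_dispersed, find_ssrs,
                      find_tandem, localize_repeats)
from mitocomp.model import revcomp
from mitocomp.repeats import SSR_THRESHOLDS, repeat_region_class
from tests.conftest import random_dna

# ---------------------------------------------------------------------------
# Independent oracles


def _primitive(unit):
    return (unit + unit).find(unit, 1) == len(unit)


def _canon(unit):
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def ssr_oracle(seq):
    """Char-by-char maximal-run scan over every motif length (linear)."""
    out = set()
    n = len(seq)
    for k in range(1, 7):
        i = 0
        while i + k < n:
            if seq[i] != seq[i + k]:
                i += 1
                continue
            j = i
            while j + k < n and seq[j] == seq[j + k]:
                j += 1
            region = (j - i) + k
            copies = region // k
            unit = seq[i:i + k]
            if copies >= SSR_THRESHOLDS[k] and _primitive(unit):
                out.add((_canon(unit), copies, i))
            i = j + 1
    return out


def dispersed_oracle(seq, min_len=30, max_len=5000, budget=3):
    """Full O(n^2) diagonal scan with sentinel window enumeration (linear)."""
    recs = set()
    n = len(seq)

    def windows_on(x, y, d):
        lo, hi = max(0, -d), min(len(x), len(y) - d)
        if hi - lo < min_len:
            return
        mism = [p for p in range(lo, hi) if x[p] != y[p + d]]
        P = [lo - 1] + mism + [hi]
        cand = ([(lo, hi)] if len(mism) <= budget else
                [(P[j] + 1, P[j + budget + 1]) for j in range(len(P) - budget - 1)])
        ms = set(mism)
        for ws, we in cand:
            while ws < we and ws in ms:
                ws += 1
            while we > ws and (we - 1) in ms:
                we -= 1
            ln = we - ws
            if min_len <= ln <= max_len:
                yield ws, ln, sum(1 for m in mism if ws <= m < we)

    for d in range(1, n - min_len + 1):
        for ws, ln, nm in windows_on(seq, seq, d):
            a, b = sorted((ws, ws + d))
            recs.add((a, b, ln, "forward", nm))
    rc = revcomp(seq)
    for d in range(-(n - min_len), n - min_len + 1):
        for ws, ln, nm in windows_on(seq, rc, d):
            bs = n - (ws + d + ln)
            if ws == bs:
                continue
            a, b = sorted((ws, bs))
            recs.add((a, b, ln, "palindromic", nm))
    return recs


def _as_set(records):
    return {(r.start_a, r.start_b, r.length, r.orientation, r.mismatches)
            for r in records}


# ---------------------------------------------------------------------------
# SSRs


class TestSSR:
    def test_mono_threshold_boundary(self, rng):
        flank1 = random_dna(rng, 60, p=(0.1, 0.4, 0.4, 0.1))
        flank2 = random_dna(rng, 60, p=(0.1, 0.4, 0.4, 0.1))
        hit = [r for r in find_ssrs(flank1 + "A" * 10 + flank2)
               if r.motif_class == "mono"]
        assert [(r.motif, r.copies) for r in hit] == [("A", 10)]
        assert [r for r in find_ssrs(flank1 + "A" * 9 + flank2)
                if r.motif_class == "mono"] == []

    @pytest.mark.parametrize("motif,copies,cls", [
        ("AG", 5, "di"), ("ACT", 4, "tri"), ("ACGT", 3, "tetra"),
        ("ACGTC", 3, "penta"), ("ACGTCA", 3, "hexa")])
    def test_class_thresholds(self, motif, copies, cls):
        seq = "G" * 9 + motif * copies + "C" * 9
        recs = [r for r in find_ssrs(seq) if r.motif_class == cls]
        assert len(recs) == 1
        assert recs[0].copies == copies
        assert recs[0].motif == _canon(motif)
        below = "G" * 9 + motif * (copies - 1) + "C" * 9
        assert [r for r in find_ssrs(below) if r.motif_class == cls] == []

    def test_interval_length_is_motif_times_copies(self):
        recs = find_ssrs("G" * 9 + "ATC" * 4 + "AT" + "G" * 9)
        (r,) = [x for x in recs if x.motif_class == "tri"]
        assert r.end - r.start == 3 * r.copies

    def test_non_primitive_motifs_suppressed(self):
        # AT x 10 must be reported as a di-SSR, never as tetra "ATAT"
        recs = find_ssrs("GC" * 10 + "AT" * 10 + "CG" * 10)
        assert {r.motif_class for r in recs} == {"di"}

    def test_matches_run_scan_oracle(self, rng):
        for _ in range(8):
            seq = random_dna(rng, 10000, p=(0.37, 0.13, 0.13, 0.37))
            got = {(r.motif, r.copies, r.start) for r in find_ssrs(seq)}
            assert got == ssr_oracle(seq)

    def test_circular_rotation_invariance(self, rng):
        base = random_dna(rng, 900) + "A" * 12 + random_dna(rng, 80)
        L = len(base)
        ref = {((r.start + 250) % L, r.motif, r.copies)
               for r in find_ssrs(Mitogenome("x", base, circular=True))}
        rotated = base[-250:] + base[:-250]
        got = {(r.start % L, r.motif, r.copies)
               for r in find_ssrs(Mitogenome("x", rotated, circular=True))}
        assert got == ref


# ---------------------------------------------------------------------------
# Dispersed repeats


def _with_mismatch_fence(rng, unit_a, unit_b, n=600):
    """Plant two copies with 4 immediately-adjacent mismatches on each flank,
    so the maximal windows are exactly the planted units."""
    assert len(unit_a) == len(unit_b)
    k = len(unit_a)
    filler = random_dna(rng, n)
    p1, p2 = 100, 400
    s = list(filler)
    s[p1:p1 + k] = unit_a
    s[p2:p2 + k] = unit_b
    # force mismatches on the 4 flanking columns of the forward diagonal
    d = p2 - p1
    comp = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for off in list(range(-4, 0)) + list(range(k, k + 4)):
        s[p2 + off] = comp[s[p1 + off]]
    return "".join(s), p1, p2


class TestDispersed:
    def test_planted_exact_forward_duplication(self, rng):
        unit = random_dna(rng, 40)
        seq, p1, p2 = _with_mismatch_fence(rng, unit, unit)
        recs = [r for r in find_dispersed(seq) if r.orientation == "forward"]
        exact = [r for r in recs if (r.start_a, r.start_b) == (p1, p2)]
        assert len(exact) == 1
        assert exact[0].mismatches == 0
        assert exact[0].length == 40

    def test_planted_palindromic_pair(self, rng):
        unit = random_dna(rng, 40)
        filler = random_dna(rng, 600)
        seq = filler[:100] + unit + filler[100:400] + revcomp(unit) + filler[400:]
        recs = [r for r in find_dispersed(seq) if r.orientation == "palindromic"]
        hit = [r for r in recs
               if r.start_a <= 100 < r.start_a + r.length and r.length >= 40]
        assert hit, f"planted palindrome not found in {recs}"

    def test_29nt_duplication_below_minimum_not_reported(self, rng):
        """A 29-nt exact duplication fenced by adjacent mismatches yields no
        window reaching the 30-nt minimum."""
        unit = random_dna(rng, 29)
        seq, p1, p2 = _with_mismatch_fence(rng, unit, unit)
        d = p2 - p1
        recs = [r for r in find_dispersed(seq)
                if r.orientation == "forward" and r.start_b - r.start_a == d]
        assert recs == []

    def test_reported_pairs_verify_their_contract(self, rng):
        seq = random_dna(rng, 1500)
        unit = random_dna(rng, 60)
        seq = seq[:200] + unit + seq[200:900] + unit + seq[900:]
        for r in find_dispersed(seq):
            a = seq[r.start_a:r.start_a + r.length]
            if r.orientation == "forward":
                b = seq[r.start_b:r.start_b + r.length]
            else:
                b = revcomp(seq[r.start_b:r.start_b + r.length])
            assert 30 <= r.length <= 5000
            assert r.start_a != r.start_b
            hamming = sum(x != y for x, y in zip(a, b))
            assert hamming == r.mismatches <= 3

    def test_matches_quadratic_oracle(self, rng):
        for i in range(4):
            seq = random_dna(rng, 1200, p=(0.37, 0.13, 0.13, 0.37))
            if i % 2 == 0:  # plant structure in half the cases
                unit = random_dna(rng, 45)
                seq = seq[:150] + unit + seq[150:700] + \
                    (unit if i == 0 else revcomp(unit)) + seq[700:]
            assert _as_set(find_dispersed(seq)) == dispersed_oracle(seq)

    def test_circular_origin_spanning_pair_found(self, rng):
        unit = random_dna(rng, 50)
        filler = random_dna(rng, 800)
        # copy B crosses the origin
        seq = unit[25:] + filler[:400] + unit + filler[400:] + unit[:25]
        g = Mitogenome("c", seq, circular=True)
        recs = [r for r in find_dispersed(g) if r.orientation == "forward"]
        assert any(r.length >= 50 for r in recs)


# ---------------------------------------------------------------------------
# Tandem repeats


class TestTandem:
    def test_planted_hexamer_array(self, rng):
        seq = random_dna(rng, 400) + "ACGTAC" * 4 + random_dna(rng, 400)
        calls = [t for t in find_tandem(seq) if t.period == 6]
        assert len(calls) == 1
        assert calls[0].copies >= 4
        assert calls[0].consensus in {"ACGTAC"[i:] + "ACGTAC"[:i]
                                      for i in range(6)}

    def test_perfect_dimer_reported_with_period_two(self, rng):
        seq = random_dna(rng, 300) + "AT" * 20 + random_dna(rng, 300)
        calls = find_tandem(seq)
        assert any(t.period == 2 and t.copies >= 19 for t in calls)
        # the same array is also a di-SSR: class overlap is allowed
        assert any(r.motif == "AT" and r.copies >= 20 for r in find_ssrs(seq))

    def test_shuffle_negative_control(self, rng):
        base = list(random_dna(rng, 3000) + "ACGTAC" * 5)
        for _ in range(20):
            rng.shuffle(base)
            assert find_tandem("".join(base)) == []

    def test_interval_consistent_with_period_and_copies(self, rng):
        seq = random_dna(rng, 200) + "GATTACA" * 5 + random_dna(rng, 200)
        for t in find_tandem(seq):
            assert abs((t.end - t.start) - t.copies * t.period) < t.period
            assert t.identity >= 0.85
            assert t.copies >= 1.9


# ---------------------------------------------------------------------------
# Localization


def _toy_genome():
    seq = "G" * 500
    return Mitogenome("loc", seq, circular=False, features=[
        Feature(kind="PCG", name="cox1", strand="+", parts=[(0, 100), (200, 300)]),
        Feature(kind="intron", name="i1", strand="+", parts=[(100, 200)],
                parent_gene="cox1"),
    ])


class TestLocalize:
    def test_repeat_inside_intron(self):
        g = _toy_genome()
        assert repeat_region_class(g, 120, 180) == "intron"

    def test_majority_rule_on_straddle(self):
        g = _toy_genome()
        # 60 nt in the exon [240, 300), 40 nt intergenic [300, 340)
        assert repeat_region_class(g, 240, 340) == "PCG_exon"
        # and the mirror case
        assert repeat_region_class(g, 260, 360) == "intergenic"

    def test_counts_match_ground_truth_classes(self, small_bundle):
        from mitocomp import SimulationConfig, simulate
        from mitocomp.simulate import PlantedRepeatSpec
        cfg = SimulationConfig(
            seed=21, n_species=2,
            planted_repeats=(
                PlantedRepeatSpec("SSR", motif="A", copies=12),
                PlantedRepeatSpec("dispersed_forward", length=40,
                                  location_class="intron")))
        genomes, truth = simulate(cfg)
        for g in genomes:
            for rec in truth.repeats[g.species_id]:
                assert repeat_region_class(g, rec["start"], rec["end"]) == \
                    rec["location_class"]

    def test_localize_repeats_totals(self, rng):
        g = _toy_genome()
        ssrs = find_ssrs(Mitogenome(
            "x", "G" * 120 + "A" * 12 + "G" * 368, circular=False,
            features=g.features))
        counts = localize_repeats(g, ssrs)
        assert sum(counts.values()) == len(ssrs)
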