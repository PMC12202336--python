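"""K2P, NG86 and codon alignment against independent oracles."""

import math
from itertools import permutations

import numpy as np
import pytest

from mitocomp import aggregate_rates, codon_align, gene_rates, k2p, ng86
from mitocomp.model import GENETIC_CODE_4, STOP_CODONS_4
from mitocomp.rates import GeneAlignmentError, SaturationError
from tests.conftest import random_dna


def _random_codons(rng, n):
    out = []
    while len(out) < n:
        c = random_dna(rng, 3)
        if c not in STOP_CODONS_4:
            out.append(c)
    return out


class TestK2P:
    def test_identical_sequences(self):
        pair = k2p("ACGT" * 30, "ACGT" * 30)
        assert (pair.P, pair.Q, pair.k2p) == (0.0, 0.0, 0.0)

    def test_formula_evaluation(self):
        """P=0.1, Q=0.05 over 100 sites -> -0.5 ln 0.75 - 0.25 ln 0.9."""
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85  # 10 transitions, 5 transversions
        pair = k2p(a, b)
        assert pair.P == pytest.approx(0.10)
        assert pair.Q == pytest.approx(0.05)
        expected = -0.5 * math.log(1 - 2 * 0.10 - 0.05) - \
            0.25 * math.log(1 - 2 * 0.05)
        assert pair.k2p == pytest.approx(expected, abs=1e-15)

    def test_saturation_raises(self):
        a = "A" * 100
        b = "G" * 50 + "C" * 25 + "A" * 25  # P=0.5, Q=0.25
        with pytest.raises(SaturationError):
            k2p(a, b)

    def test_jensen_bound_k2p_at_least_p_distance(self, rng):
        for _ in range(20):
            a = random_dna(rng, 300)
            b = "".join(ch if rng.random() > 0.15 else
                        rng.choice([x for x in "ACGT" if x != ch])
                        for ch in a)
            try:
                pair = k2p(a, b)
            except SaturationError:
                continue
            p_dist = pair.P + pair.Q
            assert pair.k2p >= p_dist - 1e-12
            if p_dist > 0:
                assert pair.k2p > p_dist

    def test_parameter_recovery_at_length(self):
        """Estimated P/Q converge to simulated values on a 10 kb sequence."""
        rng = np.random.default_rng(7)
        ts_rate, tv_rate = 0.08, 0.04
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
        a = random_dna(rng, 10000)
        b = []
        for ch in a:
            u = rng.random()
            if u < ts_rate:
                b.append(transitions[ch])
            elif u < ts_rate + tv_rate:
                b.append(rng.choice([x for x in "ACGT"
                                     if x != ch and x != transitions[ch]]))
            else:
                b.append(ch)
        pair = k2p(a, "".join(b))
        assert pair.P == pytest.approx(ts_rate, abs=0.01)
        assert pair.Q == pytest.approx(tv_rate, abs=0.01)


def _ng86_oracle(a, b):
    """Independent NG86: explicit per-position site counting and
    permutation-based pathway averaging (stop-avoiding)."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca in STOP_CODONS_4 or cb in STOP_CODONS_4:
            continue
        for codon in (ca, cb):
            for pos in range(3):
                for alt in "ACGT":
                    if alt == codon[pos]:
                        continue
                    mut = codon[:pos] + alt + codon[pos + 1:]
                    if mut not in STOP_CODONS_4 and \
                            GENETIC_CODE_4[mut] == GENETIC_CODE_4[codon]:
                        S += 1 / 6.0   # /3 alternatives, /2 sequences
                    else:
                        N += 1 / 6.0
        diffs = [p for p in range(3) if ca[p] != cb[p]]
        if not diffs:
            continue
        paths = []
        for order in permutations(diffs):
            cur, sd, nd, ok = ca, 0, 0, True
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if nxt in STOP_CODONS_4 and nxt != cb:
                    ok = False
                if GENETIC_CODE_4.get(nxt) == GENETIC_CODE_4.get(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd, ok))
        good = [(s, n) for s, n, ok in paths if ok] or \
            [(s, n) for s, n, _ in paths]
        Sd += sum(s for s, _ in good) / len(good)
        Nd += sum(n for _, n in good) / len(good)

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return S, N, Sd, Nd, jc(Sd / S), jc(Nd / N)


class TestNG86:
    def test_identical_sequences(self):
        cds = "ATG" + "GCT" * 50 + "TAA"
        pair = ng86(cds, cds)
        assert pair.Ka == 0.0 and pair.Ks == 0.0 and pair.ka_ks is None

    def test_single_synonymous_leucine_difference(self):
        """TTA vs TTG (both Leu under code 4) on an identical background."""
        background = _random_codons(np.random.default_rng(0), 99)
        a = "".join(background) + "TTA"
        b = "".join(background) + "TTG"
        pair = ng86(a, b)
        assert pair.Nd == 0.0
        assert pair.Sd == 1.0
        assert pair.Ka == 0.0
        assert pair.Ks > 0.0

    def test_site_totals_sum_to_three_per_codon(self, rng):
        a = "".join(_random_codons(rng, 40))
        b = "".join(_random_codons(rng, 40))
        pair = ng86(a, b)
        assert pair.S + pair.N == pytest.approx(3 * pair.codons)

    def test_symmetry(self, rng):
        a = "".join(_random_codons(rng, 30))
        b = "".join(_random_codons(rng, 30))
        p1, p2 = ng86(a, b), ng86(b, a)
        assert (p1.S, p1.N, p1.Sd, p1.Nd) == (p2.S, p2.N, p2.Sd, p2.Nd)

    def test_matches_pathway_enumeration_oracle(self, rng):
        for _ in range(25):
            base = _random_codons(rng, 30)
            mutated = []
            for c in base:
                c2 = c
                if rng.random() < 0.3:
                    pos = int(rng.integers(0, 3))
                    alt = rng.choice([x for x in "ACGT" if x != c[pos]])
                    cand = c2[:pos] + alt + c2[pos + 1:]
                    if cand not in STOP_CODONS_4:
                        c2 = cand
                mutated.append(c2)
            a, b = "".join(base), "".join(mutated)
            pair = ng86(a, b)
            S, N, Sd, Nd, Ks, Ka = _ng86_oracle(a, b)
            assert pair.S == pytest.approx(S, abs=1e-9)
            assert pair.N == pytest.approx(N, abs=1e-9)
            assert pair.Sd == pytest.approx(Sd, abs=1e-9)
            assert pair.Nd == pytest.approx(Nd, abs=1e-9)
            if Ka is not None:
                assert pair.Ka == pytest.approx(Ka, abs=1e-12)
            if Ks is not None:
                assert pair.Ks == pytest.approx(Ks, abs=1e-12)


class TestCodonAlign:
    def test_identical_inputs_unchanged(self):
        cds = "ATG" + "GCTAAATTG" * 10 + "TAA"
        aln = codon_align({"a": cds, "b": cds})
        assert aln == {"a": cds, "b": cds}

    def test_single_codon_deletion_drops_three_nt(self):
        cds = "ATG" + "GCTAAATTGCCTGAT" * 6 + "TAA"
        deleted = cds[:30] + cds[33:]
        aln = codon_align({"a": cds, "b": deleted})
        assert len(aln["a"]) == len(cds) - 3
        assert len(aln["b"]) == len(deleted)
        assert aln["b"] == deleted

    def test_internal_stop_rejected(self):
        good = "ATG" + "GCT" * 10 + "TAA"
        bad = "ATG" + "GCT" * 4 + "TAA" + "GCT" * 5 + "TAA"
        with pytest.raises(GeneAlignmentError, match="internal stop"):
            codon_align({"a": good, "b": bad})

    def test_rows_equal_length_no_gaps(self, small_bundle):
        _, genomes, _, _ = small_bundle
        aln = codon_align({g.species_id: g.cds("cox1") for g in genomes})
        widths = {len(s) for s in aln.values()}
        assert len(widths) == 1
        assert widths.pop() % 3 == 0
        assert all("-" not in s for s in aln.values())


class TestAggregation:
    def test_single_pair_means_equal_values(self, rng):
        a = "".join(_random_codons(rng, 60))
        b = list(a)
        for pos in range(0, len(b), 30):
            alt = [x for x in "ACGT" if x != b[pos]][0]
            b[pos] = alt
        b = "".join(b)
        if any(b[i:i + 3] in STOP_CODONS_4 for i in range(0, len(b), 3)):
            b = a  # degenerate fallback keeps the identity case valid
        d = k2p(a, b, gene="atp6")
        kk = ng86(a, b, gene="atp6")
        table = aggregate_rates([d], [kk], gene_order=("atp6",))
        assert table.loc["atp6", "mean_k2p"] == pytest.approx(d.k2p)
        assert table.loc["atp6", "mean_ka"] == pytest.approx(kk.Ka)
        assert table.loc["atp6", "mean_ks"] == pytest.approx(kk.Ks)

    def test_zero_pair_gene_is_nan_row(self):
        table = aggregate_rates([], [], gene_order=("cox1",))
        assert np.isnan(table.loc["cox1", "mean_k2p"])
        assert table.loc["cox1", "n_k2p_pairs"] == 0

    def test_simulation_means_match_direct_recomputation(self, small_bundle):
        _, genomes, _, _ = small_bundle
        d_pairs, k_pairs, table = gene_rates(genomes, genes=("cox1", "nad2"))
        for gene in ("cox1", "nad2"):
            vals = [p.k2p for p in d_pairs if p.gene == gene]
            assert table.loc[gene, "mean_k2p"] == pytest.approx(
                sum(vals) / len(vals))

    def test_purifying_simulation_kaks_below_one(self, small_bundle):
        """Nonsynonymous suppression in the generator yields Ka/Ks < 1 for
        every gene, the qualitative signature of purifying selection."""
        _, genomes, _, _ = small_bundle
        _, _, table = gene_rates(genomes)
        ratios = table["mean_ka_ks"].dropna()
        assert len(ratios) == 15
        assert (ratios < 1.0).all()


def _gotoh_score(a, b, match=2.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0):
    """Full Gotoh affine-gap DP, global with penalized end gaps. A gap of
    length g costs gap_open + (g-1) * gap_extend."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlignmentScoreOracle:
    def test_score_equals_full_dp_on_toy_pairs(self, rng):
        from mitocomp import align_cds_to_reference
        checked = 0
        for _ in range(50):
            n1 = int(rng.integers(8, 31))
            n2 = int(rng.integers(8, 31))
            a, b = random_dna(rng, n1), random_dna(rng, n2)
            expected = _gotoh_score(a, b)
            try:
                amap = align_cds_to_reference(a, b, min_identity=0.0)
            except Exception:
                continue
            assert amap.score == pytest.approx(expected, abs=1e-9)
            checked += 1
        assert checked >= 45
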