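"""Local alignment, E-values, precursor screening, hairpin checks, target sites."""

from functools import lru_cache

import numpy as np
import pytest

from lncovule.mirtools import (
    AlignmentParams,
    evalue,
    hairpin_score,
    local_align,
    mirna_target_sites,
    screen_precursors,
)
from lncovule.seqmodel import revcomp

# ---------------------------------------------------------------------------
# independent oracles


def sw_oracle(a: str, b: str, p: AlignmentParams) -> float:
    """Best local score = max over substring pairs of global affine alignment."""

    def global_score(x: str, y: str) -> float:
        @lru_cache(None)
        def f(i, j, state):  # 0 diagonal, 1 gap consuming y, 2 gap consuming x
            if i == len(x) and j == len(y):
                return 0.0
            best = -np.inf
            if i < len(x) and j < len(y):
                s = p.match if x[i] == y[j] else p.mismatch
                best = max(best, s + f(i + 1, j + 1, 0))
            if j < len(y):
                cost = p.gap_extend + (p.gap_open if state != 1 else 0.0)
                best = max(best, cost + f(i, j + 1, 1))
            if i < len(x):
                cost = p.gap_extend + (p.gap_open if state != 2 else 0.0)
                best = max(best, cost + f(i + 1, j, 2))
            return best

        return f(0, 0, 0)

    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, global_score(a[i0:i1], b[j0:j1]))
    return best


def nussinov_oracle(seq: str, min_loop: int = 3) -> int:
    """Explicit enumeration of nested structures (unmemoized recursion)."""
    seq = seq.upper().replace("T", "U")
    can = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

    def count(i, j):
        if j - i < min_loop + 1:
            return 0
        best = count(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in can:
                best = max(best, 1 + count(i + 1, k - 1) + count(k + 1, j))
        return best

    return count(0, len(seq) - 1)


def make_hairpin(stem: str, loop: str = "AACA") -> str:
    return stem + loop + revcomp(stem).replace("T", "U")


# ---------------------------------------------------------------------------


class TestLocalAlign:
    def test_self_alignment(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        r = local_align(seq, seq)
        assert r.score == 2.0 * len(seq)
        assert r.alignment_length == len(seq)
        assert r.identity == 1.0

    def test_no_shared_kmers_low_score(self):
        r = local_align("AAAAAAAAAAAA", "CCCCCCCCCCCC")
        assert r.score < 8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_symmetric_for_symmetric_scoring(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 20))
            b = "".join(rng.choice(list("ACGT"), 15))
            assert local_align(a, b).score == local_align(b, a).score

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(41)
        p = AlignmentParams()
        for _ in range(6):
            la, lb = rng.integers(5, 11, size=2)
            a = "".join(rng.choice(list("ACGT"), la))
            b = "".join(rng.choice(list("ACGT"), lb))
            assert local_align(a, b, p).score == pytest.approx(sw_oracle(a, b, p))
        # a related pair with indels exercises the gap model
        a = "ACGTACCGTA"
        b = "ACGTCCGTA"
        assert local_align(a, b, p).score == pytest.approx(sw_oracle(a, b, p))


class TestEvalue:
    p = AlignmentParams()

    def test_linear_in_search_space(self):
        assert evalue(10, self.p, 100, 400) == pytest.approx(2 * evalue(10, self.p, 100, 200))

    def test_decreasing_in_score(self):
        es = [evalue(s, self.p, 100, 100) for s in (10, 20, 30)]
        assert es[0] > es[1] > es[2]

    def test_unit_expectation_identity(self):
        # S chosen so lambda*S = ln(K*m*n) gives E = 1
        m, n = 137, 542
        s = np.log(self.p.karlin_k * m * n) / self.p.karlin_lambda
        assert evalue(s, self.p, m, n) == pytest.approx(1.0)

    def test_invalid_search_space(self):
        with pytest.raises(ValueError):
            evalue(10, self.p, 0, 10)


class TestScreenPrecursors:
    def test_embedded_precursor_full_ratio(self, default_data):
        """A verbatim planted precursor aligns over its full length (ratio 1)."""
        lnc_seqs = {
            tid: default_data.transcripts[tid].sequence
            for tid, _ in default_data.truth.precursor_truth
        }
        hits = screen_precursors(lnc_seqs, default_data.precursor_db)
        found = {(h.lncrna_id, h.mirna_id) for h in hits}
        for lnc, prec in default_data.truth.precursor_truth:
            assert (lnc, prec) in found
        for h in hits:
            if (h.lncrna_id, h.mirna_id) in set(default_data.truth.precursor_truth):
                assert h.alignment_ratio == pytest.approx(1.0)
                assert h.alignment_length == h.precursor_length
                assert h.evalue < 1e-10

    def test_planted_hit_regions_form_hairpins(self, default_data):
        lnc_seqs = {
            tid: default_data.transcripts[tid].sequence
            for tid, _ in default_data.truth.precursor_truth
        }
        hits = screen_precursors(lnc_seqs, default_data.precursor_db)
        planted = set(default_data.truth.precursor_truth)
        for h in hits:
            if (h.lncrna_id, h.mirna_id) in planted:
                assert h.hairpin

    def test_mutated_precursor_excluded(self, default_data):
        """15% point mutations push the alignment ratio below 0.9."""
        rng = np.random.default_rng(55)
        prec_id, prec = next(iter(default_data.precursor_db.items()))
        excluded = 0
        n_sim = 20
        for s in range(n_sim):
            mutated = list(prec)
            for pos in rng.choice(len(prec), size=int(0.15 * len(prec)), replace=False):
                mutated[pos] = rng.choice([b for b in "ACGT" if b != mutated[pos]])
            host = (
                "".join(rng.choice(list("ACGT"), 300))
                + "".join(mutated)
                + "".join(rng.choice(list("ACGT"), 300))
            )
            hits = screen_precursors({"host": host}, {prec_id: prec}, check_hairpin=False)
            excluded += not hits
        assert excluded / n_sim >= 0.95

    def test_shuffled_lncrnas_give_no_hits(self, default_data):
        rng = np.random.default_rng(77)
        shuffled = {}
        for tid, _ in default_data.truth.precursor_truth:
            seq = list(default_data.transcripts[tid].sequence)
            rng.shuffle(seq)
            shuffled[tid] = "".join(seq)
        hits = screen_precursors(shuffled, default_data.precursor_db, check_hairpin=False)
        assert hits == []

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            screen_precursors({"x": "ACGT" * 30}, {"x": "ACGT" * 10})

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            screen_precursors({}, {"p": "ACGT" * 10})


class TestHairpinScore:
    def test_constructed_hairpin(self):
        rng = np.random.default_rng(1)
        stem = "".join(rng.choice(list("ACGU"), 20))
        pairs, flag = hairpin_score(make_hairpin(stem))
        assert pairs >= 20
        assert flag

    def test_poly_a_no_pairs(self):
        pairs, flag = hairpin_score("A" * 40)
        assert pairs == 0 and not flag

    def test_short_stem_no_flag(self):
        rng = np.random.default_rng(2)
        stem = "".join(rng.choice(list("ACGU"), 8))
        _pairs, flag = hairpin_score(make_hairpin(stem))
        assert not flag

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            hairpin_score("ACGUA")

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(19)
        for _ in range(8):
            n = int(rng.integers(10, 15))
            seq = "".join(rng.choice(list("ACGU"), n))
            assert hairpin_score(seq)[0] == nussinov_oracle(seq)


class TestMirnaTargetSites:
    MIRNA = "UGACAGAAGAGAGUGAGCAC"

    def test_perfect_complement_site(self):
        site = revcomp(self.MIRNA)
        transcript = "AAGG" + site + "CCAA"
        sites = mirna_target_sites(self.MIRNA, transcript)
        assert len(sites) == 1
        assert sites[0].position == 4
        assert sites[0].score == 0.0

    def test_three_seed_mismatches_rejected(self):
        site = list(revcomp(self.MIRNA))
        # three mismatches opposite miRNA positions 3, 6, 9 (inside 2-13): 3 * 2 = 6 > 4
        for mir_pos in (3, 6, 9):
            idx = len(site) - mir_pos
            mir_base = self.MIRNA[mir_pos - 1]
            complement = {"A": "T", "C": "G", "G": "C", "U": "A"}[mir_base]
            site[idx] = {"T": "G", "G": "T", "C": "A", "A": "C"}[complement]
        transcript = "AAGG" + "".join(site) + "CCAA"
        assert mirna_target_sites(self.MIRNA, transcript) == []

    def test_invariant_to_flanks(self):
        site = revcomp(self.MIRNA)
        s1 = mirna_target_sites(self.MIRNA, "A" * 10 + site)
        s2 = mirna_target_sites(self.MIRNA, "GCGC" * 8 + site + "TTTT")
        assert len(s1) == len(s2) == 1
        assert s1[0].score == s2[0].score

    def test_mirna_length_validated(self):
        with pytest.raises(ValueError):
            mirna_target_sites("ACGU", "ACGUACGUACGUACGUACGUACGU")
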