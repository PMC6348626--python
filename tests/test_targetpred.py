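"""Correlation gate, cis classification, duplex energy, pair prediction."""

from functools import lru_cache

import numpy as np
import pytest

from lncovule.annotation import Exon, TranscriptModel
from lncovule.targetpred import (
    CisWindow,
    DUPLEX_INIT,
    LOOP_OPEN,
    LOOP_PER_NT,
    MAX_BULGE,
    TransThresholds,
    _PAIR_CODE,
    _STACK_DG,
    classify_cis,
    correlation_gate,
    duplex_energy,
    predict_pairs,
)


# ---------------------------------------------------------------------------
# independent oracles


class Feature:
    def __init__(self, chrom, start, end, strand, exons=None):
        self.chrom, self.start, self.end, self.strand = chrom, start, end, strand
        self.exons = exons or [Exon(start, end)]


def cis_oracle(lnc, gene, up=10_000, down=20_000):
    """Position-set re-derivation of the cis class from raw coordinates."""
    if lnc.chrom != gene.chrom:
        return "none"
    lnc_pos = set(range(lnc.start, lnc.end + 1))
    gene_pos = set(range(gene.start, gene.end + 1))
    same = lnc.strand == gene.strand
    if lnc_pos & gene_pos:
        if gene_pos <= lnc_pos:
            for e in lnc.exons:
                if gene_pos <= set(range(e.start, e.end + 1)):
                    return "mrna_in_lnc_exon"
            exon_pos = set()
            for e in lnc.exons:
                exon_pos |= set(range(e.start, e.end + 1))
            introns = lnc_pos - exon_pos
            # containment in a single intron == containment in the intronic set
            if gene_pos <= introns:
                return "mrna_in_lnc_intron" if same else "mrna_in_lnc_reverse_intron"
        return "sense_overlap" if same else "antisense_overlap"
    if lnc.end < gene.start:
        gap = len(set(range(lnc.end + 1, gene.start)))
        lnc_upstream = gene.strand == "+"
    else:
        gap = len(set(range(gene.end + 1, lnc.start)))
        lnc_upstream = gene.strand == "-"
    if lnc_upstream and gap <= up:
        return "upstream_window"
    if not lnc_upstream and gap <= down:
        return "downstream_window"
    return "none"


def duplex_oracle(a, b):
    """Exhaustive chain enumeration under the same energy model."""
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")
    n, m = len(a), len(b)

    def pc(i, j):
        return _PAIR_CODE.get((a[i], b[j]), 0)

    @lru_cache(None)
    def tail(i, j):
        best = 0.0
        for i2 in range(i + 1, min(n, i + MAX_BULGE + 2)):
            g1 = i2 - i - 1
            for j2 in range(j - 1, max(-1, j - MAX_BULGE - 2), -1):
                g2 = j - j2 - 1
                c2 = pc(i2, j2)
                if not c2:
                    continue
                if g1 == 0 and g2 == 0:
                    cost = float(_STACK_DG[pc(i, j), c2])
                else:
                    cost = LOOP_OPEN + LOOP_PER_NT * (g1 + g2)
                best = min(best, cost + tail(i2, j2))
        return best

    energies = [DUPLEX_INIT + tail(i, j) for i in range(n) for j in range(m) if pc(i, j)]
    best = min(energies, default=None)
    return None if best is None or best >= 0 else best


# ---------------------------------------------------------------------------
# correlation gate


class TestCorrelationGate:
    def test_perfect_linear(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        passed, pe, sp = correlation_gate(x, 2 * x)
        assert passed and pe == pytest.approx(1.0) and sp == pytest.approx(1.0)

    def test_anticorrelation_mode(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        passed_abs, pe, _ = correlation_gate(x, -x)
        assert passed_abs and pe == pytest.approx(-1.0)
        passed_signed, _, _ = correlation_gate(x, -x, TransThresholds(signed=True))
        assert not passed_signed

    def test_constant_vector_fails_with_nan(self):
        passed, pe, sp = correlation_gate([1.0, 1, 1, 1, 1, 1], [1.0, 2, 3, 4, 5, 6])
        assert not passed and np.isnan(pe) and np.isnan(sp)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            correlation_gate([1, 2, 3], [1, 2])

    def test_matches_definitional_formulas(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            x, y = rng.normal(size=(2, 6))
            _passed, pe, sp = correlation_gate(x, y)
            # direct formulas: centered dot product; rank transform for Spearman
            pe_direct = np.dot(x - x.mean(), y - y.mean()) / (
                np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            )
            rx = np.argsort(np.argsort(x)).astype(float)
            ry = np.argsort(np.argsort(y)).astype(float)
            sp_direct = np.dot(rx - rx.mean(), ry - ry.mean()) / (
                np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
            )
            assert pe == pytest.approx(pe_direct)
            assert sp == pytest.approx(sp_direct)


# ---------------------------------------------------------------------------
# cis classification


class TestClassifyCis:
    def test_upstream_boundary_inclusive(self):
        # lncRNA ends 9,999 bp 5' of a +strand gene: inside the 10 kb window
        lnc = Feature("Chr1", 1_000, 2_000, "+")
        gene = Feature("Chr1", 12_000, 14_000, "+")
        cls, dist = classify_cis(lnc, gene)
        assert (cls, dist) == ("upstream_window", 9_999)

    def test_just_outside_window(self):
        lnc = Feature("Chr1", 1_000, 2_000, "+")
        gene = Feature("Chr1", 12_002, 14_000, "+")
        assert classify_cis(lnc, gene) == ("none", None)

    def test_exactly_at_window_bound(self):
        lnc = Feature("Chr1", 1_000, 2_000, "+")
        gene = Feature("Chr1", 12_001, 14_000, "+")
        assert classify_cis(lnc, gene) == ("upstream_window", 10_000)

    def test_orientation_follows_gene_strand(self):
        lnc = Feature("Chr1", 20_000, 21_000, "+")
        gene_plus = Feature("Chr1", 10_000, 15_000, "+")
        gene_minus = Feature("Chr1", 10_000, 15_000, "-")
        assert classify_cis(lnc, gene_plus)[0] == "downstream_window"
        assert classify_cis(lnc, gene_minus)[0] == "upstream_window"

    def test_containment_classes(self):
        exons = [Exon(1_000, 3_000), Exon(10_000, 12_000)]
        lnc = Feature("Chr1", 1_000, 12_000, "+", exons)
        inside_exon = Feature("Chr1", 1_500, 2_500, "+")
        inside_intron_same = Feature("Chr1", 4_000, 6_000, "+")
        inside_intron_rev = Feature("Chr1", 4_000, 6_000, "-")
        spanning = Feature("Chr1", 2_000, 8_000, "+")
        assert classify_cis(lnc, inside_exon)[0] == "mrna_in_lnc_exon"
        assert classify_cis(lnc, inside_intron_same)[0] == "mrna_in_lnc_intron"
        assert classify_cis(lnc, inside_intron_rev)[0] == "mrna_in_lnc_reverse_intron"
        assert classify_cis(lnc, spanning)[0] == "sense_overlap"

    def test_overlap_strandedness(self):
        lnc = Feature("Chr1", 1_000, 5_000, "+")
        gene_same = Feature("Chr1", 4_000, 9_000, "+")
        gene_anti = Feature("Chr1", 4_000, 9_000, "-")
        assert classify_cis(lnc, gene_same) == ("sense_overlap", 0)
        assert classify_cis(lnc, gene_anti) == ("antisense_overlap", 0)

    def test_different_chromosome(self):
        lnc = Feature("Chr1", 1_000, 2_000, "+")
        gene = Feature("Chr2", 1_000, 2_000, "+")
        assert classify_cis(lnc, gene) == ("none", None)

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_cis(Feature("Chr1", 100, 50, "+"), Feature("Chr1", 1, 10, "+"))

    def test_agrees_with_interval_oracle_on_random_pairs(self):
        rng = np.random.default_rng(99)
        n_checked = 0
        for _ in range(10_000):
            chrom_l = f"Chr{rng.integers(1, 3)}"
            chrom_g = f"Chr{rng.integers(1, 3)}"
            s1 = int(rng.integers(1, 60_000))
            lnc_len = int(rng.integers(200, 8_000))
            if rng.random() < 0.5:
                exons = [Exon(s1, s1 + lnc_len - 1)]
            else:
                e1 = lnc_len // 3
                gap = int(rng.integers(200, 5_000))
                exons = [Exon(s1, s1 + e1 - 1), Exon(s1 + e1 + gap, s1 + lnc_len + gap - 1)]
            lnc = Feature(chrom_l, exons[0].start, exons[-1].end, "+-"[rng.integers(2)], exons)
            s2 = int(rng.integers(1, 60_000))
            gene = Feature(chrom_g, s2, s2 + int(rng.integers(100, 4_000)), "+-"[rng.integers(2)])
            cls, _dist = classify_cis(lnc, gene)
            assert cls == cis_oracle(lnc, gene), (vars(lnc), vars(gene))
            n_checked += 1
        assert n_checked == 10_000


# ---------------------------------------------------------------------------
# duplex energy


class TestDuplexEnergy:
    def test_no_complementarity(self):
        assert duplex_energy("AAAAAAAAAA", "AAAAAAAAAA") is None

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = "".join(rng.choice(list("ACGU"), 30))
            b = "".join(rng.choice(list("ACGU"), 25))
            ra, rb = duplex_energy(a, b), duplex_energy(b, a)
            if ra is None:
                assert rb is None
            else:
                assert ra[0] == pytest.approx(rb[0])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            duplex_energy("", "ACGU")

    def test_perfect_complement_strongly_negative(self):
        from lncovule.seqmodel import revcomp

        rng = np.random.default_rng(7)
        a = "".join(rng.choice(list("ACGU"), 40))
        energy, pairs = duplex_energy(a, revcomp(a))
        assert energy < -30
        assert len(pairs) == 40

    def test_monotone_under_complementary_extension(self):
        from lncovule.seqmodel import revcomp

        rng = np.random.default_rng(13)
        a = "".join(rng.choice(list("ACGU"), 20))
        b = revcomp(a)
        e1 = duplex_energy(a, b)[0]
        # append one complementary stack to both molecules
        e2 = duplex_energy(a + "G", "C" + b)[0]
        assert e2 <= e1

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(31)
        from lncovule.seqmodel import revcomp

        cases = []
        for _ in range(12):
            la, lb = rng.integers(6, 13, size=2)
            cases.append(("".join(rng.choice(list("ACGU"), la)), "".join(rng.choice(list("ACGU"), lb))))
        # include guaranteed-pairing cases
        for _ in range(4):
            a = "".join(rng.choice(list("ACGU"), 10))
            cases.append((a, revcomp(a)))
        for a, b in cases:
            got = duplex_energy(a, b)
            expected = duplex_oracle(a, b)
            if expected is None:
                assert got is None, (a, b)
            else:
                assert got is not None and got[0] == pytest.approx(expected), (a, b)


# ---------------------------------------------------------------------------
# pair prediction on generator truth


class TestPredictPairs:
    def test_planted_pairs_recovered(self, default_data, grouped_fpkm):
        data = default_data
        lnc_ids = [t for t, l in data.truth.lncRNA_labels.items() if l == "noncoding"]
        mrna_ids = [t for t, l in data.truth.lncRNA_labels.items() if l == "coding"]
        pairs, counts = predict_pairs(
            lnc_ids, mrna_ids, data.genes, grouped_fpkm, data.transcript_seqs
        )
        emitted = {(p.lncRNA, p.mRNA): p for p in pairs}
        gene_to_tid = {g.gene_id: g.transcripts[0].transcript_id for g in data.genes}
        planted_cis = {
            (lnc, gene_to_tid[gene]): cls for lnc, gene, cls in data.truth.cis_truth
        }
        n_cis = sum(key in emitted for key in planted_cis)
        assert n_cis >= 0.9 * len(planted_cis)
        for key, cls in planted_cis.items():
            if key in emitted:
                assert emitted[key].cis_class == cls
                assert emitted[key].mechanism == "cis"
        planted_trans = set(data.truth.trans_truth)
        n_trans = sum(key in emitted for key in planted_trans)
        assert n_trans >= 0.85 * len(planted_trans)
        for key in planted_trans & set(emitted):
            assert emitted[key].mechanism == "trans"
            assert emitted[key].energy < -30
        false = set(emitted) - set(planted_cis) - planted_trans
        assert len(false) <= max(1, 0.1 * len(emitted))

    def test_distant_uncomplementary_pair_not_emitted(self, default_data, grouped_fpkm):
        # planted cis lncRNA against a gene on the other chromosome: no pair
        data = default_data
        lnc = data.truth.cis_truth[0][0]
        far_mrna = next(
            t.transcript_id
            for t in data.transcripts.values()
            if t.biotype == "mRNA" and t.chrom != data.transcripts[lnc].chrom
        )
        pairs, _ = predict_pairs(
            [lnc], [far_mrna], data.genes, grouped_fpkm, data.transcript_seqs
        )
        assert pairs == []

    def test_missing_expression_named(self, default_data, grouped_fpkm):
        with pytest.raises(KeyError, match="GHOST"):
            predict_pairs(["GHOST"], [], default_data.genes, grouped_fpkm, {})


def test_cis_window_validation():
    with pytest.raises(ValueError):
        CisWindow(upstream_bp=-1)
    with pytest.raises(ValueError):
        TransThresholds(max_energy=5.0)
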