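"""Pairing of differentially expressed lncRNAs with candidate target mRNAs.

A candidate pair must first pass a co-expression gate (|Pearson| >= 0.6 and
|Spearman| >= 0.6 across the six integrated groups; absolute values by
default because both positively and negatively correlated partners are
reported).  A gated pair becomes:

* **cis** when the lncRNA gene lies within 10 kb upstream / 20 kb downstream
  of the coding gene (boundaries inclusive, orientation by the coding gene's
  strand) or overlaps it — with overlaps refined into sense / antisense
  overlap and exon / intron / reverse-intron containment classes;
* **trans** when the intermolecular RNA-RNA hybridization energy is below
  -30 kcal/mol, computed by a nearest-neighbor duplex energy minimization
  (Watson-Crick and G:U stacks, linear bulge/interior-loop penalties, duplex
  initiation penalty, no intramolecular pairs).

Containment classes take precedence over plain overlap, which takes
precedence over the distance windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Exon, GeneModel, TranscriptModel

__all__ = [
    "CisWindow",
    "TransThresholds",
    "LncTargetPair",
    "CIS_CLASSES",
    "correlation_gate",
    "classify_cis",
    "duplex_energy",
    "predict_pairs",
]


@dataclass(frozen=True)
class CisWindow:
    upstream_bp: int = 10_000
    downstream_bp: int = 20_000

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window bounds must be >= 0")


@dataclass(frozen=True)
class TransThresholds:
    max_energy: float = -30.0   # kcal/mol
    min_spearman: float = 0.6
    min_pearson: float = 0.6
    signed: bool = False        # False: gate on |r|; True: require positive r

    def __post_init__(self) -> None:
        if self.max_energy >= 0:
            raise ValueError("max_energy must be negative")
        for r in (self.min_spearman, self.min_pearson):
            if not 0 <= r <= 1:
                raise ValueError("correlation thresholds are magnitudes in [0, 1]")


CIS_CLASSES = (
    "upstream_window",
    "downstream_window",
    "sense_overlap",
    "antisense_overlap",
    "mrna_in_lnc_exon",
    "mrna_in_lnc_intron",
    "mrna_in_lnc_reverse_intron",
    "none",
)


@dataclass
class LncTargetPair:
    lncRNA: str
    mRNA: str
    mechanism: str          # "cis" | "trans"
    cis_class: str          # CIS_CLASSES entry; "none" for trans pairs
    distance: int | None    # bp between gene boundaries (cis window classes)
    energy: float | None    # kcal/mol (trans pairs)
    pearson: float
    spearman: float


# ---------------------------------------------------------------------------
# correlation gate


def correlation_gate(
    x: Sequence[float],
    y: Sequence[float],
    thresholds: TransThresholds = TransThresholds(),
) -> tuple[bool, float, float]:
    """Pearson/Spearman co-expression gate over matched group profiles.

    Returns ``(passed, pearson, spearman)``.  Constant profiles leave both
    coefficients undefined (nan) and fail the gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles have different lengths")
    if x.size < 3:
        raise ValueError("need at least 3 matched groups")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return False, float("nan"), float("nan")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    if thresholds.signed:
        passed = pearson >= thresholds.min_pearson and spearman >= thresholds.min_spearman
    else:
        passed = (
            abs(pearson) >= thresholds.min_pearson
            and abs(spearman) >= thresholds.min_spearman
        )
    return bool(passed), pearson, spearman


# ---------------------------------------------------------------------------
# cis classification


def _lnc_exons(lnc) -> list[Exon]:
    if isinstance(lnc, GeneModel) and lnc.transcripts:
        return list(lnc.transcripts[0].exons)
    exons = getattr(lnc, "exons", None)
    if exons:
        return [e if isinstance(e, Exon) else Exon(*e) for e in exons]
    return [Exon(lnc.start, lnc.end)]


def classify_cis(lnc, gene, window: CisWindow = CisWindow()) -> tuple[str, int | None]:
    """Positional relation of a lncRNA gene to a coding gene.

    ``lnc`` and ``gene`` need ``chrom`` / ``start`` / ``end`` / ``strand``
    attributes; the lncRNA's exon chain (for the containment classes) is taken
    from its transcript when available.  Returns ``(cis_class, distance)``:
    distance is the bp count strictly between gene boundaries for the window
    classes, 0 for overlap/containment, ``None`` for ``"none"``.
    """
    if lnc.start > lnc.end or gene.start > gene.end:
        raise ValueError("malformed interval: start > end")
    if lnc.chrom != gene.chrom:
        return "none", None

    same_strand = lnc.strand == gene.strand

    if lnc.start <= gene.end and gene.start <= lnc.end:  # spans overlap
        if lnc.start <= gene.start and gene.end <= lnc.end:
            exons = _lnc_exons(lnc)
            for e in exons:
                if e.start <= gene.start and gene.end <= e.end:
                    return "mrna_in_lnc_exon", 0
            introns = TranscriptModel("_", "_", lnc.chrom, lnc.strand, exons).introns
            for i in introns:
                if i.start <= gene.start and gene.end <= i.end:
                    return ("mrna_in_lnc_intron" if same_strand else "mrna_in_lnc_reverse_intron"), 0
        return ("sense_overlap" if same_strand else "antisense_overlap"), 0

    # disjoint: gap measured strictly between boundaries
    if lnc.end < gene.start:
        gap = gene.start - lnc.end - 1
        lnc_is_upstream = gene.strand == "+"
    else:
        gap = lnc.start - gene.end - 1
        lnc_is_upstream = gene.strand == "-"

    if lnc_is_upstream and gap <= window.upstream_bp:
        return "upstream_window", gap
    if not lnc_is_upstream and gap <= window.downstream_bp:
        return "downstream_window", gap
    return "none", None


# ---------------------------------------------------------------------------
# duplex hybridization energy

_PAIR_CODE = {
    ("A", "U"): 1, ("U", "A"): 2, ("C", "G"): 3,
    ("G", "C"): 4, ("G", "U"): 5, ("U", "G"): 6,
}

# Watson-Crick nearest-neighbor stack energies (kcal/mol), keyed by
# "XY/WZ" = 5'-XY-3' paired with 3'-WZ-5' (pairs X:W and Y:Z).
_WC_STACKS = {
    "AA/UU": -0.93, "AU/UA": -1.10, "UA/AU": -1.33, "CU/GA": -2.08,
    "CA/GU": -2.11, "GU/CA": -2.24, "GA/CU": -2.35, "CG/GC": -2.36,
    "GG/CC": -3.26, "GC/CG": -3.42,
}

DUPLEX_INIT = 4.1        # duplex initiation penalty, kcal/mol
LOOP_OPEN = 6.0          # bulge / interior-loop opening penalty
LOOP_PER_NT = 1.5        # linear penalty per unpaired nt in the loop
MAX_BULGE = 4           # max unpaired nt per strand between consecutive pairs
_WOBBLE_STACK = -1.2     # stack with one G:U pair
_WOBBLE_WOBBLE = -0.5    # stack with two G:U pairs


def _stack_table() -> np.ndarray:
    """7x7 stack-energy matrix indexed by (pair_code_prev, pair_code_next)."""
    code_pair = {v: k for k, v in _PAIR_CODE.items()}
    dg = np.full((7, 7), np.inf)
    for c1 in range(1, 7):
        for c2 in range(1, 7):
            (x, xp), (y, yp) = code_pair[c1], code_pair[c2]
            key = f"{x}{y}/{xp}{yp}"
            alt = f"{yp}{xp}/{y}{x}"  # same physical stack read from the other strand
            if key in _WC_STACKS:
                dg[c1, c2] = _WC_STACKS[key]
            elif alt in _WC_STACKS:
                dg[c1, c2] = _WC_STACKS[alt]
            else:
                n_wobble = (c1 >= 5) + (c2 >= 5)
                dg[c1, c2] = _WOBBLE_STACK if n_wobble == 1 else _WOBBLE_WOBBLE
    return dg


_STACK_DG = _stack_table()


def _rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return seq


def duplex_energy(a: str, b: str) -> tuple[float, list[tuple[int, int]]] | None:
    """Minimum-free-energy intermolecular duplex of two RNA strands.

    Returns ``(energy, pairs)`` where ``pairs`` lists ``(i, j)`` indices of
    ``a[i]:b[j]`` base pairs (a read 5'->3', b antiparallel), or ``None``
    when no stable duplex (energy < 0) exists.  The model: Watson-Crick and
    G:U nearest-neighbor stacks, a duplex initiation penalty, and bulges /
    interior loops penalized linearly with at most ``MAX_BULGE`` unpaired nt
    per strand between consecutive pairs; no intramolecular structure.
    """
    a = _rna(a)
    b = _rna(b)
    n, m = len(a), len(b)
    code = np.zeros((n, m), dtype=np.int8)
    for (x, y), c in _PAIR_CODE.items():
        code[np.ix_([i for i, ch in enumerate(a) if ch == x],
                    [j for j, ch in enumerate(b) if ch == y])] = c

    INF = np.inf
    G = MAX_BULGE
    H = np.full((n, m), INF)
    valid = code > 0

    def windowed_min(row: np.ndarray) -> np.ndarray:
        # P[j] = min_{g2=0..G} row[j+g2] + LOOP_PER_NT*g2
        out = row.copy()
        for g in range(1, G + 1):
            shifted = np.full(m, INF)
            shifted[: m - g] = row[g:] + LOOP_PER_NT * g
            np.minimum(out, shifted, out=out)
        return out

    h_prev: np.ndarray | None = None
    p_rows: list[np.ndarray] = []  # P rows for the last G+1 values of i
    for i in range(n):
        h = np.full(m, INF)
        v = valid[i]
        if v.any():
            h[v] = DUPLEX_INIT
            if h_prev is not None:
                # stacking on the adjacent previous pair (i-1, j+1)
                prev = np.full(m, INF)
                prev[:-1] = h_prev[1:]
                prev_code = np.zeros(m, dtype=np.int8)
                prev_code[:-1] = code[i - 1, 1:]
                ok = v & np.isfinite(prev) & (prev_code > 0)
                if ok.any():
                    stack = prev[ok] + _STACK_DG[prev_code[ok], code[i, ok]]
                    h[ok] = np.minimum(h[ok], stack)
                # loop transition from H[i-1-g1][j+1+g2], g1, g2 <= G each
                q = np.full(m, INF)
                for g1, prow in enumerate(reversed(p_rows)):
                    np.minimum(q, prow + LOOP_PER_NT * g1, out=q)
                loop = np.full(m, INF)
                loop[:-1] = q[1:] + LOOP_OPEN
                h[v] = np.minimum(h[v], loop[v])
        p_rows.append(windowed_min(h))
        if len(p_rows) > G + 1:
            p_rows.pop(0)
        H[i] = h
        h_prev = h

    best = H.min()
    if not np.isfinite(best) or best >= -1e-9:  # tolerance for exact-zero sums
        return None
    # traceback (loop search bounded; ample for the linear penalties used)
    i, j = np.unravel_index(int(H.argmin()), H.shape)
    pairs = [(int(i), int(j))]
    while abs(H[i, j] - DUPLEX_INIT) > 1e-9:  # until the duplex-opening pair
        found = False
        # stack predecessor
        if i > 0 and j + 1 < m and code[i - 1, j + 1] > 0 and np.isfinite(H[i - 1, j + 1]):
            e = H[i - 1, j + 1] + _STACK_DG[code[i - 1, j + 1], code[i, j]]
            if abs(e - H[i, j]) < 1e-9:
                i, j = i - 1, j + 1
                pairs.append((int(i), int(j)))
                found = True
        if not found:
            for i0 in range(i - 1, max(-1, i - 2 - G), -1):
                for j0 in range(j + 1, min(m, j + 2 + G)):
                    g1, g2 = i - i0 - 1, j0 - j - 1
                    g = g1 + g2
                    if g < 1 or g1 > G or g2 > G or not np.isfinite(H[i0, j0]):
                        continue
                    e = H[i0, j0] + LOOP_OPEN + LOOP_PER_NT * g
                    if abs(e - H[i, j]) < 1e-9:
                        i, j = i0, j0
                        pairs.append((int(i), int(j)))
                        found = True
                        break
                if found:
                    break
        if not found:
            break
    pairs.reverse()
    return float(best), pairs


# ---------------------------------------------------------------------------
# pair prediction


def predict_pairs(
    de_lncRNAs: Sequence[str],
    mRNAs: Sequence[str],
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    sequences: Mapping[str, str],
    window: CisWindow = CisWindow(),
    thresholds: TransThresholds = TransThresholds(),
    seed_kmer: int | None = 12,
) -> tuple[list[LncTargetPair], dict[str, int]]:
    """Emit lncRNA-mRNA pairs by correlation gating plus cis/trans mechanism.

    ``expression`` is the integrated (group-level) FPKM matrix indexed by
    transcript.  A pair is emitted when the correlation gate passes and either
    the cis class is not "none" (a cis pair) or the duplex energy is below
    ``thresholds.max_energy`` (a trans pair).  Returns the pairs and per-class
    counts (trans counted under ``"trans"``).

    ``seed_kmer`` enables a BLAST-style seed heuristic for the trans search:
    the duplex DP runs only when the two transcripts share a perfect
    complementary word of that length.  A duplex strong enough to clear the
    -30 kcal/mol bar essentially always contains such a word; set ``None``
    for the exhaustive search.
    """
    gene_of_tx: dict[str, GeneModel] = {}
    tx_of_gene: dict[str, TranscriptModel] = {}
    for g in genes:
        for t in g.transcripts:
            gene_of_tx[t.transcript_id] = g
            tx_of_gene.setdefault(g.gene_id, t)

    def profile(tid: str) -> np.ndarray:
        if tid not in expression.index:
            raise KeyError(f"no expression profile for transcript {tid!r}")
        return expression.loc[tid].to_numpy(dtype=float)

    kmer_cache: dict[str, set[str]] = {}

    def _shares_seed(lnc: str, mrna: str) -> bool:
        if seed_kmer is None:
            return True
        k = seed_kmer
        if lnc not in kmer_cache:
            s = _rna(sequences[lnc])
            kmer_cache[lnc] = {s[i : i + k] for i in range(len(s) - k + 1)}
        from .seqmodel import revcomp

        rc = _rna(revcomp(sequences[mrna]))
        return any(rc[i : i + k] in kmer_cache[lnc] for i in range(len(rc) - k + 1))

    pairs: list[LncTargetPair] = []
    counts = {c: 0 for c in CIS_CLASSES if c != "none"}
    counts["trans"] = 0
    for lnc in de_lncRNAs:
        x = profile(lnc)
        lnc_feature = gene_of_tx.get(lnc)
        for mrna in mRNAs:
            if mrna == lnc:
                continue
            y = profile(mrna)
            passed, pe, sp = correlation_gate(x, y, thresholds)
            if not passed:
                continue
            cls, dist = "none", None
            if lnc_feature is not None and mrna in gene_of_tx:
                cls, dist = classify_cis(lnc_feature, gene_of_tx[mrna], window)
            if cls != "none":
                pairs.append(LncTargetPair(lnc, mrna, "cis", cls, dist, None, pe, sp))
                counts[cls] += 1
                continue
            if lnc not in sequences:
                raise KeyError(f"no sequence for transcript {lnc!r}")
            if mrna not in sequences:
                raise KeyError(f"no sequence for transcript {mrna!r}")
            if not _shares_seed(lnc, mrna):
                continue
            duplex = duplex_energy(sequences[lnc], sequences[mrna])
            if duplex is not None and duplex[0] < thresholds.max_energy:
                pairs.append(LncTargetPair(lnc, mrna, "trans", "none", None, duplex[0], pe, sp))
                counts["trans"] += 1
    return pairs, counts


def pairs_table(pairs: list[LncTargetPair]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pairs])
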