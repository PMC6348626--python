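"""miRNA-precursor screening of lncRNAs and hairpin verification.

Every lncRNA is locally aligned (Smith-Waterman, blastn-like scoring) against
a miRNA-precursor database; hits whose alignment covers at least 90% of the
precursor length are retained and reported with a Karlin-Altschul E-value.
The aligned lncRNA window is then checked for hairpin-forming capability: a
base-pair-maximization fold plus a search for a long perfect stem (>= 16
stacked pairs, G:U allowed) around the hit.

Plant-style miRNA target-site scanning (for the ceRNA network) scores the
reverse-complement match of a mature miRNA against transcript windows with
the usual penalty scheme: mismatch 1, G:U wobble 0.5, penalties doubled at
positions 2-13, keep sites scoring <= 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio import Align

from .seqmodel import revcomp

__all__ = [
    "AlignmentParams",
    "PrecursorHit",
    "TargetSite",
    "local_align",
    "evalue",
    "screen_precursors",
    "hairpin_score",
    "mirna_target_sites",
]


@dataclass(frozen=True)
class AlignmentParams:
    """blastn-like local alignment scoring and Karlin-Altschul statistics.

    A gap of length k costs ``|gap_open| + k * |gap_extend|`` (existence +
    per-base), matching megablast's accounting.  ``karlin_lambda`` is in
    natural-log units.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    karlin_k: float = 0.711
    karlin_lambda: float = 1.37

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.karlin_lambda <= 0:
            raise ValueError("karlin_lambda must be positive")


@dataclass
class LocalAlignment:
    score: float
    query_span: tuple[int, int]    # 0-based half-open on the query
    subject_span: tuple[int, int]  # 0-based half-open on the subject
    identity: float                # matches / alignment columns
    alignment_length: int          # alignment columns (matches+mismatches+gaps)


@dataclass
class PrecursorHit:
    """One retained lncRNA x miRNA-precursor alignment (Table-2 style schema)."""

    mirna_id: str
    lncrna_id: str
    precursor_length: int
    lncrna_length: int
    alignment_length: int
    evalue: float
    alignment_ratio: float  # identical positions / precursor length
    hairpin: bool


def _dna(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    return seq


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # PairwiseAligner's open score applies to the first gap base
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def local_align(query: str, subject: str, params: AlignmentParams = AlignmentParams()) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of ``query`` vs ``subject``."""
    query = _dna(query)
    subject = _dna(subject)
    aligner = _aligner(params)
    score = aligner.score(query, subject)
    if score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0), 0.0, 0)
    aln = next(iter(aligner.align(query, subject)))  # leftmost-highest tie-break
    qblocks, sblocks = aln.aligned
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]), int(sblocks[-1][1]))
    matches = sum(
        1
        for (qs, qe), (ss, se) in zip(qblocks, sblocks)
        for k in range(qe - qs)
        if query[qs + k] == subject[ss + k]
    )
    alen = int(aln.length)
    return LocalAlignment(float(score), qspan, sspan, matches / alen if alen else 0.0, alen)


def evalue(score: float, params: AlignmentParams, m: int, n: int) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S).

    The equivalent bit score is (lambda*S - ln K) / ln 2.
    """
    if m <= 0 or n <= 0:
        raise ValueError("search-space sizes must be positive")
    return float(params.karlin_k * m * n * np.exp(-params.karlin_lambda * score))


def screen_precursors(
    lncRNAs: Mapping[str, str],
    precursors: Mapping[str, str],
    min_ratio: float = 0.9,
    params: AlignmentParams = AlignmentParams(),
    check_hairpin: bool = True,
    hairpin_flank: int = 10,
) -> list[PrecursorHit]:
    """Align every lncRNA against every precursor; keep high-coverage hits.

    The alignment ratio is the number of identically aligned positions over
    the precursor length, i.e. the fraction of the precursor recovered
    exactly; hits with ratio >= ``min_ratio`` (ties retained) are reported.
    (A full-length alignment with mismatches therefore has ratio < 1, which
    is how published screens report such hits.)  One lncRNA may hit
    several precursors and several lncRNAs the same precursor.  Duplicate IDs
    across the two inputs are rejected.
    """
    if not lncRNAs or not precursors:
        raise ValueError("both FASTA inputs must be non-empty")
    dup = set(lncRNAs) & set(precursors)
    if dup:
        raise ValueError(f"duplicate sequence IDs across inputs: {sorted(dup)}")
    hits: list[PrecursorHit] = []
    for lnc_id, lnc_seq in lncRNAs.items():
        lnc_seq = _dna(lnc_seq)
        for mir_id, pre_seq in precursors.items():
            pre_seq = _dna(pre_seq)
            aln = local_align(lnc_seq, pre_seq, params)
            if aln.alignment_length == 0:
                continue
            matches = aln.identity * aln.alignment_length
            ratio = matches / len(pre_seq)
            if ratio < min_ratio:
                continue
            hp = True
            if check_hairpin:
                w0 = max(0, aln.query_span[0] - hairpin_flank)
                w1 = min(len(lnc_seq), aln.query_span[1] + hairpin_flank)
                _pairs, hp = hairpin_score(lnc_seq[w0:w1])
            hits.append(
                PrecursorHit(
                    mirna_id=mir_id,
                    lncrna_id=lnc_id,
                    precursor_length=len(pre_seq),
                    lncrna_length=len(lnc_seq),
                    alignment_length=aln.alignment_length,
                    evalue=evalue(aln.score, params, len(lnc_seq), len(pre_seq)),
                    alignment_ratio=ratio,
                    hairpin=bool(hp),
                )
            )
    hits.sort(key=lambda h: (h.evalue, h.mirna_id, h.lncrna_id))
    return hits


# ---------------------------------------------------------------------------
# hairpin verification

_CAN_PAIR = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def _pairable(x: str, y: str) -> bool:
    return (x, y) in _CAN_PAIR


def hairpin_score(window: str, min_loop: int = 3, min_stem: int = 16) -> tuple[int, bool]:
    """Base-pair maximization fold and stem-loop check of an RNA window.

    Returns ``(max_pairs, stem_loop)``: the maximum number of nested base
    pairs (Watson-Crick + G:U, hairpin loops >= ``min_loop``) and whether the
    window contains a perfect stem of at least ``min_stem`` stacked pairs
    (again with loop >= ``min_loop`` inside the innermost pair).
    """
    seq = _dna(window).replace("T", "U")
    n = len(seq)
    if n < 10:
        raise ValueError("window too short (need >= 10 nt)")

    # Nussinov base-pair maximization: dp[i][j] = max pairs in seq[i..j]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]  # j unpaired
            for k in range(i, j - min_loop):  # j paired with k
                if _pairable(seq[k], seq[j]):
                    left = dp[i, k - 1] if k > i else 0
                    best = max(best, left + 1 + dp[k + 1, j - 1])
            dp[i, j] = best
    max_pairs = int(dp[0, n - 1])

    # longest perfect stem: r(i,j) = consecutive stacked pairs inward from (i,j)
    best_stem = 0
    r = np.zeros((n, n), dtype=np.int32)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            if _pairable(seq[i], seq[j]):
                inner = r[i + 1, j - 1] if (i + 1) < (j - 1) else 0
                r[i, j] = inner + 1
    # a stem of depth d rooted at (i, j) is valid if its innermost pair
    # (i+d-1, j-d+1) encloses a loop of >= min_loop unpaired bases
    for i in range(n):
        for j in range(i + 1, n):
            d = int(r[i, j])
            while d > 0:
                if (j - d + 1) - (i + d - 1) - 1 >= min_loop:
                    break
                d -= 1
            best_stem = max(best_stem, d)
    return max_pairs, best_stem >= min_stem


# ---------------------------------------------------------------------------
# miRNA target sites


@dataclass
class TargetSite:
    position: int      # 0-based start of the site on the transcript
    score: float       # penalty score (0 = perfect complement)
    duplex: str        # three-line duplex rendering


def mirna_target_sites(
    mature: str,
    transcript: str,
    max_score: float = 4.0,
) -> list[TargetSite]:
    """Scan a transcript for plant-style miRNA target sites.

    The reverse complement of each transcript window is compared to the miRNA
    5'->3'; penalties: mismatch 1, G:U wobble 0.5, doubled at miRNA positions
    2-13; sites scoring <= ``max_score`` are reported.  Indels are not
    considered (sites are ungapped).
    """
    mature = _dna(mature).replace("T", "U")
    if not 19 <= len(mature) <= 24:
        raise ValueError("mature miRNA must be 19-24 nt")
    transcript = _dna(transcript).replace("T", "U")
    k = len(mature)
    sites: list[TargetSite] = []
    for start in range(len(transcript) - k + 1):
        window = transcript[start : start + k]
        site_rc = revcomp(window).replace("T", "U")  # aligned 5'->3' with the miRNA
        score = 0.0
        marks = []
        for pos, (a, b) in enumerate(zip(mature, site_rc), start=1):
            if a == b:
                pen = 0.0
                marks.append("|")
            elif (a, b) in (("G", "A"), ("U", "C")):
                # miRNA G opposite site U, or miRNA U opposite site G, i.e.
                # a G:U wobble in the duplex: rc mismatch patterns G/A and U/C
                pen = 0.5
                marks.append("o")
            else:
                pen = 1.0
                marks.append(" ")
            if 2 <= pos <= 13:
                pen *= 2.0
            score += pen
            if score > max_score:
                break
        if score <= max_score:
            duplex = f"miRNA 5'-{mature}-3'\n        {''.join(marks)}\nsite  3'-{revcomp(site_rc).replace('T', 'U')[::-1]}-5'"
            sites.append(TargetSite(position=start, score=score, duplex=duplex))
    return sites
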