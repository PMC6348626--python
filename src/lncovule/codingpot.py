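"""Coding-potential scoring and the 3-of-4 lncRNA classification vote.

A transcript is called lncRNA when it is longer than 200 nt and at least three
of four independent judgements agree that it is noncoding:

1. a CPC-style linear score over ORF coverage, ORF length and hexamer bias
   (score < 0 => noncoding);
2. a CNCI-style in-frame hexamer log-odds of the best ORF window
   (score < 0 => noncoding);
3. a txCdsPredict-style score on a 0-1000 scale (score < 500 => noncoding);
4. a protein-domain scan over all translated ORFs (no hit => noncoding).

The numeric scales of the original tools are not reproduced; each score is a
transparent re-implementation of the discriminative signal the tool uses, with
the decision thresholds of the published pipeline (0, 0, 500) kept exact.
Boundary values (exactly 0, exactly 500) count as coding: the thresholds are
strict inequalities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .seqmodel import CODING_HEXAMER_FREQS, NONCODING_HEXAMER_FREQS

__all__ = [
    "CodingVoteThresholds",
    "CodingReport",
    "Orf",
    "find_orfs",
    "hexamer_log_ratio",
    "cpc_like_score",
    "cnci_like_score",
    "txcds_like_score",
    "domain_scan",
    "classify_transcript",
    "DEFAULT_MOTIF_LIBRARY",
]


@dataclass(frozen=True)
class CodingVoteThresholds:
    """Decision thresholds of the lncRNA identification vote."""

    cpc_max: float = 0.0      # score < cpc_max => noncoding vote
    cnci_max: float = 0.0     # score < cnci_max => noncoding vote
    txcds_max: float = 500.0  # score < txcds_max => noncoding vote (0-1000 scale)
    min_length: int = 200     # transcripts <= min_length are never lncRNA
    min_agree: int = 3        # votes required for the lncRNA verdict

    def __post_init__(self) -> None:
        if not 1 <= self.min_agree <= 4:
            raise ValueError("min_agree must be in [1, 4]")
        if not 0 < self.txcds_max < 1000:
            raise ValueError("txcds_max must lie in (0, 1000)")


@dataclass
class CodingReport:
    """Per-transcript scores, the four noncoding votes, and the verdict."""

    transcript_id: str
    length: int
    cpc_like: float
    cnci_like: float
    txcds_like: float
    domain_hits: list[str]
    votes: tuple[bool, bool, bool, bool]  # True = "noncoding" vote
    verdict: str  # "lncRNA" | "coding"

    @property
    def n_noncoding_votes(self) -> int:
        return sum(self.votes)


@dataclass(frozen=True)
class Orf:
    frame: int   # 0, 1, 2 (forward frames only; libraries are strand-specific)
    start: int   # 0-based offset of the ATG
    end: int     # exclusive end, past the stop codon
    length: int  # nt, includes the stop codon

    def extract(self, seq: str) -> str:
        return seq[self.start : self.end]


def _clean(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return seq


def _is_terminator(codon: str) -> bool:
    # N is treated as stop-equivalent: it conservatively breaks ORFs.
    return codon in ("TAA", "TAG", "TGA") or "N" in codon


def find_orfs(seq: str) -> list[Orf]:
    """All ATG->stop open reading frames in the three forward frames.

    Each ATG is extended to its nearest in-frame terminator; nested ATGs that
    share a stop yield separate (shorter) ORFs.  Returned longest-first, ties
    broken by (frame, start).
    """
    seq = _clean(seq)
    orfs: list[Orf] = []
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "ATG":
                starts.append(pos)
            if _is_terminator(codon) and starts:
                for s in starts:
                    orfs.append(Orf(frame, s, pos + 3, pos + 3 - s))
                starts = []
    orfs.sort(key=lambda o: (-o.length, o.frame, o.start))
    return orfs


def hexamer_log_ratio(
    seq: str,
    coding_freqs: dict[str, float] = CODING_HEXAMER_FREQS,
    noncoding_freqs: dict[str, float] = NONCODING_HEXAMER_FREQS,
) -> float:
    """Mean in-frame hexamer log-odds log(f_coding / f_noncoding).

    Hexamers are read at step 3 from position 0 of ``seq`` (i.e. as codon
    pairs in the frame of the supplied window).  Positive values indicate
    coding-like composition.  Hexamers containing N are skipped; sequences
    shorter than one hexamer score 0.0 with a warning.
    """
    seq = _clean(seq)
    if len(seq) < 6:
        warnings.warn("sequence shorter than one hexamer; hexamer score is 0", stacklevel=2)
        return 0.0
    total = 0.0
    n = 0
    for pos in range(0, len(seq) - 5, 3):
        h = seq[pos : pos + 6]
        if "N" in h:
            continue
        total += math.log(coding_freqs[h] / noncoding_freqs[h])
        n += 1
    return total / n if n else 0.0


def _orf_features(seq: str) -> tuple[float, float, float]:
    """(ORF coverage, log2 ORF length, hexamer log-odds of the best ORF window)."""
    seq = _clean(seq)
    orfs = find_orfs(seq)
    if orfs:
        best = orfs[0]
        cov = best.length / len(seq)
        loglen = math.log2(best.length)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hexr = hexamer_log_ratio(best.extract(seq))
    else:
        cov = 0.0
        loglen = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hexr = hexamer_log_ratio(seq)
    return cov, loglen, hexr


# Fixed weights of the CPC-style linear score, calibrated once on the
# generator's labelled transcripts so that 0 separates the classes, then
# frozen.  Features: ORF coverage, log2 ORF length, best-ORF hexamer log-odds.
_CPC_W = (5.0, 0.3, 2.0)
_CPC_B = 4.2

# txCdsPredict-style logistic uses its own (deliberately different) weighting.
_TXCDS_W = (7.0, 0.6, 2.0)
_TXCDS_B = 8.0


def cpc_like_score(seq: str) -> float:
    """CPC-style signed score; < 0 indicates noncoding."""
    cov, loglen, hexr = _orf_features(seq)
    w = _CPC_W
    return w[0] * cov + w[1] * loglen + w[2] * hexr - _CPC_B


def cnci_like_score(seq: str) -> float:
    """CNCI-style signed score: hexamer log-odds of the best ORF window.

    Expected positive for sequence drawn from the codon model and negative for
    background-composition sequence; < 0 indicates noncoding.
    """
    _cov, _loglen, hexr = _orf_features(seq)
    return hexr


def txcds_like_score(seq: str) -> float:
    """txCdsPredict-style score on a 0-1000 scale; < 500 indicates noncoding."""
    cov, loglen, hexr = _orf_features(seq)
    w = _TXCDS_W
    z = w[0] * cov + w[1] * loglen + w[2] * hexr - _TXCDS_B
    return 1000.0 / (1.0 + math.exp(-z))


# ---------------------------------------------------------------------------
# Protein-domain scan


@dataclass(frozen=True)
class ProteinMotif:
    """A consensus amino-acid motif with an allowed mismatch budget.

    Stands in for a profile search: a hit is a window of the translated ORF
    matching the consensus with at most ``max_mismatches`` substitutions.
    """

    name: str
    consensus: str
    max_mismatches: int = 3


#: Bundled motif library used as the domain-evidence vote.  The synthetic
#: generator embeds these consensus peptides (DNA-encoded) in coding CDSs.
DEFAULT_MOTIF_LIBRARY: tuple[ProteinMotif, ...] = (
    ProteinMotif("PKIN_SYN", "GEGSFGKVYKAWDLRTGREV", 3),
    ProteinMotif("MYB_SYN", "WTPEEDRLLKRAVEQHGEKN", 3),
    ProteinMotif("PPR_SYN", "VTYNTLIDGLCKAGRLDEAL", 3),
)

_MIN_DOMAIN_ORF_CODONS = 30


def domain_scan(
    seq: str, motif_library: tuple[ProteinMotif, ...] = DEFAULT_MOTIF_LIBRARY
) -> tuple[bool, list[str]]:
    """Scan all translated ORFs (>= 30 codons) for protein-domain motifs.

    Returns ``(hit, hits)`` where ``hits`` lists matched motif names.  The
    scan is a function of the translated ORFs only, so it is invariant to
    UTR padding around an ORF.
    """
    if not motif_library:
        raise ValueError("empty motif library")
    seq = _clean(seq)
    hits: list[str] = []
    peptides = []
    for orf in find_orfs(seq):
        if orf.length // 3 < _MIN_DOMAIN_ORF_CODONS:
            continue
        dna = orf.extract(seq).replace("N", "A")  # N never reaches here mid-ORF
        peptides.append(str(Seq(dna).translate(to_stop=True)))
    for motif in motif_library:
        m = len(motif.consensus)
        found = False
        for pep in peptides:
            for i in range(len(pep) - m + 1):
                window = pep[i : i + m]
                mismatches = sum(a != b for a, b in zip(window, motif.consensus))
                if mismatches <= motif.max_mismatches:
                    found = True
                    break
            if found:
                break
        if found:
            hits.append(motif.name)
    return bool(hits), hits


def classify_transcript(
    seq: str,
    thresholds: CodingVoteThresholds = CodingVoteThresholds(),
    transcript_id: str = "",
    motif_library: tuple[ProteinMotif, ...] = DEFAULT_MOTIF_LIBRARY,
) -> CodingReport:
    """Apply the four coding-potential judgements and the agreement vote.

    Verdict is ``"lncRNA"`` iff the transcript is longer than
    ``thresholds.min_length`` and at least ``thresholds.min_agree`` of the four
    votes are "noncoding"; otherwise ``"coding"``.
    """
    seq = _clean(seq)
    cpc = cpc_like_score(seq)
    cnci = cnci_like_score(seq)
    txcds = txcds_like_score(seq)
    hit, hits = domain_scan(seq, motif_library)
    votes = (
        cpc < thresholds.cpc_max,
        cnci < thresholds.cnci_max,
        txcds < thresholds.txcds_max,
        not hit,
    )
    is_lnc = len(seq) > thresholds.min_length and sum(votes) >= thresholds.min_agree
    return CodingReport(
        transcript_id=transcript_id,
        length=len(seq),
        cpc_like=cpc,
        cnci_like=cnci,
        txcds_like=txcds,
        domain_hits=hits,
        votes=votes,
        verdict="lncRNA" if is_lnc else "coding",
    )


def classify_fasta(seqs: dict[str, str], thresholds: CodingVoteThresholds = CodingVoteThresholds()):
    """Classify every sequence in an ``{id: seq}`` dict; returns a DataFrame."""
    import pandas as pd

    rows = []
    for tid, seq in seqs.items():
        r = classify_transcript(seq, thresholds, transcript_id=tid)
        rows.append(
            {
                "transcript_id": tid,
                "length": r.length,
                "cpc_like": r.cpc_like,
                "cnci_like": r.cnci_like,
                "txcds_like": r.txcds_like,
                "domain_hits": ",".join(r.domain_hits),
                "vote_cpc": r.votes[0],
                "vote_cnci": r.votes[1],
                "vote_txcds": r.votes[2],
                "vote_domain": r.votes[3],
                "verdict": r.verdict,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")
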