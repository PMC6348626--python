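"""Shared sequence composition models.

The synthetic-data generator and the coding-potential scores both reference a
single pair of composition models:

* a biased codon-usage model for coding sequence (CDS) — codon probabilities
  favour G/C-ending synonymous codons, giving coding sequence a distinctive
  in-frame hexamer signature, as real plant CDS has;
* an AT-rich background model for intergenic/noncoding sequence.

From these the module derives, analytically and deterministically at import
time, the in-frame hexamer frequency tables used by the discriminative
coding-potential scores: the coding table is the outer product of the codon
distribution with itself (a hexamer read in frame is a codon pair), the
noncoding table the product of independent base frequencies.  Both are mixed
with a small pseudocount mass so every one of the 4096 hexamers has nonzero
frequency.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

BASES = "ACGT"

STOP_CODONS = ("TAA", "TAG", "TGA")

#: background (noncoding / intergenic) base composition — AT-rich
NONCODING_BASE_FREQS = {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31}

# Codon weights: uniform over sense codons, tilted toward G/C in the wobble
# position.  Kept deliberately simple — the point is a reproducible hexamer
# bias, not a faithful rice codon-usage table.
_WOBBLE_WEIGHT = {"A": 0.6, "C": 1.7, "G": 1.7, "T": 0.6}


def _codon_probs() -> dict[str, float]:
    probs = {}
    for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
        if codon in STOP_CODONS:
            continue
        probs[codon] = _WOBBLE_WEIGHT[codon[2]]
    total = sum(probs.values())
    return {c: w / total for c, w in probs.items()}


CODON_PROBS: dict[str, float] = _codon_probs()

_PSEUDO = 0.02  # pseudocount mass mixed uniformly over all 4096 hexamers


def _coding_hexamer_freqs() -> dict[str, float]:
    freqs = dict.fromkeys(("".join(h) for h in itertools.product(BASES, repeat=6)), 0.0)
    for c1, p1 in CODON_PROBS.items():
        for c2, p2 in CODON_PROBS.items():
            freqs[c1 + c2] += p1 * p2
    return {h: (1 - _PSEUDO) * f + _PSEUDO / 4096 for h, f in freqs.items()}


def _noncoding_hexamer_freqs() -> dict[str, float]:
    freqs = {}
    for h in ("".join(x) for x in itertools.product(BASES, repeat=6)):
        f = math.prod(NONCODING_BASE_FREQS[b] for b in h)
        freqs[h] = (1 - _PSEUDO) * f + _PSEUDO / 4096
    return freqs


CODING_HEXAMER_FREQS: dict[str, float] = _coding_hexamer_freqs()
NONCODING_HEXAMER_FREQS: dict[str, float] = _noncoding_hexamer_freqs()


def sample_noncoding(rng: np.random.Generator, length: int) -> str:
    """Draw a background-composition sequence of the given length."""
    bases = np.array(list(NONCODING_BASE_FREQS))
    probs = np.array(list(NONCODING_BASE_FREQS.values()))
    return "".join(rng.choice(bases, size=length, p=probs))


_CODON_LIST = list(CODON_PROBS)
_CODON_P = np.array([CODON_PROBS[c] for c in _CODON_LIST])


def sample_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Draw a CDS: ATG + (n_codons-2) biased sense codons + a stop codon."""
    if n_codons < 3:
        raise ValueError("CDS needs at least 3 codons (start, one sense, stop)")
    idx = rng.choice(len(_CODON_LIST), size=n_codons - 2, p=_CODON_P)
    body = "".join(_CODON_LIST[i] for i in idx)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + body + stop


_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction over A/C/G/T positions, ignoring N."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt
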