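"""Differential expression between sample groups.

Replicate counts are pooled (summed) within each group and compared with a
pooled two-proportion z-test — the same null as count-sampling DE methods
(equal sampling proportions across libraries).  P values are corrected by
Benjamini-Hochberg FDR; a transcript is significant when fold change >= 2
(|log2FC| >= 1, computed on mean per-replicate FPKM) and FDR <= 0.001.

The z-test models sampling (multinomial) noise only: with biologically
overdispersed counts its p-values are anticonservative, which is a known
property of this test family and is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEThresholds",
    "DEResult",
    "two_proportion_test",
    "bh_fdr",
    "call_de",
    "de_table",
    "cluster_de_profiles",
]


@dataclass(frozen=True)
class DEThresholds:
    min_fold_change: float = 2.0
    max_fdr: float = 0.001

    def __post_init__(self) -> None:
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")
        if not 0 < self.max_fdr < 1:
            raise ValueError("max_fdr must lie in (0, 1)")


@dataclass
class DEResult:
    transcript_id: str
    x1: int
    x2: int
    n1: float
    n2: float
    log2_fold: float        # log2(group2 / group1) on mean replicate FPKM; nan if undefined
    z: float
    p: float
    q: float
    direction: str          # "up" | "down" | "none"
    significant: bool


def two_proportion_test(x1: float, n1: float, x2: float, n2: float) -> tuple[float, float]:
    """Pooled two-proportion z-test of x1/n1 vs x2/n2.

    Returns ``(z, p)`` with a two-sided p from the standard normal.  Both
    counts zero gives ``(0, 1)`` by convention.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if x1 > n1 or x2 > n2:
        raise ValueError("count exceeds its library size")
    if x1 == 0 and x2 == 0:
        return 0.0, 1.0
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    counts: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    contrast: tuple[str, str],
    thresholds: DEThresholds = DEThresholds(),
) -> list[DEResult]:
    """Test every transcript between the two groups of ``contrast``.

    ``counts`` is transcripts x replicate columns; ``design`` maps replicate
    columns to groups.  Replicates are summed within each group for the test;
    the fold change is the ratio of mean per-replicate FPKM (transcript length
    cancels between groups, so lengths are not needed).  ``log2_fold`` is
    log2(group2 / group1).
    """
    design = pd.Series(design)
    g1, g2 = contrast
    cols1 = [c for c in counts.columns if design.get(c) == g1]
    cols2 = [c for c in counts.columns if design.get(c) == g2]
    if not cols1:
        raise ValueError(f"unknown or empty group {g1!r}")
    if not cols2:
        raise ValueError(f"unknown or empty group {g2!r}")

    lib = counts.sum(axis=0).astype(float)
    x1 = counts[cols1].sum(axis=1)
    x2 = counts[cols2].sum(axis=1)
    n1 = float(lib[cols1].sum())
    n2 = float(lib[cols2].sum())

    # mean per-replicate count fraction == mean FPKM up to a constant factor
    frac1 = (counts[cols1] / lib[cols1]).mean(axis=1)
    frac2 = (counts[cols2] / lib[cols2]).mean(axis=1)

    results: list[DEResult] = []
    zs, ps = [], []
    for tid in counts.index:
        z, p = two_proportion_test(float(x1[tid]), n1, float(x2[tid]), n2)
        zs.append(z)
        ps.append(p)
    qs = bh_fdr(ps)

    log2fc = np.full(len(counts.index), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = frac2.to_numpy() / frac1.to_numpy()
        log2fc = np.log2(ratio)

    for i, tid in enumerate(counts.index):
        lfc = float(log2fc[i])
        if frac1.iloc[i] == 0 and frac2.iloc[i] == 0:
            lfc, direction = float("nan"), "none"
        elif np.isnan(lfc) or lfc == 0:
            direction = "none"
        else:
            direction = "up" if lfc > 0 else "down"
        sig = (
            not np.isnan(lfc)
            and abs(lfc) >= np.log2(thresholds.min_fold_change)
            and qs[i] <= thresholds.max_fdr
        )
        results.append(
            DEResult(
                transcript_id=str(tid),
                x1=int(x1[tid]),
                x2=int(x2[tid]),
                n1=n1,
                n2=n2,
                log2_fold=lfc,
                z=zs[i],
                p=ps[i],
                q=float(qs[i]),
                direction=direction,
                significant=bool(sig),
            )
        )
    return results


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """DEResult list as a DataFrame indexed by transcript."""
    return pd.DataFrame([vars(r) for r in results]).set_index("transcript_id")


def cluster_de_profiles(log2fc: pd.DataFrame):
    """Average-linkage hierarchical clustering of DE profiles.

    Rows are transcripts, columns contrasts; missing / non-finite values are
    imputed as 0.  Rows are pre-sorted by ID so the merge order is
    deterministic.  Returns ``(leaf_order, linkage_matrix)`` where
    ``leaf_order`` is the list of transcript IDs in dendrogram order and
    ``linkage_matrix`` is in scipy ``linkage`` format over the sorted rows.
    """
    if log2fc.shape[0] == 0:
        raise ValueError("empty matrix")
    m = log2fc.sort_index()
    X = m.to_numpy(dtype=float)
    X[~np.isfinite(X)] = 0.0
    ids = list(m.index)
    if len(ids) == 1:
        return ids, np.zeros((0, 4))
    from scipy.cluster.hierarchy import leaves_list, linkage

    Z = linkage(X, method="average", metric="euclidean")
    order = [ids[i] for i in leaves_list(Z)]
    return order, Z
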