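"""FPKM quantification, expressed sets, Venn partitions, descriptive summaries.

Expression is quantified as FPKM = 10^6 * C / (N * L / 10^3), where C is the
transcript's unique-alignment read count, N the library's total aligned reads
and L the transcript length in bp.  Replicates of a group are integrated by
the arithmetic mean of their FPKM (median optionally); a transcript counts as
"expressed" in a column when its value is strictly greater than the threshold
(default 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .seqmodel import gc_content

__all__ = [
    "FpkmTerms",
    "fpkm",
    "fpkm_matrix",
    "integrate_replicates",
    "expressed_sets",
    "venn_partition",
    "aggregate_partition",
    "descriptive_stats",
]


@dataclass(frozen=True)
class FpkmTerms:
    """The three terms of the FPKM formula for one transcript in one library."""

    C: float  # unique-alignment count for the transcript
    N: float  # total aligned reads in the library
    L: float  # transcript length in bp

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N (library size) must be > 0")
        if self.L <= 0:
            raise ValueError("L (transcript length) must be > 0")
        if self.C < 0:
            raise ValueError("C (count) must be >= 0")


def fpkm(terms: FpkmTerms) -> float:
    """FPKM = 10^6 * C / (N * L / 10^3)."""
    return 1e6 * terms.C / (terms.N * terms.L / 1e3)


def fpkm_matrix(
    counts: pd.DataFrame,
    lengths: Mapping[str, float] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Elementwise FPKM of a transcripts x libraries count matrix.

    ``library_sizes`` defaults to the column sums of ``counts``.  Every row
    index must have a length; a missing one raises with the transcript named.
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no length for transcript {missing[0]!r}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes.isna() | (library_sizes <= 0)][0]
        raise ValueError(f"invalid library size for column {bad!r}")
    L = lengths.reindex(counts.index).to_numpy()[:, None]
    N = library_sizes.to_numpy()[None, :]
    values = 1e6 * counts.to_numpy(dtype=float) / (N * L / 1e3)
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def integrate_replicates(
    m: pd.DataFrame, design: Mapping[str, str] | pd.Series, how: str = "mean"
) -> pd.DataFrame:
    """Collapse replicate columns to group columns (e.g. A1-1..A1-3 -> A1).

    ``design`` maps each replicate column to its group.  ``how`` is ``"mean"``
    (the default integration rule) or ``"median"``.
    """
    design = pd.Series(design)
    missing = m.columns.difference(design.index)
    if len(missing):
        raise ValueError(f"design does not cover column {missing[0]!r}")
    if how not in ("mean", "median"):
        raise ValueError("how must be 'mean' or 'median'")
    grouped = m.T.groupby(design.reindex(m.columns))
    out = grouped.mean().T if how == "mean" else grouped.median().T
    if (grouped.size() == 0).any():  # pragma: no cover - groupby cannot emit empty groups
        raise ValueError("group with zero replicates")
    # preserve first-appearance group order
    order = list(dict.fromkeys(design.reindex(m.columns)))
    return out[order]


def expressed_sets(m: pd.DataFrame, min_fpkm: float = 0.0) -> dict[str, set[str]]:
    """Per-column sets of transcripts with value strictly above ``min_fpkm``."""
    return {col: set(m.index[m[col] > min_fpkm]) for col in m.columns}


def venn_partition(
    named_sets: Mapping[str, set] | Iterable[tuple[str, set]],
) -> dict[frozenset, int]:
    """Exclusive-region counts of up to six named sets.

    Keys are frozensets of set names; the value counts elements belonging to
    exactly those sets.  Regions with zero members are included (value 0) so
    the partition always covers all 2^k - 1 regions.
    """
    if not isinstance(named_sets, Mapping):
        pairs = list(named_sets)
        names = [n for n, _s in pairs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate set names")
        named_sets = dict(pairs)
    names = list(named_sets)
    if not 1 <= len(names) <= 6:
        raise ValueError("venn_partition supports 1-6 sets")
    from itertools import combinations

    regions: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(set(), *(named_sets[n] for n in names if n not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def aggregate_partition(region_counts: Mapping[frozenset, int]) -> dict[str, int]:
    """Per-set totals from exclusive-region counts (inverse of the partition)."""
    totals: dict[str, int] = {}
    for region, count in region_counts.items():
        for name in region:
            totals[name] = totals.get(name, 0) + count
    return totals


def descriptive_stats(
    transcripts: Mapping[str, TranscriptModel],
    expression: pd.DataFrame | None = None,
    length_bin: int = 500,
    chrom_bin: int = 100_000,
) -> dict[str, pd.Series | pd.DataFrame]:
    """Descriptive summaries of a transcript set.

    Returns length / exon-count / transcripts-per-gene histograms, per-
    transcript GC content (N ignored), and — when an expression matrix is
    given — per-chromosome binned expression totals (transcripts are assigned
    to the bin containing their span midpoint; bins are left-closed).
    """
    lengths = pd.Series({tid: t.length for tid, t in transcripts.items()})
    max_len = int(lengths.max()) if len(lengths) else 0
    edges = np.arange(0, max_len + length_bin + 1, length_bin)
    length_hist = pd.Series(
        np.histogram(lengths, bins=edges)[0],
        index=pd.IntervalIndex.from_breaks(edges, closed="left"),
        name="n_transcripts",
    )

    exon_counts = pd.Series({tid: len(t.exons) for tid, t in transcripts.items()})
    exon_hist = exon_counts.value_counts().sort_index().rename("n_transcripts")

    per_gene = pd.Series({tid: t.gene_id for tid, t in transcripts.items()}).value_counts()
    tpg_hist = per_gene.value_counts().sort_index().rename("n_genes")

    gc = pd.Series(
        {tid: gc_content(t.sequence) for tid, t in transcripts.items() if t.sequence},
        name="gc_content",
    )

    out: dict[str, pd.Series | pd.DataFrame] = {
        "length_hist": length_hist,
        "exon_count_hist": exon_hist,
        "transcripts_per_gene_hist": tpg_hist,
        "gc_content": gc,
    }

    if expression is not None:
        totals = expression.sum(axis=1)
        rows = []
        for tid, t in transcripts.items():
            if tid not in totals.index:
                continue
            mid = (t.start + t.end) // 2
            rows.append((t.chrom, (mid // chrom_bin) * chrom_bin, totals[tid]))
        chrom_expr = (
            pd.DataFrame(rows, columns=["chrom", "bin_start", "expression"])
            .groupby(["chrom", "bin_start"])["expression"]
            .sum()
            .reset_index()
        )
        out["chrom_expression"] = chrom_expr
    return out
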