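"""lncRNA-miRNA-mRNA interaction network assembly and GO enrichment.

The network (miRNA decoy analysis) is the union of three typed edge sets:
miRNA-target edges (a miRNA bound to a lncRNA decoy or an mRNA) and the cis /
trans lncRNA-mRNA pairs from target prediction.  Node types are inferred from
the edge tables and must be consistent.  Export is Cytoscape-ready node and
edge TSVs.

GO enrichment of lncRNA target genes is the hypergeometric upper tail:
the probability of observing at least k study hits for a term with K
population hits, study size n, population size N; terms with p < 0.05 are
flagged significant (a BH-adjusted column is reported alongside but not used
for the flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .diffex import bh_fdr

__all__ = [
    "CeRNANetwork",
    "EnrichmentRow",
    "build_cerna_network",
    "export_network",
    "import_network",
    "go_enrichment",
]

NODE_TYPES = ("miRNA", "mRNA", "lncRNA")
EDGE_KINDS = ("mirna_target", "cis", "trans")


@dataclass
class CeRNANetwork:
    """Typed interaction network over miRNA / mRNA / lncRNA nodes."""

    graph: nx.Graph

    @property
    def nodes(self) -> dict[str, str]:
        return {n: d["type"] for n, d in self.graph.nodes(data=True)}

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        return [(a, b, d["kind"]) for a, b, d in self.graph.edges(data=True)]

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    def mirna_partition(self, mirna: str) -> dict[str, int]:
        """How many lncRNA decoys vs mRNA targets a miRNA is bound to."""
        if self.graph.nodes[mirna]["type"] != "miRNA":
            raise ValueError(f"{mirna!r} is not a miRNA node")
        counts = {"lncRNA": 0, "mRNA": 0}
        for nb in self.graph.neighbors(mirna):
            t = self.graph.nodes[nb]["type"]
            if t in counts:
                counts[t] += 1
        return counts


def _add_typed(graph: nx.Graph, node: str, ntype: str) -> None:
    existing = graph.nodes.get(node, {}).get("type")
    if existing is not None and existing != ntype:
        raise ValueError(f"node {node!r} appears with two types: {existing}, {ntype}")
    graph.add_node(node, type=ntype)


def build_cerna_network(
    lnc_mi_sites: Iterable[tuple[str, str]],
    mi_mrna_sites: Iterable[tuple[str, str]],
    lnc_mrna_pairs: Iterable[tuple[str, str, str]],
) -> CeRNANetwork:
    """Assemble the network from (miRNA, lncRNA), (miRNA, mRNA) and
    (lncRNA, mRNA, kind) tables; ``kind`` is ``"cis"`` or ``"trans"``.

    Duplicate edge rows collapse; self-edges are rejected; an ID used with
    two different types raises.
    """
    g = nx.Graph()
    for mi, lnc in lnc_mi_sites:
        if mi == lnc:
            raise ValueError(f"self-edge on {mi!r}")
        _add_typed(g, mi, "miRNA")
        _add_typed(g, lnc, "lncRNA")
        g.add_edge(mi, lnc, kind="mirna_target")
    for mi, mrna in mi_mrna_sites:
        if mi == mrna:
            raise ValueError(f"self-edge on {mi!r}")
        _add_typed(g, mi, "miRNA")
        _add_typed(g, mrna, "mRNA")
        g.add_edge(mi, mrna, kind="mirna_target")
    for lnc, mrna, kind in lnc_mrna_pairs:
        if kind not in ("cis", "trans"):
            raise ValueError(f"unknown lncRNA-mRNA edge kind {kind!r}")
        if lnc == mrna:
            raise ValueError(f"self-edge on {lnc!r}")
        _add_typed(g, lnc, "lncRNA")
        _add_typed(g, mrna, "mRNA")
        g.add_edge(lnc, mrna, kind=kind)
    return CeRNANetwork(g)


def export_network(net: CeRNANetwork, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write Cytoscape-importable ``<prefix>.nodes.tsv`` / ``<prefix>.edges.tsv``.

    Output is deterministically sorted, so identical networks give identical
    bytes.
    """
    out_prefix = Path(out_prefix)
    node_path = out_prefix.with_suffix(".nodes.tsv")
    edge_path = out_prefix.with_suffix(".edges.tsv")
    nodes = pd.DataFrame(sorted(net.nodes.items()), columns=["id", "type"])
    edges = pd.DataFrame(
        sorted((min(a, b), max(a, b), k) for a, b, k in net.edges),
        columns=["source", "target", "kind"],
    )
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)
    return node_path, edge_path


def import_network(out_prefix: str | Path) -> CeRNANetwork:
    """Read back a node/edge table pair written by :func:`export_network`."""
    out_prefix = Path(out_prefix)
    nodes = pd.read_csv(out_prefix.with_suffix(".nodes.tsv"), sep="\t")
    edges = pd.read_csv(out_prefix.with_suffix(".edges.tsv"), sep="\t")
    g = nx.Graph()
    for _, row in nodes.iterrows():
        g.add_node(row["id"], type=row["type"])
    for _, row in edges.iterrows():
        g.add_edge(row["source"], row["target"], kind=row["kind"])
    return CeRNANetwork(g)


@dataclass
class EnrichmentRow:
    go_id: str
    go_name: str
    category: str       # BP | MF | CC
    study_hits: int     # k
    study_size: int     # n
    population_hits: int  # K
    population_size: int  # N
    p: float            # hypergeometric upper tail P(X >= k)
    q: float            # BH-adjusted p (reported, not used for the flag)
    significant: bool   # p < alpha


def go_enrichment(
    study_genes: Sequence[str],
    population_genes: Sequence[str],
    go_map: Mapping[str, tuple[str, str, set[str]]] | pd.DataFrame,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Hypergeometric GO-term enrichment of a study set within a population.

    ``go_map`` maps GO id -> (name, category, annotated gene set), or is a
    DataFrame with columns go_id/go_name/category/gene.  Rows are returned
    sorted by p value.
    """
    study = set(study_genes)
    if not study:
        raise ValueError("empty study set")
    population = set(population_genes)
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")

    if isinstance(go_map, pd.DataFrame):
        terms: dict[str, tuple[str, str, set[str]]] = {}
        for go_id, sub in go_map.groupby("go_id"):
            terms[str(go_id)] = (
                str(sub["go_name"].iloc[0]),
                str(sub["category"].iloc[0]),
                set(sub["gene"]),
            )
    else:
        terms = dict(go_map)

    N = len(population)
    n = len(study)
    rows: list[EnrichmentRow] = []
    for go_id, (name, category, genes) in terms.items():
        annotated = genes & population
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append(EnrichmentRow(go_id, name, category, k, n, K, N, min(p, 1.0), 0.0, False))
    qs = bh_fdr([r.p for r in rows]) if rows else []
    for r, q in zip(rows, qs):
        r.q = float(q)
        r.significant = r.p < alpha
    rows.sort(key=lambda r: (r.p, r.go_id))
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])
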