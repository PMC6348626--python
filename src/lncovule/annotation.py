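"""Genomic feature models and GFF3/FASTA input-output.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive on both
ends.  A :class:`TranscriptModel` is the unit the pipeline classifies as
lncRNA or mRNA; a :class:`GeneModel` groups transcripts for the positional
(cis) analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Exon",
    "TranscriptModel",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "read_gff3",
]


@dataclass(frozen=True, order=True)
class Exon:
    """One exon interval, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"malformed exon interval ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """A transcript: its exon chain on the genome, strand, parent gene, sequence.

    ``sequence`` is the spliced transcript in sense (5'->3') orientation; it may
    be ``None`` when only coordinates are known.  ``biotype`` is ``"mRNA"`` for
    coding transcripts and ``"lnc_RNA"`` for noncoding ones.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon]
    biotype: str = "mRNA"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Spliced transcript length in nt."""
        return sum(e.length for e in self.exons)

    @property
    def introns(self) -> list[Exon]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end + 1:
                out.append(Exon(a.end + 1, b.start - 1))
        return out

    def extract(self, chrom_seq: str) -> str:
        """Splice the transcript sequence out of its chromosome sequence."""
        parts = [chrom_seq[e.start - 1 : e.end] for e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @classmethod
    def from_transcripts(cls, gene_id: str, transcripts: list[TranscriptModel]) -> "GeneModel":
        if not transcripts:
            raise ValueError(f"gene {gene_id} has no transcripts")
        t0 = transcripts[0]
        return cls(
            gene_id=gene_id,
            chrom=t0.chrom,
            strand=t0.strand,
            start=min(t.start for t in transcripts),
            end=max(t.end for t in transcripts),
            transcripts=list(transcripts),
        )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    if isinstance(seqs, dict):
        seqs = seqs.items()
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_gff3(genes: list[GeneModel], path: str | Path, source: str = "lncovule") -> None:
    """Write gene / (mRNA|lnc_RNA) / exon / CDS features as GFF3.

    CDS rows are emitted for coding transcripts whose exons fully contain the
    CDS; in this pipeline coding transcripts carry their CDS implicitly via
    sequence annotation, so a CDS feature spanning the whole exon chain is
    written for ``mRNA`` transcripts (sufficient for positional analysis).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{t.chrom}\t{source}\t{t.biotype}\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for i, e in enumerate(t.exons, 1):
                    fh.write(
                        f"{t.chrom}\t{source}\texon\t{e.start}\t{e.end}\t.\t{t.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )
                if t.biotype == "mRNA":
                    for i, e in enumerate(t.exons, 1):
                        fh.write(
                            f"{t.chrom}\t{source}\tCDS\t{e.start}\t{e.end}\t.\t{t.strand}\t0\t"
                            f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}\n"
                        )


def _parse_attrs(col9: str) -> dict[str, str]:
    out = {}
    for item in col9.strip().split(";"):
        if not item:
            continue
        key, _, val = item.partition("=")
        out[key] = val
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read a GFF3 file back into :class:`GeneModel` objects.

    Only gene / transcript / exon rows are used; transcript feature types other
    than ``mRNA`` and ``lnc_RNA`` (e.g. ``transcript``) are accepted and kept
    as their literal type.
    """
    tx: dict[str, TranscriptModel] = {}
    tx_exons: dict[str, list[Exon]] = {}
    tx_meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, chrom, strand, biotype)
    gene_order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            a = _parse_attrs(attrs)
            if ftype == "gene":
                gene_order.append(a["ID"])
            elif ftype in ("mRNA", "lnc_RNA", "transcript"):
                tx_meta[a["ID"]] = (a["Parent"], chrom, strand, ftype)
                tx_exons.setdefault(a["ID"], [])
            elif ftype == "exon":
                tx_exons.setdefault(a["Parent"], []).append(Exon(int(start), int(end)))
    for tid, (gid, chrom, strand, biotype) in tx_meta.items():
        tx[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=tx_exons[tid],
            biotype=biotype,
        )
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in tx.values():
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = []
    for gid in gene_order:
        if gid in by_gene:
            genes.append(GeneModel.from_transcripts(gid, sorted(by_gene[gid], key=lambda t: t.transcript_id)))
    return genes
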