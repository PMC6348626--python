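"""Synthetic genome, annotation, transcript and count-matrix generator.

Everything downstream of read alignment/assembly in an ovule lncRNA survey is
exercised against data from this module: it emits a small genome, a GFF3
annotation, spliced transcript sequences, and an 18-library count matrix
(2 lines x 3 stages x 3 replicates), together with machine-readable truth
tables recording exactly what was planted:

- coding genes carry a CDS drawn from a hexamer-biased codon model (plus an
  embedded protein-domain motif), lncRNA loci carry AT-rich background
  sequence with all long ORFs broken;
- lncRNA loci are placed at configured offsets/containments relative to coding
  genes (cis truth);
- designated lncRNAs contain a verbatim hairpin-forming miRNA precursor
  (precursor truth) or a reverse-complement stretch of a target mRNA
  (trans truth);
- counts are negative-binomial around group means, with planted fold changes
  between groups and a shared lognormal latent factor inducing co-expression
  for planted target pairs.

All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Exon, GeneModel, TranscriptModel, write_fasta, write_gff3
from .seqmodel import revcomp, sample_cds, sample_noncoding
from .codingpot import DEFAULT_MOTIF_LIBRARY, find_orfs

__all__ = [
    "Design",
    "CisPlant",
    "TransPlant",
    "FoldPlant",
    "PrecursorPlant",
    "SimulationConfig",
    "TruthTables",
    "SyntheticData",
    "simulate_genome",
    "simulate_counts",
    "simulate_labeled_transcripts",
    "write_outputs",
]


@dataclass(frozen=True)
class Design:
    """The replicate design: lines x stages x replicates (default 2 x 3 x 3)."""

    lines: tuple[str, ...] = ("A", "B")
    n_stages: int = 3
    n_replicates: int = 3

    @property
    def groups(self) -> list[str]:
        return [f"{ln}{s}" for ln in self.lines for s in range(1, self.n_stages + 1)]

    @property
    def replicate_ids(self) -> list[str]:
        return [f"{g}-{r}" for g in self.groups for r in range(1, self.n_replicates + 1)]

    def group_of(self, replicate_id: str) -> str:
        return replicate_id.rsplit("-", 1)[0]


@dataclass(frozen=True)
class CisPlant:
    """Place a lncRNA locus at a controlled position relative to a coding gene.

    ``relation`` is one of ``upstream`` / ``downstream`` (offset = bp of gap
    between gene boundaries, orientation defined by the coding gene's strand),
    ``intron`` (the coding gene is wholly contained in the lncRNA's intron,
    same strand) or ``reverse_intron`` (contained, opposite strand).
    """

    lnc: str
    gene: str
    offset: int
    relation: str = "upstream"

    #: cis class the target-prediction stage is expected to assign
    @property
    def expected_class(self) -> str:
        return {
            "upstream": "upstream_window",
            "downstream": "downstream_window",
            "intron": "mrna_in_lnc_intron",
            "reverse_intron": "mrna_in_lnc_reverse_intron",
        }[self.relation]


@dataclass(frozen=True)
class TransPlant:
    lnc: str
    mrna: str
    duplex_length: int = 40


@dataclass(frozen=True)
class FoldPlant:
    """Shift a transcript's mean between two groups by ``fold`` (> 0)."""

    transcript: str
    group_a: str
    group_b: str
    fold: float


@dataclass(frozen=True)
class PrecursorPlant:
    lnc: str
    precursor: str


@dataclass
class SimulationConfig:
    seed: int = 42
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_coding_genes: int = 40
    n_lncRNA_loci: int = 30
    design: Design = field(default_factory=Design)
    nb_dispersion: float = 0.005
    mean_depth: float = 500_000.0
    library_size_cv: float = 0.1
    motif_frequency: float = 1.0
    lnc_length_range: tuple[int, int] = (500, 2000)
    cds_codon_range: tuple[int, int] = (150, 380)
    planted_base_expression: float = 60.0
    planted_fold_changes: list[FoldPlant] = field(default_factory=list)
    planted_cis_offsets: list[CisPlant] = field(default_factory=list)
    planted_trans_pairs: list[TransPlant] = field(default_factory=list)
    planted_precursors: list[PrecursorPlant] = field(default_factory=list)
    n_decoy_precursors: int = 4

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        for fp in self.planted_fold_changes:
            if fp.fold <= 0:
                raise ValueError(f"planted fold for {fp.transcript} must be > 0")

    @classmethod
    def default(cls, seed: int = 42) -> "SimulationConfig":
        """The standard benchmark configuration with a full set of plants."""
        cis = [
            CisPlant("LNC0001", "GENE0001", 2_000, "upstream"),
            CisPlant("LNC0002", "GENE0002", 5_000, "upstream"),
            CisPlant("LNC0003", "GENE0003", 9_500, "upstream"),
            CisPlant("LNC0004", "GENE0004", 9_999, "upstream"),
            CisPlant("LNC0005", "GENE0005", 4_000, "downstream"),
            CisPlant("LNC0006", "GENE0006", 15_000, "downstream"),
            CisPlant("LNC0007", "GENE0007", 19_900, "downstream"),
            CisPlant("LNC0008", "GENE0008", 0, "intron"),
            CisPlant("LNC0009", "GENE0009", 0, "reverse_intron"),
        ]
        trans = [
            TransPlant("LNC0010", "MRNA0015", 40),
            TransPlant("LNC0011", "MRNA0016", 40),
            TransPlant("LNC0012", "MRNA0017", 45),
            TransPlant("LNC0013", "MRNA0018", 40),
        ]
        precursors = [
            PrecursorPlant("LNC0020", "syn-miR9001"),
            PrecursorPlant("LNC0021", "syn-miR9002"),
            PrecursorPlant("LNC0022", "syn-miR9003"),
            PrecursorPlant("LNC0023", "syn-miR9004"),
        ]
        # fold plants avoid pair members: the shared co-expression factor of a
        # planted pair adds group-level variation that would confound the fold
        folds = [
            FoldPlant("LNC0014", "A1", "B1", 4.0),
            FoldPlant("LNC0015", "A1", "B1", 0.25),
            FoldPlant("LNC0016", "A2", "B2", 4.0),
            FoldPlant("LNC0024", "A1", "A3", 4.0),
            FoldPlant("MRNA0020", "A1", "B1", 4.0),
            FoldPlant("MRNA0021", "A2", "B2", 0.25),
        ]
        return cls(
            seed=seed,
            planted_cis_offsets=cis,
            planted_trans_pairs=trans,
            planted_precursors=precursors,
            planted_fold_changes=folds,
        )


@dataclass
class TruthTables:
    """Machine-readable record of everything the generator planted."""

    lncRNA_labels: dict[str, str]                       # transcript -> noncoding|coding
    de_truth: dict[tuple[str, str], float]              # (transcript, "A1_vs_B1") -> log2 fold
    cis_truth: list[tuple[str, str, str]]               # (lnc transcript, gene, expected class)
    trans_truth: list[tuple[str, str]]                  # (lnc transcript, mRNA transcript)
    precursor_truth: list[tuple[str, str]]              # (lnc transcript, precursor id)


@dataclass
class SyntheticData:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    transcripts: dict[str, TranscriptModel]             # with sequences, insertion-order stable
    precursor_db: dict[str, str]
    truth: TruthTables

    @property
    def transcript_seqs(self) -> dict[str, str]:
        return {tid: t.sequence for tid, t in self.transcripts.items()}


# ---------------------------------------------------------------------------
# sequence builders

_AA_TO_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGA",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTC", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAG", "R": "AGA", "S": "TCC", "T": "ACA", "V": "GTC",
    "W": "TGG", "Y": "TAC",
}


def _encode_peptide(pep: str) -> str:
    return "".join(_AA_TO_CODON[a] for a in pep)


def _build_coding_transcript(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[str, tuple[int, int] | None]:
    """UTR5 + CDS (+embedded domain motif) + UTR3, in sense orientation.

    Returns the sequence and the half-open span of the motif insert (the
    motif DNA is shared between genes carrying the same motif, so downstream
    plants must avoid it when sampling "unique" windows).
    """
    n_codons = int(rng.integers(*cfg.cds_codon_range))
    cds = sample_cds(rng, n_codons)
    motif_span = None
    utr5 = sample_noncoding(rng, int(rng.integers(30, 80)))
    if rng.random() < cfg.motif_frequency:
        motif = DEFAULT_MOTIF_LIBRARY[rng.integers(len(DEFAULT_MOTIF_LIBRARY))]
        ins = _encode_peptide(motif.consensus)
        # replace codons mid-CDS, keeping frame and start/stop intact
        k = len(ins) // 3
        pos = 3 * int(rng.integers(1, n_codons - 1 - k))
        cds = cds[:pos] + ins + cds[pos + len(ins) :]
        motif_span = (len(utr5) + pos, len(utr5) + pos + len(ins))
    utr3 = sample_noncoding(rng, int(rng.integers(50, 150)))
    return utr5 + cds + utr3, motif_span


def _disrupt_long_orfs(seq: str, max_coverage: float, protected: list[tuple[int, int]]) -> str:
    """Replace mid-ORF codons with TAA until the longest ORF covers less than
    ``max_coverage`` of the sequence.  Positions inside ``protected``
    half-open intervals (planted precursors / trans stretches) are left
    untouched; in the rare case an entire long ORF is protected it is kept.
    """

    def is_protected(i: int, j: int) -> bool:
        return any(i < e and j > s for s, e in protected)

    seq = list(seq)
    for _ in range(200):  # bounded; each pass shortens the longest breakable ORF
        orfs = find_orfs("".join(seq))
        target = None
        for o in orfs:
            if o.length / len(seq) < max_coverage:
                break
            # pick an in-frame codon near the ORF middle, outside protection
            candidates = range(o.start + 3 * ((o.length // 3) // 2), o.end - 3, 3)
            pos = next(
                (p for p in list(candidates) + list(range(o.start + 3, o.end - 3, 3))
                 if not is_protected(p, p + 3)),
                None,
            )
            if pos is not None:
                target = pos
                break
        if target is None:
            break
        seq[target : target + 3] = "TAA"
    return "".join(seq)


def _build_hairpin_precursor(rng: np.random.Generator, stem: int = 55, loop: int = 7) -> str:
    """A hairpin-forming precursor: perfect inverted repeat around a short loop."""
    arm = sample_noncoding(rng, stem)
    loop_seq = sample_noncoding(rng, loop)
    return arm + loop_seq + revcomp(arm)


def _build_lnc_sequence(
    rng: np.random.Generator,
    length: int,
    inserts: list[tuple[str, str]],  # (kind, sequence) planted verbatim
    max_orf_coverage: float = 0.28,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Background-composition lncRNA sequence with planted inserts and no long ORF.

    Returns the sequence and the half-open span of each insert by kind.
    """
    seq = sample_noncoding(rng, length)
    spans: dict[str, tuple[int, int]] = {}
    cursor = 20
    for kind, ins in inserts:
        if cursor + len(ins) > length - 20:
            raise ValueError("lncRNA too short for its planted inserts")
        start = int(rng.integers(cursor, min(cursor + 200, length - 20 - len(ins)) + 1))
        seq = seq[:start] + ins + seq[start + len(ins) :]
        spans[kind] = (start, start + len(ins))
        cursor = start + len(ins) + 10
    protected = list(spans.values())
    seq = _disrupt_long_orfs(seq, max_orf_coverage, protected)
    return seq, spans


# ---------------------------------------------------------------------------
# genome assembly


def _split_exons(
    rng: np.random.Generator, anchor: int, total_len: int, n_exons: int, strand: str
) -> list[Exon]:
    """Exon chain starting at genomic position ``anchor`` (1-based)."""
    if n_exons == 1:
        return [Exon(anchor, anchor + total_len - 1)]
    cuts = np.sort(rng.choice(np.arange(100, total_len - 100), size=n_exons - 1, replace=False))
    lens = np.diff(np.concatenate([[0], cuts, [total_len]])).astype(int)
    exons = []
    pos = anchor
    for L in lens:
        exons.append(Exon(pos, pos + int(L) - 1))
        pos += int(L) + int(rng.integers(100, 400))
    return exons


def _paste(genome: bytearray, t: TranscriptModel) -> None:
    """Write a transcript's spliced sequence into its chromosome."""
    seq = t.sequence
    exons = list(t.exons)
    order = exons[::-1] if t.strand == "-" else exons
    offset = 0
    for e in order:
        part = seq[offset : offset + e.length]
        offset += e.length
        if t.strand == "-":
            part = revcomp(part)
        genome[e.start - 1 : e.end] = part.encode()


def simulate_genome(cfg: SimulationConfig) -> SyntheticData:
    """Generate genome, annotation, transcript sequences and truth tables."""
    rng = np.random.default_rng([cfg.seed, 0])
    design_ok = cfg.design.groups  # validates design early
    assert design_ok

    chrom_names = [f"Chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genomes = {c: bytearray(sample_noncoding(rng, cfg.chrom_length).encode()) for c in chrom_names}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    # --- coding genes, evenly spaced with jitter
    genes: list[GeneModel] = []
    transcripts: dict[str, TranscriptModel] = {}
    motif_spans: dict[str, tuple[int, int] | None] = {}
    per_chrom = int(np.ceil(cfg.n_coding_genes / cfg.n_chromosomes))
    margin = 60_000
    spacing = (cfg.chrom_length - 2 * margin) // max(per_chrom, 1)
    for gi in range(cfg.n_coding_genes):
        gid = f"GENE{gi + 1:04d}"
        tid = f"MRNA{gi + 1:04d}"
        chrom = chrom_names[gi % cfg.n_chromosomes]
        slot = gi // cfg.n_chromosomes
        anchor = margin + slot * spacing + int(rng.integers(0, 2_000))
        strand = "+" if rng.random() < 0.5 else "-"
        seq, motif_span = _build_coding_transcript(rng, cfg)
        motif_spans[tid] = motif_span
        n_exons = int(rng.integers(2, 5))
        exons = _split_exons(rng, anchor, len(seq), n_exons, strand)
        if exons[-1].end > cfg.chrom_length:
            raise ValueError(f"gene {gid} extends past the end of {chrom}")
        t = TranscriptModel(tid, gid, chrom, strand, exons, biotype="mRNA", sequence=seq)
        transcripts[tid] = t
        genes.append(GeneModel.from_transcripts(gid, [t]))
        occupied[chrom].append((t.start, t.end))

    gene_by_id = {g.gene_id: g for g in genes}

    # --- precursor database (planted + decoys)
    precursor_db: dict[str, str] = {}
    for plant in cfg.planted_precursors:
        stem = int(rng.integers(45, 62))
        precursor_db[plant.precursor] = _build_hairpin_precursor(rng, stem=stem)
    for di in range(cfg.n_decoy_precursors):
        stem = int(rng.integers(45, 62))
        precursor_db[f"syn-miR8{di + 1:03d}"] = _build_hairpin_precursor(rng, stem=stem)

    cis_by_lnc = {p.lnc: p for p in cfg.planted_cis_offsets}
    trans_by_lnc: dict[str, list[TransPlant]] = {}
    for p in cfg.planted_trans_pairs:
        trans_by_lnc.setdefault(p.lnc, []).append(p)
    prec_by_lnc: dict[str, list[PrecursorPlant]] = {}
    for p in cfg.planted_precursors:
        prec_by_lnc.setdefault(p.lnc, []).append(p)

    cis_truth: list[tuple[str, str, str]] = []
    trans_truth: list[tuple[str, str]] = []
    precursor_truth: list[tuple[str, str]] = []

    def _far_enough(chrom: str, start: int, end: int, min_gap: int = 21_000) -> bool:
        return all(start > e + min_gap or end < s - min_gap for s, e in occupied[chrom])

    # --- lncRNA loci
    for li in range(cfg.n_lncRNA_loci):
        tid = f"LNC{li + 1:04d}"
        gid = f"LNCG{li + 1:04d}"
        length = int(rng.integers(*cfg.lnc_length_range))

        inserts: list[tuple[str, str]] = []
        for p in prec_by_lnc.get(tid, []):
            inserts.append((f"precursor:{p.precursor}", precursor_db[p.precursor]))
        for p in trans_by_lnc.get(tid, []):
            target = transcripts[p.mrna]
            tseq = target.sequence
            avoid = motif_spans.get(p.mrna)
            for _try in range(100):  # window must miss the shared motif insert
                w0 = int(rng.integers(0, len(tseq) - p.duplex_length))
                if avoid is None or w0 >= avoid[1] or w0 + p.duplex_length <= avoid[0]:
                    break
            inserts.append((f"trans:{p.mrna}", revcomp(tseq[w0 : w0 + p.duplex_length])))
        need = sum(len(s) for _k, s in inserts) + 300
        length = max(length, need)
        seq, _spans = _build_lnc_sequence(rng, length, inserts)

        plant = cis_by_lnc.get(tid)
        if plant is not None and plant.relation in ("intron", "reverse_intron"):
            g = gene_by_id[plant.gene]
            gspan = g.end - g.start + 1
            # two exons flanking an intron that wholly contains the gene
            e1 = length // 2
            e2 = length - e1
            pad = 500
            intron_len = gspan + 2 * pad
            start = g.start - pad - e1
            strand = g.strand if plant.relation == "intron" else ("-" if g.strand == "+" else "+")
            exons = [Exon(start, start + e1 - 1), Exon(g.end + pad + 1, g.end + pad + e2)]
            if start < 1 or exons[-1].end > cfg.chrom_length:
                raise ValueError(f"planted lncRNA locus {tid} falls outside {g.chrom}")
            chrom = g.chrom
        else:
            n_exons = 1 if rng.random() < 0.6 else 2
            if plant is not None:
                g = gene_by_id[plant.gene]
                chrom = g.chrom
                # genomic side of the gene: upstream = 5' side by gene strand
                left_side = (plant.relation == "upstream") == (g.strand == "+")
                span = length if n_exons == 1 else length + 250  # reserve intron room
                if left_side:
                    start = g.start - plant.offset - span  # gap of exactly `offset` bp
                else:
                    start = g.end + plant.offset + 1
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                chrom = chrom_names[int(rng.integers(cfg.n_chromosomes))]
                strand = "+" if rng.random() < 0.5 else "-"
                span = length + 300
                for _try in range(200):
                    start = int(rng.integers(1_000, cfg.chrom_length - span - 1_000))
                    if _far_enough(chrom, start, start + span):
                        break
                else:
                    raise ValueError(f"could not place intergenic lncRNA {tid}")
            if n_exons == 1:
                exons = [Exon(start, start + length - 1)]
            else:
                e1 = length // 2
                intron = 250
                exons = [Exon(start, start + e1 - 1),
                         Exon(start + e1 + intron, start + length + intron - 1)]
            if start < 1 or exons[-1].end > cfg.chrom_length:
                raise ValueError(f"planted lncRNA locus {tid} falls outside {chrom}")

        t = TranscriptModel(tid, gid, chrom, strand, exons, biotype="lnc_RNA", sequence=seq)
        transcripts[tid] = t
        genes.append(GeneModel.from_transcripts(gid, [t]))
        occupied[chrom].append((t.start, t.end))

        if plant is not None:
            cis_truth.append((tid, plant.gene, plant.expected_class))
        for p in trans_by_lnc.get(tid, []):
            trans_truth.append((tid, p.mrna))
        for p in prec_by_lnc.get(tid, []):
            precursor_truth.append((tid, p.precursor))

    # --- paste transcripts into the genome (coding first, lncRNAs second)
    for t in transcripts.values():
        _paste(genomes[t.chrom], t)

    genome = {c: bytes(g).decode() for c, g in genomes.items()}

    labels = {tid: ("coding" if t.biotype == "mRNA" else "noncoding") for tid, t in transcripts.items()}
    de_truth = {
        (fp.transcript, f"{fp.group_a}_vs_{fp.group_b}"): float(np.log2(fp.fold))
        for fp in cfg.planted_fold_changes
    }
    truth = TruthTables(labels, de_truth, cis_truth, trans_truth, precursor_truth)
    return SyntheticData(cfg, genome, genes, transcripts, precursor_db, truth)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    data: SyntheticData, cfg: SimulationConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix (transcripts x replicates) + design table.

    Group means are ``library_size * w / W`` where ``w`` is the transcript's
    relative expression weight (length-scaled), shifted by planted fold
    changes and multiplied, for planted target pairs, by a shared per-group
    lognormal latent factor that induces co-expression across the six groups.
    ``nb_dispersion == 0`` gives exact Poisson sampling.
    """
    cfg = cfg or data.config
    if cfg.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    # expression weights (base levels, pair latents) are a property of the
    # dataset; only library sizes and count noise vary with `seed`
    rng = np.random.default_rng([cfg.seed, 1])
    rng_counts = np.random.default_rng([cfg.seed if seed is None else seed, 2])
    design = cfg.design
    tids = list(data.transcripts)
    lengths = np.array([data.transcripts[t].length for t in tids], dtype=float)

    planted_ids = {fp.transcript for fp in cfg.planted_fold_changes}
    pair_members: set[str] = set()
    # cis truth records gene ids; expression pairing is at transcript level
    pair_lists: list[tuple[str, str]] = []
    gene_to_tid = {g.gene_id: g.transcripts[0].transcript_id for g in data.genes}
    for lnc, gene, _cls in data.truth.cis_truth:
        pair_lists.append((lnc, gene_to_tid[gene]))
    pair_lists.extend(data.truth.trans_truth)
    for a, b in pair_lists:
        pair_members.update((a, b))

    base = np.exp(rng.normal(np.log(20.0), 1.0, size=len(tids)))
    idx = {t: i for i, t in enumerate(tids)}
    for t in planted_ids | pair_members:
        if t in idx:
            base[idx[t]] = cfg.planted_base_expression

    groups = design.groups
    W = float(np.sum(base * lengths / 1_000.0))  # fixed normaliser across groups
    weight = np.tile(base[:, None], (1, len(groups)))  # transcripts x groups

    for fp in cfg.planted_fold_changes:
        if fp.transcript not in idx:
            raise KeyError(f"planted fold change names unknown transcript {fp.transcript}")
        gb = groups.index(fp.group_b)
        weight[idx[fp.transcript], gb] *= fp.fold

    # shared latent factor per planted pair: lognormal across the 6 groups
    for a, b in pair_lists:
        factor = np.exp(rng.normal(0.0, 0.8, size=len(groups)))
        weight[idx[a]] *= factor
        weight[idx[b]] *= factor

    lib_sizes = cfg.mean_depth * np.exp(
        rng_counts.normal(0.0, cfg.library_size_cv, size=len(design.replicate_ids))
    )
    counts = np.zeros((len(tids), len(design.replicate_ids)), dtype=np.int64)
    for ri, rid in enumerate(design.replicate_ids):
        g = groups.index(design.group_of(rid))
        mu = lib_sizes[ri] * weight[:, g] * (lengths / 1_000.0) / W
        if cfg.nb_dispersion == 0:
            counts[:, ri] = rng_counts.poisson(mu)
        else:
            n = 1.0 / cfg.nb_dispersion
            p = n / (n + mu)
            counts[:, ri] = rng_counts.negative_binomial(n, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(tids, name="transcript_id"),
                             columns=design.replicate_ids)
    design_df = pd.DataFrame(
        {
            "replicate": design.replicate_ids,
            "group": [design.group_of(r) for r in design.replicate_ids],
            "line": [r[0] for r in design.replicate_ids],
            "stage": [int(r[1]) for r in design.replicate_ids],
        }
    ).set_index("replicate")
    return counts_df, design_df


def simulate_null_counts(
    n_transcripts: int = 2000,
    seed: int = 0,
    design: Design = Design(),
    mean_depth: float = 500_000.0,
    nb_dispersion: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts with no planted effects: every group shares the same mean.

    The type-I benchmark for the DE caller.  With the default
    ``nb_dispersion = 0`` the counts are Poisson, i.e. the count-sampling
    null the two-proportion test models; positive dispersion adds biological
    overdispersion the test does not model (its calls then overstate
    significance, see the methods note).
    """
    rng = np.random.default_rng([seed, 3])
    base = np.exp(rng.normal(np.log(20.0), 1.0, size=n_transcripts))
    w = base / base.sum()
    reps = design.replicate_ids
    counts = np.zeros((n_transcripts, len(reps)), dtype=np.int64)
    for ri in range(len(reps)):
        mu = mean_depth * w
        if nb_dispersion == 0:
            counts[:, ri] = rng.poisson(mu)
        else:
            n = 1.0 / nb_dispersion
            counts[:, ri] = rng.negative_binomial(n, n / (n + mu))
    tids = [f"NULL{i + 1:05d}" for i in range(n_transcripts)]
    counts_df = pd.DataFrame(counts, index=pd.Index(tids, name="transcript_id"), columns=reps)
    design_df = pd.DataFrame(
        {"replicate": reps, "group": [design.group_of(r) for r in reps]}
    ).set_index("replicate")
    return counts_df, design_df


# ---------------------------------------------------------------------------
# labelled transcript sets (no genome placement) for classifier benchmarking


def simulate_labeled_transcripts(
    n_coding: int, n_noncoding: int, seed: int = 0, cfg: SimulationConfig | None = None
) -> tuple[dict[str, str], dict[str, str]]:
    """Transcript sequences with coding/noncoding labels, no genome placement.

    Used to benchmark the coding-potential vote at scale without paying for
    genome assembly.  Same sequence models as :func:`simulate_genome`.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng([seed, 2])
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    for i in range(n_coding):
        tid = f"CODT{i + 1:05d}"
        seqs[tid], _span = _build_coding_transcript(rng, cfg)
        labels[tid] = "coding"
    for i in range(n_noncoding):
        tid = f"NCT{i + 1:05d}"
        length = int(rng.integers(*cfg.lnc_length_range))
        seqs[tid], _ = _build_lnc_sequence(rng, length, [])
        labels[tid] = "noncoding"
    return seqs, labels


# ---------------------------------------------------------------------------
# file output


def write_outputs(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Write genome/transcript FASTA, GFF3, counts, design, and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "transcripts": outdir / "transcripts.fa",
        "annotation": outdir / "annotation.gff3",
        "precursors": outdir / "precursors.fa",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "truth_labels": outdir / "truth_labels.tsv",
        "truth_de": outdir / "truth_de.tsv",
        "truth_cis": outdir / "truth_cis.tsv",
        "truth_trans": outdir / "truth_trans.tsv",
        "truth_precursors": outdir / "truth_precursors.tsv",
    }
    write_fasta(data.genome, paths["genome"])
    write_fasta(data.transcript_seqs, paths["transcripts"])
    write_gff3(data.genes, paths["annotation"])
    write_fasta(data.precursor_db, paths["precursors"])
    counts, design = simulate_counts(data)
    counts.to_csv(paths["counts"], sep="\t")
    design.to_csv(paths["design"], sep="\t")
    t = data.truth
    pd.DataFrame(sorted(t.lncRNA_labels.items()), columns=["transcript_id", "label"]).to_csv(
        paths["truth_labels"], sep="\t", index=False)
    pd.DataFrame(
        [(tid, contrast, lfc) for (tid, contrast), lfc in sorted(t.de_truth.items())],
        columns=["transcript_id", "contrast", "log2_fold"],
    ).to_csv(paths["truth_de"], sep="\t", index=False)
    pd.DataFrame(t.cis_truth, columns=["lncRNA", "gene", "expected_class"]).to_csv(
        paths["truth_cis"], sep="\t", index=False)
    pd.DataFrame(t.trans_truth, columns=["lncRNA", "mRNA"]).to_csv(
        paths["truth_trans"], sep="\t", index=False)
    pd.DataFrame(t.precursor_truth, columns=["lncRNA", "precursor"]).to_csv(
        paths["truth_precursors"], sep="\t", index=False)
    return paths
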