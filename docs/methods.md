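# Methods

This note documents the models and procedures implemented in `lncovule`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices made where the published analysis chain leaves details open.

## The analysis chain

The package re-implements the desk-scale core of a stranded RNA-seq lncRNA
survey with a 2 lines x 3 stages x 3 replicates design. Read sequencing,
alignment and transcript assembly are out of scope: the pipeline starts from
assembled transcript models (FASTA + GFF3) and per-replicate count matrices,
which the `synthio` module fabricates with known ground truth.

### Coding-potential vote (`codingpot`)

A transcript longer than 200 nt is called lncRNA when at least 3 of 4
judgements agree it is noncoding. The four judgements re-implement the
discriminative signal of the classical tools without reproducing their
numeric scales; the decision thresholds (0, 0, 500, domain presence) are kept
exact, and boundary values count as coding (strict inequalities).

- *Hexamer log-odds.* Both sequence-composition scores are built on in-frame
  hexamer frequencies. The coding table is derived analytically as the outer
  product of a G/C-wobble-biased codon distribution with itself; the
  noncoding table is the product of AT-rich background base frequencies
  (A/T 0.31, C/G 0.19). Both are mixed with 2% uniform pseudocount mass.
  The expected per-hexamer log-odds is +KL(coding‖noncoding) for coding-model
  sequence and −KL(noncoding‖coding) for background sequence, so the 0
  threshold separates the classes without calibration constants.
- *CPC-style score* = 5.0·(ORF coverage) + 0.3·log2(ORF length) +
  2.0·(best-ORF hexamer log-odds) − 4.2. The weights were fit once against
  the generator's labelled transcripts and are shipped as frozen constants
  (determinism over adaptivity).
- *txCdsPredict-style score* = 1000·logistic(7.0·coverage + 0.6·log2 length +
  2.0·hexamer − 8.0), thresholded at 500.
- *Domain scan.* A bundled library of three consensus peptide motifs with a
  3-mismatch budget stands in for a profile-HMM search; every ORF of ≥ 30
  codons is translated and scanned. The verdict is a function of translated
  ORFs only, hence invariant to UTR padding.
- Only the three forward frames are scanned (libraries are strand-specific),
  and codons containing N are treated as stop-equivalent (conservative).

### Quantification (`quantexpr`)

FPKM = 10⁶·C/(N·L/10³) with N interpreted as total aligned reads per library
(the published formula's description of N is ambiguous). Replicate
integration is the arithmetic mean of FPKM (median available); "expressed"
means strictly greater than the threshold, default 0. Venn partitions are
computed over up to six named sets as exclusive-region counts;
`aggregate_partition` is their exact inverse. GC content ignores N; length
histograms use 500-nt left-closed bins.

### Differential expression (`diffex`)

Replicates are summed within each group and compared by a pooled
two-proportion z-test — the same null (equal sampling proportions) as
count-sampling DE methods, validated against Fisher's exact test by rank
agreement (Spearman rho > 0.99 on a 0–50 count grid at n = 10⁵). BH-FDR is
computed via `statsmodels`; significance requires fold change ≥ 2 (measured
on depth-normalised mean replicate expression, where transcript length
cancels) and FDR ≤ 0.001. Transcripts with zero counts in both groups get
p = 1 and direction "none".

The z-test models sampling noise only. Under biologically overdispersed
counts its p-values are anticonservative — a known property of this test
family, inherited deliberately. The type-I benchmark therefore runs on the
test's own null (Poisson counts, no planted effects, 2,000 transcripts),
where the expected number of calls at FDR ≤ 0.001 is ~0. Dispersion-modelling
GLMs are explicitly out of scope.

Profile clustering is average-linkage agglomeration on Euclidean distance
(scipy), rows pre-sorted by ID for deterministic input order; non-finite
fold changes are imputed as 0.

### Target pairing (`targetpred`)

Candidate pairs must pass |Pearson| ≥ 0.6 *and* |Spearman| ≥ 0.6 across the
six group profiles. Absolute values are the default because published
surveys report both positively and negatively correlated partners; a signed
mode is available. Constant profiles fail the gate with undefined
coefficients.

*Cis*: classification precedence is containment > overlap > window. A coding
gene wholly inside one lncRNA exon, one intron (same strand), or one intron
(opposite strand) gets the corresponding containment class; any other span
overlap is sense/antisense overlap by strand; otherwise the gap between gene
boundaries is measured (strictly-between base count) and compared against
10 kb upstream / 20 kb downstream windows, inclusive, with orientation
defined by the coding gene's strand.

*Trans*: intermolecular duplex minimum free energy from a dynamic program
over antiparallel pair chains scoring Watson–Crick and G:U nearest-neighbor
stacks (Turner-derived WC values; wobble stacks approximated at −1.2 / −0.5
kcal/mol and symmetrised), a +4.1 duplex initiation penalty, and
bulges/interior loops penalized 6.0 + 1.5/nt with at most 4 unpaired nt per
strand between consecutive pairs. No intramolecular structure is considered.
A duplex is reported only below 0 (with a 10⁻⁹ tolerance against exact-zero
float sums); a pair becomes trans below −30 kcal/mol. The bulge cap and loop
penalties matter: with unbounded cheap loops, two long random transcripts can
chain many short complementary stretches into spuriously low energies and the
−30 threshold loses all specificity. With the defaults, random 1–2 kb
transcript pairs score ≈ −17 to −29 while a planted 40-nt perfect complement
scores ≈ −80. A BLAST-style seed heuristic (shared complementary 12-mer,
disableable) prunes the trans search; a duplex clearing −30 essentially
always contains such a word.

### Precursor screen (`mirtools`)

Smith–Waterman local alignment (via Biopython's PairwiseAligner) with
blastn-like scoring: match +2, mismatch −3, gap of length k costing 5 + 2k;
E = K·m·n·e^(−λS) with K = 0.711, λ = 1.37. The alignment ratio is the
number of identically aligned positions divided by the precursor length —
the fraction of the precursor recovered exactly. This reading (rather than
alignment length over precursor length) is the one consistent with published
screens, where full-length alignments with mismatches are reported at ratios
like 0.919, and it is what makes a 15%-mutated precursor fall below the 0.9
retention threshold. Hairpin verification (default on) requires a perfect
stem of ≥ 16 stacked pairs (G:U allowed, terminal loop ≥ 3 nt) in the
flanked hit window; the maximum nested base-pair count is also reported from
a base-pair-maximization DP. miRNA target-site scanning is gapless
plant-style complementarity scoring: mismatch 1, G:U 0.5, doubled at miRNA
positions 2–13, keep ≤ 4 (indels are not considered).

### Network and enrichment (`netenrich`)

The ceRNA network is the deduplicated union of miRNA-target edges and
cis/trans pairs on typed nodes; an ID appearing with two types is an error.
Export is deterministically sorted node/edge TSVs importable by Cytoscape.
GO enrichment is the hypergeometric upper tail P(X ≥ k); significance uses
raw p < 0.05 (matching the published figure convention), with a BH-adjusted
column reported alongside. Terms are reported at the annotation level given
in the input map; GO-graph propagation is out of scope. Note the tail
probability is non-increasing when unannotated genes are added to the
population (the observed overlap becomes rarer).

## The synthetic-data generator (`synthio`)

The generator emulates the post-assembly state of the study design: two
chromosomes of 2 Mb, 40 coding genes (2–4 exons, CDS of 150–380 codons from
the biased codon model, one embedded domain motif per CDS), 30 lncRNA loci
(AT-rich background sequence, 1–2 exons, all ORFs disrupted below 28%
coverage), and an 18-library count matrix.

Planted truth (defaults of `SimulationConfig.default()`):

- 9 cis placements: upstream gaps of 2,000/5,000/9,500/9,999 bp, downstream
  gaps of 4,000/15,000/19,900 bp, and one intron / one reverse-intron
  containment (the coding gene sits wholly inside the lncRNA's intron, so
  sequences never collide on the genome);
- 4 trans pairs: a 40–45 nt reverse-complement stretch of the target mRNA
  inserted into the lncRNA, sampled away from the mRNA's domain-motif insert
  (the motif DNA is shared between genes and would otherwise create
  cross-complementarity);
- 4 embedded hairpin precursors (perfect inverted repeats, stems 45–61 bp,
  7-nt loops) plus 4 decoy precursors in the database;
- 6 fold changes (x4 or x0.25 between specific groups) on transcripts that
  are *not* pair members — a pair's shared co-expression factor adds
  group-level variation that would confound a planted fold.

Counts are negative-binomial: mean = library size x length-scaled expression
weight / fixed normaliser; dispersion 0.005 shared across transcripts
(chosen so that the generator's own calibration — a planted 4-fold recovered
as a sample-mean ratio in [3.2, 4.8] in ≥ 95% of runs — holds with margin);
dispersion 0 gives exact Poisson draws. Library sizes are lognormal around
500,000 reads with CV 0.1 (a knob, since real library-size spread varies).
Planted pairs share a per-group lognormal latent factor (sigma 0.8), which
makes their six-group profiles strongly correlated and the Spearman/Pearson
gate meaningfully testable. Expression weights (base levels and latents) are
drawn from the dataset seed; only library sizes and count noise vary with
the draw seed, so repeated count draws from one dataset probe pure counting
noise.

What the generator does **not** emulate: read-level data and sequencing
error, isoform complexity (one transcript per gene), mapping ambiguity,
GC/length biases in counting, dispersion heterogeneity across transcripts,
and genuinely diffuse biological co-expression structure. Passing the
recovery benchmarks therefore demonstrates correctness of the decision rules
and algorithms under their stated assumptions, not performance on real
tissue libraries.

Benchmark problem sizes (classifier sets of 100 transcripts/seed over 20
seeds, 70-transcript genomes, 2,000-transcript nulls) were chosen as the
smallest sets at which the binomial error of the measured rates is well below
the thresholds being asserted.

## Numerical choices and degenerate inputs

- Ties at score thresholds (0, 500, window bounds, ratio 0.9): thresholds on
  scores are strict (boundary = coding); genomic windows and the alignment
  ratio are inclusive ("within", "ties retained").
- Correlation gate on constant vectors: fail, coefficients NaN.
- `x1 = x2 = 0` in the DE test: z = 0, p = 1 by convention.
- Duplex and local-alignment tie-breaks are deterministic (leftmost-highest
  via the aligner's enumeration order; duplex traceback prefers stacking).
- All simulation randomness flows from explicit seeds through
  `numpy.random.default_rng` seed sequences; identical configurations yield
  byte-identical output files.

## Known limitations

- The two-proportion test inherits the anticonservativeness of
  count-sampling DE tests under biological overdispersion (see above).
- The duplex energy model is a reduced nearest-neighbor scheme (linear loop
  penalties, capped bulges, no accessibility/intramolecular structure); its
  −30 kcal/mol threshold is calibrated to the model, not to full Turner-2004
  thermodynamics.
- The domain scan is a consensus-motif stand-in, not a profile-HMM search.
- GO enrichment treats annotations as flat sets; no DAG propagation.
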