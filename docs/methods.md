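# Methods

`metatx` is a desk-scale, fully deterministic implementation of a *de novo*
metatranscriptome analysis workflow for single-end microbial RNA-Seq,
bundled with the simulation and scoring machinery needed to validate it
against known ground truth. This note records the models, the parameters
that matter, the numerical choices, and what the validation results do and
do not show.

## Read filtering

Reads pass four stages in order; every input read ends up in exactly one
output bucket, so stage counts always sum to the input count.

* **rRNA screening.** A read is called rRNA when at least a fraction
  (default 0.25) of its canonical k-mers (default k = 31; a k-mer and its
  reverse complement are identified) occur in the rRNA reference k-mer set.
  This is a deliberate simplification of seed-based rRNA filters: exact
  k-mer containment instead of seed-and-extend alignment. Reads shorter
  than k cannot be screened and pass as mRNA (counted separately). rRNA
  screening runs first, on untrimmed reads, to maximise k-mer evidence.
* **Adapter handling.** A read showing the adapter — an exact internal
  occurrence, or a read-suffix/adapter-prefix overlap of ≥ 10 nt with at
  most one mismatch — is discarded entirely by default rather than
  trimmed: adapter-trimmed remainders show a strong adenine bias and are
  not trustworthy. Trimming at the match start is available as an option.
* **Edge trimming.** Bases are stripped from either end while the terminal
  phred is ≤ 30 (a literal "keep while quality > 30" rule, per-base, not
  windowed); then a terminal run of ≥ 5 A's (or a leading run of T's, the
  reverse-complement tail) is removed. The two trims repeat to a fixed
  point, which makes the whole cascade idempotent. Interior bases are never
  touched.
* **Length filter.** Reads shorter than 50 nt are discarded.

## Assembly

A multi-k de Bruijn assembler over canonical k-mers (k odd, so no
reverse-complement palindromes). Defaults: k = 31, 41, 51; contigs below
2 × max(k) suppressed.

* **No absolute count cutoff by default** (`min_count = 1`). Expressed
  transcripts legitimately sit at very low coverage; an absolute singleton
  cutoff destroys them (empirically it pushes the coverage needed for
  partial assembly from ~3× to ~10×). Sequencing-error structure is removed
  instead by two graph cleaners:
  * *relative-depth branch pruning*: at any junction, alternative
    extensions with count ≤ 1/3 of the strongest sibling are deleted —
    recurrent errors are weak side branches next to a full-depth true
    path, while genuine repeats and strain variants have balanced depths
    and are left alone;
  * *tip clipping*: dead-end paths shorter than k + 75 nt (the longest
    path a read-terminal error can support) hanging off a junction are
    removed.
  This is the progressive relative-depth idea of iterative-k assemblers,
  in minimal form. There is no bubble *traversal* logic: unitig extraction
  remains strictly unbranched, and no consensus polishing is performed.
* **Multi-k iteration.** Each round's contigs re-enter the next (larger-k)
  round as weight-1 pseudo-reads alongside the original reads: small k
  bridges low-coverage gaps, large k resolves repeats.
* **Determinism.** K-mers are iterated in sorted canonical order and
  contigs emitted in sorted canonical-sequence order; two runs on the same
  input are byte-identical.
* **Known behaviour at transcript termini.** Terminal k-mers are covered
  by few reads; at 20× coverage a transcript typically returns as one
  contig at 100 % identity covering ~90–95 % of its length, with the ends
  missing. Downstream read mapping therefore allows soft-clipped
  placements at contig ends.

Externally produced contigs (e.g. from a production assembler) can be
imported in place of the built-in one.

## ORF calling and expression

* **Six-frame scan.** In each frame of each strand, maximal stop-to-stop
  windows are scanned. Complete ORFs start at the first ATG/GTG/TTG after a
  stop and end at a stop (≥ 60 aa); windows truncated by a contig edge are
  emitted as 5'- and/or 3'-partial ORFs (≥ 30 aa) with no start/stop
  requirement — metatranscriptome contigs routinely end mid-gene, and the
  partial calls carry much of the annotatable signal. No coding-potential
  statistics are computed. Alternative starts translate as M (table 11).
* **Overlap resolution.** Six-frame calling reports spurious open
  stretches in other frames on top of nearly every true gene. Before read
  counting, heavily overlapping calls (> 50 % of the shorter interval) are
  resolved greedily, preferring ORFs with a protein-database homolog —
  the strongest available evidence for the true frame — then longer and
  complete ORFs. This mirrors how statistical gene callers resolve
  overlapping candidates, substituting homology for a coding model; it is
  the one place annotation feeds back into gene calling. The unresolved
  call set remains available.
* **Mapping.** Exact-seed (first/central/last 21-mers, both orientations)
  plus ungapped verification, best single placement (fewest clipped bases,
  then fewest mismatches ≤ 3, then lexicographic tie-break); soft clipping
  at contig ends with ≥ 50 aligned bases. No fractional multi-mapping: one
  read, one placement, matching default primary-alignment behaviour.
* **Counting.** A mapped read credits the ORF it overlaps most (ties to
  the smaller start); reads overlapping no ORF are intergenic. Expression
  is reported as read count and reads per kilobase.

## Annotation

* **Alignment.** Optimal local alignment under BLOSUM62 with BLAST-style
  affine gaps (gap of length L costs 11 + L). The implementation wraps a
  C-accelerated pairwise aligner; the test suite checks score identity
  against an independent explicit three-matrix dynamic program on hundreds
  of random and homologous pairs.
* **Statistics.** Bit score = (λ·S − ln K)/ln 2 with fixed gapped
  constants λ = 0.267, K = 0.041 (the standard BLOSUM62/11/1 values);
  E-value = m·n·2^(−bit) on raw sequence lengths, not effective lengths.
  Deterministic and adequate for ranking; E-values are not calibrated
  p-values. Search threshold: E ≤ 1e-4.
* **Label transfer.** Single best hit only: the top-ranked subject's KO and
  COG transfer to the query; an unlabeled best hit leaves the query
  unannotated (no fallback), bit-score ties break to the smaller subject
  id. A shared-4-mer prefilter skips hopeless pairs when the database has
  ≥ 50 proteins; correctness-critical tests disable it.
* **SRV.** bit(best hit)/bit(self-alignment) ∈ (0, 1]; 1.0 means the query
  itself is in the database; no hit ⇒ 0 by convention. Histogram binning at
  0.05 for similarity-distribution plots.
* **COG profiles.** Read counts are summed per one-letter category;
  multi-category COGs split their reads equally; fractions are over
  labeled reads.

## Taxonomy

* **LCA.** Naive lowest-common-ancestor over retained hits: keep hits with
  bit ≥ 50 and within 10 % of the best bit, assign the deepest node
  ancestral to all their taxa; fewer than min-support (1) retained hits ⇒
  unclassified. These are conventional values for MEGAN-style
  classification; they are configurable.
* **Two-step restriction.** Proteins whose best hit against a bundled
  marker family database has SRV ≥ 0.5 are flagged as essential
  single-copy gene (ESCG) homologs. Step 1 classifies only those markers
  against the full database; the order-level ancestors claiming ≥ 1 marker
  define the search space. Step 2 classifies *all* proteins (markers
  included) against the database restricted to that space. The benefit is
  a much smaller second search; the documented cost is that members of
  orders contributing no detected marker are unclassifiable — the
  validation suite constructs exactly this failure. A taxid blacklist
  supports leave-self-out evaluation designs.
* **Ranks.** The canonical ladder superkingdom…species; nodes with other
  rank strings are transparent when walking to a target rank. Read-level
  profiles credit each ORF's reads to the rank-level ancestor of its
  assigned taxon, pooling everything above the rank as unclassified.

## The simulator

The generator emulates the design of published in-silico mock communities:
few members, strongly skewed abundances, optionally congeneric genomes.

* **Genomes.** Genes are genuine ORFs (ATG start, stop, no internal
  in-frame stop) placed non-overlapping on both strands with 20–100 nt
  spacers; gene lengths uniform in a configurable range (default
  150–600 nt). Members sharing a relatedness group derive from one
  ancestor parts list, each copy mutated i.i.d. at rate (1 − ANI);
  substitutions that would break ORF structure are rejected, so coding
  divergence runs slightly below nominal. A configurable subset of genes
  per member (default 8) descends from shared marker-family ancestors
  (10 % nt divergence), giving the ESCG machinery realistic targets;
  marker families carry fixed KOs.
* **Labels.** 200 synthetic KO ids assigned uniformly; COG ids with one or
  two of the 25 one-letter categories.
* **Reads.** Uniform windows within transcripts, strand-random, i.i.d.
  substitution errors, constant phred (default 38). Per-member mRNA counts
  are exact; within a member, reads follow per-gene weights (log-normal
  σ = 1.5 by default — the within-transcriptome abundance distribution is
  a modelling choice, not an empirical estimate) by largest-remainder
  allocation. rRNA reads come from per-member 1.5 kb "16S-like" decoys
  mutated from a common template, host reads from a 100 kb random decoy
  genome; contaminant counts are derived from the requested fractions by
  largest remainder. Optional library artefacts (adapter read-through,
  poly-A tails, low-quality 3' tails) are applied to mRNA reads only and
  recorded in read metadata.
* **What it does not emulate.** Indels, quality-dependent and
  position-dependent error profiles, strand-specific libraries, rRNA
  secondary-structure conservation, real codon usage and GC skew,
  uneven transcript fragmentation. Consequently, passing the validation
  battery shows the pipeline's logic is correct and calibrated under the
  stated noise model; it does not certify performance on real Illumina
  data, where error structure and compositional biases are harsher.

## Validation battery

`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes,
from scratch:

* exact reconstruction of 50 error-free, repeat-free 1–3 kb transcripts;
* the recovery experiment: 3 members across two orders, 200 genes, every
  expressed gene ≥ 10× coverage (log-normal spread above the floor, member
  activity skew 3:1.5:1), 1 % error, 10 % rRNA, database = the true
  proteins; measures read-level functional precision/recall, genus-rank
  precision and the log-scale Pearson correlation of KO profiles;
* two-step vs one-step classification equivalence on 20 two-order
  communities plus the no-marker outsider counterexample;
* chimera-detector calibration (20 constructed 300+300 bp cross-member
  joins, 20 exact substrings);
* the assembled-fraction-vs-coverage curve (genes at 0.5/1/2/3/5/10×,
  15 genes per level, 1 % error) and its detected threshold;
* exact recovery of simulated rRNA/adapter fractions by the filter
  cascade (error-free, 10 % rRNA, 5 % adapter);
* byte-identity of two identically seeded full pipeline runs.

Problem sizes were chosen so the whole battery completes in minutes on one
CPU. The corresponding assertions live in `tests/test_acceptance.py`.

## Numerical and design notes

* Internal coordinates are 0-based half-open everywhere; conversion to the
  1-based inclusive on-disk convention happens only in the GFF3/TSV
  writers.
* Contig-to-reference comparison uses edit-distance infix alignment
  (edlib) rather than a scored nucleotide Smith–Waterman: for the
  classification rules (identity thresholds, gapless check, windowed
  organism attribution at 150 nt / 90 % identity, chimera = ≥ 2 organisms
  owning ≥ 150 nt segments) the two are interchangeable, and the
  edit-distance kernel is orders of magnitude faster.
* A read whose prediction disagrees with the truth counts as a false
  positive *and* a false negative: precision penalises the wrong call,
  recall records that the true label was not recovered. TP + FN therefore
  partitions the evaluable reads.
* Coverage-curve fractions are reported as measured; monotonicity is a
  property of the data, not enforced.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; independent substreams (genome content,
  expression weights, decoys, reads) use fixed seed offsets so that
  supplying an explicit abundance profile does not perturb anything else.

## Limitations

* The aligner-based frame resolution makes gene calling partially
  database-dependent: genuinely novel proteins (no homolog) compete on
  length alone and lose more often to spurious frames.
* The assembler has no strain awareness: at ANI ≳ 0.97 congeners collapse
  into mixed contigs (at 0.95 the chimeric fraction stays below 10 % in
  the bundled benchmark, usually ~1–3 %).
* E-values are uncorrected for composition; SRV and bit thresholds were
  chosen as round conventional values, not fitted.
* Expression counting ignores multi-mapping ambiguity by design (single
  best placement), which undercounts recent paralogs.
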