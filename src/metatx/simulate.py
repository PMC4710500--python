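"""Mock metatranscriptome generator with complete per-read ground truth.

Emulates the design of published in-silico mock communities: a handful of
members with strongly skewed read abundances, optionally including groups
of closely related genomes (congeneric species generated by mutating a
common ancestor at a chosen nucleotide identity), contaminating rRNA and
host reads, and uniform substitution sequencing error.  Every emitted read
carries a truth row (source organism, taxon, gene, molecule class, KO and
COG labels), which is what turns the simulator into a benchmarking device:
read-level precision and recall of the full pipeline can be computed
exactly.

Genes are genuine open reading frames (ATG start, stop, no internal
in-frame stop) placed non-overlapping on both strands, so a six-frame ORF
caller can rediscover them.  A subset of genes per member is derived from
shared "essential single-copy gene" family ancestors, giving the two-step
taxonomic classifier realistic marker homologs to find.

Everything is deterministic given the spec seed; per-member read counts
are exact (integer allocation by largest remainder), not sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import ReferenceProteinDB
from .assembler import revcomp
from .formats import FeatureRow, SequenceRecord, write_fasta, write_fastq, write_gff3
from .genecalling import _STOPS, translate
from .taxonomy import RANKS, TaxNode, TaxonomyTree

COG_CATEGORIES = "JAKLBDYVTMNZWUOCGEFHIPQRS"
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class MemberSpec:
    """One community member: a genome to synthesise and transcribe."""

    name: str
    lineage: dict[str, str]  # rank -> name, over the canonical ranks
    genome_length: int = 100_000
    n_genes: int = 50
    gene_len_range: tuple[int, int] = (150, 600)
    relatedness_group: str | None = None
    ani_to_group: float = 1.0
    n_marker_genes: int = 8
    taxid: int = 0  # assigned by build_taxonomy

    def __post_init__(self) -> None:
        if self.relatedness_group is not None and not (
            0.8 <= self.ani_to_group <= 1.0
        ):
            raise ValueError("ani_to_group must be in [0.8, 1.0] for grouped members")
        mean_len = sum(self.gene_len_range) / 2
        if self.n_genes * mean_len > self.genome_length:
            raise ValueError(
                f"member {self.name}: {self.n_genes} genes of mean length "
                f"{mean_len:.0f} cannot fit in {self.genome_length} bp"
            )


@dataclass
class CommunitySpec:
    members: list[MemberSpec]
    read_counts: dict[str, int]  # mRNA reads per member, exact
    read_length: int = 75
    error_rate: float = 0.0
    rrna_fraction: float = 0.0
    host_fraction: float = 0.0
    seed: int = 0
    abundance_sigma: float = 1.5  # log-normal spread of per-gene expression
    abundance_profile: dict[str, Sequence[float]] | None = None
    base_qual: int = 38
    low_qual_tail_fraction: float = 0.0
    polya_fraction: float = 0.0
    adapter_fraction: float = 0.0
    adapter_seq: str = DEFAULT_ADAPTER
    n_marker_families: int = 10
    marker_gene_length: int = 450
    host_genome_length: int = 100_000

    def __post_init__(self) -> None:
        for name, n in self.read_counts.items():
            if n <= 0:
                raise ValueError(f"read count for {name} must be positive")
        if not (
            0 <= self.rrna_fraction <= 1
            and 0 <= self.host_fraction <= 1
            and self.rrna_fraction + self.host_fraction < 1
        ):
            raise ValueError("molecule fractions must be in [0,1] and sum below 1")


@dataclass
class Gene:
    gene_id: str
    start: int  # 0-based half-open on the forward genome strand
    end: int
    strand: str
    seq: str  # oriented coding sequence (starts with ATG)
    protein: str
    ko: str
    cog: str
    categories: str
    family: str = ""  # marker family, empty for non-marker genes
    weight: float = 1.0  # relative expression

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AnnotatedGenome:
    member: str
    taxid: int
    seq: str
    genes: list[Gene]


@dataclass
class CommunityData:
    """Everything generate_genomes produces: genomes, tree, decoys, markers."""

    spec: CommunitySpec
    tree: TaxonomyTree
    genomes: list[AnnotatedGenome]
    marker_db: ReferenceProteinDB  # marker family ancestor proteins
    rrna_refs: dict[str, str]  # member -> 16S-like decoy
    host_genome: str

    def genome(self, member: str) -> AnnotatedGenome:
        for g in self.genomes:
            if g.member == member:
                return g
        raise KeyError(member)


def build_taxonomy(members: Sequence[MemberSpec]) -> TaxonomyTree:
    """Construct the rank-complete tree implied by the member lineages.

    Taxids are assigned deterministically (breadth of first mention); each
    member's species-level taxid is written back onto its spec.
    """
    nodes = [TaxNode(1, 1, "no rank", "root")]
    by_path: dict[tuple[str, ...], int] = {}
    next_id = 2
    for m in members:
        parent = 1
        path: tuple[str, ...] = ()
        for rank in RANKS:
            name = m.lineage.get(rank)
            if name is None:
                raise ValueError(f"member {m.name}: lineage lacks rank {rank}")
            path = path + (name,)
            if path not in by_path:
                by_path[path] = next_id
                nodes.append(TaxNode(next_id, parent, rank, name))
                next_id += 1
            parent = by_path[path]
        m.taxid = parent
    return TaxonomyTree(nodes)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_orf(rng: np.random.Generator, length_nt: int) -> str:
    """ATG + random non-stop codons + stop; length_nt must be divisible by 3."""
    n_mid = length_nt // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_mid + 1:
        codon = _random_dna(rng, 3)
        if codon not in _STOPS:
            codons.append(codon)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(codons)


def _mutate_coding(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases i.i.d. at ``rate``, preserving ORF structure.

    Proposed substitutions that would alter the start codon, destroy the
    stop, or create an internal in-frame stop are rejected (left as the
    ancestral base), so divergence at coding sites is slightly below the
    nominal rate — the unavoidable price of keeping genes callable.
    """
    if rate <= 0:
        return seq
    bases = list(seq)
    hits = np.nonzero(rng.random(len(bases)) < rate)[0]
    for pos in hits:
        if pos < 3 or pos >= len(bases) - 3:
            continue
        old = bases[pos]
        new = "ACGT"[rng.integers(4)]
        if new == old:
            new = "ACGT"[("ACGT".index(old) + 1) % 4]
        codon_start = (pos // 3) * 3
        trial = bases[codon_start:codon_start + 3]
        trial[pos - codon_start] = new
        if "".join(trial) in _STOPS:
            continue
        bases[pos] = new
    return "".join(bases)


def _mutate_dna(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    bases = list(seq)
    hits = np.nonzero(rng.random(len(bases)) < rate)[0]
    for pos in hits:
        old = bases[pos]
        new = "ACGT"[rng.integers(4)]
        if new == old:
            new = "ACGT"[("ACGT".index(old) + 1) % 4]
        bases[pos] = new
    return "".join(bases)


def _allocate(weights: Sequence[float], total: int) -> list[int]:
    """Largest-remainder integer allocation of ``total`` over ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0 or total <= 0:
        return [0] * len(w)
    shares = w / w.sum() * total
    counts = np.floor(shares).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(shares - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


# --- genome generation -----------------------------------------------------


def _member_parts(
    rng: np.random.Generator,
    member: MemberSpec,
    family_orfs: list[str],
    label_pool: "LabelPool",
) -> list[tuple[str, Gene | None, str]]:
    """Build a genome as a parts list [(kind, gene, oriented_seq)].

    Marker-family genes come first (mutated family ancestors); remaining
    genes are fresh random ORFs.  Parts alternate spacer/gene; grouped
    members later mutate this shared parts list member-by-member.
    """
    lo, hi = member.gene_len_range
    parts: list[tuple[str, Gene | None, str]] = []
    n_markers = min(member.n_marker_genes, len(family_orfs), member.n_genes)
    marker_idx = sorted(
        rng.choice(len(family_orfs), size=n_markers, replace=False).tolist()
    )
    used = 0
    for gi in range(member.n_genes):
        spacer = _random_dna(rng, int(rng.integers(20, 101)))
        used += len(spacer)
        parts.append(("spacer", None, spacer))
        if gi < n_markers:
            fam = marker_idx[gi]
            seq = _mutate_coding(rng, family_orfs[fam], 0.10)
            family = f"ESCG{fam + 1:04d}"
            ko = label_pool.family_ko[fam]
        else:
            length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
            seq = _random_orf(rng, length)
            family = ""
            ko = label_pool.random_ko(rng)
        cog, cats = label_pool.random_cog(rng)
        used += len(seq)
        strand = "+" if rng.random() < 0.5 else "-"
        gene = Gene(
            gene_id=f"{member.name}_g{gi + 1:04d}",
            start=0,
            end=0,
            strand=strand,
            seq=seq,
            protein=translate(seq[:-3], as_start=True),
            ko=ko,
            cog=cog,
            categories=cats,
            family=family,
        )
        parts.append(("gene", gene, seq))
    if used > member.genome_length:
        raise ValueError(
            f"member {member.name}: genes + spacers ({used} bp) exceed genome "
            f"length {member.genome_length}"
        )
    # pad to the requested genome length so grouped members share it too
    parts.append(("spacer", None, _random_dna(rng, member.genome_length - used)))
    return parts


class LabelPool:
    """Synthetic KO/COG label pools: 200 KO ids, COG ids with 1-2 of the
    25 one-letter categories.  Marker families carry fixed per-family KOs."""

    def __init__(self, rng: np.random.Generator, n_families: int):
        self.n_ko = 200
        self.family_ko = [f"K{90001 + i:05d}" for i in range(n_families)]
        self._cog_cats: dict[str, str] = {}
        self._rng_cache = rng

    def random_ko(self, rng: np.random.Generator) -> str:
        return f"K{int(rng.integers(1, self.n_ko + 1)):05d}"

    def random_cog(self, rng: np.random.Generator) -> tuple[str, str]:
        cog = f"COG{int(rng.integers(1, 501)):04d}"
        if cog not in self._cog_cats:
            n = 1 if rng.random() < 0.8 else 2
            letters = rng.choice(list(COG_CATEGORIES), size=n, replace=False)
            self._cog_cats[cog] = "".join(sorted(letters))
        return cog, self._cog_cats[cog]


def generate_genomes(spec: CommunitySpec) -> CommunityData:
    """Synthesise annotated genomes, decoys and the marker ancestor set.

    Members sharing a ``relatedness_group`` are derived from one common
    ancestor parts list, each copy mutated at per-base rate
    (1 - ani_to_group); ani 1.0 therefore yields byte-identical genomes.
    """
    rng = np.random.default_rng(spec.seed)
    tree = build_taxonomy(spec.members)
    label_pool = LabelPool(rng, spec.n_marker_families)

    family_orfs = [
        _random_orf(rng, spec.marker_gene_length)
        for _ in range(spec.n_marker_families)
    ]
    marker_db = ReferenceProteinDB(
        {
            f"ESCG{i + 1:04d}": translate(orf[:-3], as_start=True)
            for i, orf in enumerate(family_orfs)
        },
        pd.DataFrame(
            {
                "taxid": 1,
                "family": [f"ESCG{i + 1:04d}" for i in range(len(family_orfs))],
            },
            index=[f"ESCG{i + 1:04d}" for i in range(len(family_orfs))],
        ),
    )

    # one shared ancestor parts list per relatedness group
    group_parts: dict[str, list] = {}
    for m in spec.members:
        if m.relatedness_group and m.relatedness_group not in group_parts:
            group_parts[m.relatedness_group] = _member_parts(
                rng, m, family_orfs, label_pool
            )

    genomes: list[AnnotatedGenome] = []
    for m in spec.members:
        if m.relatedness_group:
            ancestor = group_parts[m.relatedness_group]
            rate = 1.0 - m.ani_to_group
            parts = []
            for kind, gene, seq in ancestor:
                if kind == "gene":
                    parts.append((kind, gene, _mutate_coding(rng, seq, rate)))
                else:
                    parts.append((kind, gene, _mutate_dna(rng, seq, rate)))
        else:
            parts = _member_parts(rng, m, family_orfs, label_pool)

        chunks: list[str] = []
        pos = 0
        genes: list[Gene] = []
        for gi, (kind, gene, seq) in enumerate(parts):
            if kind == "gene":
                oriented = seq if gene.strand == "+" else revcomp(seq)
                new_gene = Gene(
                    gene_id=f"{m.name}_g{len(genes) + 1:04d}",
                    start=pos,
                    end=pos + len(seq),
                    strand=gene.strand,
                    seq=seq,
                    protein=translate(seq[:-3], as_start=True),
                    ko=gene.ko,
                    cog=gene.cog,
                    categories=gene.categories,
                    family=gene.family,
                )
                genes.append(new_gene)
                chunks.append(oriented)
            else:
                chunks.append(seq)
            pos += len(seq)
        genomes.append(AnnotatedGenome(m.name, m.taxid, "".join(chunks), genes))

    # per-gene expression weights (own rng stream so that supplying an
    # explicit profile does not shift any other draw)
    weights_rng = np.random.default_rng(spec.seed + 5)
    for m, genome in zip(spec.members, genomes):
        if spec.abundance_profile and m.name in spec.abundance_profile:
            weights = list(spec.abundance_profile[m.name])
            if len(weights) != len(genome.genes):
                raise ValueError(
                    f"abundance profile for {m.name} has {len(weights)} entries "
                    f"for {len(genome.genes)} genes"
                )
        else:
            weights = np.exp(
                weights_rng.normal(0.0, spec.abundance_sigma, size=len(genome.genes))
            ).tolist()
        for gene, w in zip(genome.genes, weights):
            gene.weight = float(w)

    decoy_rng = np.random.default_rng(spec.seed + 9)
    template_16s = _random_dna(decoy_rng, 1500)
    rrna_refs = {
        m.name: _mutate_dna(decoy_rng, template_16s, 0.03) for m in spec.members
    }
    host_genome = _random_dna(decoy_rng, spec.host_genome_length)
    return CommunityData(spec, tree, genomes, marker_db, rrna_refs, host_genome)


# --- read simulation -------------------------------------------------------

TRUTH_COLUMNS = [
    "read_id",
    "organism",
    "taxid",
    "gene_id",
    "molecule",
    "ko",
    "cog",
    "categories",
    "truncated",
]


def _apply_error(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    return _mutate_dna(rng, seq, rate)


def molecule_counts(spec: CommunitySpec) -> tuple[int, int, int]:
    """Exact (mRNA, rRNA, host) read counts implied by the spec fractions.

    mRNA counts are fixed by the spec; the contaminant counts are derived
    so that observed fractions match the requested ones as closely as
    integer arithmetic allows (largest remainder between the two
    contaminant classes).
    """
    n_mrna = sum(spec.read_counts.values())
    f_cont = spec.rrna_fraction + spec.host_fraction
    if f_cont == 0:
        return n_mrna, 0, 0
    total = round(n_mrna / (1.0 - f_cont))
    n_cont = total - n_mrna
    n_rrna, n_host = _allocate(
        [spec.rrna_fraction, spec.host_fraction], n_cont
    )
    return n_mrna, n_rrna, n_host


def simulate_reads(
    spec: CommunitySpec, data: CommunityData
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Emit reads and the authoritative truth table.

    mRNA reads are uniform windows within transcripts, strand-random, with
    i.i.d. substitution errors; per-member counts are exact and per-gene
    counts follow the expression weights by largest-remainder allocation.
    Optional library artefacts (low-quality 3' tails, poly-A tails, adapter
    read-through) are applied to mRNA reads only, giving the filter cascade
    known positives.
    """
    rng = np.random.default_rng(spec.seed + 1)
    L = spec.read_length
    reads: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    n_mrna, n_rrna, n_host = molecule_counts(spec)

    def emit(seq, qual, organism, taxid, gene_id, molecule, ko, cog, cats, trunc,
             artifact=""):
        rid = f"r{len(reads) + 1:07d}"
        meta = {"organism": organism, "molecule": molecule}
        if artifact:
            meta["artifact"] = artifact
        reads.append(SequenceRecord(rid, seq, qual, meta))
        truth_rows.append(
            {
                "read_id": rid,
                "organism": organism,
                "taxid": taxid,
                "gene_id": gene_id,
                "molecule": molecule,
                "ko": ko,
                "cog": cog,
                "categories": cats,
                "truncated": trunc,
            }
        )

    for member, genome in zip(spec.members, data.genomes):
        n_member = spec.read_counts[member.name]
        per_gene = _allocate([g.weight for g in genome.genes], n_member)
        for gene, n_reads in zip(genome.genes, per_gene):
            transcript = gene.seq
            for _ in range(n_reads):
                truncated = len(transcript) < L
                if truncated:
                    frag = transcript
                else:
                    start = int(rng.integers(0, len(transcript) - L + 1))
                    frag = transcript[start : start + L]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                frag = _apply_error(rng, frag, spec.error_rate)
                qual = [spec.base_qual] * len(frag)
                artifact = ""
                if rng.random() < spec.adapter_fraction:
                    artifact = "adapter"
                    a_len = int(
                        rng.integers(12, len(spec.adapter_seq) + 1)
                    )
                    a_len = min(a_len, len(frag) - 1)
                    frag = frag[: len(frag) - a_len] + spec.adapter_seq[:a_len]
                elif rng.random() < spec.polya_fraction:
                    artifact = "polya"
                    tail = int(rng.integers(8, 21))
                    frag = frag + "A" * tail
                    qual = qual + [spec.base_qual] * tail
                if rng.random() < spec.low_qual_tail_fraction:
                    tail = int(rng.integers(5, 16))
                    qual[-tail:] = [2] * min(tail, len(qual))
                qual = qual[: len(frag)] + [spec.base_qual] * (len(frag) - len(qual))
                emit(
                    frag,
                    qual,
                    member.name,
                    member.taxid,
                    gene.gene_id,
                    "mRNA",
                    gene.ko,
                    gene.cog,
                    gene.categories,
                    truncated,
                    artifact,
                )

    member_weights = [spec.read_counts[m.name] for m in spec.members]
    for member, n_reads in zip(spec.members, _allocate(member_weights, n_rrna)):
        ref = data.rrna_refs[member.name]
        for _ in range(n_reads):
            start = int(rng.integers(0, len(ref) - L + 1))
            frag = ref[start : start + L]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            frag = _apply_error(rng, frag, spec.error_rate)
            emit(
                frag,
                [spec.base_qual] * len(frag),
                member.name,
                member.taxid,
                "16S",
                "rRNA",
                "",
                "",
                "",
                False,
            )

    for _ in range(n_host):
        start = int(rng.integers(0, len(data.host_genome) - L + 1))
        frag = data.host_genome[start : start + L]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        frag = _apply_error(rng, frag, spec.error_rate)
        emit(frag, [spec.base_qual] * len(frag), "host", 0, "host", "host", "", "", "", False)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


def expected_coverage(spec: CommunitySpec, data: CommunityData) -> pd.DataFrame:
    """Per-gene mean read depth: reads(g) * read_length / gene_length.

    Uses the same deterministic allocation as ``simulate_reads``, so the
    returned counts are exactly the emitted ones.
    """
    rows = []
    for member, genome in zip(spec.members, data.genomes):
        per_gene = _allocate(
            [g.weight for g in genome.genes], spec.read_counts[member.name]
        )
        for gene, n_reads in zip(genome.genes, per_gene):
            rows.append(
                {
                    "organism": member.name,
                    "gene_id": gene.gene_id,
                    "length_nt": gene.length,
                    "reads": n_reads,
                    "coverage": n_reads * spec.read_length / gene.length,
                }
            )
    return pd.DataFrame(rows)


# --- reference databases and on-disk output --------------------------------


def build_protein_db(data: CommunityData) -> ReferenceProteinDB:
    """The community's true proteins as a labeled reference database."""
    seqs: dict[str, str] = {}
    rows = []
    for genome in data.genomes:
        for gene in genome.genes:
            pid = gene.gene_id
            seqs[pid] = gene.protein
            rows.append(
                {
                    "protein_id": pid,
                    "taxid": genome.taxid,
                    "ko": gene.ko,
                    "cog": gene.cog,
                    "categories": gene.categories,
                    "family": gene.family,
                }
            )
    labels = pd.DataFrame(rows).set_index("protein_id")
    return ReferenceProteinDB(seqs, labels)


def gene_features(data: CommunityData) -> list[FeatureRow]:
    rows = []
    for genome in data.genomes:
        for g in genome.genes:
            rows.append(
                FeatureRow(
                    seq_id=genome.member,
                    start=g.start + 1,
                    end=g.end,
                    strand=g.strand,
                    ftype="CDS",
                    attrs={
                        "ID": g.gene_id,
                        "ko": g.ko,
                        "cog": g.cog,
                        "categories": g.categories,
                        "family": g.family,
                    },
                )
            )
    return rows


def write_community(
    data: CommunityData,
    reads: list[SequenceRecord],
    truth: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """Write the full simulated dataset to a directory."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    write_fastq(reads, outdir / "reads.fastq")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    for genome in data.genomes:
        write_fasta(
            [SequenceRecord(genome.member, genome.seq)],
            outdir / "genomes" / f"{genome.member}.fasta",
        )
    write_gff3(gene_features(data), outdir / "genes.gff3")
    db = build_protein_db(data)
    db.to_files(outdir / "proteins.faa", outdir / "protein_labels.tsv")
    data.marker_db.to_files(outdir / "markers.faa", outdir / "marker_labels.tsv")
    write_fasta(
        [SequenceRecord(f"16S_{m}", seq) for m, seq in data.rrna_refs.items()],
        outdir / "rrna.fasta",
    )
    write_fasta(
        [SequenceRecord("host", data.host_genome)], outdir / "host.fasta"
    )
    data.tree.to_files(outdir / "nodes.tsv", outdir / "names.tsv")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"taxid": int}, keep_default_na=False
    )


# --- canned community builders --------------------------------------------


def _default_lineage(
    phylum: str, klass: str, order: str, family: str, genus: str, species: str
) -> dict[str, str]:
    return {
        "superkingdom": "Bacteria",
        "phylum": phylum,
        "class": klass,
        "order": order,
        "family": family,
        "genus": genus,
        "species": species,
    }


def three_member_community(
    seed: int = 0,
    genes_per_member: tuple[int, int, int] = (70, 70, 60),
    min_coverage: float = 10.0,
    coverage_spread: float = 0.6,
    read_length: int = 75,
    error_rate: float = 0.01,
    rrna_fraction: float = 0.10,
    host_fraction: float = 0.0,
) -> tuple[CommunitySpec, CommunityData]:
    """The standard recovery benchmark: three unrelated members in two
    orders, every gene expressed at >= ``min_coverage``-fold depth with a
    log-normal spread above the floor, skewed member activity.
    """
    lineages = [
        _default_lineage("Bacteroidetes", "Bacteroidia", "Bacteroidales",
                         "Bacteroidaceae", "Bacteroides", "Bacteroides simulans"),
        _default_lineage("Firmicutes", "Clostridia", "Clostridiales",
                         "Clostridiaceae", "Clostridium", "Clostridium fictum"),
        _default_lineage("Firmicutes", "Clostridia", "Clostridiales",
                         "Lachnospiraceae", "Blautia", "Blautia synthetica"),
    ]
    members = [
        MemberSpec(
            name=f"member{i + 1}",
            lineage=lin,
            genome_length=n_genes * 800,
            n_genes=n_genes,
        )
        for i, (lin, n_genes) in enumerate(zip(lineages, genes_per_member))
    ]
    # provisional spec to generate genomes and gene lengths
    spec = CommunitySpec(
        members=members,
        read_counts={m.name: 1 for m in members},
        read_length=read_length,
        error_rate=error_rate,
        rrna_fraction=rrna_fraction,
        host_fraction=host_fraction,
        seed=seed,
    )
    data = generate_genomes(spec)
    # activity skew between members, log-normal spread per gene, floor at
    # min_coverage: target per-gene read counts become the abundance profile
    rng = np.random.default_rng(seed + 17)
    activity = [3.0, 1.5, 1.0]
    profile: dict[str, list[float]] = {}
    counts: dict[str, int] = {}
    for member, genome, act in zip(members, data.genomes, activity):
        per_gene = []
        for gene in genome.genes:
            cov = min_coverage * act * math.exp(abs(rng.normal(0.0, coverage_spread)))
            per_gene.append(int(math.ceil(cov * gene.length / read_length)))
        profile[member.name] = [float(c) for c in per_gene]
        counts[member.name] = int(sum(per_gene))
    spec.read_counts = counts
    spec.abundance_profile = profile
    for member, genome in zip(members, data.genomes):
        for gene, w in zip(genome.genes, profile[member.name]):
            gene.weight = w
    return spec, data


def grouped_pair_community(
    seed: int = 0,
    ani: float = 0.95,
    n_genes: int = 40,
    reads_per_member: int = 4000,
    read_length: int = 75,
) -> tuple[CommunitySpec, CommunityData]:
    """Two congeneric members at the given nucleotide identity — the
    worst case for chimeric (cross-member) assembly."""
    lineages = [
        _default_lineage("Firmicutes", "Bacilli", "Lactobacillales",
                         "Streptococcaceae", "Streptococcus", f"Streptococcus sp{i}")
        for i in (1, 2)
    ]
    members = [
        MemberSpec(
            name=f"strain{i + 1}",
            lineage=lin,
            genome_length=n_genes * 800,
            n_genes=n_genes,
            relatedness_group="strep",
            ani_to_group=ani,
        )
        for i, lin in enumerate(lineages)
    ]
    spec = CommunitySpec(
        members=members,
        read_counts={m.name: reads_per_member for m in members},
        read_length=read_length,
        error_rate=0.0,
        seed=seed,
    )
    data = generate_genomes(spec)
    return spec, data
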