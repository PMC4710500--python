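"""Six-frame ORF prediction, read mapping and per-ORF expression.

ORF calling is a deterministic six-frame scan: in every frame of both
strands, the regions between stop codons are examined; a complete ORF runs
from the first start codon (ATG/GTG/TTG) after a stop to the next stop,
while regions truncated by a contig edge are emitted as partial ORFs (no
start and/or stop required) — metatranscriptome contigs frequently end
mid-gene, so partial calls carry much of the signal.  No coding-potential
scoring is applied.

Read mapping is exact-seed + ungapped extension: seeds from the read ends
and centre are looked up in a contig k-mer index, candidate placements are
verified by Hamming distance, and the single best placement is kept
(bowtie2-style primary alignment; no fractional multi-mapping).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .assembler import Contig, revcomp
from .formats import SequenceRecord

_TABLE11 = unambiguous_dna_by_id[11]
_CODON_TO_AA = dict(_TABLE11.forward_table)
_STOPS = set(_TABLE11.stop_codons)
START_CODONS = ("ATG", "GTG", "TTG")


def translate(seq: str, as_start: bool = False) -> str:
    """Translate an in-frame nucleotide sequence (table 11).

    ``as_start`` renders the first codon as M (initiator tRNA) when it is
    a start codon.  Trailing incomplete codons are ignored; unknown codons
    become X.
    """
    aas = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            aas.append("*")
        else:
            aas.append(_CODON_TO_AA.get(codon, "X"))
    if as_start and aas and seq[:3] in START_CODONS:
        aas[0] = "M"
    return "".join(aas)


@dataclass
class Orf:
    """A predicted coding region anchored to a contig.

    ``start``/``end`` are 0-based half-open on the forward contig strand;
    coordinates include the stop codon when present.  ``partial5`` /
    ``partial3`` mark ends truncated by the contig edge (relative to the
    reading direction).
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    partial5: bool
    partial3: bool
    protein: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def _scan_frame(
    seq: str, frame: int, min_orf_aa: int, min_partial_aa: int
) -> list[tuple[int, int, bool, bool, str]]:
    """Scan one frame of one strand; coordinates are on ``seq``."""
    n_codons = (len(seq) - frame) // 3
    out = []
    window_start = None  # codon index where current inter-stop window begins
    preceded_by_stop = False
    ci = 0
    while ci <= n_codons:
        at_end = ci == n_codons
        codon = seq[frame + 3 * ci : frame + 3 * ci + 3] if not at_end else ""
        if at_end or codon in _STOPS:
            if window_start is None:
                window_start = 0
            first, last = window_start, ci  # codons [first, last) code
            partial5 = not preceded_by_stop
            partial3 = at_end
            if not partial5:
                # complete 5' end: require a start codon inside the window
                start_ci = None
                for j in range(first, last):
                    if seq[frame + 3 * j : frame + 3 * j + 3] in START_CODONS:
                        start_ci = j
                        break
                first = start_ci
            if first is not None and last > first:
                aa_len = last - first
                min_aa = (
                    min_partial_aa if (partial5 or partial3) else min_orf_aa
                )
                if aa_len >= min_aa:
                    s = frame + 3 * first
                    e = frame + 3 * last + (0 if partial3 else 3)
                    prot = translate(seq[s : frame + 3 * last], as_start=not partial5)
                    out.append((s, e, partial5, partial3, prot))
            window_start = ci + 1
            preceded_by_stop = not at_end
        ci += 1
    return out


def call_orfs(
    contig: Contig | SequenceRecord,
    min_orf_aa: int = 60,
    min_partial_aa: int = 30,
) -> list[Orf]:
    """Predict ORFs in all six frames of a contig.

    Complete ORFs must encode at least ``min_orf_aa`` amino acids; ORFs
    truncated by a contig edge are kept down to ``min_partial_aa``.
    Overlapping calls in different frames/strands are all reported.
    """
    seq = contig.seq.upper()
    length = len(seq)
    found: list[Orf] = []
    for strand in "+-":
        work = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            for s, e, p5, p3, prot in _scan_frame(
                work, frame, min_orf_aa, min_partial_aa
            ):
                if strand == "+":
                    start, end = s, e
                else:
                    start, end = length - e, length - s
                found.append(
                    Orf("", contig.id, start, end, strand, frame, p5, p3, prot)
                )
    found.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    for i, orf in enumerate(found):
        orf.id = f"{contig.id}_orf{i + 1}"
    return found


def resolve_overlaps(
    orfs: Sequence[Orf],
    max_overlap_frac: float = 0.5,
    annotated: set[str] | None = None,
) -> list[Orf]:
    """Resolve heavily overlapping ORF calls on the same contig.

    Six-frame scanning reports spurious open stretches in the other five
    frames on top of nearly every true gene; for read counting these
    duplicated intervals are poison.  ORFs are kept greedily and a
    candidate overlapping a kept ORF by more than ``max_overlap_frac`` of
    the shorter interval is dropped.  Lightly overlapping genes
    (adjacent, opposite strands) survive.

    Ranking: ORFs named in ``annotated`` (those with a database homolog —
    the strongest available evidence for the true reading frame) first,
    then longer before shorter, complete before partial.
    """
    kept: list[Orf] = []
    by_contig: dict[str, list[Orf]] = {}
    annotated = annotated or set()
    ranked = sorted(
        orfs,
        key=lambda o: (
            o.id not in annotated,
            -o.length_nt,
            o.partial5 + o.partial3,
            o.start,
            o.id,
        ),
    )
    for orf in ranked:
        ok = True
        for other in by_contig.get(orf.contig_id, ()):
            ov = min(orf.end, other.end) - max(orf.start, other.start)
            if ov > max_overlap_frac * min(orf.length_nt, other.length_nt):
                ok = False
                break
        if ok:
            kept.append(orf)
            by_contig.setdefault(orf.contig_id, []).append(orf)
    kept.sort(key=lambda o: (o.contig_id, o.start, o.end))
    return kept


@dataclass
class Placement:
    contig_id: str
    start: int  # 0-based on forward contig strand
    strand: str
    mismatches: int
    length: int


def map_reads(
    reads: Iterable[SequenceRecord],
    contigs: Sequence[Contig],
    seed_k: int = 21,
    max_mismatch: int = 3,
    min_aligned: int = 50,
) -> dict[str, Placement | None]:
    """Place each read on its best contig position, or None if unmapped.

    Seeds are taken from the first, central and last ``seed_k``-mers of the
    read in both orientations.  A read may overhang a contig end
    (soft-clipped), as long as at least ``min_aligned`` bases (or the whole
    read, if shorter) lie on the contig.  Placements are ranked by
    (clipped bases, mismatches) with ties broken to the lexicographically
    smallest (contig_id, start, strand), '+' before '-'.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    seqs: dict[str, str] = {}
    for contig in contigs:
        seqs[contig.id] = contig.seq
        cseq = contig.seq
        for i in range(len(cseq) - seed_k + 1):
            index.setdefault(cseq[i : i + seed_k], []).append((contig.id, i))

    out: dict[str, Placement | None] = {}
    for read in reads:
        rseq = read.seq
        L = len(rseq)
        need = min(L, min_aligned)
        best: tuple[int, int, str, int, str, int] | None = None
        if L >= seed_k:
            for strand, oriented in (("+", rseq), ("-", revcomp(rseq))):
                offsets = sorted({0, (L - seed_k) // 2, L - seed_k})
                candidates: set[tuple[str, int]] = set()
                for off in offsets:
                    for cid, pos in index.get(oriented[off : off + seed_k], ()):
                        candidates.add((cid, pos - off))
                for cid, start in sorted(candidates):
                    a_start = max(start, 0)
                    a_end = min(start + L, len(seqs[cid]))
                    aligned = a_end - a_start
                    if aligned < need:
                        continue
                    window = seqs[cid][a_start:a_end]
                    segment = oriented[a_start - start : a_end - start]
                    mm = sum(a != b for a, b in zip(segment, window))
                    if mm > max_mismatch:
                        continue
                    key = (L - aligned, mm, cid, a_start, strand, aligned)
                    if best is None or key < best:
                        best = key
        out[read.id] = (
            Placement(best[2], best[3], best[4], best[1], best[5])
            if best
            else None
        )
    return out


@dataclass
class ExpressionTable:
    """Per-ORF read counts plus the per-read ORF assignment map."""

    table: pd.DataFrame  # orf_id, contig_id, length_nt, read_count, reads_per_kb
    read_orf: dict[str, str | None]  # mapped read -> orf id (None = intergenic)
    n_intergenic: int
    n_unmapped: int

    @property
    def counts(self) -> dict[str, int]:
        return dict(zip(self.table["orf_id"], self.table["read_count"]))


def quantify(
    placements: Mapping[str, Placement | None], orfs: Sequence[Orf]
) -> ExpressionTable:
    """Assign each mapped read to the ORF it overlaps most.

    Ties go to the ORF with the smaller start; reads overlapping no ORF
    count as intergenic.  ``reads_per_kb`` is read_count per kilobase of
    ORF, the length normalisation used for expression comparisons.
    """
    by_contig: dict[str, list[Orf]] = {}
    for orf in orfs:
        by_contig.setdefault(orf.contig_id, []).append(orf)
    for lst in by_contig.values():
        lst.sort(key=lambda o: (o.start, o.end))

    counts: dict[str, int] = {o.id: 0 for o in orfs}
    read_orf: dict[str, str | None] = {}
    n_intergenic = n_unmapped = 0
    for rid in sorted(placements):
        pl = placements[rid]
        if pl is None:
            n_unmapped += 1
            continue
        r_start, r_end = pl.start, pl.start + pl.length
        best_orf = None
        best_key = None
        for orf in by_contig.get(pl.contig_id, ()):
            ov = min(r_end, orf.end) - max(r_start, orf.start)
            if ov > 0:
                key = (-ov, orf.start, orf.id)
                if best_key is None or key < best_key:
                    best_key = key
                    best_orf = orf
        if best_orf is None:
            n_intergenic += 1
            read_orf[rid] = None
        else:
            counts[best_orf.id] += 1
            read_orf[rid] = best_orf.id

    table = pd.DataFrame(
        [
            {
                "orf_id": o.id,
                "contig_id": o.contig_id,
                "length_nt": o.length_nt,
                "read_count": counts[o.id],
                "reads_per_kb": counts[o.id] / (o.length_nt / 1000.0),
            }
            for o in orfs
        ]
    )
    return ExpressionTable(table, read_orf, n_intergenic, n_unmapped)


def orfs_to_features(orfs: Iterable[Orf]):
    """Convert ORFs to 1-based GFF3 feature rows."""
    from .formats import FeatureRow

    rows = []
    for o in orfs:
        rows.append(
            FeatureRow(
                seq_id=o.contig_id,
                start=o.start + 1,
                end=o.end,
                strand=o.strand,
                frame=0,
                ftype="CDS",
                attrs={
                    "ID": o.id,
                    "partial5": str(o.partial5).lower(),
                    "partial3": str(o.partial3).lower(),
                },
            )
        )
    return rows
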