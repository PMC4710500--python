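"""Validation machinery: how good was the assembly, really?

Given reference genomes with known organism of origin and a per-read truth
table, this module measures everything the pipeline claims: contig-level
correctness (full-length matches, end mismatches, cross-member chimeras),
read-level functional and taxonomic precision/recall against the truth,
congruence of expression profiles, the gene-coverage threshold below which
assembly fails, and tetranucleotide-signature similarity between genomes.

Contig-to-reference comparison uses banded edit-distance alignment (edlib)
in infix mode: the whole contig must align inside a genome; identity is
1 - edits/contig_length.  Chimera calls rest on windowed attribution: the
contig is cut into fixed windows, each window is attributed to the genome
it matches best, and two or more long runs attributed to different
organisms make the contig chimeric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .assembler import Contig, revcomp
from .taxonomy import TaxonomyTree


@dataclass
class ContigClass:
    contig_id: str
    cls: str  # clean_full_length | end_mismatch | chimeric | unaligned
    best_ref: str
    aligned_fraction: float
    n_ref_segments: int


def _infix_identity(query: str, target: str) -> tuple[float, bool]:
    """Best identity of ``query`` inside ``target`` (either strand).

    Returns (identity, gapless) where identity = 1 - edits/len(query) and
    gapless is True when the best alignment contains no indels.
    """
    best_dist = len(query)
    best_gapless = False
    for q in (query, revcomp(query)):
        res = edlib.align(q, target, mode="HW", task="path", k=best_dist)
        if res["editDistance"] == -1:
            continue
        dist = res["editDistance"]
        gapless = "I" not in res["cigar"] and "D" not in res["cigar"]
        if dist < best_dist or (dist == best_dist and gapless and not best_gapless):
            best_dist, best_gapless = dist, gapless
    return 1.0 - best_dist / len(query), best_gapless


def classify_contigs(
    contigs: Sequence[Contig],
    ref_genomes: Mapping[str, str],
    min_identity: float = 0.95,
    window: int = 150,
    window_identity: float = 0.90,
    min_segment: int = 150,
    edge_window: int = 100,
) -> list[ContigClass]:
    """Classify each contig against the annotated reference genomes.

    clean_full_length: the whole contig aligns gaplessly to one genome at
    >= ``min_identity``.  end_mismatch: only the contig interior (edges of
    ``edge_window`` bp trimmed) reaches ``min_identity`` — mismatches are
    confined to the termini.  chimeric: two or more organisms each own a
    high-identity segment of >= ``min_segment`` bp.  unaligned: none of
    the above.
    """
    out: list[ContigClass] = []
    orgs = sorted(ref_genomes)
    for contig in contigs:
        seq = contig.seq
        # windowed attribution
        win_org: list[str | None] = []
        starts = list(range(0, max(len(seq) - window + 1, 1), window))
        for ws in starts:
            piece = seq[ws : ws + window]
            best: tuple[float, str] | None = None
            for org in orgs:
                ident, _ = _infix_identity(piece, ref_genomes[org])
                if best is None or ident > best[0]:
                    best = (ident, org)
            win_org.append(best[1] if best and best[0] >= window_identity else None)

        # merge windows into per-organism segments
        seg_lengths: dict[str, int] = {}
        segments: list[tuple[str, int]] = []
        for org in win_org:
            if org is None:
                continue
            if segments and segments[-1][0] == org:
                segments[-1] = (org, segments[-1][1] + window)
            else:
                segments.append((org, window))
        for org, length in segments:
            seg_lengths[org] = max(seg_lengths.get(org, 0), length)
        owners = [o for o, ln in seg_lengths.items() if ln >= min_segment]

        attributed = sum(o is not None for o in win_org) / len(win_org)
        if len(owners) >= 2:
            n_seg = sum(1 for org, ln in segments if ln >= min_segment)
            best_ref = max(seg_lengths, key=lambda o: (seg_lengths[o], o))
            out.append(
                ContigClass(contig.id, "chimeric", best_ref, attributed, n_seg)
            )
            continue
        if len(owners) == 1:
            org = owners[0]
            ident, gapless = _infix_identity(seq, ref_genomes[org])
            if ident >= min_identity and gapless:
                cls = "clean_full_length"
            else:
                core = seq[edge_window : len(seq) - edge_window]
                if len(core) >= window:
                    core_ident, _ = _infix_identity(core, ref_genomes[org])
                else:
                    core_ident = ident
                cls = "end_mismatch" if core_ident >= min_identity else "unaligned"
            out.append(ContigClass(contig.id, cls, org, attributed, 1))
            continue
        out.append(ContigClass(contig.id, "unaligned", "", attributed, 0))
    return out


@dataclass
class PrReport:
    """Read-level confusion counts at one level (function, or one rank).

    A read whose prediction disagrees with the truth is a false positive
    (it hurts precision) *and* a false negative (its true label was not
    recovered, hurting recall), so tp + fn equals the evaluable read
    count while fp <= fn.
    """

    level: str
    rank: str = ""
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


def functional_pr(
    truth: Mapping[str, str], predicted: Mapping[str, str | None]
) -> PrReport:
    """Per-read KO assignment confusion.

    ``truth`` maps every evaluable read to its true KO; ``predicted`` maps
    reads to the KO transferred through the pipeline (absent or None =
    unassigned).  A read predicted but missing from the truth is a label
    leak and a hard error.  Reads whose truth KO is empty are excluded.
    """
    extra = set(predicted) - set(truth)
    if extra:
        raise ValueError(
            f"{len(extra)} predicted reads not in truth (e.g. {sorted(extra)[:3]})"
        )
    report = PrReport("function")
    for rid, true_ko in truth.items():
        if not true_ko:
            continue
        pred = predicted.get(rid)
        if pred is None or pred == "":
            report.fn += 1
        elif pred == true_ko:
            report.tp += 1
        else:
            report.fp += 1
            report.fn += 1
    return report


def taxonomic_pr(
    truth: Mapping[str, int],
    predicted: Mapping[str, int | None],
    tree: TaxonomyTree,
    ranks: Sequence[str] = ("phylum", "class", "order", "family", "genus"),
) -> dict[str, PrReport]:
    """Per-read taxonomic confusion at each requested rank.

    At rank r a read is TP when the predicted taxon's rank-r ancestor
    equals the truth's, FP when both exist and differ, FN when the truth
    has a rank-r ancestor but the read is unassembled/unclassified or its
    prediction has no rank-r ancestor.  Reads whose truth lacks rank r are
    excluded at that rank.
    """
    extra = set(predicted) - set(truth)
    if extra:
        raise ValueError(f"{len(extra)} predicted reads not in truth")
    reports: dict[str, PrReport] = {}
    true_anc: dict[str, dict[int, int | None]] = {}
    for rank in ranks:
        rep = PrReport("taxonomy", rank=rank)
        cache: dict[int, int | None] = {}

        def anc(taxid: int | None) -> int | None:
            if taxid is None:
                return None
            if taxid not in cache:
                cache[taxid] = (
                    tree.rank_ancestor(taxid, rank) if taxid in tree else None
                )
            return cache[taxid]

        for rid, true_taxid in truth.items():
            t_anc = anc(true_taxid)
            if t_anc is None:
                continue
            p_anc = anc(predicted.get(rid))
            if p_anc is None:
                rep.fn += 1
            elif p_anc == t_anc:
                rep.tp += 1
            else:
                rep.fp += 1
                rep.fn += 1
        reports[rank] = rep
    return reports


def profile_correlation(
    profile_a: Mapping[str, float],
    profile_b: Mapping[str, float],
    log_transform: bool = True,
) -> float:
    """Pearson correlation of two keyed abundance profiles.

    Keys are united, missing values are 0; counts are log10(x+1)
    transformed by default (expression comparisons are log-log).
    """
    keys = sorted(set(profile_a) | set(profile_b))
    a = np.array([profile_a.get(k, 0.0) for k in keys], dtype=float)
    b = np.array([profile_b.get(k, 0.0) for k in keys], dtype=float)
    if log_transform:
        a = np.log10(a + 1.0)
        b = np.log10(b + 1.0)
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class CoverageCurve:
    bins: list[float]  # ascending coverage bin lower edges
    fractions: list[float]  # fraction of genes with an assembled transcript
    n_genes: list[int]
    threshold: float | None  # smallest bin with fraction >= q


def coverage_curve(
    gene_coverage: Mapping[str, float],
    assembled: Mapping[str, bool],
    bins: Sequence[float] = (0.5, 1.0, 2.0, 3.0, 5.0, 10.0),
    q: float = 0.5,
) -> CoverageCurve:
    """Assembled-gene fraction as a function of expected read coverage.

    A gene falls in bin i when bins[i] <= coverage < bins[i+1].  The
    detected threshold is the smallest bin whose assembled fraction
    reaches ``q``; monotonicity of the curve is reported, not enforced.
    """
    edges = list(bins)
    if edges != sorted(edges):
        raise ValueError("bins must be ascending")
    counts = [0] * len(edges)
    hits = [0] * len(edges)
    for gene, cov in gene_coverage.items():
        idx = None
        for i, edge in enumerate(edges):
            if cov >= edge:
                idx = i
        if idx is None:
            continue
        counts[idx] += 1
        hits[idx] += bool(assembled.get(gene, False))
    fractions = [h / c if c else 0.0 for h, c in zip(hits, counts)]
    threshold = None
    for edge, frac, c in zip(edges, fractions, counts):
        if c and frac >= q:
            threshold = edge
            break
    return CoverageCurve(edges, fractions, counts, threshold)


def gene_assembled(
    data,
    contigs: Sequence[Contig],
    k: int = 31,
    min_fraction: float = 0.5,
) -> dict[str, bool]:
    """Which true genes have >= ``min_fraction`` of their k-mers in some
    assembled contig (at least a partial transcript assembly)."""
    from .assembler import canonical

    contig_kmers: set[str] = set()
    for contig in contigs:
        for i in range(len(contig.seq) - k + 1):
            contig_kmers.add(canonical(contig.seq[i : i + k]))
    out: dict[str, bool] = {}
    for genome in data.genomes:
        for gene in genome.genes:
            total = len(gene.seq) - k + 1
            if total <= 0:
                out[gene.gene_id] = False
                continue
            found = sum(
                canonical(gene.seq[i : i + k]) in contig_kmers
                for i in range(total)
            )
            out[gene.gene_id] = found / total >= min_fraction
    return out


def tetranucleotide_regression(genome_a: str, genome_b: str) -> float:
    """r-squared of the 256-dimensional tetranucleotide frequency vectors.

    Frequencies are counted on both strands with overlapping windows
    (step 1), the genome-signature statistic used to gauge compositional
    relatedness between community members.
    """
    va = _tetra_freqs(genome_a)
    vb = _tetra_freqs(genome_b)
    r = stats.pearsonr(va, vb).statistic
    return float(r * r)


def _tetra_freqs(seq: str) -> np.ndarray:
    from itertools import product

    idx = {"".join(p): i for i, p in enumerate(product("ACGT", repeat=4))}
    counts = np.zeros(256, dtype=float)
    for s in (seq, revcomp(seq)):
        for i in range(len(s) - 3):
            j = idx.get(s[i : i + 4])
            if j is not None:
                counts[j] += 1
    total = counts.sum()
    return counts / total if total else counts


def pr_table(reports: Mapping[str, PrReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "level": rep.level,
                "rank": rep.rank,
                "tp": rep.tp,
                "fp": rep.fp,
                "fn": rep.fn,
                "precision": rep.precision,
                "recall": rep.recall,
            }
            for rep in reports.values()
        ]
    )
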