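"""Multi-k de Bruijn assembly of filtered mRNA reads.

A deliberately conservative assembler for transcript-scale problems: count
canonical k-mers, clean sequencing-error artefacts by relative-depth
branch pruning and tip clipping, and emit maximal non-branching paths
(unitigs) — no scaffolding, no consensus polishing.  Running several
ascending k values in sequence, feeding each round's contigs back in as
pseudo-reads, lets small-k rounds bridge low-coverage regions and large-k
rounds resolve repeats, the idea behind iterative-k assemblers.  All
k-mers are kept by default (min_count=1): expressed transcripts can sit
at very low coverage and absolute-count pruning destroys them, while the
relative-depth cleaner removes error branches without a hard cutoff.
Coverage at branch points is never averaged across members, which keeps
cross-species (chimeric) joins rare.

Determinism: k-mers are iterated in sorted canonical order and contigs are
emitted in sorted canonical-sequence order, so identical input yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .formats import SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class Contig:
    id: str
    seq: str
    mean_coverage: float = 0.0
    read_ids: list[str] | None = None

    def __len__(self) -> int:
        return len(self.seq)


class DeBruijnGraph:
    """Canonical k-mer graph; edges are implicit (k-1)-overlap adjacencies."""

    def __init__(self, k: int, counts: dict[str, int]):
        self.k = k
        self.counts = counts

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def count(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    def successors(self, kmer: str) -> list[str]:
        """Oriented k-mers reachable by a one-base extension to the right."""
        suffix = kmer[1:]
        return [suffix + b for b in "ACGT" if canonical(suffix + b) in self.counts]

    def predecessors(self, kmer: str) -> list[str]:
        prefix = kmer[:-1]
        return [b + prefix for b in "ACGT" if canonical(b + prefix) in self.counts]


def build_graph(
    reads: Iterable[SequenceRecord | str], k: int, min_count: int = 2
) -> DeBruijnGraph:
    """Count canonical k-mers and drop those below ``min_count``.

    k must be odd (no reverse-complement palindromes) and in [15, 127].
    k-mers containing N are skipped.
    """
    if k % 2 == 0 or not (15 <= k <= 127):
        raise ValueError("k must be odd and within [15, 127]")
    counts: dict[str, int] = {}
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    if min_count > 1:
        counts = {km: c for km, c in counts.items() if c >= min_count}
    return DeBruijnGraph(k, counts)


def prune_branches(
    graph: DeBruijnGraph, ratio: float = 1 / 3, max_rounds: int = 3
) -> int:
    """Remove weak branches at junctions (relative-depth pruning).

    At any junction, alternative extensions whose k-mer count is at most
    ``ratio`` times the strongest extension are deleted — recurrent
    sequencing errors form side branches supported by a couple of reads
    next to a true path supported by the full local depth.  Junctions with
    balanced depths (genuine repeats, strain variants) are left alone.
    Returns the number of k-mers removed; modifies the graph in place.
    """
    removed_total = 0
    for _ in range(max_rounds):
        doomed: set[str] = set()
        for ckmer in graph.counts:
            for oriented in (ckmer, revcomp(ckmer)):
                succs = graph.successors(oriented)
                if len(succs) < 2:
                    continue
                counts = [graph.count(s) for s in succs]
                cmax = max(counts)
                for s, c in zip(succs, counts):
                    if c <= ratio * cmax:
                        doomed.add(canonical(s))
        doomed = {d for d in doomed if d in graph.counts}
        if not doomed:
            break
        for d in doomed:
            del graph.counts[d]
        removed_total += len(doomed)
    return removed_total


def clip_tips(
    graph: DeBruijnGraph, max_tip_len: int | None = None, max_rounds: int = 3
) -> int:
    """Remove short dead-end paths hanging off junctions.

    A tip is a unitig with a dead end on one side, a junction on the
    other, and total length below ``max_tip_len`` (default k + 75, the
    longest path a read-terminal sequencing error can support).  Modifies
    the graph in place; returns the number of k-mers removed.
    """
    k = graph.k
    if max_tip_len is None:
        max_tip_len = k + 75
    removed_total = 0
    for _ in range(max_rounds):
        doomed: set[str] = set()
        for contig in traverse_unitigs(graph):
            if len(contig.seq) >= max_tip_len:
                continue
            first, last = contig.seq[:k], contig.seq[-k:]
            n_pred = len(graph.predecessors(first))
            n_succ = len(graph.successors(last))
            # dead on one side, attached on the other (isolated short
            # unitigs are left for the length filter)
            if (n_pred == 0) != (n_succ == 0):
                for i in range(len(contig.seq) - k + 1):
                    doomed.add(canonical(contig.seq[i : i + k]))
        doomed = {d for d in doomed if d in graph.counts}
        if not doomed:
            break
        for d in doomed:
            del graph.counts[d]
        removed_total += len(doomed)
    return removed_total


def traverse_unitigs(graph: DeBruijnGraph) -> list[Contig]:
    """Emit maximal non-branching paths as contigs.

    Extension through a junction is refused in both directions (a unitig
    ends where the next node has in-degree != 1 or the current node has
    out-degree != 1).  Output is deterministic: contig sequences are
    canonicalized and sorted.  ``mean_coverage`` is the mean count of the
    constituent k-mers.
    """
    k = graph.k
    visited: set[str] = set()
    raw: list[tuple[str, float]] = []

    def _extend(start: str) -> tuple[str, list[str]]:
        seq = start
        used = [canonical(start)]
        cur = start
        while True:
            succs = graph.successors(cur)
            if len(succs) != 1:
                break
            nxt = succs[0]
            cnx = canonical(nxt)
            if cnx in visited or cnx in used_set:
                break
            if len(graph.predecessors(nxt)) != 1:
                break
            seq += nxt[-1]
            used.append(cnx)
            used_set.add(cnx)
            cur = nxt
        return seq, used

    for ckmer in sorted(graph.counts):
        if ckmer in visited:
            continue
        used_set = {ckmer}
        fwd_seq, fwd_used = _extend(ckmer)
        # extend the other direction by walking from the reverse complement
        rev_seq, rev_used = _extend(revcomp(ckmer))
        seq = revcomp(rev_seq) + fwd_seq[k:]
        used = set(fwd_used) | set(rev_used)
        visited |= used
        cov = sum(graph.counts[c] for c in used) / len(used)
        raw.append((canonical_seq(seq), cov))

    raw.sort()
    return [
        Contig(f"contig_{i + 1:05d}", seq, mean_coverage=cov)
        for i, (seq, cov) in enumerate(raw)
    ]


def canonical_seq(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def assemble_multi_k(
    reads: Sequence[SequenceRecord],
    k_list: Sequence[int] = (31, 41, 51),
    min_count: int = 1,
    min_contig_len: int | None = None,
    compute_coverage: bool = True,
    clean: bool = True,
) -> list[Contig]:
    """Iterative-k assembly.

    Each round's contigs join the original reads as weight-1 pseudo-reads
    for the next, larger, k.  When ``clean`` is set (default), each
    round's graph is error-cleaned by relative-depth branch pruning and
    tip clipping before traversal.  Contigs shorter than
    ``min_contig_len`` (default twice the largest k) are suppressed from
    the final output.  When ``compute_coverage`` is set, reads are
    re-mapped onto the final contigs and ``mean_coverage`` becomes mapped
    bases / contig length.
    """
    if list(k_list) != sorted(k_list):
        raise ValueError("k_list must be ascending")
    if min_contig_len is None:
        min_contig_len = 2 * max(k_list)

    contigs: list[Contig] = []
    for k in k_list:
        pool: list[str] = [r.seq for r in reads] + [c.seq for c in contigs]
        graph = build_graph(pool, k, min_count=min_count)
        if clean:
            prune_branches(graph)
            clip_tips(graph)
        contigs = traverse_unitigs(graph)

    contigs = [c for c in contigs if len(c) >= min_contig_len]
    for i, c in enumerate(contigs):
        c.id = f"contig_{i + 1:05d}"

    if compute_coverage and contigs:
        from .genecalling import map_reads

        placements = map_reads(reads, contigs)
        bases: dict[str, int] = {c.id: 0 for c in contigs}
        members: dict[str, list[str]] = {c.id: [] for c in contigs}
        for rid, pl in placements.items():
            if pl is not None:
                bases[pl.contig_id] += pl.length
                members[pl.contig_id].append(rid)
        for c in contigs:
            c.mean_coverage = bases[c.id] / len(c)
            c.read_ids = members[c.id]
    return contigs


def import_contigs(fasta_path: str | Path) -> list[Contig]:
    """Wrap externally assembled contigs (e.g. from IDBA-UD) for the pipeline."""
    from .formats import read_fasta

    return [Contig(rec.id, rec.seq) for rec in read_fasta(fasta_path)]


def write_contigs(contigs: Iterable[Contig], path: str | Path) -> None:
    from .formats import SequenceRecord, write_fasta

    write_fasta(
        (
            SequenceRecord(
                c.id, c.seq, meta={"cov": f"{c.mean_coverage:.2f}"}
            )
            for c in contigs
        ),
        path,
    )
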