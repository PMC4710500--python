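"""Protein similarity search and functional label transfer.

Local alignment uses BLOSUM62 with BLAST-style affine gaps (a gap of length
L costs gap_open + L * gap_extend, default 11 + L).  Raw scores are mapped
to bit scores with fixed gapped Karlin-Altschul constants (lambda = 0.267,
K = 0.041, the standard values for BLOSUM62/11/1) and E-values use the plain
m*n search-space product rather than effective lengths — deterministic and
adequate for ranking.  Function labels (KO, COG) are transferred from the
single best hit only; an unlabeled best hit yields no label.

The SRV (similarity ratio value) of a query is the bit score of its best
database hit divided by the bit score of its self-alignment: 1.0 means the
query itself is in the database, values near 0 mean only remote homologs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

LAMBDA = 0.267
LN_K = math.log(0.041)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(_BLOSUM62.alphabet)


def _make_aligner(gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    # Biopython charges open on the first gapped position; BLAST charges
    # open + extend there, hence the -(open + extend) first-position score.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner(11, 1)


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if all(c in _ALPHABET for c in seq):
        return seq
    return "".join(c if c in _ALPHABET else "X" for c in seq)


def bit_score(raw: float) -> float:
    return (LAMBDA * raw - LN_K) / math.log(2)


def evalue(bit: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bit)


@dataclass
class Hit:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity_fraction: float


@dataclass
class SrvScore:
    query_id: str
    srv: float


def smith_waterman(
    query_aa: str,
    subject_aa: str,
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> Hit:
    """Optimal local alignment of two protein sequences.

    Unknown residues are scored as X.  An all-negative pair has raw score 0
    (the empty local alignment) and identity 0.
    """
    if not query_aa or not subject_aa:
        raise ValueError("sequences must be non-empty")
    q, s = _sanitize(query_aa), _sanitize(subject_aa)
    if gap_open == 11 and gap_extend == 1:
        aligner = _DEFAULT_ALIGNER
    else:
        aligner = _make_aligner(gap_open, gap_extend)
    raw = int(aligner.score(q, s))
    identity = 0.0
    if raw > 0:
        aln = aligner.align(q, s)[0]
        counts = aln.counts()
        cols = counts.aligned + counts.gaps
        identity = counts.identities / cols if cols else 0.0
    bit = bit_score(raw)
    return Hit(query_id, subject_id, raw, bit, evalue(bit, len(q), len(s)), identity)


class ReferenceProteinDB:
    """Labeled protein database: sequences plus a per-protein label table.

    The label table is a DataFrame indexed by protein id with at least a
    ``taxid`` column; ``ko``, ``cog``, ``categories`` and (for marker sets)
    ``family`` are optional.  Missing labels are empty strings.
    """

    def __init__(self, seqs: Mapping[str, str], labels: pd.DataFrame):
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate protein ids")
        self.seqs = dict(seqs)
        labels = labels.reindex(list(seqs))
        if "taxid" not in labels.columns:
            labels["taxid"] = 0
        labels["taxid"] = labels["taxid"].fillna(0).astype(int)
        for col in ("ko", "cog", "categories", "family"):
            if col not in labels.columns:
                labels[col] = ""
            labels[col] = labels[col].fillna("").astype(str)
        self.labels = labels
        self.taxids: dict[str, int] = labels["taxid"].to_dict()

    @classmethod
    def from_files(
        cls, fasta_path: str | Path, labels_path: str | Path | None = None
    ) -> "ReferenceProteinDB":
        from .formats import read_fasta

        seqs = {rec.id: rec.seq for rec in read_fasta(fasta_path)}
        if labels_path is not None:
            labels = pd.read_csv(labels_path, sep="\t", dtype=str).set_index(
                "protein_id"
            )
            if "taxid" in labels.columns:
                labels["taxid"] = labels["taxid"].astype(float).astype(int)
        else:
            labels = pd.DataFrame(index=list(seqs))
        return cls(seqs, labels)

    def to_files(self, fasta_path: str | Path, labels_path: str | Path) -> None:
        from .formats import SequenceRecord, write_fasta

        write_fasta(
            (SequenceRecord(pid, seq) for pid, seq in self.seqs.items()), fasta_path
        )
        out = self.labels.copy()
        out.index.name = "protein_id"
        out.to_csv(labels_path, sep="\t")

    def label(self, protein_id: str, column: str) -> str:
        val = self.labels.at[protein_id, column]
        return "" if pd.isna(val) else str(val)

    def __len__(self) -> int:
        return len(self.seqs)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.seqs

    def subset(self, protein_ids: Iterable[str]) -> "ReferenceProteinDB":
        ids = [pid for pid in self.seqs if pid in set(protein_ids)]
        return ReferenceProteinDB(
            {pid: self.seqs[pid] for pid in ids}, self.labels.loc[ids]
        )

    def exclude(self, taxids: set[int] | None) -> "ReferenceProteinDB":
        if not taxids:
            return self
        keep = [pid for pid, t in self.taxids.items() if t not in taxids]
        return self.subset(keep)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


# db size below which the shared-4-mer prefilter is skipped entirely
PREFILTER_MIN_DB = 50


def search(
    query_proteins: Mapping[str, str],
    db: ReferenceProteinDB,
    min_bit: float = 0.0,
    max_evalue: float = 1e-4,
    prefilter: bool = True,
    prefilter_k: int = 4,
) -> dict[str, list[Hit]]:
    """All-vs-db local alignment search.

    Returns, per query, hits with E-value <= ``max_evalue`` and bit score
    >= ``min_bit``, sorted by bit score descending then subject id
    ascending.  A shared-4-mer prefilter skips hopeless pairs when the
    database has at least ``PREFILTER_MIN_DB`` proteins.
    """
    use_prefilter = prefilter and len(db) >= PREFILTER_MIN_DB
    db_index: dict[str, set[str]] = {}
    if use_prefilter:
        index: dict[str, list[str]] = {}
        for sid, seq in db.seqs.items():
            for kmer in _kmer_set(_sanitize(seq), prefilter_k):
                index.setdefault(kmer, []).append(sid)
        db_index = {k: set(v) for k, v in index.items()}

    results: dict[str, list[Hit]] = {}
    for qid in sorted(query_proteins):
        qseq = query_proteins[qid]
        if use_prefilter:
            candidates: set[str] = set()
            for kmer in _kmer_set(_sanitize(qseq), prefilter_k):
                candidates |= db_index.get(kmer, set())
            subject_ids: Iterable[str] = sorted(candidates)
        else:
            subject_ids = sorted(db.seqs)
        hits = []
        for sid in subject_ids:
            hit = smith_waterman(qseq, db.seqs[sid], query_id=qid, subject_id=sid)
            if hit.evalue <= max_evalue and hit.bit_score >= min_bit:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
        results[qid] = hits
    return results


@dataclass
class Annotation:
    query_id: str
    subject_id: str = ""
    ko: str = ""
    cog: str = ""
    categories: str = ""

    @property
    def annotated(self) -> bool:
        return bool(self.subject_id)


def annotate_sbh(
    hits: Mapping[str, list[Hit]], db: ReferenceProteinDB
) -> dict[str, Annotation]:
    """Single-best-hit label transfer.

    Only the top-ranked hit contributes; if it carries no KO/COG the query
    stays unlabeled (no fallback to lower-ranked hits).  Ties on bit score
    are already broken to the smaller subject id by ``search``.
    """
    out: dict[str, Annotation] = {}
    for qid, hit_list in hits.items():
        if not hit_list:
            out[qid] = Annotation(qid)
            continue
        best = hit_list[0]
        out[qid] = Annotation(
            qid,
            best.subject_id,
            db.label(best.subject_id, "ko"),
            db.label(best.subject_id, "cog"),
            db.label(best.subject_id, "categories"),
        )
    return out


def srv(query_seq: str, hits: list[Hit], query_id: str = "query") -> SrvScore:
    """Bit score of the best hit over the query's self-alignment bit score.

    No hit above threshold -> 0.0 by convention.
    """
    if not hits:
        return SrvScore(query_id, 0.0)
    self_bit = smith_waterman(query_seq, query_seq).bit_score
    return SrvScore(query_id, hits[0].bit_score / self_bit)


def srv_histogram(scores: Iterable[float], width: float = 0.05) -> pd.DataFrame:
    """Bin SRV scores for a similarity-distribution plot."""
    edges = np.arange(0.0, 1.0 + width, width)
    counts, _ = np.histogram(np.clip(list(scores), 0, 1), bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )


def lump_cog_categories(
    read_counts: Mapping[str, int], annotations: Mapping[str, Annotation]
) -> pd.DataFrame:
    """Sum read counts per one-letter COG category.

    A COG labeled with several categories (e.g. "KT") splits its reads
    equally among the letters.  Fractions are over labeled reads and sum
    to 1.  Columns: category / reads / fraction.
    """
    sums: dict[str, float] = {}
    for pid, count in read_counts.items():
        ann = annotations.get(pid)
        if ann is None or not ann.categories:
            continue
        letters = [c for c in ann.categories if c.isalpha()]
        if not letters:
            continue
        share = count / len(letters)
        for letter in letters:
            sums[letter] = sums.get(letter, 0.0) + share
    total = sum(sums.values())
    return pd.DataFrame(
        [
            {
                "category": cat,
                "reads": reads,
                "fraction": reads / total if total else 0.0,
            }
            for cat, reads in sorted(sums.items())
        ]
    )
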