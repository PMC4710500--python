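"""The read-filtering cascade applied before assembly.

Stages, in order: rRNA screening (canonical k-mer containment against rRNA
references — a lightweight stand-in for seed-based rRNA filters), adapter
handling (reads with adapter evidence are discarded outright by default:
adapter-trimmed tails show a strong adenine bias, so trimmed remainders are
not trustworthy), per-base quality edge trimming (phred > threshold must
hold at both termini) followed by poly-A tail removal, and a minimum-length
filter.  Every input read lands in exactly one output bucket, so the stage
counts in the report always sum to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .assembler import canonical
from .formats import SequenceRecord

# TruSeq universal adapter prefix
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@dataclass
class FilterConfig:
    qual_threshold: int = 30
    min_length: int = 50
    polya_min_run: int = 5
    adapter_seqs: list[str] = field(default_factory=lambda: [DEFAULT_ADAPTER])
    adapter_min_overlap: int = 10
    rrna_k: int = 31
    rrna_kmer_fraction: float = 0.25
    drop_adapter_reads: bool = True

    def __post_init__(self) -> None:
        if min(self.qual_threshold, self.min_length, self.polya_min_run) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.rrna_k < 15:
            raise ValueError("rrna_k must be >= 15")


@dataclass
class FilterReport:
    """Per-stage read counts; trimming conserves reads, so
    input = removed_rrna + removed_adapter + removed_short + passed."""

    input: int = 0
    removed_rrna: int = 0
    removed_adapter: int = 0
    trimmed: int = 0
    removed_short: int = 0
    passed: int = 0
    too_short_for_rrna_screen: int = 0

    def check(self) -> None:
        total = self.removed_rrna + self.removed_adapter + self.removed_short + self.passed
        if total != self.input:
            raise AssertionError(
                f"filter conservation violated: {total} != {self.input}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"stage": "input", "reads": self.input},
                {"stage": "removed_rrna", "reads": self.removed_rrna},
                {"stage": "removed_adapter", "reads": self.removed_adapter},
                {"stage": "trimmed", "reads": self.trimmed},
                {"stage": "removed_short", "reads": self.removed_short},
                {"stage": "passed", "reads": self.passed},
            ]
        )


def rrna_kmer_set(rrna_refs: Iterable[SequenceRecord | str], k: int) -> set[str]:
    kmers: set[str] = set()
    for ref in rrna_refs:
        seq = ref if isinstance(ref, str) else ref.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                kmers.add(canonical(kmer))
    return kmers


def screen_rrna(
    reads: Sequence[SequenceRecord],
    rrna_refs: Sequence[SequenceRecord | str],
    k: int = 31,
    fraction: float = 0.25,
) -> tuple[list[SequenceRecord], list[SequenceRecord], int]:
    """Partition reads into (mRNA, rRNA) by canonical k-mer containment.

    A read is called rRNA iff at least ``fraction`` of its k-mers occur in
    the reference k-mer set.  Reads shorter than k cannot be screened and
    are kept as mRNA; their count is returned as the third element.
    """
    if not rrna_refs:
        raise ValueError("rrna_refs must be non-empty")
    refset = rrna_kmer_set(rrna_refs, k)
    mrna: list[SequenceRecord] = []
    rrna: list[SequenceRecord] = []
    n_short = 0
    for read in reads:
        n_kmers = len(read.seq) - k + 1
        if n_kmers <= 0:
            n_short += 1
            mrna.append(read)
            continue
        hits = sum(
            canonical(read.seq[i : i + k]) in refset for i in range(n_kmers)
        )
        (rrna if hits / n_kmers >= fraction else mrna).append(read)
    return mrna, rrna, n_short


def _adapter_match(seq: str, adapter: str, min_overlap: int) -> int | None:
    """Position of an adapter match in ``seq``, or None.

    Full internal occurrences must be exact; a read-suffix / adapter-prefix
    overlap of at least ``min_overlap`` bases may carry one mismatch.
    """
    pos = seq.find(adapter)
    if pos != -1:
        return pos
    max_ov = min(len(adapter), len(seq))
    for ov in range(max_ov, min_overlap - 1, -1):
        tail = seq[len(seq) - ov :]
        mismatches = sum(a != b for a, b in zip(tail, adapter[:ov]))
        if mismatches <= 1:
            return len(seq) - ov
    return None


def handle_adapters(
    reads: Sequence[SequenceRecord], config: FilterConfig
) -> tuple[list[SequenceRecord], int]:
    """Discard (default) or trim reads showing adapter sequence."""
    if not config.adapter_seqs:
        raise ValueError("adapter list must be non-empty")
    kept: list[SequenceRecord] = []
    n_removed = 0
    for read in reads:
        match = None
        for adapter in config.adapter_seqs:
            match = _adapter_match(read.seq, adapter, config.adapter_min_overlap)
            if match is not None:
                break
        if match is None:
            kept.append(read)
        elif config.drop_adapter_reads or match == 0:
            n_removed += 1
        else:
            kept.append(
                SequenceRecord(
                    read.id,
                    read.seq[:match],
                    read.qual[:match] if read.qual else None,
                    read.meta,
                )
            )
    return kept, n_removed


def trim_edges(
    read: SequenceRecord, qual_threshold: int = 30, polya_min_run: int = 5
) -> SequenceRecord | None:
    """Quality- and poly-A-trim both read ends; interior bases never move.

    Bases are stripped from either end while the terminal phred is <=
    ``qual_threshold``; then a terminal run of >= ``polya_min_run`` A's
    (or a leading run of T's — the reverse-complement tail) is removed.
    The two trims repeat until a fixed point, so the operation is
    idempotent.  Returns None when the read is trimmed away entirely.
    """
    if read.qual is None:
        raise ValueError(f"read {read.id!r} has no qualities")
    seq, qual = read.seq, read.qual
    while True:
        lo, hi = 0, len(seq)
        while lo < hi and qual[lo] <= qual_threshold:
            lo += 1
        while hi > lo and qual[hi - 1] <= qual_threshold:
            hi -= 1
        seq, qual = seq[lo:hi], qual[lo:hi]
        changed = (lo, hi) != (0, len(read.seq)) if seq else False

        run = 0
        while run < len(seq) and seq[len(seq) - 1 - run] == "A":
            run += 1
        if run >= polya_min_run:
            seq, qual = seq[: len(seq) - run], qual[: len(qual) - run]
            changed = True
        run = 0
        while run < len(seq) and seq[run] == "T":
            run += 1
        if run >= polya_min_run:
            seq, qual = seq[run:], qual[run:]
            changed = True
        if not seq:
            return None
        if not changed:
            break
        read = SequenceRecord(read.id, seq, qual, read.meta)
    if seq == read.seq:
        return read
    return SequenceRecord(read.id, seq, qual, read.meta)


def filter_length(
    reads: Iterable[SequenceRecord], min_length: int = 50
) -> list[SequenceRecord]:
    return [r for r in reads if len(r) >= min_length]


def run_filters(
    reads: Sequence[SequenceRecord],
    rrna_refs: Sequence[SequenceRecord | str],
    config: FilterConfig | None = None,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Apply the full cascade: rRNA -> adapter -> edge trim -> length."""
    config = config or FilterConfig()
    report = FilterReport(input=len(reads))

    mrna, rrna, n_short = screen_rrna(
        reads, rrna_refs, k=config.rrna_k, fraction=config.rrna_kmer_fraction
    )
    report.removed_rrna = len(rrna)
    report.too_short_for_rrna_screen = n_short

    kept, report.removed_adapter = handle_adapters(mrna, config)

    trimmed: list[SequenceRecord] = []
    for read in kept:
        out = trim_edges(read, config.qual_threshold, config.polya_min_run)
        if out is None:
            report.removed_short += 1  # trimmed to nothing
            continue
        if out.seq != read.seq:
            report.trimmed += 1
        trimmed.append(out)

    passed = []
    for read in trimmed:
        if len(read) >= config.min_length:
            passed.append(read)
        else:
            report.removed_short += 1
    report.passed = len(passed)
    report.check()
    return passed, report
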