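"""Readers and writers for the on-disk formats used throughout the pipeline.

FASTA and FASTQ (phred+33) parsing is delegated to Biopython's low-level
iterators; this module adds the validation and the header-token metadata
convention used by the simulator (``key=value`` tokens after the record id).
All on-disk coordinates are 1-based inclusive (GFF3 convention); in-memory
coordinates are 0-based half-open and converted at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FormatError(ValueError):
    """A malformed record in an input file."""


@dataclass
class SequenceRecord:
    """A sequence with optional per-base phred qualities and metadata.

    ``meta`` carries free-form string labels; the simulator uses it for
    per-read truth (organism, molecule class, source gene).
    """

    id: str
    seq: str
    qual: list[int] | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FeatureRow:
    """One annotated interval on a sequence, GFF3-style.

    ``start``/``end`` are 1-based inclusive, matching the on-disk format.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    frame: int = 0
    ftype: str = "CDS"
    attrs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature on {self.seq_id}: need 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"invalid frame {self.frame!r}")


_META_TOKEN = re.compile(r"^(\w+)=(\S*)$")


def _parse_description(title: str) -> tuple[str, dict[str, str]]:
    parts = title.split()
    rec_id = parts[0] if parts else ""
    meta: dict[str, str] = {}
    for tok in parts[1:]:
        m = _META_TOKEN.match(tok)
        if m:
            meta[m.group(1)] = m.group(2)
    return rec_id, meta


def _format_description(rec: SequenceRecord) -> str:
    if not rec.meta:
        return rec.id
    toks = " ".join(f"{k}={v}" for k, v in sorted(rec.meta.items()))
    return f"{rec.id} {toks}"


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream phred+33 FASTQ records, validating each one.

    Raises :class:`FormatError` naming the 1-based record index on a
    length mismatch or a truncated file.
    """
    n = 0
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"malformed FASTQ record {n + 1}: {exc}") from exc
            n += 1
            rec_id, meta = _parse_description(title)
            if len(seq) != len(qual):
                raise FormatError(
                    f"malformed FASTQ record {n}: sequence/quality length mismatch"
                )
            try:
                yield SequenceRecord(
                    rec_id, seq, [ord(c) - 33 for c in qual], meta
                )
            except ValueError as exc:
                raise FormatError(f"malformed FASTQ record {n}: {exc}") from exc


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(q + 33) for q in rec.qual)
            out.write(f"@{_format_description(rec)}\n{rec.seq}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream FASTA records; multi-line sequences are concatenated."""
    n = 0
    with open(path) as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError("sequence data before first '>' header")
                break
        handle.seek(0)
        it = SimpleFastaParser(handle)
        while True:
            try:
                title, seq = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"malformed FASTA record {n + 1}: {exc}") from exc
            n += 1
            rec_id, meta = _parse_description(title)
            try:
                yield SequenceRecord(rec_id, seq, None, meta)
            except ValueError as exc:
                raise FormatError(f"malformed FASTA record {n}: {exc}") from exc


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, wrap: int = 80
) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{_format_description(rec)}\n")
            for i in range(0, len(rec.seq), wrap):
                out.write(rec.seq[i : i + wrap] + "\n")


def _esc(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(
    features: Iterable[FeatureRow], path: str | Path, source: str = "metatx"
) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={_esc(v)}" for k, v in f.attrs.items())
            out.write(
                "\t".join(
                    [
                        f.seq_id,
                        source,
                        f.ftype,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        str(f.frame),
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[FeatureRow]:
    """Permissive GFF3 reader (used for round-tripping our own output)."""
    rows: list[FeatureRow] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"GFF3 line with {len(cols)} columns: {line!r}")
            attrs: dict[str, str] = {}
            if cols[8] != ".":
                for item in cols[8].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k] = (
                            v.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")
                        )
            rows.append(
                FeatureRow(
                    seq_id=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    frame=0 if cols[7] == "." else int(cols[7]),
                    ftype=cols[2],
                    attrs=attrs,
                )
            )
    return rows


def read_taxonomy(nodes_path: str | Path, names_path: str | Path):
    """Load a taxonomy tree from two NCBI-dump-like TSVs.

    ``nodes`` columns: taxid, parent_taxid, rank; ``names`` columns:
    taxid, name. Exactly one root (parent == self) is required.
    """
    from .taxonomy import TaxonomyTree

    return TaxonomyTree.from_files(nodes_path, names_path)
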