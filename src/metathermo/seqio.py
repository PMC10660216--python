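"""Reading, writing and filtering of FASTA/FASTQ sequence records.

Streams :class:`SequenceRecord` objects from plain or gzip-compressed
FASTA/FASTQ files (format sniffed when requested), applies the read-level
quality filters used upstream of temperature prediction (minimum length,
maximum ambiguous-base count), and supports exclusion of reads by
identifier — the contract by which externally host-depleted read sets
(e.g. "keep only reads unmapped to a host/gut catalogue") are consumed.

Parsing is delegated to Biopython's low-level FASTA/FASTQ iterators;
this module adds gzip sniffing, sequence normalization and error context.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "FilterStats",
    "ParseError",
    "read_sequences",
    "write_sequences",
    "quality_filter",
    "exclude_by_id",
    "read_id_list",
]

# Uppercase normalization: A/C/G/T kept, every other IUPAC nucleotide
# code (and anything else) becomes N, so downstream ambiguity handling
# has a single currency.
_NORMALIZE = str.maketrans(
    "acgtnRYSWKMBDHVryswkmbdhvUu.-",
    "ACGTNNNNNNNNNNNNNNNNNNNNNTTNN",
)
_VALID = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed sequence file; carries record index and file offset."""

    def __init__(self, message: str, record_index: int, offset: int | None = None):
        loc = f"record {record_index}"
        if offset is not None:
            loc += f", file offset ~{offset}"
        super().__init__(f"{message} ({loc})")
        self.record_index = record_index
        self.offset = offset


@dataclass(frozen=True)
class SequenceRecord:
    """One read or contig: id, normalized nucleotide sequence, optional quality.

    ``id`` is the first whitespace-delimited token of the header line.
    ``seq`` is uppercase over {A,C,G,T,N}; qualities are kept verbatim and
    never interpreted numerically.
    """

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_count(self) -> int:
        return self.seq.count("N")


@dataclass
class FilterStats:
    """Bookkeeping for :func:`quality_filter`.

    A record failing both the length and the N-count criterion is tallied
    once, under ``n_fail_len``, so the three tallies partition ``n_in``.
    """

    n_in: int = 0
    n_pass: int = 0
    n_fail_len: int = 0
    n_fail_n: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_in": self.n_in,
            "n_pass": self.n_pass,
            "n_fail_len": self.n_fail_len,
            "n_fail_n": self.n_fail_n,
        }


def _normalize_seq(raw: str) -> str:
    seq = raw.upper().translate(_NORMALIZE)
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        seq = "".join(c if c in _VALID else "N" for c in seq)
        del bad
    return seq


def _open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed text file (gzip detected by magic bytes)."""
    handle = open(path, "rb")
    magic = handle.read(2)
    handle.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=handle))
    return io.TextIOWrapper(handle)


def _sniff_format(handle: IO[str]) -> str:
    first = handle.read(1)
    handle.seek(0)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    if first == "":
        return "empty"
    raise ParseError(
        f"cannot sniff format: file starts with {first!r}, expected '>' or '@'",
        record_index=0,
        offset=0,
    )


def read_sequences(
    path: str | Path, format: str = "auto"
) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file (gzip transparent).

    Parameters
    ----------
    path
        Input file. Gzip compression is detected from magic bytes, not the
        file name.
    format
        ``fasta``, ``fastq`` or ``auto`` (sniff from the first character).

    Yields records in file order. An empty file yields nothing. Malformed
    records raise :class:`ParseError` naming the record index.
    """
    if format not in {"fasta", "fastq", "auto"}:
        raise ValueError(f"unknown format {format!r}")
    with _open_text(path) as handle:
        fmt = _sniff_format(handle) if format == "auto" else format
        if fmt == "empty":
            return
        if fmt == "fasta":
            yield from _iter_fasta(handle)
        else:
            yield from _iter_fastq(handle)


def _iter_fasta(handle: IO[str]) -> Iterator[SequenceRecord]:
    for index, (title, seq) in enumerate(SimpleFastaParser(handle)):
        if not seq:
            raise ParseError(
                f"FASTA record {title.split()[0] if title else '?'!r} has no sequence",
                record_index=index,
                offset=_tell(handle),
            )
        rec_id = title.split()[0] if title.split() else ""
        if not rec_id:
            raise ParseError("FASTA header has no id token", index, _tell(handle))
        yield SequenceRecord(id=rec_id, seq=_normalize_seq(seq))


def _iter_fastq(handle: IO[str]) -> Iterator[SequenceRecord]:
    index = -1
    try:
        for index, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
            if len(seq) != len(qual):
                raise ValueError("sequence and quality lengths differ")
            rec_id = title.split()[0] if title.split() else ""
            if not rec_id:
                raise ParseError("FASTQ header has no id token", index, _tell(handle))
            yield SequenceRecord(id=rec_id, seq=_normalize_seq(seq), qual=qual)
    except ParseError:
        raise
    except ValueError as exc:
        raise ParseError(f"malformed FASTQ: {exc}", index + 1, _tell(handle)) from exc


def _tell(handle: IO[str]) -> int | None:
    try:
        return handle.buffer.raw.tell()  # type: ignore[union-attr]
    except Exception:
        return None


def write_sequences(
    records: Iterable[SequenceRecord], path: str | Path, format: str = "auto"
) -> int:
    """Write records as FASTA or FASTQ; returns the number written.

    With ``format='auto'`` the first record decides: FASTQ if it carries
    qualities, FASTA otherwise. Writing FASTQ requires qualities on every
    record.
    """
    n = 0
    fmt = format
    with open(path, "w") as out:
        for rec in records:
            if fmt == "auto":
                fmt = "fastq" if rec.qual is not None else "fasta"
            if fmt == "fastq":
                if rec.qual is None:
                    raise ValueError(f"record {rec.id!r} has no qualities for FASTQ output")
                out.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
            else:
                out.write(f">{rec.id}\n{rec.seq}\n")
            n += 1
    return n


def quality_filter(
    records: Iterable[SequenceRecord],
    min_len: int = 50,
    max_n: int = 1,
) -> tuple[Iterator[SequenceRecord], FilterStats]:
    """Apply the read-level quality criteria: length and ambiguous-base count.

    A record survives iff ``len(seq) >= min_len`` and the number of N bases
    is ``<= max_n`` (both limits inclusive: defaults admit a 50 bp read and
    a read with exactly one N). Returns a lazy stream of survivors plus a
    :class:`FilterStats` object that is complete once the stream has been
    consumed.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_n < 0:
        raise ValueError("max_n must be >= 0")
    stats = FilterStats()

    def _gen() -> Iterator[SequenceRecord]:
        for rec in records:
            stats.n_in += 1
            if len(rec.seq) < min_len:
                stats.n_fail_len += 1
            elif rec.n_count > max_n:
                stats.n_fail_n += 1
            else:
                stats.n_pass += 1
                yield rec

    return _gen(), stats


def exclude_by_id(
    records: Iterable[SequenceRecord], excluded_ids: frozenset[str] | set[str]
) -> Iterator[SequenceRecord]:
    """Drop records whose id is in ``excluded_ids``, preserving order.

    Consumes the id list produced by an external host/contaminant mapping
    step (the mapping itself is out of scope here).
    """
    for rec in records:
        if rec.id not in excluded_ids:
            yield rec


def read_id_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text exclusion list, one read id per line (gzip ok)."""
    with _open_text(path) as handle:
        return frozenset(line.split()[0] for line in handle if line.strip())
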