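"""Sequence and table I/O for the profiling pipeline.

Reads FASTQ (plain or gzip/bzip2/zip-compressed, detected by magic bytes,
never by extension) and FASTA, and writes the per-level abundance tables.
Quality encoding is fixed to Phred+33 (Illumina GAIIx-era data); Phred+64
detection is deliberately out of scope.
"""

from __future__ import annotations

import bz2
import gzip
import io
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "Read",
    "RefSeq",
    "FastqFormatError",
    "FastaFormatError",
    "open_maybe_compressed",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_profile",
]

_PHRED_OFFSET = 33
_ALPHABET = frozenset("ACGTN")


class FastqFormatError(ValueError):
    """Malformed FASTQ record (record number is included in the message)."""


class FastaFormatError(ValueError):
    """Malformed or inconsistent FASTA input."""


@dataclass(slots=True)
class Read:
    """One sequencing read.

    ``mate`` is 0 for unpaired reads, 1 or 2 for paired-end mates; mates are
    treated as independent reads throughout the pipeline, each contributing
    one count.
    """

    read_id: str
    bases: str
    quals: list[int]
    mate: int = 0

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if self.quals and not all(0 <= q <= 60 for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: Phred scores outside [0, 60]")
        if self.mate not in (0, 1, 2):
            raise ValueError(f"read {self.read_id!r}: mate must be 0, 1 or 2")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(slots=True)
class RefSeq:
    """A reference sequence (viral genome or contaminant reference)."""

    accession: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("reference accession must be non-empty")

    def __len__(self) -> int:
        return len(self.bases)


def open_maybe_compressed(path: str | Path, mode: str = "rt") -> IO:
    """Open ``path``, transparently decompressing gzip, bzip2 or zip.

    The container is detected from magic bytes. For zip archives only the
    first entry is read; a warning is emitted if the archive holds more.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] == b"\x1f\x8b":
        return gzip.open(path, mode)
    if magic[:3] == b"BZh":
        return bz2.open(path, mode)
    if magic[:4] == b"PK\x03\x04":
        zf = zipfile.ZipFile(path)
        names = zf.namelist()
        if not names:
            raise FastqFormatError(f"{path}: empty zip archive")
        if len(names) > 1:
            warnings.warn(
                f"{path}: zip archive has {len(names)} entries; reading only "
                f"the first ({names[0]})",
                stacklevel=2,
            )
        raw = zf.open(names[0])
        return io.TextIOWrapper(raw) if "t" in mode else raw
    return open(path, mode)


def read_fastq(path: str | Path, mate: int = 0) -> Iterator[Read]:
    """Stream reads from a FASTQ file, one per 4-line record, in file order.

    Raises :class:`FastqFormatError` naming the offending record for any
    malformed record (missing '@'/'+' markers, base/quality length mismatch,
    truncated file).
    """
    with open_maybe_compressed(path, "rt") as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header:  # tolerate trailing blank lines
                continue
            record += 1
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"{path}: record {record}: header does not start with '@'"
                )
            bases = fh.readline().rstrip("\n").upper()
            plus = fh.readline().rstrip("\n")
            qline = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise FastqFormatError(
                    f"{path}: record {record}: missing '+' separator line"
                )
            if not bases or not qline:
                raise FastqFormatError(f"{path}: record {record}: truncated record")
            if len(bases) != len(qline):
                raise FastqFormatError(
                    f"{path}: record {record}: {len(bases)} bases but "
                    f"{len(qline)} quality characters"
                )
            if not _ALPHABET.issuperset(bases):
                bad = sorted(set(bases) - _ALPHABET)
                raise FastqFormatError(
                    f"{path}: record {record}: invalid base(s) {bad}"
                )
            quals = [ord(c) - _PHRED_OFFSET for c in qline]
            if any(q < 0 or q > 60 for q in quals):
                raise FastqFormatError(
                    f"{path}: record {record}: Phred+33 score outside [0, 60]"
                )
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            yield Read(read_id=read_id, bases=bases, quals=quals, mate=mate)


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as plain Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "wt") as fh:
        for r in reads:
            qline = "".join(chr(q + _PHRED_OFFSET) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qline}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[RefSeq]:
    """Load a FASTA file as a list of :class:`RefSeq`, input order preserved.

    Accession is the first whitespace-delimited token of the header; bases
    are uppercased. Duplicate accessions and sequence-less headers are fatal.
    """
    refs: list[RefSeq] = []
    seen: set[str] = set()
    with open_maybe_compressed(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            bases = str(rec.seq).upper()
            if not bases:
                raise FastaFormatError(f"{path}: record {rec.id!r} has no sequence")
            if rec.id in seen:
                raise FastaFormatError(f"{path}: duplicate accession {rec.id!r}")
            seen.add(rec.id)
            refs.append(RefSeq(accession=rec.id, bases=bases, description=rec.description))
    if not refs:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return refs


def write_fasta(refs: Iterable[RefSeq], path: str | Path, width: int = 80) -> None:
    with open(path, "wt") as fh:
        for ref in refs:
            header = ref.accession if not ref.description or ref.description == ref.accession else ref.description
            fh.write(f">{header}\n")
            for i in range(0, len(ref.bases), width):
                fh.write(ref.bases[i : i + width] + "\n")


def write_profile(profile, out_dir: str | Path) -> dict[str, Path]:
    """Write one TSV per taxonomic level: columns taxon / read_count /
    relative_abundance, rows sorted by descending count then taxon name,
    abundances printed with 6 decimal places. Returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for level, counts in profile.counts.items():
        rel = profile.rel_abundance.get(level, {})
        path = out_dir / f"{profile.sample_id}_{level}.tsv"
        rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        with open(path, "wt") as fh:
            fh.write("taxon\tread_count\trelative_abundance\n")
            for taxon, count in rows:
                fh.write(f"{taxon}\t{count}\t{rel.get(taxon, 0.0):.6f}\n")
        paths[level] = path
    return paths
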