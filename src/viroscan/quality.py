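"""Quality filtering of candidate viral reads.

Bases of quality 2 or lower are deemed unreliable (Illumina's EAMMS, End
Anchored Max Scoring Segments, convention), so the maximal contiguous run of
such bases is trimmed from each end of the read; reads trimmed below 60 bp
are removed. Trimming is symmetric (both ends), and runs after candidate
screening, before contaminant removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .formats import Read

__all__ = ["TrimParams", "TrimStats", "trim_read", "filter_reads"]


@dataclass(frozen=True)
class TrimParams:
    q_threshold: int = 2  # trim end bases with Phred quality <= this
    min_length: int = 60  # discard reads trimmed below this length

    def __post_init__(self) -> None:
        if self.q_threshold < 0:
            raise ValueError("q_threshold must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class TrimStats:
    input_count: int = 0
    output_count: int = 0
    discarded_count: int = 0
    trimmed_bases: int = 0


def trim_read(read: Read, params: TrimParams = TrimParams()) -> Optional[Read]:
    """Trim low-quality runs off both ends; return None (discard) if the
    surviving read is shorter than ``min_length``.

    The output bases are always a contiguous substring of the input, and the
    operation is idempotent.
    """
    q = params.q_threshold
    quals = read.quals
    n = len(quals)
    start = 0
    while start < n and quals[start] <= q:
        start += 1
    end = n
    while end > start and quals[end - 1] <= q:
        end -= 1
    if end - start < params.min_length:
        return None
    if start == 0 and end == n:
        return read
    return Read(
        read_id=read.read_id,
        bases=read.bases[start:end],
        quals=quals[start:end],
        mate=read.mate,
    )


def filter_reads(
    reads: Iterable[Read], params: TrimParams = TrimParams()
) -> tuple[list[Read], TrimStats]:
    """Apply :func:`trim_read` to a stream; order preserved.

    input_count == output_count + discarded_count always holds.
    """
    stats = TrimStats()
    kept: list[Read] = []
    for read in reads:
        stats.input_count += 1
        trimmed = trim_read(read, params)
        if trimmed is None:
            stats.discarded_count += 1
            stats.trimmed_bases += len(read)
        else:
            stats.trimmed_bases += len(read) - len(trimmed)
            kept.append(trimmed)
    stats.output_count = len(kept)
    return kept, stats
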