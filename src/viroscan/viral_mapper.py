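"""Seed-and-extend read mapping against the hierarchical viral reference.

The same mapper serves both mapping stages of the pipeline: the inclusive
candidate screen run on raw input reads (SCREEN mode, error budget relaxed
x1.5) and the definitive post-filter assignment (ASSIGN mode). Seeds are
canonical 21-mers indexed at every reference offset; each seeded locus is
extended with a banded end-to-end alignment of the read against the implied
reference window, and hits within the error budget (a fraction of read
length, substitutions and indels unit cost) are kept. All hits tied at the
maximum score are returned; ties are broken downstream by smallest
accession, so assignment is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import edlib

from ._kmers import canonical_kmers_oriented, reverse_complement
from .formats import Read, RefSeq
from .taxonomy import TaxonomyTable

__all__ = [
    "MapParams",
    "Hit",
    "ViralIndex",
    "ScreenStats",
    "build_viral_index",
    "map_read",
    "screen_candidates",
    "assign_final",
]

SCREEN = "SCREEN"
ASSIGN = "ASSIGN"


@dataclass(frozen=True)
class MapParams:
    seed_size: int = 21
    max_error_rate: float = 0.1  # fraction of read length
    mode: str = ASSIGN
    screen_relax: float = 1.5  # error-budget multiplier in SCREEN mode
    band: int = 5  # window padding for the extension alignment

    def __post_init__(self) -> None:
        if not 0.0 < self.max_error_rate < 1.0:
            raise ValueError("max_error_rate must be in (0, 1)")
        if self.mode not in (SCREEN, ASSIGN):
            raise ValueError(f"mode must be {SCREEN} or {ASSIGN}")

    def error_budget(self, read_length: int) -> int:
        rate = self.max_error_rate
        if self.mode == SCREEN:
            rate *= self.screen_relax
        return int(rate * read_length)


@dataclass(frozen=True, order=True)
class Hit:
    """One alignment of a read to a reference genome.

    score = aligned (read) length - errors; strand '+' means the read matches
    the forward reference strand.
    """

    accession: str
    ref_start: int
    strand: str
    errors: int
    score: int


@dataclass
class ViralIndex:
    k: int
    seed_map: dict[str, list[tuple[str, int, bool]]]  # kmer -> (acc, offset, fwd)
    refs: dict[str, RefSeq]
    taxonomy: TaxonomyTable


@dataclass
class ScreenStats:
    input_count: int = 0
    candidate_count: int = 0


def build_viral_index(
    refs: list[RefSeq], taxonomy: TaxonomyTable, params: MapParams = MapParams()
) -> ViralIndex:
    """Index canonical seeds at every offset (stride 1) of every genome.

    Every reference accession must be present in the taxonomy table.
    """
    seed_map: dict[str, list[tuple[str, int, bool]]] = {}
    ref_map: dict[str, RefSeq] = {}
    for ref in refs:
        if ref.accession not in taxonomy:
            raise ValueError(
                f"reference {ref.accession!r} missing from taxonomy table"
            )
        if ref.accession in ref_map:
            raise ValueError(f"duplicate reference accession {ref.accession!r}")
        ref_map[ref.accession] = ref
        for pos, kmer, fwd in canonical_kmers_oriented(ref.bases, params.seed_size):
            seed_map.setdefault(kmer, []).append((ref.accession, pos, fwd))
    return ViralIndex(k=params.seed_size, seed_map=seed_map, refs=ref_map,
                      taxonomy=taxonomy)


def _candidate_loci(
    read: Read, index: ViralIndex
) -> Iterator[tuple[str, int, bool]]:
    """Distinct (accession, implied reference start, same-strand) loci seeded
    by the read's k-mers, in deterministic order."""
    L = len(read)
    k = index.k
    seen: set[tuple[str, int, bool]] = set()
    for read_off, kmer, read_fwd in canonical_kmers_oriented(read.bases, k):
        locs = index.seed_map.get(kmer)
        if not locs:
            continue
        for acc, ref_pos, ref_fwd in locs:
            same = read_fwd == ref_fwd
            start = ref_pos - (read_off if same else L - k - read_off)
            key = (acc, start, same)
            if key not in seen:
                seen.add(key)
                yield key


def _extend(
    read_bases: str,
    rc_cache: list[Optional[str]],
    ref: RefSeq,
    start: int,
    same_strand: bool,
    budget: int,
    band: int,
) -> Optional[tuple[int, int]]:
    """Align the read end-to-end inside the padded window; returns
    (errors, ref_start) or None if over budget."""
    L = len(read_bases)
    lo = max(0, start - band)
    hi = min(len(ref.bases), start + L + band)
    if hi - lo < L - budget:
        return None
    if same_strand:
        query = read_bases
    else:
        if rc_cache[0] is None:
            rc_cache[0] = reverse_complement(read_bases)
        query = rc_cache[0]
    res = edlib.align(query, ref.bases[lo:hi], mode="HW", task="locations", k=budget)
    dist = res["editDistance"]
    if dist == -1:
        return None
    return dist, lo + res["locations"][0][0]


def map_read(read: Read, index: ViralIndex, params: MapParams = MapParams()) -> list[Hit]:
    """Best-scoring hits of a read against the viral reference (possibly empty).

    All hits tied at the maximum score are returned, sorted by (accession,
    ref_start, strand) for determinism.
    """
    L = len(read)
    if L < index.k:
        return []
    budget = params.error_budget(L)
    rc_cache: list[Optional[str]] = [None]
    best: dict[tuple[str, int, str], Hit] = {}
    for acc, start, same in _candidate_loci(read, index):
        ext = _extend(read.bases, rc_cache, index.refs[acc], start, same,
                      budget, params.band)
        if ext is None:
            continue
        errors, ref_start = ext
        strand = "+" if same else "-"
        key = (acc, ref_start, strand)
        hit = Hit(accession=acc, ref_start=ref_start, strand=strand,
                  errors=errors, score=L - errors)
        prev = best.get(key)
        if prev is None or hit.score > prev.score:
            best[key] = hit
    if not best:
        return []
    top = max(h.score for h in best.values())
    hits = [h for h in best.values() if h.score == top]
    hits.sort(key=lambda h: (h.accession, h.ref_start, h.strand))
    return hits


def _has_hit(read: Read, index: ViralIndex, params: MapParams) -> bool:
    """Early-exit existence check used by the screen."""
    L = len(read)
    if L < index.k:
        return False
    budget = params.error_budget(L)
    rc_cache: list[Optional[str]] = [None]
    for acc, start, same in _candidate_loci(read, index):
        if _extend(read.bases, rc_cache, index.refs[acc], start, same,
                   budget, params.band) is not None:
            return True
    return False


def screen_candidates(
    reads: Iterable[Read], index: ViralIndex, params: MapParams | None = None
) -> tuple[list[Read], ScreenStats]:
    """First mapping pass: retain exactly the reads with at least one hit.

    Run on raw input reads before any filtering; on metagenomes the candidate
    set is typically a small fraction of the input, which is where the
    pipeline gains its speed.
    """
    if params is None:
        params = MapParams(mode=SCREEN)
    elif params.mode != SCREEN:
        params = MapParams(seed_size=params.seed_size,
                           max_error_rate=params.max_error_rate, mode=SCREEN,
                           screen_relax=params.screen_relax, band=params.band)
    stats = ScreenStats()
    candidates: list[Read] = []
    for read in reads:
        stats.input_count += 1
        if _has_hit(read, index, params):
            candidates.append(read)
    stats.candidate_count = len(candidates)
    return candidates, stats


def assign_final(
    reads: Iterable[Read], index: ViralIndex, params: MapParams | None = None
) -> tuple[dict[str, int], list[tuple[str, Optional[str]]]]:
    """Definitive per-read assignment to one viral genome.

    Each read with at least one hit contributes one count to exactly one
    accession; multi-mapping ties go to the lexicographically smallest
    accession. Returns (accession -> count, per-read assignment list with
    None for unassigned reads).
    """
    if params is None:
        params = MapParams(mode=ASSIGN)
    counts: dict[str, int] = {}
    assignments: list[tuple[str, Optional[str]]] = []
    for read in reads:
        hits = map_read(read, index, params)
        if hits:
            acc = min(h.accession for h in hits)
            counts[acc] = counts.get(acc, 0) + 1
            assignments.append((read.read_id, acc))
        else:
            assignments.append((read.read_id, None))
    return counts, assignments
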