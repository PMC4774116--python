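"""Human and bacterial read removal: a two-stage Best Match Tagger.

Stage 1 screens each read's canonical 18-mers against an index built from the
contaminant references; a read whose k-mer hit fraction reaches
``kmer_fraction`` is tagged immediately, and a read with no hits at all is
clean. Stage 2 resolves the inconclusive middle ground: every matching 18-mer
seeds a banded end-to-end comparison of the read against the implied
reference window, and the read is tagged if any window aligns with at most
``max_errors`` edits (substitutions and indels counted equally).

The same machinery is applied twice in the pipeline, once with the human
references and once with the bacterial references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import edlib

from ._kmers import canonical_kmers_oriented, reverse_complement
from .formats import Read, RefSeq

__all__ = [
    "CONTAMINANT",
    "CLEAN",
    "ContamIndex",
    "TagParams",
    "FilterStats",
    "build_contam_index",
    "tag_read",
    "stage2_verify",
    "filter_contaminants",
    "save_contam_index",
    "load_contam_index",
]

CONTAMINANT = "CONTAMINANT"
CLEAN = "CLEAN"

_K = 18


@dataclass(frozen=True)
class TagParams:
    """Tagger thresholds.

    kmer_fraction: minimum fraction of a read's k-mers that must hit the
        index for the stage-1 fast accept. The default 0.8 tolerates the
        k-mer shadow of one mutation on a 100 bp read while accepting
        near-identical reads without alignment.
    max_errors: stage-2 edit budget (two, per the tagger contract).
    verify_band: padding (bases) around the implied reference window; a
        half-width of 3 suffices for up to two indels.
    """

    kmer_fraction: float = 0.8
    max_errors: int = 2
    verify_band: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.kmer_fraction <= 1.0:
            raise ValueError("kmer_fraction must be in [0, 1]")
        if self.max_errors < 0 or self.verify_band < 0:
            raise ValueError("max_errors and verify_band must be >= 0")


@dataclass
class ContamIndex:
    """Canonical 18-mer index over contaminant references.

    ``kmer_map`` records, for each canonical k-mer, every (reference index,
    offset, forward-is-canonical) occurrence so stage 2 can locate the
    implied window; ``kmer_set`` is the membership view used by stage 1.
    """

    k: int
    kmer_map: dict[str, list[tuple[int, int, bool]]]
    refs: list[RefSeq]

    @property
    def kmer_set(self) -> set[str]:
        return set(self.kmer_map)

    def __len__(self) -> int:
        return len(self.kmer_map)


@dataclass
class FilterStats:
    input_count: int = 0
    tagged_count: int = 0
    output_count: int = 0


def build_contam_index(refs: list[RefSeq], k: int = _K) -> ContamIndex:
    """Index the canonical k-mer of every position of every reference.

    Both strands are covered via canonicalization; windows containing N are
    skipped; references shorter than k are skipped with a warning.
    """
    if not refs:
        raise ValueError("contaminant reference set is empty")
    kmer_map: dict[str, list[tuple[int, int, bool]]] = {}
    kept: list[RefSeq] = []
    for ref in refs:
        if len(ref) < k:
            warnings.warn(
                f"reference {ref.accession!r} shorter than {k} bp; skipped",
                stacklevel=2,
            )
            continue
        idx = len(kept)
        kept.append(ref)
        for pos, kmer, fwd in canonical_kmers_oriented(ref.bases, k):
            kmer_map.setdefault(kmer, []).append((idx, pos, fwd))
    return ContamIndex(k=k, kmer_map=kmer_map, refs=kept)


def _matching_seeds(read: Read, index: ContamIndex) -> tuple[int, list[tuple[int, str, bool]]]:
    """(number of valid k-mers, list of read k-mers present in the index)."""
    kmers = canonical_kmers_oriented(read.bases, index.k)
    hits = [(i, km, fwd) for i, km, fwd in kmers if km in index.kmer_map]
    return len(kmers), hits


def stage2_verify(
    read: Read,
    index: ContamIndex,
    params: TagParams,
    seeds: list[tuple[int, str, bool]] | None = None,
) -> bool:
    """True iff some matching 18-mer extends to a full-read alignment with at
    most ``max_errors`` edits against the implied reference window."""
    if seeds is None:
        _, seeds = _matching_seeds(read, index)
    L = len(read)
    k = index.k
    pad = params.verify_band
    rc_bases: str | None = None
    tried: set[tuple[int, int, bool]] = set()
    for read_off, kmer, read_fwd in seeds:
        for ref_idx, ref_pos, ref_fwd in index.kmer_map[kmer]:
            same_strand = read_fwd == ref_fwd
            if same_strand:
                start = ref_pos - read_off
            else:
                start = ref_pos - (L - k - read_off)
            key = (ref_idx, start, same_strand)
            if key in tried:
                continue
            tried.add(key)
            ref = index.refs[ref_idx].bases
            lo = max(0, start - pad)
            hi = min(len(ref), start + L + pad)
            if hi - lo < L - params.max_errors:
                continue
            if same_strand:
                query = read.bases
            else:
                if rc_bases is None:
                    rc_bases = reverse_complement(read.bases)
                query = rc_bases
            res = edlib.align(query, ref[lo:hi], mode="HW", task="distance",
                              k=params.max_errors)
            if res["editDistance"] != -1:
                return True
    return False


def tag_read(read: Read, index: ContamIndex, params: TagParams = TagParams()) -> str:
    """Classify a read as CONTAMINANT or CLEAN.

    Reads shorter than the word size carry no 18-mers to seed either stage
    and are reported CLEAN (they cannot occur after length filtering).
    """
    if len(read) < index.k:
        return CLEAN
    total, seeds = _matching_seeds(read, index)
    if total == 0:
        return CLEAN
    fraction = len(seeds) / total
    if fraction >= params.kmer_fraction:
        return CONTAMINANT
    if fraction == 0.0:
        return CLEAN
    return CONTAMINANT if stage2_verify(read, index, params, seeds) else CLEAN


def filter_contaminants(
    reads: Iterable[Read], index: ContamIndex, params: TagParams = TagParams()
) -> tuple[list[Read], FilterStats]:
    """Retain reads tagged CLEAN; order preserved; verdicts are per-read and
    independent of the rest of the stream."""
    stats = FilterStats()
    clean: list[Read] = []
    for read in reads:
        stats.input_count += 1
        if tag_read(read, index, params) == CONTAMINANT:
            stats.tagged_count += 1
        else:
            clean.append(read)
    stats.output_count = len(clean)
    return clean, stats


_INDEX_MAGIC = "VIROSCAN-CONTAM-INDEX\t1"


def save_contam_index(index: ContamIndex, path: str | Path) -> None:
    """Serialize to a text sidecar (magic line, k, references, k-mer rows)."""
    with open(path, "wt") as fh:
        fh.write(_INDEX_MAGIC + "\n")
        fh.write(f"k\t{index.k}\n")
        fh.write(f"refs\t{len(index.refs)}\n")
        for ref in index.refs:
            fh.write(f"{ref.accession}\t{ref.bases}\n")
        for kmer in sorted(index.kmer_map):
            locs = ";".join(
                f"{i},{p},{int(f)}" for i, p, f in index.kmer_map[kmer]
            )
            fh.write(f"{kmer}\t{locs}\n")


def load_contam_index(path: str | Path) -> ContamIndex:
    with open(path, "rt") as fh:
        if fh.readline().rstrip("\n") != _INDEX_MAGIC:
            raise ValueError(f"{path}: not a contaminant index file")
        k = int(fh.readline().split("\t")[1])
        n_refs = int(fh.readline().split("\t")[1])
        refs = []
        for _ in range(n_refs):
            acc, bases = fh.readline().rstrip("\n").split("\t")
            refs.append(RefSeq(accession=acc, bases=bases))
        kmer_map: dict[str, list[tuple[int, int, bool]]] = {}
        for line in fh:
            kmer, locs = line.rstrip("\n").split("\t")
            kmer_map[kmer] = [
                (int(a), int(b), bool(int(c)))
                for a, b, c in (loc.split(",") for loc in locs.split(";"))
            ]
    return ContamIndex(k=k, kmer_map=kmer_map, refs=refs)
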