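"""Mock-community simulator: the validation harness's input generator.

Emulates the validation design of profiling benchmarks: 100 bp reads sampled
uniformly (with replacement, both strands equiprobable) from a declared mix
of viral, human and bacterial genomes at given weights. Reads are error-free
by default; a substitution rate and injected low-quality tails are available
to exercise the trimming and robustness paths. Read IDs encode provenance
("accession|start|strand|serial") so every downstream assignment is
auditable, and the ground truth is the *realized* composition — the exact
per-source read counts of the emitted file — not the nominal weights, which
removes multinomial noise from accuracy metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._kmers import reverse_complement
from .formats import Read, RefSeq, write_fastq
from .taxonomy import TaxonomyTable, rollup

__all__ = [
    "MockMember",
    "MockSpec",
    "TruthTable",
    "generate_genome",
    "build_mock",
    "read_provenance",
]

ROLES = ("viral", "bacterial", "human")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DEFAULT_QUAL = 35
_TAIL_QUAL = 2


@dataclass(frozen=True)
class MockMember:
    ref: RefSeq
    role: str  # viral | bacterial | human
    weight: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.weight < 0:
            raise ValueError("member weight must be >= 0")


@dataclass(frozen=True)
class MockSpec:
    """Declarative composition of one simulated metagenome."""

    seed: int
    members: tuple[MockMember, ...]
    total_reads: int
    read_length: int = 100
    substitution_rate: float = 0.0
    low_quality_tail_fraction: float = 0.0
    max_tail_length: int = 50

    def __post_init__(self) -> None:
        if not any(m.role == "viral" and m.weight > 0 for m in self.members):
            raise ValueError("at least one viral member with weight > 0 required")
        if self.total_reads < 1 or self.read_length < 1:
            raise ValueError("total_reads and read_length must be >= 1")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")


@dataclass
class TruthTable:
    """Realized relative abundances among viral reads, per taxonomic level."""

    levels: dict[str, dict[str, float]]
    viral_read_counts: dict[str, int]  # accession -> emitted viral reads

    def __post_init__(self) -> None:
        for level, table in self.levels.items():
            if table:
                total = sum(table.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{level} truth abundances sum to {total}")


def generate_genome(
    length: int, gc: float, seed: int, accession: Optional[str] = None
) -> RefSeq:
    """I.i.d. random genome at the given GC fraction, reproducible from seed."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    acc = accession or f"SYN{seed}_L{length}"
    return RefSeq(accession=acc, bases=arr.tobytes().decode("ascii"))


def read_provenance(read_id: str) -> tuple[str, int, str, int]:
    """Decode 'accession|start|strand|serial' back into its parts."""
    acc, start, strand, serial = read_id.rsplit("|", 3)
    return acc, int(start), strand, int(serial)


def _mutate(bases: str, n_subs: int, rng: np.random.Generator) -> str:
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    # shift each chosen base to a different one of the remaining three
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def build_mock(
    spec: MockSpec,
    taxonomy: TaxonomyTable,
    fastq_path: str | Path | None = None,
) -> tuple[list[Read], TruthTable]:
    """Draw a mock metagenome and its realized ground truth.

    Each read's source genome is drawn by normalized weight, start position
    uniform, strand uniform; qualities are uniform 35 except injected
    quality-2 tails on ``low_quality_tail_fraction`` of reads. The truth
    table is computed from the realized viral read counts and rolled up to
    genus and family through ``taxonomy``. Same seed, same spec: byte-identical
    output.
    """
    L = spec.read_length
    for m in spec.members:
        if len(m.ref) < L:
            raise ValueError(
                f"genome {m.ref.accession!r} shorter than read length {L}"
            )
    rng = np.random.default_rng(spec.seed)
    weights = np.array([m.weight for m in spec.members], dtype=float)
    probs = weights / weights.sum()
    sources = rng.choice(len(spec.members), size=spec.total_reads, p=probs)
    starts = np.empty(spec.total_reads, dtype=np.int64)
    for i, m in enumerate(spec.members):
        mask = sources == i
        starts[mask] = rng.integers(0, len(m.ref) - L + 1, size=int(mask.sum()))
    strands = rng.random(spec.total_reads) < 0.5  # True -> reverse
    tails = (
        rng.random(spec.total_reads) < spec.low_quality_tail_fraction
        if spec.low_quality_tail_fraction > 0
        else np.zeros(spec.total_reads, dtype=bool)
    )

    reads: list[Read] = []
    viral_counts: dict[str, int] = {}
    base_quals = [_DEFAULT_QUAL] * L
    for serial in range(spec.total_reads):
        member = spec.members[sources[serial]]
        start = int(starts[serial])
        bases = member.ref.bases[start : start + L]
        strand = "-" if strands[serial] else "+"
        if strand == "-":
            bases = reverse_complement(bases)
        if spec.substitution_rate > 0:
            n_subs = rng.binomial(L, spec.substitution_rate)
            if n_subs:
                bases = _mutate(bases, n_subs, rng)
        if tails[serial]:
            tail_len = int(rng.integers(1, spec.max_tail_length + 1))
            quals = base_quals[:-tail_len] + [_TAIL_QUAL] * tail_len
        else:
            quals = list(base_quals)
        acc = member.ref.accession
        reads.append(
            Read(
                read_id=f"{acc}|{start}|{strand}|{serial}",
                bases=bases,
                quals=quals,
            )
        )
        if member.role == "viral":
            viral_counts[acc] = viral_counts.get(acc, 0) + 1

    # realized truth: species counts from the emitted viral reads
    species_counts: dict[str, int] = {}
    for acc, n in viral_counts.items():
        sp = taxonomy.species_of(acc)
        species_counts[sp] = species_counts.get(sp, 0) + n
    upper = rollup(species_counts, taxonomy)
    total = sum(species_counts.values())
    levels = {
        "species": {t: c / total for t, c in species_counts.items()},
        "genus": {t: c / total for t, c in upper["genus"].items()},
        "family": {t: c / total for t, c in upper["family"].items()},
    }
    truth = TruthTable(levels=levels, viral_read_counts=viral_counts)

    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    return reads, truth


def write_truth(truth: TruthTable, out_dir: str | Path, prefix: str = "truth") -> None:
    """One TSV per level: taxon, true relative abundance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for level, table in truth.levels.items():
        with open(out_dir / f"{prefix}_{level}.tsv", "wt") as fh:
            fh.write("taxon\trelative_abundance\n")
            for taxon in sorted(table, key=lambda t: (-table[t], t)):
                fh.write(f"{taxon}\t{table[taxon]:.6f}\n")
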