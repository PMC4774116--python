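"""Pipeline orchestration: screen → trim → human filter → bacterial filter →
assign → tabulate.

Candidate screening runs first, on raw reads, because on a metagenome it
shrinks the working set to a small fraction of the input and every later
stage then pays only for candidates. The surviving reads are quality
trimmed, passed twice through the contaminant tagger (human references,
then bacterial), definitively assigned to viral genomes, and the counts are
rolled up the taxonomy and normalized into relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import decontam, quality, viral_mapper
from .decontam import ContamIndex, TagParams
from .formats import Read, read_fasta, read_fastq, write_profile
from .quality import TrimParams
from .taxonomy import TaxonomyTable, load_taxonomy, rollup
from .viral_mapper import MapParams, ViralIndex

__all__ = [
    "AbundanceProfile",
    "PipelineConfig",
    "run_pipeline",
    "profile_reads",
    "normalize",
]

logger = logging.getLogger("viroscan")

STAGES = ("input", "candidates", "post_trim", "post_human", "post_bacterial",
          "assigned")

DATABASE_PRESETS = ("human-DNA", "human-DNA/RNA", "eukaryotic-DNA",
                    "eukaryotic-DNA/RNA", "custom")


def normalize(counts: Mapping[str, int]) -> dict[str, float]:
    """Counts → relative abundances (empty map if the total is zero)."""
    for taxon, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for {taxon!r}")
    total = sum(counts.values())
    if total == 0:
        return {}
    return {taxon: c / total for taxon, c in counts.items()}


@dataclass
class AbundanceProfile:
    """Per-sample viral counts and relative abundances at species, genus and
    family level, with the per-stage read accounting."""

    sample_id: str
    counts: dict[str, dict[str, int]]
    rel_abundance: dict[str, dict[str, float]]
    stage_stats: dict[str, int]
    accession_counts: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    def validate(self) -> None:
        for level, rel in self.rel_abundance.items():
            if rel:
                total = sum(rel.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"{level} relative abundances sum to {total}"
                    )
        ordered = [self.stage_stats[s] for s in STAGES if s in self.stage_stats]
        if any(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("stage read counts must be non-increasing")


@dataclass
class PipelineConfig:
    """Paths and parameters for one run.

    ``database`` names one of the reference presets; every preset, including
    ``custom``, resolves to a user-supplied viral FASTA plus taxonomy TSV
    (no reference snapshots are shipped).
    """

    viral_fasta: str | Path
    taxonomy_tsv: str | Path
    human_fasta: str | Path
    bacterial_fasta: str | Path
    database: str = "custom"
    trim: TrimParams = field(default_factory=TrimParams)
    tag: TagParams = field(default_factory=TagParams)
    mapping: MapParams = field(default_factory=MapParams)
    out_dir: Optional[Path] = None
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.database not in DATABASE_PRESETS:
            raise ValueError(f"unknown database preset {self.database!r}")
        for p in (self.viral_fasta, self.taxonomy_tsv, self.human_fasta,
                  self.bacterial_fasta):
            if not Path(p).exists():
                raise FileNotFoundError(f"reference path does not exist: {p}")


def profile_reads(
    reads: Sequence[Read],
    viral_index: ViralIndex,
    human_index: ContamIndex,
    bacterial_index: ContamIndex,
    trim: TrimParams = TrimParams(),
    tag: TagParams = TagParams(),
    mapping: MapParams = MapParams(),
    sample_id: str = "sample",
) -> AbundanceProfile:
    """Run the profiling stages on an in-memory read set with pre-built
    indexes. This is the pipeline core; :func:`run_pipeline` wraps it with
    file handling."""
    stats: dict[str, int] = {"input": len(reads)}

    candidates, screen_stats = viral_mapper.screen_candidates(
        reads, viral_index, mapping
    )
    stats["candidates"] = screen_stats.candidate_count
    logger.info("stage=screen in=%d out=%d removed=%d", stats["input"],
                stats["candidates"], stats["input"] - stats["candidates"])

    trimmed, trim_stats = quality.filter_reads(candidates, trim)
    stats["post_trim"] = trim_stats.output_count
    logger.info("stage=trim in=%d out=%d discarded=%d trimmed_bases=%d",
                trim_stats.input_count, trim_stats.output_count,
                trim_stats.discarded_count, trim_stats.trimmed_bases)

    no_human, human_stats = decontam.filter_contaminants(trimmed, human_index, tag)
    stats["post_human"] = human_stats.output_count
    logger.info("stage=human_filter in=%d out=%d tagged=%d",
                human_stats.input_count, human_stats.output_count,
                human_stats.tagged_count)

    clean, bact_stats = decontam.filter_contaminants(no_human, bacterial_index, tag)
    stats["post_bacterial"] = bact_stats.output_count
    logger.info("stage=bacterial_filter in=%d out=%d tagged=%d",
                bact_stats.input_count, bact_stats.output_count,
                bact_stats.tagged_count)

    acc_counts, assignments = viral_mapper.assign_final(clean, viral_index, mapping)
    assigned = sum(acc_counts.values())
    stats["assigned"] = assigned
    unassigned = len(clean) - assigned
    logger.info("stage=assign in=%d assigned=%d unassigned=%d",
                len(clean), assigned, unassigned)

    taxonomy = viral_index.taxonomy
    species_counts: dict[str, int] = {}
    for acc, n in acc_counts.items():
        sp = taxonomy.species_of(acc)
        species_counts[sp] = species_counts.get(sp, 0) + n
    upper = rollup(species_counts, taxonomy)
    counts = {"species": species_counts, "genus": upper["genus"],
              "family": upper["family"]}
    rel = {level: normalize(c) for level, c in counts.items()}

    profile = AbundanceProfile(
        sample_id=sample_id,
        counts=counts,
        rel_abundance=rel,
        stage_stats=stats,
        accession_counts=acc_counts,
        unassigned=unassigned,
    )
    profile.validate()
    return profile


def run_pipeline(
    fastq_paths: Sequence[str | Path], config: PipelineConfig
) -> AbundanceProfile:
    """Full file-to-table run: load references, build indexes, stream the
    FASTQ input(s) (paired-end inputs are two parallel files whose mates are
    processed independently), profile, and write the per-level tables plus a
    stage-stats TSV when an output directory is configured."""
    if not fastq_paths:
        raise ValueError("at least one input FASTQ required")

    viral_refs = read_fasta(config.viral_fasta)
    taxonomy = load_taxonomy(config.taxonomy_tsv)
    viral_index = viral_mapper.build_viral_index(viral_refs, taxonomy,
                                                 config.mapping)
    human_index = decontam.build_contam_index(read_fasta(config.human_fasta))
    bact_index = decontam.build_contam_index(read_fasta(config.bacterial_fasta))

    reads: list[Read] = []
    for i, path in enumerate(fastq_paths):
        mate = 0 if len(fastq_paths) == 1 else i + 1
        reads.extend(read_fastq(path, mate=mate))
    if not reads:
        logger.warning("no input reads; producing an empty profile")

    profile = profile_reads(
        reads, viral_index, human_index, bact_index,
        trim=config.trim, tag=config.tag, mapping=config.mapping,
        sample_id=config.sample_id,
    )

    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        write_profile(profile, out_dir)
        with open(out_dir / f"{config.sample_id}_stage_stats.tsv", "wt") as fh:
            fh.write("stage\treads\n")
            for stage in STAGES:
                fh.write(f"{stage}\t{profile.stage_stats[stage]}\n")
    return profile
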