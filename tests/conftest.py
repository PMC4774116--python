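from __future__ import annotations

import numpy as np
import pytest

from viroscan.formats import Read, RefSeq
from viroscan.mocksim import MockMember, MockSpec, build_mock, generate_genome
from viroscan.taxonomy import Lineage, TaxonomyTable
from viroscan import decontam, viral_mapper


def make_read(bases: str, qual: int = 35, read_id: str = "r") -> Read:
    return Read(read_id=read_id, bases=bases, quals=[qual] * len(bases))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_taxonomy() -> TaxonomyTable:
    return TaxonomyTable({
        "NC_001": Lineage("Human herpesvirus 1", "Simplexvirus", "Herpesviridae"),
        "NC_002": Lineage("Human herpesvirus 2", "Simplexvirus", "Herpesviridae"),
        "NC_003": Lineage("BK polyomavirus", "Betapolyomavirus", "Polyomaviridae"),
        "NC_004": Lineage("Human adenovirus 54", "Mastadenovirus", "Adenoviridae"),
    })


@pytest.fixture(scope="session")
def small_viral_refs(small_taxonomy) -> list[RefSeq]:
    return [
        generate_genome(3000, 0.45, seed=1000 + i, accession=acc)
        for i, acc in enumerate(sorted(small_taxonomy.rows))
    ]


@pytest.fixture(scope="session")
def small_viral_index(small_viral_refs, small_taxonomy):
    return viral_mapper.build_viral_index(small_viral_refs, small_taxonomy)


# ---- acceptance-scale resources, shared across the acceptance tests ----

N_SPECIES = 20
N_GENERA = 6
N_FAMILIES = 3


def make_viral_panel(seed: int):
    """20 synthetic viral genomes spread over 6 genera and 3 families."""
    rng = np.random.default_rng(seed)
    refs, rows = [], {}
    for i in range(N_SPECIES):
        length = int(rng.integers(8_000, 25_000))
        acc = f"VIR{i:02d}"
        refs.append(generate_genome(length, 0.45, int(rng.integers(0, 2**31)),
                                    accession=acc))
        rows[acc] = Lineage(f"Virus_{i:02d}", f"Genus_{i % N_GENERA}",
                            f"Family_{i % N_FAMILIES}")
    return refs, TaxonomyTable(rows)


def make_contaminants(seed: int):
    """Synthetic human genome segment and three bacterial genomes
    (scaled-down stand-ins for the real contaminant references)."""
    human = generate_genome(150_000, 0.41, seed, accession="HUMAN1")
    bact = [generate_genome(100_000, 0.5, seed + 1 + i, accession=f"BACT{i}")
            for i in range(3)]
    return human, bact


def mock_members(refs, human, bacteria, viral_total=0.4, human_w=0.25,
                 seed=0):
    """Uneven viral weights (each species >= 1% of viral reads) plus
    contaminant members; non-viral reads are >= 50% of the sample."""
    rng = np.random.default_rng(seed)
    weights = rng.permutation(np.linspace(2.0, 10.0, len(refs)))
    weights = weights / weights.sum() * viral_total
    members = tuple(MockMember(r, "viral", float(w))
                    for r, w in zip(refs, weights))
    members += (MockMember(human, "human", human_w),)
    bact_w = (1.0 - viral_total - human_w) / len(bacteria)
    members += tuple(MockMember(b, "bacterial", bact_w) for b in bacteria)
    return members


@pytest.fixture(scope="session")
def study_panel():
    """Viral panel + contaminants + pre-built indexes, shared by the
    full-pipeline tests."""
    refs, taxonomy = make_viral_panel(20_260_101)
    human, bacteria = make_contaminants(777)
    viral_index = viral_mapper.build_viral_index(refs, taxonomy)
    human_index = decontam.build_contam_index([human])
    bact_index = decontam.build_contam_index(bacteria)
    return {
        "refs": refs,
        "taxonomy": taxonomy,
        "human": human,
        "bacteria": bacteria,
        "viral_index": viral_index,
        "human_index": human_index,
        "bacterial_index": bact_index,
    }
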