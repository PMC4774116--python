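import numpy as np
import pytest

from viroscan._kmers import reverse_complement
from viroscan.formats import RefSeq
from viroscan.mocksim import generate_genome
from viroscan.taxonomy import Lineage, TaxonomyTable
from viroscan.viral_mapper import (
    MapParams,
    SCREEN,
    assign_final,
    build_viral_index,
    map_read,
    screen_candidates,
)

from _oracles import best_edit_distance_batch, best_edit_distance_both_strands
from conftest import make_read, random_seq


def tiny_taxonomy(accessions):
    return TaxonomyTable({
        acc: Lineage(f"sp_{acc}", f"g_{acc}", f"f_{acc}") for acc in accessions
    })


class TestBuildIndex:
    def test_single_21bp_genome_one_seed(self):
        refs = [RefSeq("A", "ACGTACGTACGTACGTACGTA")]
        idx = build_viral_index(refs, tiny_taxonomy(["A"]))
        assert sum(len(v) for v in idx.seed_map.values()) == 1

    def test_seed_position_count(self):
        g = generate_genome(1000, 0.5, seed=5, accession="A")
        idx = build_viral_index([g], tiny_taxonomy(["A"]))
        assert sum(len(v) for v in idx.seed_map.values()) == 980  # 1000-21+1

    def test_reverse_complement_genomes_share_seeds(self):
        seq = random_seq(np.random.default_rng(6), 500)
        refs = [RefSeq("A", seq), RefSeq("B", reverse_complement(seq))]
        idx = build_viral_index(refs, tiny_taxonomy(["A", "B"]))
        for locs in idx.seed_map.values():
            assert {acc for acc, _, _ in locs} == {"A", "B"}

    def test_missing_taxonomy_fatal(self):
        refs = [RefSeq("A", "ACGT" * 10)]
        with pytest.raises(ValueError, match="missing from taxonomy"):
            build_viral_index(refs, tiny_taxonomy(["B"]))


@pytest.fixture(scope="module")
def two_genomes():
    a = generate_genome(4000, 0.45, seed=21, accession="A")
    b = generate_genome(3000, 0.55, seed=22, accession="B")
    return [a, b]


@pytest.fixture(scope="module")
def two_genome_index(two_genomes):
    return build_viral_index(two_genomes, tiny_taxonomy(["A", "B"]))


class TestMapRead:
    def test_exact_copy_single_best_hit(self, two_genomes, two_genome_index):
        read = make_read(two_genomes[0].bases[100:200])
        hits = map_read(read, two_genome_index)
        assert len(hits) == 1
        assert hits[0].accession == "A"
        assert hits[0].ref_start == 100
        assert hits[0].errors == 0
        assert hits[0].strand == "+"

    def test_reverse_strand_hit(self, two_genomes, two_genome_index):
        read = make_read(reverse_complement(two_genomes[1].bases[500:600]))
        hits = map_read(read, two_genome_index)
        assert hits[0].accession == "B"
        assert hits[0].strand == "-"
        assert hits[0].ref_start == 500

    def test_random_read_no_hit(self, two_genome_index):
        read = make_read(random_seq(np.random.default_rng(9), 100))
        assert map_read(read, two_genome_index) == []

    def test_duplicated_segment_gives_tied_hits(self):
        rng = np.random.default_rng(30)
        seg = random_seq(rng, 150)
        a = RefSeq("A", random_seq(rng, 1000) + seg + random_seq(rng, 1000))
        b = RefSeq("B", random_seq(rng, 500) + seg + random_seq(rng, 1500))
        idx = build_viral_index([a, b], tiny_taxonomy(["A", "B"]))
        read = make_read(seg[20:120])
        hits = map_read(read, idx)
        assert {h.accession for h in hits} == {"A", "B"}
        assert len({h.score for h in hits}) == 1


class TestMapperOracle:
    def test_best_scores_match_brute_force_alignment(self, two_genomes,
                                                     two_genome_index):
        """Mapper best scores equal an exhaustive DP over every window of
        every reference, both strands, for planted and random reads."""
        rng = np.random.default_rng(777)
        targets = [g.bases for g in two_genomes]
        params = MapParams()
        queries, metas = [], []
        for i in range(300):
            if i % 3 == 0:  # random read
                queries.append(random_seq(rng, 100))
            else:  # planted with 0-3 substitutions
                g = two_genomes[int(rng.integers(0, 2))]
                s = int(rng.integers(0, len(g.bases) - 100))
                bases = list(g.bases[s:s + 100])
                for p in rng.choice(100, size=int(rng.integers(0, 4)),
                                    replace=False):
                    bases[p] = "ACGT"[("ACGT".index(bases[p]) + 1) % 4]
                bases = "".join(bases)
                if rng.random() < 0.5:
                    bases = reverse_complement(bases)
                queries.append(bases)
        oracle = best_edit_distance_batch(queries, targets)
        budget = params.error_budget(100)
        for q, best in zip(queries, oracle):
            hits = map_read(make_read(q), two_genome_index, params)
            if best <= budget:
                assert hits and hits[0].errors == best
            else:
                assert hits == []

    def test_indel_reads_match_oracle(self, two_genomes, two_genome_index):
        rng = np.random.default_rng(88)
        params = MapParams()
        for _ in range(30):
            g = two_genomes[int(rng.integers(0, 2))]
            s = int(rng.integers(0, len(g.bases) - 110))
            seg = g.bases[s:s + 103]
            # one deletion and one insertion
            d = int(rng.integers(10, 90))
            seg = seg[:d] + seg[d + 1 :]
            ins = int(rng.integers(10, 90))
            seg = seg[:ins] + "A" + seg[ins:]
            read = make_read(seg[:100])
            best = best_edit_distance_both_strands(read.bases,
                                                   [x.bases for x in two_genomes])
            hits = map_read(read, two_genome_index, params)
            assert hits and hits[0].errors == best


class TestScreenAndAssign:
    def test_screen_keeps_only_mappable_reads(self, two_genomes, two_genome_index):
        rng = np.random.default_rng(14)
        viral = [make_read(two_genomes[0].bases[s:s + 100], read_id=f"v{i}")
                 for i, s in enumerate(rng.integers(0, 3900, size=2))]
        noise = [make_read(random_seq(rng, 100), read_id=f"n{i}")
                 for i in range(998)]
        cands, stats = screen_candidates(noise + viral, two_genome_index)
        assert stats.input_count == 1000
        assert {r.read_id for r in cands} == {"v0", "v1"}

    def test_assign_counts_by_source(self, two_genomes, two_genome_index):
        rng = np.random.default_rng(15)
        reads = [make_read(two_genomes[0].bases[s:s + 100])
                 for s in rng.integers(0, 3900, size=30)]
        reads += [make_read(two_genomes[1].bases[s:s + 100])
                  for s in rng.integers(0, 2900, size=70)]
        counts, assignments = assign_final(reads, two_genome_index)
        assert counts == {"A": 30, "B": 70}
        assert len(assignments) == 100

    def test_tie_goes_to_smallest_accession(self):
        rng = np.random.default_rng(31)
        seg = random_seq(rng, 200)
        a = RefSeq("B2", random_seq(rng, 600) + seg)
        b = RefSeq("A9", seg + random_seq(rng, 600))
        idx = build_viral_index([a, b], tiny_taxonomy(["B2", "A9"]))
        counts, assignments = assign_final([make_read(seg[50:150])], idx)
        assert counts == {"A9": 1}

    def test_screen_never_removes_assignable_reads(self, two_genomes,
                                                   two_genome_index):
        """assign(screen(stream)) == assign(stream): the relaxed screen is a
        superset of what final assignment can place."""
        rng = np.random.default_rng(16)
        reads = []
        for i in range(200):
            g = two_genomes[i % 2]
            s = int(rng.integers(0, len(g.bases) - 100))
            bases = list(g.bases[s:s + 100])
            for p in rng.choice(100, size=int(rng.integers(0, 9)), replace=False):
                bases[p] = "ACGT"[("ACGT".index(bases[p]) + 1) % 4]
            reads.append(make_read("".join(bases), read_id=f"r{i}"))
        reads += [make_read(random_seq(rng, 100), read_id=f"x{i}")
                  for i in range(100)]
        direct, _ = assign_final(reads, two_genome_index)
        cands, _ = screen_candidates(reads, two_genome_index)
        screened, _ = assign_final(cands, two_genome_index)
        assert direct == screened

    def test_determinism(self, two_genomes, two_genome_index):
        rng = np.random.default_rng(17)
        reads = [make_read(two_genomes[0].bases[s:s + 100], read_id=f"r{i}")
                 for i, s in enumerate(rng.integers(0, 3900, size=50))]
        out1 = assign_final(list(reads), two_genome_index)
        out2 = assign_final(list(reads), two_genome_index)
        assert out1 == out2
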