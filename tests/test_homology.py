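from collections import Counter

import numpy as np
import pytest

from syntelink.errors import SynteLinkError
from syntelink.homology import (
    SeedPanel,
    SimilarityRecord,
    assign_families,
    builtin_score,
    cscore_filter,
    merge_split_models,
    read_pairwise_scores,
)
from syntelink.simgenome import random_cds

from conftest import make_assignment, make_genome

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


class TestReadPairwiseScores:
    ROW = "{q}\t{s}\t95.0\t200\t10\t0\t1\t200\t1\t200\t1e-50\t{sc}\n"

    def test_score_parsing_dedup_and_self_hits(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text(
            self.ROW.format(q="a", s="b", sc="250.3")
            + self.ROW.format(q="a", s="b", sc="110")
            + self.ROW.format(q="b", s="a", sc="90")
            + self.ROW.format(q="c", s="c", sc="999")
        )
        recs = read_pairwise_scores(p)
        assert recs == [
            SimilarityRecord("a", "b", 250.3),
            SimilarityRecord("b", "a", 90.0),
        ]

    def test_short_row_reports_line_number(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text(self.ROW.format(q="a", s="b", sc="10") + "a\tb\t1\n")
        with pytest.raises(SynteLinkError, match=":2:"):
            read_pairwise_scores(p)


class TestBuiltinScore:
    def test_identical_proteins_share_all_kmers(self, rng):
        seq = random_protein(rng, 100)
        recs = builtin_score({"a": seq}, {"b": seq}, k=4)
        assert recs == [SimilarityRecord("a", "b", 97.0)]

    def test_disjoint_proteins_are_omitted(self):
        recs = builtin_score({"a": "AAAAAAAA"}, {"b": "WWWWWWWW"}, k=4)
        assert recs == []

    def test_matches_brute_force_counter(self, rng):
        prots_a = {f"a{i}": random_protein(rng, int(rng.integers(20, 60))) for i in range(10)}
        prots_b = {f"b{i}": random_protein(rng, int(rng.integers(20, 60))) for i in range(10)}
        recs = {(r.query_id, r.subject_id): r.score
                for r in builtin_score(prots_a, prots_b, k=3)}
        for ga, sa in prots_a.items():
            ca = Counter(sa[i:i + 3] for i in range(len(sa) - 2))
            for gb, sb in prots_b.items():
                cb = Counter(sb[i:i + 3] for i in range(len(sb) - 2))
                expected = sum((ca & cb).values())
                assert recs.get((ga, gb), 0) == expected


class TestCscoreFilter:
    def records(self):
        return [
            SimilarityRecord("a", "b", 100.0),
            SimilarityRecord("a", "c", 60.0),
            SimilarityRecord("c", "d", 80.0),
        ]

    def test_hand_computed_cscores(self):
        # best(a)=100, best(b)=100, best(c)=80, best(d)=80
        kept = {(p.gene_a, p.gene_b): p.c_score for p in cscore_filter(self.records(), 0.7)}
        assert kept[("a", "b")] == 1.0
        assert ("a", "c") not in kept  # 60/100 = 0.6 < 0.7
        assert kept[("c", "d")] == 1.0

    def test_boundary_is_inclusive(self):
        recs = [SimilarityRecord("a", "b", 70.0), SimilarityRecord("a", "x", 100.0),
                SimilarityRecord("b", "y", 100.0)]
        kept = {(p.gene_a, p.gene_b) for p in cscore_filter(recs, 0.7)}
        assert ("a", "b") in kept

    def test_symmetry_of_directions(self):
        recs = [SimilarityRecord("a", "b", 80.0), SimilarityRecord("b", "a", 80.0),
                SimilarityRecord("a", "x", 100.0)]
        pairs = cscore_filter(recs, 0.5)
        assert len([p for p in pairs if {p.gene_a, p.gene_b} == {"a", "b"}]) == 1

    def test_raising_threshold_never_adds_pairs(self, rng):
        recs = [
            SimilarityRecord(f"g{int(i)}", f"g{int(j)}", float(s))
            for i, j, s in zip(rng.integers(0, 15, 80), rng.integers(0, 15, 80),
                               rng.uniform(1, 100, 80))
            if i != j
        ]
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
            kept = {(p.gene_a, p.gene_b) for p in cscore_filter(recs, thr)}
            if prev is not None:
                assert kept <= prev
            prev = kept

    @pytest.mark.parametrize("thr", [0.0, 1.5, -0.2])
    def test_threshold_domain(self, thr):
        with pytest.raises(ValueError):
            cscore_filter(self.records(), thr)


class TestAssignFamilies:
    def panel_and_genome(self, rng):
        genome = make_genome(chrom_sizes=(6,))
        seed_seq = random_protein(rng, 80)
        other_seed = random_protein(rng, 80)
        panel = SeedPanel({"LHY/CCA1": {"seedC": seed_seq}, "PRR5/9": {"seedP": other_seed}})
        proteins = {g.gene_id: random_protein(rng, 60) for g in genome.iter_genes()}
        proteins["chr01_g2"] = seed_seq  # exact copy of the CCA1-clade seed
        genome.proteins.update(proteins)
        return genome, panel

    def test_exact_seed_copy_assigned_at_c_one(self, rng):
        genome, panel = self.panel_and_genome(rng)
        assigns = assign_families(genome, panel, min_c=0.3)
        by_id = {a.gene_id: a for a in assigns}
        assert by_id["chr01_g2"].family == "LHY/CCA1"
        assert by_id["chr01_g2"].c_score == 1.0

    def test_tie_across_families_is_ambiguous(self, rng):
        genome = make_genome(chrom_sizes=(2,))
        seq = random_protein(rng, 50)
        genome.proteins.update({"chr01_g0": seq, "chr01_g1": random_protein(rng, 50)})
        panel = SeedPanel({"PRR5/9": {"s1": seq}, "PRR3/7": {"s2": seq}})
        assigns = assign_families(genome, panel, min_c=0.3)
        a = next(x for x in assigns if x.gene_id == "chr01_g0")
        assert a.ambiguous

    def test_invariant_to_gene_input_order(self, rng):
        genome, panel = self.panel_and_genome(rng)
        a1 = assign_families(genome, panel)
        reversed_proteins = dict(reversed(list(genome.proteins.items())))
        genome.proteins = reversed_proteins
        a2 = assign_families(genome, panel)
        assert a1 == a2


class TestMergeSplitModels:
    def test_adjacent_same_family_models_merge(self, toy_genome):
        a1 = make_assignment(toy_genome, "chr01_g4", "PRR5/9", c_score=0.9)
        a2 = make_assignment(toy_genome, "chr01_g5", "PRR5/9", c_score=0.8)
        merged = merge_split_models([a1, a2], toy_genome)
        assert len(merged) == 1
        unit = merged[0]
        assert unit.gene_id == "chr01_g4_chr01_g5"
        assert unit.merged_from == ("chr01_g4", "chr01_g5")
        assert (unit.rank, unit.rank_max) == (4, 5)
        assert unit.start == toy_genome.gene("chr01_g4").start
        assert unit.end == toy_genome.gene("chr01_g5").end

    def test_distant_same_family_models_stay_separate(self, toy_genome):
        a1 = make_assignment(toy_genome, "chr01_g0", "PRR5/9")
        a2 = make_assignment(toy_genome, "chr01_g5", "PRR5/9")
        merged = merge_split_models([a1, a2], toy_genome, max_gap_ranks=1)
        assert len(merged) == 2

    def test_transitive_runs_close_like_brute_force(self, toy_genome, rng):
        for _ in range(20):
            ranks = sorted(set(map(int, rng.integers(0, 20, size=6))))
            assigns = [make_assignment(toy_genome, f"chr01_g{r}", "FAM") for r in ranks]
            merged = merge_split_models(assigns, toy_genome, max_gap_ranks=1)
            # brute-force union-find over the adjacency relation
            clusters = []
            for r in ranks:
                for c in clusters:
                    if any(abs(r - x) <= 1 for x in c):
                        c.append(r)
                        break
                else:
                    clusters.append([r])
            assert len(merged) == len(clusters)
            assert sorted(m.rank for m in merged) == sorted(min(c) for c in clusters)

    def test_three_consecutive_models_become_one_unit(self, toy_genome):
        assigns = [make_assignment(toy_genome, f"chr01_g{r}", "PRR5/9") for r in (7, 8, 9)]
        merged = merge_split_models(assigns, toy_genome)
        assert len(merged) == 1
        assert merged[0].merged_from == ("chr01_g7", "chr01_g8", "chr01_g9")


def test_simulated_family_genes_found_by_seed_panel(small_sim):
    """Every truth family member is recovered by homology-based assignment."""
    for sp, genome in small_sim.genomes.items():
        assigns = assign_families(genome, small_sim.seed_panel, min_c=0.3)
        got = {(a.gene_id, a.family) for a in assigns if not a.ambiguous}
        expected = {
            (gid, fam)
            for fam, gids in small_sim.truth.family_members[sp].items()
            for gid in gids
        }
        assert expected <= got


def test_random_cds_scores_do_not_cross_assign(rng):
    """Unrelated random proteins stay below the family C-score floor."""
    from Bio.Seq import Seq

    seeds = {f"F{i}": {f"s{i}": str(Seq(random_cds(rng, 150)).translate())} for i in range(3)}
    panel = SeedPanel(seeds)
    genome = make_genome(chrom_sizes=(5,))
    genome.proteins.update(
        {g.gene_id: str(Seq(random_cds(rng, 150)).translate()) for g in genome.iter_genes()}
    )
    assigns = assign_families(genome, panel, min_c=0.3)
    assert assigns == []
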