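import itertools
import math

import numpy as np
import pytest

from syntelink.errors import DistanceUndefinedError, FamilyError
from syntelink.linkage import (
    CANONICAL_COMBINATIONS,
    classify_combination,
    count_intervening,
    family_copy_table,
    find_linkages,
    permutation_null,
    retention_summary,
)

from conftest import make_assignment, make_genome


class TestCountIntervening:
    def test_arithmetic(self, toy_genome):
        assert count_intervening(toy_genome, "chr01_g10", "chr01_g14") == 3

    def test_adjacent_genes(self, toy_genome):
        assert count_intervening(toy_genome, "chr01_g3", "chr01_g4") == 0

    def test_symmetry(self, toy_genome, rng):
        for _ in range(10):
            i, j = rng.integers(0, 20, size=2)
            a, b = f"chr01_g{i}", f"chr01_g{j}"
            assert count_intervening(toy_genome, a, b) == count_intervening(toy_genome, b, a)

    def test_cross_chromosome_is_undefined(self, toy_genome):
        with pytest.raises(DistanceUndefinedError):
            count_intervening(toy_genome, "chr01_g0", "chr02_g0")


class TestFindLinkages:
    def test_toy_pair_three_genes_apart(self, toy_genome):
        assigns = [
            make_assignment(toy_genome, "chr01_g5", "LHY/CCA1"),
            make_assignment(toy_genome, "chr01_g9", "PRR5/9"),
        ]
        hits = find_linkages(toy_genome, assigns, "LHY/CCA1", "PRR5/9", max_intervening=12)
        assert len(hits) == 1
        h = hits[0]
        assert h.n_intervening == 3
        assert h.combination == "LHY/CCA1-PRR5/9"
        assert h.linkage_class == "LHY/CCA1-PRR5/9"
        assert h.bp_distance == 4000

    def test_bp_mode_spans_megabases_without_gene_cap(self):
        # bryophyte-style: genes far apart in gene ranks but within 12 Mb
        genome = make_genome(chrom_sizes=(200,), spacing=50_000)
        assigns = [
            make_assignment(genome, "chr01_g10", "LHY/CCA1"),
            make_assignment(genome, "chr01_g170", "PRR3/7"),
        ]
        hits = find_linkages(genome, assigns, "LHY/CCA1", "PRR3/7",
                             max_bp=12_000_000)
        assert len(hits) == 1
        assert hits[0].bp_distance == 8_000_000
        assert hits[0].canonical is False

    def test_families_on_different_chromosomes_give_nothing(self, toy_genome):
        assigns = [
            make_assignment(toy_genome, "chr01_g5", "LHY/CCA1"),
            make_assignment(toy_genome, "chr02_g5", "PRR5/9"),
        ]
        assert find_linkages(toy_genome, assigns, "LHY/CCA1", "PRR5/9",
                             max_intervening=12) == []

    def test_thresholds_required(self, toy_genome):
        with pytest.raises(ValueError):
            find_linkages(toy_genome, [], "A", "B")

    def test_merged_unit_members_not_counted_as_intervening(self, toy_genome):
        # merged split model at ranks 5-6; partner at rank 9 -> 2 genes between
        merged = make_assignment(
            toy_genome, "chr01_g5_chr01_g6", "PRR5/9", rank=5, rank_max=6,
            merged_from=("chr01_g5", "chr01_g6"),
        )
        partner = make_assignment(toy_genome, "chr01_g9", "LHY/CCA1")
        hits = find_linkages(toy_genome, [merged, partner], "PRR5/9", "LHY/CCA1",
                             max_intervening=12)
        assert hits[0].n_intervening == 2

    def test_monotone_in_max_intervening(self, toy_genome, rng):
        assigns = []
        for i, r in enumerate(sorted(map(int, rng.choice(20, size=8, replace=False)))):
            assigns.append(make_assignment(toy_genome, f"chr01_g{r}",
                                           "LHY/CCA1" if i % 2 else "PRR5/9"))
        prev = -1
        for cap in (0, 1, 3, 6, 12, 20):
            n = len(find_linkages(toy_genome, assigns, "LHY/CCA1", "PRR5/9",
                                  max_intervening=cap))
            assert n >= prev
            prev = n

    def test_every_cross_pair_reported_once(self, toy_genome):
        assigns = [
            make_assignment(toy_genome, "chr01_g1", "LHY/CCA1"),
            make_assignment(toy_genome, "chr01_g4", "LHY/CCA1"),
            make_assignment(toy_genome, "chr01_g7", "PRR5/9"),
        ]
        hits = find_linkages(toy_genome, assigns, "LHY/CCA1", "PRR5/9",
                             max_intervening=12)
        assert len(hits) == 2
        assert len({(h.gene_a, h.gene_b) for h in hits}) == 2


class TestClassifyCombination:
    def test_the_eight_canonical_combinations(self):
        smyb_prr = [("LHY", "PRR5"), ("LHY", "PRR9"), ("CCA1", "PRR5"), ("CCA1", "PRR9"),
                    ("RVE4", "PRR3"), ("RVE4", "PRR7"), ("RVE8", "PRR3"), ("RVE8", "PRR7")]
        labels = set()
        for a, b in smyb_prr:
            c = classify_combination(b, a)  # order-insensitive, sMYB first
            assert c.canonical
            assert c.label == f"{a}-{b}"
            labels.add(c.label)
        assert labels == set(CANONICAL_COMBINATIONS)

    def test_clade_level_pairs_are_classified_but_not_canonical(self):
        c = classify_combination("PRR5/9", "LHY/CCA1")
        assert c.label == "LHY/CCA1-PRR5/9"
        assert c.linkage_class == "LHY/CCA1-PRR5/9"
        assert not c.canonical

    def test_cross_clade_pair_flagged_non_canonical(self):
        # the bryophyte-style LHY/CCA1 with PRR3/7 combination
        c = classify_combination("LHY/CCA1", "PRR3/7")
        assert not c.canonical
        assert c.linkage_class == "other"
        assert c.label == "LHY/CCA1-PRR3/7"

    def test_pif_phya_pair(self):
        c = classify_combination("PHYA", "PIF3")
        assert c.label == "PIF3-PHYA"
        assert c.linkage_class == "PIF3-PHYA"
        assert c.canonical

    def test_unknown_label_raises_in_strict_mode(self):
        with pytest.raises(FamilyError):
            classify_combination("LHY", "NOT_A_FAMILY")
        c = classify_combination("FAM_X", "FAM_A", strict=False)
        assert c.label == "FAM_A-FAM_X"


class TestFamilyCopyTable:
    def test_counts_and_absences(self, toy_genome):
        assigns = {
            "sp1": [
                make_assignment(toy_genome, "chr01_g1", "LHY/CCA1"),
                make_assignment(toy_genome, "chr02_g1", "LHY/CCA1"),
                make_assignment(toy_genome, "chr01_g9", "PRR5/9"),
            ],
            "sp2": [make_assignment(toy_genome, "chr01_g4", "PRR5/9")],
        }
        counts, locations = family_copy_table(assigns)
        assert counts.loc["sp1", "LHY/CCA1"] == 2
        assert counts.loc["sp2", "LHY/CCA1"] == 0  # PAV candidate
        assert counts.loc["sp2", "PRR5/9"] == 1
        assert len(locations) == 4

    def test_simulated_clade_counts_equal_truth(self, small_sim):
        from syntelink.simgenome import assignments_from_truth

        assigns = {
            sp: assignments_from_truth(g, small_sim.truth.family_members[sp])
            for sp, g in small_sim.genomes.items()
        }
        counts, _ = family_copy_table(assigns)
        for sp in small_sim.genomes:
            for fam, gids in small_sim.truth.family_members[sp].items():
                assert counts.loc[sp, fam] == len(gids)


class TestRetentionSummary:
    def hit(self, sp, cls, chrom="c1"):
        from syntelink.linkage import LinkageHit

        return LinkageHit(sp, chrom, "x", "y", "f", "g", 1, 100, cls,
                          linkage_class=cls)

    def test_half_of_species_with_hits(self):
        hits = {
            "sp1": [self.hit("sp1", "LHY/CCA1-PRR5/9")],
            "sp2": [],
            "sp3": [self.hit("sp3", "RVE4/8-PRR3/7")],
            "sp4": [],
        }
        s = retention_summary(hits)
        assert s.has_at_least_one == 0.5
        assert s.has_both == 0.0

    def test_species_with_both_classes_counts_once(self):
        hits = {
            "sp1": [self.hit("sp1", "LHY/CCA1-PRR5/9"),
                    self.hit("sp1", "RVE4/8-PRR3/7")],
            "sp2": [],
        }
        s = retention_summary(hits)
        assert s.has_at_least_one == 0.5
        assert s.has_both == 0.5
        assert s.has_more_than_one == 0.0

    def test_random_tables_match_independent_recount(self, rng):
        classes = ("LHY/CCA1-PRR5/9", "RVE4/8-PRR3/7")
        for _ in range(20):
            n_sp = int(rng.integers(2, 8))
            hits = {}
            for i in range(n_sp):
                k = int(rng.integers(0, 5))
                hits[f"s{i}"] = [self.hit(f"s{i}", classes[int(rng.integers(2))])
                                 for _ in range(k)]
            s = retention_summary(hits, classes)
            # independent recount
            per = {
                sp: [sum(1 for h in hs if h.linkage_class == c) for c in classes]
                for sp, hs in hits.items()
            }
            assert s.has_at_least_one == round(
                sum(any(v) for v in per.values()) / n_sp, 4)
            assert s.has_both == round(
                sum(all(x >= 1 for x in v) for v in per.values()) / n_sp, 4)
            assert s.has_more_than_one == round(
                sum(any(x > 1 for x in v) for v in per.values()) / n_sp, 4)

    def test_empty_species_set_rejected(self):
        with pytest.raises(ValueError):
            retention_summary({})


class TestPermutationNull:
    def test_two_gene_genome_degenerates_to_p_one(self):
        g = make_genome(chrom_sizes=(2,))
        assigns = [make_assignment(g, "chr01_g0", "A"),
                   make_assignment(g, "chr01_g1", "B")]
        res = permutation_null(g, assigns, "A", "B", n_perm=200, seed=1)
        assert res.p_value == 1.0
        assert res.observed_min_distance == 0

    def test_determinism_under_seed(self, toy_genome):
        assigns = [make_assignment(toy_genome, "chr01_g2", "A"),
                   make_assignment(toy_genome, "chr01_g11", "B")]
        r1 = permutation_null(toy_genome, assigns, "A", "B", n_perm=300, seed=42)
        r2 = permutation_null(toy_genome, assigns, "A", "B", n_perm=300, seed=42)
        assert r1 == r2

    def test_absent_family_raises(self, toy_genome):
        assigns = [make_assignment(toy_genome, "chr01_g2", "A")]
        with pytest.raises(FamilyError, match="B"):
            permutation_null(toy_genome, assigns, "A", "B", n_perm=100)

    def test_sampled_p_within_three_se_of_exact_enumeration(self):
        """6-gene single-chromosome toy genome: compare with the exhaustive
        p over all slot arrangements."""
        g = make_genome(chrom_sizes=(6,))
        assigns = [make_assignment(g, "chr01_g0", "A"),
                   make_assignment(g, "chr01_g3", "B")]
        res = permutation_null(g, assigns, "A", "B", n_perm=4000, seed=5)
        observed = 2  # ranks 0 and 3
        n_le = sum(
            1 for r1, r2 in itertools.permutations(range(6), 2)
            if abs(r1 - r2) - 1 <= observed
        )
        exact = n_le / (6 * 5)
        se = math.sqrt(exact * (1 - exact) / res.n_perm)
        assert abs(res.p_value - exact) <= 3 * se

    def test_infinite_observed_distance_compares_above_finite(self):
        g = make_genome(chrom_sizes=(10, 10))
        assigns = [make_assignment(g, "chr01_g2", "A"),
                   make_assignment(g, "chr02_g2", "B")]
        res = permutation_null(g, assigns, "A", "B", n_perm=200, seed=0)
        assert res.observed_min_distance == math.inf
        assert res.p_value == 1.0
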