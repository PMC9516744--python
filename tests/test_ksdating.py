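import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from syntelink._codons import GENETIC_CODE, STOP_CODONS, SENSE_CODONS
from syntelink.errors import SynteLinkError, TranslationError
from syntelink.ksdating import (
    WgdBin,
    block_ks,
    codon_align,
    load_bins,
    ng86,
    pair_ks,
)
from syntelink.simgenome import evolve_sequences, random_cds


def translate(cds):
    return str(Seq(cds).translate())


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def gotoh_score(a, b, matrix, gap_open, gap_extend):
    """Quadratic-space affine-gap global alignment score (Gotoh), written
    independently of Biopython's aligner."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (moving along a)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def oracle_ng86(codons_a, codons_b):
    """Brute-force NG86: explicit per-site mutation enumeration for potential
    sites and explicit path lists for observed differences."""
    S = N = sd = nd = 0.0
    used = 0
    for ca, cb in zip(codons_a, codons_b):
        paths = []
        diff = [i for i in range(3) if ca[i] != cb[i]]
        for order in itertools.permutations(diff):
            steps = []
            cur = ca
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                steps.append((cur, nxt))
                cur = nxt
            if any(y in STOP_CODONS for _, y in steps):
                continue
            paths.append(steps)
        if diff and not paths:
            continue  # fully blocked codon
        used += 1
        for codon in (ca, cb):
            syn = 0.0
            for pos in range(3):
                for nt in "ACGT":
                    if nt == codon[pos]:
                        continue
                    alt = codon[:pos] + nt + codon[pos + 1:]
                    if alt not in STOP_CODONS and GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                        syn += 1 / 3
            S += syn / 2
            N += (3 - syn) / 2
        if paths:
            s_tot = n_tot = 0.0
            for steps in paths:
                for x, y in steps:
                    if GENETIC_CODE[x] == GENETIC_CODE[y]:
                        s_tot += 1
                    else:
                        n_tot += 1
            sd += s_tot / len(paths)
            nd += n_tot / len(paths)
    ps, pn = sd / S, nd / N
    ks = None if ps >= 0.75 else -0.75 * math.log(1 - 4 * ps / 3)
    ka = None if pn >= 0.75 else -0.75 * math.log(1 - 4 * pn / 3)
    return S, N, ks, ka, used


def random_codon_pairs(rng, n_codons, n_mut):
    """A sense-codon sequence and a mutated copy (stop codons rejected)."""
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    other = list(codons)
    for _ in range(n_mut):
        while True:
            i = int(rng.integers(n_codons))
            p = int(rng.integers(3))
            nt = "ACGT"[int(rng.integers(4))]
            alt = other[i][:p] + nt + other[i][p + 1:]
            if alt not in STOP_CODONS:
                other[i] = alt
                break
    return "".join(codons), "".join(other)


class TestCodonAlign:
    def test_identical_sequences_have_no_gap_columns(self, rng):
        cds = random_cds(rng, 50)
        aln = codon_align(translate(cds), translate(cds), cds, cds)
        assert aln.n_ungapped == 50
        assert len(aln.columns) == 50

    def test_internal_deletion_produces_matching_gap_columns(self, rng):
        cds = random_cds(rng, 60)
        deleted = cds[:30] + cds[45:]  # drop codons 10..14
        aln = codon_align(translate(cds), translate(deleted), cds, deleted)
        gaps = sum(1 for ca, cb in aln.columns if ca is None or cb is None)
        assert gaps == 5
        assert aln.n_ungapped == 55

    def test_translation_mismatch_is_rejected(self, rng):
        cds = random_cds(rng, 30)
        with pytest.raises(TranslationError):
            codon_align("M" * 30, translate(cds), cds, cds)

    def test_score_matches_independent_gotoh_aligner(self, rng):
        matrix = substitution_matrices.load("BLOSUM62")
        for _ in range(20):
            a = random_cds(rng, int(rng.integers(20, 50)))
            b = evolve_sequences(a, 0.6, 0.5, rng)
            if rng.random() < 0.5:  # occasionally force an indel
                cut = int(rng.integers(3, len(b) // 3)) * 3
                b = b[:cut - 3] + b[cut:]
            pa, pb = translate(a), translate(b)
            aln = codon_align(pa, pb, a, b)
            assert aln.score == pytest.approx(
                gotoh_score(pa, pb, matrix, -10.0, -0.5))


class TestNg86:
    def test_identical_sequences_give_zero_rates(self, rng):
        cds = random_cds(rng, 40)
        est = ng86(codon_align(translate(cds), translate(cds), cds, cds))
        assert est.ks == 0.0 and est.ka == 0.0 and not est.saturated

    def test_single_synonymous_difference_at_fourfold_site(self):
        # GGT -> GGC (Gly, 4-fold degenerate third position)
        a = "ATGGGT" + "GAAGAT" * 4
        b = "ATGGGC" + "GAAGAT" * 4
        est = ng86(codon_align(translate(a), translate(b), a, b))
        S, N, ks, ka, _ = oracle_ng86(
            [a[i:i + 3] for i in range(0, len(a), 3)],
            [b[i:i + 3] for i in range(0, len(b), 3)],
        )
        assert est.s_sites == pytest.approx(S, abs=1e-12)
        assert est.ks == pytest.approx(ks, abs=1e-9)
        assert est.ka == pytest.approx(ka, abs=1e-9)

    def test_matches_path_enumeration_oracle_on_random_pairs(self, rng):
        for _ in range(40):
            n = int(rng.integers(10, 50))
            a, b = random_codon_pairs(rng, n, int(rng.integers(0, 2 * n)))
            aln = codon_align(translate(a), translate(b), a, b)
            est = ng86(aln)
            S, N, ks, ka, used = oracle_ng86(
                [a[i:i + 3] for i in range(0, len(a), 3)],
                [b[i:i + 3] for i in range(0, len(b), 3)],
            )
            assert est.s_sites == pytest.approx(S, abs=1e-9)
            assert est.n_sites == pytest.approx(N, abs=1e-9)
            assert est.n_codons == used
            if ks is None:
                assert est.saturated
            else:
                assert est.ks == pytest.approx(ks, abs=1e-9)

    def test_site_conservation_and_symmetry(self, rng):
        for _ in range(10):
            a, b = random_codon_pairs(rng, 30, 25)
            e1 = ng86(codon_align(translate(a), translate(b), a, b))
            e2 = ng86(codon_align(translate(b), translate(a), b, a))
            assert e1.s_sites + e1.n_sites == pytest.approx(3 * e1.n_codons, abs=1e-9)
            assert e1.ks == pytest.approx(e2.ks, abs=1e-12)
            assert e1.ka == pytest.approx(e2.ka, abs=1e-12)

    def test_saturation_flag(self):
        # serine codons TCA vs AGT: every position differs
        a = "TCA" * 20
        b = "AGT" * 20
        est = ng86(codon_align(translate(a), translate(b), a, b))
        assert est.saturated and est.ks is None

    def test_minimum_codon_requirement(self, rng):
        cds = random_cds(rng, 5)
        with pytest.raises(SynteLinkError, match="usable codon"):
            ng86(codon_align(translate(cds), translate(cds), cds, cds))


class TestBlockKs:
    def _blockish(self, anchors):
        class B:
            block_id = "blk0000"
        B.anchors = anchors
        return B

    def test_median_and_bin_assignment(self, small_sim):
        bins = [WgdBin("recent", 0.05, 0.9), WgdBin("ancient", 0.9, 3.0)]
        gA = small_sim.genomes["speciesA"]
        gB = small_sim.genomes["speciesB"]
        truth_pairs = small_sim.truth.ortholog_pairs[("speciesA", "speciesB")][:6]

        from syntelink.synteny import Anchor

        anchors = [Anchor(a, b, "x", "y", 0, 0, 1.0) for a, b in truth_pairs]
        bk = block_ks(self._blockish(anchors), gA, gB, bins)
        # two branches of 0.15 each -> expected pairwise Ks ~ 0.3
        assert bk.bin_label == "recent"
        assert 0.05 < bk.ks < 0.9
        assert bk.n_anchors_used >= 3

    def test_too_few_anchors_stays_unlabeled(self, small_sim):
        gA = small_sim.genomes["speciesA"]
        gB = small_sim.genomes["speciesB"]
        pair = small_sim.truth.ortholog_pairs[("speciesA", "speciesB")][0]
        from syntelink.synteny import Anchor

        anchors = [Anchor(pair[0], pair[1], "x", "y", 0, 0, 1.0)] * 2
        bk = block_ks(self._blockish(anchors), gA, gB, [])
        assert bk.ks is None and bk.bin_label is None
        assert "usable anchors" in bk.reason

    def test_bins_config_round_trip_and_overlap_check(self, tmp_path):
        p = tmp_path / "bins.tsv"
        p.write_text("recent\t0.0\t0.5\t13\nold\t0.5\t2.0\t59\n")
        bins = load_bins(p)
        assert [b.label for b in bins] == ["recent", "old"]
        assert bins[0].age_mya == 13
        p.write_text("a\t0.0\t0.6\nb\t0.5\t2.0\n")
        with pytest.raises(SynteLinkError, match="overlap"):
            load_bins(p)


def test_two_wgd_clade_blocks_date_to_their_events():
    """Self-syntenic blocks of a two-WGD genome are binned to the correct
    polyploidy event for >= 90% of labeled blocks."""
    from syntelink.homology import builtin_score, cscore_filter
    from syntelink.simgenome import Diverge, Lineage, SimConfig, Wgd, simulate
    from syntelink.synteny import self_synteny

    cfg = SimConfig(
        n_genes=80,
        n_chromosomes=2,
        tree=Lineage("sp", events=(
            Wgd(2, "wgd_old"), Diverge(0.35, 0.2), Wgd(2, "wgd_recent"),
            Diverge(0.08, 0.2),
        )),
        codons_min=200, codons_max=300,
        seed=5,
    )
    res = simulate(cfg)
    genome = res.genomes["sp"]
    # a relaxed C-score keeps the older, more diverged paralog pairs
    pairs = cscore_filter(builtin_score(genome.proteins, genome.proteins), 0.4)
    blocks = self_synteny(genome, pairs)
    assert blocks

    event_of_pair = {
        frozenset((a, b)): label for a, b, label in res.truth.paralog_pairs["sp"]
    }
    # expected pairwise Ks: recent pairs ~2*0.08=0.16, old pairs ~2*(0.35+0.08)=0.86
    bins = [WgdBin("wgd_recent", 0.0, 0.45), WgdBin("wgd_old", 0.45, 2.5)]
    n_labeled = n_correct = 0
    for b in blocks:
        events = [event_of_pair.get(frozenset((a.gene_a, a.gene_b)))
                  for a in b.anchors]
        events = [e for e in events if e]
        if not events:
            continue
        true_event = max(set(events), key=events.count)
        bk = block_ks(b, genome, genome, bins)
        if bk.bin_label is None:
            continue
        n_labeled += 1
        n_correct += bk.bin_label == true_event
    assert n_labeled >= 4
    assert n_correct / n_labeled >= 0.9
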