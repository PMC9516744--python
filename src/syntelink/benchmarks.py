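"""Self-evaluation routines: oracle comparisons and simulation recovery.

Each function re-derives one headline property of the package from
scratch — comparing the anchor-chaining DP against exhaustive chain
enumeration, the NG86 estimator against a brute-force path-enumeration
implementation, the permutation null against exact enumeration and a
uniformity check, and the end-to-end pipeline against simulator ground
truth. The oracles here are deliberately written as naive enumerations,
independent of the implementation code paths they check.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from ._codons import GENETIC_CODE, STOP_CODONS
from .homology import builtin_score, cscore_filter
from .ksdating import codon_align, ng86
from .linkage import find_linkages, permutation_null
from .simgenome import (
    Lineage,
    Placement,
    SimConfig,
    assignments_from_truth,
    easy_clade_config,
    evaluate_recovery,
    evolve_sequences,
    random_cds,
    simulate,
)
from .synteny import Anchor, anchors_from_pairs, best_chain, chain_anchors, collapse_tandem

__all__ = [
    "chain_oracle_agreement",
    "ng86_oracle_error",
    "permutation_exactness",
    "permutation_uniformity",
    "easy_regime_recovery",
    "ks_calibration",
]


# ---------------------------------------------------------------------------
# 1. Chaining DP vs exhaustive enumeration
# ---------------------------------------------------------------------------

def _enumerate_best_chain(anchors, max_gap: int) -> float:
    """Exhaustive DFS over every monotone chain respecting the gap rule."""
    n = len(anchors)
    best = 0.0

    def extendable(i, j, sign):
        a, b = anchors[i], anchors[j]
        if b.rank_a <= a.rank_a or b.rank_a - a.rank_a > max_gap:
            return False
        d = (b.rank_b - a.rank_b) * sign
        return 0 < d <= max_gap

    def dfs(last, score, sign):
        nonlocal best
        if score > best:
            best = score
        for j in range(n):
            if extendable(last, j, sign):
                dfs(j, score + anchors[j].score, sign)

    for sign in (1, -1):
        for i in range(n):
            dfs(i, anchors[i].score, sign)
    return best


def chain_oracle_agreement(seed: int = 0, n_sets: int = 500, max_anchors: int = 12) -> dict:
    """Fraction of random anchor sets where the DP chain score equals the
    brute-force maximum over all valid chains."""
    rng = np.random.default_rng([seed, 1])
    agree = 0
    for _ in range(n_sets):
        n = int(rng.integers(1, max_anchors + 1))
        max_gap = int(rng.integers(2, 25))
        seen, anchors = set(), []
        while len(anchors) < n:
            ra, rb = int(rng.integers(25)), int(rng.integers(25))
            if (ra, rb) in seen:
                continue
            seen.add((ra, rb))
            anchors.append(Anchor(f"a{ra}", f"b{rb}", "c1", "c2", ra, rb,
                                  float(rng.integers(1, 50))))
        dp = max(best_chain(anchors, max_gap, "+")[0],
                 best_chain(anchors, max_gap, "-")[0])
        if math.isclose(dp, _enumerate_best_chain(anchors, max_gap)):
            agree += 1
    return {"value": agree / n_sets, "n": n_sets}


# ---------------------------------------------------------------------------
# 2. NG86 vs brute-force path enumeration
# ---------------------------------------------------------------------------

def _oracle_ng86_ks_ka(codons_a, codons_b):
    S = N = sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        diff = [i for i in range(3) if ca[i] != cb[i]]
        paths = []
        for order in itertools.permutations(diff):
            cur, steps, ok = ca, [], True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in STOP_CODONS:
                    ok = False
                    break
                steps.append((cur, nxt))
                cur = nxt
            if ok:
                paths.append(steps)
        if diff and not paths:
            continue
        for codon in (ca, cb):
            syn = sum(
                1 / 3
                for pos in range(3)
                for nt in "ACGT"
                if nt != codon[pos]
                and (alt := codon[:pos] + nt + codon[pos + 1:]) not in STOP_CODONS
                and GENETIC_CODE[alt] == GENETIC_CODE[codon]
            )
            S += syn / 2
            N += (3 - syn) / 2
        if paths:
            sd += sum(
                sum(1 for x, y in p if GENETIC_CODE[x] == GENETIC_CODE[y]) for p in paths
            ) / len(paths)
            nd += sum(
                sum(1 for x, y in p if GENETIC_CODE[x] != GENETIC_CODE[y]) for p in paths
            ) / len(paths)
    ps, pn = sd / S, nd / N
    jc = lambda p: None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(ps), jc(pn)


def ng86_oracle_error(seed: int = 0, n_pairs: int = 100) -> dict:
    """Max |Ks - Ks_oracle| (and Ka) over random 10-50-codon pairs."""
    from .ksdating import CodonAlignment

    rng = np.random.default_rng([seed, 2])
    worst = 0.0
    done = 0
    while done < n_pairs:
        n = int(rng.integers(10, 51))
        a = random_cds(rng, n)
        b = evolve_sequences(a, float(rng.uniform(0.02, 0.8)), float(rng.uniform(0, 1)), rng)
        # pair codons positionally (no indels were simulated) so both
        # routes score exactly the same codon columns
        columns = [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]
        est = ng86(CodonAlignment("a", "b", columns, 0.0), min_codons=5)
        ks_o, ka_o = _oracle_ng86_ks_ka(
            [a[i:i + 3] for i in range(0, len(a), 3)],
            [b[i:i + 3] for i in range(0, len(b), 3)],
        )
        if ks_o is None or ka_o is None or est.saturated:
            assert (ks_o is None) == est.saturated
            continue
        worst = max(worst, abs(est.ks - ks_o), abs(est.ka - ka_o))
        done += 1
    return {"value": worst, "n": n_pairs}


# ---------------------------------------------------------------------------
# 3. Permutation null: exactness and uniformity
# ---------------------------------------------------------------------------

def permutation_exactness(seed: int = 0, n_perm: int = 4000) -> dict:
    """|sampled p - exact p| in standard errors, on a 6-gene toy genome."""
    from .genome_io import GeneModel, GenomeAnnotation
    from .homology import FamilyAssignment

    genes = {"c1": [GeneModel(f"g{i}", "c1", 1 + 1000 * i, 500 + 1000 * i, "+", i)
                    for i in range(6)]}
    genome = GenomeAnnotation("toy", genes)

    def asg(gid, fam):
        g = genome.gene(gid)
        return FamilyAssignment(gid, fam, "s", 1.0, g.chromosome, g.rank,
                                g.rank, g.start, g.end)

    assigns = [asg("g0", "A"), asg("g3", "B")]
    res = permutation_null(genome, assigns, "A", "B", n_perm=n_perm, seed=seed)
    observed = 2
    n_le = sum(1 for r1, r2 in itertools.permutations(range(6), 2)
               if abs(r1 - r2) - 1 <= observed)
    exact = n_le / 30
    se = math.sqrt(exact * (1 - exact) / n_perm)
    return {"value": abs(res.p_value - exact) / se, "n": n_perm, "exact_p": exact,
            "sampled_p": res.p_value}


def _neutral_genome(seed_pair):
    placements = tuple(
        Placement(fam) for fam in ("FAM_A",) * 3 + ("FAM_B",) * 3
    )
    cfg = SimConfig(
        n_genes=400, n_chromosomes=2, tree=Lineage("sp"),
        family_placements=placements, codons_min=30, codons_max=30,
        seed=int(np.random.default_rng(seed_pair).integers(2**31 - 1)),
    )
    return simulate(cfg)


def permutation_uniformity(seed: int = 0, n_genomes: int = 200, n_perm: int = 199) -> dict:
    """KS p-value of the permutation p-values against Uniform(0,1) when
    family placement is itself uniform-random (neutral simulator)."""
    ps = []
    for i in range(n_genomes):
        res = _neutral_genome([seed, 3, i])
        genome = res.genomes["sp"]
        assigns = assignments_from_truth(genome, res.truth.family_members["sp"])
        null = permutation_null(genome, assigns, "FAM_A", "FAM_B",
                                n_perm=n_perm, seed=i)
        ps.append(null.p_value)
    ks = stats.kstest(ps, "uniform")
    return {"value": ks.pvalue, "n": n_genomes, "ks_stat": float(ks.statistic)}


# ---------------------------------------------------------------------------
# 4. End-to-end recovery on the easy simulation regime
# ---------------------------------------------------------------------------

def easy_regime_recovery(seed: int = 0, n_genes: int = 500) -> dict:
    """Block and linkage recall of the full pipeline against simulator
    truth: two species, one shared WGD, loss 0.4, bias 0.7, dS 0.3."""
    res = simulate(easy_clade_config(seed=seed, n_genes=n_genes))
    gA, gB = res.genomes["speciesA"], res.genomes["speciesB"]
    pairs = cscore_filter(builtin_score(gA.proteins, gB.proteins), 0.7)
    anchors = anchors_from_pairs(pairs, gA, gB)
    anchors, _ = collapse_tandem(anchors)
    blocks = chain_anchors(anchors, min_pairs=5, max_gap=20)

    from .homology import assign_families, merge_split_models

    hits = {}
    for sp, genome in res.genomes.items():
        assigns = merge_split_models(
            assign_families(genome, res.seed_panel, min_c=0.3), genome, 1
        )
        sp_hits = []
        for fa, fb in itertools.combinations(sorted(res.seed_panel.labels), 2):
            sp_hits.extend(
                find_linkages(genome, assigns, fa, fb,
                              max_intervening=res.config.linkage_window)
            )
        hits[sp] = sp_hits
    rep = evaluate_recovery(res.truth, {("speciesA", "speciesB"): blocks}, hits)
    return {
        "block_recall": rep.block_recall,
        "linkage_recall": rep.linkage_recall,
        "block_precision": rep.block_precision,
        "anchor_precision": rep.anchor_precision,
        "n_true_blocks": len(res.truth.true_blocks[("speciesA", "speciesB")]),
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# 5. Ks estimator calibration
# ---------------------------------------------------------------------------

def ks_calibration(seed: int = 0, n_pairs: int = 200, n_codons: int = 300,
                   targets=(0.1, 0.5, 1.0), dn_ds: float = 0.2) -> dict:
    """Median NG86 Ks over simulated pairs at each true dS."""
    rng = np.random.default_rng([seed, 4])
    out = {}
    for ds in targets:
        vals = []
        for _ in range(n_pairs):
            parent = random_cds(rng, n_codons)
            child = evolve_sequences(parent, ds, dn_ds, rng)
            est = ng86(codon_align(str(Seq(parent).translate()),
                                   str(Seq(child).translate()), parent, child))
            if not est.saturated:
                vals.append(est.ks)
        out[ds] = {"median": float(np.median(vals)), "n": len(vals)}
    return out
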