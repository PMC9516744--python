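"""Tandem collapsing, anchor chaining, self-synteny, duplicate modes.

Syntenic blocks are chains of homolog anchors found by sparse dynamic
programming over anchors sorted by rank, DAGchainer-style: within a chain
the query ranks increase strictly and the subject ranks are strictly
monotone (increasing for '+' blocks, decreasing for '-'), and consecutive
anchors may be at most ``max_gap`` gene ranks apart on both genomes. The
default acceptance rule — at least five anchor pairs with a 20-gene gap
window — mirrors the defaults of the classic collinearity tools. Blocks
are extracted greedily in order of decreasing chain score; each anchor
belongs to at most one block.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .genome_io import GenomeAnnotation
from .homology import FilteredPair

__all__ = [
    "Anchor",
    "SyntenicBlock",
    "anchors_from_pairs",
    "collapse_tandem",
    "chain_anchors",
    "self_synteny",
    "classify_duplicate_mode",
    "best_chain",
]


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chr_a: str
    chr_b: str
    rank_a: int
    rank_b: int
    score: float


@dataclass
class SyntenicBlock:
    block_id: str
    chr_a: str
    chr_b: str
    orientation: str  # '+' or '-'
    n_anchors: int
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    score: float
    anchors: list[Anchor] = field(repr=False, default_factory=list)

    def gene_ids(self) -> set[str]:
        out = set()
        for a in self.anchors:
            out.add(a.gene_a)
            out.add(a.gene_b)
        return out


def anchors_from_pairs(
    pairs: list[FilteredPair],
    genome_a: GenomeAnnotation,
    genome_b: GenomeAnnotation,
) -> list[Anchor]:
    """Attach rank coordinates to filtered pairs.

    For within-genome use pass the same annotation twice; each unordered
    pair yields one anchor with side a = the lower (chromosome, rank).
    Pairs with a gene missing from either annotation are skipped.
    """
    same = genome_a is genome_b or genome_a.species_id == genome_b.species_id
    out = []
    for p in pairs:
        if same:
            if p.gene_a not in genome_a or p.gene_b not in genome_a:
                continue
            ga, gb = genome_a.gene(p.gene_a), genome_a.gene(p.gene_b)
            if (gb.chromosome, gb.rank) < (ga.chromosome, ga.rank):
                ga, gb = gb, ga
        else:
            if p.gene_a in genome_a and p.gene_b in genome_b:
                ga, gb = genome_a.gene(p.gene_a), genome_b.gene(p.gene_b)
            elif p.gene_b in genome_a and p.gene_a in genome_b:
                ga, gb = genome_a.gene(p.gene_b), genome_b.gene(p.gene_a)
            else:
                continue
        out.append(
            Anchor(ga.gene_id, gb.gene_id, ga.chromosome, gb.chromosome,
                   ga.rank, gb.rank, p.score)
        )
    out.sort(key=lambda a: (a.chr_a, a.chr_b, a.rank_a, a.rank_b))
    return out


def collapse_tandem(
    anchors: list[Anchor],
    max_tandem_gap: int = 5,
) -> tuple[list[Anchor], list[tuple[str, ...]]]:
    """Collapse tandem-array hits to one representative anchor.

    On either side, anchors sharing the same partner gene whose members lie
    within ``max_tandem_gap`` ranks of each other on one chromosome are
    reduced to the highest-scoring member (ties: lowest rank). Returns the
    surviving anchors and the tandem arrays that were collapsed.
    """
    arrays: list[tuple[str, ...]] = []

    def one_side(ancs, key_partner, key_chrom, key_rank, key_gene):
        groups: dict[str, list[Anchor]] = defaultdict(list)
        for a in ancs:
            groups[key_partner(a)].append(a)
        keep = []
        for partner in sorted(groups):
            members = sorted(groups[partner], key=lambda a: (key_chrom(a), key_rank(a)))
            cluster = [members[0]]
            for a in members[1:]:
                prev = cluster[-1]
                if key_chrom(a) == key_chrom(prev) and key_rank(a) - key_rank(prev) <= max_tandem_gap:
                    cluster.append(a)
                else:
                    keep.append(_pick_rep(cluster, key_rank, key_gene, arrays))
                    cluster = [a]
            keep.append(_pick_rep(cluster, key_rank, key_gene, arrays))
        return keep

    step1 = one_side(anchors, lambda a: a.gene_b, lambda a: a.chr_a,
                     lambda a: a.rank_a, lambda a: a.gene_a)
    step2 = one_side(step1, lambda a: a.gene_a, lambda a: a.chr_b,
                     lambda a: a.rank_b, lambda a: a.gene_b)
    step2.sort(key=lambda a: (a.chr_a, a.chr_b, a.rank_a, a.rank_b))
    return step2, arrays


def _pick_rep(cluster, key_rank, key_gene, arrays):
    if len(cluster) > 1:
        arrays.append(tuple(sorted({key_gene(a) for a in cluster})))
    return max(cluster, key=lambda a: (a.score, -key_rank(a)))


def best_chain(
    anchors: list[Anchor],
    max_gap: int,
    orientation: str,
    min_len: int = 1,
) -> tuple[float, list[int]]:
    """Best-scoring monotone chain among ``anchors`` (one chromosome pair).

    Dynamic program over anchors sorted by (rank_a, rank_b); chain length
    is capped at ``min_len`` in the DP state so the maximum-score chain of
    length >= min_len can be recovered. Returns (score, anchor indices);
    score 0 and an empty list when no such chain exists.
    """
    sign = 1 if orientation == "+" else -1
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b))
    n = len(order)
    L = max(1, min_len)
    NEG = float("-inf")
    # dp[i][l]: best score of a chain ending at order[i] with capped length l+1
    dp = [[NEG] * L for _ in range(n)]
    back = [[None] * L for _ in range(n)]
    for ii in range(n):
        a = anchors[order[ii]]
        dp[ii][0] = a.score
        for jj in range(ii):
            b = anchors[order[jj]]
            if b.rank_a >= a.rank_a or a.rank_a - b.rank_a > max_gap:
                continue
            d_b = (a.rank_b - b.rank_b) * sign
            if d_b <= 0 or d_b > max_gap:
                continue
            for l in range(L):
                if dp[jj][l] == NEG:
                    continue
                nl = min(l + 1, L - 1)
                cand = dp[jj][l] + a.score
                if cand > dp[ii][nl]:
                    dp[ii][nl] = cand
                    back[ii][nl] = (jj, l)
    best_score, best_end = 0.0, None
    for ii in range(n):
        if dp[ii][L - 1] > best_score:
            best_score, best_end = dp[ii][L - 1], ii
    if best_end is None:
        return 0.0, []
    chain = []
    ii, l = best_end, L - 1
    while ii is not None:
        chain.append(order[ii])
        step = back[ii][l]
        ii, l = step if step else (None, None)
    chain.reverse()
    return best_score, chain


def chain_anchors(
    anchors: list[Anchor],
    min_pairs: int = 5,
    max_gap: int = 20,
) -> list[SyntenicBlock]:
    """Chain anchors into syntenic blocks (see module docstring)."""
    groups: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
    for a in anchors:
        groups[(a.chr_a, a.chr_b)].append(a)

    blocks = []
    for (chr_a, chr_b) in sorted(groups):
        pool = list(groups[(chr_a, chr_b)])
        while pool:
            candidates = []
            for orient in "+-":
                score, chain = best_chain(pool, max_gap, orient, min_len=min_pairs)
                if chain and len(chain) >= min_pairs:
                    start = min(pool[i].rank_a for i in chain)
                    candidates.append((-score, start, orient, chain))
            if not candidates:
                break
            candidates.sort()
            _, _, orient, chain = candidates[0]
            chosen = [pool[i] for i in chain]
            blocks.append(_make_block(chosen, orient))
            used = set(chain)
            pool = [a for i, a in enumerate(pool) if i not in used]

    blocks.sort(key=lambda b: (b.chr_a, b.start_a, b.chr_b, b.start_b, b.orientation))
    for i, b in enumerate(blocks):
        b.block_id = f"blk{i:04d}"
    return blocks


def _make_block(chosen: list[Anchor], orient: str) -> SyntenicBlock:
    chosen = sorted(chosen, key=lambda a: a.rank_a)
    return SyntenicBlock(
        block_id="",
        chr_a=chosen[0].chr_a,
        chr_b=chosen[0].chr_b,
        orientation=orient,
        n_anchors=len(chosen),
        start_a=min(a.rank_a for a in chosen),
        end_a=max(a.rank_a for a in chosen),
        start_b=min(a.rank_b for a in chosen),
        end_b=max(a.rank_b for a in chosen),
        score=sum(a.score for a in chosen),
        anchors=chosen,
    )


def self_synteny(
    genome: GenomeAnnotation,
    pairs: list[FilteredPair],
    min_diag_offset: int = 30,
    min_pairs: int = 5,
    max_gap: int = 20,
    max_tandem_gap: int = 5,
) -> list[SyntenicBlock]:
    """Within-genome syntenic (WGD paralog) blocks.

    Anchors on or near the self-comparison diagonal (same chromosome,
    |rank_a - rank_b| < min_diag_offset) are removed before chaining so
    tandem arrays and trivial self-matches do not seed blocks; each
    unordered paralog pair is used once.
    """
    anchors = anchors_from_pairs(pairs, genome, genome)
    anchors = [
        a for a in anchors
        if a.chr_a != a.chr_b or abs(a.rank_a - a.rank_b) >= min_diag_offset
    ]
    anchors, _ = collapse_tandem(anchors, max_tandem_gap=max_tandem_gap)
    return chain_anchors(anchors, min_pairs=min_pairs, max_gap=max_gap)


def classify_duplicate_mode(
    family_assignments,
    blocks: list[SyntenicBlock],
    genome: GenomeAnnotation,
    max_tandem_gap: int = 5,
) -> dict[str, str]:
    """Per family copy: 'syntenic', 'tandem', or 'dispersed'.

    A copy is syntenic if any of its constituent gene models is an anchor
    member of a retained block; otherwise tandem if another copy of the
    same family lies within ``max_tandem_gap`` ranks on the same
    chromosome; otherwise dispersed.
    """
    block_genes = set()
    for b in blocks:
        block_genes |= b.gene_ids()

    modes: dict[str, str] = {}
    by_family: dict[str, list] = defaultdict(list)
    for a in family_assignments:
        if not a.ambiguous:
            by_family[a.family].append(a)
    for fam, members in by_family.items():
        for a in members:
            constituents = a.merged_from or (a.gene_id,)
            if any(g in block_genes for g in constituents):
                modes[a.gene_id] = "syntenic"
                continue
            tandem = any(
                other is not a
                and other.chromosome == a.chromosome
                and min(
                    abs(other.rank - a.rank_max),
                    abs(a.rank - other.rank_max),
                    abs(other.rank - a.rank),
                )
                <= max_tandem_gap
                for other in members
            )
            modes[a.gene_id] = "tandem" if tandem else "dispersed"
    return modes
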