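"""Same-chromosome genetic linkage between gene families.

The central measurement of the package: for two gene families (e.g. the
morning-expressed sMYB clock genes and the midday PRRs), find all pairs of
family members on the same chromosome, count the protein-coding genes
strictly between them, classify the pair combination, summarise retention
across a set of species, and test observed proximity against a permutation
null that shuffles gene labels over the genome's rank slots.

Counting convention: the distance between two loci is the number of
protein-coding genes strictly between them (|rank difference| - 1); a
merged split gene model counts as a single gene and none of its
constituents are counted as intervening.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .errors import DistanceUndefinedError, FamilyError
from .genome_io import GenomeAnnotation
from .homology import FamilyAssignment

__all__ = [
    "LinkageHit",
    "Combination",
    "RetentionSummary",
    "NullResult",
    "CANONICAL_COMBINATIONS",
    "count_intervening",
    "find_linkages",
    "classify_combination",
    "family_copy_table",
    "retention_summary",
    "permutation_null",
]


@dataclass(frozen=True)
class LinkageHit:
    species: str
    chromosome: str
    gene_a: str
    gene_b: str
    family_a: str
    family_b: str
    n_intervening: int
    bp_distance: int
    combination: str
    in_syntenic_block: bool = False
    canonical: bool = False
    linkage_class: str = "other"


@dataclass(frozen=True)
class Combination:
    label: str
    linkage_class: str
    canonical: bool
    family_first: str
    family_second: str


@dataclass(frozen=True)
class RetentionSummary:
    n_species: int
    counts_per_class: tuple[tuple[str, int], ...]  # class -> n species with >=1 hit
    has_at_least_one: float
    has_both: float
    has_more_than_one: float


@dataclass(frozen=True)
class NullResult:
    observed_min_distance: float  # intervening genes; inf if never co-chromosomal
    n_perm: int
    p_value: float
    seed: int


# Sub-clade vocabulary of the circadian/light panel. Slash labels are the
# pre-duplication clade names used outside the Brassicaceae.
_SMYB_A = {"LHY", "CCA1", "LHY/CCA1", "CCA1/LHY"}
_SMYB_B = {"RVE4", "RVE8", "RVE4/8"}
_PRR_A = {"PRR5", "PRR9", "PRR5/9"}
_PRR_B = {"PRR3", "PRR7", "PRR3/7"}
_PIF = {"PIF3", "PIF"}
_PHY = {"PHYA"}
_KNOWN_OTHER = {
    "PRR1", "TOC1", "RVE1/2/7", "RVE6", "RVE3", "RVE5", "RVE3/5",
    "PHYB", "LKP2", "ZTL", "SRR1", "BOA", "LUX", "CHE", "TCP7", "ELF3", "GI",
}
_VOCABULARY = _SMYB_A | _SMYB_B | _PRR_A | _PRR_B | _PIF | _PHY | _KNOWN_OTHER

CLASS_SMYB_PRR_A = "LHY/CCA1-PRR5/9"
CLASS_SMYB_PRR_B = "RVE4/8-PRR3/7"
CLASS_PIF_PHY = "PIF3-PHYA"
SMYB_PRR_CLASSES = (CLASS_SMYB_PRR_A, CLASS_SMYB_PRR_B)

#: The eight canonical sMYB-PRR gene-pair combinations.
CANONICAL_COMBINATIONS = (
    "LHY-PRR5", "LHY-PRR9", "CCA1-PRR5", "CCA1-PRR9",
    "RVE4-PRR3", "RVE4-PRR7", "RVE8-PRR3", "RVE8-PRR7",
)


def classify_combination(family_a: str, family_b: str, strict: bool = True) -> Combination:
    """Canonical "A-B" label for a cross-family pair, sMYB/PIF member first.

    A combination is canonical when both members are single-gene labels of
    matching sub-clades (the eight sMYB-PRR pairs); clade-level or
    cross-clade pairs (e.g. LHY/CCA1 with PRR3/7) are labelled and flagged
    non-canonical but still classified. With ``strict`` a label outside the
    clock/light vocabulary raises; otherwise such pairs get an
    alphabetical label and class equal to that label.
    """
    fams = (family_a, family_b)
    if strict:
        for f in fams:
            if f not in _VOCABULARY:
                raise FamilyError(f"unknown family label {f!r}")

    def role(f):
        if f in _SMYB_A or f in _SMYB_B or f in _PIF:
            return 0
        return 1

    first, second = sorted(fams, key=lambda f: (role(f), f))
    label = f"{first}-{second}"

    if (family_a in _SMYB_A) != (family_b in _SMYB_A) and (
        family_a in _PRR_A or family_b in _PRR_A
    ) and {family_a, family_b} <= (_SMYB_A | _PRR_A):
        linkage_class = CLASS_SMYB_PRR_A
    elif {family_a, family_b} <= (_SMYB_B | _PRR_B) and (
        (family_a in _SMYB_B) != (family_b in _SMYB_B)
    ):
        linkage_class = CLASS_SMYB_PRR_B
    elif {family_a, family_b} <= (_PIF | _PHY) and (
        (family_a in _PIF) != (family_b in _PIF)
    ):
        linkage_class = CLASS_PIF_PHY
    elif fams[0] in _VOCABULARY and fams[1] in _VOCABULARY:
        linkage_class = "other"
    else:
        linkage_class = label

    canonical = label in CANONICAL_COMBINATIONS or (
        linkage_class == CLASS_PIF_PHY and first == "PIF3"
    )
    return Combination(label, linkage_class, canonical, first, second)


def count_intervening(genome: GenomeAnnotation, gene_a: str, gene_b: str) -> int:
    """Protein-coding genes strictly between two genes on one chromosome."""
    ga, gb = genome.gene(gene_a), genome.gene(gene_b)
    if ga.chromosome != gb.chromosome:
        raise DistanceUndefinedError(
            f"{gene_a} ({ga.chromosome}) and {gene_b} ({gb.chromosome}) "
            "are on different chromosomes"
        )
    return abs(ga.rank - gb.rank) - 1 if ga.rank != gb.rank else 0


def _unit_distance(a: FamilyAssignment, b: FamilyAssignment) -> tuple[int, int]:
    """(intervening genes, bp start-to-start) between two assignment units.

    Uses unit rank spans so constituents of a merged model are never
    counted as intervening genes.
    """
    left, right = (a, b) if a.rank <= b.rank else (b, a)
    n_between = max(0, right.rank - left.rank_max - 1)
    return n_between, abs(a.start - b.start)


def find_linkages(
    genome: GenomeAnnotation,
    assignments: list[FamilyAssignment],
    family_a: str,
    family_b: str,
    max_intervening: int | None = None,
    max_bp: int | None = None,
    blocks=None,
    strict_families: bool = False,
) -> list[LinkageHit]:
    """All same-chromosome cross-family pairs passing every given threshold.

    At least one of ``max_intervening`` (gene-count mode, the angiosperm
    screen) or ``max_bp`` (Mb-scale mode for bryophyte/gymnosperm genomes)
    must be given; when both are given, both must pass. Every qualifying
    pair is reported once, sorted by (chromosome, min rank). Ambiguous
    family assignments are excluded. If ``blocks`` is given, a hit is
    flagged in_syntenic_block when both members participate in anchors of
    retained blocks.
    """
    if max_intervening is None and max_bp is None:
        raise ValueError("give max_intervening and/or max_bp")
    members_a = [x for x in assignments if x.family == family_a and not x.ambiguous]
    members_b = [x for x in assignments if x.family == family_b and not x.ambiguous]

    block_genes = set()
    if blocks:
        for blk in blocks:
            block_genes |= blk.gene_ids()

    def in_block(unit: FamilyAssignment) -> bool:
        return any(g in block_genes for g in (unit.merged_from or (unit.gene_id,)))

    keyed = []
    seen = set()
    for ua in members_a:
        for ub in members_b:
            if ua.gene_id == ub.gene_id or ua.chromosome != ub.chromosome:
                continue
            key = tuple(sorted((ua.gene_id, ub.gene_id)))
            if key in seen:
                continue
            seen.add(key)
            n_between, bp = _unit_distance(ua, ub)
            if max_intervening is not None and n_between > max_intervening:
                continue
            if max_bp is not None and bp > max_bp:
                continue
            combo = classify_combination(ua.family, ub.family, strict=strict_families)
            left, right = (ua, ub) if ua.rank <= ub.rank else (ub, ua)
            keyed.append(
                ((ua.chromosome, min(ua.rank, ub.rank), left.gene_id),
                 LinkageHit(
                    species=genome.species_id,
                    chromosome=ua.chromosome,
                    gene_a=left.gene_id,
                    gene_b=right.gene_id,
                    family_a=left.family,
                    family_b=right.family,
                    n_intervening=n_between,
                    bp_distance=bp,
                    combination=combo.label,
                    in_syntenic_block=bool(blocks) and in_block(ua) and in_block(ub),
                    canonical=combo.canonical,
                    linkage_class=combo.linkage_class,
                ))
            )
    keyed.sort(key=lambda kh: kh[0])
    return [h for _, h in keyed]


def family_copy_table(assignments_by_species: dict[str, list[FamilyAssignment]]):
    """Per-species x family copy counts plus a chromosome-location table.

    Merged split models count once. Returns (counts DataFrame indexed by
    species with one column per family, locations DataFrame).
    """
    import pandas as pd

    families = sorted(
        {a.family for assigns in assignments_by_species.values()
         for a in assigns if not a.ambiguous}
    )
    counts = {}
    loc_rows = []
    for species in sorted(assignments_by_species):
        row = dict.fromkeys(families, 0)
        for a in assignments_by_species[species]:
            if a.ambiguous:
                continue
            row[a.family] += 1
            loc_rows.append(
                {
                    "species": species,
                    "family": a.family,
                    "gene_id": a.gene_id,
                    "chromosome": a.chromosome,
                    "start": a.start,
                    "rank": a.rank,
                }
            )
        counts[species] = row
    counts_df = pd.DataFrame.from_dict(counts, orient="index", dtype=int)[families]
    counts_df.index.name = "species"
    loc_df = pd.DataFrame(
        loc_rows, columns=["species", "family", "gene_id", "chromosome", "start", "rank"]
    ).sort_values(["species", "family", "chromosome", "rank"]).reset_index(drop=True)
    return counts_df, loc_df


def retention_summary(
    hits_by_species: dict[str, list[LinkageHit]],
    linkage_classes: tuple[str, ...] = SMYB_PRR_CLASSES,
) -> RetentionSummary:
    """Cross-species retention fractions of the listed linkage classes.

    has_at_least_one: fraction of species with >=1 hit in any listed
    class; has_both: hits in every listed class; has_more_than_one: >1
    hit in at least one single class. Fractions are rounded to 0.1%.
    """
    if not hits_by_species:
        raise ValueError("empty species set")
    n = len(hits_by_species)
    per_class = dict.fromkeys(linkage_classes, 0)
    at_least_one = both = more_than_one = 0
    for species in sorted(hits_by_species):
        class_counts = defaultdict(int)
        for h in hits_by_species[species]:
            if h.linkage_class in linkage_classes:
                class_counts[h.linkage_class] += 1
        for cls in class_counts:
            per_class[cls] += 1
        if class_counts:
            at_least_one += 1
        if all(class_counts.get(c, 0) >= 1 for c in linkage_classes):
            both += 1
        if any(v > 1 for v in class_counts.values()):
            more_than_one += 1

    def frac(k):  # reported to 0.1%
        return round(k / n, 4)

    return RetentionSummary(
        n_species=n,
        counts_per_class=tuple(sorted(per_class.items())),
        has_at_least_one=frac(at_least_one),
        has_both=frac(both),
        has_more_than_one=frac(more_than_one),
    )


def _min_cross_distance(chrom_a, rank_a, chrom_b, rank_b) -> float:
    """Minimum intervening-gene distance over cross-family pairs (inf if none
    co-chromosomal). Arrays are chromosome indices and ranks."""
    best = math.inf
    for ca, ra in zip(chrom_a, rank_a):
        same = chrom_b == ca
        if same.any():
            d = np.abs(rank_b[same] - ra) - 1
            best = min(best, max(0, int(d.min())))
    return best


def permutation_null(
    genome: GenomeAnnotation,
    assignments: list[FamilyAssignment],
    family_a: str,
    family_b: str,
    n_perm: int = 999,
    seed: int = 0,
) -> NullResult:
    """Permutation test of family-pair proximity.

    The statistic is the minimum cross-family intervening-gene distance
    anywhere in the genome (infinite when the families never share a
    chromosome, which compares as larger than any finite distance). Family
    member labels are shuffled uniformly over the genome's rank slots,
    preserving family sizes and chromosome gene counts. The p-value uses
    the add-one estimator p = (1 + #{perm <= obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    members_a = [x for x in assignments if x.family == family_a and not x.ambiguous]
    members_b = [x for x in assignments if x.family == family_b and not x.ambiguous]
    if not members_a or not members_b:
        raise FamilyError(
            f"family absent from genome {genome.species_id}: "
            f"{family_a if not members_a else family_b}"
        )

    chrom_index = {c: i for i, c in enumerate(genome.chromosomes)}
    slots_chrom = []
    slots_rank = []
    for c in genome.chromosomes:
        for g in genome.genes_on(c):
            slots_chrom.append(chrom_index[c])
            slots_rank.append(g.rank)
    slots_chrom = np.array(slots_chrom, dtype=np.int64)
    slots_rank = np.array(slots_rank, dtype=np.int64)
    n_slots = len(slots_chrom)

    oc_a = np.array([chrom_index[x.chromosome] for x in members_a])
    or_a = np.array([x.rank for x in members_a])
    oc_b = np.array([chrom_index[x.chromosome] for x in members_b])
    or_b = np.array([x.rank for x in members_b])
    observed = _min_cross_distance(oc_a, or_a, oc_b, or_b)

    na, nb = len(members_a), len(members_b)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_perm):
        pick = rng.choice(n_slots, size=na + nb, replace=False)
        pa, pb = pick[:na], pick[na:]
        stat = _min_cross_distance(
            slots_chrom[pa], slots_rank[pa], slots_chrom[pb], slots_rank[pb]
        )
        if stat <= observed:
            n_le += 1
    p = (1 + n_le) / (n_perm + 1)
    return NullResult(observed, n_perm, p, seed)
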