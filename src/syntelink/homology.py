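"""Pairwise protein similarity, C-score filtering, and family assignment.

The C-score of a homolog pair is its alignment score divided by the larger
of the two genes' best scores against any partner: a relative-best-hit
filter that keeps pairs within a chosen fraction (default 70%) of either
gene's best match. External all-by-all alignments are accepted in the
12-column tabular dialect; a deterministic shared-k-mer scorer is provided
so simulated and toy data need no external aligner.

Gene families are anchored to a curated seed panel (family label -> seed
genes); each target gene joins the family of its best-C-score seed. Runs of
consecutive same-family gene models are merged into one compound unit to
repair loci split during gene prediction.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from pathlib import Path

from .errors import FamilyError, SynteLinkError
from .genome_io import GenomeAnnotation

__all__ = [
    "SimilarityRecord",
    "FilteredPair",
    "FamilyAssignment",
    "SeedPanel",
    "read_pairwise_scores",
    "builtin_score",
    "cscore_filter",
    "assign_families",
    "merge_split_models",
]


@dataclass(frozen=True)
class SimilarityRecord:
    query_id: str
    subject_id: str
    score: float


@dataclass(frozen=True)
class FilteredPair:
    gene_a: str
    gene_b: str
    score: float
    c_score: float


@dataclass(frozen=True)
class FamilyAssignment:
    """One gene (or merged compound unit) assigned to a seed-panel family."""

    gene_id: str
    family: str
    seed_id: str
    c_score: float
    chromosome: str
    rank: int  # min rank of the unit
    rank_max: int  # max rank of the unit (== rank for single genes)
    start: int
    end: int
    ambiguous: bool = False
    merged_from: tuple[str, ...] | None = None


def read_pairwise_scores(path) -> list[SimilarityRecord]:
    """Read a 12-column tabular alignment file ("outfmt 6" dialect).

    Column 12 is taken as the score. Self-hits are dropped; duplicate
    (query, subject) rows keep the maximum score.
    """
    best: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise SynteLinkError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            q, s = cols[0], cols[1]
            if q == s:
                continue
            try:
                score = float(cols[11])
            except ValueError:
                raise SynteLinkError(f"{path}:{lineno}: non-numeric score {cols[11]!r}") from None
            key = (q, s)
            if score > best.get(key, float("-inf")):
                best[key] = score
    return [SimilarityRecord(q, s, sc) for (q, s), sc in sorted(best.items())]


def builtin_score(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    k: int = 4,
) -> list[SimilarityRecord]:
    """Score protein pairs by shared amino-acid k-mer count.

    The score of (a, b) is the size of the multiset intersection of their
    k-mer spectra. Pairs sharing no k-mer are omitted; self-pairs (same
    gene ID) are skipped so a proteome can be scored against itself.
    Deterministic; intended for simulated/toy data, not a LAST substitute
    at real-proteome scale.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if not proteins_a or not proteins_b:
        raise SynteLinkError("builtin_score: empty proteome")

    def spectra(proteins):
        return {
            gid: Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
            for gid, seq in proteins.items()
        }

    spec_a = spectra(proteins_a)
    spec_b = spectra(proteins_b)
    index_b: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for gid, cnt in spec_b.items():
        for kmer, c in cnt.items():
            index_b[kmer].append((gid, c))

    out = []
    for ga in sorted(spec_a):
        shared: dict[str, int] = defaultdict(int)
        for kmer, ca in spec_a[ga].items():
            for gb, cb in index_b.get(kmer, ()):
                shared[gb] += min(ca, cb)
        for gb in sorted(shared):
            if ga == gb:
                continue
            out.append(SimilarityRecord(ga, gb, float(shared[gb])))
    return out


def _best_scores(records) -> dict[str, float]:
    best: dict[str, float] = {}
    for r in records:
        for g in (r.query_id, r.subject_id):
            if r.score > best.get(g, 0.0):
                best[g] = r.score
    return best


def cscore_filter(records, threshold: float = 0.7) -> list[FilteredPair]:
    """Keep pairs whose score is >= threshold x max(best(a), best(b)).

    The boundary is inclusive. Pairs are symmetric: (a, b) and (b, a)
    collapse to one record with gene_a < gene_b and the maximum score.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"C-score threshold must be in (0, 1], got {threshold}")
    pair_score: dict[tuple[str, str], float] = {}
    for r in records:
        a, b = sorted((r.query_id, r.subject_id))
        key = (a, b)
        if r.score > pair_score.get(key, float("-inf")):
            pair_score[key] = r.score
    best = _best_scores(records)
    out = []
    for (a, b), score in sorted(pair_score.items()):
        c = score / max(best[a], best[b])
        if c >= threshold:
            out.append(FilteredPair(a, b, score, c))
    return out


class SeedPanel:
    """Curated gene families: family label -> {seed gene ID: protein}."""

    def __init__(self, families: dict[str, dict[str, str]]):
        for fam, seeds in families.items():
            if not seeds:
                raise FamilyError(f"family {fam!r} has no seed protein")
        self.families = families

    @property
    def labels(self) -> list[str]:
        return sorted(self.families)

    def seed_proteins(self) -> dict[str, str]:
        return {sid: seq for seeds in self.families.values() for sid, seq in seeds.items()}

    def family_of_seed(self) -> dict[str, str]:
        return {sid: fam for fam, seeds in self.families.items() for sid in seeds}

    @classmethod
    def from_tsv(cls, path, genomes: dict[str, GenomeAnnotation]) -> "SeedPanel":
        """Load a panel TSV (family_label, seed_gene_id, seed_source_species),
        pulling seed protein sequences from the registered genomes."""
        families: dict[str, dict[str, str]] = defaultdict(dict)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 3:
                    raise FamilyError(f"{path}:{lineno}: expected 3 columns")
                fam, seed_id, species = cols[:3]
                if species not in genomes:
                    raise FamilyError(
                        f"{path}:{lineno}: seed source species {species!r} not loaded"
                    )
                seq = genomes[species].proteins.get(seed_id)
                if seq is None:
                    raise FamilyError(f"{path}:{lineno}: no protein for seed {seed_id!r}")
                families[fam][seed_id] = seq
        return cls(dict(families))


def assign_families(
    genome: GenomeAnnotation,
    seed_panel: SeedPanel,
    min_c: float = 0.3,
    k: int = 4,
) -> list[FamilyAssignment]:
    """Assign genes to seed-panel families by best C-score against seeds.

    For each target gene, the C-score against a seed divides the shared
    k-mer score by the larger of the two sequences' best scores, where a
    sequence's best score is floored at its self k-mer count (the maximum
    attainable); an exact copy of a seed therefore scores 1.0 while
    spurious single-k-mer matches between unrelated proteins score near 0.
    A gene whose best C-score ties across two families is flagged
    ambiguous (excluded from linkage scans downstream).
    """
    seeds = seed_panel.seed_proteins()
    records = builtin_score(genome.proteins, seeds, k=k) if genome.proteins else []
    best = _best_scores(records)
    for gid, seq in list(genome.proteins.items()) + list(seeds.items()):
        self_score = float(max(0, len(seq) - k + 1))
        if self_score > best.get(gid, 0.0):
            best[gid] = self_score
    fam_of = seed_panel.family_of_seed()

    by_gene: dict[str, list[SimilarityRecord]] = defaultdict(list)
    for r in records:
        by_gene[r.query_id].append(r)

    out = []
    for gid in sorted(by_gene):
        if gid not in genome:
            continue
        scored = []
        for r in by_gene[gid]:
            c = r.score / max(best[r.query_id], best[r.subject_id])
            scored.append((c, r.subject_id))
        scored.sort(key=lambda t: (-t[0], t[1]))
        c_best, seed_best = scored[0]
        if c_best < min_c:
            continue
        tied_fams = {fam_of[s] for c, s in scored if c == c_best}
        g = genome.gene(gid)
        out.append(
            FamilyAssignment(
                gene_id=gid,
                family=fam_of[seed_best] if len(tied_fams) == 1 else "|".join(sorted(tied_fams)),
                seed_id=seed_best,
                c_score=c_best,
                chromosome=g.chromosome,
                rank=g.rank,
                rank_max=g.rank,
                start=g.start,
                end=g.end,
                ambiguous=len(tied_fams) > 1,
            )
        )
    out.sort(key=lambda a: (a.chromosome, a.rank, a.gene_id))
    return out


def merge_split_models(
    assignments: list[FamilyAssignment],
    genome: GenomeAnnotation,
    max_gap_ranks: int = 1,
) -> list[FamilyAssignment]:
    """Merge runs of same-family gene models into one compound unit.

    Gene prediction sometimes splits one locus into several adjacent
    models; runs of assignments to the same family whose consecutive ranks
    differ by at most ``max_gap_ranks`` on one chromosome are merged into a
    single unit with compound ID "A_B", spanning min start to max end and
    using the minimum rank for distance computations.
    """
    groups: dict[tuple[str, str], list[FamilyAssignment]] = defaultdict(list)
    singles = []
    for a in assignments:
        if a.ambiguous:
            singles.append(a)
        else:
            groups[(a.chromosome, a.family)].append(a)

    out = list(singles)
    for (chrom, fam), members in groups.items():
        members.sort(key=lambda a: a.rank)
        run = [members[0]]
        for a in members[1:]:
            if a.rank - run[-1].rank <= max_gap_ranks:
                run.append(a)
            else:
                out.append(_close_run(run))
                run = [a]
        out.append(_close_run(run))
    out.sort(key=lambda a: (a.chromosome, a.rank, a.gene_id))
    return out


def _close_run(run: list[FamilyAssignment]) -> FamilyAssignment:
    if len(run) == 1:
        return run[0]
    best = max(run, key=lambda a: a.c_score)
    return replace(
        best,
        gene_id="_".join(a.gene_id for a in run),
        rank=min(a.rank for a in run),
        rank_max=max(a.rank for a in run),
        start=min(a.start for a in run),
        end=max(a.end for a in run),
        merged_from=tuple(a.gene_id for a in run),
    )


def default_seed_panel_path() -> Path:
    """Path of the shipped example panel (Arabidopsis clock/light genes)."""
    return Path(__file__).parent / "data" / "seed_panel_arabidopsis.tsv"
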