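"""Clade-scale genome-evolution simulator with full ground truth.

Simulates a clade of annotated genomes under speciation, whole-genome
duplication/triplication, biased fractionation, rearrangement, tandem
duplication and codon-level sequence divergence, and emits the same
objects the analysis pipeline consumes (ranked annotations, protein and
CDS sequences, standard GFF3/FASTA on request) together with a truth set:
homolog/ortholog pairs, paralog pairs labelled by the WGD event that
created them, true collinear blocks, and true family-linkage states.

Model sketch
------------
An ancestral genome of unrelated random coding genes is placed on
``n_chromosomes``; designated gene families are planted at configurable
positions, optionally at a fixed intervening-gene distance from a partner
family (a "designated linkage"). A species tree of branches carries
ordered events:

* ``Wgd(multiplier)`` copies every chromosome (2 = WGD, 3 = WGT) and
  records the duplicate groups.
* ``Fractionate(loss_rate, subgenome_bias, linkage_preservation)`` visits
  every duplicate group of the most recent polyploidy with >= 2 surviving
  members and deletes one member per attempt with probability
  ``loss_rate``; the victim comes from the disfavoured (newer) subgenome
  with probability ``subgenome_bias``, and a victim participating in a
  designated family linkage is spared with probability
  ``linkage_preservation`` — the simulator's explicit handle on
  preferential retention of linked genes. Singletons are immune.
* ``Invert`` / ``Translocate`` rearrange contiguous gene spans.
* ``TandemDuplicate(rate)`` inserts adjacent copies.
* ``Diverge(ds, dn_ds)`` evolves every gene's CDS by uniform
  single-nucleotide proposals until the expected synonymous divergence
  reaches ``ds``; stop-creating proposals are rejected and nonsynonymous
  proposals are accepted with probability ``dn_ds``.

Everything is driven by one seeded generator, so identical configurations
produce byte-identical output.
"""

from __future__ import annotations

import copy
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from ._codons import SENSE_CODONS, STOP_CODONS, GENETIC_CODE, synonymous_sites
from .errors import ConfigError
from .genome_io import GeneModel, GenomeAnnotation, write_fasta, write_gff3
from .homology import FamilyAssignment, SeedPanel

__all__ = [
    "Wgd",
    "Fractionate",
    "Invert",
    "Translocate",
    "TandemDuplicate",
    "Diverge",
    "Lineage",
    "Placement",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate",
    "evolve_sequences",
    "evaluate_recovery",
    "easy_clade_config",
    "assignments_from_truth",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Wgd:
    multiplier: int = 2
    label: str = "wgd"

    def __post_init__(self):
        if self.multiplier not in (2, 3):
            raise ConfigError("Wgd multiplier must be 2 or 3")


@dataclass(frozen=True)
class Fractionate:
    loss_rate: float
    subgenome_bias: float = 0.5
    linkage_preservation: float = 0.0

    def __post_init__(self):
        for name in ("loss_rate", "subgenome_bias", "linkage_preservation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"Fractionate.{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class Invert:
    n_events: int = 1
    mean_span: int = 10


@dataclass(frozen=True)
class Translocate:
    n_events: int = 1
    mean_span: int = 10


@dataclass(frozen=True)
class TandemDuplicate:
    rate: float = 0.01


@dataclass(frozen=True)
class Diverge:
    ds: float = 0.1
    dn_ds: float = 0.2

    def __post_init__(self):
        if self.ds < 0:
            raise ConfigError("Diverge.ds must be >= 0")


@dataclass(frozen=True)
class Lineage:
    """A branch of the species tree: events applied in order, then either a
    leaf (no children) or a speciation into children."""

    name: str
    events: tuple = ()
    children: tuple = ()


@dataclass(frozen=True)
class Placement:
    """Plant a family gene on the ancestral genome.

    Either give (chromosome, rank) explicitly, give a partner family plus
    an intervening-gene gap (the gene lands that many genes downstream of
    the partner on the partner's chromosome, creating a designated
    linkage), or leave rank None for a uniformly random position.
    """

    family: str
    chromosome: int | None = None
    rank: int | None = None
    partner_family: str | None = None
    partner_gap: int | None = None


@dataclass(frozen=True)
class SimConfig:
    n_genes: int
    n_chromosomes: int
    tree: Lineage
    family_placements: tuple = ()
    codons_min: int = 150
    codons_max: int = 400
    linkage_window: int = 25  # intervening genes defining a "linked" state
    truth_min_pairs: int = 5
    truth_max_gap: int = 20
    seed: int = 0


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueBlock:
    chr_a: str
    chr_b: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    n_pairs: int
    orientation: str


@dataclass(frozen=True)
class TrueLinkage:
    species: str
    chromosome: str
    family_a: str
    family_b: str
    gene_a: str
    gene_b: str
    n_intervening: int


@dataclass
class SimTruth:
    species: list[str]
    ortholog_pairs: dict  # (sp1, sp2) -> list[(gid1, gid2)]
    homolog_pairs: dict  # (sp1, sp2) -> list[(gid1, gid2)]; root-level homology
    paralog_pairs: dict  # sp -> list[(gid1, gid2, event_label)]
    true_blocks: dict  # (sp1, sp2) -> list[TrueBlock]
    true_self_blocks: dict  # sp -> list[TrueBlock]
    true_linkages: dict  # sp -> list[TrueLinkage]
    family_members: dict  # sp -> {family -> [gene ids]}
    ds_from_root: dict  # sp -> float
    fractionation_log: list


@dataclass
class SimResult:
    config: SimConfig
    genomes: dict  # sp -> GenomeAnnotation
    truth: SimTruth
    seed_panel: SeedPanel

    def write(self, outdir):
        """Emit GFF3 + protein/CDS FASTA per species under ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp, genome in sorted(self.genomes.items()):
            write_gff3(genome, outdir / f"{sp}.gff3")
            write_fasta(genome.proteins, outdir / f"{sp}.protein.fa")
            write_fasta(genome.cds, outdir / f"{sp}.cds.fa")
        return outdir


# ---------------------------------------------------------------------------
# Internal state
# ---------------------------------------------------------------------------

@dataclass
class _SimGene:
    uid: int
    family: str | None
    cds: str
    subgenome: int = 0


class _Registry:
    """Global gene genealogy shared across the whole simulation."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.parent: dict[int, int | None] = {}
        self.birth: dict[int, int] = {}
        self.time = 0
        self._next_uid = 0

    def tick(self) -> int:
        self.time += 1
        return self.time

    def new_gene(self, family, cds, parent_uid=None, subgenome=0) -> _SimGene:
        uid = self._next_uid
        self._next_uid += 1
        self.parent[uid] = parent_uid
        self.birth[uid] = self.time
        return _SimGene(uid, family, cds, subgenome)

    def ancestor_at(self, uid: int, t: int) -> int:
        while self.birth[uid] > t:
            uid = self.parent[uid]
        return uid


@dataclass
class _State:
    chromosomes: list  # list[list[_SimGene]]
    wgd_events: list = field(default_factory=list)  # (label, [uid tuples])
    ds_from_root: float = 0.0


@dataclass(frozen=True)
class FractionationLog:
    branch: str
    n_groups: int
    n_losses: int
    n_spared: int
    genes_before: int
    genes_after: int


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def evolve_sequences(parent_cds: str, dS_target: float, dN_dS: float, seed) -> str:
    """Evolve a CDS until its expected synonymous divergence reaches
    ``dS_target`` (substitution events per synonymous site).

    Proposals are uniform single-nucleotide changes; stop-creating
    proposals are rejected, synonymous proposals always accepted, and
    nonsynonymous proposals accepted with probability ``dN_dS``.
    """
    if dS_target < 0:
        raise ConfigError("dS_target must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = [parent_cds[i : i + 3] for i in range(0, len(parent_cds), 3)]
    S = sum(synonymous_sites(c) for c in codons)
    target = dS_target * S
    if target <= 0 or not codons:
        return parent_cds
    n_syn = 0.0
    max_iter = int(200 * target + 100_000)
    it = 0
    L3 = 3 * len(codons)
    while n_syn < target and it < max_iter:
        it += 1
        pos = int(rng.integers(L3))
        i, off = divmod(pos, 3)
        cur = codons[i]
        nt = "ACGT"[int(rng.integers(4))]
        if nt == cur[off]:
            continue
        alt = cur[:off] + nt + cur[off + 1 :]
        if alt in STOP_CODONS:
            continue
        if GENETIC_CODE[alt] == GENETIC_CODE[cur]:
            codons[i] = alt
            n_syn += 1
        elif rng.random() < dN_dS:
            codons[i] = alt
    return "".join(codons)


# ---------------------------------------------------------------------------
# Event application
# ---------------------------------------------------------------------------

def _apply_wgd(state: _State, reg: _Registry, ev: Wgd):
    t_event = reg.tick()
    for g in (g for chrom in state.chromosomes for g in chrom):
        g.subgenome = 0
    groups = []
    new_chroms = []
    group_of: dict[int, list[int]] = {}
    for j in range(1, ev.multiplier):
        for chrom in list(state.chromosomes):
            copy_chrom = []
            for g in chrom:
                c = reg.new_gene(g.family, g.cds, parent_uid=g.uid, subgenome=j)
                copy_chrom.append(c)
                group_of.setdefault(g.uid, [g.uid]).append(c.uid)
            new_chroms.append(copy_chrom)
    state.chromosomes.extend(new_chroms)
    for uid in sorted(group_of):
        groups.append(tuple(group_of[uid]))
    state.wgd_events.append((ev.label, groups, t_event))


def _linked(state: _State, gene: _SimGene, designated, window: int) -> bool:
    if gene.family is None:
        return False
    partners = {
        other
        for pair in designated
        if gene.family in pair
        for other in pair
        if other != gene.family
    }
    if not partners:
        return False
    for chrom in state.chromosomes:
        positions = {g.uid: i for i, g in enumerate(chrom)}
        if gene.uid not in positions:
            continue
        i = positions[gene.uid]
        for j, g in enumerate(chrom):
            if g.family in partners and abs(j - i) - 1 <= window:
                return True
        return False
    return False


def _apply_fractionate(
    state: _State, reg: _Registry, ev: Fractionate, designated, window, branch, log
):
    if not state.wgd_events:
        raise ConfigError("fractionate before any wgd in the event script")
    reg.tick()
    label, groups, _t = state.wgd_events[-1]
    alive = {g.uid for chrom in state.chromosomes for g in chrom}
    gene_by_uid = {g.uid: g for chrom in state.chromosomes for g in chrom}
    genes_before = len(alive)
    to_remove = set()
    n_losses = n_spared = n_groups = 0
    rng = reg.rng
    for group in groups:
        members = [u for u in group if u in alive and u not in to_remove]
        if len(members) < 2:
            continue
        n_groups += 1
        n_attempts = len(members) - 1
        for _ in range(n_attempts):
            if len(members) < 2:
                break
            if rng.random() >= ev.loss_rate:
                continue
            members_sorted = sorted(members, key=lambda u: (gene_by_uid[u].subgenome, u))
            disfavoured = members_sorted[-1]
            if rng.random() < ev.subgenome_bias:
                victim = disfavoured
            else:
                others = [u for u in members_sorted if u != disfavoured]
                victim = others[int(rng.integers(len(others)))]
            if ev.linkage_preservation > 0 and _linked(
                state, gene_by_uid[victim], designated, window
            ):
                if rng.random() < ev.linkage_preservation:
                    n_spared += 1
                    continue
            to_remove.add(victim)
            members.remove(victim)
            n_losses += 1
    if to_remove:
        state.chromosomes = [
            [g for g in chrom if g.uid not in to_remove] for chrom in state.chromosomes
        ]
    genes_after = sum(len(c) for c in state.chromosomes)
    log.append(
        FractionationLog(branch, n_groups, n_losses, n_spared, genes_before, genes_after)
    )


def _geom_span(rng, mean_span: int, limit: int) -> int:
    span = 1 + int(rng.geometric(1.0 / max(1, mean_span)))
    return min(span, limit)


def _apply_invert(state: _State, reg: _Registry, ev: Invert):
    reg.tick()
    rng = reg.rng
    for _ in range(ev.n_events):
        sizes = np.array([len(c) for c in state.chromosomes], dtype=float)
        if sizes.sum() == 0:
            return
        ci = int(rng.choice(len(sizes), p=sizes / sizes.sum()))
        chrom = state.chromosomes[ci]
        if len(chrom) < 2:
            continue
        span = _geom_span(rng, ev.mean_span, len(chrom))
        start = int(rng.integers(0, len(chrom) - span + 1))
        chrom[start : start + span] = chrom[start : start + span][::-1]


def _apply_translocate(state: _State, reg: _Registry, ev: Translocate):
    reg.tick()
    rng = reg.rng
    for _ in range(ev.n_events):
        if len(state.chromosomes) < 2:
            return
        sizes = np.array([len(c) for c in state.chromosomes], dtype=float)
        if sizes.sum() == 0:
            return
        src = int(rng.choice(len(sizes), p=sizes / sizes.sum()))
        chrom = state.chromosomes[src]
        if not chrom:
            continue
        span = _geom_span(rng, ev.mean_span, len(chrom))
        start = int(rng.integers(0, len(chrom) - span + 1))
        segment = chrom[start : start + span]
        del chrom[start : start + span]
        dst_options = [i for i in range(len(state.chromosomes)) if i != src]
        dst = dst_options[int(rng.integers(len(dst_options)))]
        target = state.chromosomes[dst]
        at = int(rng.integers(0, len(target) + 1))
        target[at:at] = segment


def _apply_tandem(state: _State, reg: _Registry, ev: TandemDuplicate, tandem_log):
    reg.tick()
    rng = reg.rng
    for chrom in state.chromosomes:
        i = 0
        while i < len(chrom):
            g = chrom[i]
            if rng.random() < ev.rate:
                c = reg.new_gene(g.family, g.cds, parent_uid=g.uid, subgenome=g.subgenome)
                chrom.insert(i + 1, c)
                tandem_log.append((g.uid, c.uid))
                i += 1
            i += 1


def _apply_diverge(state: _State, reg: _Registry, ev: Diverge):
    reg.tick()
    for chrom in state.chromosomes:
        for g in chrom:
            g.cds = evolve_sequences(g.cds, ev.ds, ev.dn_ds, reg.rng)
    state.ds_from_root += ev.ds


# ---------------------------------------------------------------------------
# Ancestral genome and tree traversal
# ---------------------------------------------------------------------------

def _build_ancestor(config: SimConfig, reg: _Registry) -> _State:
    rng = reg.rng
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    chroms = []
    for n in per_chrom:
        chrom = []
        for _ in range(n):
            n_codons = int(rng.integers(config.codons_min, config.codons_max + 1))
            chrom.append(reg.new_gene(None, random_cds(rng, n_codons)))
        chroms.append(chrom)
    state = _State(chromosomes=chroms)

    placed: dict[str, tuple[int, int]] = {}
    deferred = []
    taken = set()
    for p in config.family_placements:
        if p.partner_family is not None:
            deferred.append(p)
            continue
        if p.rank is None or p.chromosome is None:
            flat = [(ci, gi) for ci, c in enumerate(chroms) for gi in range(len(c))]
            free = [x for x in flat if x not in taken]
            ci, gi = free[int(rng.integers(len(free)))]
        else:
            ci, gi = p.chromosome, p.rank
        _place(chroms, ci, gi, p.family, taken, placed)
    for p in deferred:
        if p.partner_family not in placed:
            raise ConfigError(f"placement of {p.family!r}: partner "
                              f"{p.partner_family!r} not placed")
        ci, gi = placed[p.partner_family]
        gap = p.partner_gap if p.partner_gap is not None else 3
        _place(chroms, ci, gi + gap + 1, p.family, taken, placed)
    return state


def _place(chroms, ci, gi, family, taken, placed):
    if ci >= len(chroms) or gi >= len(chroms[ci]):
        raise ConfigError(f"placement of {family!r} out of range (chrom {ci}, rank {gi})")
    if (ci, gi) in taken:
        raise ConfigError(f"placement collision for {family!r} at (chrom {ci}, rank {gi})")
    chroms[ci][gi].family = family
    taken.add((ci, gi))
    placed[family] = (ci, gi)


def _designated_pairs(config: SimConfig) -> set[frozenset]:
    out = set()
    for p in config.family_placements:
        if p.partner_family is not None:
            out.add(frozenset({p.family, p.partner_family}))
    return out


def simulate(config: SimConfig) -> SimResult:
    """Run the full clade simulation. Deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    reg = _Registry(rng)
    designated = _designated_pairs(config)
    state = _build_ancestor(config, reg)
    ancestor_proteins = {
        f"seed_{g.family}": str(Seq(g.cds).translate())
        for chrom in state.chromosomes
        for g in chrom
        if g.family is not None
    }

    leaves: dict[str, _State] = {}
    leaf_paths: dict[str, tuple] = {}
    frac_log: list[FractionationLog] = []
    tandem_log: list[tuple[int, int]] = []

    def run(state: _State, lineage: Lineage, path: tuple):
        for ev in lineage.events:
            if isinstance(ev, Wgd):
                _apply_wgd(state, reg, ev)
            elif isinstance(ev, Fractionate):
                _apply_fractionate(state, reg, ev, designated,
                                   config.linkage_window, lineage.name, frac_log)
            elif isinstance(ev, Invert):
                _apply_invert(state, reg, ev)
            elif isinstance(ev, Translocate):
                _apply_translocate(state, reg, ev)
            elif isinstance(ev, TandemDuplicate):
                _apply_tandem(state, reg, ev, tandem_log)
            elif isinstance(ev, Diverge):
                _apply_diverge(state, reg, ev)
            else:
                raise ConfigError(f"unknown event {ev!r}")
        if not lineage.children:
            if lineage.name in leaves:
                raise ConfigError(f"duplicate leaf name {lineage.name!r}")
            leaves[lineage.name] = state
            leaf_paths[lineage.name] = path
            return
        split_time = reg.tick()
        for child in lineage.children:
            run(copy.deepcopy(state), child, path + ((lineage.name, split_time),))

    run(state, config.tree, ())
    if not leaves:
        raise ConfigError("species tree has no leaves")

    return _emit(config, reg, leaves, leaf_paths, frac_log, tandem_log,
                 ancestor_proteins, designated)


# ---------------------------------------------------------------------------
# Output assembly
# ---------------------------------------------------------------------------

def _gene_id(sp: str, uid: int) -> str:
    return f"{sp}G{uid:06d}"


def _emit(config, reg, leaves, leaf_paths, frac_log, tandem_log,
          ancestor_proteins, designated) -> SimResult:
    rng = reg.rng
    genomes: dict[str, GenomeAnnotation] = {}
    uid_of_gene: dict[str, dict[str, int]] = {}
    family_members: dict[str, dict[str, list[str]]] = {}
    chrom_rank: dict[str, dict[int, tuple[str, int]]] = {}  # sp -> uid -> (chrom, rank)

    for sp in sorted(leaves):
        state = leaves[sp]
        genes: dict[str, list[GeneModel]] = {}
        proteins, cds = {}, {}
        fams: dict[str, list[str]] = defaultdict(list)
        pos_of: dict[int, tuple[str, int]] = {}
        uids: dict[str, int] = {}
        for ci, chrom in enumerate(state.chromosomes):
            cname = f"{sp}_chr{ci + 1:02d}"
            pos = 1
            models = []
            for rank, g in enumerate(chrom):
                gid = _gene_id(sp, g.uid)
                start = pos
                end = start + len(g.cds) - 1
                pos = end + 1 + int(rng.integers(200, 2000))
                strand = "+" if rng.random() < 0.5 else "-"
                models.append(GeneModel(gid, cname, start, end, strand, rank))
                proteins[gid] = str(Seq(g.cds).translate())
                cds[gid] = g.cds
                uids[gid] = g.uid
                pos_of[g.uid] = (cname, rank)
                if g.family is not None:
                    fams[g.family].append(gid)
            if models:
                genes[cname] = models
        genomes[sp] = GenomeAnnotation(sp, genes, proteins, cds)
        uid_of_gene[sp] = uids
        family_members[sp] = dict(fams)
        chrom_rank[sp] = pos_of

    species = sorted(leaves)
    lca_time = _lca_times(leaf_paths)

    ortholog_pairs, homolog_pairs, true_blocks = {}, {}, {}
    for i, s1 in enumerate(species):
        for s2 in species[i + 1 :]:
            t = lca_time[(s1, s2)]
            ortho = _lifted_pairs(reg, leaves[s1], leaves[s2], s1, s2, t)
            homo = _lifted_pairs(reg, leaves[s1], leaves[s2], s1, s2, 0)
            ortholog_pairs[(s1, s2)] = ortho
            homolog_pairs[(s1, s2)] = homo
            anchors = [
                (*chrom_rank[s1][u1], *chrom_rank[s2][u2], _gene_id(s1, u1), _gene_id(s2, u2))
                for u1, u2 in _lifted_uid_pairs(reg, leaves[s1], leaves[s2], 0)
            ]
            true_blocks[(s1, s2)] = _collinear_runs(
                anchors, config.truth_max_gap, config.truth_min_pairs
            )

    paralog_pairs, true_self_blocks = {}, {}
    for sp in species:
        pairs = _paralog_pairs(reg, leaves[sp], tandem_log)
        paralog_pairs[sp] = [
            (_gene_id(sp, u1), _gene_id(sp, u2), label) for u1, u2, label in pairs
        ]
        anchors = []
        for u1, u2, _label in pairs:
            p1, p2 = chrom_rank[sp][u1], chrom_rank[sp][u2]
            if p2 < p1:
                p1, p2 = p2, p1
                u1, u2 = u2, u1
            anchors.append((*p1, *p2, _gene_id(sp, u1), _gene_id(sp, u2)))
        true_self_blocks[sp] = _collinear_runs(
            anchors, config.truth_max_gap, config.truth_min_pairs
        )

    true_linkages = {
        sp: _linkage_states(sp, leaves[sp], chrom_rank[sp], designated,
                            config.linkage_window)
        for sp in species
    }

    truth = SimTruth(
        species=species,
        ortholog_pairs=ortholog_pairs,
        homolog_pairs=homolog_pairs,
        paralog_pairs=paralog_pairs,
        true_blocks=true_blocks,
        true_self_blocks=true_self_blocks,
        true_linkages=true_linkages,
        family_members=family_members,
        ds_from_root={sp: leaves[sp].ds_from_root for sp in species},
        fractionation_log=frac_log,
    )
    panel = SeedPanel(
        {
            fam.removeprefix("seed_"): {fam: seq}
            for fam, seq in sorted(ancestor_proteins.items())
        }
    ) if ancestor_proteins else SeedPanel({"_none": {"_none": "M"}})
    return SimResult(config=config, genomes=genomes, truth=truth, seed_panel=panel)


def _lca_times(leaf_paths) -> dict:
    out = {}
    names = sorted(leaf_paths)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            t = 0
            for (na, ta), (nb, tb) in zip(leaf_paths[a], leaf_paths[b]):
                if na == nb:
                    t = ta
                else:
                    break
            out[(a, b)] = t
    return out


def _lifted_uid_pairs(reg, state1, state2, t):
    g1 = defaultdict(list)
    for chrom in state1.chromosomes:
        for g in chrom:
            g1[reg.ancestor_at(g.uid, t)].append(g.uid)
    pairs = []
    for chrom in state2.chromosomes:
        for g in chrom:
            anc = reg.ancestor_at(g.uid, t)
            for u1 in g1.get(anc, ()):
                pairs.append((u1, g.uid))
    pairs.sort()
    return pairs


def _lifted_pairs(reg, state1, state2, s1, s2, t):
    return [
        (_gene_id(s1, u1), _gene_id(s2, u2))
        for u1, u2 in _lifted_uid_pairs(reg, state1, state2, t)
    ]


def _paralog_pairs(reg, state, tandem_log):
    alive = [g.uid for chrom in state.chromosomes for g in chrom]
    alive_set = set(alive)
    out = []
    for label, groups, t_event in state.wgd_events:
        lifted = defaultdict(list)
        for uid in alive:
            lifted[reg.ancestor_at(uid, t_event)].append(uid)
        # members of one group are distinct ancestors at event time
        for grp in groups:
            survivors = [lifted.get(u, []) for u in grp]
            for a in range(len(grp)):
                for b in range(a + 1, len(grp)):
                    for u1 in survivors[a]:
                        for u2 in survivors[b]:
                            out.append((u1, u2, label))
    for orig, cp in tandem_log:
        if orig in alive_set and cp in alive_set:
            out.append((orig, cp, "tandem"))
    out.sort()
    return out


def _collinear_runs(anchors, max_gap: int, min_pairs: int) -> list[TrueBlock]:
    """Greedy direction-consistent run scan over true homolog anchors.

    Independent of (and simpler than) the detection-side DP: anchors are
    grouped per chromosome pair, sorted by rank_a, and consecutive anchors
    within ``max_gap`` on both sides with a consistent subject direction
    extend the current run.
    """
    groups = defaultdict(list)
    for ca, ra, cb, rb, *_ in anchors:
        groups[(ca, cb)].append((ra, rb))
    blocks = []
    for (ca, cb), pts in sorted(groups.items()):
        pts = sorted(set(pts))
        run: list[tuple[int, int]] = []
        direction = 0
        for ra, rb in pts:
            if not run:
                run = [(ra, rb)]
                continue
            pra, prb = run[-1]
            d = np.sign(rb - prb)
            ok = (
                0 < ra - pra <= max_gap
                and 0 < abs(rb - prb) <= max_gap
                and (direction == 0 or d == direction)
            )
            if ok:
                run.append((ra, rb))
                if direction == 0:
                    direction = d
            else:
                _flush_run(blocks, ca, cb, run, direction, min_pairs)
                run, direction = [(ra, rb)], 0
        _flush_run(blocks, ca, cb, run, direction, min_pairs)
    return blocks


def _flush_run(blocks, ca, cb, run, direction, min_pairs):
    if len(run) >= min_pairs:
        ras = [p[0] for p in run]
        rbs = [p[1] for p in run]
        blocks.append(
            TrueBlock(ca, cb, min(ras), max(ras), min(rbs), max(rbs),
                      len(run), "-" if direction < 0 else "+")
        )


def _linkage_states(sp, state, pos_of, designated, window) -> list[TrueLinkage]:
    by_family = defaultdict(list)
    for chrom in state.chromosomes:
        for g in chrom:
            if g.family is not None:
                by_family[g.family].append(g.uid)
    out = []
    for pair in sorted(designated, key=sorted):
        fa, fb = sorted(pair)
        for u1 in by_family.get(fa, ()):
            for u2 in by_family.get(fb, ()):
                c1, r1 = pos_of[u1]
                c2, r2 = pos_of[u2]
                if c1 != c2:
                    continue
                n_between = abs(r1 - r2) - 1
                if n_between <= window:
                    out.append(
                        TrueLinkage(sp, c1, fa, fb,
                                    _gene_id(sp, u1), _gene_id(sp, u2), n_between)
                    )
    out.sort(key=lambda t: (t.chromosome, t.gene_a, t.gene_b))
    return out


# ---------------------------------------------------------------------------
# Bridges to the analysis side
# ---------------------------------------------------------------------------

def assignments_from_truth(genome: GenomeAnnotation, families: dict) -> list[FamilyAssignment]:
    """Turn the truth's family membership into FamilyAssignment records
    (bypasses homology-based assignment; for tests and calibration)."""
    out = []
    for fam, gids in sorted(families.items()):
        for gid in gids:
            g = genome.gene(gid)
            out.append(
                FamilyAssignment(gid, fam, "truth", 1.0, g.chromosome,
                                 g.rank, g.rank, g.start, g.end)
            )
    out.sort(key=lambda a: (a.chromosome, a.rank))
    return out


@dataclass
class RecoveryReport:
    anchor_precision: float | None
    anchor_recall: float | None
    block_precision: float | None
    block_recall: float | None
    linkage_precision: float | None
    linkage_recall: float | None


def _jaccard(lo1, hi1, lo2, hi2) -> float:
    inter = min(hi1, hi2) - max(lo1, lo2) + 1
    union = max(hi1, hi2) - min(lo1, lo2) + 1
    return max(0, inter) / union if union > 0 else 0.0


def _block_matches(det, tb: TrueBlock) -> bool:
    return (
        det.chr_a == tb.chr_a
        and det.chr_b == tb.chr_b
        and _jaccard(det.start_a, det.end_a, tb.start_a, tb.end_a) >= 0.5
        and _jaccard(det.start_b, det.end_b, tb.start_b, tb.end_b) >= 0.5
    )


def evaluate_recovery(
    truth: SimTruth,
    detected_blocks: dict,
    detected_linkages: dict,
    self_blocks: bool = False,
) -> RecoveryReport:
    """Precision/recall of detected blocks/anchors/linkages against truth.

    ``detected_blocks`` maps (sp1, sp2) species pairs (or species, when
    ``self_blocks``) to lists of SyntenicBlock; ``detected_linkages`` maps
    species to lists of LinkageHit. A detected block recovers a true block
    when both rank spans overlap with Jaccard >= 0.5 on the same
    chromosome pair. Undefined ratios (empty denominator) are None.
    """
    for key in detected_blocks:
        sps = (key,) if isinstance(key, str) else key
        for sp in sps:
            if sp not in truth.species:
                raise ConfigError(f"species {sp!r} not in truth")
    for sp in detected_linkages:
        if sp not in truth.species:
            raise ConfigError(f"species {sp!r} not in truth")

    truth_pairs = truth.paralog_pairs if self_blocks else truth.homolog_pairs
    truth_blocks = truth.true_self_blocks if self_blocks else truth.true_blocks

    det_anchor_n = det_anchor_tp = 0
    true_anchor_sets = {}
    for key, blocks in detected_blocks.items():
        tp = truth_pairs.get(key, [])
        tset = {frozenset(p[:2]) for p in tp}
        true_anchor_sets[key] = tset
        for b in blocks:
            for a in b.anchors:
                det_anchor_n += 1
                if frozenset((a.gene_a, a.gene_b)) in tset:
                    det_anchor_tp += 1
    total_true_anchors = sum(len(v) for v in true_anchor_sets.values())
    recovered_true_anchors = 0
    for key, blocks in detected_blocks.items():
        det_set = {
            frozenset((a.gene_a, a.gene_b)) for b in blocks for a in b.anchors
        }
        recovered_true_anchors += len(true_anchor_sets[key] & det_set)

    det_block_n = det_block_tp = 0
    true_block_n = true_block_recovered = 0
    for key, blocks in detected_blocks.items():
        tbs = truth_blocks.get(key, [])
        true_block_n += len(tbs)
        for b in blocks:
            det_block_n += 1
            if any(_block_matches(b, tb) for tb in tbs):
                det_block_tp += 1
        for tb in tbs:
            if any(_block_matches(b, tb) for b in blocks):
                true_block_recovered += 1

    det_link_n = det_link_tp = 0
    true_link_n = true_link_recovered = 0
    for sp, hits in detected_linkages.items():
        tls = truth.true_linkages.get(sp, [])
        true_link_n += len(tls)
        for h in hits:
            det_link_n += 1
            if any(_linkage_matches(h, tl) for tl in tls):
                det_link_tp += 1
        for tl in tls:
            if any(_linkage_matches(h, tl) for h in hits):
                true_link_recovered += 1

    def ratio(num, den):
        return num / den if den else None

    return RecoveryReport(
        anchor_precision=ratio(det_anchor_tp, det_anchor_n),
        anchor_recall=ratio(recovered_true_anchors, total_true_anchors),
        block_precision=ratio(det_block_tp, det_block_n),
        block_recall=ratio(true_block_recovered, true_block_n),
        linkage_precision=ratio(det_link_tp, det_link_n),
        linkage_recall=ratio(true_link_recovered, true_link_n),
    )


def _linkage_matches(hit, tl: TrueLinkage) -> bool:
    if hit.chromosome != tl.chromosome:
        return False
    det_units = [set(hit.gene_a.split("_")), set(hit.gene_b.split("_"))]
    truth_genes = ({tl.gene_a}, {tl.gene_b})
    return (
        (truth_genes[0] & det_units[0] and truth_genes[1] & det_units[1])
        or (truth_genes[0] & det_units[1] and truth_genes[1] & det_units[0])
    ) != set()


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def easy_clade_config(
    seed: int = 0,
    n_genes: int = 500,
    n_chromosomes: int = 5,
    loss_rate: float = 0.4,
    subgenome_bias: float = 0.7,
    linkage_preservation: float = 0.0,
    branch_ds: float = 0.15,
) -> SimConfig:
    """Two sister species sharing one WGD, with per-species fractionation
    and divergence; two designated clock-like family linkages planted."""
    per_chrom = max(1, n_genes // n_chromosomes)
    placements = (
        Placement("FAM_MYB1", chromosome=0, rank=per_chrom // 3),
        Placement("FAM_PRR1", partner_family="FAM_MYB1", partner_gap=3),
        Placement("FAM_MYB2", chromosome=min(2, n_chromosomes - 1), rank=2 * per_chrom // 3),
        Placement("FAM_PRR2", partner_family="FAM_MYB2", partner_gap=5),
    )
    leafs = tuple(
        Lineage(
            name,
            events=(
                Fractionate(loss_rate, subgenome_bias, linkage_preservation),
                Diverge(branch_ds, 0.2),
            ),
        )
        for name in ("speciesA", "speciesB")
    )
    tree = Lineage("root", events=(Wgd(2, "wgd1"),), children=leafs)
    return SimConfig(
        n_genes=n_genes,
        n_chromosomes=n_chromosomes,
        tree=tree,
        family_placements=placements,
        seed=seed,
    )
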