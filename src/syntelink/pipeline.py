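"""End-to-end scan workflow: homology -> synteny -> linkage -> Ks.

`run_scan` reproduces the shape of a cross-species clock-gene linkage
survey: per genome, families are assigned from a seed panel; per genome
pair (including each genome against itself), filtered homolog pairs are
chained into syntenic blocks; linkage hits, copy tables, retention
summaries and permutation nulls are computed and written as deterministic
TSV/JSON reports plus a manifest recording parameters, seed and output
digests.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError, SynteLinkError
from .genome_io import GenomeAnnotation, read_annotation, write_table
from .homology import (
    SeedPanel,
    assign_families,
    builtin_score,
    cscore_filter,
    merge_split_models,
    read_pairwise_scores,
)
from .ksdating import block_ks, load_bins
from .linkage import (
    LinkageHit,
    family_copy_table,
    find_linkages,
    permutation_null,
    retention_summary,
)
from .synteny import anchors_from_pairs, chain_anchors, collapse_tandem, self_synteny

log = logging.getLogger("syntelink")

__all__ = ["RunConfig", "ScanReport", "run_scan"]


@dataclass
class GenomePaths:
    gff3: str
    protein_fasta: str
    cds_fasta: str | None = None


@dataclass
class RunConfig:
    outdir: str
    genome_paths: dict[str, GenomePaths] = field(default_factory=dict)
    seed_panel_path: str | None = None
    score_tables: dict[tuple[str, str], str] = field(default_factory=dict)
    cscore: float = 0.7
    min_pairs: int = 5
    max_gap: int = 20
    diag_offset: int = 30
    tandem_gap: int = 5
    merge_gap: int = 1
    min_family_c: float = 0.3
    kmer: int = 4
    max_intervening: int | None = 12
    max_bp: int | None = None
    compute_ks: bool = False
    ks_bins_path: str | None = None
    n_perm: int = 999
    null_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        genome_paths = {
            sp: GenomePaths(**entry) for sp, entry in (raw.pop("genomes", {}) or {}).items()
        }
        scores = {
            tuple(sorted((a, b))): p
            for a, b, p in (raw.pop("score_tables", []) or [])
        }
        null_pairs = [tuple(p) for p in raw.pop("null_pairs", []) or []]
        cfg = cls(genome_paths=genome_paths, score_tables=scores,
                  null_pairs=null_pairs, **raw)
        cfg.validate()
        return cfg

    def validate(self):
        for sp, gp in self.genome_paths.items():
            for p in (gp.gff3, gp.protein_fasta, gp.cds_fasta):
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"genome {sp!r}: path does not exist: {p}")
        for p in (self.seed_panel_path, self.ks_bins_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"path does not exist: {p}")


@dataclass
class ScanReport:
    outdir: Path
    genomes: dict
    assignments: dict
    blocks: dict  # (s1, s2) or species -> blocks (self when key is str)
    hits: dict  # species -> list[LinkageHit]
    copy_counts: object
    retention: object
    nulls: dict
    block_ages: dict
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except SynteLinkError as exc:
                raise SynteLinkError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("load-genomes")
def _load_genomes(config) -> dict[str, GenomeAnnotation]:
    out = {}
    for sp, gp in sorted(config.genome_paths.items()):
        out[sp] = read_annotation(gp.gff3, gp.protein_fasta, gp.cds_fasta, species_id=sp)
        log.info("  %s: %d genes on %d chromosomes", sp, out[sp].n_genes,
                 len(out[sp].chromosomes))
    return out


def _pair_scores(config, genomes, s1, s2):
    key = tuple(sorted((s1, s2)))
    if key in config.score_tables:
        return read_pairwise_scores(config.score_tables[key])
    return builtin_score(genomes[s1].proteins, genomes[s2].proteins, k=config.kmer)


def run_scan(
    config: RunConfig,
    genomes: dict[str, GenomeAnnotation] | None = None,
    seed_panel: SeedPanel | None = None,
) -> ScanReport:
    """Execute the full workflow and write the report bundle.

    ``genomes``/``seed_panel`` may be passed directly (e.g. straight from
    the simulator); otherwise they are loaded from the configured paths.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if genomes is None:
        genomes = _load_genomes(config)
    if not genomes:
        raise ConfigError("no genomes configured")
    if seed_panel is None:
        if config.seed_panel_path is None:
            raise ConfigError("no seed panel given")
        seed_panel = SeedPanel.from_tsv(config.seed_panel_path, genomes)

    species = sorted(genomes)
    written: list[Path] = []

    # --- families -----------------------------------------------------
    log.info("stage assign-families")
    assignments = {}
    for sp in species:
        raw = assign_families(genomes[sp], seed_panel, min_c=config.min_family_c,
                              k=config.kmer)
        for a in raw:
            if a.ambiguous:
                log.warning("ambiguous family assignment: %s (%s)", a.gene_id, a.family)
        assignments[sp] = merge_split_models(raw, genomes[sp], config.merge_gap)
        written.append(write_table(assignments[sp], outdir / f"families_{sp}.tsv"))

    # --- homology + synteny -------------------------------------------
    log.info("stage synteny")
    blocks: dict = {}
    for s1, s2 in itertools.combinations(species, 2):
        pairs = cscore_filter(_pair_scores(config, genomes, s1, s2), config.cscore)
        anchors = anchors_from_pairs(pairs, genomes[s1], genomes[s2])
        anchors, _ = collapse_tandem(anchors, config.tandem_gap)
        blocks[(s1, s2)] = chain_anchors(anchors, config.min_pairs, config.max_gap)
        written.append(
            write_table(blocks[(s1, s2)], outdir / f"blocks_{s1}__{s2}.tsv")
        )
    for sp in species:
        pairs = cscore_filter(_pair_scores(config, genomes, sp, sp), config.cscore)
        blocks[sp] = self_synteny(
            genomes[sp], pairs,
            min_diag_offset=config.diag_offset,
            min_pairs=config.min_pairs,
            max_gap=config.max_gap,
            max_tandem_gap=config.tandem_gap,
        )
        written.append(write_table(blocks[sp], outdir / f"selfblocks_{sp}.tsv"))

    # --- linkage -------------------------------------------------------
    log.info("stage linkage")
    families = sorted({a.family for asg in assignments.values()
                       for a in asg if not a.ambiguous})
    hits: dict[str, list[LinkageHit]] = {}
    for sp in species:
        sp_blocks = [b for key, bs in blocks.items()
                     for b in bs if key == sp or (isinstance(key, tuple) and sp in key)]
        sp_hits = []
        for fa, fb in itertools.combinations(families, 2):
            sp_hits.extend(
                find_linkages(
                    genomes[sp], assignments[sp], fa, fb,
                    max_intervening=config.max_intervening,
                    max_bp=config.max_bp,
                    blocks=sp_blocks,
                )
            )
        hits[sp] = sorted(sp_hits, key=lambda h: (h.chromosome, h.gene_a, h.gene_b))
    all_hits = [h for sp in species for h in hits[sp]]
    written.append(write_table(
        all_hits, outdir / "linkage_hits.tsv",
        columns=[f.name for f in LinkageHit.__dataclass_fields__.values()]
        if not all_hits else None,
    ))

    copy_counts, locations = family_copy_table(assignments)
    copy_counts.to_csv(outdir / "copy_table.tsv", sep="\t")
    locations.to_csv(outdir / "locations.tsv", sep="\t", index=False)
    written += [outdir / "copy_table.tsv", outdir / "locations.tsv"]

    observed_classes = tuple(sorted({h.linkage_class for h in all_hits})) or ("other",)
    retention = retention_summary(hits, observed_classes)
    with open(outdir / "retention.json", "w") as fh:
        json.dump(
            {
                "n_species": retention.n_species,
                "counts_per_class": dict(retention.counts_per_class),
                "has_at_least_one": retention.has_at_least_one,
                "has_both": retention.has_both,
                "has_more_than_one": retention.has_more_than_one,
            },
            fh, indent=1, sort_keys=True,
        )
    written.append(outdir / "retention.json")

    # --- permutation nulls ---------------------------------------------
    nulls = {}
    null_pairs = config.null_pairs or []
    for sp in species:
        for fa, fb in null_pairs:
            try:
                res = permutation_null(genomes[sp], assignments[sp], fa, fb,
                                       n_perm=config.n_perm, seed=config.seed)
            except SynteLinkError as exc:
                log.warning("null test skipped for %s %s-%s: %s", sp, fa, fb, exc)
                continue
            nulls[f"{sp}:{fa}-{fb}"] = {
                "observed_min_distance": (None if res.observed_min_distance == float("inf")
                                          else res.observed_min_distance),
                "n_perm": res.n_perm,
                "p_value": res.p_value,
                "seed": res.seed,
            }
    with open(outdir / "null_tests.json", "w") as fh:
        json.dump(nulls, fh, indent=1, sort_keys=True)
    written.append(outdir / "null_tests.json")

    # --- Ks dating ------------------------------------------------------
    block_ages = {}
    if config.compute_ks:
        log.info("stage ks-dating")
        for sp in species:
            if not genomes[sp].cds:
                raise SynteLinkError(
                    f"stage 'ks-dating' failed: no CDS sequences for species {sp!r}"
                )
        bins = load_bins(config.ks_bins_path) if config.ks_bins_path else []
        for key, bs in sorted(blocks.items(), key=str):
            ga, gb = (genomes[key], genomes[key]) if isinstance(key, str) else (
                genomes[key[0]], genomes[key[1]])
            ages = [block_ks(b, ga, gb, bins) for b in bs]
            for bk in ages:
                if bk.bin_label is None and bk.reason:
                    log.warning("block %s unlabeled: %s", bk.block_id, bk.reason)
            block_ages[key] = ages
            name = key if isinstance(key, str) else f"{key[0]}__{key[1]}"
            written.append(write_table(ages, outdir / f"block_ks_{name}.tsv"))

    manifest = _write_manifest(outdir, config, written)
    return ScanReport(outdir, genomes, assignments, blocks, hits, copy_counts,
                      retention, nulls, block_ages, manifest)


def _write_manifest(outdir: Path, config: RunConfig, written: list[Path]) -> dict:
    digests = {}
    for p in sorted(set(written)):
        digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    params = {
        k: v for k, v in vars(config).items()
        if isinstance(v, (int, float, str, bool, type(None)))
    }
    manifest = {
        "package": "syntelink",
        "version": __version__,
        "parameters": params,
        "seed": config.seed,
        "outputs": digests,
    }
    manifest["digest"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
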