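"""Genome annotation input/output and the ranked gene-order model.

A genome is reduced to an ordered list of protein-coding gene models per
chromosome. Every gene gets a 0-based *rank* among the protein-coding genes
of its chromosome (sorted by start coordinate, then gene ID), because the
linkage statistics of this package are expressed in "intervening genes"
rather than base pairs. Coordinates are kept 1-based inclusive as in GFF3.

One representative transcript per locus is chosen (largest summed CDS
length, ties broken by lexicographically smallest transcript ID), the
standard convention of synteny pipelines.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AnnotationError, IdMappingError, TranslationError

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "read_annotation",
    "write_table",
    "read_table",
    "write_fasta",
    "write_gff3",
]


@dataclass(frozen=True, order=True)
class GeneModel:
    """One protein-coding gene locus with rank coordinates."""

    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    rank: int  # 0-based ordinal among coding genes of the chromosome

    def __post_init__(self):
        if self.start > self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GenomeAnnotation:
    """Ranked protein-coding gene models plus sequences for one species."""

    species_id: str
    genes: dict[str, list[GeneModel]]  # chromosome -> genes sorted by rank
    proteins: dict[str, str] = field(default_factory=dict)
    cds: dict[str, str] = field(default_factory=dict)
    missing_protein: frozenset[str] = frozenset()

    def __post_init__(self):
        self._by_id = {g.gene_id: g for gs in self.genes.values() for g in gs}
        for chrom, gs in self.genes.items():
            ranks = [g.rank for g in gs]
            if ranks != list(range(len(gs))):
                raise AnnotationError(f"{chrom}: ranks not consecutive 0..n-1")

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.genes)

    @property
    def n_genes(self) -> int:
        return len(self._by_id)

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return self.genes[chromosome]

    def iter_genes(self):
        for chrom in self.chromosomes:
            yield from self.genes[chrom]


def _rank_genes(species_id, raw_genes) -> dict[str, list[GeneModel]]:
    by_chrom: dict[str, list] = {}
    for g in raw_genes:
        by_chrom.setdefault(g["chromosome"], []).append(g)
    out = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g["start"], g["gene_id"]))
        out[chrom] = [
            GeneModel(
                gene_id=g["gene_id"],
                chromosome=chrom,
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                rank=i,
            )
            for i, g in enumerate(gs)
        ]
    return out


def _check_cds(gene_id: str, cds: str, protein: str | None) -> None:
    if len(cds) % 3 != 0:
        raise AnnotationError(
            f"gene {gene_id}: CDS length {len(cds)} is not a multiple of 3"
        )
    if protein is None:
        return
    translated = str(Seq(cds).translate()).rstrip("*")
    expected = protein.rstrip("*")
    if translated != expected:
        pos = next(
            (i for i, (x, y) in enumerate(zip(translated, expected)) if x != y),
            min(len(translated), len(expected)),
        )
        raise TranslationError(
            f"gene {gene_id}: CDS does not translate to protein "
            f"(first mismatch at residue {pos})"
        )


def read_annotation(
    gff3_path,
    protein_fasta_path,
    cds_fasta_path=None,
    *,
    species_id: str | None = None,
    id_regex: str = r"^(.+?)\.\d+$",
    validate_cds: bool = True,
) -> GenomeAnnotation:
    """Read GFF3 + FASTA into a ranked :class:`GenomeAnnotation`.

    Parameters
    ----------
    gff3_path
        GFF3 annotation with gene/mRNA/CDS features.
    protein_fasta_path
        Protein FASTA; record IDs must resolve to gene or mRNA IDs,
        optionally after applying ``id_regex`` (first capture group).
    cds_fasta_path
        Optional CDS FASTA, same ID rules; needed only for Ks dating.
    species_id
        Defaults to the GFF3 file stem.
    """
    gff3_path = Path(gff3_path)
    species_id = species_id or gff3_path.stem
    _scan_gff3_coordinates(gff3_path)

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    raw_genes = []
    representative: dict[str, str] = {}  # mRNA id -> gene id
    gene_of_mrna: dict[str, str] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue  # non-coding locus: excluded from ranking
        best = None
        for m in mrnas:
            gene_of_mrna[m.id] = gene.id
            cds_len = sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))
            key = (-cds_len, m.id)
            if best is None or key < best[0]:
                best = (key, m.id)
        representative[best[1]] = gene.id
        raw_genes.append(
            {
                "gene_id": gene.id,
                "chromosome": gene.seqid,
                "start": gene.start,
                "end": gene.end,
                "strand": gene.strand if gene.strand in "+-" else "+",
            }
        )
    if not raw_genes:
        raise AnnotationError(f"{gff3_path}: no gene features with mRNA children")

    genes = _rank_genes(species_id, raw_genes)
    gene_ids = {g["gene_id"] for g in raw_genes}

    def resolve(fasta_id: str) -> str | None:
        for candidate in (fasta_id,):
            if candidate in representative:
                return representative[candidate]
            if candidate in gene_of_mrna:  # non-representative isoform
                return ""
            if candidate in gene_ids:
                return candidate
        m = re.match(id_regex, fasta_id)
        if m:
            c = m.group(1)
            if c in representative:
                return representative[c]
            if c in gene_of_mrna:
                return ""
            if c in gene_ids:
                return c
        return None

    proteins: dict[str, str] = {}
    unresolved: list[str] = []
    for rec in SeqIO.parse(str(protein_fasta_path), "fasta"):
        target = resolve(rec.id)
        if target is None:
            unresolved.append(rec.id)
        elif target:
            proteins[target] = str(rec.seq).rstrip("*")
    if unresolved:
        shown = ", ".join(unresolved[:10])
        raise IdMappingError(
            f"{len(unresolved)} protein FASTA IDs could not be mapped to "
            f"{gff3_path.name} gene IDs (first 10: {shown})"
        )

    cds: dict[str, str] = {}
    if cds_fasta_path is not None:
        for rec in SeqIO.parse(str(cds_fasta_path), "fasta"):
            target = resolve(rec.id)
            if target is None:
                unresolved.append(rec.id)
            elif target:
                seq = str(rec.seq).upper()
                if validate_cds:
                    _check_cds(target, seq, proteins.get(target))
                cds[target] = seq
        if unresolved:
            shown = ", ".join(unresolved[:10])
            raise IdMappingError(
                f"{len(unresolved)} CDS FASTA IDs could not be mapped "
                f"(first 10: {shown})"
            )

    missing = frozenset(gid for gid in gene_ids if gid not in proteins)
    return GenomeAnnotation(
        species_id=species_id,
        genes=genes,
        proteins=proteins,
        cds=cds,
        missing_protein=missing,
    )


def _scan_gff3_coordinates(path: Path) -> None:
    """Cheap pre-scan so malformed coordinates fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 1 or start > end:
                raise AnnotationError(
                    f"{path}:{lineno}: invalid coordinate range {start}..{end}"
                )


# ---------------------------------------------------------------------------
# Tabular report output
# ---------------------------------------------------------------------------

def _record_rows(records) -> tuple[list[str], list[dict]]:
    first = records[0]
    if not dataclasses.is_dataclass(first):
        raise TypeError("write_table expects a list of dataclass records")
    rtype = type(first)
    if any(type(r) is not rtype for r in records):
        raise TypeError("write_table expects records of a single type")
    columns = [f.name for f in dataclasses.fields(rtype) if not f.name.startswith("_")]
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        rows.append({c: _cell(d[c]) for c in columns})
    rows.sort(key=lambda row: tuple(str(row[c]) for c in columns))
    return columns, rows


def _cell(value):
    if isinstance(value, (list, tuple)):
        return ";".join(str(v) for v in value)
    if value is None:
        return ""
    return value


def write_table(records, path, format: str = "tsv", columns: list[str] | None = None):
    """Write a homogeneous list of dataclass records to TSV or JSON.

    The column order is the dataclass field order; rows are sorted by the
    stringified tuple of all columns, so identical inputs always produce
    byte-identical files. An empty list with explicit ``columns`` produces
    a header-only table.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown table format {format!r}")
    path = Path(path)
    if records:
        columns, rows = _record_rows(list(records))
    else:
        columns, rows = (columns or []), []
    if format == "tsv":
        df = pd.DataFrame(rows, columns=columns)
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    else:
        with open(path, "w") as fh:
            json.dump({"columns": columns, "rows": rows}, fh, indent=1, default=str)
            fh.write("\n")
    return path


def read_table(path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    with open(path) as fh:
        payload = json.load(fh)
    return pd.DataFrame(payload["rows"], columns=payload["columns"])


# ---------------------------------------------------------------------------
# Writers used to emit simulated genomes in standard formats
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


def write_gff3(genome: GenomeAnnotation, path) -> Path:
    """Write gene/mRNA/CDS features; round-trips through read_annotation."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in genome.chromosomes:
            for g in genome.genes_on(chrom):
                base = f"{chrom}\tsyntelink\t"
                coords = f"{g.start}\t{g.end}\t.\t{g.strand}\t"
                fh.write(f"{base}gene\t{coords}.\tID={g.gene_id}\n")
                mrna = f"{g.gene_id}.1"
                fh.write(f"{base}mRNA\t{coords}.\tID={mrna};Parent={g.gene_id}\n")
                fh.write(f"{base}CDS\t{coords}0\tID={mrna}.cds;Parent={mrna}\n")
    return path
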