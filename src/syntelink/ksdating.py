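"""Codon-aware alignment and Nei-Gojobori (1986) Ka/Ks estimation.

Syntenic blocks are dated by the synonymous divergence (Ks) of their anchor
pairs: proteins are globally aligned with affine gap penalties, the
alignment is back-translated codon-wise onto the CDS, and synonymous /
nonsynonymous proportions are converted to rates with the Jukes-Cantor
multiple-hit correction,

    Ks = -(3/4) ln(1 - (4/3) ps),   ps = sd / S,

where S is the (fractional) number of potential synonymous sites averaged
over both sequences and sd the observed synonymous differences averaged
over all shortest mutational paths of each codon (paths through stop
codons excluded). ps >= 3/4 marks the pair saturated. Block Ks is the
median over non-saturated anchors and is placed into user-configured Ks
intervals (WGD bins); the shipped example bin file is illustrative, not a
calibrated timescale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._codons import is_valid_codon, path_averaged_differences, synonymous_sites
from .errors import SynteLinkError, TranslationError

__all__ = [
    "CodonAlignment",
    "KsEstimate",
    "WgdBin",
    "codon_align",
    "ng86",
    "block_ks",
    "load_bins",
]


@dataclass
class CodonAlignment:
    gene_a: str
    gene_b: str
    columns: list[tuple[str | None, str | None]]  # None marks a gap
    score: float

    @property
    def n_ungapped(self) -> int:
        return sum(1 for ca, cb in self.columns if ca and cb)


@dataclass
class KsEstimate:
    gene_a: str
    gene_b: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    saturated: bool
    n_codons: int  # usable codon columns
    n_blocked: int  # codons skipped because all paths hit stops


@dataclass(frozen=True)
class WgdBin:
    label: str
    lo: float
    hi: float  # half-open interval [lo, hi)
    age_mya: float | None = None


@dataclass
class BlockKs:
    block_id: str
    ks: float | None
    bin_label: str | None
    n_anchors_used: int
    reason: str | None = None


def _check_translation(name: str, protein: str, cds: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(f"{name}: CDS length {len(cds)} not a multiple of 3")
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
        cds = cds[:-3]
    protein = protein.rstrip("*")
    if aa != protein:
        pos = next(
            (i for i, (x, y) in enumerate(zip(aa, protein)) if x != y),
            min(len(aa), len(protein)),
        )
        raise TranslationError(
            f"{name}: CDS does not translate to protein (mismatch at residue {pos})"
        )
    return cds


def codon_align(
    protein_a: str,
    protein_b: str,
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
    substitution_matrix_name: str = "BLOSUM62",
) -> CodonAlignment:
    """Protein-guided codon alignment (global, affine gaps, back-translated)."""
    cds_a = _check_translation(gene_a, protein_a, cds_a)
    cds_b = _check_translation(gene_b, protein_b, cds_b)
    protein_a = protein_a.rstrip("*")
    protein_b = protein_b.rstrip("*")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix_name)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(protein_a, protein_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    columns: list[tuple[str | None, str | None]] = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        codon_a = codon_b = None
        if ca != "-":
            codon_a = cds_a[3 * ia : 3 * ia + 3]
            ia += 1
        if cb != "-":
            codon_b = cds_b[3 * ib : 3 * ib + 3]
            ib += 1
        columns.append((codon_a, codon_b))
    return CodonAlignment(gene_a, gene_b, columns, float(aln.score))


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(alignment: CodonAlignment, min_codons: int = 10) -> KsEstimate:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Potential sites are averaged over both sequences; multi-substitution
    codons average their synonymous/nonsynonymous differences over all
    shortest mutational paths that avoid stop codons. Codons whose paths
    are all blocked by stops are skipped (and counted in n_blocked).
    """
    S = N = sd = nd = 0.0
    n_codons = 0
    n_blocked = 0
    for ca, cb in alignment.columns:
        if ca is None or cb is None:
            continue
        if not (is_valid_codon(ca) and is_valid_codon(cb)):
            continue
        diffs = path_averaged_differences(ca, cb)
        if diffs is None:
            n_blocked += 1
            continue
        s_here = (synonymous_sites(ca) + synonymous_sites(cb)) / 2.0
        S += s_here
        N += 3.0 - s_here
        sd += diffs[0]
        nd += diffs[1]
        n_codons += 1
    if n_codons < min_codons:
        raise SynteLinkError(
            f"{alignment.gene_a}/{alignment.gene_b}: only {n_codons} usable codon "
            f"columns (< {min_codons})"
        )
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jc(ps)
    ka = _jc(pn)
    return KsEstimate(
        gene_a=alignment.gene_a,
        gene_b=alignment.gene_b,
        s_sites=S,
        n_sites=N,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        saturated=ks is None,
        n_codons=n_codons,
        n_blocked=n_blocked,
    )


def pair_ks(genome_a, genome_b, gene_a: str, gene_b: str, **align_kwargs) -> KsEstimate:
    """Convenience: codon-align two annotated genes and run NG86."""
    for genome, gid in ((genome_a, gene_a), (genome_b, gene_b)):
        if gid not in genome.cds:
            raise SynteLinkError(f"no CDS for {gid} in {genome.species_id}")
    aln = codon_align(
        genome_a.proteins[gene_a],
        genome_b.proteins[gene_b],
        genome_a.cds[gene_a],
        genome_b.cds[gene_b],
        gene_a=gene_a,
        gene_b=gene_b,
        **align_kwargs,
    )
    return ng86(aln)


def block_ks(
    block,
    genome_a,
    genome_b,
    bins: list[WgdBin] | None = None,
    min_anchors: int = 3,
) -> BlockKs:
    """Block-level Ks (median over non-saturated anchors) and WGD bin label.

    Blocks with fewer than ``min_anchors`` usable anchor estimates stay
    unlabeled with a reason. Anchors without CDS are skipped.
    """
    values = []
    for a in block.anchors:
        try:
            est = pair_ks(genome_a, genome_b, a.gene_a, a.gene_b)
        except SynteLinkError:
            continue
        if not est.saturated:
            values.append(est.ks)
    if len(values) < min_anchors:
        return BlockKs(block.block_id, None, None,
                       len(values), f"only {len(values)} usable anchors (< {min_anchors})")
    values.sort()
    mid = len(values) // 2
    med = values[mid] if len(values) % 2 else (values[mid - 1] + values[mid]) / 2.0
    label = None
    for b in bins or ():
        if b.lo <= med < b.hi:
            label = b.label
            break
    return BlockKs(block.block_id, med, label, len(values))


def load_bins(path) -> list[WgdBin]:
    """Read a WGD bin config TSV: label, lo, hi[, age_mya]; intervals must
    not overlap."""
    bins = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise SynteLinkError(f"{path}:{lineno}: expected >=3 columns")
            age = float(cols[3]) if len(cols) > 3 and cols[3] else None
            bins.append(WgdBin(cols[0], float(cols[1]), float(cols[2]), age))
    bins.sort(key=lambda b: b.lo)
    for prev, cur in zip(bins, bins[1:]):
        if cur.lo < prev.hi:
            raise SynteLinkError(
                f"overlapping Ks bins: {prev.label} [{prev.lo},{prev.hi}) and "
                f"{cur.label} [{cur.lo},{cur.hi})"
            )
    return bins


def example_bins_path() -> Path:
    return Path(__file__).parent / "data" / "ks_bins_example.tsv"
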