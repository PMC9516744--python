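"""Standard genetic code tables and per-codon synonymous-site fractions.

Shared by the Ks estimator and the sequence-evolution simulator. Only the
standard nuclear code is supported; stop-producing single-nucleotide changes
count as nonsynonymous so that synonymous + nonsynonymous potential sites
always sum to 3 per codon.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

NUCLEOTIDES = "ACGT"

# Standard genetic code, '*' marks stop.
GENETIC_CODE = {
    "".join(c): aa
    for c, aa in zip(
        product("TCAG", repeat=3),
        "FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR" "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG",
    )
}

CODONS = sorted(GENETIC_CODE)
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon]


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Potential synonymous sites of one codon (NG86 convention).

    Each of the three positions contributes (number of synonymous
    single-nucleotide changes) / 3; changes producing a stop codon are
    nonsynonymous. Returns a value in [0, 3]; nonsynonymous sites are
    3 minus this.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if GENETIC_CODE[alt] == aa and alt not in STOP_CODONS:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def path_averaged_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Synonymous/nonsynonymous differences between two codons (NG86).

    Averages over every shortest mutational path between the codons,
    excluding paths that pass through a stop codon. Returns (sd, nd), or
    None when every path is blocked by stops.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)
    syn_tot = 0.0
    nonsyn_tot = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = codon_a
        syn = 0.0
        nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        if not blocked:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return (syn_tot / n_paths, nonsyn_tot / n_paths)


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(nt in NUCLEOTIDES for nt in codon)
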