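# Methods

This note documents the models, defaults and numerical choices behind
`syntelink`, and what the simulation-based tests do and do not establish.

## Gene-order model

A genome is reduced to ranked protein-coding gene models: per chromosome,
genes are sorted by start coordinate (ties by gene ID) and given
consecutive 0-based ranks. Only loci with mRNA+CDS children participate;
non-coding genes are excluded both from ranking and from intervening-gene
counts, because the linkage statistic is defined against the
protein-coding gene order that synteny detection itself operates on.
Coordinates stay 1-based inclusive (GFF3 native). One representative
transcript per locus is chosen by largest summed CDS length, ties by
lexicographically smallest transcript ID — the convention of common
synteny pipelines, as annotation databases differ in how they flag
primary transcripts.

The distance between two loci is the number of protein-coding genes
strictly between them, `|rank_a - rank_b| - 1`. Published descriptions of
the same gene pairs sometimes differ by one depending on whether an
endpoint is counted; strict between-counting is used consistently here. A
merged split gene model (below) counts as a single gene and none of its
constituents are counted as intervening.

## Homology and C-score

External all-by-all alignments are read from 12-column tabular files
(column 12 = score; duplicate rows keep the max; self-hits dropped). The
C-score of a pair divides its score by the larger of the two genes' best
scores; pairs with C >= 0.7 are kept by default, boundary inclusive. The
"either genome" phrasing of the original filter is ambiguous between max
and min of the two best scores; max is the stricter reading and the one
implemented.

The built-in scorer counts shared amino-acid k-mers (multiset
intersection, k = 4). It exists so simulated and toy data need no
external aligner; it is not a substitute for a real aligner at proteome
scale, though at the divergences the simulator produces (dS <= 1, i.e.
roughly >= 85% protein identity) it separates homologs from noise by two
orders of magnitude.

Family assignment is seed-anchored rather than cluster-based: each gene
joins the family of its best-C-score seed protein if C >= `min_c`
(default 0.3). For this search the denominator's best scores are floored
at each sequence's self k-mer count — the attainable maximum — so an
exact seed copy scores C = 1.0 while spurious single-k-mer matches score
near 0. Ties across families mark the gene ambiguous and exclude it from
linkage scans. Runs of same-family gene models within `max_gap_ranks`
(default 1) on one chromosome are merged into a compound unit
(`A_B`-style ID, min-start/max-end span, min rank), repairing loci split
during gene prediction; the default of 1 reflects that observed split
models are adjacent.

## Syntenic block chaining

Anchors (rank-coordinated filtered pairs) are chained per chromosome pair
by sparse dynamic programming: within a chain, ranks increase strictly on
the query and are strictly monotone on the subject (increasing for `+`
blocks, decreasing for `-`), and consecutive anchors differ by at most
`max_gap` ranks (default 20) on both sides. Chains need `min_pairs`
anchors (default 5). These are the classic collinearity-tool defaults
("five syntenic pairs per 20-gene block"); the gap rule is enforced as a
maximum rank gap between consecutive anchors, not a fixed window
partition, matching DAGchainer semantics.

Block score is the plain sum of anchor scores (no gap penalty): the DP
state is (anchor, chain length capped at `min_pairs`), which lets the
maximum-score chain of length >= `min_pairs` be recovered exactly; this
is verified against exhaustive enumeration of all valid chains on random
anchor sets. Blocks are extracted greedily in order of decreasing chain
score (ties by chromosome and start rank, `+` before `-`), each anchor
used at most once, so output is deterministic.

Tandem arrays are collapsed before chaining: anchors sharing a partner
gene whose members lie within `max_tandem_gap` ranks (default 5) keep
only the highest-scoring member. Self-synteny removes near-diagonal
anchors first (same chromosome, rank offset < `min_diag_offset`, default
30) so tandem arrays and residual self-matches cannot seed blocks; 30
exceeds the tandem-array scale by design while preserving genuine
intra-chromosomal WGD blocks, and is exposed as a parameter. Duplicate
copies are classified syntenic (anchor of a retained block), tandem
(same-family copy within the tandem gap), or dispersed.

## Linkage statistics

`find_linkages` reports every cross-family same-chromosome pair passing
all given thresholds — gene-count mode (`max_intervening`, default 12,
the angiosperm screen) and/or bp mode (`max_bp`, start-to-start, for
sparse Mb-scale linkage in bryophyte and gymnosperm genomes). All
qualifying pairs are reported, not just the closest; retention summaries
deduplicate per species and class. Combinations are labelled with the
sMYB (or PIF) member first; the eight canonical sMYB–PRR gene pairs are
enumerated, clade-level or cross-clade pairs are labelled but flagged
non-canonical, and labels outside the clock/light vocabulary are only
accepted in non-strict mode (used for simulated families).

Retention fractions over species — at least one linkage in any class,
linkages in every class, more than one linkage in a single class — are
rounded to 0.1%.

The permutation null shuffles family labels uniformly over the genome's
rank slots (family sizes and chromosome gene counts preserved); the
statistic is the genome-wide minimum cross-family intervening distance,
with "never co-chromosomal" treated as larger than any finite value. The
p-value uses the add-one estimator `p = (1 + #{perm <= obs}) / (n_perm +
1)`, which cannot return 0 and is mildly conservative in the presence of
ties. Calibration: on neutral genomes (400 genes, 2 chromosomes, two
3-copy families placed uniformly at random) the p-values are uniform; a
Kolmogorov–Smirnov check over 200 replicate genomes at the 1% level is
part of the acceptance suite. Because the null is tested at its nominal
level, a small fraction of seeds is expected to produce KS p-values below
any fixed threshold.

## Ks estimation and block dating

Proteins are globally aligned (BLOSUM62, gap open -10, extend -0.5,
Biopython's pairwise aligner, verified against an independent Gotoh
implementation) and back-translated codon-wise; gap columns are dropped.
NG86 sites: per codon, each position contributes the fraction of its
three single-nucleotide changes that are synonymous, counting
stop-producing changes as nonsynonymous, so S + N = 3 x (usable codons)
exactly, averaged over both sequences. Differences at multi-substitution
codons are averaged over all shortest mutational paths, excluding paths
through stop codons; codons whose paths are all blocked are skipped and
counted. Jukes–Cantor correction is applied; ps >= 3/4 flags saturation.
At least 10 usable codon columns are required (configurable). The
estimator matches a brute-force path-enumeration oracle to 1e-9 and
recovers simulated dS of 0.1/0.5/1.0 within a few percent (median over
200 pairs of 300 codons).

Block Ks is the median over non-saturated anchor estimates, requiring at
least 3 usable anchors (else the block stays unlabeled with a reason).
WGD bins are user configuration — published events are dated in Ma, not
universal Ks cutoffs, so the shipped bin file is explicitly illustrative
and should be set from the Ks distribution of the genomes at hand.

## Simulator

The simulator exists to give the pipeline a closed-loop test with known
truth. An ancestral genome of unrelated random coding genes (uniform
150–400 codons by default) is distributed over chromosomes; designated
families are planted at fixed positions, optionally at a fixed
intervening-gene distance from a partner family (a designated linkage). A
species tree of branches carries ordered events:

* **Wgd(m)** copies every chromosome (m = 2 or 3), tags subgenomes, and
  records duplicate groups with an event label and time.
* **Fractionate(loss_rate, subgenome_bias, linkage_preservation)** makes
  one loss attempt per surplus member of each surviving duplicate group
  of the most recent polyploidy: with probability `loss_rate` a member is
  deleted, drawn from the disfavoured (newest) subgenome with probability
  `subgenome_bias`; a victim whose family participates in a designated
  linkage (partner-family copy within `linkage_window`, default 25
  intervening genes, on the same chromosome) is spared with probability
  `linkage_preservation`. This parameter is the explicit handle on
  preferential retention of linked genes: 0 gives neutral loss (used for
  null calibration), 1 makes every designated linkage survive.
  Singletons are immune, matching post-polyploidy gene-loss biology;
  bookkeeping is exact (genes after = genes before - losses).
* **Invert / Translocate** rearrange contiguous spans (geometric span
  lengths, chromosomes drawn by size).
* **TandemDuplicate(rate)** inserts adjacent copies.
* **Diverge(ds, dn_ds)** evolves every CDS by uniform single-nucleotide
  proposals — stop-creating proposals rejected, synonymous accepted,
  nonsynonymous accepted with probability `dn_ds` — until the count of
  synonymous events reaches `ds` x (potential synonymous sites). Because
  events accumulate linearly while the estimator applies the multiple-hit
  correction, estimated Ks tracks the nominal dS across the tested range.

All randomness flows through one seeded generator with a fixed traversal
order, so identical configurations give byte-identical output. Ground
truth comprises: ortholog pairs (shared ancestor at the two leaves'
split), root-level homolog pairs (shared ancestor at time 0, which
includes cross-species homeologs — the set detection is scored against),
paralog pairs per event, true blocks (greedy direction-consistent
collinear runs over truth anchors, gap <= 20, >= 5 pairs — a deliberately
simpler algorithm than the detection DP), and true linkage states for
designated family pairs within the linkage window.

The standard test regime ("easy"): two sister species, one shared WGD,
per-species fractionation at loss 0.4 / bias 0.7, dS 0.15 per terminal
branch, two designated linkages with 3- and 5-gene gaps, 500 ancestral
genes over 5 chromosomes (problem sizes chosen to exercise every code
path at desk scale). On it the pipeline reaches block and linkage recall
of 1.0.

**What the simulator does not emulate:** real intron/UTR structure and
annotation noise beyond split models, transposons and segmental
duplications, gene-length and GC heterogeneity, codon-usage bias,
rate variation among sites and lineages, gene conversion between
homeologs, and assembly artefacts. Passing recovery tests therefore
demonstrates the correctness of the detection chain under its own model
assumptions, not field performance on real annotations; on real genomes
the external-aligner route (12-column tables) should be used and
parameters reviewed against the genome's Ks and tandem landscape.

## Design notes and limitations

* The C-score boundary is inclusive; with >=-semantics the filter is
  anti-monotone in the threshold (tested property).
* Permutation p-values use "<= observed" tie counting; with heavily
  discrete statistics this is conservative, never anti-conservative.
* Block extraction is greedy over chain scores; a globally optimal
  non-overlapping chain cover is not attempted (the classic tools do not
  either), so in pathological overlapping-diagonal cases block boundaries
  can differ from an optimal partition.
* `block_ks` dates blocks by median anchor Ks only; no mixture-model
  decomposition of multi-peak Ks distributions.
* The CLI is a thin layer; the library API and `examples/` are the
  primary interface.
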