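# Methods

This note documents the models, conventions and numerical choices behind
`synsel`, what the synthetic-data generator does and does not emulate, and
the problem sizes used by the test suite and the acceptance script.

## Setting and assumptions

The package targets gene families in which every member encodes the *same*
protein (duplicate genes with an invariant product, and their orthologs in
other species). Under that premise:

* every CDS translates cleanly under the standard nuclear genetic code
  (the code table is a fixed internal constant; alternative codes are out
  of scope);
* codon-level multiple alignment of equal-length, identical-protein CDSs is
  the trivial column stacking — no aligner heuristics enter the headline
  statistics;
* all between-gene differences are synonymous, so selection is measured on
  synonymous sites directly rather than through dN/dS (which is undefined
  without amino-acid variation).

Inputs that violate the premise are still handled where meaningful:
non-identical proteins are codon-aligned by back-translating a protein-level
global alignment into whole-codon gaps (pairwise, or reference-guided with
insertions merged per reference position for more than two sequences).

## Sequence comparison

**Pairwise alignment.** Global (Needleman–Wunsch) with affine gaps, backed
by Biopython's `PairwiseAligner`. A gap run of length L costs
`gap_open + (L−1)·gap_extend`. Defaults: nucleotides match +2 / mismatch −1
/ open −5 / extend −1; proteins BLOSUM62 with open −11 / extend −1. End
gaps are penalised (true global mode). Among co-optimal alignments the
aligner's first traceback is returned — deterministic across runs and
platforms; all downstream scores depend only on the optimal score and the
gap-excluded columns, which are robust to tie choice. The test suite checks
optimality against a brute-force enumeration of all alignments for short
sequences.

**Gap-excluded identity.** `identity = 1 − M/N`, with N the columns where
neither row has a gap and M the mismatching ones among them. Columns with a
gap in either row contribute to neither term, so insertions and deletions
cannot deflate the score — the property that makes the measure stable for
indel-rich 3'UTRs. When N = 0 the score is undefined and an error is
raised rather than returning 0.

**Substitution score.** Mismatching gap-free columns divided by all
gap-free columns of the codon alignment. For the focal case (equal-length
identical-protein CDSs) the denominator equals the CDS length. Under indels
the gap-free-column denominator is the only choice consistent with the
identity formula above.

## Conservation statistics

A codon alignment column is classified per codon: third positions are
*wobble* when the codon tolerates ≥ 2 synonymous bases in **every** row,
and *fourfold degenerate* when all four bases are synonymous in every row —
"any possible substitution is synonymous" must hold for every organism
counted. Codon columns containing a gap or a stop codon in any row are
excluded from all site counts, as is GC3's terminal stop: stop codons are
not wobble-classified sense codons. "Third position" reports count all
third positions (wobble-only is available as an option).

A site is *absolutely conserved* when every row carries the identical
nucleotide. Reports carry raw counts so frequencies and the
paralog-A/paralog-B frequency ratio (FreqA/FreqB) are always recomputable;
a zero-site report carries an undefined frequency, never a silent 0.

**Rank-sum test.** Mann–Whitney U via scipy: exact null distribution when
the smaller group has ≤ 8 observations and there are no ties; otherwise
tie-corrected normal approximation with continuity correction. The switch
point makes p-values reproducible at the small group sizes typical of
per-clade score comparisons. Degenerate input (all values identical)
returns p = 1 with a warning.

**Distance distributions.** Bimodality of substitution-score distributions
(within-clade vs between-clade pairs) is reported descriptively via the
per-group tables; no mixture model is fitted.

## Codon usage

Two metrics: *amino-acid specific codon frequencies* (count of a codon
divided by the count of its amino acid — the conditional probability
P(codon | amino acid)) and raw *codon frequencies* (count divided by total
codons). Conventions that matter:

* Codons of amino acids absent from a gene are **undefined** under the
  aa-specific metric (a conditional with no conditioning events), not zero;
  correlations drop such dimensions pairwise. Zero-imputation would distort
  r for short genes.
* Under the aa-specific metric, single-codon amino acids (Met, Trp) are
  excluded from correlation vectors by default: their frequency is the
  constant 1 in every gene and only inflates r. All 61 sense codons are
  retained under raw frequencies. Both filters are configurable, and every
  correlation reports the number of codon dimensions used.
* Gene-set profiles pool counts across member genes before normalising
  (long genes weigh proportionally); a mean-of-profiles variant is not the
  default.
* When a benchmarked gene belongs to a program set, its own counts are
  removed from that set's pooled profile (leave-one-out) to avoid
  self-correlation bias; switchable off.
* Program assignment is the argmax of the focal gene's correlation over
  program profiles, flagged ambiguous on ties; the gene's rank percentile
  within each program's own-member benchmark distribution is reported
  alongside.

The pipeline also reports, per supplied gene set, the mean correlation of
its member genes with the genome-wide profile — supplying a
ubiquitously-expressed (housekeeping) gene list here yields the
broad-expression calibration line against which focal genes are read; a
"calibration subset" is simply a second list. No gene lists ship with the
package.

Genome-wide profiles are parsed from Kazusa-layout codon usage tables
(codon, per-mille, count triplets; RNA or DNA spelling); all 64 codons are
required and stop codons are dropped from the profile.

## Synteny

Neighborhoods take at most `n_genes` = 30 flanking genes per side **and**
only genes within `window_bp` = 1.5 Mb of the focal gene's span (both caps
apply simultaneously; both configurable). Strand affects only the
upstream/downstream labels, not membership — the comparison treats the two
flanking sets as unordered; collinearity is not scored.

Every query flanking gene is aligned against every reference flanking gene
at the CDS and protein level; the maxima of each identity are recorded
independently (so both are monotone non-decreasing as references are
pooled). A query gene is *syntenic* when its best protein identity with
≥ 50% coverage of the shorter protein is ≥ 0.40 and its best CDS identity
is ≥ 0.50. These thresholds are a package choice — in simulation they
separate orthologs at ≤ 20% synonymous + ≤ 10% nonsynonymous divergence
from unrelated decoy genes with sensitivity ≥ 0.95 and false-positive rate
≤ 0.05 — and are echoed into output metadata. Pooled references
deduplicate by gene id only; paralogs with distinct ids are retained.

## Synthetic data: what it emulates, and what it does not

The generator stands in for a database retrieval of ortholog panels,
annotations and gene sets. Design choices:

* **Codon-space substitution.** Synonymous evolution resamples one codon
  among its synonyms per event (Poisson event count with mean
  branch_length × number of codons with > 1 synonym, so branch length is
  calibrated in events per wobble-capable codon). Protein invariance holds
  by construction. Events may redraw the current codon and may hit a site
  repeatedly, so observed divergence saturates below the event count,
  Jukes–Cantor-style. Not modelled: transition/transversion bias, CpG
  effects, position-heterogeneous rates beyond the synonymous constraint.
* **Trees.** A star tree (default 8 tips, branch length 0.05) or any
  newick tree, in which case each tip evolves along its root-to-tip depth
  as one compound branch — adequate for statistics that treat tips within
  a paralog as exchangeable, but it does not generate the covariance
  structure of shared internal branches.
* **Paralog rates.** Default multipliers 1 (paralog A) and 5 (paralog B):
  a strongly conserved copy against a faster one, the regime the
  conservation statistics are designed to detect.
* **Default protein.** A fixed 136-residue sequence of proteome-average
  composition (H3.3-like length), generated once and hard-coded; it is
  synthetic, not a database sequence. Any protein can be supplied.
* **Codon-bias targets.** aa-specific profiles with Dirichlet(0.5)-sampled
  synonym preferences per amino acid; independently drawn profiles differ
  by a mean per-amino-acid Jensen–Shannon divergence of ≈ 0.2–0.35
  (base 2), comfortably above the ≥ 0.05 regime in which program recovery
  is asserted. Program genes draw every codon from their program profile;
  the synthetic genome-wide table pools genes drawn from the equal-weight
  mixture of the program profiles (a broad, unspecialised usage).
* **Neighborhoods.** Planted orthologs diverge by synonymous evolution at
  0.2 events per wobble codon plus 5% per-residue nonsynonymous noise;
  decoys are unrelated random-protein genes (default 100 residues,
  i.e. 300 bp of CDS); genes are evenly spaced (30 kb) on one
  chromosome. CDSs never receive indels.
* **3'UTRs.** Per-site substitutions (default 0.25) and Poisson indels
  (rate 0.02/site, geometric lengths of mean 3) on 500-base UTRs — chosen
  to reproduce the ~60–80% identity band typical of conserved vertebrate
  3'UTRs while exercising the gap-exclusion property.
* **Determinism.** All randomness derives from one integer seed via named
  substreams (seed + CRC32 of a key path), so outputs are byte-identical
  across runs and independent of iteration order. The truth file records
  generating profiles, every substitution event per branch (replayable to
  the exact tip sequences), ortholog pairings, and UTR edit lists.

Because decoys are unrelated random sequences and substitution processes
are homogeneous, passing the planted-truth tests demonstrates internal
consistency and statistical power in a clean regime — not robustness to
real-data complications such as paralogy gradients, GC-biased gene
conversion, alignment error from real indel patterns, or
annotation-version differences.

## Problem sizes

Test suite: selection-strength and synteny recovery use 200 seeded
replicates at the default conditions (8-tip families; 10 planted + 20
decoys per side); rank-sum calibration uses 10,000 null replicates of
20 vs 20; program recovery uses 200 genes per program of 136 codons. The
acceptance script uses 100 family replicates, 40 synteny replicates, 50
UTR replicates and 5,000 null replicates, with all other conditions
identical; each reported value is recomputed from scratch at run time from
the given seed.

## Known limitations

* Identity scores shift by a few percent under different gap penalties;
  the defaults are fixed and recorded, but cross-tool comparisons should
  expect small offsets.
* The exact codon-dimension convention (61 vs 59 codons, per-amino-acid
  weighting) materially affects absolute correlation values between
  published analyses; `n_codons` is reported with every correlation to
  keep the choice auditable.
* The reference-guided multiple codon alignment for non-identical proteins
  is adequate for near-identical products but is not a general-purpose MSA.
* Synteny thresholds are calibrated on the synthetic decoy model; real
  annotations with paralog families may need stricter settings.
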