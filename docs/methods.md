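# Methods

## Data model

A transcriptional regulatory network (TRN) is a directed graph of
transcription factors (TFs) regulating target genes (TGs), with targets
grouped into transcription units (TUs) — genes co-transcribed from one
promoter. All TF–TF interactions are excluded before analysis: edges whose
target is a TF are removed, and a TF left without non-TF targets is dropped.
A TF that is itself somebody's target keeps its TF role and never enters any
TG set, because the analysis compares regulators only with non-regulator
targets. Regulon size N_TU is the number of TUs a TF regulates; among fully
overlapping TUs (one gene set contained in another) only the largest is kept,
while partial overlaps are all retained and a TU regulated by several TFs
counts towards each of their regulon sizes. Regulators with N_TU ≥ 10
(inclusive) are classed global (GR), the rest local (LR). Coordinates are
0-based half-open throughout.

## Diversity estimation

### Pseudo-codon alignments

Read-level cohorts never yield per-isolate assemblies, so alignments are
reconstructed from the variant caller's SNP matrix: each row is initialised
with the reference CDS and the run's called variant codons are substituted in.
Rows are built only for runs in which the gene was detected by coverage. Rows
carrying an internal stop codon, or a complete non-stop codon at the terminal
stop position, are removed (likely frame or calling artifacts). A variant
codon with any missing base is treated as entirely missing, and every codon
column missing in any retained row is removed from all rows (global column
removal rather than per-pair weighting — the simpler convention, and the one
consistent with removing gapped columns from conventional alignments). The
terminal stop codon never enters site or difference counts. Alignments with
fewer than two retained rows are flagged insufficient and the gene's diversity
is undefined.

Internally the alignment is stored sparsely (reference codons plus per-row
variant dictionaries). All estimators work from per-column codon counts, which
is algebraically identical to the textbook all-pairs sums; the test suite
asserts equality with a brute-force all-pairs oracle to 1e-12.

### π, π_S, π_N

Nucleotide diversity is the uncorrected average pairwise difference per site:
π = Σ_{i<j} d_ij / C(n,2) / L. No multiple-hit (Jukes–Cantor) correction is
applied anywhere — the quantity of interest is the raw average pairwise
difference.

Synonymous and non-synonymous components follow Nei–Gojobori (1986)
unweighted counting under NCBI translation table 11 (bacterial; identical
sense-codon assignments to the standard code, configurable):

* Per codon, each of the nine single-base neighbours contributes 1/3 of a
  site to the synonymous tally if it encodes the same amino acid, otherwise
  (including changes to stop codons) to the non-synonymous tally; the counts
  always sum to exactly 3.
* Codon pairs differing at k > 1 positions are scored by averaging the
  per-step synonymous/non-synonymous tallies over the k! substitution
  orderings, skipping orderings that pass through a stop codon; when every
  ordering is blocked, all k differences are counted as non-synonymous.
* π_S divides the mean pairwise synonymous difference count by the
  pair-averaged synonymous site count, which equals the row-mean site count;
  π_N analogously.

Conventional codon alignments of assembled sequences take the same estimator
after dropping every codon column containing a gap in any row. Columns
containing a stop codon in any row are dropped as well, a package choice that
keeps the pathway accounting defined on real alignments.

### Standardization

Because average diversity varies across cohorts, per-gene estimates are
standardized by the median and median absolute deviation (MAD) of the TG
values: scaled(x) = (x − median_TG) / (1.4826 · MAD_TG). The 1.4826
consistency constant makes the scale comparable to a normal standard
deviation (raw MAD available by flag). TGs then have median zero in every
cohort, and any systematic TF shift appears as a nonzero TF median on a
common scale.

## Pipeline rules

* **SNP-matrix cleaning.** Positions outside coding regions are removed;
  positions ambiguous in > 10% of runs are removed; remaining ambiguous calls
  are imputed with the modal unambiguous base (ties resolve to the reference
  base — deterministic and reference-conservative); positions invariant after
  imputation are removed. Cleaning is idempotent. An upstream per-position
  quality filter belongs to the variant caller and is not re-applied here.
* **Gene presence.** Genes with coverage breadth ≥ 0.6 ("a minimum breadth of
  0.6" is read as attainable, hence inclusive) and nonzero depth form the
  candidate set; the depth mean x̄ is computed, depths ≥ 2x̄ are trimmed to
  obtain a Gaussian-like distribution with mean ȳ and sample standard
  deviation s (n − 1); genes with depth ≥ ȳ − 3s are present. The trimmed
  high-depth genes (duplications, repeats) are classified present — they are
  unquestionably covered; trimming exists only to stabilise ȳ and s. With
  fewer than two genes after trimming, s is undefined and all candidates are
  called present with a warning. Runs with fewer than 3000 detected genes are
  excluded (strict <), counting trimmed high-depth genes as present.
* **Marker genes and declustering.** Declustering markers are core, non-gapped
  genes with diversity strictly above the 75th percentile and at most
  Q3 + IQR (linear-interpolation percentiles, the scientific-stack default;
  configurable). Each run maps to the vector of per-marker variant-codon
  fractions; runs are admitted greedily in lexicographic id order iff their
  Euclidean distance to every admitted run exceeds 0.1 (strict, per "greater
  than 0.1"; the admission order is a package choice — any maximal
  independent-at-distance set satisfies the contract, which is asserted
  post hoc).

## Regulon-level inference

Regulon diversity is the grand mean over TUs (mean of per-TU means over genes
with defined values), not the gene-weighted mean: operon length tracks
metabolic-pathway length and would otherwise leak into the estimate. TUs with
no valued gene are skipped; TFs with no valued TU are dropped from paired
analyses.

Paired TF-vs-regulon comparisons use the one-sided Wilcoxon signed-rank test
(zeros dropped, midranks for ties; exact null for n ≤ 25 without ties, normal
approximation with corrections otherwise). Fewer than six pairs is logged as
underpowered, not refused.

The randomization test controls for comparing a single TF value against a
many-gene mean. The observed statistic is the mean over TFs of (TF value −
regulon grand mean); each of N trials draws per original TF a pseudo-TF
uniformly from the TGs (without replacement within a trial; a
with-replacement flag exists) and a pseudo-regulon of random TGs excluding
the pseudo-TF with the same TU count and TU sizes (the strongest reading of
"keeping regulon sizes constant"; a genes-only variant that preserves the
total gene count is available by flag). The tail probability is
max(k, 1)/N — the smallest reportable p at N = 1000 trials is 0.001. The mean
paired difference was chosen as the trial statistic because it is smooth and
cheap; the signed-rank statistic is available by flag.

The gene-length confound is handled as a pipeline recipe, not a separate
algorithm: drop every edge whose target is longer than its TF and re-run the
paired comparisons.

## Conservation

Orthogroups are connected components of the bidirectional-best-hit graph. A
component where every member identifies every other (a clique; edges never
join proteins of one genome, so a clique has one member per genome) is
*closed*; a closed component spanning all genomes is *strict core*; anything
else is *open* and is reduced to its closed part by greedy peeling — repeatedly
deleting the member with the fewest within-group links (lexicographic
tie-break) until a clique remains. Exact maximum clique would be NP-hard and
is unnecessary at orthogroup sizes; the greedy result is asserted to be a
clique. Conservation of a gene is the fraction of genomes with an accepted
ortholog; hits whose pairwise global alignment has more than 10% gaps are
rejected (inclusive boundary at exactly 10%), because gap-heavy hits suggest
domain gain/loss. Genome deduplication keys strains on the 14-tuple of
round-half-up whole-number identity/overlap percentages over the seven MLST
fragments (adk, fumC, gyrB, icd, mdh, purA, recA) after identity ≥ 70%,
overlap ≥ 90%, E ≤ 1e-5 thresholds; strains missing any fragment are removed
and one seeded-random representative is kept per signature.

## Evolution dynamics

The derived allele frequency of gene g in population p,
M_p(t) = Σ_m f_{p,m}(t), sums the frequencies of the gene's mutations at
time t. Class-mean DAF averages M over every gene of a class, assigning zero
to unmutated genes, restricted to non-synonymous mutations; population series
are computed per population and then averaged across populations. A mutation
is *de novo* in the 10 000-generation interval containing its first observed
nonzero frequency (origination is unobservable between 500-generation
samples); per-interval counts are normalized by the class-wide non-synonymous
site count. Interval frequency maxima pool variants from all populations; a
variant enters an interval only if observed nonzero inside it. The
extreme-outlier rule scores each mutated gene by (#mutations, fraction of its
mutations reaching fixation) and drops the lexicographic maximum; the
fixation threshold defaults to frequency 1.0 at any observed timepoint,
configurable down to 0.95 for noisy data. Significance series are reported as
raw −log10 p without within-trajectory multiplicity correction. Mutator and
non-mutator populations are a grouping column, not separate code paths.

Lab-evolution enrichment treats each study as a 2×2 table of non-synonymous
mutation counts versus site counts for TFs and TGs: one-sided Fisher's exact
test (TF rate greater), Holm–Bonferroni across studies, and a one-sided
rank-sum comparing odds ratios between selection-driven (ALE/AR/LTEE) and
mutation-accumulation studies. The literature-curated variant compares the
count of beneficially mutated TFs against the genome background fraction
(default 304 TFs of 4140 proteins, ≈ 7.3%).

## Synthetic-data model

The generators emulate the statistical structure of the real inputs, not
their biology in full:

* **Network.** Regulon sizes follow a discrete power law P(k) ∝ k^−α
  truncated at the available TU count (default α = 2.5; TRN out-degrees are
  scale-free); TGs are partitioned into TUs of geometric size (mean 2) and
  every TF is anchored on at least one single-gene TU.
* **Genome.** Random CDS with ATG start, random sense codons, one stop; TFs
  average 250 codons and TGs 300 (TFs run shorter in real annotations),
  lognormal length variation with CV 0.2.
* **Isolates.** Per gene, segregating codon sites arise as a Poisson process
  calibrated so expected π_N equals θ_TG for TGs (default 0.005, an
  E. coli-like non-synonymous diversity) and δ·θ_TG for TFs; synonymous
  variation is calibrated identically for both classes to θ_S (default 0.02,
  preserving π_S > π_N). Candidate changes are uniform single-base codon
  edits accepted into the non-synonymous or synonymous budget by translation,
  keeping the generator honest with respect to the downstream Nei–Gojobori
  accounting. Each site's derived allele count is uniform on 1..n−1, giving
  an expected per-pair contribution of (n+1)/(3(n−1)) per site, which is the
  calibration constant. The truth table records each gene's target π_N.
* **Coverage.** Present genes get breadth near 1 and gamma-distributed depth
  around the 50× target (CV 0.15); duplicated genes 2×; absent genes exactly
  (0, 0).
* **Trajectories.** Mutations originate per gene as a Poisson process at
  2e-8 per non-synonymous site per generation — the rate of mutations that
  reach observable frequency in whole-population sequencing, deliberately far
  above the raw point-mutation rate. A class can receive an early origination
  boost 1 + b·exp(−t/τ) (the LTEE-like regulatory burst; the examples use
  b = 8, τ = 5000 generations, chosen to mimic a rapid early excess that
  decays within the first ~10k generations). A fraction (default 0.1) of
  mutations sweeps as a deterministic logistic curve with selection
  coefficient uniform in [0.001, 0.003] from a detection-scale initial
  frequency of 0.01 — the simplest mechanism reproducing the rapid-rise
  dynamics; a full Wright–Fisher model is unnecessary for these summaries.
  The rest drift as a small absorbing random walk (step σ = 0.02 per
  500-generation sample). Fixation (frequency 1) is absorbing unless a
  clonal-interference flag caps sweeps below 1. Output is sampled every 500
  generations over a 60 000-generation horizon, six populations by default.

What the generators do **not** emulate: linkage between variants,
recombination, read-level error (FASTQ), clonal interference dynamics beyond
the cap flag, and population structure. Passing tests therefore demonstrate
that the estimators and tests recover planted effects under the assumed
sampling model, not that the biological conclusions hold on any particular
real dataset.

## Numerical and testing choices

* Exact-test cutoffs: signed-rank exact for n ≤ 25 (tie-free), rank-sum exact
  for m + n ≤ 12 (tie-free), Spearman full-permutation p for n ≤ 8; all
  configurable. These keep enumeration instantaneous while the large-sample
  approximations are already accurate.
* Statistical backends: scipy.stats (wilcoxon, mannwhitneyu, fisher_exact)
  and statsmodels (Holm); every exact path is verified against in-repo
  brute-force enumeration oracles.
* Problem sizes in the test suite — 30 TFs / 300 TGs, 200 isolates, 20–100
  replicate cohorts, 200-trial randomization in calibration loops (1000 where
  the floor itself is the claim), 50 trajectory seeds — were chosen as the
  smallest sizes at which the planted effects and calibration envelopes are
  statistically decisive.
* Degenerate inputs: all-zero paired differences give p = 1 with a warning;
  constant vectors are an error for correlation and min-max scaling; a zero
  TG MAD is an error; an all-removed SNP matrix is a warning, not an error;
  fewer than two alignment rows flags the gene as missing rather than
  failing the cohort.

## Known limitations

* The declustering output depends on the (deterministic) admission order;
  only the pairwise-distance contract is guaranteed, not a canonical subset.
* Greedy clique peeling may retain a smaller clique than the true maximum on
  adversarial open orthogroups.
* π on read-based cohorts uses global column removal; cohorts with heavy,
  run-specific missingness lose more columns than per-pair weighting would.
* The drift model is a bounded random walk, not Wright–Fisher; absolute
  drift-variant frequencies are stylised, though the de-novo and maximum-
  frequency summaries behave correctly under it.
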