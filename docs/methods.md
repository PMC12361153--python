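# Methods

This note documents the statistical procedures, the defaults and the design
choices behind `methvalley`, and what the synthetic-data tests do and do not
establish about real data.

## Data model and conventions

The atomic observation is a strand-resolved cytosine with methylated and
unmethylated read counts and a sequence context (CG, CHG, CHH).  Symmetric
CG positions are *not* collapsed across strands: each strand's cytosine is
an independent site, the native representation of Bismark-style CX reports.
All intervals (windows, DMRs, DMVs, genes) are 0-based half-open internally;
cytosine positions are stored 1-based as in the report and converted for
interval queries.  Chromosome order follows the declared chromosome-size
map, with a lexicographic fallback.

Two distinct "methylation level" summaries are used deliberately:

- **read-weighted level** Σm/Σ(m+u) over a site set — coverage-robust, used
  for global summaries, DMR group levels, chromosome tracks and metagene
  bins;
- **per-site mean** of m/(m+u) — used for the DMV window score, where a
  deeply covered site should not dominate the valley criterion.

## Methylcytosine calling

A site with coverage ≥ 4 is called methylated when the one-sided binomial
tail P(X ≥ m | n = coverage, p = error) is ≤ 0.05 after BH adjustment across
all tested sites.  The error rate (default 0.005) models bisulfite
non-conversion plus sequencing error.  This is the established
binomial-test convention for WGBS; the context proportions of called
methylcytosines are reported per context and sum to 1.  For plain level
computations the coverage floor is 1 (all covered sites); the floor of 4
applies where per-base methylation *status* matters (mC calling, DMR site
qualification, DMV window sites).

## DMR calling

200-bp non-overlapping tiles per chromosome (final partial tile included).
Per tile, context and tissue group, read counts are pooled over replicates —
a position qualifies per sample when that sample covers it with ≥ 4 reads,
so a position may contribute in one replicate and not another.  The site
count per group is the number of distinct qualifying (position, strand)
pairs.  A tile is tested only when both groups have ≥ the context's minimum
sites ("both", not "either": a one-sided rule would test windows with no
information in one group) and the pooled 2×2 table has no zero margin;
degenerate tiles are excluded from the multiple-testing family rather than
assigned p = 1.  The test is Pearson's χ² with 1 df and no continuity
correction; q-values are BH step-up, applied per context across all tested
windows genome-wide.  A DMR must satisfy all three context criteria
simultaneously (sites, |Δ| of pooled read-weighted levels, q).

Replicates are pooled by count summation; there is no per-replicate
dispersion model.  Under replicate-level overdispersion (site levels varying
between biological replicates) the pooled χ² is anti-conservative; the null
calibration reported by the test suite and acceptance script therefore uses
pure binomial sampling, which is the test's own sampling model.  The
|Δ| ≥ 0.25 effect-size gate absorbs much of the practical inflation, but
callers on strongly overdispersed data should treat borderline q-values with
caution.  Beta-binomial or logistic-regression models are out of scope.

## DMV detection

1-kb windows sliding in 200-bp steps; trailing windows shorter than 1 kb are
not evaluated (a short window would change the meaning of a 5% mean).  A
window qualifies when it has ≥ 5 sites with coverage ≥ 4 (any context) and
their per-site mean level is < 0.05.  Both floors are configurable; they
exist to keep near-empty windows from qualifying on one or two sites.
Qualifying windows overlapping by ≥ 1 bp are merged by union into maximal
regions (two qualifying windows that merely touch are not merged).  Each
region reports the per-site mean over its span.  Per-tissue DMV calls pool
that tissue's replicates by count summation first, producing one valley set
per tissue.

A gene is a DMV gene when the *cumulative* overlap of its body with the DMV
union is ≥ 80% of its length, boundary inclusive.  The union (not a single
DMV) is the natural object once windows are merged.

The detector is verified against an independent enumerate-filter-merge
oracle on random genomes, and is provably a union of qualifying windows (no
reported base pair lies outside every qualifying window).

## TAU and differential expression

τ = Σᵢ(1 − xᵢ/max)/(n − 1) on raw FPKM values; with two tissues this is
1 − min/max, so any monotone per-gene transform leaves the classification
unchanged and raw values are the minimal assumption.  τ is undefined (gene
excluded) for an all-zero vector — treating silence as τ = 0 would class
dead genes as constitutive.  Genes with τ ≥ 0.99 and maximum abundance ≥ 1
FPKM are tissue-preferential, assigned to their argmax tissue; argmax ties
are excluded and logged.  The abundance floor guards against noise-only
genes whose zero-versus-epsilon profile scores τ = 1; set it to 0 to
disable.  The fold-change classifier is boundary-inclusive
((a + ε)/(b + ε) ≥ 2, pseudocount ε = 0.01 keeping zero denominators
finite).

## Enrichment

Hypergeometric upper tail P(X ≥ k), k inclusive, via scipy's log-space
survival function; verified against exact integer enumeration for every
universe up to N = 25.  The default universe is the genes with defined τ
(expressed somewhere); a universe of all annotated genes is selectable.
The p-value is symmetric in the two sets.

## Metagene profiles

Gene bodies are scaled to 60 equal fractional bins; 2-kb flanks use 20
fixed-width bins each (flank length must divide the bin counts so binning is
exact).  The body bin of a site is floor((pos − start)/length × 60), clamped
at the last bin.  Minus-strand genes are mirrored so bin 0 is always
5′-most; the body mirror flips the *bin index* rather than the coordinate,
which makes strand reversal an exact bin reversal even when the gene length
is not a multiple of the bin count.  Per bin and context the value is the
read-weighted level pooled over all genes (sum of reads, not a mean of
per-gene means — robust to sparsely covered genes and exactly additive
under pooling of gene sets).  Bins with no reads are missing, never 0.
Genes shorter than the body bin count are skipped with a warning.

## Synthetic data generator

The generator emulates the features the estimators rely on: a genome
partitioned into compartments with per-class per-context methylation
probabilities (defaults: TE blocks CG/CHG/CHH 0.95/0.80/0.15, gene regions
0.60/0.15/0.05, valleys 0.005 everywhere, valley flanks 0.90/0.80/0.50,
background 0.90/0.65/0.12 — a plant-like landscape with global CG ≈ 0.77
and CHH ≈ 0.13), per-site beta-binomial noise (concentration 50, giving
replicate-level variance; None switches to pure binomial), i.i.d. Poisson
coverage (default 10×, no mappability structure) and planted differential
windows overriding the compartment probability per tissue.  Contexts are
derived from the simulated sequence with the CX convention on both strands;
cytosines within 2 bp of a chromosome end (incomplete trinucleotide) are
omitted from the catalog.

The default demo study is 3 chromosomes × 200 kb with 2 tissues × 3
replicates: six valleys per chromosome (2, 2.4 and 3.2 kb, two of each),
each containing one gene inset 100 bp from the valley edges; valley
boundaries are aligned to the 200-bp scan grid and flanked by 1-kb hot
compartments, so the 1-kb/200-bp scan has sharp, well-posed boundaries (a
window straddling a valley edge by ≥ 200 bp of ≥ 0.6-level flank exceeds
the 5% mean and drops out).  Thirty CG windows (root 0.9 vs leaf 0.4) and
twelve CHH windows (0.45 vs 0.10) are planted in background.  Expression
classes are planted exactly (exclusive ratio 0, preferential ratio 0.005 →
τ = 0.995, constitutive ratio uniform in [0.6, 1) → τ ≤ 0.4), with 12 of 18
valley genes root-preferential versus 6 of 42 other genes, so the
preferential-among-DMV enrichment is built into the design.  Baseline
abundances are log-normal (median 20 FPKM, σ = 0.8, clipped at 2 so every
gene clears the τ abundance floor).  The truth manifest (valleys, planted
windows with their probabilities, gene classes with exact τ) is serialised
as JSON next to the data.

The scale (600 kb, ~300 k cytosines per sample, 6 samples) runs the whole
pipeline in seconds while leaving every window statistic with realistic site
and read counts.  What passing recovery tests shows: the estimators
correctly invert the generative model they assume (binomial/beta-binomial
counts, compartment-wise levels, exact expression ratios).  What they do
not show: robustness to mappability bias, non-uniform coverage, bisulfite
conversion failure beyond a flat error rate, chromatin-scale methylation
autocorrelation, or expression measurement noise — none of which the
generator models.

## Numerical and degenerate-input choices

- "No data" (no qualifying sites, empty called set, all-zero expression) is
  an explicit error or a missing value, never a silent 0.
- χ² on a zero-margin table is undefined and the window is skipped, not
  p = 1.
- BH is statsmodels' `fdr_bh`; q-values are clipped to [0, 1] and
  order-preserving.
- The hypergeometric tail returns exactly 1.0 at k = 0.
- DMV merging keeps touching-but-not-overlapping windows separate; the
  boundary of the 80% gene rule and the 2-fold cutoff are inclusive.
- Simulation RNG streams are namespaced by (seed, purpose, tissue-CRC,
  replicate), so outputs are byte-identical for a fixed seed and samples are
  mutually independent.

## Known limitations

- The DMR model has no replicate dispersion term (see above).
- DMV detection has no explicit handling of assembly gaps; unsequenced
  regions with no sites simply never qualify (site floor), which also means
  a valley overlapping a long site-free gap is split.
- TAU with two tissues cannot distinguish "preferential" from "exclusive"
  beyond the min/max ratio.
- The metagene profile reports pooled levels without confidence bands;
  between-set comparison is descriptive, not tested.
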