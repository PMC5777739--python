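# Methods

This note documents the statistical procedures, their assumptions, the
numerical choices, and what the synthetic-data validation does and does not
establish.

## Purity scoring

Per sample, genes are ranked by expression with average ranks on ties
(highest expression → highest rank). For a gene set S, walking the genes
from highest to lowest rank, the enrichment score is the running sum of the
difference between the weighted in-set empirical CDF (weights rankᵅ,
α = 0.25) and the unweighted out-of-set CDF — the unnormalized single-sample
GSEA statistic. Stromal and immune scores are summed into a combined score,
converted to an estimated tumor-cell fraction with the published cosine
calibration

    purity = cos(0.6049872018 + 0.0001467884 · combined_score),

clamped to [0, 1] with a `clamped` flag rather than dropped when the cosine
argument leaves the valid range. The two calibration constants are hardcoded
from the original publication of the method. Because scoring is rank-based,
any strictly monotone per-sample transform of expression (log, quantile
normalization) leaves scores unchanged, so whether the upstream matrix was
log-scale is immaterial.

The tumor filter keeps samples with purity ≥ 0.60, boundary inclusive. The
shipped `data/*_signature.synthetic.txt` files are synthetic stand-ins that
mirror the 141-gene structure of the published stromal/immune signatures;
they pair with the synthetic generator. For real cohorts, users supply the
published signature lists as ordinary gene-set files.

Duplicate gene symbols in expression input are collapsed to the row with
the highest mean expression — deterministic and standard practice for
probe-level inputs; the collapse is logged.

## Copy number

**Projection.** Gene value = overlap-length-weighted mean of the log2
segment means of all segments intersecting the gene span (1-based inclusive
coordinates throughout SEG and the gene model; BED is 0-based half-open). A
gene fully inside one segment carries exactly that segment's value; a gene
with no overlapping segment is missing. X/Y genes are dropped by default so
male- and female-derived samples compare fairly.

**FGA.** FGA = Σ Lᵢ·[|CNᵢ| > T] / Σ Lᵢ over autosomal segments. The
threshold T is not fixed by the method's source; the default is 0.2 on the
log2 scale, the convention of the statistic's original use, configurable.
The comparison is strict (">") by default with an `inclusive` switch, since
the definition says "above" the threshold. FGA is invariant under segment
subdivision, which the tests assert as a property.

**Correlation.** Pearson r per (cell line, tumor) pair over
pairwise-complete genes, with `n_genes_used` reported per cell; cells with
fewer than 3 usable genes or a zero-variance vector are missing with a
reason rather than an error. Correlation to the tumor mean profile uses the
gene-wise mean over tumors ignoring missing entries. Restricting to a
focal-peak gene list is a simple intersection; peak discovery itself is
upstream and out of scope.

## Mutation statistics

**Presence matrix.** A gene/sample bit is set by ≥ 1 non-synonymous SNP,
DNP, insertion, or deletion surviving the VAF ≥ 0.1 and depth ≥ 8 filters.
Records lacking read counts pass the filters (such files are pre-filtered
upstream by their producers).

**Differential mutation.** Two-sided Fisher exact test per gene on
[mutated, unmutated] × [cohort A, cohort B]; the two-sided tail sums all
fixed-margin tables whose probability is ≤ the observed table's with
relative slack 1 + 10⁻⁷ (the convention of the standard R/scipy
implementations — the slack is part of the statistic's definition here, and
the exact-rational test oracle applies the same rule so ties are
well-defined). Genes with fewer than five mutated samples in both cohorts
combined are skipped; "five total" rather than per-cohort is a deliberate
reading of an ambiguous rule. The default Bonferroni multiplier is the
shared-gene-universe size, the multiplier that reproduces the published
per-gene values.

**Mutual exclusivity.** For a gene pair with margins fixed, the
both-mutated count B is hypergeometric; the reported p is the mid-p lower
tail P(B < b) + ½·P(B = b). The mid-p convention is not stated by the
analyses this reproduces — it was identified because it reproduces their
printed values to all printed digits (e.g. 0.438538739) — and is documented
prominently for that reason. Co-occurring pairs give p near 1; a pair whose
second gene is never mutated gives exactly ½ (B is forced to 0). The
Bonferroni multiplier defaults to the number of pairs tested (28 for 8
genes).

**Numerics.** Both tests compute hypergeometric terms as lgamma
differences and sum tails in log space (shift by the maximum, `math.fsum`),
so p-values far below 10⁻⁵⁰ are representable with ~10⁻¹⁴ relative error.
The test suite checks both tails against independent exact-rational
enumeration (integer binomial coefficients, `fractions.Fraction`) to ≥ 10
significant digits over a margin grid covering every table size n ≤ 60 —
all n from 1 to 60 with margins on a stride-⌈n/8⌉ grid including the
boundary values, every observed count per margin pair (> 10,000 tables);
the grid rather than the full margin lattice keeps the check inside a few
seconds without losing coverage of the boundary and interior regimes.

**Burden.** mutations/Mb = n / (breadth / 10⁶), with n counting all
variant classes including synonymous (unlike the presence matrix), filtered
at VAF ≥ 0.1 and depth ≥ 14. Breadth is Σ(end − start) for interval tracks
(already depth-thresholded by their producer) and the count of positions
with depth ≥ 14 for per-position tracks. log2(mutations/Mb) is undefined at
zero mutations and reported as missing. Depth defaults deliberately differ
by analysis — 8 reads for the presence matrix and UV signature, 14 for
burden — matching the differing requirements of the source protocols; both
are configurable.

**UV signature.** Substitutions are SNP and DNP records; indels are
excluded from numerator and denominator. Each single-base substitution is
strand-normalized to the pyrimidine reference (G>A with complemented,
swapped flanks counts as C>T). A C>T counts as dipyrimidine when either
flank is C or T; the stricter 5′-only definition is available via
`either_flank=False` since the source wording supports "either". CC>TT
dinucleotide substitutions feed the 5% branch. C>T records without flank
context cannot be judged and are excluded from both numerator and
denominator, tallied in `n_context_unknown`. A sample is UV-positive when
the dipyrimidine C>T fraction is ≥ 0.60 or the CC>TT fraction ≥ 0.05;
zero-substitution samples are negative by definition.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
per-chromosome baseline segments with Gaussian log2 means (SD 0.05) plus
planted focal amp/del events (effect ±1.0, carrier probability per group);
mutations placed uniformly over covered gene space at a configurable rate
(default 15/Mb, a realistic cutaneous-melanoma burden), with UV-context
substitutions at weight 0.65 (the approximate tumor-cohort rate for this
disease) of which 5% are CC>TT; a planted exclusive driver pair (one driver
in ~74% of samples, both in ~2%, an asymmetric 64/36 split — margins shaped
like the strongest published melanoma pair); VAF ~ Beta(2, 5) and depth ~
negative binomial (mean 60, size 3), so a known share of variants fails the
0.1/8/14 filters; hybrid-capture-like coverage over gene bodies at 90%
breadth (BED intervals for tumors, WIG depth tracks for cell lines, with
sub-threshold positions emitted so the ≥ 14-read rule is exercised); and
expression as a convex mixture of a tumor archetype and a stromal+immune
archetype at planted purity levels (1.0 down to 0.5) plus Gaussian noise
(SD 0.25). Planted driver mutations are guaranteed to survive the filters
so the exclusivity pattern in the emitted files equals the assignment in
the truth table; they are deliberately non-UV substitutions.

The default genome is 2 chromosomes × 1 Mb with 200 genes of 1 kb, so the
full pipeline runs in seconds; all sizes are config knobs. One RNG stream
per file type is split from the master seed, so outputs are byte-identical
across reruns and adding a generator leaves the others unchanged.

What the generator does **not** emulate: real chromosome lengths, mutation
hotspots, full signature spectra beyond the UV rule, copy-number/expression
coupling, or subclonal structure. Passing tests therefore demonstrate that
the statistics recover what they are defined to measure under their own
model assumptions — not that real TCGA/CCLE cohort values (mean FGA, cohort
UV rates, correlation levels) are reproduced; those require the original
downloads and are explicitly out of scope.

## Validation design

Per-statistic validation uses planted-truth recovery at problem sizes
chosen to keep the whole suite under a minute of exact-test checking and a
few minutes overall: FGA recovery is exact (10⁻¹²) on noise-free cohorts;
the planted exclusive pair at 412-sample margins is detected at adjusted
p < 0.05 in 20/20 seeded replicates while an independently mutated pair
with identical margins is flagged in ≤ 1/20; the UV classifier recovers
planted labels (≥ 99% positive at weight 1.0, ≤ 1% at 0.0, 200 samples
with ≥ 20 substitutions); estimated purity is strictly decreasing across
noise-free admixture levels; and mean pairwise copy-number correlation
rises monotonically with the planted shared-event fraction.

## Known limitations

* The cosine purity calibration was fitted on real tumor cohorts; on
  synthetic cohorts only the ordering of purity estimates is meaningful,
  not their absolute level.
* The exclusivity test is pairwise only; no k ≥ 3 generalization.
* No BAM/FASTQ handling, genome-build liftover, signature deconvolution,
  or driver-discovery background models.
* The two-sided Fisher inclusion slack (10⁻⁷ relative) can, in principle,
  include a table whose probability is within that slack of the observed
  one without being exactly tied; this matches the mainstream convention
  and is applied consistently in the oracle.
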