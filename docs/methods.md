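# Methods

## Generative model of the synthetic data

The generator emulates a two-strain cross profiled by allele-specific
RNA-seq: parents O and S, reciprocal F1 crosses (F1A = O mother,
F1B = S mother), four developmental temperatures, three replicate libraries
per genotype and temperature.  Six measurement channels exist per library
slot: `F0_O`, `F0_S`, and the per-allele channels `F1A_O`, `F1A_S`,
`F1B_O`, `F1B_S`; the two allele channels of one F1 library share a
replicate index and depth multiplier.

For gene *g*, temperature *t*, with baseline *b* (log2 mean count at unit
depth), cis effect *c*, trans effect *r* and F1 total offset *d* (all log2):

    mu_F0O = 2^(b + (c + r)/2)       mu_F1O = 2^(b + d + c/2)
    mu_F0S = 2^(b − (c + r)/2)       mu_F1S = 2^(b + d − c/2)

so log2(mu_F0O/mu_F0S) = c + r and log2(mu_F1O/mu_F1S) = c hold exactly,
and the difference of the two ratios recovers *r* — the identity the
effect-size decomposition rests on.  Counts are independent
negative-binomial draws, NB(mean = mu × depth multiplier, dispersion φ):
variance mu + φ·mu².  The four channels are independent NB draws rather
than binomial splits of a library total; this matches the downstream GLMs,
which treat allele channels as count libraries, and keeps every channel's
overdispersion explicit.

Defaults (the study conditions of the benchmark suite): 2,000 genes, four
temperature labels (13C/18C/23C/29C), 3 replicates, b = 8 (≈ 256; the
recovery benchmarks use log2(200)), φ = 0.1, log-normal depth multipliers
with CV 0.15.  The data do not state a dispersion magnitude; φ = 0.1 is a
typical bulk-RNA-seq value for replicated inbred lines and is exposed in
`SimConfig` (scalar, per-gene array, or gamma-sampled via
`SimConfig.sample_gamma_dispersions`).

Architecture designers map class labels to effects:

- regulatory classes (effect size 2 log2 units, random sign): cis-only
  (c = e, r = 0), trans-only (c = 0, r = e), cis+trans (r = c = e),
  compensatory (r = −c, by definition the cancelling geometry), and
  cis×trans with r = −2c — opposite signs *without* cancelling the parental
  divergence, which would otherwise collapse into the compensatory class.
- inheritance modes place the parental separation entirely in trans
  (c = 0, r = Δ) and position the F1 total via d: at a parent (dominant),
  at the midpoint (additive), or 1 log2 unit outside the parental range
  (over-/under-dominant).  Dominance-swapped genes interpolate d from
  −Δ/2 at the lowest temperature to +Δ/2 at the highest.  Default
  Δ = 3 log2 units (8-fold): the hardest class to recover is additive,
  whose per-parent contrast is Δ/2; at depth ~200 with 3 + 6 libraries a
  2.8-fold contrast carries ≈ 95% per-side power, which is what a
  simulation designed to measure classifier recovery (rather than test
  power) requires.  Smaller separations mainly measure the power curve of
  the NB test: at Δ = 2 roughly half the designed additive genes are
  (correctly, given the evidence) called dominant.
- an optional "mito-like" gene with an extreme, opposite allelic imbalance
  in the two reciprocal crosses (O fraction 0.9999 in F1A, 0.0001 in F1B,
  high depth) exercises the imprinting screen's extreme-case path,
  emulating maternally inherited mitochondrial transcripts.

A companion read-level simulator lays the genes on one synthetic
chromosome (2 kb genes, 500 bp spacers), injects SNPs at a configurable
density into the S genome, and samples error-bearing paired-end fragments
(250 bp fragments, 75 bp mates, uniform substitution errors) from each
haplotype in proportion to the parental channel means, tagging each pair
with its true origin.

What the generator does **not** emulate: splicing and intron structure,
GC/positional coverage bias, strand-specific artifacts, quality-score
structure, correlated dispersion between channels of one library, batch
effects.  Passing benchmarks therefore demonstrate statistical correctness
of the pipeline under a faithful count-level model, not robustness to every
real-data artifact.

## Read assignment

Parental pseudo-genomes are built by substituting strain-diagnostic SNPs
(called at majority-base frequency ≥ 0.98 and depth ≥ 2 from per-parent
pileups) into a shared reference; coordinates are identical by construction
(substitutions only, no indels).  A read pair is compared against both
genomes at its locus by an exact ungapped matcher and assigned to the
genome with *strictly* fewer mismatches; ties — including pairs covering no
SNP and pairs with conflicting SNP evidence — are ambiguous, and pairs
exceeding a 10% mismatch budget on both genomes are unmapped.  Counting
accepts a pair for a gene only if both mates fall entirely inside the
gene's interval and outside any region shared with an overlapping gene
(computed from the annotation); an optional strand-aware restriction counts
only the 3′-most L bases.  Internally coordinates are 0-based half-open;
GFF3 is read and written 1-based inclusive.

The mapping-bias screen simulates equal numbers of error-free pairs from
both haplotypes of every gene, runs them through assignment and counting,
and flags genes whose (O, S) counts reject 1:1 in an exact binomial test
(BH ≤ 5% across genes); genes with no assignable pair are reported as
uninformative instead.  One property of the exact matcher is worth
stating: because both genomes share coordinates and differ only by
substitutions, a fragment from either haplotype mismatches exactly the
other genome at every covered SNP site — assignability is symmetric, and no
arrangement of SNPs or overlap masks can produce *expected* imbalance.
Genuine mapping bias is a property of real aligners (mappability
differences between the pseudo-genomes), so the screen accepts a pluggable
`assign_fn`; the benchmarks verify its operating characteristics by
plugging in an assigner with an emulated one-genome mappability hole.

## Normalization, filtering, down-sampling

TMM factors follow the standard doubly-trimmed (30% on M, 5% on A)
precision-weighted mean of gene-wise log-ratios against a reference sample
(the library whose upper-quartile rate is closest to the mean), with
factors geometrically centered; the implementation reproduces edgeR's
`calcNormFactors(method="TMM")` to ~1e-6 and is cross-checked against it in
the test suite.  The expression filter keeps genes detected (≥ 1 read) in
every sample with at least one sample ≥ 20 reads, applied to parents on
single channels and to hybrids on the per-library sum of both allele
channels.  Rank-matched down-sampling equalizes depth across genotypes
within each temperature: libraries are ranked by total within genotype,
each rank's target is the minimum total at that rank, and counts are
reduced by multivariate-hypergeometric sampling (exactly equivalent to
drawing reads without replacement, by exchangeability); the two allele
channels of an F1 library are down-sampled jointly.

## Statistical machinery

**NB GLMs.**  Log-link negative-binomial GLMs with offsets
log(library size × TMM factor), fitted by IRLS vectorized across genes.
Gene-wise dispersions maximize the Cox–Reid adjusted profile likelihood
(APL) on a 25-point log grid spanning 1e-8–30 with parabolic
interpolation; a trend over abundance comes from maximizing the average
APL within ~20 abundance bins, and tag-wise shrinkage maximizes
APL_g + (prior_df / residual_df) × bin-average APL (weighted-likelihood
empirical Bayes, prior_df = 10 by default).  The differential tests consume
the **trended** dispersions and capture gene-level departures in a
gene-wise quasi-likelihood dispersion (residual deviance / residual df),
squeezed across genes by moment-matching a scaled-F prior (trigamma
inversion); the group contrast is then an F-test of the deviance drop
against the squeezed dispersion with residual + prior df.  Feeding the
tag-wise-shrunk dispersions in instead would count gene-level variation
twice (once in the NB variance, once in the QL dispersion) and measurably
inflates the far tail that BH thresholds live in, so the trended route is
the default throughout the pipeline.

**Quasi-binomial ratio tests.**  Each library contributes one
(O, O+S) observation; fitted group proportions are pooled counts (the
closed-form MLE), dispersion is the full-model Pearson statistic over its
residual df, squeezed across genes exactly as above, and the group effect
is an F-test on the scaled deviance change.  Effects are reported as the
logit difference of O fractions (equivalently Δlog2(O/S)).  Libraries with
O+S = 0 are dropped per gene.  For the trans test the F0 ratio pairs the
O-strain and S-strain libraries of the same replicate, after scaling each
library to a common effective depth (counts need not be integral —
quasi-likelihood uses only means and variances); F1 libraries contribute
their two allele channels directly, needing no depth correction.  The
reciprocal crosses are pooled after an imprinting screen (the same test
with groups F1A vs F1B) removes parent-of-origin-biased genes at BH ≤ 5%.

**Joint temperature models.**  Complementing the per-temperature analyses,
an allele × temperature NB model on F1 allelic counts and a
generation × temperature quasi-binomial model on the O/(O+S) ratio test
each term (main effects, interaction) by nested-model F-tests with the same
moderation, BH-adjusted within term family.  A temperature-dependent cis
effect appears in the allelic interaction; a temperature-dependent trans
effect appears in the ratio interaction.

**Multiple testing.**  BH step-up with cumulative-minimum monotonicity,
NaNs excluded from ranking and propagated.  Each temperature and each test
family is its own BH family; the joint model's term families are separate
additional outputs.

## Classification rules

Cis/trans categories follow the three-flag rule table (README); with all
three tests significant the sign comparison of (e_cis, e_trans) splits
cis+trans from cis×trans.  Combinations with exactly one significant test
are ambiguous — including (F0−, F1+, T−).  Effects are computed from
TMM-normalized channel means with a 0.5 pseudo-count guarding zeros in
*reported* effects only; tests never see pseudo-counts.

Inheritance calls gate divergence on both an FDR ≤ 5% and a normalized
fold-change > 1.25 (the GLM coefficient, i.e. the model's estimate of the
normalized group-mean ratio); dominance requires the resembled parent to be
*non-diverged*, not merely less diverged.  With both parents diverged the
F1 is additive when strictly between them (opposite signs of the two
log-fold-changes), over-/under-dominant outside; the measure-zero boundary
case of an exactly-parental mean with both tests diverged cannot satisfy
the fold gate and so resolves to dominant, never additive.  Dominance
swapping requires opposite single-parent dominance at the two extreme
temperatures; any weaker pattern (dominant/not-different, same-parent
dominance) is not a swap.  An optional robustness variant classifies F1A
and F1B separately and intersects the swap sets.

## Enrichment

Single-TF enrichment: upper-tail hypergeometric p of the overlap between
the test set and each TF's targets within the expressed background, BH
across TFs; TFs with no background targets are skipped with a warning.
Empirical calibration draws N random same-size gene sets and reports the
mean count of TFs passing a raw-p threshold — for a discrete test this
equals the sum of attained test sizes, which the test suite verifies.  The
combination search enumerates TF combinations up to a bounded arity
(default 3), scores the **union** of member target sets (a combination "may
affect" any gene either member binds), collapses duplicate unions, and
controls the FWER at 5% by Tarone's procedure: the correction factor K is
the smallest integer with at most K candidates whose minimum attainable p
(all-overlap configuration) is ≤ α/K, and candidates are rejected at α/K.
The bounded-arity hypergeometric statistic replaces a rank-based statistic
sometimes used in limitless-arity itemset testing; the set-overlap
statistic is the natural choice when the input is a gene set rather than a
per-gene score, and the FWER guarantee is unchanged.

## Numerical choices and edge cases

- IRLS: linear predictors clipped to ±30; 1e-10 ridge on normal equations
  (makes all-zero groups solvable); convergence on relative deviance change
  < 1e-8, ≤ 50 iterations.
- Identical counts in both groups short-circuit to p = 1 exactly.
- All-zero genes must be filtered before dispersion estimation (the filter
  guarantees this in the pipeline); all-zero *groups* get a flagged,
  clipped effect.
- Dispersion grid bottom 1e-8 ≈ Poisson; Poisson-simulated data recover
  median φ < 0.02.
- Quasi-dispersions floored at 1e-8; squeezing degenerates gracefully to no
  moderation when fewer than ~10 genes are testable.
- `downsample_rank_matched` raises on an empty rank target rather than
  emitting empty libraries.
- Seeds: one master seed; all child seeds derived via `SeedSequence` so
  every output is bit-reproducible for a fixed config.

## Benchmark problem sizes

The packaged benchmarks (driven by `scripts/acceptance.py` and the
acceptance tests) use 2,000 genes × 4 temperatures × 3 replicates for
calibration and recovery, 20 simulated datasets for FDR control and the
bias-screen operating characteristics, 10–20 k read pairs for assignment
accuracy, and 1,000 draws for the down-sampling expectation check — sizes
at which every reported rate has small Monte-Carlo error while a full run
of suite plus benchmarks completes in a few minutes on one CPU.

## Known limitations

- The built-in matcher serves synthetic substitution-only genomes; real
  data need a spliced, indel-aware aligner behind the pluggable interface,
  and the mapping-bias screen is then essential rather than illustrative.
- Independent-NB allele channels ignore the weak negative correlation a
  fixed library total induces between alleles of the same library.
- The quasi-binomial trans test depth-scales F0 counts, which rescales
  but does not re-weight their sampling variance; moderation absorbs the
  residual misfit at realistic depths.
- Inheritance ground-truth labels are defined from generative means with
  the same 1.25-fold gate the classifier uses; recovery rates therefore
  measure the test-and-gate pipeline, not the gate itself.
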