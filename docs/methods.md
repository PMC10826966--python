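# Methods

## The inference problem

A cross between two yeast parents yields haploid segregants whose
phenotype distribution reflects the genetic architecture of the trait.
With full tetrads (four spores per meiosis) the segregation pattern within
tetrads is observable as well: a single biallelic causal locus forces
exactly two spores per tetrad into each phenotype group. `tetraclass`
classifies one cross × condition distribution — 160 segregants in 40
tetrads plus the two parental phenotypes, all in growth-ratio units — into
monogenic, oligogenic or complex, or declares it undetermined when the
cross essentially does not grow under the condition.

Because real surveys provide no ground truth at scale, the classifier is
trained and validated entirely on simulated panels with known
architectures, then applied to experimental panels that have passed the
same preprocessing.

## Meiosis and phenotype simulation

Genotypes live on a linear string of 101 binary loci. Per tetrad, two
recombinant strings are drawn independently: a recombinant carries the
parental 1-allele outside an interval `[b1, b2)` and the 0-allele inside
it, with `0 ≤ b1 ≤ b2 ≤ 101` uniform on locus boundaries (coincident
breakpoints give an untouched parental string). The tetrad is the two
recombinants plus their locus-wise complements, which guarantees 2:2
segregation at every locus by construction. This is a deliberately
minimal meiosis — two breakpoints, no crossover interference, no
chromosome structure — sufficient to produce the linkage and segregation
patterns the features measure.

The phenotype of a spore is

    y = w1 · f(primary states) + Σ_i w_i · x_i + ε,   ε ~ N(0, σ²)

* `w1 ∈ [0, 1]`: weight of the primary gene, the bimodality dial.
* 100 secondary weights `w_i`: iid uniforms renormalised to sum to
  `1 − w1` (a flat symmetric choice; any law with many small positive
  effects gives the same CLT-like behaviour). Genes are assigned to loci
  by a uniform random bijection.
* `f`: identity for a single primary locus; AND of two primary loci
  (recessive epistasis) or OR (dominant). The two epistatic loci share the
  weight `w1` and are drawn independently, so they may be linked on the
  string — both configurations occur in the training distribution.
* `σ` (noise_sd), default **0.05** on the [0, 1] phenotype scale: emulates
  measurement error of colony growth ratios. Real screens report duplicate
  correlations around 0.96; with typical panel variances this corresponds
  to a noise sd of a few hundredths. The value is configurable everywhere
  it appears.

Parental phenotypes are the noiseless phenotypes of the two parental
genotypes (all-0 and all-1 strings): 0 and 1 exactly. Noise is applied to
segregants, whose replicate variance the noise term models.

The default training set holds 50,000 labeled panels: 25,000
non-epistatic, 12,500 recessive and 12,500 dominant, with `w1` uniform on
[0, 1] per panel (the generating law of the primary weight is
configurable via `w1_sampler`).

## The 24 features

Per panel, in canonical order (the order is part of the trained-model
contract and is stored with saved models):

1–11. Quantiles of the growth ratio at 0%, 10%, …, 100% (linear
interpolation; the endpoints are the sample min and max). Eleven levels
including both endpoints are used so the full feature count is 24.

12–15. Means and standard deviations of a two-component normal mixture
fitted by EM. The EM is deterministic: components initialised at the
25th/75th percentiles with the pooled sd and equal weights; tolerance
1e−8 on the log-likelihood, at most 500 iterations, variances floored at
1e−6 × the data variance. Components are reported sorted by mean.

16. A two-vs-one-component statistic: `max(0, 2·(ℓ₂ − ℓ₁))`, the
likelihood-ratio of the mixture against the single-normal MLE, with the
same variance floor. Only its monotone association with bimodality
matters, because the forest is trained on these features end to end.

17. Ashman's `D = √2·|μ1 − μ2| / √(σ1² + σ2²)`; `D > 2` indicates clearly
separated modes. Invariant under affine rescaling of the data.

18–19. Two-sided one-sample Kolmogorov–Smirnov statistic and p-value of
the panel against a normal with the panel's own mean and (population)
variance. Complex traits give small statistics; bimodal panels deviate
strongly.

20–24. Frequencies of tetrads with 0, 1, 2, 3 or 4 spores strictly above
the panel-wide mean. A noiseless monogenic panel concentrates all mass on
2; ties count as "not above", so a constant panel gives (1, 0, 0, 0, 0).

Degenerate inputs (all-equal panels, collapsed variances) produce flagged
sentinel values — 0 for statistics, 1 for p-values — so feature vectors
are always finite. All-equal detection uses the sample range rather than
the variance, which float round-off can leave slightly positive.

## Bimodality model and calibration

A random-forest regressor (100 trees) maps the 24 features to the
primary-gene weight; the prediction, clipped to [0, 1], serves as a
bimodality score. Hyperparameters follow the classic regression-forest
defaults (mtry = p/3 features per split, minimum node size 5), which also
keep single-core training on 50,000 panels around half a minute.

The score threshold is calibrated on labeled panels by ROC analysis:
among the ROC cutoffs, the one minimising |sensitivity − specificity| is
chosen (ties resolved toward the lower cutoff, deterministically). In the
packaged workflow the labeled set is simulated — `w1 ∈ [0, 0.3]` labeled
unimodal, `w1 ∈ [0.7, 1]` bimodal, the intermediate band excluded as
ambiguous. On 2,000 such held-out panels the AUC is ≈ 1.0 and the
threshold lands near 0.66; Spearman correlation between predicted and
true `w1` on held-out panels with the full mode mix is ≈ 0.98.

## Decision tree

1. **Callability.** Undetermined if ≥ 80% of segregant ratios are below
   0.05 (essentially no growth) or the panel variance is below 1e−6.
   Both thresholds are configurable module constants.
2. **Complex.** Predicted weight below the calibrated threshold.
3. **Bimodal panels** are split into modes by the mixture fit; if the fit
   fails to converge or degenerates, a kernel-density fallback is used:
   Gaussian KDE with Silverman bandwidth on a 512-point grid, peaks
   located by the sign change of the numerical derivative, threshold at
   the density minimum between the two highest peaks. The lower-mode
   proportion `p_low` is the mixture weight of the lower component (or
   the fraction below the fallback threshold). Parents are placed
   low/high by maximum posterior under the mixture (by side of the
   threshold for the fallback); a maximum posterior below 0.6 — including
   the posterior-equality point — is "intermediate".
4. **Monogenic** requires `p_low ∈ [0.4, 0.6]` *and* parents on opposite
   modes. The window is ±2.5 binomial standard deviations around perfect
   2:2 segregation for 160 spores (sd ≈ 0.04). Every other bimodal
   configuration is **oligogenic**, with a subtype string recording why:
   `bimodal_unbalanced`, `bimodal_parents_same_mode`,
   `bimodal_parent_intermediate`, or `bimodal_unresolved` when even the
   fallback finds no valley (the panel is then split at its mean).

Calls expose the evidence (predicted weight, `p_low`, parent placements,
method) and satisfy the invariant that monogenic/oligogenic calls are
bimodal and complex calls are not.

## Preprocessing

Colony growth is `size_24h − size_0h`, clamped at zero (a colony imaged
smaller at endpoint carries no information about growth). Colonies whose
*reference-condition* endpoint size is strictly under 200 pixels are
removed across all conditions; the filter acts per colony
(strain × replicate), so a strain keeps its other replicate when only one
fails. Growth ratios divide treatment growth by reference growth,
replicate-matched when the same replicate index exists on the reference
plate and otherwise by the strain's mean reference growth; a zero
reference growth makes the ratio missing rather than infinite. Duplicate
ratios are averaged arithmetically. Ratios are consumed raw — no
winsorising or log transform — matching what the features expect.

## Synthetic half-diallel panels

The generator plants a known architecture per cross × treatment and maps
phenotypes to colony sizes invertibly: `size_24h = size_0h +
round(G_ref · ratio)` with reference growth `G_ref = 400` pixels and
`size_0h` uniform on [80, 120]. Preprocessing therefore recovers the
planted ratio to within `1/G_ref`. Replicate noise is multiplicative
lognormal (sd 0.05) on the growth increment, giving duplicate
correlations above 0.9 as in real screens. Planted classes draw
`w1 ∈ [0.85, 1]` (monogenic: single locus; oligogenic: epistatic pair) or
`w1 ∈ [0, 0.15]` (complex); a `no_growth` class plants all-zero
phenotypes to exercise the undetermined path, mirroring real conditions
where some crosses simply fail to grow.

What the generator does *not* emulate: plate-position and edge effects,
spatial autocorrelation, image-segmentation artefacts, spore-viability
failures, batch effects between plates. Passing end-to-end tests
therefore demonstrates correctness of the inference machinery under the
stated generative model, not robustness to every artefact of real colony
imaging.

## Summaries

Spectra report counts and percentages of the three called levels;
undetermined calls are excluded from denominators (their complexity is
simply unknown). Per-parent summaries attribute each cross to both of its
parents. Shannon entropy is computed in base 2 (bits) over the observed
class frequencies of a parent's called crosses; divide by `log2(3)` ≈
1.585 for a normalised value, or multiply by `ln 2` for nats. The
variant-group comparison is a one-sided Welch t-test (group A lower),
Bonferroni-adjusted by the number of candidate variants tested in the
same gene; Welch is preferred over the pooled-variance test because
carrier groups of rare variants are small and unbalanced.

## Numerical and design notes

* All randomness flows through `numpy.random.Generator`; every public
  entry point takes a seed or generator, and batch generation is
  vectorised without changing the statistical model.
* The EM is hand-rolled and batched across panels (one array pass per
  iteration over all unconverged panels), which is what makes extracting
  features from 50,000 panels take ~40 s on one CPU. An independent
  brute-force likelihood grid search cross-checks it in the test suite.
* The two-vs-one-component statistic is *not* numerically equivalent to
  published EM-test statistics; it is a plain penalised LRT, documented
  above, and the forest is trained on it directly.
* Classification is stable under affine rescaling of a panel for clearly
  monogenic or clearly complex architectures; panels whose predicted
  weight sits near the calibrated threshold can flip under rescaling
  because the 11 quantile features are not scale-free. If phenotype
  scales vary wildly across conditions, normalising ratios per panel
  before classification is advisable.
* Benchmark problem sizes: the packaged benchmark trains on the full
  50,000-panel default set and evaluates on 2,000 held-out panels
  (ROC and rank correlation) plus 200 panels per planted class; the
  shared test model uses a 3,000-panel training set, which already ranks
  bimodality cleanly.

## Known limitations

* The monogenic window and parent-posterior cutoff are heuristics tuned
  to 160-spore panels; much smaller panels need wider windows.
* Oligogenic recovery is intrinsically imperfect: an epistatic pair of
  tightly linked loci segregates almost like a single locus and is
  legitimately called monogenic (~20% of planted epistatic panels).
* Experimental panels with missing spores keep their tetrad structure as
  NaN markers, but feature extraction requires complete panels; filtering
  or imputation policy is left to the caller.
* The classifier inherits the generative model's assumptions (binary
  loci, additive secondary background, Gaussian noise); phenotypes with
  heavy-tailed noise or strong transgressive segregation are outside the
  training distribution.
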