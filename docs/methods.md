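# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions that matter for reproducing results.

## GINI / NMD differential expression

Each individual contributes one two-color array: the treated channel
carries transcripts stabilised by NMD inhibition, the untreated channel the
baseline. The analysis models one observation per individual — the
normalized `ln(r/g)` ratio — so the "treatment" contrast in the mixed model
is affection status (affected man vs healthy brother), with the sibship as
a random intercept:

```
y_fi = mu + beta * affected_fi + u_f + e_fi
```

- **Background adjustment.** Per-channel median-background subtraction with
  a floor (default 1.0 intensity unit) so log-ratios stay defined on weak
  probes. The method is pluggable; nothing downstream depends on the floor
  except probes whose signal is at background level.
- **Quantile normalization.** Bolstad-style between-array normalization:
  every column is mapped to the mean of the sorted columns; ties receive
  the mean of the reference values at their tied ranks. This makes all
  column distributions identical while preserving within-column rank order
  — identical *sorted* columns are only guaranteed for tie-free data, which
  is why the tie convention is tested separately.
- **REML.** The restricted likelihood is profiled over the variance ratio
  `lambda = s2_fam/s2_res` and minimised by bounded scalar search on
  `log(lambda)` (tolerance 1e-10), with an explicit check of the
  `lambda = 0` boundary (the fit then degenerates to ordinary regression,
  flagged on the result). Covariance solves use the closed-form
  block inverse `(I + lambda*J)^-1 = I − lambda/(1 + lambda*n_f) * J`.
- **Degrees of freedom.** Containment: `n_families − 1`. In the balanced
  one-affected/one-healthy design the whole fit collapses analytically to
  the paired t-test (the between-pair means carry no information about
  `beta` once the intercept is free), and the test suite checks agreement
  to 1e-8. Satterthwaite approximations are deliberately not implemented;
  with 6–13 families the containment convention is exact for the design
  the study actually used.
- **Selection rule.** `beta > 0` and `p < alpha` with `alpha = 0.025`
  one gene at a time and no multiplicity correction — the screen is a
  candidate generator, not a confirmatory test. A fold-change threshold
  (affected-vs-healthy ratio of geometric means, e.g. `> 1.5`) and a
  location-based include list are optional refinements; stress-response
  genes are excluded by identifier list and reported with their own reason
  code. Whether the p-value should be one- or two-sided is genuinely
  ambiguous in this kind of screen; the implementation reports two-sided
  p-values and the directional sign constraint separately, so either
  reading is recoverable.

## Directional Kendall-tau family statistic

The tau-a correlation between two individuals' profiles over M features
treats tied pairs as contributing zero. Its distance `(1 − tau)/2` equals
the discordant-pair fraction (plus half the tied mass); splitting each
pair's mass equally between its two member features gives the per-feature
decomposition

```
c_m = sum_{m' != m} (1 − s_mm') / (2 M (M−1)),     sum_m c_m = (1 − tau)/2
```

which is exact, non-negative, and the only symmetric equal-split scheme.

- **Family components.** For multi-member families the base magnitude is
  the mean `c_m` over all (patient, healthy) pairs, keeping families of
  different sizes comparable. The sign compares mean within-profile ranks
  of the feature between status groups (`sign_mode="within-profile"`);
  ranking family members within each feature is available as
  `sign_mode="per-feature"` since both readings of "average rank
  expression" are defensible. A tied mean rank zeroes the family's
  contribution for that feature.
- **Permutation test.** Labels are permuted within families only,
  preserving each family's patient/healthy counts — the exchangeability
  the sibling design supports. Monte-Carlo p-values use the add-one
  estimator `p = (1 + #extreme)/(B + 1)` so p is never zero; exact
  enumeration over all `prod_f C(n_f, k_f)` labelings (bounded at 1e6) is
  available for audit and uses the plain proportion. For all-sibling-pair
  designs the permutation statistic is a signed sum of the observed family
  components, which the implementation exploits to vectorise over
  permutations.
- **Ward clustering.** Tau distances have no Euclidean embedding, so Ward
  is run as the Lance–Williams recurrence on the raw distances (the
  `ward.D` convention) with index-order tie-breaking; dendrograms are
  written as Newick.
- **Expression filtering.** Features detected in fewer than half the
  samples, then samples detecting fewer than half the remaining features,
  are dropped (floors configurable); the study's own filter thresholds are
  unknown, so these are exposed rather than asserted.

## Variant target-site deltas

The scorer approximates the published miRanda scheme: Watson–Crick +5,
G:U wobble +2, mismatch −3, affine gaps −9/−4, pair scores doubled at
miRNA positions 2–8 (the seed region that dominates recognition). A
perfect 22-mer duplex scores `5 * (7*2 + 15) = 145`. Alignment is
Smith–Waterman/Gotoh, miRNA 5'→3' against the window read 3'→5', with
deterministic tie-breaking (first maximal cell in row-major order;
pairing preferred over window-gap over miRNA-gap in traceback). A
per-pair energy surrogate (G:C −2.0, A:U −1.0, G:U −0.5 kcal/mol) is
accumulated over the optimal trace; the reported total is
`complementarity − lambda * energy` with `lambda = 0` by default, so the
total equals the alignment score unless a user opts into the surrogate.
Full nearest-neighbour thermodynamics and cross-species conservation
filtering are out of scope: the quantity of interest is the wild-type
minus mutant difference on equal windows (default ±25 nt around the
variant), and the top 5% of deltas (type-7 quantile, ties included) are
flagged.

A caution from testing: "variant destroys a seed match ⇒ delta = 16" holds
only when the mutant's best alignment keeps the wild-type register; the
optimum may recover a few points in a shifted register, so observed
in-site deltas range roughly 13–16 under the defaults. The invariant that
survives everything is `delta = 0` whenever no optimal alignment covers
the variant.

## Association statistics

Woolf (logit) intervals with `z = 1.959964` are the only standard method
consistent with every printed interval in the study's association table,
which is why they are the default and the acceptance anchor. The p-value
reported alongside is a Pearson chi-square (1 df, no continuity
correction); the test used for the published p-values is unstated, so
p-values are reported but never used as reproduction anchors. Zero cells
trigger the Haldane–Anscombe +0.5 correction with an explicit flag.
Carrier frequencies carry Clopper–Pearson exact intervals. The X-linked
Hardy–Weinberg check uses female genotypes only by default — males are
hemizygous and have no genotype to test — with optional pooling of male
alleles into the frequency estimate. Report rounding is 2 decimal places,
half-up.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; identical seeds give byte-identical files, and
the pipeline derives per-stage seeds from the master seed by stage name.

- **NMD arrays.** Linear-scale lognormal signal around a baseline
  intensity (default 1000) plus a known additive background (default 50)
  carried in the background columns, so background subtraction is exactly
  invertible as noise vanishes. "True" genes shift the treated channel by
  `effect_log_ratio` only in affected men; "stress" genes shift it in
  everyone. Planted genes are annotated to Xq27/Xq28 bands along with a
  configurable share of null probes. Not emulated: spatial artifacts, dye
  bias, probe-level correlation — the real arrays' noise model is unknown,
  and the lognormal choice is a stand-in, not an inference.
- **miRNA matrix.** Log-scale values with per-feature baselines drawn
  uniformly over an 8-unit span, a per-family random intercept shared by
  brothers (sd 0.5), iid noise (sd 0.3), and ±shift planted in patients.
  The uniform baseline is deliberate: a rank statistic is insensitive to
  shifts in features already at the extremes of the profile, so
  Gaussian-tail baselines would make a fixed shift invisible for a
  fraction of planted features — a real phenomenon worth remembering when
  interpreting the real data, but one that would make the generator's
  planted truth unrecoverable by construction.
- **Sequences.** Planted sites are full-length DNA reverse complements of
  a miRNA (hence containing the exact seed complement); site-disrupting
  variants hit seed-complementary positions with alleles chosen to break
  pairing, and the remaining variants avoid all planted sites. Bare
  7-nt seed sites are not used as planted truth because they are not
  dominant against random local alignments of a 22-mer.
- **Genotype tables.** Binomial carrier draws with the case probability
  solving the configured odds ratio against the control frequency;
  female genotypes multinomial at Hardy–Weinberg proportions.

Passing tests on these generators show the statistics behave as designed
under their own assumptions (exchangeability within families, additive
family effects, independent noise); they cannot show robustness to the
unmodelled features of real arrays listed above.

## Problem sizes and defaults in the shipped analyses

The numbered drivers use 2000 probes (10% in-region), the full
333-miRNA × 9-family design with B = 2000 permutations, 8 miRNAs × 40
variants for delta scoring, and the published carrier counts. The null
calibration and power checks in the test suite run 300 null miRNAs at
B = 2000 and 50 replicates of the planted-shift design, sizes at which the
Monte-Carlo bands being tested are meaningful.

## Known limitations

- The exact background-adjustment algorithm, the permutation count, the
  array filter thresholds, and the miRanda version/parameters used in the
  original study are unrecoverable; all are exposed as configuration with
  documented defaults rather than guessed silently.
- The mixed-model p-value relies on the containment-df t distribution;
  for strongly unbalanced designs with few families it is approximate.
- The energy surrogate is not a thermodynamic model; with
  `lambda > 0` the totals change scale and the 5% threshold with them.
- Exact enumeration grows as the product of per-family binomial
  coefficients and refuses designs beyond 1e6 labelings.
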