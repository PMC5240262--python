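# Methods

## Scoring framework

The packaged default framework encodes the nine orphan-drug criteria of
Hughes-Wilson et al. (2012), each with three ordinal levels scored 1–3
(1 = lowest attribution). The framework ships as a YAML file
(`src/orphanmcda/data/framework_default.yaml`) with stable snake-case
criterion ids used as join keys by profiles and scenarios; display names
carry the published wording. Serialisation round-trips exactly
(`load_framework(dump_framework(fw)) == fw`).

**Rarity binning.** Published level descriptions overlap at their printed
endpoints (1:2,000–1:20,000 vs 1:20,000–1:200,000). We adopt half-open
intervals with each shared endpoint assigned to the rarer, higher-scoring
bin: N ∈ [2,000, 20,000) → 1, [20,000, 200,000) → 2, [200,000, ∞) → 3,
where N is the prevalence denominator ("1 case per N"). A prevalence more
common than 1:2,000 is outside the orphan range and raises a domain error
rather than scoring 0: the framework defines no level below 1.

**Validation** is non-throwing and exhaustive: every missing criterion,
unknown id and out-of-range score across a batch is reported, so a file of
profiles can be fixed in one pass.

## Aggregation and scenarios

The aggregate is the weighted sum S_w = Σ w_i·s_i. Weights are
non-negative and normalised to sum to one on construction; inputs that
already sum exactly to 1.0 are left untouched so hand-constructed exact
weights survive. A zero weight excludes a criterion — its score provably
cannot move S_w — which is *not* the same as deleting the criterion and
renormalising the rest.

The base-case scenario uses exact ninths (printed weight tables round this
to 11.1%, summing to 99.9%; we treat those as rounded ninths). Scenario 2
(weights 14/0/0/0/6/30/20/30/0 %) drops the four criteria HTA bodies are
unlikely to weigh; Scenario 3 (10/20/10/0/15/15/10/20/0 %) re-admits two
of them. Published totals are sometimes plotted without stating whether
they are raw sums or weighted values, so every result carries
`weighted_score` (scale [1, 3]), `raw_sum` ([9, 27]) and
`percent_of_max` side by side, and downstream analyses declare which scale
they use (`--score-scale` on the CLI).

**Ranking** is competition-style (tied drugs share the better rank; the
next rank skips), with lexicographic drug-id ordering for display only —
determinism without implying false distinctions. Cross-scenario agreement
uses Kendall tau-b because competition ranking produces ties; tau-a would
be undefined-ish under tie groups.

## Annual cost construction

Annual cost = administrations/year × billed quantity/administration ×
unit price × exchange rate, assuming routine on-label use for a full
year. Weight-based regimens use a single assumed body weight per drug
(no separate paediatric/adult mix). Vial rounding (ceiling each
administration to whole vials) is opt-in and defaults off, matching an
average-dose costing that excludes wastage; administration, monitoring
and ancillary costs are out of scope. No default exchange rate is
shipped — the rate is a required input, since any built-in value would be
an invented number.

## Regression

`fit_score_cost` is simple two-variable OLS with intercept (via
`scipy.stats.linregress`), on linear or log10 cost; R² = 1 − SS_res/SS_tot
equals the squared Pearson r. It requires n ≥ 3, non-constant scores, and
positive costs on the log scale; degenerate inputs raise with a named
cause instead of returning a meaningless fit. No adjusted R² and no
inference are reported: with cohorts of a handful of drugs the statistic
is descriptive. The log scale is the sensible default choice for orphan
drug prices, which are positive and span orders of magnitude, but the CLI
refuses to guess — `--y-scale` is mandatory.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* criterion scores drawn independently per criterion from a categorical
  distribution over {1, 2, 3} (uniform by default);
* annual cost log-linear in the aggregate score with Gaussian noise,
  cost_j = exp(α + β·S_j + ε_j), ε_j ~ N(0, σ²).

The population R² of log-cost on S is β²Var(S)/(β²Var(S) + σ²), inverted
by `calibrate_noise`: σ = |β|·sd(S)·√(1/R² − 1). Under uniform
independent scores the raw-sum SD is √6, computed by
`theoretical_score_sd`. Defaults: n_drugs = 6 (a realistic prototype
cohort size), target R² = 0.79, α = 8.5, β = 0.12 per raw-sum point —
chosen once to place costs in the €10k–€500k per-patient-year range
orphan drugs span. All draws flow through one `numpy.random.default_rng`
seeded per cohort; equal configs give bit-identical serialised cohorts.

An optional shared per-drug latent tilt (`latent_weight` ∈ [0, 1)) mixes
one uniform draw into every criterion's inverse-CDF draw, inducing
positive criterion correlation within drugs; it slightly distorts the
marginal score distribution and is off by default because no dependence
structure is asserted by the framework.

What the generator does *not* emulate: real criterion dependence
structures, confidential-discount pricing, currency effects, or any
particular published cohort's values — so green tests show the pipeline's
estimators and plumbing are correct under the planted model, not that the
score-price correlation holds for real drugs.

**Small-n fragility.** At n = 6 the sample R² of a cohort calibrated to
0.79 is highly variable (observed range roughly 0.01–0.99 across 200
seeds; see `examples/05_synthetic_cohort.py`). The test suite therefore
asserts only that the median across 1,000 replicates lies within ±0.15 of
the target — documenting, not hiding, that a single six-drug R² is a
fragile statistic. (The median sits above the target because the small-n
sampling distribution of R² under this model is left-skewed.)

## Numerical choices

* Weighted sums use `math.fsum`; contribution sums match S_w to 1e-9.
* Scenario weight normalisation tolerance: inputs may be percentages or
  fractions; anything positive is accepted and divided by its total.
* Problem sizes in tests and the acceptance script — 100 random cases per
  estimator-oracle comparison, 20 seeds at n = 500, 1,000 replicates at
  n = 6, one 100,000-drug cohort for the calibration check — were chosen
  as the smallest sizes at which the corresponding sampling error is
  comfortably below the asserted tolerance.
* Exit codes (CLI): 0 success, 2 input/validation error, 3 I/O error.
  Figure *data* exports are always written; rendered plots only with
  `--plots`, keeping the pipeline testable without a graphics backend.
* Outputs carry a provenance comment/field (tool version, config hash,
  seed) and no timestamps, so reruns are byte-identical.

## Known limitations

* All criterion scores except rarity are analyst-asserted; the package
  validates but cannot audit them.
* The equal-interval 1–3 scale implies a 1→2 step is worth the same as
  2→3, an assumption inherited from the framework.
* The weighted-sum model is fully compensatory; outranking and
  value-measurement MCDA methods are deliberately out of scope.
* `calibrate_noise` targets the *population* R²; any single small cohort
  will scatter around it (see small-n fragility above).
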