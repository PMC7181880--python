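# Methods

`allorecall` simulates and analyses a landmark-based spatial-recall
experiment in which target locations are drawn from a condition-specific
prior distribution and participants must recall them in an allocentric
(world-based) reference frame. The package has three layers: generators
for the task (priors and trial structure), synthetic observers embodying
competing hypotheses about recall bias, and the bias analysis that
separates those hypotheses.

## Task model

The environment is a flat plane (meters, origin at the circle center)
with a circle of radius 1.3 m and three identical beacons at
(−0.65, 0), (0, 0.65) and (0, −0.65). Four conditions define the target
prior:

| condition          | prior                                              |
|--------------------|----------------------------------------------------|
| `beacon_normal`    | isotropic Gaussian, mean (−0.65, 0), SD 0.15 m     |
| `non_beacon_normal`| isotropic Gaussian, mean (0.65, 0), SD 0.15 m      |
| `beacon_donut`     | ring about (−0.65, 0): uniform angle, radial normal with mean 0.35 m, SD 0.07 m |
| `offset`           | isotropic Gaussian, mean (−0.65, 0.25), SD 0.15 m  |

Targets are constrained to the inner 98% of the prior by rejection
sampling. "Inner 98%" is operationalized as the isodensity region: for
Gaussian priors, squared Mahalanobis radius at most the 98% quantile of
a chi-square with 2 df; for the ring prior, the radial coordinate within
±2.3263 SD of the radial mean (the central 98% of its normal law).
Per-axis and other readings of the truncation are conceivable; the
isodensity/radial reading reproduces the 5 cm mean mode-to-target
distance the design diagnostics require (see below), and the quantiles
are computed from `scipy.stats`, not hard-coded.

A session has 60 trials of 3 simultaneous targets. The first 30 trials
use 90 fresh draws; the second 30 re-use exactly those 90 locations,
randomly re-partitioned into new triplets in a new order, so the
empirical prior exhibited in the first half is exactly the prior in
force during the analysed second half. Viewpoint displacement fractions
(1/8 … 7/8 of a turn) are tiled to 63, truncated to 60 and shuffled; any
full-coverage scheme would do, since displacement is not otherwise
modelled. Each session splits its master seed into independent
substreams for targets, re-grouping and displacements, so regenerating
one stream cannot perturb another.

The vertical dimension, the encoding column, and all rendering are
outside scope: only floor-plane coordinates matter to the statistics.

## Observer models

Every observer first forms a noisy memory of each target: the target
plus isotropic Gaussian noise with per-axis SD `sigma_mem`. The default
`sigma_mem = 0.16` m makes the null observer's mean recall error (the
Rayleigh mean `sigma * sqrt(pi/2)`) ≈ 0.20 m, the magnitude of recall
error the simulated task is designed around. Viewpoint rotation is not
modelled separately; its contribution to imprecision is absorbed into
`sigma_mem`. An optional per-trial `swap_prob` exchanges two memories
(mis-binding); it defaults to 0.

* **null** reports the memory unchanged.
* **beacon_attraction** pulls each memory a fraction `attraction_gain`
  of the way toward its nearest beacon.
* **bayes** combines the memory (likelihood, Gaussian with SD
  `sigma_mem`) with the condition prior and reports a posterior
  read-out. The posterior is computed on a square grid (step 1 cm,
  extent = prior support + 4·`sigma_mem` margin, normalized by the grid
  sum). The prior placed on the grid is the *untruncated* density — an
  ideal learner inferring a smooth law from 90 samples would not infer
  the rejection boundary. The Gaussian likelihood is separable in x and
  y, so posterior means cost two small matrix contractions per memory
  and full studies run in seconds.

### Read-out choice (posterior mode vs mean)

The default Bayesian read-out is the posterior mode (grid MAP), with the
posterior mean available via `estimator="mean"`. For the Gaussian
conditions the two coincide (the posterior is symmetric and unimodal)
and match the conjugate closed form
μ_post = μ + w·(m − μ), w = σ_prior²/(σ_prior² + σ_mem²),
which the tests verify to within one grid step. For the ring prior they
differ sharply: the posterior is an arc, and its *mean* falls inside the
ring, off the posterior ridge, at a location the observer itself assigns
low probability. Measured with the distance-to-modal-circle statistic,
the posterior-mean observer shows essentially no prior-mode bias
(≈ +0.1 cm, n.s., at `sigma_mem = 0.16`) even though it reduces mean
squared error by ~40%; the posterior-mode observer shows a clear
+3 cm bias. Since the prior-using observer exists here to generate the
"responses biased toward the prior mode" signature that the analysis is
designed to detect — and since for every unimodal symmetric posterior in
the design the mode equals the mean — the mode is the default. The MSE
superiority of the Bayesian observer over the null observer holds under
both read-outs and is tested under both.

### Attraction gain and noise convexity

Unbiased isotropic noise *inflates* expected Euclidean distances:
E‖t + ε − b‖ > ‖t − b‖. At `sigma_mem = 0.16` this inflation is large
(e.g. targets in `beacon_normal` average 0.19 m from the beacon, noisy
memories 0.27 m), so an attraction observer measured with the
target-minus-response distance statistics starts ~9 cm in the *negative*
direction in that condition. A token pull of a few percent toward the
beacon cannot overcome this; the measured beacon bias only turns
positive once the gain exceeds ≈0.3. The default
`attraction_gain = 0.4` is the smallest round value that produces a
positive measured beacon bias in all four conditions (≈ +2 to +12 cm),
i.e. an observer that genuinely exhibits the non-learned-bias signature
rather than being swamped by its own noise. The signed-x statistic used
in `non_beacon_normal` is linear, hence immune to the convexity effect,
and is positive at any gain.

## Bias analysis

Only second-half, non-excluded trials are analysed by default (the
first half is the learning opportunity); a flag allows analysing both
halves. Per participant, four statistics are averaged over exposures:

1. mean distance from the prior mode to the targets,
2. the same for responses,
3. mean distance from the local beacons to the targets,
4. the same for responses.

For the ring prior the "distance to the mode" is
|‖p − center‖ − 0.35| — the distance to the nearest point of the modal
circle. For `non_beacon_normal` the beacon statistic is the signed
x-coordinate (the whole beacon array lies leftward, so moving left *is*
moving beacon-ward); it is kept signed because the hypothesis is
directional. The bias scores are (1) − (2) and (3) − (4); positive means
responses pulled toward the feature.

Trials are excluded as gross outliers when every target is nearest the
left beacon but at least one response is nearest another beacon — a
wrong-landmark error, not imprecision. The rule is scoped to the three
conditions whose targets concentrate near the left beacon (its premise
cannot hold in `non_beacon_normal`); flags generalize the rule ("any"
target, all conditions). Exclusion flags are set before summarization
and excluded trials drop out of every statistic.

Condition-level inference is a one-sample, one-tailed t-test across the
12 per-participant bias values (df = 11), with Cohen's d = mean/SD
(hence t = d·√n identically) and a conventional two-sided 95% t-interval
for plotting. No multiple-testing correction is applied, matching
per-condition reporting; a Bonferroni option exists but is off by
default. A study-level classifier makes the verbal decision logic
explicit: prior-mode bias significantly positive everywhere (including
off-beacon-mode conditions) → `rapid_prior_use`; beacon bias positive
everywhere while prior-mode bias is not positive off-beacon →
`non_learned_biases`; anything else → `null`.

Two per-trial utilities support design diagnostics rather than the bias
scores (which are pairing-free): the minimum-error pairing of the three
responses to the three targets (six permutations; implemented with the
assignment solver and cross-checked against brute force) and the
distance between target and response centroids.

### Calibration of the test under the null

The one-tailed test's nominal type-I rate applies to a statistic whose
null expectation is zero. That holds exactly for the signed-x beacon
statistic, and simulation confirms a ≈5% rejection rate there. The
Euclidean-distance statistics have *negative* expectation under the null
observer (the convexity effect above), so the positive-direction test is
conservative for them: its null rejection rate is far below α. Observed
positive biases are therefore stronger evidence than the nominal level
suggests, not weaker.

## Synthetic data: what it does and does not emulate

The generators reproduce the task's statistical structure: prior shapes
and truncation, trial counts, the half-to-half re-grouping, displacement
schedule, response noise magnitude, and optional mis-binding. They do
not emulate learning dynamics within a session (observers either use the
prior fully or not at all), heading recovery after teleportation,
feedback-driven adaptation, or any participant heterogeneity beyond
independent noise streams. Passing tests therefore demonstrate that the
pipeline's logic, statistics and decision rule behave as designed under
the stated generating models — not that human data would match any of
those models, nor do they reproduce human-level effect sizes (measured
human biases in such tasks are ~1–3 cm; the synthetic generators are run
at parameters that make their signatures unambiguous at n = 12).

## Numerical choices and problem sizes

Grid step 1 cm with a warning when the step exceeds `sigma_mem`/3; a
memory far enough outside the grid to underflow the posterior raises
rather than returning garbage. Ring density at the center is floored at
r = 10⁻⁴ m to stay finite (the radial law carries ~10⁻⁴ of its peak
density there for the default parameters). Nearest-beacon ties break to
the lowest index. Rejection sampling oversamples by ~10% per pass
(acceptance is 98%). Monte-Carlo checks use 10⁵ draws for generator
moments, 10³ replicates for type-I calibration, 12 participants × 4
conditions for study-scale runs; noise-SD recovery inverts the Rayleigh
mean on the true target–response correspondence at 12 × 30 analysable
trials, recovering the generating value within a few percent.

## Known limitations

* The minimum-error paired target–response distance under the null
  observer at `sigma_mem = 0.16` is ≈18.6–19.4 cm, slightly below the
  true-correspondence mean of 20.05 cm, because the best of six pairings
  is selected; the noise calibration targets the true-correspondence
  error.
* The grid MAP is quantized to grid nodes (≤ 0.5 cm per axis); bias
  statistics are means over hundreds of exposures, so the quantization
  noise is negligible at the centimeter scale analysed.
* The classifier treats per-condition significance as the unit of
  evidence, mirroring per-condition reporting; it is a transparent rule,
  not a model comparison (no Bayes factors, by design).
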