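# allorecall

Simulation and bias analysis of allocentric spatial recall with learned
priors and landmark beacons.

## The problem

Can people rapidly learn and exploit the long-run statistical
distribution of locations (a spatial *prior*) when they must remember
those locations in an allocentric, world-based frame — relative to
stable landmarks rather than to their own body? A normative Bayesian
observer would: given a noisy memory (the likelihood) and a learned
prior, its response is shrunk toward the prior mode, so its responses
end up *closer to the prior mode than the targets themselves*. The
competing account is that responses are biased toward the landmark
beacons regardless of the prior; the null account is noise with no
systematic bias.

`allorecall` builds this experimental logic as a tested pipeline for
researchers in computational cognitive science: generators for the
task's four prior conditions and its trial structure, synthetic
observers embodying the three hypotheses, and the bias analysis that
discriminates them. With no public human dataset for this design, the
package serves as a design/power workbench and an executable
specification of the analysis; real sessions in the documented CSV
format can be fed straight into `allorecall analyze`.

## The model in brief

Targets live on a floor plane (meters) with three beacons at
(−0.65, 0), (0, 0.65), (0, −0.65). Each condition draws targets from a
prior truncated to its inner 98%:
Gaussians with SD σ_p = 0.15 m centered on a beacon (`beacon_normal`),
opposite the array (`non_beacon_normal`), or offset from a beacon
(`offset`); and a ring ("donut") prior about the left beacon with
radial mean 0.35 m and SD 0.07 m (`beacon_donut`). A 60-trial session
shows 3 targets per trial; the second half randomly re-groups the first
half's 90 locations, so the learnable prior is exact at the midpoint.

Memory noise is isotropic with SD σ_m (default 0.16 m, giving a mean
recall error σ_m·√(π/2) ≈ 0.20 m). The Bayesian observer responds with
a read-out of the grid posterior p(x|m) ∝ prior(x)·N(m; x, σ_m²I); for
Gaussian priors this reproduces the conjugate shrinkage
μ + w(m − μ), w = σ_p²/(σ_p² + σ_m²). The attraction observer moves
each memory a fixed fraction toward its nearest beacon; the null
observer reports the memory unchanged.

Per participant, over second-half non-excluded trials, the analysis
computes mean distances from prior mode and from the beacons, for
targets and for responses; the differences are the **prior-mode bias**
and **beacon bias** (positive = responses pulled toward the feature).
Per condition, a one-tailed one-sample t-test across 12 participants
(with Cohen's d = mean/SD) tests each bias, and the cross-condition
pattern is classified as `rapid_prior_use`, `non_learned_biases`, or
`null`. See `docs/methods.md` for the full treatment.

## Worked example

Simulate a full study generated by the beacon-attraction observer and
classify the resulting bias pattern:

```bash
$ allorecall study --model beacon_attraction --seed 42
        condition  n  bias_type  mean_diff_m          t  df  p_one_tailed   cohens_d  ...
    beacon_normal 12 prior_mode     0.018694   7.674362  11  4.837907e-06   2.215397
    beacon_normal 12     beacon     0.018694   7.674362  11  4.837907e-06   2.215397
non_beacon_normal 12 prior_mode    -0.279853 -99.121146  11  1.000000e+00 -28.613810
non_beacon_normal 12     beacon     0.260244  78.793848  11  8.564423e-17  22.745825
     beacon_donut 12 prior_mode    -0.091132 -33.900961  11  1.000000e+00  -9.786364
     beacon_donut 12     beacon     0.128180  47.053354  11  2.446766e-14  13.583133
           offset 12 prior_mode    -0.003567  -1.428368  11  9.095206e-01  -0.412334
           offset 12     beacon     0.082557  25.464773  11  1.975090e-11   7.351047
hypothesis supported: non_learned_biases
```

Reading the table: in every condition the beacon bias is significantly
positive (responses end up nearer the beacons than the targets were —
e.g. +1.9 cm in `beacon_normal`), while the prior-mode bias is positive
only where the mode sits on a beacon and goes negative where mode and
beacon dissociate. That is exactly the signature of non-learned
landmark attraction, and the classifier says so. Running with
`--model bayes` instead yields positive prior-mode bias in all four
conditions and the label `rapid_prior_use`; `--model null` yields
`null`.

The design diagnostics (distances in cm) show why the design has room
to detect prior use — the prior is much tighter than memory noise:

```bash
$ allorecall diagnostics --samples 100000 --seed 1
        condition  mode_dist_truncated_cm  mode_dist_untruncated_cm  recall_error_cm  min_error_dist_cm
    beacon_normal                   18.17                     18.75            20.05              18.62
non_beacon_normal                   18.18                     18.77            20.03              18.58
     beacon_donut                    5.33                      5.55            20.12              19.42
           offset                   18.24                     18.78            20.01              18.57
```

Targets sit ~5 cm from the modal circle in the donut condition and
~19 cm from the mode in the Gaussian conditions, against a ~20 cm
recall error. Other entry points: `allorecall simulate` writes session
CSVs (one row per exposure), `allorecall analyze` runs the bias
analysis on session CSVs, and `allorecall recover` checks that the
generating memory-noise SD can be recovered from simulated data:

```bash
$ allorecall recover --seed 3
sigma_true=0.1600 m  sigma_hat=0.1556 m  relative error=2.74%  (mean recall error 19.50 cm over 1080 exposures)
```

Everything is also available as a library (`allorecall.make_condition`,
`build_session`, `simulate_responses`, `participant_summary`,
`condition_test`, `simulate_study`, ...).

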