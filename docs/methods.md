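# Methods

## The delta computation and its propagated standard error

A bracketed observation consists of three acquisitions in sequence order:
bracketing standard (`mu_b1, sigma_b1`), sample (`mu_s, sigma_s`),
bracketing standard (`mu_b2, sigma_b2`), each a mean isotope ratio with the
standard error of that mean over its integration cycles. The delta value is

    delta = ( mu_s / m - 1 ) * 1000,   m = (mu_b1 + mu_b2) / 2   [per mil]

Adjacent brackets share a standard acquisition (the standard closing one
bracket opens the next), which is the standard alternating-acquisition
practice; two samples with no standard between them are rejected rather
than averaged, because the scheme is strictly standard-sample-standard.
The two brackets enter with equal weight: the sample sits midway between
them in acquisition time, which is also the condition under which a linear
mass-bias drift cancels exactly in `m` (verified to 1e-9 per mil in the
simulator tests). A common multiplicative factor on all three ratios
cancels algebraically, which is the point of the method.

First-order (Taylor) propagation of the three standard errors through the
formula gives the per-delta standard error

    SD_delta = (1000 / m) * sqrt( sigma_s^2
               + (mu_s / (2 m))^2 * (sigma_b1^2 + sigma_b2^2) )

This expression was derived here by differentiating the delta formula and
is gated by two independent oracles in the test suite: a 1e6-draw
brute-force sampler of the formula (agreement within 1 % relative, which is
the sampling error at that draw count) and a central-finite-difference
gradient combined in quadrature (agreement within 1e-6 relative). At the
relative standard errors encountered in practice (1e-5 to 1e-3) the
linearisation error is second-order and negligible against both oracles.

## Deviations, validation tests, and the two uncertainty tiers

For sample *j* with accepted value `delta_true_j`, each measurement yields
a deviation `Delta_ij = delta_ij - delta_true_j`. When no literature value
exists the sample's own mean delta is substituted; the mean deviation is
then exactly zero by construction (it is computed as difference of means,
so the identity holds in floating point too), the one-sample t statistic is
zero and its p-value 1.0000. When several literature values exist they are
averaged, and the individual values are retained for reporting.

Pooling deviations across samples puts every sample on a common zero, so a
single reproducibility estimate can serve any newly measured sample. On
the pooled set (and per sample) the package reports:

* `SD_Delta`: sample standard deviation of the deviations, n-1 denominator
  (the metrology convention for reproducibility estimates; the choice
  matters at the percent level for small n and is fixed here).
* `U = z * SD_Delta` with `z = 1.959964`, the exact 0.975 standard normal
  quantile (not 1.96; both round identically at two decimals). `U` is the
  95 % bound for the difference between a new delta and its true value,
  justified by the normality and zero-mean tests below.
* Shapiro-Wilk p-value (validity range 3 <= n <= 5000; outside it, or for
  zero-variance input, the report carries an explicit not-applicable
  marker, never a silent default) and a two-sided one-sample t-test
  p-value for mean zero. Two-sided because the alternative of interest is
  any displacement of the deviation population.

The Monte Carlo tier recognises that each delta also carries its own
`SD_delta`. In every MC run, each deviation is perturbed by independent
zero-mean normal noise with standard deviation equal to its own `SD_delta`,
and the per-sample and pooled standard deviations are recomputed on the
disturbed set; `SD_Delta^MC` is the arithmetic mean of the per-run standard
deviations (exactly that, not the root-mean-square of per-run variances —
the two differ slightly and the mean-of-SDs convention is the one
implemented). The default is 1e6 runs; 1e4 runs reproduce it to well under
0.5 % relative on desk-scale datasets and are used in the test suite. For
independent noise of constant scale sigma over a long series the estimator
converges to `sqrt(SD_Delta^2 + sigma^2)`, which is the closed-form check
used in the tests. With all `SD_delta = 0` the implementation returns
`SD_Delta` exactly at any run count (the degenerate case is short-circuited
rather than sampled).

Noise is drawn observation-major within each run, with observations taken
in a canonical (seq_index, label) order, so results are bit-reproducible
from (data, runs, seed) and independent of the order in which sample series
are supplied. Noise is generated as standard normals scaled by `SD_delta`,
which makes the whole report exactly scale-equivariant under a common
rescaling of deltas, references and standard errors at fixed seed.

The ratio `SD_Delta^MC / SD_Delta` drives a per-row diagnostic flag
(threshold 1.5 by default): below it the uncertainty is
reproducibility-dominated (the absolute ratios were measured precisely and
the spread between deltas dominates); above it the individual absolute
ratios were measured with comparatively low precision, the pattern seen in
low-concentration geological samples where `SD_Delta^MC` can exceed
`SD_Delta` several-fold.

## The synthetic-run generator

`simulate_run` emulates the structure of a real bracketing sequence, not
the plasma physics: a standard of fixed true ratio (default 0.0873/0.2377
= 0.3673, the natural-abundance 82/78 selenium ratio), samples whose true
ratios are offset by known deltas, a multiplicative drift over acquisition
index (none, linear, or geometric random walk with per-step relative SD
`drift_rate`), and per-acquisition ratio noise of relative SD
`cycle_rsd / sqrt(n_cycles)`. The reported `std_error` column carries the
nominal (true) standard error rather than a per-acquisition empirical
estimate, so a noiseless configuration is exactly noiseless. Noise is
placed directly on the ratio level — the whole statistical pipeline
operates on ratio-level means and standard errors, so simulating
per-isotope intensities would add no testable surface. Defaults
(`cycle_rsd = 5e-4`, `n_cycles = 60`, `drift_rate = 9e-5`) were chosen once
to land the propagated per-delta standard errors near 0.08 per mil and the
bracket-to-bracket scatter near 0.065 per mil, the magnitudes typical of
hydride-generation MC-ICP-MS selenium work; no published numeric drift rate
exists, so the drift default is an order-of-magnitude choice and fully
overridable.

What the generator does **not** emulate: session-to-session (different-day)
reproducibility structure, blank and interference drift, heteroscedastic
cycle counts, and correlated noise between the two isotope beams. Passing
tests therefore demonstrate the internal consistency and coverage of the
estimators under the stated noise model, not the trueness of any real
measurement.

An optional heavy-tailed probe (`cycle_noise_df`) replaces the normal cycle
noise by a Student t of the given degrees of freedom, scaled by the nominal
standard error but not variance-standardised, while the `std_error` column
keeps claiming the normal-model value. This is a deliberate model
violation: in measurement-dominated configurations the normal-quantile
bound loses coverage relative to its normal-noise counterpart.

## The coverage experiment

For each replicate dataset, the pipeline runs end to end on simulated
calibration data (deltas, deviations against the known true values, pooled
`SD_Delta^MC`, `U^MC`), then fresh held-out measurements from the same
configuration are checked against `|delta - delta_true| <= U^MC`. An
absolute guard of 1e-12 per mil is applied in the comparison so that a
noiseless configuration (where both sides are zero up to float rounding)
counts as covered.

The nominal-coverage validation uses a reproducibility-dominated
configuration (random-walk drift dominant, measurement variance about 9 %
of the total delta variance; calibration sets of 50 brackets, held-out
sets of 10). This is the regime in which `U^MC` is approximately
calibrated: because a held-out delta's spread already contains its own
measurement noise, `U^MC` — which adds the propagated errors on top of the
empirical spread — is intentionally conservative, and its overshoot grows
with the measurement-noise share (about +1 coverage point at a 9 % share,
analytically `2*Phi(1.96*sqrt(1+q))-1` for share q). Treating it as a 95 %
bound is therefore safe rather than optimistic, which is the design intent
of the two-tier scheme.

## Numerical and interface choices

* Deltas are stored in per mil at full precision; report tables round to
  two decimals (p-values to four) and the JSON report retains full
  precision plus the MC run count and seed, so written reports are exactly
  reproducible and round-trip numerically identically.
* Input tables auto-detect comma vs tab from the header line; output is
  always tab-delimited; `#` lines are ignored; role labels are normalised
  case-insensitively. Parse errors carry file and line number.
* Degenerate inputs: single-observation series yield NaN standard
  deviations (n-1 convention) and not-applicable test markers; zero
  coverage or nonpositive ratios raise errors rather than propagate.
* All RNG use goes through `numpy.random.default_rng` with explicit seeds;
  every randomised CLI command logs its seed and run count to stderr.

## Known limitations

* The uncertainty budget covers only the ratio-measurement statistics: no
  weighing, dilution, blank or interference terms, and no outlier
  rejection.
* `U^MC` conservatism in measurement-dominated regimes (above) means the
  reported bound can over-cover when `SD_delta` is large relative to the
  reproducibility spread — exactly the situation its diagnostic flag is
  designed to surface.
* The t-test and Shapiro-Wilk validation assume independent deviations;
  drift-induced correlation between brackets sharing a standard is ignored
  (it is second-order for the magnitudes simulated here).
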