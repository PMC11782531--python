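# Methods

This note records the statistical model the package implements, the
conventions and numerical choices behind it, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
the procedure was genuinely open.

## The image-formation model

A scintillation-coupled CCD converts each beam electron into hundreds to
thousands of secondary quanta (photons, then charge carriers), which
spread laterally with the composite detector PSF `Omega_d` before being
counted.  Because the quanta of one electron share a common origin, the
convolution acts on the *realized* Poisson noise, not only on its
expectation; the counts are therefore a scaled ("super-") Poisson variable
whose variance is `g * S_c` reduced by a smoothing factor
`beta = beta_conv * beta_corr`:

* `beta_conv = [Omega_d (x) Omega_d]_{0,0} = 1 / sum(rho)` — the variance
  reduction by convolution, equal to the reciprocal of the summed Pearson
  coefficients of the induced correlation;
* `beta_corr` — the bias of a *within-frame* sample variance on a finite
  M x N grid of correlated pixels,
  `beta_corr = MN/(MN-1) (1 - (MN)^-2 sum (M-|m|)(N-|n|) rho_mn)`,
  bounded by 0 (total correlation) and exactly 2 (total anti-correlation).

On top of the signal chain sit, per ADC quadrant: Gaussian read-out noise
`sigma_read` around a bias offset (~252 counts), a per-row bias
fluctuation `sigma_row` constant along each row, and Poisson dark current
accumulating with exposure time.  A static quantum-efficiency pattern
(unit-mean gain map, spread `sigma_QE` ~ 6.7 %) multiplies the signal; a
third-order polynomial distortion models charge-well saturation; and the
PSF widens slightly with signal (brighter-fatter effect), parameterized by
a smoothing factor `beta_BF(S)` normalized to 1 at the gain-reference
intensity.

The gains of the individual detector layers (fluorescence, fiber optics,
CCD, ADC) are not separately identifiable on a closed camera, so the model
exposes only the composite `g` (counts per beam electron) and a
charge-to-count conversion gain `g_c`, which defaults to 1 so that all
noise parameters are stated directly in counts.

## Estimators and their conventions

**Autocovariance.**  All correlation estimates use the circular
(periodogram) estimator: `K = F^-1[|F[frame - mean]|^2 / (MN)]`, unfolded
onto a centred odd lag grid, with `K_{0,0}` equal to the frame's mean
squared deviation.  Accordingly, every synthetic-data oracle in the test
suite uses *circular* convolution.  A periodogram estimate sums to zero
over one circular lag period, which pushes the estimated far lags slightly
negative; downstream estimators therefore clip negative autocovariance
entries (`K+`) exactly where the measurement procedure calls for it — in
the signal-difference terms of the gain-reference and smoothed-gain
estimators — while dark-difference autocovariances are left signed, since
genuine read-noise anti-correlation would otherwise be destroyed.

**Gain-reference uncertainty `k_ref`.**  Two independent routes are
implemented: the spread of the difference of two same-protocol references,
`k = SD(map_A - map_B) / sqrt(2 (1 + sigma_ref^2))`, and the
autocovariance route,
`k^2 rho = mean_pairs(K+(dSig) - K(dDark)) / (2 (1 + sigma_ref^2) w S_ref^2)`.
The latter's central element equals the closed form
`k^2 = (beta g S_ref + 2 sigma_d^2)/(w S_ref^2)` up to an
`O(sigma_d^2 / beta g S_ref)` (~0.1 %) term; the two estimators agree at
the per-cent level on simulated stacks, with the autocovariance route
biased marginally low — the residual of the periodogram's zero-sum
property.

**Smoothed gain.**  From gain-normalized flat frames,
`K_sig = (K+(xi* - S_c) - S_c^2 k_ref^2 rho_ref - K(xi_DB)) / (1 + k_ref^2)`,
where `k_ref^2 rho_ref` is the reference's *noise* autocovariance (from
the route above, so the subtraction carries the correct PSF shape) and
`K(xi_DB)` a gain-normalized dark-difference autocovariance.  `beta*g` is
the central element over `S_c` after the `beta_corr` adjustment (which is
negligible, ~1/MN, at the frame sizes used).  The same field, restricted
to the 3 x 3 nearest-neighbour block (higher lags are estimator noise),
yields the brighter-fatter curve `beta_BF(S)` as the reciprocal local sum
normalized at the reference intensity, summarized by a ridge-damped
Pade [4/5] rational fit (ties in degenerate fits resolve toward low-order
behaviour).  An 8-neighbourhood is the default; 4 is available.

**Detector-noise decomposition.**  Ordinary least squares of dark-pair
variance against exposure time gives `2 sigma_read^2` (intercept) and
`2 g_c I_dark` (slope) per quadrant, with 95 % confidence intervals from
the regression.  For this decomposition the per-row means are subtracted
*exactly* (not rounded), with an `ncol/(ncol-1)` degrees-of-freedom
correction and removal of the pixel-noise leakage `var/ncol` from the
row-mean variance — at desk-scale quadrant widths the row-mean measurement
error is not negligible relative to 0.5 counts, so the integer-rounding
shortcut that is exact on a 1024-column quadrant would bias `sigma_row`
upward by ~20 %.  The artifact-removal path (`split_row_noise`) keeps the
rounding convention (nearest integer, ties away from zero), where it is
the right tool: it avoids biting into read noise when the row bias steps
are integer-valued.

**PSF reconstruction.**  `Omega_d = F^-1[(K_sig - G_corr)^(1/2)]`, where
`G_corr` is an offsetted 2-D Gaussian fitted to the Pearson field with the
PSF-dominated core excluded (default exclusion radius 10 px, an order of
magnitude above the ~2 px core FWHM).  Two numerical choices matter at
desk scale: (i) frames are gain-normalized *before* differencing —
otherwise the QE modulation of the Poisson noise adds a white component to
the autocovariance whose Fourier square root artificially sharpens the
kernel by ~3 % in FWHM; (ii) lags beyond a window radius (default off; the
pipeline uses ~12 px) are zeroed after the surface subtraction, since the
square root of pure estimator noise otherwise biases the kernel tails.
The FWHM is read from the radial profile interpolated on exact pixel
radii.

**Beam-correlation probability.**  In the Pearson field the broad beam
term carries weight `2p(1-p)` against the `(1-p)^2` core, so
`p = r/(2+r)` with `r` the ratio of the fitted surface amplitude to the
summed core coefficients.  The `p^2` term is treated as part of the fitted
constant offset.  This algebraic convention is one of several possible
readings of the mixture model; it is exposed, documented, and validated by
forward–inverse consistency on the simulator rather than asserted as
unique.

**Non-linearity fit.**  The linearization
`g_lin(xi) = xi / (xi - x1 - x2 xi^2 - x3 xi^3)`, normalized to 1 at the
mean raw signal of the gain reference, is found by minimizing the misfit
between measured flat-frame variances and the variance model over an
intensity ladder, re-deriving the corrected gain reference and all
dependent statistics at every iterate.  Three identifiability choices were
forced by experiment on simulated data:

1. the reference uncertainty `k` is *tied* to its closed form and
   recomputed from the corrected reference per iterate — fitting `k`
   freely is exactly degenerate with the quadratic coefficient through the
   `k^2 S^2` term;
2. the polynomial is released in stages (x2 alone, then x3, then x1), and
   a higher-order stage is kept only when it at least halves the misfit —
   the constant term trades against a near-linear remap of the counts axis
   that the variance data barely constrains, so an unguarded 4-parameter
   simplex reliably walks into a degenerate valley at the noise level;
3. the smoothed gain is profiled out by an inner weighted-least-squares
   step, so the outer derivative-free simplex works in at most three
   dimensions.

The bracketed-repeat-exposure (BRE) validation rescales each measurement
by its bracketing fixed-exposure reference means, subtracts a weighted
baseline line fitted below a configurable threshold (default 6600 counts),
and tests the residual slope.  Both regressions are weighted by per-point
uncertainties (frame-mean noise plus bracket-ratio noise, which grows with
signal), and the baseline's own slope uncertainty is propagated into the
residual-slope confidence interval — without it the test rejects linear
detectors on extrapolation noise alone.

**Binning.**  Post-binning propagates the Pearson coefficients through the
summation weights (`(H-|h|)(V-|v|)`, horizontal bins pairing with column
lags), recomputes `beta_conv` from the binned coefficient sum and
`beta_corr` on the binned grid, and evaluates the binned reference
uncertainty `k_{H,V}` from the closed form with the binned `beta`.  The
distribution factor used alongside `k_{H,V}` is the *normalized* variant
`alpha = HV sum (S/sum S)^2` (1 for flat signal): the correlation
enhancement of the summed fixed-pattern noise is already contained in
`k_{H,V}` through `beta_{H,V}`, and pairing `k_{H,V}` with the literal
(`1/HV`-for-flat) factor double-discounts it — the literal factor remains
available as `alpha_factor` for uses where the unbinned `k` appears.  The
spectrum (EELS) model is the `H = 1` special case summed over the
spectrum band, with per-channel detector noise given by the two quadrants
each column crosses and `alpha` evaluated from a 2-D zero-loss-peak image
(a peak concentrated in a few rows has normalized `alpha >> 1`).

## The synthetic-data generator

`ccdnoise.simulate` is first-class, tested code, and its defaults are the
study conditions used throughout: flat fields at ~7050 counts per 0.84 s
frame, smoothed gain `beta*g = 1.55` counts/electron realized as a
Gaussian PSF of FWHM 2.0 px (so `beta_conv ~ 0.11`, `g ~ 14`),
`sigma_read = 4.0`, `sigma_row = 0.6`, offset 252 counts, QE spread 6.7 %,
dark rate 1.2 counts/s, 2 x 2 ADC quadrants.  Gain-reference protocols use
30 signal + 30 dark frames; frames are 256 x 256 (128 x 128 where a test
needs many of them) — statements about precision therefore refer to these
problem sizes.

Choices the generator makes, and their limits:

* **Beam correlation** follows the mixture-kernel picture: the realized
  source-plane Poisson noise spreads with `p * Omega_TEM + (1-p) * delta`,
  so the induced Pearson weights are exactly the `p^2 / 2p(1-p) / (1-p)^2`
  triple of the model's algebra, and the `estimate_p` inverse is
  self-consistent with the forward model.  On a desk-scale frame the beam
  disc cannot be orders of magnitude larger than the sensor, so the
  `p^2` term is not perfectly constant and the periodogram's zero-sum
  property eats part of the broad surface — `p` recovery is
  order-of-magnitude at `p ~ 1e-3` and the fitted surface width is
  underestimated, a distortion that grows with the disc-to-frame ratio.
* **Brighter-fatter blur** is an extra count-conserving Gaussian blur
  whose per-axis kernel comes from inverting the Fourier relation at the
  configured `beta_BF(mean counts)`; it is applied *before* the gain map,
  keeping the fixed pattern purely multiplicative as the model assumes.
  A real detector diffuses charge after the pattern is imprinted, which
  would make the gain reference slightly intensity-dependent — that
  second-order effect is deliberately outside the model and the generator.
  The blur is evaluated at the frame's mean signal, not per pixel.
* **Row bias** is drawn as a continuous Gaussian per row per read-out
  (independently between frames); the integer-valued bias steps of real
  hardware are a property of particular ADCs that the model's Gaussian
  term does not encode.
* **Non-linearity** distorts the accumulated (offset-free) charge-well
  counts before read noise is added, while the correction operates on
  offset-inclusive raw counts; the resulting mismatch is a pure gain/offset
  shift absorbed by the fit's normalization.
* Not emulated: delayed phosphorescence, charge-transfer inefficiency,
  vendor binning modes, position-dependent PSFs, and real cosmic-ray
  morphology (spikes are single-pixel).

Passing recovery tests on this generator shows the estimators invert the
stated model at desk scale; it does not certify behaviour on real frames
with effects outside the model.

## The brighter-fatter kernel convention

The blur kernel reconstructed from a smoothing factor is built from a
**one-dimensional** Gaussian Pearson profile whose coefficient sum is
`1/beta_BF`, Fourier-square-rooted into a per-axis kernel and extended
separably to 2-D.  This is the only construction consistent with all three
reference numbers at `beta_BF = 0.995`: kernel width sigma ~ 0.27 px
(FWHM ~ 0.64 px), off-centre per-axis mass `(1/beta - 1)/2 ~ 0.0025`, and
~75 counts migrating out of the central channel when a 30,000-count spike
is blurred and summed along columns.  An isotropic 2-D construction with
`sum(rho_2D) = 1/beta` gives sigma ~ 0.19 px and ~38 counts instead.

Note also that the nearest-neighbour window used to *measure*
`beta_BF(S)` captures only part of the blur-induced correlation change
when the base PSF extends beyond 3 x 3 pixels; the recovery test therefore
compares the estimate against a forward-propagated oracle of the same
windowed statistic, not against the injected factor directly.

## Tolerances and degenerate inputs

* Pmf normalization on truncated grids: 1e-9; the fractional-gain scaled
  Poisson density carries an `O(g)` raw normalization that is divided out
  numerically.
* Bessel evaluation uses the exponentially weighted form (`ive`), so
  Skellam probabilities are finite at arbitrarily large means.
* `psf_from_pearson` clips negative spectral mass; more than 5 % clipped
  raises a warning (an error in strict mode).
* Constant images yield an all-zero autocovariance (not an error);
  degenerate Pearson normalizations (central element <= 0) raise.
* Negative fitted variance components are clamped to zero with a warning.
* Cosmic-ray removal is two-pass (flag, patch, re-estimate, flag once
  more), not iterated to convergence; above 1 % flagged pixels the frame
  is rejected as contaminated.  Heavily contaminated frames whose spikes
  drag the global sigma upward can evade a 5-sigma clip entirely — the
  1 % guard is the protection, not the clip.

## Problem sizes and runtimes

All simulation-based checks run on 128 x 128 or 256 x 256 sensors with
tens of frames; the complete test-suite (including the end-to-end
non-linearity minimization, the heaviest step at ~1.5 minutes) finishes in
about two minutes on one CPU.  The quoted recovery precisions — `beta*g`
within 2 %, `sigma_read` within 3 %, `sigma_row` within 10 %, `k_ref`
within 5 % of its closed form, injected `x2` within 10 %, PSF FWHM within
5 % — are what these problem sizes support; larger sensors tighten all of
them roughly with the pixel count's square root.
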