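# ccdnoise

Noise modelling, calibration and point-spread-function reconstruction for
scintillation-coupled CCD detectors — the cameras used behind transmission
electron microscopes, X-ray imagers and image filters, in which every
incident electron produces a cloud of secondary quanta before a CCD counts
them.

## The model

Counts in a pixel (i, j) of such a detector follow a mixed
Poisson–Gaussian law.  After dark-frame subtraction, gain normalization and
gain linearization, the within-frame variance of a flat field at mean
signal S_c is

```
sigma_total^2 = (1 + k^2) * beta_BF * beta * g * S_c  +  k^2 * S_c^2  +  2 * sigma_d,corr^2
```

with

* `g` — composite gain (counts per beam electron),
* `beta = beta_conv * beta_corr` — smoothing of the Poisson variance by
  convolution with the detector PSF Omega_d (`beta_conv = 1 / sum(rho)`,
  the reciprocal Pearson-coefficient sum) and by finite-frame correlation
  (`beta_corr`, the factor between the single-frame sample variance and
  the true per-pixel variance),
* `beta_BF(S)` — signal-dependent extra smoothing from the brighter-fatter
  effect (charge diffusion widens the PSF with signal),
* `k` — relative uncertainty of the flat-field gain reference,
  `k^2 = (beta g S_ref + 2 sigma_d^2) / (w S_ref^2)` for `w` summed pairs,
* `sigma_d^2 = sigma_read^2 + sigma_row^2 + sigma_therm^2` — read-out, row
  and dark-current noise, handled per ADC quadrant.

Because the PSF correlates the noise of neighbouring pixels, the
Wiener–Khinchin theorem turns flat-field noise into a measurement of the
PSF itself: the autocovariance of a mean-subtracted frame is the inverse
Fourier transform of its periodogram, and
`Omega_d = F^-1[ sqrt(F[rho]) ]` recovers the kernel — once the faint,
far-reaching correlation of the electron beam itself (a fitted Gaussian
surface) has been subtracted.  The same Pearson coefficients propagate the
noise through post-binning (`H x V` block sums, e.g. spectrum formation in
electron energy-loss spectroscopy), where read/thermal noise adds linearly,
row noise adds quadratically along rows, and `beta` is recomputed from the
binned coefficient sums.

The package contains a forward simulator of the whole image-formation
chain (correlated beam, PSF, fixed-pattern gain map, dark current,
quadrant read-out, polynomial gain non-linearity, brighter-fatter blur) and
the full calibration suite that inverts it: cosmic-ray removal, detector
noise decomposition by exposure-time regression, gain-reference
construction with uncertainty, smoothed-gain and PSF reconstruction,
photon-transfer linearization with bracketed-repeat-exposure validation,
and binning / spectrum noise propagation.

## Worked example

Simulate the standard gain-reference acquisition (30 flat + 30 dark frames
at ~7050 counts on a 256 x 256 sensor with smoothed gain 1.55), build the
reference, and recover its uncertainty and the smoothed gain:

```python
import numpy as np
from ccdnoise.simulate import DetectorModel, BeamModel, simulate_flat_stack, \
    simulate_dark, simulate_frame
from ccdnoise.calibration import (build_gain_reference, estimate_kref_autocov,
    kref_theoretical, dark_subtract, apply_gain_reference, estimate_smoothed_gain)

det = DetectorModel.reference((256, 256), seed=1)
beam = BeamModel.flat(7050.0 / det.g / 0.84)
frames = simulate_flat_stack(det, beam, 30, 30, 0.84, seed=1)
sigs = [f for f in frames if f.kind == "signal"]
darks = [f for f in frames if f.kind == "dark"]

ref = build_gain_reference(sigs, darks)
ref.k_ref, ref.noise_rho = estimate_kref_autocov(sigs, darks, ref.sigma_ref)
flats = [apply_gain_reference(dark_subtract(simulate_frame(det, beam, 0.84, (2, i)),
                                            simulate_dark(det, 0.84, (3, i))), ref)
         for i in range(10)]
dd = apply_gain_reference(dark_subtract(simulate_dark(det, 0.84, (4, 0)),
                                        simulate_dark(det, 0.84, (4, 1))), ref)
res = estimate_smoothed_gain(flats, ref, dd)
```

which prints

```
reference intensity   S_ref,c =   7050.0 counts
QE spread             sigma_QE = 0.0670
measured uncertainty  k_ref = 0.0027002
closed-form k_ref     k_ref = 0.0027114
smoothed gain         beta*g = 1.5563 counts/electron
```

The measured `k_ref` agrees with its closed form to 0.4 % and the smoothed
gain is recovered to 0.4 % of the configured 1.55 counts/electron.  `k_ref`
is the pixel-to-pixel relative error of the flat-field map: multiplying an
image by the reference imprints this error on the signal, which is why it
appears squared against `S_c^2` in the variance model.

A command line wraps the same pipelines (`ccdnoise simulate / fixtures /
calibrate / gainref / nonlin / bf / psf / bin / eels`); every command reads
and writes multi-page float32 TIFF stacks with a JSON sidecar.

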