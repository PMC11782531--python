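"""Separating beam-induced correlation from the detector PSF.

Under flat illumination the Pearson field of the signal contains two
components: a narrow core from the detector PSF (the kernel convolved with
itself) and a faint, far-reaching surface from correlated beam electrons
(Coulomb interactions near the gun give a fraction ``p`` of electrons a
common origin).  Reconstructing the PSF naively from the full field smears
nearly all of its mass into the tails; the beam component must be fitted
(an offsetted 2-D Gaussian, with the PSF-dominated core excluded) and
subtracted from the autocovariance before taking the Fourier square root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .correlation import AutocovarianceField, Kernel, PearsonField

__all__ = [
    "BeamCorrelationFit",
    "fit_beam_correlation",
    "detector_psf",
    "estimate_p",
    "kernel_fwhm",
]


@dataclass
class BeamCorrelationFit:
    """Offsetted Gaussian surface fitted to the broad part of a Pearson field."""

    amplitude: float
    sigma_tem: float
    offset: float
    p_hat: float = 0.0

    def surface(self, shape: tuple[int, int]) -> np.ndarray:
        """Evaluate offset + A exp(-(m^2+n^2)/(2 sigma^2)) on a centred grid."""
        cm, cn = shape[0] // 2, shape[1] // 2
        m = np.arange(shape[0]) - cm
        n = np.arange(shape[1]) - cn
        r2 = m[:, None] ** 2 + n[None, :] ** 2
        return self.offset + self.amplitude * np.exp(-r2 / (2.0 * self.sigma_tem**2))


def fit_beam_correlation(
    rho: PearsonField, exclusion_radius: float = 10.0
) -> BeamCorrelationFit:
    """Least-squares fit of the beam-correlation surface to a Pearson field.

    Lags inside ``exclusion_radius`` (where the detector PSF dominates) are
    omitted from the fit.
    """
    v = rho.values
    cm, cn = rho.center
    m = np.arange(v.shape[0]) - cm
    n = np.arange(v.shape[1]) - cn
    r2 = m[:, None] ** 2 + n[None, :] ** 2
    mask = r2 > exclusion_radius**2
    if mask.sum() < 10:
        raise ValueError("Pearson field smaller than the exclusion region")
    x = r2[mask].ravel()
    y = v[mask].ravel()

    def model(r2v, amp, sig, off):
        return off + amp * np.exp(-r2v / (2.0 * sig**2))

    a0 = max(float(np.percentile(y, 95)), 1e-12)
    s0 = max(np.sqrt(float(x.max())) / 3.0, exclusion_radius)
    try:
        popt, _ = optimize.curve_fit(
            model,
            x,
            y,
            p0=(a0, s0, float(np.median(y))),
            bounds=([0.0, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"beam-correlation fit did not converge: {exc}") from exc
    amp, sig, off = (float(p) for p in popt)
    return BeamCorrelationFit(amplitude=amp, sigma_tem=sig, offset=off)


def kernel_fwhm(kernel: Kernel) -> float:
    """FWHM (pixels) of a kernel from its interpolated radial profile."""
    om = kernel.omega
    cm, cn = kernel.center
    peak = om[cm, cn]
    if peak <= 0:
        raise ValueError("kernel has a non-positive central element")
    m = np.arange(om.shape[0]) - cm
    n = np.arange(om.shape[1]) - cn
    r = np.sqrt(m[:, None] ** 2 + n[None, :] ** 2).ravel()
    vals = om.ravel() / peak
    # radial profile on the exact distinct radii (mean over equal-r pixels)
    r_round = np.round(r, 9)
    uniq = np.unique(r_round)
    prof_r = uniq
    prof_v = np.array([vals[r_round == u].mean() for u in uniq])
    below = np.nonzero(prof_v < 0.5)[0]
    if len(below) == 0:
        return float("inf")
    i = below[0]
    r1, r0 = prof_r[i], prof_r[i - 1]
    v1, v0 = prof_v[i], prof_v[i - 1]
    r_half = r0 + (0.5 - v0) * (r1 - r0) / (v1 - v0)
    return float(2.0 * r_half)


def detector_psf(
    K_sig: AutocovarianceField,
    beam_fit: BeamCorrelationFit | None = None,
    *,
    window_radius: float | None = None,
) -> tuple[Kernel, float]:
    """Detector PSF from the signal autocovariance, beam correlation removed.

    Omega_d = F^-1[(K_sig - G_corr)^(1/2)], recentred, clipped and
    sum-normalized; returns the kernel and its radial-profile FWHM in
    pixels.  With ``beam_fit=None`` no surface is subtracted (the ablation
    that collapses the central mass into the tails).  ``window_radius``
    optionally zeroes lags beyond that radius after the subtraction: the
    PSF support is a few pixels, so windowing suppresses the estimator
    noise whose square root would otherwise bias the kernel tails.
    """
    vals = K_sig.values.copy()
    if beam_fit is not None:
        # the surface was fitted on the Pearson normalization (rho = K/K00),
        # so scale it back to autocovariance units before subtracting
        vals = vals - beam_fit.surface(vals.shape) * K_sig.central
    if window_radius is not None:
        m = np.arange(vals.shape[0]) - vals.shape[0] // 2
        n = np.arange(vals.shape[1]) - vals.shape[1] // 2
        vals[(m[:, None] ** 2 + n[None, :] ** 2) > window_radius**2] = 0.0
    cm, cn = K_sig.center
    if vals[cm, cn] <= 0:
        raise ValueError("negative central element after beam-correlation subtraction")
    spec = np.fft.fft2(np.fft.ifftshift(vals)).real
    amp = np.sqrt(np.clip(spec, 0.0, None))
    omega = np.fft.fftshift(np.real(np.fft.ifft2(amp)))
    omega = np.clip(omega, 0.0, None)
    total = omega.sum()
    if total <= 0:
        raise ValueError("PSF reconstruction produced an empty kernel")
    kern = Kernel(omega / total, "sum-to-one")
    return kern, kernel_fwhm(kern)


def estimate_p(beam_fit: BeamCorrelationFit, rho_core_sum: float) -> float:
    """Correlated-electron probability from the fitted surface amplitude.

    In the Pearson field the broad beam term carries weight 2p(1-p) against
    the (1-p)^2 weight of the PSF core, so with the fitted amplitude A and
    the summed core coefficients S (both in the same normalization),

        A / S = 2p(1-p) / (1-p)^2  =>  p = r / (2 + r),  r = A / S,

    returning the smaller root, p in [0, 1/2).  An amplitude implying
    p >= 1/2 (the maximum of 2p(1-p)) raises an error.
    """
    if beam_fit.amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if rho_core_sum <= 0:
        raise ValueError("core coefficient sum must be > 0")
    r = beam_fit.amplitude / rho_core_sum
    p = r / (2.0 + r)
    if p >= 0.5:
        raise ValueError("fitted amplitude implies p >= 1/2 (outside the model)")
    return float(p)
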