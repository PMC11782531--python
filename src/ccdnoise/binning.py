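"""Post-binning of frames and noise propagation into EEL spectra.

Summing H x V neighbouring pixels after acquisition (post-binning, the
operation that turns the 2-D spectrum region into a 1-D EEL spectrum)
changes every noise term differently:

* the Poisson term loses part of its convolutional smoothing -- the Pearson
  coefficients add under binning, so beta_{H,V} is recomputed from the
  binned field,
* the fixed-pattern term k^2 (Sum S)^2 acquires a distribution factor
  alpha_{H,V} = Sum (S_ij / Sum S)^2 because the summation loses where the
  signal sat inside the bin,
* read-out and thermal noise add linearly with the number of pixels, while
  the row bias is constant along a row and therefore adds *quadratically*
  in the horizontal direction.

The EELS model specializes this to a vertical sum over the spectrum band
(V = 260 rows on the reference detector), with the detector-noise sets per
channel taken as the sums of the two quadrants each column crosses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .correlation import Kernel, PearsonField, beta_conv, beta_corr, bin_pearson, cconv2
from .frames import Frame

__all__ = [
    "BinningSpec",
    "EELSModel",
    "post_bin",
    "binned_beta",
    "predict_binned_variance",
    "alpha_factor",
    "alpha_factor_normalized",
    "binned_kref",
    "eels_variance_model",
    "compose_zlp",
]


@dataclass(frozen=True)
class BinningSpec:
    """Non-overlapping H x V block summation with leftover-pixel anchoring.

    ``anchor`` picks which edge keeps the complete blocks when the frame
    size is not divisible by the bin factor: ``front`` discards the
    trailing remainder, ``back`` the leading one, and ``average-both``
    signals that downstream statistics should average the two croppings.
    """

    H: int
    V: int
    anchor: str = "front"

    def __post_init__(self) -> None:
        if self.H < 1 or self.V < 1:
            raise ValueError("bin factors must be >= 1")
        if self.anchor not in ("front", "back", "average-both"):
            raise ValueError(f"unknown anchor {self.anchor!r}")


def _block_sum(data: np.ndarray, H: int, V: int, from_back: bool) -> np.ndarray:
    rows, cols = data.shape
    nr, nc = rows // V, cols // H
    if nr < 1 or nc < 1:
        raise ValueError("bin factors exceed the frame size")
    if from_back:
        sub = data[rows - nr * V :, cols - nc * H :]
    else:
        sub = data[: nr * V, : nc * H]
    return sub.reshape(nr, V, nc, H).sum(axis=(1, 3))


def post_bin(frame: Frame, spec: BinningSpec) -> Frame | tuple[Frame, Frame]:
    """Block-sum a frame; leftover pixels at the anchor-opposite edge are
    discarded.  ``anchor="average-both"`` returns both croppings so the
    caller can average their statistics."""
    if spec.anchor == "average-both":
        a = _block_sum(frame.data, spec.H, spec.V, from_back=False)
        b = _block_sum(frame.data, spec.H, spec.V, from_back=True)
        return (
            frame.copy_with(a, binned=(spec.H, spec.V), crop="front"),
            frame.copy_with(b, binned=(spec.H, spec.V), crop="back"),
        )
    data = _block_sum(frame.data, spec.H, spec.V, from_back=spec.anchor == "back")
    return frame.copy_with(data, binned=(spec.H, spec.V), crop=spec.anchor)


def binned_beta(
    rho: PearsonField,
    spec: BinningSpec,
    *,
    include_corr: bool = False,
    frame_shape: Optional[tuple[int, int]] = None,
) -> float:
    """Smoothing factor beta_{H,V} after binning a correlated system.

    The Pearson coefficients are propagated through the binning sums and
    beta_conv recomputed as the reciprocal coefficient sum; with
    ``include_corr`` the finite-frame correlation factor beta_corr of the
    *binned* frame is multiplied in (needed when comparing against
    within-frame sample variances).
    """
    rho_b, _ = bin_pearson(rho, spec.H, spec.V)
    b = beta_conv(rho_b)
    if include_corr:
        shape = frame_shape or rho.source_shape
        m = max(shape[0] // spec.V, 2)
        n = max(shape[1] // spec.H, 2)
        b *= beta_corr(rho_b, m, n)
    return float(b)


def alpha_factor(s_grid: np.ndarray) -> float:
    """Distribution factor alpha = Sum (S_ij / Sum S)^2 over one bin.

    1 when all signal sits in a single pixel, 1/(H V) for a flat bin.
    """
    s = np.asarray(s_grid, dtype=float)
    tot = s.sum()
    if tot <= 0:
        raise ValueError("bin has no signal")
    return float(((s / tot) ** 2).sum())


def alpha_factor_normalized(s_grid: np.ndarray) -> float:
    """Normalized distribution factor H V Sum (S_ij / Sum S)^2 (1 for flat).

    This is the variant that pairs with the *binned* reference uncertainty
    k_{H,V}: the correlation enhancement of the summed fixed-pattern noise
    is already inside k_{H,V} (through beta_{H,V}), so the distribution
    factor must be normalized to one for homogeneous signal.
    """
    return alpha_factor(s_grid) * float(np.asarray(s_grid).size)


def predict_binned_variance(
    s_grid: np.ndarray,
    spec: BinningSpec,
    k_binned: float,
    beta_binned: float,
    beta_bf_binned: float,
    sigma_pix_var: float,
    row_var: float = 0.0,
    g: float = 1.0,
) -> np.ndarray:
    """Model variance of each binned pixel of a corrected flat frame.

    ``s_grid`` holds the expected counts of the unbinned pixels;
    ``sigma_pix_var`` the per-pixel detector-noise variance excluding the
    row bias (already including the dark-subtraction factor 2 and any gain
    normalization/linearization scaling) and ``row_var`` the corresponding
    row-bias variance, which adds quadratically along rows:

    var = alpha k^2 (Sum S)^2 + k^2 beta_{H,V} beta_BF Sum S
          + Sum sigma_pix^2 + H^2 V row_var
          + beta_{H,V} beta_BF g * Sum S   (the Poisson term itself)

    ``beta_binned`` enters the Poisson term as g beta_{H,V} beta_BF Sum S;
    pass ``g`` explicitly so the Poisson term is on the counts scale.
    """
    H, V = spec.H, spec.V
    rows, cols = np.asarray(s_grid).shape
    nr, nc = rows // V, cols // H
    sub = np.asarray(s_grid, dtype=float)[: nr * V, : nc * H].reshape(nr, V, nc, H)
    s_sum = sub.sum(axis=(1, 3))
    # normalized distribution factor (1 for flat signal); pairs with k_{H,V}
    alpha = H * V * ((sub / s_sum[:, None, :, None]) ** 2).sum(axis=(1, 3))
    poisson = g * beta_binned * beta_bf_binned * s_sum
    fixed = alpha * k_binned**2 * s_sum**2
    cross = k_binned**2 * g * beta_binned * beta_bf_binned * s_sum
    det = H * V * sigma_pix_var + H**2 * V * row_var
    return poisson + fixed + cross + det


def binned_kref(
    s_ref_c: float,
    g: float,
    rho_ref: PearsonField,
    spec: BinningSpec,
    sigma_d2: float,
    w: int,
    *,
    g_lin_mean: float = 1.0,
    include_corr: bool = True,
    frame_shape: Optional[tuple[int, int]] = None,
) -> float:
    """Uncertainty of the (linearized) gain reference after binning.

    k^2 = (sum_w g^2 beta_{H,V} Sum_{H,V} S_ref + 2 sum_w Sum_{H,V}
    g_lin_bar^2 sigma_d^2) / (g sum_w Sum_{H,V} S_ref)^2, with beta_{H,V}
    propagated from the reference Pearson field.  Reduces to the unbinned
    closed form at H = V = 1, g_lin_bar = 1.
    """
    H, V = spec.H, spec.V
    b = binned_beta(rho_ref, spec, include_corr=include_corr, frame_shape=frame_shape)
    s_bin = H * V * s_ref_c  # counts per binned pixel
    num = w * b * g * s_bin + 2.0 * w * H * V * g_lin_mean**2 * sigma_d2
    den = (w * s_bin) ** 2
    return float(np.sqrt(num / den))


# ---------------------------------------------------------------------------
# EELS


@dataclass
class EELSModel:
    """Noise model of a spectrum formed by vertically summing V rows.

    ``beta_eels`` is the smoothing factor of the summed system (propagated
    through the binning sums from the detector-PSF Pearson field),
    ``alpha`` the *normalized* vertical distribution factor of the 2-D
    spectrum (1 for homogeneous illumination, V * Sum (S/Sum S)^2 in
    general; > 1 for a concentrated zero-loss peak),
    ``kref_binned`` the binned gain-reference uncertainty, and
    ``sigma_d_sets`` the per-channel detector-noise variances -- for the
    reference geometry the Q1+Q3 sum for the left half of the channels and
    Q2+Q4 for the right half.
    """

    V: int = 260
    beta_eels: float = 1.0
    alpha: float = 1.0
    kref_binned: float = 0.0
    sigma_d_sets: tuple[float, float] = (0.0, 0.0)
    p_stem: float = 0.0
    zlp_kernel: Optional[Kernel] = None

    def __post_init__(self) -> None:
        if self.V < 1:
            raise ValueError("V must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta_eels <= 0:
            raise ValueError("beta_eels must be > 0")


def eels_variance_model(spectrum_2d: np.ndarray, model: EELSModel, g: float) -> np.ndarray:
    """Per-channel variance of a spectrum summed over the first V rows.

    var_i = g beta_EELS Sum_j S + alpha k^2 (Sum_j S)^2
            + k^2 g beta_EELS Sum_j S + 2 Sum_j sigma_EELS,corr^2
    """
    s = np.asarray(spectrum_2d, dtype=float)
    if model.V > s.shape[0]:
        raise ValueError("V exceeds the number of rows in the spectrum region")
    s_sum = s[: model.V].sum(axis=0)
    n = s.shape[1]
    sigma = np.where(
        np.arange(n) < n // 2, model.sigma_d_sets[0], model.sigma_d_sets[1]
    )
    k2 = model.kref_binned**2
    return (
        g * model.beta_eels * s_sum
        + model.alpha * k2 * s_sum**2
        + k2 * g * model.beta_eels * s_sum
        + 2.0 * model.V * sigma
    )


def compose_zlp(omega_d: Kernel, omega_disp: Kernel, omega_stem: Kernel) -> Kernel:
    """2-D zero-loss peak: Omega_d (x) Omega_disp (x) Omega_STEM, height-one.

    Asymmetric dispersion kernels are preserved (plain convolution, no
    symmetrization).
    """
    shapes = [omega_d.omega.shape, omega_disp.omega.shape, omega_stem.omega.shape]
    rows = sum(s[0] for s in shapes) - 2
    cols = sum(s[1] for s in shapes) - 2
    rows += 1 - rows % 2
    cols += 1 - cols % 2
    base = np.zeros((rows, cols))
    c = (rows // 2, cols // 2)
    r0, c0 = omega_d.center
    base[
        c[0] - r0 : c[0] - r0 + omega_d.omega.shape[0],
        c[1] - c0 : c[1] - c0 + omega_d.omega.shape[1],
    ] = omega_d.omega
    out = cconv2(base, omega_disp.omega)
    out = cconv2(out, omega_stem.omega)
    out = np.clip(out, 0.0, None)
    if out.max() <= 0:
        raise ValueError("degenerate ZLP composition")
    return Kernel(out / out.max(), "height-one")
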