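"""Measurement pipeline: artifact removal, noise decomposition, gain reference.

Implements the calibration route for a four-quadrant scintillation CCD:

* cosmic-ray removal (5-sigma two-sided clip with neighbourhood replacement),
* dark-frame subtraction,
* splitting off the per-row bias fluctuation (row noise) by rounding row
  means to integers,
* decomposing detector noise into read-out / thermal / row components by
  linear regression of dark-frame variance against exposure time,
* building a flat-field gain reference, its uncertainty k_ref (by the
  difference-image and by the autocovariance estimator), and the smoothed
  gain beta*g from the signal autocovariance.

Variance bookkeeping follows the mixed Poisson--Gaussian model: a gain
normalized, dark subtracted flat frame has variance

    (1 + k^2) beta g S_c + k^2 S_c^2 + 2 sigma_d*^2

with S_c the mean counts, beta the PSF smoothing factor, k the
gain-reference uncertainty and sigma_d*^2 the gain-normalized detector
noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats as sps

from .correlation import AutocovarianceField, PearsonField, autocovariance_wk, beta_corr
from .frames import QUADRANTS, Frame, quadrant_slices

__all__ = [
    "NoiseBudget",
    "GainReference",
    "remove_cosmic_rays",
    "dark_subtract",
    "split_row_noise",
    "regress_read_thermal",
    "build_gain_reference",
    "apply_gain_reference",
    "estimate_kref_difference",
    "kref_theoretical",
    "estimate_kref_autocov",
    "estimate_smoothed_gain",
    "sample_variance",
]


def sample_variance(data: np.ndarray) -> float:
    """Within-frame sample variance with the MN/(MN-1) factor."""
    return float(np.var(data, ddof=1))


# ---------------------------------------------------------------------------
# artifact removal and decomposition


def remove_cosmic_rays(
    frame: Frame, *, nsigma: float = 5.0, max_fraction: float = 0.01
) -> tuple[Frame, np.ndarray]:
    """Flag spikes beyond ``nsigma`` from the frame mean and patch them.

    Both sides of the mean are clipped (a subtracted dark can carry negative
    spikes).  Flagged pixels and their 3x3 neighbourhood are replaced by the
    frame mean; the statistics are re-estimated once after replacement and
    the clip is applied a second time (two-pass).
    """
    data = frame.data.copy()
    mask = np.zeros(data.shape, dtype=bool)
    for _ in range(2):
        mu, sd = data.mean(), data.std()
        if sd == 0:
            break
        hits = np.abs(data - mu) > nsigma * sd
        if not hits.any():
            break
        patch = ndimage.binary_dilation(hits, structure=np.ones((3, 3), bool))
        mask |= patch
        data[patch] = mu
    frac = mask.mean()
    if frac > max_fraction:
        raise ValueError(
            f"{frac:.2%} of pixels flagged as cosmic rays (limit {max_fraction:.0%}); "
            "frame too contaminated for statistics"
        )
    return frame.copy_with(data, cosmic_mask_fraction=float(frac)), mask


def dark_subtract(signal: Frame, dark: Frame) -> Frame:
    """Pixel-wise signal - dark; removes offset, doubles detector-noise variance."""
    if signal.shape != dark.shape:
        raise ValueError("shape mismatch between signal and dark frame")
    if not np.isclose(signal.t_acq, dark.t_acq, rtol=1e-6, atol=1e-9):
        raise ValueError(
            f"exposure mismatch: signal {signal.t_acq} s vs dark {dark.t_acq} s"
        )
    out = signal.copy_with(signal.data - dark.data, dark_subtracted=True)
    return out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def split_row_noise(frame: Frame) -> tuple[Frame, Frame]:
    """Split a dark-subtracted frame into row-bias offsets and the residual.

    Per quadrant, each row's mean is rounded to the nearest integer (ties
    away from zero; the row bias steps are integer-valued) and subtracted.
    The decomposition is exact: input = residual + offsets.
    """
    resid = frame.data.copy()
    offsets = np.zeros_like(resid)
    for rs, cs in quadrant_slices(frame.shape):
        block = resid[rs, cs]
        row_means = _round_half_away(block.mean(axis=1))
        offsets[rs, cs] = row_means[:, None]
        resid[rs, cs] = block - row_means[:, None]
    return frame.copy_with(resid, row_noise_removed=True), frame.copy_with(offsets)


# ---------------------------------------------------------------------------
# detector-noise decomposition


@dataclass
class NoiseBudget:
    """Per-quadrant decomposition of the detector noise (counts^2).

    ``read_var`` is sigma_read^2, ``thermal_rate`` is the dark-current
    variance accumulation rate g_c*I_dark (counts^2/s, so that
    sigma_therm^2 = thermal_rate * t), ``row_var`` is sigma_row^2.
    ``scale`` records the (phi^-2 + sigma_ref^2/phi^4) factor that was
    divided out when the input stack had a gain reference applied.
    Confidence intervals are 95 % regression intervals on the *fitted*
    intercept/slope (2 sigma_read^2 and 2 thermal_rate).
    """

    read_var: np.ndarray
    thermal_rate: np.ndarray
    row_var: np.ndarray
    read_var_ci: np.ndarray
    thermal_rate_ci: np.ndarray
    scale: np.ndarray = field(default_factory=lambda: np.ones(4))
    g_lin_mean: float = 1.0

    def thermal_var(self, t_acq: float) -> np.ndarray:
        return self.thermal_rate * t_acq

    def sigma_d2(self, t_acq: float) -> np.ndarray:
        """sigma_d^2 = sigma_read^2 + sigma_row^2 + sigma_therm^2 per quadrant."""
        return self.read_var + self.row_var + self.thermal_var(t_acq)

    def sigma_d_star2(self, t_acq: float, ref: "GainReference") -> np.ndarray:
        """Gain-normalized detector noise (phi^-2 + sigma_ref^2/phi^4) sigma_d^2."""
        fac = ref.phi**-2 + ref.sigma_ref**2 / ref.phi**4
        return fac * self.sigma_d2(t_acq)

    def sigma_d_corr2(self, t_acq: float, ref: "GainReference", g_lin_mean: float = 1.0) -> np.ndarray:
        """Linearization-corrected detector noise g_lin_bar^2 sigma_d*^2."""
        return g_lin_mean**2 * self.sigma_d_star2(t_acq, ref)

    def as_dict(self) -> dict:
        return {
            "quadrants": list(QUADRANTS),
            "read_var": self.read_var.tolist(),
            "thermal_rate": self.thermal_rate.tolist(),
            "row_var": self.row_var.tolist(),
            "read_var_ci": self.read_var_ci.tolist(),
            "thermal_rate_ci": self.thermal_rate_ci.tolist(),
            "scale": self.scale.tolist(),
        }


def regress_read_thermal(
    frames: Sequence[Frame],
    ref: Optional["GainReference"] = None,
    *,
    clean_cosmics: bool = True,
) -> NoiseBudget:
    """Decompose dark noise by OLS of single-frame variance against exposure.

    ``frames`` are dark-subtracted frames (dark-minus-dark pairs) at three
    or more distinct exposure times.  Per quadrant, the per-row means are
    split off first; the residual variance follows
    2 sigma_read^2 + 2 g_c I_dark t (times the gain-reference factor of the
    variance when ``ref`` was applied to the stack, which is then divided
    out).  Row variance is half the variance of the row means after
    removing their pixel-noise leakage (half, because the inputs are
    differences of two frames).
    """
    t = np.array([f.t_acq for f in frames], dtype=float)
    if len(np.unique(np.round(t, 12))) < 3:
        raise ValueError("need at least 3 distinct exposure times")

    n_q = 4
    var = np.zeros((len(frames), n_q))
    rowvar = np.zeros((len(frames), n_q))
    for i, f in enumerate(frames):
        if clean_cosmics:
            f, _ = remove_cosmic_rays(f)
        for q, (rs, cs) in enumerate(quadrant_slices(f.shape)):
            block = f.data[rs, cs]
            ncol = block.shape[1]
            row_means = block.mean(axis=1)
            resid = block - row_means[:, None]
            # exact row-mean subtraction removes 1/ncol of the pixel noise;
            # undo that so the intercept/slope stay unbiased at desk scale
            var[i, q] = sample_variance(resid) * ncol / (ncol - 1)
            rowvar[i, q] = np.var(row_means, ddof=1)

    read_var = np.zeros(n_q)
    thermal = np.zeros(n_q)
    read_ci = np.zeros((n_q, 2))
    thermal_ci = np.zeros((n_q, 2))
    scale = np.ones(n_q)
    if ref is not None:
        scale = ref.phi**-2 + ref.sigma_ref**2 / ref.phi**4
    tcrit = sps.t.ppf(0.975, max(len(frames) - 2, 1))
    for q in range(n_q):
        res = sps.linregress(t, var[:, q])
        inter, slope = res.intercept, res.slope
        if inter < 0 or slope < 0:
            warnings.warn(
                f"negative fitted variance component in {QUADRANTS[q]}; clamped to 0",
                RuntimeWarning,
            )
        inter_c = max(inter, 0.0) / scale[q]
        slope_c = max(slope, 0.0) / scale[q]
        read_var[q] = inter_c / 2.0
        thermal[q] = slope_c / 2.0
        read_ci[q] = (
            inter_c / 2.0 - tcrit * res.intercept_stderr / (2 * scale[q]),
            inter_c / 2.0 + tcrit * res.intercept_stderr / (2 * scale[q]),
        )
        thermal_ci[q] = (
            slope_c / 2.0 - tcrit * res.stderr / (2 * scale[q]),
            slope_c / 2.0 + tcrit * res.stderr / (2 * scale[q]),
        )
    # each raw row mean carries pixel-noise leakage var_resid/ncol, which is
    # subtracted per frame before halving (inputs are frame differences)
    ncols = np.array(
        [cs.stop - cs.start for _, cs in quadrant_slices(frames[0].shape)], dtype=float
    )
    row_var = np.clip((rowvar - var / ncols[None, :]).mean(axis=0), 0.0, None) / 2.0
    row_var = row_var / scale
    return NoiseBudget(read_var, thermal, row_var, read_ci, thermal_ci, scale)


# ---------------------------------------------------------------------------
# gain reference


@dataclass
class GainReference:
    """Flat-field gain reference: unit-mean map plus its uncertainty record.

    ``map`` has unit mean over the full detector; ``phi`` are the per
    quadrant means (they differ slightly from 1 because the normalization is
    global), ``sigma_ref`` the overall standard deviation of the map (the
    quantum-efficiency spread sigma_QE plus the measurement noise k_ref in
    quadrature), ``s_ref_c`` the per-frame mean signal in counts, ``w`` the
    number of frame pairs summed.  ``k_ref``/``noise_rho`` are filled by the
    k_ref estimators.
    """

    map: np.ndarray
    w: int
    s_ref_c: float
    phi: np.ndarray
    sigma_ref: float
    k_ref: Optional[float] = None
    noise_rho: Optional[PearsonField] = None

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=float)
        if np.any(self.map <= 0):
            raise ValueError("gain reference map must be positive everywhere")
        if abs(self.map.mean() - 1.0) > 1e-6:
            raise ValueError("gain reference map must have unit mean")
        self._recip = 1.0 / self.map

    @property
    def sigma_qe(self) -> float:
        """Fixed-pattern (QE) spread: sigma_ref^2 ~ sigma_QE^2 + k_ref^2."""
        if self.k_ref is None:
            return self.sigma_ref
        return float(np.sqrt(max(self.sigma_ref**2 - self.k_ref**2, 0.0)))


def build_gain_reference(
    signal_frames: Sequence[Frame],
    dark_frames: Sequence[Frame],
    *,
    clean_cosmics: bool = True,
) -> GainReference:
    """Sum w dark-subtracted flat pairs and normalize to unit mean.

    Cosmic rays are removed from every contributing frame first.  A warning
    is raised when the illumination is visibly non-flat (quadrant means
    differing by more than 10 %).
    """
    if len(signal_frames) == 0 or len(signal_frames) != len(dark_frames):
        raise ValueError("need matched, non-empty signal and dark frame lists")
    total = np.zeros(signal_frames[0].shape)
    for s, d in zip(signal_frames, dark_frames):
        if clean_cosmics:
            s, _ = remove_cosmic_rays(s)
            d, _ = remove_cosmic_rays(d)
        total += dark_subtract(s, d).data
    w = len(signal_frames)
    mean_total = total.mean()
    if mean_total <= 0:
        raise ValueError("non-positive mean signal; cannot build gain reference")
    m = total / mean_total
    m = np.clip(m, 1e-6, None)
    m /= m.mean()
    phi = np.array([m[rs, cs].mean() for rs, cs in quadrant_slices(m.shape)])
    if phi.max() / phi.min() > 1.10:
        warnings.warn(
            "quadrant means differ by more than 10%: illumination not flat",
            RuntimeWarning,
        )
    return GainReference(
        map=m,
        w=w,
        s_ref_c=float(mean_total / w),
        phi=phi,
        sigma_ref=float(m.std()),
    )


def apply_gain_reference(image: Frame, ref: GainReference) -> Frame:
    """Gain-normalize a dark-subtracted frame (multiplication by 1/map)."""
    if image.shape != ref.map.shape:
        raise ValueError("frame / gain reference shape mismatch")
    return image.copy_with(image.data * ref._recip, gain_normalized=True)


# ---------------------------------------------------------------------------
# k_ref estimators


def kref_theoretical(
    s_ref_c: float, g: float, beta: float, sigma_d2: float, w: int
) -> float:
    """Predicted gain-reference uncertainty.

    k^2 = (sum_w g^2 beta S_ref + 2 sum_w sigma_d^2) / (g sum_w S_ref)^2
        = (beta g S_ref,c + 2 sigma_d^2) / (w S_ref,c^2),

    with ``s_ref_c`` the per-frame mean counts, ``sigma_d2`` the
    single-frame detector-noise variance and ``w`` frames summed.
    """
    if s_ref_c <= 0 or g <= 0 or beta <= 0 or w <= 0:
        raise ValueError("all arguments must be positive")
    return float(np.sqrt((beta * g * s_ref_c + 2.0 * sigma_d2) / (w * s_ref_c**2)))


def estimate_kref_difference(refA: GainReference, refB: GainReference) -> float:
    """k_ref from the difference of two same-protocol gain references.

    k_ref = SD(mapA - mapB) / sqrt(2 (1 + sigma_ref,all^2)) with the
    quadrant mean set to phi = 1 (the non-inverted reference is used).
    """
    if refA.w != refB.w:
        raise ValueError("references built from different numbers of frames")
    if abs(refA.s_ref_c - refB.s_ref_c) > 0.05 * refA.s_ref_c:
        raise ValueError("references acquired at different target intensities")
    sigma_all2 = 0.5 * (refA.sigma_ref**2 + refB.sigma_ref**2)
    return float((refA.map - refB.map).std() / np.sqrt(2.0 * (1.0 + sigma_all2)))


def estimate_kref_autocov(
    signal_frames: Sequence[Frame],
    dark_frames: Sequence[Frame],
    sigma_ref_all: float,
    *,
    clean_cosmics: bool = True,
) -> tuple[float, PearsonField]:
    """k_ref and its Pearson field from signal/dark difference autocovariances.

    Disjoint pairs of raw signal frames are differenced; their
    autocovariance (negative entries clipped, K+) minus the *signed*
    autocovariance of matching dark-frame differences isolates the
    Poisson-plus-smoothing part of the reference noise.  The anti-correlated
    read-noise entries of the dark term are deliberately left unclipped.

    Central element:  k_ref^2 ~ beta g / (w S_ref,c), i.e. Eq.-of-state of
    the gain reference without the (relatively ~0.1 %) detector-noise term.
    """
    n_pairs = min(len(signal_frames), len(dark_frames)) // 2
    if n_pairs < 1:
        raise ValueError("need at least 2 signal and 2 dark frames")
    acc = None
    s_means = []
    w = len(signal_frames)
    for i in range(n_pairs):
        s1, s2 = signal_frames[2 * i], signal_frames[2 * i + 1]
        d1, d2 = dark_frames[2 * i], dark_frames[2 * i + 1]
        if clean_cosmics:
            s1, _ = remove_cosmic_rays(s1)
            s2, _ = remove_cosmic_rays(s2)
            d1, _ = remove_cosmic_rays(d1)
            d2, _ = remove_cosmic_rays(d2)
        ks = autocovariance_wk(s1.data - s2.data).clipped()
        kd = autocovariance_wk(d1.data - d2.data)
        term = ks.values - kd.values
        acc = term if acc is None else acc + term
        s_means.append(0.5 * (s1.data.mean() + s2.data.mean()) - 0.5 * (d1.data.mean() + d2.data.mean()))
    s_ref_c = float(np.mean(s_means))
    if s_ref_c <= 0:
        raise ValueError("non-positive reference intensity")
    k2_rho = acc / (2.0 * n_pairs * (1.0 + sigma_ref_all**2) * w * s_ref_c**2)
    cm = (k2_rho.shape[0] // 2, k2_rho.shape[1] // 2)
    k2 = float(k2_rho[cm])
    if k2 <= 0:
        raise ValueError("non-positive central element in k_ref autocovariance")
    rho = PearsonField(k2_rho / k2, signal_frames[0].shape)
    return float(np.sqrt(k2)), rho


# ---------------------------------------------------------------------------
# smoothed gain


@dataclass
class SmoothedGainResult:
    beta_g: float
    rho: PearsonField
    k_sig: AutocovarianceField
    s_c: float


def estimate_smoothed_gain(
    flats: Frame | Sequence[Frame],
    ref: GainReference,
    dark_diff: Frame,
) -> SmoothedGainResult:
    """Smoothed gain beta*g and signal Pearson field from flat frames.

    ``flats`` are gain-normalized, dark-subtracted flat-field frames;
    ``dark_diff`` is a gain-normalized difference of two dark frames (its
    autocovariance supplies the 2 sigma_d*^2 detector term).  The signal
    autocovariance is

        K(xi_Sig) = (K+(xi* - S_c) - S_c^2 k_ref^2 rho_ref - K(xi_DB)) / (1 + k_ref^2)

    and beta*g is its central element divided by S_c, after the
    finite-frame correlation adjustment of the sample variance.  The
    reference must carry its noise field (run ``estimate_kref_autocov``
    first).
    """
    if ref.k_ref is None or ref.noise_rho is None:
        raise ValueError(
            "gain reference lacks its noise autocovariance; run "
            "estimate_kref_autocov and set ref.k_ref / ref.noise_rho first"
        )
    if isinstance(flats, Frame):
        flats = [flats]
    acc = None
    means = []
    for f in flats:
        k = autocovariance_wk(f.data).clipped()
        acc = k.values if acc is None else acc + k.values
        means.append(f.data.mean())
    acc /= len(flats)
    s_c = float(np.mean(means))
    if s_c <= 0:
        raise ValueError("non-positive mean signal")

    k_db = autocovariance_wk(dark_diff.data)
    ref_noise = ref.k_ref**2 * _embed(ref.noise_rho.values, acc.shape)
    k_sig_vals = (acc - s_c**2 * ref_noise - _embed(k_db.values, acc.shape)) / (
        1.0 + ref.k_ref**2
    )
    shape = flats[0].shape
    k_sig = AutocovarianceField(k_sig_vals, shape)
    if k_sig.central <= 0:
        raise ValueError("negative central element in signal autocovariance")
    rho = PearsonField(k_sig_vals / k_sig.central, shape)
    M, N = shape
    bc = beta_corr(rho, M, N)
    # msd -> sample variance -> true variance (Eq. 22 direction)
    beta_g = k_sig.central * (M * N / (M * N - 1.0)) / (bc * s_c)
    return SmoothedGainResult(float(beta_g), rho, k_sig, s_c)


def _embed(values: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad or crop a centred lag grid to another centred shape."""
    out = np.zeros(shape)
    co = (shape[0] // 2, shape[1] // 2)
    ci = (values.shape[0] // 2, values.shape[1] // 2)
    m = min(co[0], ci[0])
    n = min(co[1], ci[1])
    out[co[0] - m : co[0] + m + 1, co[1] - n : co[1] + n + 1] = values[
        ci[0] - m : ci[0] + m + 1, ci[1] - n : ci[1] + n + 1
    ]
    return out
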