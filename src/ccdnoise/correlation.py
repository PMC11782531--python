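"""Lag-space machinery: autocovariance, Pearson fields, smoothing factors, PSFs.

The detector point-spread function correlates the Poisson noise of
neighbouring pixels.  Under homogeneous illumination the Wiener--Khinchin
theorem turns that correlation into something measurable: the autocovariance
of a mean-subtracted frame is the inverse Fourier transform of its
periodogram, and normalizing by the central element yields the Pearson
correlation coefficients rho_{m,n} per pixel lag (m, n).

From a Pearson field derive:

* ``beta_corr`` -- how correlation biases the within-frame sample variance
  relative to the true per-pixel variance,
* ``beta_conv`` -- the reduction of Poisson variance caused by convolution
  with the PSF (reciprocal of the coefficient sum),
* ``bin_pearson`` -- the coefficients of the system after summing H x V
  neighbouring pixels (post-binning, e.g. spectrum formation),
* ``psf_from_pearson`` -- the PSF itself, as the inverse Fourier transform
  of the square root of the power spectral density.

Conventions
-----------
Lag grids are stored centred with odd dimensions ``(2M-1, 2N-1)`` for a
source frame of shape ``(M, N)``; index ``(M-1, N-1)`` is lag ``(0, 0)``.
The estimator is the circular (periodogram) one, so all synthetic-data
oracles in the test-suite use circular convolution.  Estimated fields from a
single frame satisfy sum(rho) ~= 0 over one circular period (a property of
the periodogram, not of the underlying process), which is why downstream
estimators clip negative autocovariance entries where the measurement
procedure calls for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AutocovarianceField",
    "PearsonField",
    "Kernel",
    "autocovariance_wk",
    "pearson_normalize",
    "beta_corr",
    "bin_pearson",
    "beta_conv",
    "psf_from_pearson",
    "cconv2",
    "delta_field",
    "rho_from_kernel",
]


def _check_centered(values: np.ndarray) -> None:
    if values.ndim != 2 or values.shape[0] % 2 == 0 or values.shape[1] % 2 == 0:
        raise ValueError(f"centred lag grids must be 2-D with odd shape, got {values.shape}")


@dataclass
class AutocovarianceField:
    """Autocovariance K over centred lags, in counts^2.

    ``values[M-1 + m, N-1 + n]`` is K_{m,n}; ``source_shape`` is the frame
    shape (M, N) the field was estimated from (or refers to).
    """

    values: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_centered(self.values)

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)

    @property
    def central(self) -> float:
        c = self.center
        return float(self.values[c])

    def at(self, m: int, n: int) -> float:
        c = self.center
        return float(self.values[c[0] + m, c[1] + n])

    def clipped(self) -> "AutocovarianceField":
        """K+ : the field with all negative entries set to zero."""
        return AutocovarianceField(np.clip(self.values, 0.0, None), self.source_shape)


@dataclass
class PearsonField:
    """Pearson correlation coefficients rho_{m,n} over centred lags."""

    values: np.ndarray
    source_shape: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_centered(self.values)
        if self.source_shape == (0, 0):
            self.source_shape = (
                self.values.shape[0] // 2 + 1,
                self.values.shape[1] // 2 + 1,
            )

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)

    @property
    def central(self) -> float:
        return float(self.values[self.center])

    def at(self, m: int, n: int) -> float:
        c = self.center
        return float(self.values[c[0] + m, c[1] + n])

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class Kernel:
    """Non-negative convolution kernel on a centred odd grid.

    ``normalization`` is ``"sum-to-one"`` (probability kernel, Omega) or
    ``"height-one"`` (beam-disc convention, Omega^*).
    """

    omega: np.ndarray
    normalization: str = "sum-to-one"

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        _check_centered(self.omega)
        if self.normalization not in ("sum-to-one", "height-one"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def center(self) -> tuple[int, int]:
        return (self.omega.shape[0] // 2, self.omega.shape[1] // 2)

    def normalized(self, normalization: str) -> "Kernel":
        if normalization == "sum-to-one":
            return Kernel(self.omega / self.omega.sum(), normalization)
        return Kernel(self.omega / self.omega.max(), normalization)


def delta_field(shape: tuple[int, int] = (3, 3)) -> PearsonField:
    """A delta Pearson field (uncorrelated noise) on a small centred grid."""
    v = np.zeros((2 * shape[0] - 1, 2 * shape[1] - 1))
    v[shape[0] - 1, shape[1] - 1] = 1.0
    return PearsonField(v, shape)


def cconv2(image: np.ndarray, kernel_centered: np.ndarray) -> np.ndarray:
    """Circular 2-D convolution of ``image`` with a centred kernel.

    The kernel is zero-embedded into the image shape with its centre at
    index (0, 0); matches the periodogram estimator's circular convention.
    """
    image = np.asarray(image, dtype=float)
    k = np.asarray(kernel_centered, dtype=float)
    pad = np.zeros_like(image)
    kc = (k.shape[0] // 2, k.shape[1] // 2)
    rows = (np.arange(k.shape[0]) - kc[0]) % image.shape[0]
    cols = (np.arange(k.shape[1]) - kc[1]) % image.shape[1]
    # accumulate so kernels wider than the frame fold circularly
    np.add.at(pad, (rows[:, None], cols[None, :]), k)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * np.fft.fft2(pad)))


def rho_from_kernel(kernel: Kernel, radius: int | None = None) -> PearsonField:
    """Exact Pearson field of noise convolved with a kernel: Omega (x) Omega
    normalized to a central value of one."""
    om = kernel.omega
    half = (max(om.shape) - 1) // 2
    if radius is None:
        radius = max(om.shape) - 1
    radius = max(radius, half)
    n = 2 * radius + 1
    base = np.zeros((n, n))
    c = (n // 2, n // 2)
    r0, c0 = kernel.center
    base[
        c[0] - r0 : c[0] - r0 + om.shape[0], c[1] - c0 : c[1] - c0 + om.shape[1]
    ] = om
    # autocorrelation (kernel flipped), not self-convolution: the two only
    # coincide for centro-symmetric kernels
    conv = cconv2(base, om[::-1, ::-1])
    central = conv[c]
    if central <= 0:
        raise ValueError("degenerate kernel")
    return PearsonField(conv / central, (radius + 1, radius + 1))


def autocovariance_wk(image: np.ndarray) -> AutocovarianceField:
    """Autocovariance of a frame via the Wiener--Khinchin theorem.

    K is the inverse 2-D Fourier transform of |F[image - mean]|^2 / (M N),
    i.e. the circular-lag (periodogram) estimator; K_{0,0} is the mean
    squared deviation of the frame.  The circular M x N result is unfolded
    onto the centred (2M-1, 2N-1) lag grid (lags m and m - M alias to the
    same circular entry).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be 2-D with at least 2x2 pixels")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    M, N = img.shape
    f = np.fft.fft2(img - img.mean())
    psd = (f * np.conj(f)).real / (M * N)
    # ifft2 carries its own 1/(MN); by Parseval this makes K_{0,0} the mean
    # squared deviation of the frame.
    k_circ = np.real(np.fft.ifft2(psd))
    rows = np.arange(-(M - 1), M) % M
    cols = np.arange(-(N - 1), N) % N
    return AutocovarianceField(k_circ[np.ix_(rows, cols)], (M, N))


def pearson_normalize(K: AutocovarianceField) -> PearsonField:
    """rho = K / K_{0,0}; requires a positive central element."""
    c = K.central
    if c <= 0:
        raise ValueError(f"degenerate field: central autocovariance {c} <= 0")
    return PearsonField(K.values / c, K.source_shape)


def _padded_window(rho: PearsonField, M: int, N: int) -> np.ndarray:
    """rho on the full +-(M-1), +-(N-1) lag grid (zero-padded or cropped)."""
    out = np.zeros((2 * M - 1, 2 * N - 1))
    cm, cn = M - 1, N - 1
    rm, rn = rho.center
    m_max = min(cm, rm)
    n_max = min(cn, rn)
    out[cm - m_max : cm + m_max + 1, cn - n_max : cn + n_max + 1] = rho.values[
        rm - m_max : rm + m_max + 1, rn - n_max : rn + n_max + 1
    ]
    return out


def _triangle_weights(M: int, N: int) -> np.ndarray:
    wm = M - np.abs(np.arange(-(M - 1), M))
    wn = N - np.abs(np.arange(-(N - 1), N))
    return np.outer(wm, wn).astype(float)


def beta_corr(rho: PearsonField, M: int, N: int) -> float:
    """Correlation factor relating within-frame sample variance to true variance.

    beta_corr = MN/(MN-1) * (1 - (MN)^-2 sum_{m,n} (M-|m|)(N-|n|) rho_{m,n}),
    in [0, 2]: 1 for uncorrelated noise, -> 0 for total correlation, 2 in the
    total anti-correlation limit.
    """
    if M * N <= 1:
        raise ValueError("need more than one pixel")
    w = _triangle_weights(M, N)
    s = float((w * _padded_window(rho, M, N)).sum())
    return M * N / (M * N - 1.0) * (1.0 - s / (M * N) ** 2)


def bin_pearson(rho: PearsonField, H: int, V: int) -> tuple[PearsonField, float]:
    """Pearson coefficients after summing blocks of H x V neighbouring pixels.

    Returns the binned field and ``rho00_star``, the multiplier taking the
    unbinned true variance to the binned true variance:
    rho00_star = sum_{h,v} (H-|h|)(V-|v|) rho_{h,v}.
    """
    if H < 1 or V < 1:
        raise ValueError("bin factors must be >= 1")
    rm, rn = rho.center
    # vertical lags (rows, index m) bin by V; horizontal (columns, n) by H
    w = _triangle_weights(V, H)
    vs = np.arange(-(V - 1), V)
    hs = np.arange(-(H - 1), H)

    def wsum(m: int, n: int) -> float:
        rows = rm + V * m + vs
        cols = rn + H * n + hs
        ok_r = (rows >= 0) & (rows < rho.values.shape[0])
        ok_c = (cols >= 0) & (cols < rho.values.shape[1])
        if not ok_r.any() or not ok_c.any():
            return 0.0
        sub = rho.values[np.ix_(rows[ok_r], cols[ok_c])]
        return float((w[np.ix_(ok_r, ok_c)] * sub).sum())

    rho00_star = wsum(0, 0)
    if rho00_star <= 0:
        raise ValueError(f"degenerate binning: rho00* = {rho00_star} <= 0")
    m_out = rm // V
    n_out = rn // H
    out = np.zeros((2 * m_out + 1, 2 * n_out + 1))
    for m in range(-m_out, m_out + 1):
        for n in range(-n_out, n_out + 1):
            out[m_out + m, n_out + n] = wsum(m, n) / rho00_star
    src = (max(rho.source_shape[0] // V, 1), max(rho.source_shape[1] // H, 1))
    return PearsonField(out, src), rho00_star


def beta_conv(rho: PearsonField) -> float:
    """Noise-smoothing factor of a convolution: reciprocal of the coefficient sum.

    beta_conv = (sum_{m,n} rho_{m,n})^-1 = [Omega (x) Omega]_{0,0} for the
    sum-to-one kernel Omega that generated the correlation.
    """
    s = rho.total()
    if s <= 0:
        raise ValueError(
            f"coefficient sum {s} <= 0: stationarity-degenerate field "
            "(periodogram estimates sum to ~0 over a circular period)"
        )
    return 1.0 / s


def psf_from_pearson(
    rho: PearsonField, *, strict: bool = False, clip_tol: float = 0.05
) -> Kernel:
    """Reconstruct the PSF as F^-1[ sqrt(F[rho]) ], sum-normalized.

    The Fourier transform of a valid Pearson field is real and non-negative;
    estimator noise leaks small negative values (a consequence of the
    periodogram's zero-sum property), which are clipped to zero.  If the
    clipped spectral mass exceeds ``clip_tol`` of the total a warning is
    raised (an error in strict mode).
    """
    spec = np.fft.fft2(np.fft.ifftshift(rho.values))
    re = spec.real
    neg = -re[re < 0].sum()
    tot = np.abs(re).sum()
    if tot > 0 and neg / tot > clip_tol:
        msg = f"clipped {neg / tot:.1%} negative spectral mass in PSF reconstruction"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    amp = np.sqrt(np.clip(re, 0.0, None))
    omega = np.fft.fftshift(np.real(np.fft.ifft2(amp)))
    omega = np.clip(omega, 0.0, None)
    total = omega.sum()
    if total <= 0:
        raise ValueError("PSF reconstruction produced an empty kernel")
    return Kernel(omega / total, "sum-to-one")
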