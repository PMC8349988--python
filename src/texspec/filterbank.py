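"""Log-Gabor quadrature filter bank.

First processing stage of the two-stage spectral texture model: a bank of
frequency-domain log-Gabor filters indexed by orientation and spatial
frequency, used to decompose a luminance image into analytic (quadrature
pair) subbands, compute subband energy (the local contrast envelope), and
collapse subbands back into an image.

Conventions
-----------
* Arrays are indexed ``(y, x)``; frequency is measured in cycles/image and
  orientation counterclockwise from horizontal, in degrees.
* Quadrature pairs are realized as analytic filters: each gain map is
  nonzero only on the half-plane within 90 degrees of its center
  orientation, so one inverse FFT yields a complex response whose real part
  is the even-phase subband and whose imaginary part is the odd-phase
  subband.
* The image mean is removed before decomposition and restored on
  reconstruction; low/high-pass residual filters cover frequencies outside
  the band coverage so the decomposition is invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

__all__ = [
    "FilterBankConfig",
    "FilterBank",
    "SubbandStack",
    "EnergyStack",
    "make_filter_bank",
    "decompose",
    "energy",
    "reconstruct",
    "tiling_deviation",
]

# half width at half magnitude of a Gaussian, in units of sigma
_HWHM_SIGMA = np.sqrt(2.0 * np.log(2.0))

# floor for the combined squared gain when dividing in reconstruct
_GAIN_FLOOR = 1e-3


@dataclass(frozen=True)
class FilterBankConfig:
    """Geometry of the log-Gabor bank.

    Defaults give eight orientations (0-157.5 deg in 22.5 deg steps) and
    eight frequency bands with centers 1-128 cycles/image spaced one octave
    apart, with a 1-octave spatial-frequency bandwidth and a 30 degree
    orientation bandwidth (both full widths at half magnitude).
    """

    size: int = 256
    n_ori: int = 8
    n_freq: int = 8
    freq_min: float = 1.0
    freq_step_octaves: float = 1.0
    bw_octaves: float = 1.0
    bw_ori_deg: float = 30.0

    def __post_init__(self) -> None:
        n = self.size
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError(f"size must be a power of two, got {n}")
        if self.n_ori < 2:
            raise ValueError(f"n_ori must be >= 2, got {self.n_ori}")
        if self.n_freq < 1:
            raise ValueError(f"n_freq must be >= 1, got {self.n_freq}")
        if n < 2 ** self.n_freq:
            raise ValueError(
                f"size {n} too small for {self.n_freq} one-octave bands "
                f"(need size >= 2^n_freq = {2 ** self.n_freq})"
            )
        if self.freq_min <= 0:
            raise ValueError("freq_min must be positive")
        if self.bw_octaves <= 0 or self.bw_ori_deg <= 0:
            raise ValueError("bandwidths must be positive")
        nyquist = n / 2.0
        for k, f0 in enumerate(self.center_freqs):
            if f0 > nyquist + 1e-9:
                raise ValueError(
                    f"frequency band {k} (center {f0:g} cycles/image) exceeds "
                    f"the Nyquist limit {nyquist:g} for size {n}"
                )

    @property
    def center_freqs(self) -> np.ndarray:
        """Band center frequencies in cycles/image (geometric sequence)."""
        k = np.arange(self.n_freq, dtype=float)
        return self.freq_min * 2.0 ** (self.freq_step_octaves * k)

    @property
    def center_oris_deg(self) -> np.ndarray:
        """Band center orientations in degrees, spanning 180/n_ori steps."""
        return np.arange(self.n_ori) * (180.0 / self.n_ori)


@dataclass(frozen=True)
class FilterBank:
    """Frequency-domain gain maps of the bank.

    ``gains[o, k]`` is the real gain map (shape ``(N, N)``, fftshifted-off,
    i.e. DC at [0, 0]) of the analytic filter at orientation ``o`` and
    frequency band ``k``. ``lowpass`` and ``highpass`` are symmetric
    residual gains covering frequencies below the lowest and above the
    highest band. ``norm_sq`` caches the combined symmetric squared gain
    used for inverse filtering.
    """

    gains: np.ndarray          # (n_ori, n_freq, N, N)
    lowpass: np.ndarray        # (N, N)
    highpass: np.ndarray       # (N, N)
    config: FilterBankConfig
    norm_sq: np.ndarray = field(repr=False, default=None)    # (N, N)
    gains_sym: np.ndarray = field(repr=False, default=None)  # (n_ori, n_freq, N, N)


@dataclass
class SubbandStack:
    """Complex analytic subband responses of one image.

    ``responses`` has shape ``(N, N, n_ori, n_freq)``; real and imaginary
    parts of each band form a quadrature pair. Residual bands and the image
    mean are carried so the stack can be collapsed back into an image.
    """

    responses: np.ndarray      # complex, (N, N, n_ori, n_freq)
    residual_low: np.ndarray   # real, (N, N)
    residual_high: np.ndarray  # real, (N, N)
    mean: float
    config: FilterBankConfig


@dataclass
class EnergyStack:
    """Subband energy: magnitude of the analytic responses, >= 0."""

    energy: np.ndarray         # real, (N, N, n_ori, n_freq)
    config: FilterBankConfig


def _freq_grid(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radius (cycles/image) and angle (radians) of each DFT sample.

    The Nyquist row/column is assigned the positive frequency +N/2 so that
    the self-conjugate Nyquist samples fall inside the half-plane of the
    filters oriented near 0 and 90 degrees.
    """
    f = sfft.fftfreq(n) * n
    if n % 2 == 0:
        f[n // 2] = n / 2.0
    fy = f[:, None]
    fx = f[None, :]
    r = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    return r, theta, f


def _log_gabor_gain(
    r: np.ndarray,
    theta: np.ndarray,
    f0: float,
    ori_rad: float,
    sigma_oct: float,
    sigma_ang: float,
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        radial = np.exp(-(np.log2(r / f0) ** 2) / (2.0 * sigma_oct**2))
    radial[r == 0] = 0.0  # log-Gabor has no DC response
    dtheta = (theta - ori_rad + np.pi) % (2.0 * np.pi) - np.pi
    angular = np.where(
        np.abs(dtheta) <= np.pi / 2.0,
        np.exp(-(dtheta**2) / (2.0 * sigma_ang**2)),
        0.0,
    )
    return radial * angular


def _mirror(a: np.ndarray) -> np.ndarray:
    """Map sample (i, j) to (-i mod N, -j mod N): frequency negation."""
    return np.roll(a[::-1, ::-1], (1, 1), axis=(0, 1))


def make_filter_bank(config: FilterBankConfig) -> FilterBank:
    """Build the log-Gabor bank for the given geometry.

    Each filter is the product of a log-Gaussian radial profile peaking at
    its center frequency and a Gaussian angular profile peaking at its
    center orientation, restricted to one half-plane (analytic convention);
    peak gain is 1. Residual low/high-pass filters take up the complement
    ``sqrt(max(0, 1 - sum of squared symmetric gains))`` below the lowest
    and above the highest center frequency, so every frequency sample keeps
    a combined gain bounded away from zero and the bank is invertible.
    """
    n = config.size
    r, theta, _ = _freq_grid(n)
    sigma_oct = (config.bw_octaves / 2.0) / _HWHM_SIGMA
    sigma_ang = np.deg2rad(config.bw_ori_deg / 2.0) / _HWHM_SIGMA

    gains = np.empty((config.n_ori, config.n_freq, n, n))
    for o, ori in enumerate(np.deg2rad(config.center_oris_deg)):
        for k, f0 in enumerate(config.center_freqs):
            gains[o, k] = _log_gabor_gain(r, theta, f0, ori, sigma_oct, sigma_ang)

    # symmetrized (even) filters and their combined squared gain
    gains_sym = np.empty_like(gains)
    for o in range(config.n_ori):
        for k in range(config.n_freq):
            gains_sym[o, k] = gains[o, k] + _mirror(gains[o, k])
    band_sq = np.einsum("okyx,okyx->yx", gains_sym, gains_sym)

    deficit = np.sqrt(np.clip(1.0 - band_sq, 0.0, None))
    f_lo = config.center_freqs[0]
    f_hi = config.center_freqs[-1]
    lowpass = np.where(r < f_lo, deficit, 0.0)
    lowpass[0, 0] = 1.0  # DC passes only through the low residual
    highpass = np.where(r > f_hi, deficit, 0.0)

    norm_sq = band_sq + lowpass**2 + highpass**2
    return FilterBank(gains=gains, lowpass=lowpass, highpass=highpass,
                      config=config, norm_sq=norm_sq, gains_sym=gains_sym)


def decompose(image: np.ndarray, bank: FilterBank) -> SubbandStack:
    """Split an image into analytic subbands plus residual bands.

    The response of band ``(o, k)`` is ``ifft2(2 * gain * fft2(image -
    mean))``: a complex analytic signal whose real/imaginary parts are the
    even/odd quadrature pair.
    """
    n = bank.config.size
    image = np.asarray(image, dtype=float)
    if image.shape != (n, n):
        raise ValueError(
            f"image shape {image.shape} does not match bank size ({n}, {n})"
        )
    mean = float(image.mean())
    spectrum = sfft.fft2(image - mean)
    cfg = bank.config
    banded = sfft.ifft2(2.0 * bank.gains * spectrum, axes=(-2, -1))
    responses = np.ascontiguousarray(np.moveaxis(banded, (0, 1), (2, 3)))
    residual_low = sfft.ifft2(bank.lowpass * spectrum).real
    residual_high = sfft.ifft2(bank.highpass * spectrum).real
    return SubbandStack(responses=responses, residual_low=residual_low,
                        residual_high=residual_high, mean=mean, config=cfg)


def energy(subbands: SubbandStack) -> EnergyStack:
    """Subband energy: sqrt of the summed squares of each quadrature pair,

    i.e. the magnitude of the analytic response. Always non-negative.
    """
    return EnergyStack(energy=np.abs(subbands.responses), config=subbands.config)


def reconstruct(subbands: SubbandStack, bank: FilterBank) -> np.ndarray:
    """Collapse a subband stack back into a luminance image.

    Each band's even (real) part is re-filtered with its own symmetrized
    gain, residuals are re-filtered likewise, the sum is divided in the
    frequency domain by the combined squared gain (floored at a small
    epsilon), and the mean is restored. For an unmodified stack this
    inverts :func:`decompose` to machine precision.
    """
    cfg = bank.config
    n = cfg.size
    if subbands.responses.shape != (n, n, cfg.n_ori, cfg.n_freq):
        raise ValueError("subband stack shape does not match bank")
    even = np.moveaxis(subbands.responses.real, (2, 3), (0, 1))
    num = np.einsum("okyx,okyx->yx", bank.gains_sym,
                    sfft.fft2(even, axes=(-2, -1)))
    num += bank.lowpass * sfft.fft2(subbands.residual_low)
    num += bank.highpass * sfft.fft2(subbands.residual_high)
    out = sfft.ifft2(num / np.maximum(bank.norm_sq, _GAIN_FLOOR)).real
    return out + subbands.mean


def tiling_deviation(bank: FilterBank) -> float:
    """Max over interior non-DC samples of |combined squared gain - 1|.

    Reports how far the bank is from an exact partition of the spectrum;
    reconstruction divides the deviation out, so this measures conditioning,
    not reconstruction error. The Nyquist row/column is excluded: its
    self-conjugate samples are double-counted by the even/odd
    symmetrization, inflating the measure there by construction.
    """
    n = bank.config.size
    t = bank.norm_sq.copy()
    t[0, 0] = 1.0  # DC handled by the mean
    if n % 2 == 0:
        t[n // 2, :] = 1.0
        t[:, n // 2] = 1.0
    return float(np.max(np.abs(t - 1.0)))
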