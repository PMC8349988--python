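"""First- and second-order spectra.

The model describes a texture by two amplitude spectra: the 1st-order
spectrum (2D Fourier transform of the luminance image) and the 2nd-order
spectrum (4D Fourier transform of the subband energy data over x, y,
orientation and frequency). This module computes both, the per-band 2D
variant of the energy spectrum, a relative spectral distance, and the
model's representation-size accounting.

DFT convention: unnormalized forward transform, 1/size inverse (the numpy /
scipy default). All four axes of the 4D transform are treated as circular;
the orientation axis is physically circular (period 180 degrees) while the
scale axis is not, but the plain FFT wraps both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .filterbank import EnergyStack

__all__ = [
    "Spectrum2D",
    "Spectrum4D",
    "luminance_spectrum",
    "energy_spectrum_4d",
    "energy_spectrum_2d",
    "spectral_distance",
    "representation_size",
]


@dataclass(frozen=True)
class Spectrum2D:
    """Amplitude and phase of a 2D DFT; amplitude >= 0, phase in (-pi, pi]."""

    amplitude: np.ndarray
    phase: np.ndarray

    def to_complex(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass(frozen=True)
class Spectrum4D:
    """Amplitude and phase of a 4D DFT over (Fx, Fy, Fori, Ffreq)."""

    amplitude: np.ndarray
    phase: np.ndarray

    def to_complex(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


def _split(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.abs(z), np.angle(z)


def luminance_spectrum(image: np.ndarray) -> Spectrum2D:
    """1st-order spectrum: amplitude and phase of the image's 2D DFT."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square 2D image, got shape {image.shape}")
    amp, ph = _split(sfft.fft2(image))
    return Spectrum2D(amplitude=amp, phase=ph)


def energy_spectrum_4d(stack: EnergyStack) -> Spectrum4D:
    """2nd-order spectrum: 4D DFT of the energy data over all four axes."""
    amp, ph = _split(sfft.fftn(stack.energy, axes=(0, 1, 2, 3)))
    return Spectrum4D(amplitude=amp, phase=ph)


def energy_spectrum_2d(stack: EnergyStack) -> list[Spectrum2D]:
    """Per-band 2D spectra of the energy data, transformed across space only.

    Returns one :class:`Spectrum2D` per (orientation, frequency) band, in
    row-major band order.
    """
    z = sfft.fft2(stack.energy, axes=(0, 1))
    out: list[Spectrum2D] = []
    for o in range(z.shape[2]):
        for k in range(z.shape[3]):
            amp, ph = _split(z[:, :, o, k])
            out.append(Spectrum2D(amplitude=amp, phase=ph))
    return out


def spectral_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Relative L2 distance ||a - b|| / ||b|| between two amplitude arrays.

    ``b`` is the reference; returns 0 iff the arrays are equal. If the
    reference is identically zero the distance is 0 when ``a`` is too,
    else infinity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ref = np.linalg.norm(b.ravel())
    diff = np.linalg.norm((a - b).ravel())
    if ref == 0.0:
        return 0.0 if diff == 0.0 else np.inf
    return float(diff / ref)


def representation_size(n: int, n_ori: int = 8, n_freq: int = 8) -> int:
    """Number of values in the model's texture code for an N x N image.

    Counts the pixel histogram (N*N values), the 1st-order amplitude
    spectrum at Hermitian half size per axis ((N/2)^2), and the 2nd-order
    amplitude spectrum at half size per axis ((N/2)^2 * (n_ori/2) *
    (n_freq/2)). With the defaults (N=256, 8 orientations, 8 frequencies)
    this is 344064.
    """
    if n % 2 or n_ori % 2 or n_freq % 2:
        raise ValueError("n, n_ori and n_freq must all be even")
    half = n // 2
    return n * n + half * half + half * half * (n_ori // 2) * (n_freq // 2)
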