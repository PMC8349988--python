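"""Deterministic synthetic targets and rank data.

Stands in for a natural-texture corpus: gratings and plaids (closed-form
spectra), band-passed noise (a spectrum-only texture), periodic tilings
(strong second-order periodicity, the class phase-randomization synthesis
handles best), and white noise. Also generates Thurstonian rank tables for
the scaling pipeline. Everything is reproducible bit-exactly from its
parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .scaling import RankTable

__all__ = ["FIXTURE_KINDS", "FixtureSpec", "make_fixture", "make_rank_data"]

log = logging.getLogger(__name__)

FIXTURE_KINDS = ("grating", "plaid", "bandnoise", "tiles", "whitenoise")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic target image.

    ``frequency`` is in cycles/image (it need not be an integer; off-lattice
    frequencies produce spectral leakage and hence richer spectra),
    orientations in degrees counterclockwise from horizontal. ``band`` is
    the (low, high) annulus in cycles/image for band-passed noise;
    ``tile_period`` the lattice pitch in pixels.
    """

    kind: str
    size: int = 256
    frequency: float = 8.0
    orientation_deg: float = 0.0
    orientations_deg: tuple[float, float] = (0.0, 90.0)
    contrast: float = 1.0
    phase: float = 0.0
    band: tuple[float, float] = (8.0, 32.0)
    tile_period: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"kind must be one of {FIXTURE_KINDS}, got {self.kind!r}")
        n = self.size
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError(f"size must be a power of two, got {n}")
        nyq = n / 2.0
        if self.kind in ("grating", "plaid") and not 0 < self.frequency <= nyq:
            raise ValueError(
                f"frequency {self.frequency} outside (0, {nyq}] cycles/image"
            )
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must be in [0, 1], got {self.contrast}")
        if self.kind == "bandnoise":
            lo, hi = self.band
            if not (0 < lo < hi <= np.hypot(nyq, nyq)):
                raise ValueError(f"invalid band annulus {self.band}")
        if self.kind == "tiles" and not 2 <= self.tile_period <= n:
            raise ValueError(f"tile_period {self.tile_period} outside [2, {n}]")


def _grating(n: int, freq: float, ori_deg: float, contrast: float, phase: float
             ) -> np.ndarray:
    y, x = np.mgrid[0:n, 0:n].astype(float)
    th = np.deg2rad(ori_deg)
    arg = 2.0 * np.pi * freq * (x * np.cos(th) + y * np.sin(th)) / n + phase
    return 0.5 + 0.5 * contrast * np.sin(arg)


def _bandnoise(n: int, lo: float, hi: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n))
    f = sfft.fftfreq(n) * n
    r = np.hypot(f[None, :], f[:, None])
    mask = (r >= lo) & (r <= hi)
    y = sfft.ifft2(sfft.fft2(noise) * mask).real
    peak = np.max(np.abs(y))
    if peak == 0.0:
        return np.full((n, n), 0.5)
    return 0.5 + 0.5 * y / peak  # annulus excludes DC, so the mean is 0.5


def _tiles(n: int, period: int) -> np.ndarray:
    grout = max(1, period // 8)
    y, x = np.mgrid[0:n, 0:n]
    on_line = (x % period < grout) | (y % period < grout)
    return np.where(on_line, 0.15, 0.85)


def make_fixture(spec: FixtureSpec) -> np.ndarray:
    """Render the fixture as a luminance image with values in [0, 1].

    Out-of-range values (possible only for band-passed noise after
    rescaling, where they cannot occur either, but checked for all kinds)
    are clipped and the count logged; gratings and plaids at contrast <= 1
    never clip.
    """
    n = spec.size
    if spec.kind == "grating":
        img = _grating(n, spec.frequency, spec.orientation_deg, spec.contrast,
                       spec.phase)
    elif spec.kind == "plaid":
        a, b = spec.orientations_deg
        img = 0.5 * (
            _grating(n, spec.frequency, a, spec.contrast, spec.phase)
            + _grating(n, spec.frequency, b, spec.contrast, spec.phase)
        )
    elif spec.kind == "bandnoise":
        img = _bandnoise(n, spec.band[0], spec.band[1], spec.seed)
    elif spec.kind == "tiles":
        img = _tiles(n, spec.tile_period)
    else:  # whitenoise
        img = np.random.default_rng(spec.seed).random((n, n))
    clipped = int(np.count_nonzero((img < 0.0) | (img > 1.0)))
    if clipped:
        log.warning("fixture %s: clipped %d out-of-range pixels", spec.kind, clipped)
        img = np.clip(img, 0.0, 1.0)
    return img


def make_rank_data(
    true_scores: np.ndarray,
    n_observers: int,
    n_items: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    methods: tuple[str, ...] | None = None,
) -> RankTable:
    """Thurstonian rank generator.

    For each (observer, item) cell, method utilities are the true scores
    plus independent Gaussian noise; methods are ranked by decreasing
    utility (rank 1 = best). Deterministic given the seed.
    """
    true_scores = np.asarray(true_scores, dtype=float)
    m = true_scores.size
    if m < 2:
        raise ValueError("need at least two methods")
    rng = np.random.default_rng(seed)
    utilities = true_scores + noise_sd * rng.standard_normal((n_observers, n_items, m))
    order = np.argsort(-utilities, axis=-1, kind="stable")
    ranks = np.empty((n_observers, n_items, m), dtype=int)
    np.put_along_axis(ranks, order, np.arange(1, m + 1)[None, None, :], axis=-1)
    if methods is None:
        methods = tuple(f"method_{i}" for i in range(m))
    return RankTable(ranks=ranks, methods=tuple(methods))
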