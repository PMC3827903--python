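"""Height-map representation of mineralized substrate surfaces.

A substrate (cortical bone or dentin slice) is modelled as a rectangular
grid of surface heights in micrometres.  Height 0 is the pristine
reference plane; resorption only ever lowers heights, so after any
resorption operation every pixel is at or below its pre-operation value.

Roughness follows the profilometric convention used for machined and
biological surfaces: for a single line profile, ``Ra`` is the arithmetic
mean of the absolute deviations of the profile from its mean line and
``Rq`` is the root-mean-square deviation.  Profiles are taken along grid
rows, mimicking line scans of several hundred micrometres across a slice.
``Rq >= Ra`` holds for every profile (Cauchy-Schwarz), so it must hold
for any surface this module generates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "HeightMap",
    "RoughnessMetrics",
    "make_flat",
    "roughness_ra",
    "roughness_rq",
    "roughness_metrics",
    "synthesize_roughness",
    "UM2_PER_CM2",
]

#: square micrometres per square centimetre
UM2_PER_CM2 = 1.0e8


@dataclass
class HeightMap:
    """A surface height field.

    Parameters
    ----------
    heights:
        2-D array of heights in micrometres, shape ``(ny, nx)``.  Row
        index is the y direction.  Pixel ``(i, j)`` is centred at
        ``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)`` in
        (x, y) micrometre coordinates.
    pixel_size:
        Isotropic pixel edge length in micrometres (> 0).
    """

    heights: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")

    # -- geometry ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the map in micrometres (x, y)."""
        ny, nx = self.heights.shape
        return nx * self.pixel_size, ny * self.pixel_size

    @property
    def area_um2(self) -> float:
        ny, nx = self.heights.shape
        return nx * ny * self.pixel_size**2

    @property
    def area_cm2(self) -> float:
        return self.area_um2 / UM2_PER_CM2

    def copy(self) -> "HeightMap":
        return HeightMap(self.heights.copy(), self.pixel_size)


@dataclass(frozen=True)
class RoughnessMetrics:
    """Arithmetic-average (Ra) and RMS (Rq) roughness of a surface, μm."""

    ra: float
    rq: float
    scan_length_um: float

    def __post_init__(self) -> None:
        if self.ra < 0:
            raise ValueError("Ra must be >= 0")
        if self.rq < self.ra - 1e-12:
            raise ValueError("Rq must be >= Ra")


def make_flat(nx: int, ny: int, pixel_size: float = 1.0) -> HeightMap:
    """Create a perfectly flat (pristine) surface of ``nx`` x ``ny`` pixels."""
    if int(nx) != nx or int(ny) != ny or nx < 1 or ny < 1:
        raise ValueError("nx and ny must be integers >= 1")
    if not (pixel_size > 0):
        raise ValueError("pixel_size must be > 0")
    return HeightMap(np.zeros((int(ny), int(nx))), float(pixel_size))


def _centered(profile) -> np.ndarray:
    arr = np.asarray(profile, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("profile needs at least 2 points")
    if not np.all(np.isfinite(arr)):
        raise ValueError("profile must be finite")
    return arr - arr.mean()


def roughness_ra(profile) -> float:
    """Arithmetic-average roughness: mean |h_i - mean(h)| of a line profile."""
    return float(np.abs(_centered(profile)).mean())


def roughness_rq(profile) -> float:
    """Root-mean-square roughness of a mean-centred line profile."""
    return float(np.sqrt(np.mean(_centered(profile) ** 2)))


def roughness_metrics(surface: HeightMap) -> RoughnessMetrics:
    """Row-wise mean Ra/Rq of a surface.

    Each grid row is treated as one profilometer line scan; the reported
    Ra and Rq are means over all rows.  The scan length is the row
    length in micrometres.
    """
    h = surface.heights
    centred = h - h.mean(axis=1, keepdims=True)
    ra = float(np.abs(centred).mean(axis=1).mean())
    rq = float(np.sqrt((centred**2).mean(axis=1)).mean())
    return RoughnessMetrics(ra=ra, rq=rq, scan_length_um=h.shape[1] * surface.pixel_size)


def synthesize_roughness(
    surface: HeightMap,
    ra_target: float,
    correlation_length: float = 20.0,
    seed: int | np.random.SeedSequence = 0,
) -> HeightMap:
    """Add correlated random texture so the surface hits a target Ra.

    A Gaussian white-noise field is smoothed with an isotropic Gaussian
    kernel of standard deviation ``correlation_length`` (μm) and added to
    the input surface with an amplitude chosen so that the row-wise mean
    Ra of the result matches ``ra_target``.  Rq is emergent (a single
    amplitude cannot pin Ra and Rq simultaneously) and always satisfies
    ``Rq >= Ra``.  The result is deterministic for a given seed.

    Raises
    ------
    ValueError
        If ``ra_target`` is negative or ``correlation_length`` is smaller
        than the pixel size.
    """
    if ra_target < 0:
        raise ValueError("ra_target must be >= 0")
    if correlation_length < surface.pixel_size:
        raise ValueError("correlation_length must be >= pixel_size")
    if ra_target == 0:
        return surface.copy()

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(surface.heights.shape)
    field = ndimage.gaussian_filter(noise, sigma=correlation_length / surface.pixel_size, mode="reflect")
    field -= field.mean()

    # Secant iteration on the amplitude; exact in one step for a flat base
    # because Ra is homogeneous of degree one in the added field.
    base = surface.heights
    scale = ra_target / roughness_metrics(HeightMap(field, surface.pixel_size)).ra
    for _ in range(20):
        out = HeightMap(base + scale * field, surface.pixel_size)
        ra = roughness_metrics(out).ra
        if abs(ra - ra_target) <= 1e-3 * ra_target:
            break
        scale *= ra_target / ra
    return HeightMap(base + scale * field, surface.pixel_size)
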