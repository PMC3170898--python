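"""Imaging geometry, image container, and the Shepp-Logan phantom.

The reconstruction grid is a square of n x n pixels. Pixel (row r, col c)
has its center at continuous coordinates ``x = (c - (n-1)/2) * s`` and
``y = ((n-1)/2 - r) * s`` in a centered, x-right / y-up frame, where ``s``
is the pixel size. All rotations are about the exact grid center (0, 0).
Projection angles are in degrees, counterclockwise positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGrid",
    "ParallelBeamGeometry",
    "Sinogram",
    "make_shepp_logan",
    "default_geometry",
]


@dataclass
class ImageGrid:
    """Square n x n grid of attenuation coefficients f_j.

    Parameters
    ----------
    values : ndarray of shape (n, n)
        Attenuation coefficients, row-major, arbitrary attenuation units.
    pixel_size : float
        Side length of one square pixel, in length units. Default 1.0.
    """

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"image must be square 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError("image side length must be >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")

    @property
    def n(self) -> int:
        """Side length of the grid in pixels."""
        return self.values.shape[0]


@dataclass
class ParallelBeamGeometry:
    """Parallel-beam acquisition geometry.

    Attributes
    ----------
    angles_deg : ndarray of shape (Q,)
        Ordered projection angles in degrees, counterclockwise positive.
    n_detectors : int
        Number of detector bins D, one ray per bin.
    ray_width : float
        Detector bin pitch tau, in the same length units as the pixel
        size; conventionally tau equals the pixel width.
    """

    angles_deg: np.ndarray
    n_detectors: int
    ray_width: float = 1.0

    def __post_init__(self) -> None:
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=np.float64))
        if self.angles_deg.size < 1:
            raise ValueError("need at least one projection angle")
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("angles must be finite")
        if int(self.n_detectors) < 1:
            raise ValueError("n_detectors must be >= 1")
        self.n_detectors = int(self.n_detectors)
        if not (self.ray_width > 0):
            raise ValueError("ray_width must be > 0")

    @property
    def n_angles(self) -> int:
        return self.angles_deg.size


@dataclass
class Sinogram:
    """Raysums p_i arranged as a Q x D grid (angle index, detector bin)."""

    raysums: np.ndarray
    geometry: ParallelBeamGeometry

    def __post_init__(self) -> None:
        self.raysums = np.asarray(self.raysums, dtype=np.float64)
        expected = (self.geometry.n_angles, self.geometry.n_detectors)
        if self.raysums.shape != expected:
            raise ValueError(
                f"raysums shape {self.raysums.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.raysums)):
            raise ValueError("raysums must be finite")


# Modified Shepp-Logan head phantom: ten ellipses, each a tuple
# (intensity A, semi-axis a, semi-axis b, center x0, center y0, tilt phi in
# degrees) on the [-1, 1]^2 square. Intensities are the low-contrast
# variant so that summed overlaps stay within [0, 1].
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def _rasterize_ellipses(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sum of ellipse intensities at continuous points (x, y) in [-1, 1]^2."""
    img = np.zeros_like(x)
    for amp, a, b, x0, y0, phi_deg in SHEPP_LOGAN_ELLIPSES:
        phi = np.deg2rad(phi_deg)
        cphi, sphi = np.cos(phi), np.sin(phi)
        xr = (x - x0) * cphi + (y - y0) * sphi
        yr = -(x - x0) * sphi + (y - y0) * cphi
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += amp
    return img


def make_shepp_logan(n: int, pixel_size: float = 1.0, subsamples: int = 4) -> ImageGrid:
    """Rasterize the modified Shepp-Logan head phantom on an n x n grid.

    Each pixel averages the summed ellipse intensities over a
    ``subsamples x subsamples`` grid of points inside the pixel (area
    anti-aliasing). Boundary pixels therefore take partial-coverage
    values, which keeps line integrals of the raster close to the
    analytic ellipse integrals; ``subsamples=1`` gives plain
    pixel-center point sampling. The phantom support lies strictly
    inside the inscribed circle of the grid, so the corners are exactly
    zero.

    Parameters
    ----------
    n : int
        Grid side length in pixels, at least 2.
    pixel_size : float
        Physical pixel width stored on the returned :class:`ImageGrid`.
    subsamples : int
        Side of the subpixel sampling grid, at least 1. Default 4.

    Returns
    -------
    ImageGrid
        Deterministic phantom with values in [0, 1].
    """
    n = int(n)
    if n < 2:
        raise ValueError("phantom size must be >= 2")
    sub = int(subsamples)
    if sub < 1:
        raise ValueError("subsamples must be >= 1")
    c0 = (n - 1) / 2.0
    img = np.zeros((n, n), dtype=np.float64)
    offsets = (np.arange(sub) + 0.5) / sub - 0.5  # subpixel offsets in pixels
    for oy in offsets:
        for ox in offsets:
            xs = (np.arange(n) - c0 + ox) / (n / 2.0)
            ys = (c0 - np.arange(n) + oy) / (n / 2.0)
            x, y = np.meshgrid(xs, ys)  # row 0 at top (y > 0)
            img += _rasterize_ellipses(x, y)
    img /= sub * sub
    # exact-cancellation overlaps (1 - 0.8 - 0.2) leave -eps residue
    np.maximum(img, 0.0, out=img)
    return ImageGrid(img, pixel_size=pixel_size)


def default_geometry(
    n: int, q: int, pixel_size: float = 1.0
) -> ParallelBeamGeometry:
    """Standard geometry: q equispaced angles over 360 degrees, D = n bins.

    Angles are ``k * (360 / q)`` for ``k = 0 .. q-1``. The detector count
    equals the image side length and the ray width equals the pixel width,
    so at the base angle each ray runs down one pixel column.
    """
    n = int(n)
    q = int(q)
    if n < 2:
        raise ValueError("n must be >= 2")
    if q < 1:
        raise ValueError("q must be >= 1")
    angles = np.arange(q, dtype=np.float64) * (360.0 / q)
    return ParallelBeamGeometry(angles_deg=angles, n_detectors=n, ray_width=pixel_size)
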