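"""Siddon ray tracing and the base-angle sparse weighting matrix.

The weighting factor w_ij is the intersection (chord) length of ray i with
pixel j, computed with Siddon's parametric plane-crossing method: the ray
is clipped to the grid, the parameter values of every pixel-boundary
crossing are merged and sorted, and each resulting interval is attributed
to the pixel containing its midpoint. Cost is linear in the number of
crossed pixels. A ray that passes exactly through a pixel corner yields a
zero-length interval there, which is dropped, so corner grazes contribute
to neither adjacent pixel.

The rotation-based scheme needs the weights at a single base angle only:
0 degrees, rays parallel to the image columns, one ray per detector bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import ParallelBeamGeometry

__all__ = ["RayPath", "SparseWeightMatrix", "siddon_trace", "build_base_matrix"]

_EPS = 1e-12


@dataclass
class RayPath:
    """Pixels crossed by one ray, with chord lengths, in traversal order.

    ``pixels`` holds 0-based row-major flat indices into the n x n grid;
    ``lengths`` the matching intersection lengths (length units, >= 0).
    """

    pixels: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        if self.pixels.shape != self.lengths.shape:
            raise ValueError("pixels and lengths must have equal length")
        if np.any(self.lengths < 0):
            raise ValueError("chord lengths must be >= 0")

    @property
    def total_length(self) -> float:
        """Chord length of the ray through the whole grid."""
        return float(self.lengths.sum())


def siddon_trace(
    p0,
    p1,
    grid_n: int,
    pixel_size: float = 1.0,
) -> RayPath:
    """Trace the segment p0 -> p1 through an n x n pixel grid.

    The grid is centered at the origin and spans
    ``[-n*s/2, n*s/2]`` in both x and y, with s = ``pixel_size``.
    Both endpoints must lie on or outside the grid boundary so the
    returned lengths are full chords.

    Returns
    -------
    RayPath
        One entry per pixel whose interior the segment crosses, ordered
        monotonically along the ray. Empty if the ray misses the grid.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    d = p1 - p0
    seg_len = float(np.hypot(d[0], d[1]))
    if seg_len == 0.0:
        raise ValueError("degenerate ray: p0 == p1")
    n = int(grid_n)
    s = float(pixel_size)
    half = n * s / 2.0

    # Clip the parametric ray p0 + a*d, a in [0, 1], to the grid square.
    a_lo, a_hi = 0.0, 1.0
    for ax in (0, 1):
        if d[ax] != 0.0:
            a1 = (-half - p0[ax]) / d[ax]
            a2 = (half - p0[ax]) / d[ax]
            a_lo = max(a_lo, min(a1, a2))
            a_hi = min(a_hi, max(a1, a2))
        elif not (-half <= p0[ax] <= half):
            return RayPath(np.empty(0, dtype=np.intp), np.empty(0))
    if a_hi - a_lo <= _EPS:
        return RayPath(np.empty(0, dtype=np.intp), np.empty(0))

    # Parameter values of all pixel-boundary crossings inside [a_lo, a_hi].
    planes = -half + s * np.arange(n + 1)
    crossings = [np.array([a_lo, a_hi])]
    for ax in (0, 1):
        if d[ax] != 0.0:
            a = (planes - p0[ax]) / d[ax]
            crossings.append(a[(a > a_lo) & (a < a_hi)])
    alphas = np.unique(np.concatenate(crossings))

    mids = (alphas[:-1] + alphas[1:]) / 2.0
    dl = np.diff(alphas) * seg_len
    keep = dl > _EPS * seg_len
    mids, dl = mids[keep], dl[keep]
    if mids.size == 0:
        return RayPath(np.empty(0, dtype=np.intp), np.empty(0))

    px = p0[0] + mids * d[0]
    py = p0[1] + mids * d[1]
    cols = np.clip(np.floor((px + half) / s).astype(np.intp), 0, n - 1)
    rows = np.clip(np.floor((half - py) / s).astype(np.intp), 0, n - 1)
    flat = rows * n + cols

    # Merge consecutive duplicates (can arise from near-coincident planes).
    if flat.size > 1:
        same = flat[1:] == flat[:-1]
        if np.any(same):
            starts = np.flatnonzero(np.r_[True, ~same])
            flat = flat[starts]
            dl = np.add.reduceat(dl, starts)
    return RayPath(flat, dl)


@dataclass
class SparseWeightMatrix:
    """Base-angle weighting factors w_ij^base for all D detector rays.

    Stored both as the per-ray :class:`RayPath` list (``rows``) and as a
    CSR matrix of shape (D, n*n) for fast forward/back application.
    ``row_sums[i]`` is the total chord length of ray i through the grid,
    the per-ray normalizer of the simultaneous update.
    """

    rows: list[RayPath]
    n: int
    pixel_size: float = 1.0
    row_sums: np.ndarray = field(init=False)
    matrix: sp.csr_matrix = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.n = int(self.n)
        d = len(self.rows)
        indptr = np.zeros(d + 1, dtype=np.intp)
        indptr[1:] = np.cumsum([r.pixels.size for r in self.rows])
        indices = (
            np.concatenate([r.pixels for r in self.rows])
            if d
            else np.empty(0, dtype=np.intp)
        )
        data = np.concatenate([r.lengths for r in self.rows]) if d else np.empty(0)
        self.matrix = sp.csr_matrix(
            (data, indices, indptr), shape=(d, self.n * self.n)
        )
        # accumulate through the same CSR kernel as a forward pass so the
        # constant-1 projection at the base angle equals row_sums exactly
        self.row_sums = self.matrix @ np.ones(self.n * self.n)
        # Per-pixel sum of weights over this angle's rays (update denominator
        # before rotation); rotated copies are cached per distinct angle.
        self._weight_image = np.asarray(
            self.matrix.sum(axis=0)
        ).ravel().reshape(self.n, self.n)
        self._rotated_weight_cache: dict[float, np.ndarray] = {}

    @property
    def n_rays(self) -> int:
        return len(self.rows)

    @property
    def weight_image(self) -> np.ndarray:
        """Sum of w_ij over all base rays, as an n x n image."""
        return self._weight_image


def build_base_matrix(
    geometry: ParallelBeamGeometry, n: int, pixel_size: float = 1.0
) -> SparseWeightMatrix:
    """Build the reference weighting matrix at the base angle (0 degrees).

    Base rays run parallel to the image columns (+y direction), one per
    detector bin, with bin d centered at ``x = (d - (D-1)/2) * tau``.
    With D = n and tau equal to the pixel width, ray d runs down the
    center of pixel column d. This is a one-time computation; every other
    projection angle reuses this matrix via image rotation.
    """
    n = int(n)
    d_count = geometry.n_detectors
    tau = geometry.ray_width
    half = n * pixel_size / 2.0
    reach = half + pixel_size  # endpoints safely outside the grid
    rows = []
    for d in range(d_count):
        x = (d - (d_count - 1) / 2.0) * tau
        rows.append(
            siddon_trace((x, -reach), (x, reach), n, pixel_size=pixel_size)
        )
    return SparseWeightMatrix(rows=rows, n=n, pixel_size=pixel_size)
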