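"""OS-SART reconstruction over ordered subsets.

The image estimate f is updated once per ordered subset:

    f_j  <-  f_j + lambda * [ sum_{i in OS_l} c_i * w_ij ] / [ sum_{i in OS_l} w_ij ]

with the per-ray correction ``c_i = (p_i - sum_k w_ik f_k) / sum_k w_ik``
evaluated on the estimate as it stood at the start of the subset
(simultaneous semantics). The subset count T interpolates between the
classical algorithms: T = 1 is SIRT (one update per full pass), T = Q is
per-projection SART, and intermediate T gives ordered-subset SART with
faster early convergence.

Corrections for rays with zero chord length are zero, and pixels that
receive zero accumulated weight in a subset are left unchanged, so the
estimate never contains NaN or Inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ImageGrid, Sinogram
from .siddon import SparseWeightMatrix, build_base_matrix
from .rotation import _rotate_values, _rotated_weight_image

__all__ = [
    "OrderedSubsets",
    "ReconConfig",
    "ReconResult",
    "partition_subsets",
    "error_correction",
    "ossart_update",
    "reconstruct",
    "rmse",
]


@dataclass
class OrderedSubsets:
    """Disjoint partition of projection-angle indices into T subsets."""

    subsets: list[list[int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for s in self.subsets:
            if len(s) == 0:
                raise ValueError("every ordered subset must be non-empty")
            if seen.intersection(s):
                raise ValueError("ordered subsets must be pairwise disjoint")
            seen.update(s)

    @property
    def t(self) -> int:
        return len(self.subsets)


@dataclass
class ReconConfig:
    """Reconstruction parameters.

    lambda_relax : relaxation factor in (0, 1]; 0.2 is a robust default
        (small enough to damp noise, large enough to converge in tens of
        iterations).
    t_subsets : number of ordered subsets T (1 = SIRT, Q = SART).
    iterations : number of full passes I over all subsets.
    workers : worker count P for the parallel engine (1 = sequential).
    seed : RNG seed, reserved for noise extensions; no randomness is used
        by the update itself.
    """

    lambda_relax: float = 0.2
    t_subsets: int = 20
    iterations: int = 10
    workers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_relax <= 1.0):
            raise ValueError("relaxation factor must lie in (0, 1]")
        if int(self.t_subsets) < 1:
            raise ValueError("subset count must be >= 1")
        if int(self.iterations) < 1:
            raise ValueError("iteration count must be >= 1")
        if int(self.workers) < 1:
            raise ValueError("worker count must be >= 1")
        self.t_subsets = int(self.t_subsets)
        self.iterations = int(self.iterations)
        self.workers = int(self.workers)


@dataclass
class ReconResult:
    """Final estimate plus per-update quality history."""

    image: ImageGrid
    rmse_history: list[float]
    updates_performed: int
    config: ReconConfig


def partition_subsets(q: int, t: int) -> OrderedSubsets:
    """Partition projection indices {0..q-1} into t subsets by index modulo t.

    Subset l collects the projections whose index i satisfies
    ``i mod t = l``, in ascending order; with q = 360 and t = 20 this
    yields OS_0 = {0, 20, ..., 340}, OS_1 = {1, 21, ..., 341}, each of
    size 18.
    """
    q, t = int(q), int(t)
    if q < 1:
        raise ValueError("q must be >= 1")
    if not (1 <= t <= q):
        raise ValueError(f"subset count t={t} must satisfy 1 <= t <= q={q}")
    return OrderedSubsets([list(range(l, q, t)) for l in range(t)])


def error_correction(
    p: np.ndarray, forward: np.ndarray, row_sums: np.ndarray
) -> np.ndarray:
    """Per-ray normalized residual (p_i - forward_i) / row_sum_i.

    Rays with zero chord length through the grid get correction 0.
    """
    p = np.asarray(p, dtype=np.float64)
    forward = np.asarray(forward, dtype=np.float64)
    row_sums = np.asarray(row_sums, dtype=np.float64)
    if not (p.shape == forward.shape == row_sums.shape):
        raise ValueError("p, forward and row_sums must have equal shapes")
    if not (
        np.all(np.isfinite(p))
        and np.all(np.isfinite(forward))
        and np.all(np.isfinite(row_sums))
    ):
        raise ValueError("inputs must be finite")
    out = np.zeros_like(p)
    np.divide(p - forward, row_sums, out=out, where=row_sums > 0)
    return out


def angle_contribution(
    f_values: np.ndarray,
    angle_index: int,
    sino: Sinogram,
    base: SparseWeightMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Numerator and weight images contributed by one projection angle.

    Forward-projects the current estimate at the angle, forms the
    normalized residuals, smears them along the base rays and rotates the
    smear (and the matching weight image) back by -theta. Pure function of
    its inputs, so contributions may be computed in any order or in
    parallel and reduced later.
    """
    n = base.n
    theta = float(sino.geometry.angles_deg[angle_index])
    rotated = _rotate_values(f_values, theta)
    forward = base.matrix @ rotated.ravel()
    corr = error_correction(sino.raysums[angle_index], forward, base.row_sums)
    numerator = _rotate_values((base.matrix.T @ corr).reshape(n, n), -theta)
    weights = _rotated_weight_image(base, theta)
    return numerator, weights


def accumulate_subset(
    f_values: np.ndarray,
    subset_angles,
    sino: Sinogram,
    base: SparseWeightMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-angle contributions over a subset in ascending angle order.

    The fixed reduction order makes the result bit-reproducible and
    independent of how the per-angle work is scheduled.
    """
    angles = sorted(int(a) for a in subset_angles)
    if len(angles) == 0:
        raise ValueError("subset must be non-empty")
    num = np.zeros_like(f_values)
    wt = np.zeros_like(f_values)
    for a in angles:
        num_a, wt_a = angle_contribution(f_values, a, sino, base)
        num += num_a
        wt += wt_a
    return num, wt


def apply_update(
    f_values: np.ndarray,
    numerator: np.ndarray,
    weights: np.ndarray,
    lambda_relax: float,
) -> np.ndarray:
    """One relaxed simultaneous image update; zero-weight pixels unchanged."""
    ratio = np.zeros_like(numerator)
    np.divide(numerator, weights, out=ratio, where=weights > 0)
    return f_values + lambda_relax * ratio


def ossart_update(
    f: ImageGrid,
    subset_angles,
    sino: Sinogram,
    base: SparseWeightMatrix,
    lambda_relax: float,
) -> ImageGrid:
    """One OS-SART image update using every angle of one ordered subset.

    All corrections are computed against the estimate as passed in (not
    against intermediate states), accumulated across the subset's angles,
    and applied once.
    """
    if not np.all(np.isfinite(f.values)):
        raise ValueError("estimate must be finite")
    num, wt = accumulate_subset(f.values, subset_angles, sino, base)
    return ImageGrid(
        apply_update(f.values, num, wt, lambda_relax), pixel_size=f.pixel_size
    )


def rmse(a: ImageGrid, b: ImageGrid) -> float:
    """Root mean squared difference between two equally sized images."""
    if a.values.shape != b.values.shape:
        raise ValueError("images must have equal shapes")
    return float(np.sqrt(np.mean((a.values - b.values) ** 2)))


def reconstruct(
    sino: Sinogram,
    config: ReconConfig,
    ground_truth: ImageGrid | None = None,
    n: int | None = None,
    base: SparseWeightMatrix | None = None,
    rel_change_tol: float | None = None,
) -> ReconResult:
    """Run OS-SART from an all-zero initial estimate.

    Performs ``iterations`` full passes; each pass visits the T ordered
    subsets sequentially (l = 0 .. T-1) and performs one image update per
    subset. When ``ground_truth`` is given, the RMSE against it is
    recorded after every image update. ``rel_change_tol``, if set, stops
    early once the relative change of a full pass drops below it.

    Parameters
    ----------
    n : image side length; defaults to the detector count.
    base : precomputed base weighting matrix (built on demand otherwise).
    """
    n = int(n) if n is not None else sino.geometry.n_detectors
    if base is None:
        base = build_base_matrix(sino.geometry, n)
    subsets = partition_subsets(sino.geometry.n_angles, config.t_subsets)

    if config.workers > 1:
        from .parallel import parallel_subset_pass

    f = np.zeros((n, n), dtype=np.float64)
    history: list[float] = []
    updates = 0
    for _ in range(config.iterations):
        f_before = f.copy()
        for subset in subsets.subsets:
            if config.workers > 1:
                f = parallel_subset_pass(
                    ImageGrid(f), subset, sino, base,
                    config.lambda_relax, config.workers,
                ).values
            else:
                num, wt = accumulate_subset(f, subset, sino, base)
                f = apply_update(f, num, wt, config.lambda_relax)
            updates += 1
            if ground_truth is not None:
                history.append(rmse(ImageGrid(f), ground_truth))
        if rel_change_tol is not None:
            denom = np.linalg.norm(f_before)
            if denom > 0 and np.linalg.norm(f - f_before) / denom < rel_change_tol:
                break
    return ReconResult(
        image=ImageGrid(f),
        rmse_history=history,
        updates_performed=updates,
        config=config,
    )
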