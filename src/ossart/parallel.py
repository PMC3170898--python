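"""Coordinator/worker decomposition of one ordered-subset pass.

A coordinator splits a subset's projection angles round-robin across P
workers; each worker independently rotates the image, forward-projects,
forms corrections and back-projects for its angles; the coordinator then
reduces the per-angle partial images in ascending angle-index order and
performs the single image update for the subset. Reducing per angle in a
fixed global order (rather than per worker) makes the floating-point
result bit-identical for every worker count and completion order.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
import logging

import numpy as np

from .geometry import ImageGrid, Sinogram
from .siddon import SparseWeightMatrix
from .recon import angle_contribution, apply_update

__all__ = ["WorkAssignment", "assign_angles", "parallel_subset_pass"]

log = logging.getLogger(__name__)


@dataclass
class WorkAssignment:
    """Round-robin split of one subset's angles across P workers."""

    per_worker_angles: list[list[int]]

    @property
    def p(self) -> int:
        return len(self.per_worker_angles)


def assign_angles(subset, p: int) -> WorkAssignment:
    """Assign a subset's angles (ascending) round-robin to p workers.

    Worker w receives angles subset[w], subset[w+p], ...; sizes differ by
    at most one, and workers beyond the subset size receive empty lists.
    """
    if int(p) < 1:
        raise ValueError("worker count must be >= 1")
    p = int(p)
    ordered = sorted(int(a) for a in subset)
    return WorkAssignment([ordered[w::p] for w in range(p)])


def parallel_subset_pass(
    f: ImageGrid,
    subset,
    sino: Sinogram,
    base: SparseWeightMatrix,
    lambda_relax: float,
    p: int,
) -> ImageGrid:
    """One subset pass with P workers; bit-identical to the sequential pass.

    Workers compute per-angle (numerator, weight) contribution images
    concurrently from the same starting estimate. After the barrier (all
    workers done), the coordinator sums the contributions in ascending
    angle order and applies the single relaxed update.
    """
    assignment = assign_angles(subset, p)
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    f_values = f.values

    def worker(angles: list[int]):
        return [
            (a, *angle_contribution(f_values, a, sino, base)) for a in angles
        ]

    with ThreadPoolExecutor(max_workers=assignment.p) as pool:
        partials = list(pool.map(worker, assignment.per_worker_angles))

    # Barrier reached: merge every per-angle contribution in fixed
    # ascending angle order, independent of which worker produced it.
    contributions = sorted(
        (item for chunk in partials for item in chunk), key=lambda x: x[0]
    )
    num = np.zeros_like(f_values)
    wt = np.zeros_like(f_values)
    for _, num_a, wt_a in contributions:
        num += num_a
        wt += wt_a
    log.debug(
        "subset pass: %d angles on %d workers, 1 image update",
        len(contributions), assignment.p,
    )
    return ImageGrid(
        apply_update(f_values, num, wt, lambda_relax), pixel_size=f.pixel_size
    )
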