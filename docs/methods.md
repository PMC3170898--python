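# Methods

## Model

The object is a square grid of N = n² pixels with constant attenuation
f_j per pixel. A parallel beam at angle θ produces one raysum per
detector bin, modeled as the line integral Σ_j w_ij f_j with w_ij the
chord length of the (zero-width) ray through pixel j. The detector has
D bins of pitch τ; by default D = n and τ equals the pixel width, so at
the base angle each ray runs down one pixel column. Angles are degrees,
counterclockwise positive; pixel (r, c) has center
(c − (n−1)/2, (n−1)/2 − r) in a centered x-right/y-up frame, and all
rotations are about the exact grid center.

## OS-SART update

Projection indices {0..Q−1} are partitioned into T ordered subsets by
index modulo T (subset l holds the indices i with i mod T = l). One
image update per subset:

f_j ← f_j + λ · [Σ_{i∈OS_l} c_i w_ij] / [Σ_{i∈OS_l} w_ij],
c_i = (p_i − Σ_k w_ik f_k) / Σ_k w_ik,

with every correction in a subset evaluated on the estimate as it stood
at the start of that subset (simultaneous semantics — the defining
property that makes angles within a subset independent). Subsets are
visited sequentially l = 0..T−1; a full sweep over all T subsets is one
iteration.

Defaults and ranges:

| parameter | default | meaning |
|---|---|---|
| λ (`lambda_relax`) | 0.2 | relaxation, enforced in (0, 1]; 0.2 converges in tens of iterations while damping noise |
| T (`t_subsets`) | 20 | subset count; T=1 → SIRT, T=Q → SART |
| I (`iterations`) | 10 | full passes; quality grows with the number of updates I·T |
| P (`workers`) | 1 | worker threads per subset pass |

The initial estimate is all zeros. The stopping rule is the fixed
iteration count; an optional relative-change threshold
‖f_new − f_old‖/‖f_old‖ < ε per full pass can be enabled
(`rel_change_tol`), default off. No positivity clamp is applied.

Degenerate cases are defined, not special-cased: a ray that misses the
grid has row sum 0 and contributes correction 0; a pixel with zero
accumulated subset weight is left unchanged. Both guards are plain
`where=` divisions, so the estimate can never contain NaN or Inf.

## Siddon tracing and the base matrix

`siddon_trace` clips the ray to the grid square, collects the parameter
values of every pixel-boundary crossing, sorts them, and attributes each
interval to the pixel containing its midpoint — cost linear in the
number of crossed pixels (≤ 2n per ray). Ties where a ray passes exactly
through a pixel corner produce zero-length intervals that are dropped,
so corner grazes belong to neither adjacent pixel. The per-ray lengths
sum to the analytic clipped chord to 1e−9 relative (tested), and a
dense-sampling oracle (10⁵ equal steps per ray) reproduces the per-pixel
lengths to better than 2e−4.

The base weighting matrix is built once, at 0° with rays parallel to the
image columns: this makes the base matrix a column-sum operator, the
simplest reference orientation. It is stored as CSR; `row_sums` is
computed by applying the matrix to a constant-1 image so that the
forward projection of a flat image at the base angle equals `row_sums`
bitwise.

## Rotation-based projection

Forward projection at angle θ rotates the image by θ (bilinear, inverse
mapping, zero outside the grid — the object is assumed inside the
inscribed circle) and applies the base matrix. Back projection smears
corrections along the base rays first and then rotates by −θ; the
per-pixel weight sums take the identical rotate(−θ) path so numerator
and denominator stay geometrically consistent. Rotated weight images are
cached per distinct angle (they do not depend on the data or the
estimate). Angles that are exact multiples of 90° are handled by array
quarter-turns, which is the exact limit of bilinear resampling there.

Measured operator quality on the 64×64 head phantom (the acceptance
script recomputes these): forward projection via rotation agrees with
direct Siddon tracing of the tilted rays to 1.7–2.2% relative RMS at
15°/30°/45°, and ⟨Ax, y⟩ vs ⟨x, Aᵀy⟩ agree to better than 1% at random
angles (exactly at θ = 0). Bilinear rotation and its reverse are not
exact adjoints, which bounds the achievable consistency; higher-order
interpolation is out of scope.

## Parallel engine

Within a subset there is no data dependency between angles, so a
coordinator assigns the subset's angles round-robin to P workers
(ascending order; sizes differ by at most one; surplus workers idle).
Workers return per-angle (numerator, weight) contribution images; after
all workers finish, the coordinator reduces the contributions in
ascending angle-index order and applies the single update. Reducing per
angle in a fixed global order — rather than summing per-worker partials —
is what makes the output bit-identical for every P and every completion
order; merging per-worker sums would change the floating-point addition
order with P. Worker granularity is the angle; there is no intra-angle
parallelism. Workers are threads: the heavy kernels (sparse matvec,
`affine_transform`) release the GIL.

## Synthetic data

`make_shepp_logan` rasterizes the standard ten-ellipse head phantom
(modified intensity table, values in [0, 1]) by averaging a 4×4 grid of
point samples per pixel. The area anti-aliasing gives boundary pixels
partial-coverage values, so line integrals of the raster track the
analytic ellipse integrals; pure pixel-center sampling (available as
`subsamples=1`) leaves stair-step edges whose aliasing dominates the
error of any single-line projector — with point sampling the
direct-vs-rotation projector discrepancy at 45° rises from 1.7% to 4%,
an artifact of the raster, not of either operator.

`simulate_sinogram` traces each tilted ray directly through the
unrotated phantom — deliberately a different discretization than the
rotation-based reconstruction operator, so end-to-end convergence tests
measure genuine operator error (no inverse crime). Optional additive
Gaussian noise on the raysums (default off) is seeded and reproducible.

What the simulator does not model: beam polychromaticity, photon
counting statistics, detector blur, scatter, and fan/cone geometries.
Passing tests therefore demonstrate correctness of the algebra and the
operators on ideal parallel-beam line integrals, not robustness to
physical effects in measured data.

## Problem sizes and numerical choices

Tests and the acceptance script run at n = 64 with Q = 180 angles
(T = 20, λ = 0.2, up to 20 iterations) — small enough to execute the
full 400-update history in a couple of seconds while showing the same
monotone convergence as larger grids; structural checks also run at
n = 256 with Q = 360. RMSE against the ground-truth phantom is recorded
after every image update, so both per-update and per-iteration views of
convergence are available from one history.

Tolerances used by the test suite: chord conservation 1e−9 relative;
dense-sampling oracle agreement 1e−3 per pixel; projector consistency
3% relative RMS; adjointness 2% relative on positive random fields (the
relative measure is meaningless for zero-mean fields, whose inner
products cancel toward 0); parallel determinism exact (max abs pixel
difference 0).

## Known limitations

* 2D parallel-beam only; no fan-beam or cone-beam geometry.
* Bilinear rotation caps projector consistency at the few-percent level;
  the reconstruction inherits a smooth low-level bias near sharp edges.
* Absolute attenuation scale is arbitrary; only relative/structural
  fidelity is meaningful.
* No regularization (TV, positivity); noise handling is limited to the
  relaxation factor.
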