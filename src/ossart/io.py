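"""File I/O: float32 TIFF images, 8-bit PNG previews, HDF5 sinograms,
weight matrices and reconstruction results, CSV sinograms for tiny
fixtures.

All numeric round trips (TIFF float32, HDF5) are bit-exact at the stored
precision; PNG is a linearly rescaled 8-bit rendering for visualization
only and is never read back for computation.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .geometry import ImageGrid, ParallelBeamGeometry, Sinogram
from .recon import ReconConfig, ReconResult
from .siddon import RayPath, SparseWeightMatrix

__all__ = [
    "write_image_tiff",
    "read_image_tiff",
    "write_image_png",
    "write_sinogram_h5",
    "read_sinogram_h5",
    "write_sinogram_csv",
    "read_sinogram_csv",
    "write_weights_h5",
    "read_weights_h5",
    "write_result_h5",
    "read_result_h5",
]


def write_image_tiff(path, image: ImageGrid) -> None:
    """Write an image as 32-bit float TIFF; pixel size kept in metadata."""
    tifffile.imwrite(
        str(path),
        image.values.astype(np.float32),
        metadata={"pixel_size": image.pixel_size},
    )


def read_image_tiff(path) -> ImageGrid:
    with tifffile.TiffFile(str(path)) as tf:
        values = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return ImageGrid(
        np.asarray(values, dtype=np.float64),
        pixel_size=float(meta.get("pixel_size", 1.0)),
    )


def write_image_png(path, image: ImageGrid) -> None:
    """8-bit PNG preview, linearly rescaled to the image's value range."""
    v = image.values
    lo, hi = float(v.min()), float(v.max())
    scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    iio.imwrite(str(path), (scaled * 255).round().astype(np.uint8))


def write_sinogram_h5(path, sino: Sinogram) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("raysums", data=sino.raysums)
        f.create_dataset("angles_deg", data=sino.geometry.angles_deg)
        f.attrs["n_detectors"] = sino.geometry.n_detectors
        f.attrs["ray_width"] = sino.geometry.ray_width


def read_sinogram_h5(path) -> Sinogram:
    with h5py.File(str(path), "r") as f:
        geometry = ParallelBeamGeometry(
            angles_deg=f["angles_deg"][...],
            n_detectors=int(f.attrs["n_detectors"]),
            ray_width=float(f.attrs["ray_width"]),
        )
        return Sinogram(raysums=f["raysums"][...], geometry=geometry)


def write_sinogram_csv(path, sino: Sinogram) -> None:
    """Tiny-fixture CSV: one header line of geometry, then the Q x D grid."""
    g = sino.geometry
    header = "ray_width=%r n_detectors=%d angles_deg=%s" % (
        float(g.ray_width), g.n_detectors,
        ",".join(repr(float(a)) for a in g.angles_deg),
    )
    np.savetxt(str(path), sino.raysums, delimiter=",", header=header)


def read_sinogram_csv(path) -> Sinogram:
    with open(path) as f:
        header = f.readline().lstrip("# ").strip()
    fields = dict(kv.split("=", 1) for kv in header.split(" "))
    geometry = ParallelBeamGeometry(
        angles_deg=np.array([float(a) for a in fields["angles_deg"].split(",")]),
        n_detectors=int(fields["n_detectors"]),
        ray_width=float(fields["ray_width"]),
    )
    raysums = np.loadtxt(str(path), delimiter=",", skiprows=1, ndmin=2)
    return Sinogram(raysums=raysums, geometry=geometry)


def write_weights_h5(path, base: SparseWeightMatrix) -> None:
    """Coordinate-list layout: (ray index, pixel index, length) triplets."""
    coo = base.matrix.tocoo()
    with h5py.File(str(path), "w") as f:
        f.create_dataset("ray_index", data=coo.row.astype(np.int64))
        f.create_dataset("pixel_index", data=coo.col.astype(np.int64))
        f.create_dataset("length", data=coo.data)
        f.attrs["n"] = base.n
        f.attrs["n_rays"] = base.n_rays
        f.attrs["pixel_size"] = base.pixel_size


def read_weights_h5(path) -> SparseWeightMatrix:
    with h5py.File(str(path), "r") as f:
        ray = f["ray_index"][...]
        pix = f["pixel_index"][...]
        ln = f["length"][...]
        n = int(f.attrs["n"])
        n_rays = int(f.attrs["n_rays"])
        ps = float(f.attrs["pixel_size"])
    rows = []
    for i in range(n_rays):
        m = ray == i
        rows.append(RayPath(pix[m], ln[m]))
    return SparseWeightMatrix(rows=rows, n=n, pixel_size=ps)


def write_result_h5(path, result: ReconResult) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("image", data=result.image.values)
        f.create_dataset("rmse_history", data=np.asarray(result.rmse_history))
        f.attrs["updates_performed"] = result.updates_performed
        f.attrs["pixel_size"] = result.image.pixel_size
        c = result.config
        f.attrs["lambda_relax"] = c.lambda_relax
        f.attrs["t_subsets"] = c.t_subsets
        f.attrs["iterations"] = c.iterations
        f.attrs["workers"] = c.workers
        f.attrs["seed"] = c.seed


def read_result_h5(path) -> ReconResult:
    with h5py.File(str(path), "r") as f:
        config = ReconConfig(
            lambda_relax=float(f.attrs["lambda_relax"]),
            t_subsets=int(f.attrs["t_subsets"]),
            iterations=int(f.attrs["iterations"]),
            workers=int(f.attrs["workers"]),
            seed=int(f.attrs["seed"]),
        )
        return ReconResult(
            image=ImageGrid(f["image"][...], pixel_size=float(f.attrs["pixel_size"])),
            rmse_history=[float(x) for x in f["rmse_history"][...]],
            updates_performed=int(f.attrs["updates_performed"]),
            config=config,
        )
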