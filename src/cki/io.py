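"""Container I/O: HDF5 raw-data layout and NIfTI map export.

The raw container mirrors the printed tensor layout: dataset ``raw`` with
dimensions (readout, kz, fa, coil, average), the spiral coordinates under
``trajectory/``, and FOV/matrix attributes.  Parameter maps and difference
volumes are written as NIfTI with an affine derived from the field of view.
"""

from __future__ import annotations

import h5py
import nibabel as nib
import numpy as np

from .recon import RawKSpace, SpiralTrajectory

__all__ = ["save_raw", "load_raw", "save_map_nifti", "load_map_nifti"]


def save_raw(path, raw: RawKSpace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=raw.data.astype(np.complex64), compression="gzip")
        f["raw"].attrs["dims"] = "readout,kz,fa,coil,average"
        g = f.create_group("trajectory")
        g.create_dataset("kxy", data=raw.trajectory.kxy)
        g.attrs["dwell"] = raw.trajectory.dwell
        g.attrs["coverage"] = raw.trajectory.coverage
        g.attrs["kmax"] = raw.trajectory.kmax
        f.attrs["fov"] = raw.fov
        f.attrs["matrix"] = raw.matrix
        f.attrs["nz"] = raw.nz


def load_raw(path) -> RawKSpace:
    with h5py.File(path, "r") as f:
        traj = SpiralTrajectory(
            kxy=f["trajectory/kxy"][:],
            dwell=float(f["trajectory"].attrs["dwell"]),
            coverage=float(f["trajectory"].attrs["coverage"]),
            kmax=float(f["trajectory"].attrs["kmax"]),
        )
        return RawKSpace(
            data=f["raw"][:],
            trajectory=traj,
            fov=tuple(f.attrs["fov"]),
            matrix=int(f.attrs["matrix"]),
            nz=int(f.attrs["nz"]),
        )


def _affine(shape, fov) -> np.ndarray:
    """Voxel-to-mm affine centred on the volume."""
    scales = [fov[i] * 1000.0 / shape[i] for i in range(3)]
    aff = np.diag(scales + [1.0])
    aff[:3, 3] = [-scales[i] * shape[i] / 2.0 for i in range(3)]
    return aff


def save_map_nifti(path, volume: np.ndarray, fov=(0.23, 0.23, 0.22)) -> None:
    vol = np.asarray(volume)
    img = nib.Nifti1Image(vol.astype(np.float32), _affine(vol.shape[:3], fov))
    nib.save(img, str(path))


def load_map_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)
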