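"""HDF5 containers for raw data and sampling plans; NIfTI image output.

The raw container stores ``kspace`` as a complex array
[heartbeat, readout_in_hb, coil, kx] (zero-padded to the longest
heartbeat, with per-heartbeat readout counts in ``n_readouts``),
``traj`` as [heartbeat, readout_in_hb, 2] 0-based (ky, kz) indices on
the acquired low-resolution grid, and ``inav`` as
[heartbeat, ny, nx] navigator frames, plus grid geometry attributes.
"""

from __future__ import annotations

import h5py
import numpy as np

from .phantom import RawKSpace

__all__ = ["save_raw", "load_raw", "save_plan", "load_plan_arrays",
           "save_motion_fields", "load_motion_fields", "save_nifti", "load_nifti"]


def save_motion_fields(path, fields) -> None:
    """Motion fields as an HDF5 [bin, 3, x, y, z] dataset in voxel units."""
    with h5py.File(path, "w") as f:
        f.create_dataset("fields", data=fields.fields)
        f.attrs["reference"] = fields.reference
        f.attrs["units"] = "voxels"


def load_motion_fields(path):
    from .motion import MotionFieldSet

    with h5py.File(path, "r") as f:
        return MotionFieldSet(f["fields"][()], reference=int(f.attrs["reference"]))


def save_raw(path, raw: RawKSpace) -> None:
    n_hb = raw.n_heartbeats
    rmax = max(len(t) for t in raw.traj_lines)
    nc, nx = raw.kspace[0].shape[1:]
    k = np.zeros((n_hb, rmax, nc, nx), dtype=np.complex128)
    t = np.zeros((n_hb, rmax, 2), dtype=np.int64)
    nr = np.zeros(n_hb, dtype=np.int64)
    for h in range(n_hb):
        r = len(raw.traj_lines[h])
        nr[h] = r
        k[h, :r] = raw.kspace[h]
        t[h, :r] = raw.traj_lines[h]
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=k)
        f.create_dataset("traj", data=t)
        f.create_dataset("n_readouts", data=nr)
        f.create_dataset("inav", data=raw.inav)
        f.attrs["grid_shape"] = raw.grid_shape
        f.attrs["voxel_size_mm"] = raw.voxel_size_mm
        f.attrs["lr_grid_yz"] = raw.lr_grid_yz
        f.attrs["reference_convention"] = "end-expiration (smallest mean foot-head shift)"


def load_raw(path) -> RawKSpace:
    with h5py.File(path, "r") as f:
        k = f["kspace"][()]
        t = f["traj"][()]
        nr = f["n_readouts"][()]
        inav = f["inav"][()]
        grid = tuple(int(v) for v in f.attrs["grid_shape"])
        vox = tuple(float(v) for v in f.attrs["voxel_size_mm"])
        lr = tuple(int(v) for v in f.attrs["lr_grid_yz"])
    kspace = [k[h, : nr[h]] for h in range(len(nr))]
    traj = [t[h, : nr[h]] for h in range(len(nr))]
    return RawKSpace(kspace=kspace, traj_lines=traj, inav=inav, grid_shape=grid,
                     voxel_size_mm=vox, lr_grid_yz=lr)


def save_plan(path, plan) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_bins"] = plan.n_bins
        f.attrs["grid_yz"] = plan.grid_yz
        f.attrs["lr_grid_yz"] = plan.lr_grid_yz
        f.attrs["reference_bin"] = plan.reference_bin
        if plan.hard_assignment is not None:
            f.create_dataset("hard_assignment", data=plan.hard_assignment)
        for i, acq in enumerate(plan.bins):
            g = f.create_group(f"bins/{i}")
            g.create_dataset("readouts", data=acq.readouts)
            g.create_dataset("weights", data=acq.weights)


def load_plan_arrays(path):
    """Load per-bin readouts/weights and geometry (sources are not stored)."""
    with h5py.File(path, "r") as f:
        meta = dict(
            n_bins=int(f.attrs["n_bins"]),
            grid_yz=tuple(int(v) for v in f.attrs["grid_yz"]),
            lr_grid_yz=tuple(int(v) for v in f.attrs["lr_grid_yz"]),
            reference_bin=int(f.attrs["reference_bin"]),
        )
        bins = []
        for i in range(meta["n_bins"]):
            bins.append((f[f"bins/{i}/readouts"][()], f[f"bins/{i}/weights"][()]))
    return meta, bins


def save_nifti(path, volume: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0),
               phase_path=None) -> None:
    """Write magnitude (and optionally phase) of a complex volume."""
    import nibabel as nib

    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.abs(volume).astype(np.float32), affine), str(path))
    if phase_path is not None:
        nib.save(nib.Nifti1Image(np.angle(volume).astype(np.float32), affine), str(phase_path))


def load_nifti(path) -> np.ndarray:
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj)
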