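"""Serialization: HDF5 meshes/trajectories, CSV probes, legacy-VTK snapshots."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .geometry import LabeledMesh


def save_mesh(path: str, mesh: LabeledMesh) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=mesh.labels, compression="gzip")
        f.attrs["voxel_size_um"] = mesh.voxel_size
        f.attrs["n_cells"] = mesh.n_cells
        f.attrs["boundary_conditions"] = json.dumps(mesh.boundary_conditions)


def load_mesh(path: str) -> LabeledMesh:
    with h5py.File(path, "r") as f:
        return LabeledMesh(
            labels=f["labels"][...],
            voxel_size=float(f.attrs["voxel_size_um"]),
            n_cells=tuple(int(n) for n in f.attrs["n_cells"]),
            boundary_conditions=json.loads(f.attrs["boundary_conditions"]))


def save_trajectory(path: str, traj) -> None:
    """Store probe series and snapshots of an EMI or bidomain trajectory."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("probe_x_um", data=traj.probe_x_um)
        v = traj.v_probe if hasattr(traj, "v_probe") else traj.V_probe
        f.create_dataset("probe_potential", data=v)
        snaps = f.create_group("snapshots")
        for t, fields in traj.snapshots.items():
            g = snaps.create_group(f"t_{t:g}")
            g.attrs["time_ms"] = t
            for name, arr in fields.items():
                g.create_dataset(name, data=np.asarray(arr))


def probes_to_csv(path: str, traj) -> None:
    v = traj.v_probe if hasattr(traj, "v_probe") else traj.V_probe
    cols = {f"v_at_{x:g}um": v[:, i]
            for i, x in enumerate(traj.probe_x_um)}
    pd.DataFrame({"time_ms": traj.times, **cols}).to_csv(path, index=False)


def write_vtk_image(path: str, array: np.ndarray, spacing_um: float,
                    name: str = "field") -> None:
    """Legacy-ASCII VTK structured-points file of a 2D/3D scalar field."""
    arr = np.asarray(array)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    nx, ny, nz = arr.shape
    s = spacing_um
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n"
                f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n"
                f"DIMENSIONS {nx} {ny} {nz}\n"
                f"ORIGIN 0 0 0\nSPACING {s} {s} {s}\n"
                f"POINT_DATA {arr.size}\n"
                f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        flat = arr.transpose(2, 1, 0).ravel()  # VTK expects x fastest
        np.savetxt(f, flat.reshape(-1, 1), fmt="%.6g")
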