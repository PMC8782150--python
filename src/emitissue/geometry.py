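"""Voxelized cardiomyocyte collections and their geometric measures.

Tissue is discretized on a regular voxel grid.  Every voxel is either
extracellular or belongs to exactly one cell; the faces between voxels of
different kinds carry the physics:

* membrane faces (``Gamma``): cell voxel next to an extracellular voxel,
* intercalated-disc faces (``Gamma_g``, per axis): voxels of two different
  cells touching,
* outer-boundary faces: extracellular voxels on the domain boundary, tagged
  Dirichlet or Neumann per axis.

Cells are laid out on a regular lattice and abut directly along each axis, so
the disc plane coincides with the shared lattice plane.  The default cell is
a tapered cylinder along x (radius ``radius_end`` at both ends increasing
linearly to ``radius_center`` at mid-length); a box-shaped cell family with
square cross-section is provided for hand-checkable fixtures.

All user-facing lengths are micrometres; :class:`MeshMetrics` reports the
integrated measures in cm/cm^2/cm^3, the unit system used by the solvers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: centimetres per micrometre; the solvers work in cm internally.
CM_PER_UM = 1e-4

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class EMIParameters:
    """Physical parameters of the cell-based model.

    Defaults are the standard values for cardiac tissue: intracellular and
    extracellular conductivities ``sigma_i``/``sigma_e`` (mS/cm), specific
    membrane capacitance ``C_m`` (uF/cm^2), specific intercalated-disc
    capacitance ``C_g`` (uF/cm^2) and specific gap-junction resistance
    ``R_g`` (kOhm cm^2).
    """

    sigma_i: float = 4.0
    sigma_e: float = 20.0
    C_m: float = 1.0
    C_g: float = 0.5
    R_g: float = 0.0015

    def __post_init__(self) -> None:
        for name in ("sigma_i", "sigma_e", "C_m", "C_g", "R_g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def with_rg_factor(self, factor: float) -> "EMIParameters":
        """Return a copy with ``R_g`` multiplied by ``factor``."""
        return EMIParameters(self.sigma_i, self.sigma_e, self.C_m,
                             self.C_g, self.R_g * factor)


_DEFAULT_BC = {"x": "dirichlet", "y": "neumann", "z": "neumann"}


@dataclass(frozen=True)
class CellCollectionSpec:
    """Specification of a lattice of tapered-cylinder cells.

    ``n_cells`` gives the cell count per axis.  Cells are ``cell_length`` um
    long along x with radius tapering linearly from ``radius_end`` at both
    ends to ``radius_center`` at mid-length.  The lattice pitch transverse to
    the cell axis is ``2*radius_center`` so that neighbouring cells in y/z
    touch at their widest cross-section.  ``padding`` um of extracellular
    space surrounds the collection on all sides. ``boundary_conditions`` maps
    each axis to the outer extracellular boundary condition on both of its
    sides ("dirichlet" grounds u_e, "neumann" seals it).
    """

    n_cells: tuple[int, int, int] = (1, 1, 1)
    cell_length: float = 120.0
    radius_end: float = 6.0
    radius_center: float = 7.0
    padding: float = 2.0
    voxel_size: float = 2.0
    boundary_conditions: dict = field(default_factory=lambda: dict(_DEFAULT_BC))

    def __post_init__(self) -> None:
        if len(self.n_cells) != 3 or any(n < 1 for n in self.n_cells):
            raise ValueError("n_cells must be three counts >= 1")
        if not (self.radius_center >= self.radius_end > 0):
            raise ValueError("require radius_center >= radius_end > 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.voxel_size > self.radius_end:
            raise ValueError("voxel_size larger than radius_end: cell would vanish")
        for ax, tag in self.boundary_conditions.items():
            if ax not in _AXES or tag not in ("dirichlet", "neumann"):
                raise ValueError(f"bad boundary condition {ax}={tag}")


def _int_voxels(length: float, voxel: float, what: str) -> int:
    n = length / voxel
    ni = int(round(n))
    if abs(n - ni) > 1e-9:
        warnings.warn(f"{what} ({length} um) is not an integer number of "
                      f"voxels ({voxel} um); rounding to {ni} voxels")
    return max(ni, 1)


@dataclass
class LabeledMesh:
    """Voxel mesh with region labels and classified face sets.

    ``labels`` has shape (nx, ny, nz); -1 marks extracellular, values >= 0
    are the owning cell index.  Face arrays hold flat voxel indices into the
    C-ordered label array: membrane faces as (intracellular voxel ``mem_p``,
    extracellular voxel ``mem_q``), disc faces as (``disc_p``, ``disc_q``)
    with p on the lower-coordinate side, so the disc jump w = u[p] - u[q].
    ``dirichlet_vox`` lists the extracellular voxels with a grounded outer
    face (with multiplicity, one entry per face).
    """

    labels: np.ndarray
    voxel_size: float  # um
    n_cells: tuple[int, int, int]
    boundary_conditions: dict

    # face sets, filled by _classify_faces
    mem_p: np.ndarray = None
    mem_q: np.ndarray = None
    mem_axis: np.ndarray = None
    mem_centers: np.ndarray = None  # (n_faces, 3) um
    disc_p: np.ndarray = None
    disc_q: np.ndarray = None
    disc_axis: np.ndarray = None
    dirichlet_vox: np.ndarray = None
    neumann_face_count: int = 0

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int32)
        if self.mem_p is None:
            self._classify_faces()

    # -- derived quantities ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extents_um(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size for n in self.labels.shape)

    def voxel_centers_um(self, axis: int) -> np.ndarray:
        return (np.arange(self.labels.shape[axis]) + 0.5) * self.voxel_size

    def disc_faces(self, axis: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.disc_axis == axis
        return self.disc_p[m], self.disc_q[m]

    def _classify_faces(self) -> None:
        lab = self.labels
        flat = np.arange(lab.size).reshape(lab.shape)
        vox = self.voxel_size
        mp, mq, max_, mc = [], [], [], []
        dp, dq, dax = [], [], []
        for ax in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(None, -1)
            hi[ax] = slice(1, None)
            a, b = lab[tuple(lo)], lab[tuple(hi)]
            ia, ib = flat[tuple(lo)], flat[tuple(hi)]
            mem_ab = (a >= 0) & (b < 0)   # intra on low side
            mem_ba = (a < 0) & (b >= 0)   # intra on high side
            disc = (a >= 0) & (b >= 0) & (a != b)
            for mask, pi, qi in ((mem_ab, ia, ib), (mem_ba, ib, ia)):
                idx = np.nonzero(mask)
                mp.append(pi[idx])
                mq.append(qi[idx])
                max_.append(np.full(idx[0].size, ax, dtype=np.int8))
                centers = np.empty((idx[0].size, 3))
                for d in range(3):
                    centers[:, d] = (idx[d] + 0.5) * vox
                centers[:, ax] = (idx[ax] + 1.0) * vox  # face plane
                mc.append(centers)
            idx = np.nonzero(disc)
            dp.append(ia[idx])
            dq.append(ib[idx])
            dax.append(np.full(idx[0].size, ax, dtype=np.int8))
        self.mem_p = np.concatenate(mp)
        self.mem_q = np.concatenate(mq)
        self.mem_axis = np.concatenate(max_)
        self.mem_centers = np.concatenate(mc)
        self.disc_p = np.concatenate(dp)
        self.disc_q = np.concatenate(dq)
        self.disc_axis = np.concatenate(dax)

        # outer boundary: must be purely extracellular (padding >= 1 voxel)
        dvox = []
        self.neumann_face_count = 0
        for ax in range(3):
            for side in (0, -1):
                sl = [slice(None)] * 3
                sl[ax] = side
                face_lab = lab[tuple(sl)]
                if (face_lab >= 0).any():
                    raise ValueError("intracellular voxel touches the outer "
                                     "boundary; increase padding")
                ids = flat[tuple(sl)].ravel()
                if self.boundary_conditions[_AXES[ax]] == "dirichlet":
                    dvox.append(ids)
                else:
                    self.neumann_face_count += ids.size
        self.dirichlet_vox = (np.concatenate(dvox) if dvox
                              else np.empty(0, dtype=np.int64))


@dataclass(frozen=True)
class MeshMetrics:
    """Integrated geometric measures of a :class:`LabeledMesh` (cm units).

    Volumes are voxel counts times voxel volume, areas face counts times
    face area.  ``A_j_*`` are the total intercalated-disc areas per axis;
    ``L_*`` the domain extents; ``N_*`` the cell counts.
    """

    V_Omega: float
    V_Omega_i: float
    V_Omega_e: float
    A_Gamma: float
    A_j_x: float
    A_j_y: float
    A_j_z: float
    L_x: float
    L_y: float
    L_z: float
    N_x: int
    N_y: int
    N_z: int

    def A_j(self, axis: int) -> float:
        return (self.A_j_x, self.A_j_y, self.A_j_z)[axis]

    def L(self, axis: int) -> float:
        return (self.L_x, self.L_y, self.L_z)[axis]

    def N(self, axis: int) -> int:
        return (self.N_x, self.N_y, self.N_z)[axis]


def build_cell_collection(spec: CellCollectionSpec) -> LabeledMesh:
    """Voxelize a lattice of tapered-cylinder cells with extracellular padding.

    A voxel is intracellular iff its center lies inside the radius profile of
    the cell owning its lattice slot (linear taper from ``radius_end`` at the
    cell ends to ``radius_center`` at mid-length, revolved about the cell
    axis).  Neighbouring cells abut: along x at the shared end plane, along
    y/z at the tangent plane of the widest cross-section.
    """
    vox = spec.voxel_size
    nx_c, ny_c, nz_c = spec.n_cells
    pitch = 2.0 * spec.radius_center
    pad_vox = max(1, _int_voxels(spec.padding, vox, "padding"))
    len_vox = _int_voxels(spec.cell_length, vox, "cell_length")
    pitch_vox = _int_voxels(pitch, vox, "transverse cell pitch")
    cell_len = len_vox * vox
    cell_pitch = pitch_vox * vox
    pad = pad_vox * vox

    shape = (2 * pad_vox + nx_c * len_vox,
             2 * pad_vox + ny_c * pitch_vox,
             2 * pad_vox + nz_c * pitch_vox)
    xc = (np.arange(shape[0]) + 0.5) * vox
    yc = (np.arange(shape[1]) + 0.5) * vox
    zc = (np.arange(shape[2]) + 0.5) * vox

    def slot(centers, pad_, size, count):
        k = np.floor((centers - pad_) / size).astype(int)
        inside = (centers > pad_) & (centers < pad_ + count * size)
        return np.where(inside, np.clip(k, 0, count - 1), -1)

    kx = slot(xc, pad, cell_len, nx_c)
    ky = slot(yc, pad, cell_pitch, ny_c)
    kz = slot(zc, pad, cell_pitch, nz_c)

    # radius profile along x (per x-voxel, for its owning slot)
    xi = xc - pad - (kx + 0.5) * cell_len  # signed offset from cell midpoint
    r = spec.radius_center - ((spec.radius_center - spec.radius_end)
                              * np.abs(xi) / (cell_len / 2.0))
    dy = yc - (pad + (ky + 0.5) * cell_pitch)
    dz = zc - (pad + (kz + 0.5) * cell_pitch)
    r2 = (dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
    inside = ((kx >= 0)[:, None, None]
              & (ky >= 0)[None, :, None]
              & (kz >= 0)[None, None, :]
              & (r2 <= (r ** 2)[:, None, None]))
    cell_id = ((kx[:, None, None] * ny_c + ky[None, :, None]) * nz_c
               + kz[None, None, :])
    labels = np.where(inside, cell_id, -1).astype(np.int32)
    return LabeledMesh(labels, vox, spec.n_cells,
                       dict(spec.boundary_conditions))


def build_box_collection(n_cells: tuple[int, int, int],
                         cell_size: tuple[float, float, float] = (100.0, 10.0, 10.0),
                         padding: float = 2.0,
                         voxel_size: float = 1.0,
                         boundary_conditions: dict | None = None) -> LabeledMesh:
    """Voxelize abutting box-shaped cells (exactly hand-checkable fixture).

    Each cell completely fills its ``cell_size`` lattice slot, so volumes,
    membrane areas and disc areas are exact integer voxel counts.
    """
    bc = dict(boundary_conditions or _DEFAULT_BC)
    if any(n < 1 for n in n_cells):
        raise ValueError("n_cells must be >= 1 per axis")
    pad_vox = max(1, _int_voxels(padding, voxel_size, "padding"))
    size_vox = [_int_voxels(s, voxel_size, f"cell_size[{d}]")
                for d, s in enumerate(cell_size)]
    shape = tuple(2 * pad_vox + n_cells[d] * size_vox[d] for d in range(3))
    labels = np.full(shape, -1, dtype=np.int32)
    ks = []
    for d in range(3):
        idx = np.arange(shape[d])
        k = (idx - pad_vox) // size_vox[d]
        k = np.where((idx >= pad_vox) & (idx < pad_vox + n_cells[d] * size_vox[d]),
                     k, -1)
        ks.append(k)
    kx, ky, kz = ks
    inside = (kx >= 0)[:, None, None] & (ky >= 0)[None, :, None] & (kz >= 0)[None, None, :]
    cell_id = ((kx[:, None, None] * n_cells[1] + ky[None, :, None]) * n_cells[2]
               + kz[None, None, :])
    labels[inside] = cell_id[inside]
    return LabeledMesh(labels, voxel_size, tuple(n_cells), bc)


def compute_metrics(mesh: LabeledMesh) -> MeshMetrics:
    """Integrate volumes, membrane area and per-axis disc areas (cm units)."""
    vox_cm = mesh.voxel_size * CM_PER_UM
    n_total = mesh.labels.size
    n_intra = int((mesh.labels >= 0).sum())
    face_area = vox_cm ** 2
    vol = vox_cm ** 3
    a_j = [float((mesh.disc_axis == ax).sum()) * face_area for ax in range(3)]
    v_i = n_intra * vol
    v_e = (n_total - n_intra) * vol
    return MeshMetrics(
        V_Omega=v_i + v_e,  # exact partition by construction
        V_Omega_i=v_i,
        V_Omega_e=v_e,
        A_Gamma=float(mesh.mem_p.size) * face_area,
        A_j_x=a_j[0], A_j_y=a_j[1], A_j_z=a_j[2],
        L_x=mesh.shape[0] * vox_cm,
        L_y=mesh.shape[1] * vox_cm,
        L_z=mesh.shape[2] * vox_cm,
        N_x=mesh.n_cells[0], N_y=mesh.n_cells[1], N_z=mesh.n_cells[2],
    )
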