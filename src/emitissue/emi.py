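"""Cell-based (EMI) tissue solver on a voxel mesh.

The model couples Laplace problems for the intracellular potential u_i (per
cell) and the extracellular potential u_e through dynamic interface
conditions: at membrane faces the normal current equals the capacitive plus
ionic membrane current (potential jump v = u_i - u_e), and at intercalated
discs it equals the disc-capacitive plus gap-junction current (jump
w = u_i,1 - u_i,2).

Discretization: cell-centered finite volumes with two-point flux on the
voxel grid.  Membrane and disc faces are internal faces with a double-valued
potential; the flux closure uses the voxel-center jump.  Time integration is
first-order operator splitting:

1. explicit step — forward Euler for the gating variables, the ionic current
   (and stimulus) acting on v, and the gap-junction current acting on w;
2. elliptic step — one linear solve for all voxel potentials with the
   capacitive closure treated implicitly:

       flux(i->e) = C_m * A_f * ((u_i - u_e) - v*) / dt     at membrane faces
       flux(1->2) = C_g * A_f * ((u_1 - u_2) - w*) / dt     at disc faces

   after which v and w are reset to the new potential jumps.

The system matrix is symmetric positive definite (given at least one
Dirichlet-grounded outer face) and constant in time, so it is factorized
once per run: banded Cholesky in natural voxel order when the bandwidth is
small (strand-like meshes), sparse LU otherwise.

Units: mV, ms, uA/cm^2, mS/cm, uF/cm^2, kOhm cm^2; lengths in cm internally.
This set is closed: uF/cm^2 * mV/ms = uA/cm^2 and mS * mV = uA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import cholesky_banded, cho_solve_banded

from .geometry import CM_PER_UM, EMIParameters, LabeledMesh
from .membrane import MembraneModel, StimulusProtocol, gap_junction_current

_MAX_CHOL_BANDWIDTH = 800


@dataclass
class EMIState:
    """Solver state: full potential vector plus interface variables.

    ``u`` holds one potential per voxel (u_i on intracellular voxels, u_e on
    extracellular ones).  ``v``/``w`` are the membrane and disc jumps;
    ``gates`` the gating state per membrane face.  After an elliptic step,
    v = u[mem_p] - u[mem_q] and w = u[disc_p] - u[disc_q] by construction.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    gates: np.ndarray
    time: float = 0.0
    #: reference (resting) potential subtracted before the linear solve, so
    #: that a resting tissue yields an exactly zero right-hand side and the
    #: solver introduces no roundoff drift at rest
    v_ref: float = 0.0


class EMISystem:
    """Assembled, factorized linear operator for one (mesh, params, dt)."""

    def __init__(self, mesh: LabeledMesh, params: EMIParameters, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        if mesh.dirichlet_vox.size == 0:
            raise ValueError(
                "all outer boundaries are Neumann: the extracellular system "
                "is singular; tag at least one axis 'dirichlet'")
        self.mesh = mesh
        self.params = params
        self.dt = dt
        self.n = mesh.labels.size
        vox_cm = mesh.voxel_size * CM_PER_UM
        area = vox_cm ** 2
        self.c_m = params.C_m * area / dt      # mS per membrane face
        self.c_g = params.C_g * area / dt      # mS per disc face
        self.g_b = 2.0 * params.sigma_e * vox_cm  # mS per Dirichlet face
        self.face_area_cm2 = area

        p_list, q_list, g_list = [], [], []
        lab = mesh.labels
        flat = np.arange(self.n).reshape(lab.shape)
        for ax in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(None, -1)
            hi[ax] = slice(1, None)
            a, b = lab[tuple(lo)], lab[tuple(hi)]
            ia, ib = flat[tuple(lo)], flat[tuple(hi)]
            cond = ((a < 0) & (b < 0)) | ((a >= 0) & (a == b))
            sig = np.where(a[cond] < 0, params.sigma_e, params.sigma_i)
            p_list.append(ia[cond])
            q_list.append(ib[cond])
            g_list.append(sig * vox_cm)
        p = np.concatenate(p_list + [mesh.mem_p, mesh.disc_p])
        q = np.concatenate(q_list + [mesh.mem_q, mesh.disc_q])
        g = np.concatenate(g_list
                           + [np.full(mesh.mem_p.size, self.c_m),
                              np.full(mesh.disc_p.size, self.c_g)])

        diag = np.zeros(self.n)
        np.add.at(diag, p, g)
        np.add.at(diag, q, g)
        np.add.at(diag, mesh.dirichlet_vox, self.g_b)
        A = sp.coo_matrix(
            (np.concatenate([g * -1.0, g * -1.0, diag]),
             (np.concatenate([p, q, np.arange(self.n)]),
              np.concatenate([q, p, np.arange(self.n)]))),
            shape=(self.n, self.n)).tocsc()
        self.matrix = A
        self._factorize(A)

        self.intra_mask = (lab >= 0).ravel()
        self.extra_mask = ~self.intra_mask

    def _factorize(self, A: sp.csc_matrix) -> None:
        Au = sp.triu(A).tocoo()
        bw = int(np.max(Au.col - Au.row))
        if bw <= _MAX_CHOL_BANDWIDTH:
            ab = np.zeros((bw + 1, self.n))
            ab[bw + Au.row - Au.col, Au.col] = Au.data
            self._chol = cholesky_banded(ab, lower=False)
            self._lu = None
        else:
            self._chol = None
            self._lu = spla.splu(A)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        if self._chol is not None:
            return cho_solve_banded((self._chol, False), rhs)
        return self._lu.solve(rhs)


def assemble_system(mesh: LabeledMesh, params: EMIParameters,
                    dt: float) -> EMISystem:
    """Build and factorize the coupled finite-volume operator."""
    return EMISystem(mesh, params, dt)


def initial_state(system: EMISystem, model: MembraneModel) -> EMIState:
    """Resting state: u_e = 0, u_i = v = resting potential, w = 0."""
    v0 = model.resting_potential
    u = np.where(system.intra_mask, v0, 0.0)
    v = np.full(system.mesh.mem_p.size, v0)
    w = np.zeros(system.mesh.disc_p.size)
    gates = model.initial_gates(v.size)
    return EMIState(u=u, v=v, w=w, gates=gates, time=0.0, v_ref=v0)


def explicit_membrane_step(state: EMIState, model: MembraneModel,
                           stim: StimulusProtocol | None,
                           params: EMIParameters, dt: float,
                           stim_mask: np.ndarray | None = None) -> EMIState:
    """Forward-Euler update of gating, v (ionic + stimulus) and w (gap).

    ``stim_mask`` is the precomputed membrane-face mask of the stimulus
    region (computed from the protocol if omitted); the stimulus enters the
    membrane current balance additively.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(state.v).all() and np.isfinite(state.w).all()):
        raise FloatingPointError(
            f"non-finite membrane state at t={state.time} ms")
    i_ion = model.I_ion(state.v, state.gates, state.time)
    if stim is not None and stim.active(state.time):
        if stim_mask is None:
            raise ValueError("an active stimulus needs its membrane-face "
                             "mask (stim.region_mask(mesh.mem_centers))")
        i_ion = i_ion + np.where(stim_mask, stim.amplitude, 0.0)
    v_new = state.v - (dt / params.C_m) * i_ion
    gates_new = state.gates + dt * model.gating_rhs(state.v, state.gates)
    w_new = state.w - (dt / params.C_g) * gap_junction_current(
        state.w, params.R_g)
    return EMIState(u=state.u, v=v_new, w=w_new, gates=gates_new,
                    time=state.time + dt, v_ref=state.v_ref)


def elliptic_step(state: EMIState, system: EMISystem) -> EMIState:
    """Solve for all voxel potentials; reset v, w to the new jumps.

    The solve is performed for the deviation from the resting profile
    (u_i = v_ref, u_e = 0, v = v_ref, w = 0), which satisfies the system
    exactly; at rest the right-hand side is identically zero.
    """
    mesh = system.mesh
    rhs = np.zeros(system.n)
    dv = state.v - state.v_ref
    np.add.at(rhs, mesh.mem_p, system.c_m * dv)
    np.add.at(rhs, mesh.mem_q, -system.c_m * dv)
    np.add.at(rhs, mesh.disc_p, system.c_g * state.w)
    np.add.at(rhs, mesh.disc_q, -system.c_g * state.w)
    delta = system.solve(rhs)
    if not np.isfinite(delta).all():
        raise FloatingPointError(f"linear solve produced non-finite "
                                 f"potentials at t={state.time} ms")
    u = delta + np.where(system.intra_mask, state.v_ref, 0.0)
    v_new = delta[mesh.mem_p] - delta[mesh.mem_q] + state.v_ref
    w_new = delta[mesh.disc_p] - delta[mesh.disc_q]
    return EMIState(u=u, v=v_new, w=w_new, gates=state.gates,
                    time=state.time, v_ref=state.v_ref)


def current_balance(system: EMISystem, pre: EMIState,
                    post: EMIState) -> dict:
    """Global current bookkeeping for one elliptic step.

    Returns the summed membrane current (implicit capacitive closure,
    positive = out of the intracellular space), the summed current through
    the Dirichlet outer boundary, and a magnitude scale.  Both sums vanish
    for the conservative discretization: the intracellular space has no
    outer boundary, and the extracellular space only exchanges current with
    the membrane and the grounded boundary.
    """
    mem_flux = system.c_m * (post.v - pre.v)
    bnd_flux = system.g_b * post.u[system.mesh.dirichlet_vox]
    scale = np.abs(mem_flux).sum() + np.abs(bnd_flux).sum()
    return {"membrane_total": mem_flux.sum(),
            "boundary_total": bnd_flux.sum(),
            "scale": max(scale, 1e-30)}


@dataclass
class EMITrajectory:
    """Recorded probe series and snapshots from :func:`run_emi`."""

    times: np.ndarray                  # (n_rec,)
    probe_x_um: np.ndarray             # (n_probes,)
    v_probe: np.ndarray                # (n_rec, n_probes) membrane potential
    snapshots: dict                    # t -> {"u","centerline_x_um","u_i_centerline"}
    mesh: LabeledMesh = None


def centerline(mesh: LabeledMesh, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Intracellular potential along the voxel row nearest the domain axis.

    Returns (x centers in um, u_i) restricted to intracellular voxels.
    """
    ny, nz = mesh.shape[1], mesh.shape[2]
    j0, k0 = ny // 2, nz // 2
    lab_row = mesh.labels[:, j0, k0]
    if not (lab_row >= 0).any():  # row between cells; shift to nearest cell row
        for dj in range(1, ny):
            if (mesh.labels[:, j0 - dj, k0] >= 0).any():
                j0 -= dj
                break
        lab_row = mesh.labels[:, j0, k0]
    sel = lab_row >= 0
    x = mesh.voxel_centers_um(0)[sel]
    flat = np.arange(mesh.labels.size).reshape(mesh.shape)
    return x, u[flat[:, j0, k0][sel]]


def _probe_faces(mesh: LabeledMesh, probe_x_um) -> np.ndarray:
    """Membrane face nearest each requested x at mid cross-section."""
    c = mesh.mem_centers
    mid = np.array(mesh.extents_um)[1:] / 2.0
    idx = []
    for x in probe_x_um:
        d = ((c[:, 0] - x) ** 2 + (c[:, 1] - mid[0]) ** 2
             + (c[:, 2] - mid[1]) ** 2)
        idx.append(int(np.argmin(d)))
    return np.asarray(idx, dtype=int)


def run_emi(mesh: LabeledMesh, params: EMIParameters, model: MembraneModel,
            stim: StimulusProtocol | None, T: float, dt: float,
            probe_x_um=(), snapshot_times=(), system: EMISystem | None = None,
            stop_probe: tuple[int, float] | None = None,
            record_stride: int = 1) -> EMITrajectory:
    """Advance the EMI model from rest to time ``T`` by operator splitting.

    ``probe_x_um`` selects membrane faces (nearest to each x at the domain
    axis) whose potential v is recorded every ``record_stride`` steps.
    ``snapshot_times`` requests full-field snapshots (snapped to the nearest
    step).  ``stop_probe=(probe_index, threshold)`` ends the run early once
    that probe exceeds the threshold — used by conduction-velocity sweeps
    where only the crossing times matter.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if system is None:
        system = assemble_system(mesh, params, dt)
    state = initial_state(system, model)
    faces = _probe_faces(mesh, probe_x_um)
    stim_mask = (stim.region_mask(mesh.mem_centers)
                 if stim is not None else None)
    n_steps = int(round(T / dt))
    snap_steps = {int(round(t / dt)): t for t in snapshot_times}
    times = [0.0]
    v_probe = [state.v[faces].copy()]
    snapshots = {}

    def snap(step_state, t_label):
        x, ui = centerline(mesh, step_state.u)
        snapshots[t_label] = {
            "u": step_state.u.copy(),
            "v": step_state.v.copy(),
            "centerline_x_um": x,
            "u_i_centerline": ui,
        }

    if 0 in snap_steps:
        snap(state, snap_steps[0])
    for step in range(1, n_steps + 1):
        state = explicit_membrane_step(state, model, stim, params, dt,
                                       stim_mask)
        state = elliptic_step(state, system)
        if step % record_stride == 0 or step == n_steps:
            times.append(state.time)
            v_probe.append(state.v[faces].copy())
        if step in snap_steps:
            snap(state, snap_steps[step])
        if (stop_probe is not None
                and state.v[faces[stop_probe[0]]] > stop_probe[1]):
            break
    return EMITrajectory(times=np.asarray(times),
                         probe_x_um=np.asarray(list(probe_x_um), dtype=float),
                         v_probe=np.asarray(v_probe),
                         snapshots=snapshots, mesh=mesh)


def passive_steady_state(mesh: LabeledMesh, params: EMIParameters,
                         membrane, stim: StimulusProtocol | None) -> np.ndarray:
    """Stationary potentials for a passive membrane under sustained stimulus.

    Replaces the capacitive interface closure by its steady limit
    (membrane flux = ((u_i-u_e)-v0)/R_m + I_stim, disc flux = w/R_g) and
    solves the single linear system.  Used as a fast reference for
    steady-state checks.
    """
    vox_cm = mesh.voxel_size * CM_PER_UM
    area = vox_cm ** 2
    n = mesh.labels.size
    lab = mesh.labels
    flat = np.arange(n).reshape(lab.shape)
    p_list, q_list, g_list = [], [], []
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        a, b = lab[tuple(lo)], lab[tuple(hi)]
        ia, ib = flat[tuple(lo)], flat[tuple(hi)]
        cond = ((a < 0) & (b < 0)) | ((a >= 0) & (a == b))
        sig = np.where(a[cond] < 0, params.sigma_e, params.sigma_i)
        p_list.append(ia[cond])
        q_list.append(ib[cond])
        g_list.append(sig * vox_cm)
    g_m = area / membrane.R_m
    g_g = area / params.R_g
    p = np.concatenate(p_list + [mesh.mem_p, mesh.disc_p])
    q = np.concatenate(q_list + [mesh.mem_q, mesh.disc_q])
    g = np.concatenate(g_list + [np.full(mesh.mem_p.size, g_m),
                                 np.full(mesh.disc_p.size, g_g)])
    diag = np.zeros(n)
    np.add.at(diag, p, g)
    np.add.at(diag, q, g)
    g_b = 2.0 * params.sigma_e * vox_cm
    np.add.at(diag, mesh.dirichlet_vox, g_b)
    A = sp.coo_matrix(
        (np.concatenate([-g, -g, diag]),
         (np.concatenate([p, q, np.arange(n)]),
          np.concatenate([q, p, np.arange(n)]))), shape=(n, n)).tocsc()
    rhs = np.zeros(n)
    np.add.at(rhs, mesh.mem_p, g_m * membrane.v0)
    np.add.at(rhs, mesh.mem_q, -g_m * membrane.v0)
    if stim is not None:
        mask = stim.region_mask(mesh.mem_centers)
        np.add.at(rhs, mesh.mem_p, -area * stim.amplitude * mask)
        np.add.at(rhs, mesh.mem_q, area * stim.amplitude * mask)
    return spla.spsolve(A, rhs)
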