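"""Homogenized bidomain solver in 1D/2D with operator splitting.

The tissue-scale equations for the membrane potential V and the
extracellular potential U_e,

    chi (C_m dV/dt + I_ion) = div(M_i grad(V + U_e)),
    0 = div(M_i grad V) + div((M_i + M_e) grad U_e),

are advanced by first-order splitting: a forward-Euler membrane/gating step
per node, then a fully coupled implicit finite-difference solve of the two
PDEs (one sparse factorization per run).  Boundary conditions: U_e = 0 on
Dirichlet-tagged sides, zero normal derivative of U_e on Neumann sides, and
zero normal intracellular flux (M_i-weighted d(V+U_e)/dn = 0) on every side.
The intracellular potential is recovered nodewise as U_i = V + U_e.

The spatial operator is a vertex-centered finite-volume Laplacian (3-point
in 1D, 5-point in 2D, half control volumes at boundaries), which makes the
zero-flux conditions natural and the scheme conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CM_PER_UM
from .homogenize import BidomainParameters
from .membrane import MembraneModel, StimulusProtocol


@dataclass(frozen=True)
class BidomainGrid:
    """Regular node grid for the reduced-dimension bidomain problem.

    ``extent_um``: domain lengths per axis (matching the cell-based domain);
    ``dx_um``: target node spacing (the actual spacing divides the extent
    exactly); ``dirichlet_axes``: axes whose two sides ground U_e (all other
    sides are Neumann).  At least one Dirichlet side is required, otherwise
    the U_e block is singular.
    """

    extent_um: tuple
    dx_um: float = 10.0
    dirichlet_axes: tuple = (0,)

    def __post_init__(self) -> None:
        if self.dx_um <= 0:
            raise ValueError("dx must be positive")
        if len(self.extent_um) not in (1, 2):
            raise ValueError("bidomain grid is 1D or 2D")
        if len(self.dirichlet_axes) == 0:
            raise ValueError("at least one axis must be Dirichlet for U_e")

    @property
    def dim(self) -> int:
        return len(self.extent_um)

    @property
    def shape(self) -> tuple:
        return tuple(int(round(L / self.dx_um)) + 1 for L in self.extent_um)

    def spacing_um(self, axis: int) -> float:
        return self.extent_um[axis] / (self.shape[axis] - 1)

    def coords_um(self, axis: int) -> np.ndarray:
        return np.linspace(0.0, self.extent_um[axis], self.shape[axis])

    def nodes_um(self) -> np.ndarray:
        """Node coordinates, shape (n_nodes, dim)."""
        axes = [self.coords_um(d) for d in range(self.dim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)


@dataclass
class BidomainState:
    V: np.ndarray
    U_e: np.ndarray
    gates: np.ndarray
    time: float = 0.0
    #: resting potential subtracted before the implicit solve (exactly zero
    #: right-hand side at rest, hence no solver roundoff drift)
    v_ref: float = 0.0


def _stiffness(grid: BidomainGrid, sigma_axes) -> sp.csr_matrix:
    """Vertex-centered FV stiffness K with (K u)_j = sum_f g_f (u_j - u_nb).

    ``sigma_axes[d]`` is the conductivity used for faces along axis d.
    Conductances are per unit transverse length/area so that the matching
    node "mass" is the control-volume measure.
    """
    shape = grid.shape
    n = int(np.prod(shape))
    flat = np.arange(n).reshape(shape)
    rows, cols, vals = [], [], []
    for ax in range(grid.dim):
        h = grid.spacing_um(ax) * CM_PER_UM
        # transverse measure of a face
        trans = 1.0
        for d in range(grid.dim):
            if d != ax:
                trans *= grid.spacing_um(d) * CM_PER_UM
        g = sigma_axes[ax] * trans / h
        lo = [slice(None)] * grid.dim
        hi = [slice(None)] * grid.dim
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        a = flat[tuple(lo)].ravel()
        b = flat[tuple(hi)].ravel()
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        vals += [np.full(a.size, -g), np.full(a.size, -g),
                 np.full(a.size, g), np.full(a.size, g)]
    return sp.coo_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(n, n)).tocsr()


def _control_measure(grid: BidomainGrid) -> np.ndarray:
    """Control-volume measure per node (cm^dim), half-size at boundaries."""
    ws = []
    for d in range(grid.dim):
        h = grid.spacing_um(d) * CM_PER_UM
        w = np.full(grid.shape[d], h)
        w[0] = w[-1] = h / 2.0
        ws.append(w)
    if grid.dim == 1:
        return ws[0]
    return np.outer(ws[0], ws[1]).ravel()


class BidomainSystem:
    """Factorized coupled (V, U_e) operator for one (grid, params, dt)."""

    def __init__(self, grid: BidomainGrid, bparams: BidomainParameters,
                 dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.grid = grid
        self.bparams = bparams
        self.dt = dt
        n = int(np.prod(grid.shape))
        self.n = n
        K_i = _stiffness(grid, bparams.sigma_tilde_i)
        sig_ie = [bparams.sigma_tilde_i[d] + bparams.sigma_tilde_e[d]
                  for d in range(grid.dim)]
        K_ie = _stiffness(grid, sig_ie)
        omega = _control_measure(grid)
        self.mass = bparams.chi * bparams.C_m * omega / dt  # mS per node

        # Dirichlet row replacement for U_e on tagged sides
        flat = np.arange(n).reshape(grid.shape)
        dir_mask = np.zeros(grid.shape, dtype=bool)
        for ax in grid.dirichlet_axes:
            sl = [slice(None)] * grid.dim
            sl[ax] = 0
            dir_mask[tuple(sl)] = True
            sl[ax] = -1
            dir_mask[tuple(sl)] = True
        self.dirichlet_nodes = flat[dir_mask].ravel()

        M = sp.diags(self.mass)
        top = sp.hstack([M + K_i, K_i])
        keep = sp.diags((~dir_mask).ravel().astype(float))
        fix = sp.diags(dir_mask.ravel().astype(float))
        bottom = sp.hstack([keep @ K_i, keep @ K_ie + fix])
        A = sp.vstack([top, bottom]).tocsc()
        self.matrix = A
        self._lu = spla.splu(A)

    def solve(self, v_star: np.ndarray,
              v_ref: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        rhs = np.concatenate([self.mass * (v_star - v_ref),
                              np.zeros(self.n)])
        x = self._lu.solve(rhs)
        return x[:self.n] + v_ref, x[self.n:]


def ode_step(state: BidomainState, model: MembraneModel,
             stim: StimulusProtocol | None, bparams: BidomainParameters,
             dt: float, stim_mask: np.ndarray | None = None) -> BidomainState:
    """Forward-Euler membrane step at every node; U_e unchanged."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(state.V).all():
        raise FloatingPointError(f"non-finite V at t={state.time} ms")
    i_ion = model.I_ion(state.V, state.gates, state.time)
    if stim is not None and stim.active(state.time):
        if stim_mask is None:
            raise ValueError("an active stimulus needs its node mask")
        i_ion = i_ion + np.where(stim_mask, stim.amplitude, 0.0)
    V_new = state.V - (dt / bparams.C_m) * i_ion
    gates_new = state.gates + dt * model.gating_rhs(state.V, state.gates)
    return BidomainState(V=V_new, U_e=state.U_e, gates=gates_new,
                         time=state.time + dt, v_ref=state.v_ref)


def pde_step(state: BidomainState, system: BidomainSystem) -> BidomainState:
    """Implicit coupled solve for (V, U_e) given the post-ODE V*."""
    V, U_e = system.solve(state.V, state.v_ref)
    if not (np.isfinite(V).all() and np.isfinite(U_e).all()):
        raise FloatingPointError(f"non-finite PDE solve at t={state.time} ms")
    return BidomainState(V=V, U_e=U_e, gates=state.gates, time=state.time,
                         v_ref=state.v_ref)


def intracellular_potential(state: BidomainState) -> np.ndarray:
    """U_i = V + U_e nodewise."""
    return state.V + state.U_e


@dataclass
class BidomainTrajectory:
    times: np.ndarray
    probe_x_um: np.ndarray
    V_probe: np.ndarray
    snapshots: dict        # t -> {"V","U_e"} (grid-shaped arrays)
    grid: BidomainGrid = None


def initial_bidomain_state(grid: BidomainGrid,
                           model: MembraneModel) -> BidomainState:
    n = int(np.prod(grid.shape))
    return BidomainState(V=np.full(n, model.resting_potential),
                         U_e=np.zeros(n),
                         gates=model.initial_gates(n), time=0.0,
                         v_ref=model.resting_potential)


def run_bidomain(grid: BidomainGrid, bparams: BidomainParameters,
                 model: MembraneModel, stim: StimulusProtocol | None,
                 T: float, dt: float, probe_x_um=(), snapshot_times=(),
                 system: BidomainSystem | None = None,
                 stop_probe: tuple[int, float] | None = None,
                 record_stride: int = 1) -> BidomainTrajectory:
    """Advance the bidomain model from rest to ``T`` by operator splitting."""
    if T <= 0:
        raise ValueError("T must be positive")
    if system is None:
        system = BidomainSystem(grid, bparams, dt)
    state = initial_bidomain_state(grid, model)
    nodes = grid.nodes_um()
    stim_mask = stim.region_mask(nodes) if stim is not None else None
    # probe nodes: nearest node to each x at the transverse center
    probe_idx = []
    for x in probe_x_um:
        target = np.array([x] + [e / 2.0 for e in grid.extent_um[1:]])
        probe_idx.append(int(np.argmin(((nodes - target) ** 2).sum(axis=1))))
    probe_idx = np.asarray(probe_idx, dtype=int)

    n_steps = int(round(T / dt))
    snap_steps = {int(round(t / dt)): t for t in snapshot_times}
    times = [0.0]
    V_probe = [state.V[probe_idx].copy()]
    snapshots = {}

    def snap(s, t_label):
        snapshots[t_label] = {"V": s.V.reshape(grid.shape).copy(),
                              "U_e": s.U_e.reshape(grid.shape).copy()}

    if 0 in snap_steps:
        snap(state, snap_steps[0])
    for step in range(1, n_steps + 1):
        state = ode_step(state, model, stim, bparams, dt, stim_mask)
        state = pde_step(state, system)
        if step % record_stride == 0 or step == n_steps:
            times.append(state.time)
            V_probe.append(state.V[probe_idx].copy())
        if step in snap_steps:
            snap(state, snap_steps[step])
        if (stop_probe is not None
                and state.V[probe_idx[stop_probe[0]]] > stop_probe[1]):
            break
    return BidomainTrajectory(times=np.asarray(times),
                              probe_x_um=np.asarray(list(probe_x_um),
                                                    dtype=float),
                              V_probe=np.asarray(V_probe),
                              snapshots=snapshots, grid=grid)
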