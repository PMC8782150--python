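"""Homogenized solver: splitting steps, oracles, limits and symmetry."""

import numpy as np
import pytest

from emitissue.bidomain import (BidomainGrid, BidomainState, BidomainSystem,
                                initial_bidomain_state,
                                intracellular_potential, ode_step, pde_step,
                                run_bidomain)
from emitissue.geometry import (EMIParameters, build_cell_collection,
                                CellCollectionSpec, compute_metrics)
from emitissue.homogenize import BidomainParameters, bidomain_conductivities
from emitissue.membrane import (PassiveMembrane, StimulusProtocol,
                                surrogate_active_model)


@pytest.fixture(scope="module")
def strand_bparams():
    mesh = build_cell_collection(CellCollectionSpec(
        n_cells=(4, 1, 1), cell_length=120.0))
    return bidomain_conductivities(compute_metrics(mesh), EMIParameters())


class TestOdeStep:
    def _state(self, v):
        return BidomainState(V=np.full(5, v), U_e=np.zeros(5),
                             gates=np.zeros((5, 0)))

    def test_rest_unchanged(self, strand_bparams):
        new = ode_step(self._state(-80.0), PassiveMembrane(), None,
                       strand_bparams, 0.001)
        assert np.array_equal(new.V, np.full(5, -80.0))

    def test_passive_hand_value(self, strand_bparams):
        new = ode_step(self._state(-75.0), PassiveMembrane(), None,
                       strand_bparams, 0.001)
        assert np.allclose(new.V, -75.001)

    def test_stimulated_node_hand_value(self, strand_bparams):
        stim = StimulusProtocol(x_extent_um=1e9, amplitude=-40.0)
        new = ode_step(self._state(-80.0), PassiveMembrane(), stim,
                       strand_bparams, 0.001,
                       stim_mask=np.ones(5, dtype=bool))
        assert np.allclose(new.V, -79.96)


def test_uniform_v_star_is_fixed_point(strand_bparams):
    grid = BidomainGrid(extent_um=(500.0,), dx_um=10.0)
    system = BidomainSystem(grid, strand_bparams, dt=0.01)
    n = int(np.prod(grid.shape))
    state = BidomainState(V=np.full(n, -63.0), U_e=np.zeros(n),
                          gates=np.zeros((n, 0)))
    new = pde_step(state, system)
    assert np.abs(new.V + 63.0).max() < 1e-10
    assert np.abs(new.U_e).max() < 1e-10


def test_pde_step_matches_loop_assembled_dense_solve(strand_bparams):
    """One implicit step equals a dense solve of the same coupled system
    assembled independently node by node."""
    grid = BidomainGrid(extent_um=(400.0,), dx_um=10.0)
    dt = 0.01
    system = BidomainSystem(grid, strand_bparams, dt=dt)
    n = grid.shape[0]
    rng = np.random.default_rng(3)
    v_star = -80.0 + 30.0 * rng.random(n)
    state = BidomainState(V=v_star.copy(), U_e=np.zeros(n),
                          gates=np.zeros((n, 0)))
    new = pde_step(state, system)

    h = grid.spacing_um(0) * 1e-4
    si = strand_bparams.sigma_tilde_i[0]
    se = strand_bparams.sigma_tilde_e[0]
    chi, cm = strand_bparams.chi, strand_bparams.C_m
    A = np.zeros((2 * n, 2 * n))
    b = np.zeros(2 * n)
    for j in range(n):
        omega = h if 0 < j < n - 1 else h / 2.0
        mass = chi * cm * omega / dt
        A[j, j] += mass
        b[j] = mass * v_star[j]
        for nb in (j - 1, j + 1):
            if 0 <= nb < n:
                g = si / h
                A[j, j] += g
                A[j, nb] -= g
                A[j, n + j] += g
                A[j, n + nb] -= g
        if j in (0, n - 1):
            A[n + j, n + j] = 1.0  # grounded boundary
        else:
            for nb in (j - 1, j + 1):
                gi, gie = si / h, (si + se) / h
                A[n + j, j] += gi
                A[n + j, nb] -= gi
                A[n + j, n + j] += gie
                A[n + j, n + nb] -= gie
    x = np.linalg.solve(A, b)
    assert np.abs(new.V - x[:n]).max() < 1e-10
    assert np.abs(new.U_e - x[n:]).max() < 1e-10


def test_monodomain_limit_matches_cable_oracle(strand_bparams):
    """With a near-infinite extracellular tensor, V follows the cable
    equation with conductivity sigma_tilde_i (tridiagonal oracle)."""
    bp = BidomainParameters(
        sigma_tilde_i=strand_bparams.sigma_tilde_i,
        sigma_tilde_e=tuple(s * 1e6 for s in strand_bparams.sigma_tilde_e),
        chi=strand_bparams.chi, C_m=strand_bparams.C_m)
    grid = BidomainGrid(extent_um=(400.0,), dx_um=10.0)
    dt = 0.01
    system = BidomainSystem(grid, bp, dt=dt)
    n = grid.shape[0]
    x = grid.coords_um(0)
    V = -80.0 + 40.0 * np.exp(-((x - 200.0) / 50.0) ** 2)

    h = grid.spacing_um(0) * 1e-4
    si = bp.sigma_tilde_i[0]
    omega = np.full(n, h)
    omega[[0, -1]] = h / 2.0
    mass = bp.chi * bp.C_m * omega / dt
    K = np.zeros((n, n))
    for j in range(n):
        for nb in (j - 1, j + 1):
            if 0 <= nb < n:
                K[j, j] += si / h
                K[j, nb] -= si / h
    state = BidomainState(V=V.copy(), U_e=np.zeros(n),
                          gates=np.zeros((n, 0)))
    V_cable = V.copy()
    for _ in range(20):
        state = pde_step(state, system)
        V_cable = np.linalg.solve(np.diag(mass) + K, mass * V_cable)
    assert np.abs(state.V - V_cable).max() < 0.1


def test_intracellular_potential_identity():
    rng = np.random.default_rng(11)
    V, Ue = rng.normal(size=20), rng.normal(size=20)
    state = BidomainState(V=V, U_e=Ue, gates=np.zeros((20, 0)))
    ui = intracellular_potential(state)
    assert np.array_equal(ui, V + Ue)
    assert np.allclose(ui - Ue, V, atol=1e-12)
    rest = BidomainState(V=np.array([-80.0]), U_e=np.array([5.0]),
                         gates=np.zeros((1, 0)))
    assert intracellular_potential(rest)[0] == -75.0


def test_2d_symmetric_state_stays_symmetric(strand_bparams):
    bp = BidomainParameters(
        sigma_tilde_i=(strand_bparams.sigma_tilde_i[0],) * 3,
        sigma_tilde_e=(strand_bparams.sigma_tilde_e[0],) * 3,
        chi=strand_bparams.chi, C_m=strand_bparams.C_m)
    grid = BidomainGrid(extent_um=(400.0, 400.0), dx_um=10.0,
                        dirichlet_axes=(0, 1))
    system = BidomainSystem(grid, bp, dt=0.01)
    X = np.meshgrid(grid.coords_um(0), grid.coords_um(1), indexing="ij")
    V = -80.0 + 40.0 * np.exp(-(((X[0] - 200.0) ** 2 + (X[1] - 200.0) ** 2)
                                / 50.0 ** 2))
    n = V.size
    state = BidomainState(V=V.ravel().copy(), U_e=np.zeros(n),
                          gates=np.zeros((n, 0)))
    for _ in range(5):
        state = pde_step(state, system)
    for arr in (state.V.reshape(grid.shape), state.U_e.reshape(grid.shape)):
        assert np.abs(arr - arr[::-1, :]).max() < 1e-10
        assert np.abs(arr - arr[:, ::-1]).max() < 1e-10
        assert np.abs(arr - arr.T).max() < 1e-10


def test_rest_invariance_run(strand_bparams):
    grid = BidomainGrid(extent_um=(1000.0,), dx_um=10.0)
    traj = run_bidomain(grid, strand_bparams, PassiveMembrane(), None,
                        T=10.0, dt=0.01, probe_x_um=(500.0,),
                        record_stride=10)
    assert np.abs(traj.V_probe + 80.0).max() < 1e-9


def test_cv_self_convergence_under_refinement(strand_bparams):
    """Halving dt and dx changes the homogenized-model CV by < 2%."""
    from emitissue.experiments import measure_cv
    model = surrogate_active_model()
    stim = StimulusProtocol(x_extent_um=360.0, amplitude=-40.0, duration=1.0)
    L = 1204.0
    cvs = []
    for dx, dt in ((10.0, 0.001), (5.0, 0.0005)):
        grid = BidomainGrid(extent_um=(L,), dx_um=dx)
        traj = run_bidomain(grid, strand_bparams, model, stim, T=20.0,
                            dt=dt, probe_x_um=(L / 2, 0.8 * L),
                            stop_probe=(1, -15.0))
        cvs.append(measure_cv(traj).velocity_cm_per_s)
    assert abs(cvs[0] - cvs[1]) / cvs[1] < 0.02
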