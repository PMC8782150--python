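"""Cell-based solver: explicit step, assembly, elliptic solve, conservation."""

import numpy as np
import pytest

from emitissue.emi import (EMIState, assemble_system, centerline,
                           current_balance, elliptic_step,
                           explicit_membrane_step, initial_state,
                           passive_steady_state, run_emi)
from emitissue.geometry import (CellCollectionSpec, EMIParameters,
                                build_box_collection, build_cell_collection)
from emitissue.membrane import PassiveMembrane, StimulusProtocol

from conftest import ALL_DIRICHLET


@pytest.fixture(scope="module")
def tiny_system(tiny_box_mesh):
    return assemble_system(tiny_box_mesh, EMIParameters(), dt=0.001)


class TestExplicitStep:
    def test_passive_rest_unchanged(self, tiny_system):
        pm = PassiveMembrane()
        state = initial_state(tiny_system, pm)
        new = explicit_membrane_step(state, pm, None, tiny_system.params,
                                     0.001)
        assert np.array_equal(new.v, state.v)

    def test_disc_update_hand_value(self, tiny_system):
        pm = PassiveMembrane()
        state = initial_state(tiny_system, pm)
        state.w[:] = 1.0
        new = explicit_membrane_step(state, pm, None, tiny_system.params,
                                     0.001)
        # w <- 1 - 0.001 * (666.67 / 0.5)
        assert new.w[0] == pytest.approx(-1.0 / 3.0, rel=1e-6)

    def test_stimulated_face_hand_value(self, tiny_system):
        pm = PassiveMembrane()
        state = initial_state(tiny_system, pm)
        stim = StimulusProtocol(x_extent_um=1e9, amplitude=-10.0)
        mask = stim.region_mask(tiny_system.mesh.mem_centers)
        new = explicit_membrane_step(state, pm, stim, tiny_system.params,
                                     0.001, stim_mask=mask)
        assert np.allclose(new.v, -79.99)

    def test_nonfinite_state_aborts(self, tiny_system):
        pm = PassiveMembrane()
        state = initial_state(tiny_system, pm)
        state.v[0] = np.nan
        with pytest.raises(FloatingPointError):
            explicit_membrane_step(state, pm, None, tiny_system.params,
                                   0.001)


class TestAssembly:
    def test_matrix_symmetric(self, tiny_system):
        A = tiny_system.matrix
        asym = abs(A - A.T).max()
        assert asym <= 1e-12 * abs(A).max()

    def test_row_sums_vanish_except_dirichlet(self, tiny_system):
        rows = np.asarray(tiny_system.matrix.sum(axis=1)).ravel()
        grounded = np.zeros(tiny_system.n, dtype=bool)
        grounded[tiny_system.mesh.dirichlet_vox] = True
        scale = abs(tiny_system.matrix).max()
        assert np.abs(rows[~grounded]).max() < 1e-12 * scale
        assert np.abs(rows[grounded]).min() > 0

    def test_homogeneous_problem_gives_zero(self, tiny_box_mesh):
        mesh = build_box_collection((2, 1, 1), cell_size=(20.0, 8.0, 8.0),
                                    padding=2.0, voxel_size=2.0,
                                    boundary_conditions=ALL_DIRICHLET)
        system = assemble_system(mesh, EMIParameters(), dt=0.001)
        state = EMIState(u=np.zeros(system.n),
                         v=np.zeros(mesh.mem_p.size),
                         w=np.zeros(mesh.disc_p.size),
                         gates=np.zeros((mesh.mem_p.size, 0)))
        new = elliptic_step(state, system)
        assert np.abs(new.u).max() < 1e-12

    def test_all_neumann_rejected(self):
        mesh = build_box_collection(
            (1, 1, 1), cell_size=(20.0, 8.0, 8.0), voxel_size=2.0,
            boundary_conditions={"x": "neumann", "y": "neumann",
                                 "z": "neumann"})
        with pytest.raises(ValueError, match="[Dd]irichlet"):
            assemble_system(mesh, EMIParameters(), dt=0.001)


def test_rest_is_elliptic_fixed_point(tiny_system):
    pm = PassiveMembrane()
    state = initial_state(tiny_system, pm)
    new = elliptic_step(state, tiny_system)
    intra = tiny_system.intra_mask
    assert np.abs(new.u[~intra]).max() < 1e-12
    assert np.abs(new.u[intra] + 80.0).max() < 1e-12
    assert np.abs(new.v + 80.0).max() < 1e-12


def test_sparse_solve_matches_dense_oracle(tiny_system):
    rng = np.random.default_rng(7)
    mesh = tiny_system.mesh
    state = EMIState(u=np.zeros(tiny_system.n),
                     v=rng.normal(-80.0, 20.0, mesh.mem_p.size),
                     w=rng.normal(0.0, 5.0, mesh.disc_p.size),
                     gates=np.zeros((mesh.mem_p.size, 0)))
    new = elliptic_step(state, tiny_system)
    rhs = np.zeros(tiny_system.n)
    np.add.at(rhs, mesh.mem_p, tiny_system.c_m * state.v)
    np.add.at(rhs, mesh.mem_q, -tiny_system.c_m * state.v)
    np.add.at(rhs, mesh.disc_p, tiny_system.c_g * state.w)
    np.add.at(rhs, mesh.disc_q, -tiny_system.c_g * state.w)
    dense = np.linalg.solve(tiny_system.matrix.toarray(), rhs)
    assert np.abs(new.u - dense).max() < 1e-10


def test_steady_disc_drop_matches_lumped_circuit(params):
    """Two short box cells: disc potential jump vs a 2-node resistor network."""
    mesh = build_box_collection((2, 1, 1), cell_size=(40.0, 8.0, 8.0),
                                padding=2.0, voxel_size=2.0)
    pm = PassiveMembrane(R_m=5.0, v0=0.0)
    stim = StimulusProtocol(x_extent_um=41.0, amplitude=-10.0)
    u = passive_steady_state(mesh, params, pm, stim)
    w = u[mesh.disc_p] - u[mesh.disc_q]

    # lumped network: stimulus injects into cell 1, leaks through both
    # membranes, crosses the disc conductance
    lab = mesh.labels.ravel()
    area = (mesh.voxel_size * 1e-4) ** 2
    a_mem = [np.sum(lab[mesh.mem_p] == c) * area for c in (0, 1)]
    a_disc = mesh.disc_p.size * area
    g_m1, g_m2 = a_mem[0] / pm.R_m, a_mem[1] / pm.R_m
    g_d = a_disc / params.R_g
    i_in = 10.0 * a_mem[0]  # stimulated area = all of cell 1's membrane
    A = np.array([[g_m1 + g_d, -g_d], [-g_d, g_m2 + g_d]])
    u1, u2 = np.linalg.solve(A, [i_in, 0.0])
    assert w.mean() == pytest.approx(u1 - u2, rel=0.02)


def test_run_emi_rest_invariance(small_strand_mesh, params):
    traj = run_emi(small_strand_mesh, params, PassiveMembrane(), None,
                   T=1.0, dt=0.001, probe_x_um=(40.0,), record_stride=10)
    assert np.abs(traj.v_probe + 80.0).max() < 1e-9


def test_current_balance_each_step(small_strand_mesh, params):
    system = assemble_system(small_strand_mesh, params, dt=0.001)
    pm = PassiveMembrane()
    stim = StimulusProtocol(x_extent_um=30.0, amplitude=-10.0)
    mask = stim.region_mask(small_strand_mesh.mem_centers)
    state = initial_state(system, pm)
    for _ in range(50):
        pre = explicit_membrane_step(state, pm, stim, params, 0.001, mask)
        state = elliptic_step(pre, system)
        bal = current_balance(system, pre, state)
        assert abs(bal["membrane_total"]) / bal["scale"] < 1e-8
        assert abs(bal["boundary_total"]) / bal["scale"] < 1e-8


def test_splitting_self_convergence_and_monotone_profile(params):
    """Stimulated passive strand: dt-halving changes the profile < 0.5 mV,
    and the profile decays monotonically beyond the stimulated region."""
    spec = CellCollectionSpec(n_cells=(6, 1, 1), cell_length=50.0)
    mesh = build_cell_collection(spec)
    pm = PassiveMembrane()
    stim = StimulusProtocol(x_extent_um=60.0, amplitude=-10.0)
    profiles = {}
    for dt in (0.002, 0.001):
        traj = run_emi(mesh, params, pm, stim, T=5.0, dt=dt,
                       snapshot_times=(5.0,), record_stride=1000)
        x, ui = (traj.snapshots[5.0]["centerline_x_um"],
                 traj.snapshots[5.0]["u_i_centerline"])
        profiles[dt] = ui
    assert np.abs(profiles[0.002] - profiles[0.001]).max() < 0.5
    beyond = x > 80.0
    assert np.all(np.diff(profiles[0.001][beyond]) <= 1e-9)
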