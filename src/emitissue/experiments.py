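"""Protocol drivers comparing the cell-based and homogenized models.

Each driver builds a virtual tissue once, runs the cell-based (EMI) solver
on it, derives the homogenized parameters from the same mesh, runs the
bidomain solver on the matching domain, and quantifies the agreement:

* passive strand — intracellular potential along the strand centerline at a
  snapshot time, compared pointwise (max-norm and relative L2);
* active strand — conduction velocity (CV) as the gap-junction resistance is
  scaled up, including detection of conduction block;
* 2D cell grid — position of the depolarization wavefront along the domain
  diagonal.

CV is measured between a point a at the center of the domain (along the
propagation axis) and a point b at 4/5 of the domain length, as the distance
divided by the difference of the first times the membrane potential exceeds
-20 mV at the two points (strictly above).

Everything here is deterministic given its configuration; there is no
randomness anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bidomain as bd
from . import emi
from .geometry import (CM_PER_UM, CellCollectionSpec, EMIParameters,
                       build_cell_collection, compute_metrics)
from .homogenize import bidomain_conductivities
from .membrane import (MembraneModel, PassiveMembrane, StimulusProtocol,
                       surrogate_active_model)

CV_THRESHOLD_MV = -20.0


class StimulusFailure(RuntimeError):
    """The wave never depolarized the proximal measurement point."""


class InvalidPropagation(RuntimeError):
    """The distal point depolarized before (or with) the proximal point."""


@dataclass(frozen=True)
class CVMeasurement:
    """Conduction-velocity measurement between two upstroke probes."""

    point_a_um: float
    point_b_um: float
    threshold: float
    t_a: float | None
    t_b: float | None
    velocity_cm_per_s: float | None
    blocked: bool


def first_crossing(times: np.ndarray, v: np.ndarray,
                   threshold: float) -> float | None:
    """First recorded time with v strictly above threshold, or None."""
    above = np.nonzero(v > threshold)[0]
    return float(times[above[0]]) if above.size else None


def measure_cv(traj, axis_length_um: float | None = None,
               threshold: float = CV_THRESHOLD_MV) -> CVMeasurement:
    """Measure CV from a trajectory with probes at L/2 and 4L/5.

    ``traj`` must expose ``times``, a probe matrix (``v_probe`` or
    ``V_probe``) whose first two columns are the proximal and distal probes,
    and ``probe_x_um``.  A distal point that never crosses the threshold
    within the run is reported as conduction block.
    """
    v = traj.v_probe if hasattr(traj, "v_probe") else traj.V_probe
    x_a, x_b = float(traj.probe_x_um[0]), float(traj.probe_x_um[1])
    t_a = first_crossing(traj.times, v[:, 0], threshold)
    t_b = first_crossing(traj.times, v[:, 1], threshold)
    if t_a is None:
        raise StimulusFailure(
            "membrane potential never exceeded the threshold at point a")
    if t_b is None:
        return CVMeasurement(x_a, x_b, threshold, t_a, None, None, True)
    if t_b <= t_a:
        raise InvalidPropagation(f"t_b={t_b} <= t_a={t_a}")
    dist_cm = (x_b - x_a) * CM_PER_UM
    velocity = dist_cm / (t_b - t_a) * 1000.0  # cm/ms -> cm/s
    return CVMeasurement(x_a, x_b, threshold, t_a, t_b, velocity, False)


def _measure_or_block(traj) -> CVMeasurement:
    """CV measurement where a wave dying before the proximal probe counts
    as conduction block (the stimulated region itself did fire)."""
    try:
        return measure_cv(traj)
    except StimulusFailure:
        return CVMeasurement(float(traj.probe_x_um[0]),
                             float(traj.probe_x_um[1]), CV_THRESHOLD_MV,
                             None, None, None, True)


def auto_dt(params: EMIParameters, floor: float = 0.001,
            cap: float = 0.01) -> float:
    """Largest time step that keeps the explicit gap-junction update stable.

    The explicit update w <- w (1 - dt/(C_g R_g)) requires dt < 2 C_g R_g;
    dt = C_g R_g keeps it well inside the stable region.  The step is capped
    (accuracy relative to the membrane time constant) and floored at the
    reference resolution 0.001 ms.
    """
    return float(min(cap, max(floor, params.C_g * params.R_g)))


def compare_centerlines(traj_emi, traj_bid, time: float) -> dict:
    """Deviation metrics between intracellular potentials at one snapshot.

    Interpolates the cell-based centerline u_i onto the bidomain nodes that
    fall inside the cell region and returns max-norm and relative L2
    deviations together with the profiles.
    """
    if time not in traj_emi.snapshots or time not in traj_bid.snapshots:
        raise ValueError(f"no common snapshot at t={time}")
    snap_e = traj_emi.snapshots[time]
    snap_b = traj_bid.snapshots[time]
    x_e, ui_e = snap_e["centerline_x_um"], snap_e["u_i_centerline"]
    grid = traj_bid.grid
    L_emi = traj_emi.mesh.extents_um[0]
    if abs(grid.extent_um[0] - L_emi) > grid.extent_um[0] * 1e-6:
        raise ValueError("mismatched domain extents")
    x_b = grid.coords_um(0)
    if grid.dim == 1:
        Ui_b = snap_b["V"] + snap_b["U_e"]
    else:
        j = grid.shape[1] // 2
        Ui_b = snap_b["V"][:, j] + snap_b["U_e"][:, j]
    sel = (x_b >= x_e.min()) & (x_b <= x_e.max())
    ui_interp = np.interp(x_b[sel], x_e, ui_e)
    diff = Ui_b[sel] - ui_interp
    return {
        "x_um": x_b[sel],
        "u_i_emi": ui_interp,
        "U_i_bidomain": Ui_b[sel],
        "max_abs_mV": float(np.abs(diff).max()),
        "rel_l2": float(np.linalg.norm(diff) / np.linalg.norm(ui_interp)),
    }


@dataclass
class ComparisonReport:
    cell_length_um: float
    rg_factor: float
    time_ms: float
    metrics: dict
    cv_emi: CVMeasurement | None = None
    cv_bidomain: CVMeasurement | None = None
    extras: dict = field(default_factory=dict)


def _strand_spec(cell_length_um: float, n_cells: int, voxel_um: float,
                 radius_end: float = 6.0, radius_center: float = 7.0
                 ) -> CellCollectionSpec:
    return CellCollectionSpec(
        n_cells=(n_cells, 1, 1), cell_length=cell_length_um,
        radius_end=radius_end, radius_center=radius_center,
        padding=2.0, voxel_size=voxel_um,
        boundary_conditions={"x": "dirichlet", "y": "neumann",
                             "z": "neumann"})


def run_passive_strand_comparison(cell_length_um: float = 120.0,
                                  rg_factor: float = 1.0,
                                  strand_length_um: float = 2000.0,
                                  voxel_um: float = 2.0,
                                  dx_um: float = 10.0,
                                  dt_ms: float | None = None,
                                  t_snapshot_ms: float = 20.0,
                                  stim_extent_um: float | None = None,
                                  params: EMIParameters | None = None
                                  ) -> ComparisonReport:
    """Passive-membrane strand: cell-based vs homogenized centerline u_i.

    A strand of ``strand_length_um/cell_length_um`` cells with a linear leak
    membrane is stimulated on the leftmost fifth of the membrane (-10
    uA/cm^2, sustained) and both models are sampled at ``t_snapshot_ms``.
    """
    n_cells = strand_length_um / cell_length_um
    if abs(n_cells - round(n_cells)) > 1e-9:
        raise ValueError("strand length must be a whole number of cells")
    params = (params or EMIParameters()).with_rg_factor(rg_factor)
    dt = auto_dt(params) if dt_ms is None else dt_ms
    if stim_extent_um is None:
        stim_extent_um = 0.2 * strand_length_um
    spec = _strand_spec(cell_length_um, int(round(n_cells)), voxel_um)
    mesh = build_cell_collection(spec)
    membrane = PassiveMembrane()
    stim = StimulusProtocol(x_extent_um=stim_extent_um, amplitude=-10.0)
    traj_e = emi.run_emi(mesh, params, membrane, stim, T=t_snapshot_ms,
                         dt=dt, snapshot_times=(t_snapshot_ms,),
                         record_stride=100)
    bparams = bidomain_conductivities(compute_metrics(mesh), params)
    grid = bd.BidomainGrid(extent_um=(mesh.extents_um[0],), dx_um=dx_um,
                           dirichlet_axes=(0,))
    traj_b = bd.run_bidomain(grid, bparams, membrane, stim, T=t_snapshot_ms,
                             dt=dt, snapshot_times=(t_snapshot_ms,),
                             record_stride=100)
    metrics = compare_centerlines(traj_e, traj_b, t_snapshot_ms)
    return ComparisonReport(cell_length_um, rg_factor, t_snapshot_ms,
                            metrics,
                            extras={"bidomain_params": bparams, "dt": dt})


def run_active_strand_cv_sweep(rg_factors,
                               n_cells: int = 20,
                               cell_length_um: float = 120.0,
                               resolution: str = "default",
                               model: MembraneModel | None = None,
                               T_max_ms: float = 50.0,
                               params: EMIParameters | None = None
                               ) -> pd.DataFrame:
    """CV of both models on a cell strand as R_g is scaled up.

    Stimulates the first three cells' worth of membrane for 1 ms at -40
    uA/cm^2 and measures CV between the domain center and 4/5 of its length.
    ``resolution='refined'`` halves the time step, the bidomain node spacing
    and the voxel size.  Rows where the distal probe never depolarizes
    within ``T_max_ms`` are flagged as conduction block.
    """
    if resolution not in ("default", "refined"):
        raise ValueError("resolution must be 'default' or 'refined'")
    refined = resolution == "refined"
    base = params or EMIParameters()
    model = model or surrogate_active_model()
    voxel = 1.0 if refined else 2.0
    dx = 5.0 if refined else 10.0
    spec = _strand_spec(cell_length_um, n_cells, voxel)
    mesh = build_cell_collection(spec)
    bparams_metrics = compute_metrics(mesh)
    L = mesh.extents_um[0]
    probes = (L / 2.0, 0.8 * L)
    stim = StimulusProtocol(x_extent_um=3 * cell_length_um, amplitude=-40.0,
                            duration=1.0)
    rows = []
    for factor in rg_factors:
        p = base.with_rg_factor(factor)
        dt = auto_dt(p)
        if refined:
            dt /= 2.0
        traj_e = emi.run_emi(mesh, p, model, stim, T=T_max_ms, dt=dt,
                             probe_x_um=probes,
                             stop_probe=(1, CV_THRESHOLD_MV + 5.0),
                             record_stride=1)
        cv_e = _measure_or_block(traj_e)
        bparams = bidomain_conductivities(bparams_metrics, p)
        grid = bd.BidomainGrid(extent_um=(L,), dx_um=dx, dirichlet_axes=(0,))
        traj_b = bd.run_bidomain(grid, bparams, model, stim, T=T_max_ms,
                                 dt=dt, probe_x_um=probes,
                                 stop_probe=(1, CV_THRESHOLD_MV + 5.0),
                                 record_stride=1)
        cv_b = _measure_or_block(traj_b)
        rows.append({"rg_factor": factor,
                     "cv_emi": cv_e.velocity_cm_per_s,
                     "cv_bidomain": cv_b.velocity_cm_per_s,
                     "block_emi": cv_e.blocked,
                     "block_bidomain": cv_b.blocked,
                     "dt": dt})
    return pd.DataFrame(rows)


def wavefront_along_diagonal(points_um: np.ndarray, v: np.ndarray,
                             threshold: float = CV_THRESHOLD_MV) -> float:
    """Farthest depolarized point projected on the (1,1) diagonal (um)."""
    above = v > threshold
    if not above.any():
        return 0.0
    proj = (points_um[above, 0] + points_um[above, 1]) / np.sqrt(2.0)
    return float(proj.max())


def run_grid_comparison(n_cells: tuple[int, int] = (8, 8),
                        rg_factor: float = 1.0,
                        snapshot_times=(5.0,),
                        cell_length_um: float = 120.0,
                        voxel_um: float = 2.0,
                        dx_um: float = 10.0,
                        model: MembraneModel | None = None,
                        stim_fraction: float = 0.2,
                        stim_amplitude: float = -40.0,
                        params: EMIParameters | None = None
                        ) -> ComparisonReport:
    """2D sheet of cells: 3D cell-based vs 2D homogenized wavefront.

    Stimulates a corner block covering ``stim_fraction`` of the cell count
    per axis (the 5-of-25 cells protocol, scaled with the grid) and compares
    the position of the -20 mV isoline along the domain diagonal at each
    snapshot time.
    """
    params = (params or EMIParameters()).with_rg_factor(rg_factor)
    model = model or surrogate_active_model()
    dt = auto_dt(params)
    spec = CellCollectionSpec(
        n_cells=(n_cells[0], n_cells[1], 1), cell_length=cell_length_um,
        voxel_size=voxel_um,
        boundary_conditions={"x": "dirichlet", "y": "dirichlet",
                             "z": "neumann"})
    mesh = build_cell_collection(spec)
    Lx, Ly = mesh.extents_um[0], mesh.extents_um[1]
    n_stim = (max(1, round(stim_fraction * n_cells[0])),
              max(1, round(stim_fraction * n_cells[1])))
    pitch = 2.0 * spec.radius_center
    pad = mesh.extents_um[0] - n_cells[0] * cell_length_um  # 2 * padding
    stim = StimulusProtocol(
        x_extent_um=pad / 2 + n_stim[0] * cell_length_um,
        y_extent_um=pad / 2 + n_stim[1] * pitch,
        amplitude=stim_amplitude, duration=1.0)
    T = max(snapshot_times)
    traj_e = emi.run_emi(mesh, params, model, stim, T=T, dt=dt,
                         snapshot_times=snapshot_times, record_stride=100)
    bparams = bidomain_conductivities(compute_metrics(mesh), params)
    grid = bd.BidomainGrid(extent_um=(Lx, Ly), dx_um=dx_um,
                           dirichlet_axes=(0, 1))
    traj_b = bd.run_bidomain(grid, bparams, model, stim, T=T, dt=dt,
                             snapshot_times=snapshot_times,
                             record_stride=100)
    fronts = {}
    diag = np.sqrt(Lx ** 2 + Ly ** 2)
    for t in snapshot_times:
        se = traj_e.snapshots[t]
        v_faces = se["v"]
        front_e = wavefront_along_diagonal(mesh.mem_centers[:, :2], v_faces)
        sb = traj_b.snapshots[t]
        nodes = grid.nodes_um()
        front_b = wavefront_along_diagonal(nodes, sb["V"].ravel())
        fronts[t] = {"front_emi_um": front_e, "front_bidomain_um": front_b,
                     "difference_um": front_b - front_e,
                     "difference_frac_of_diagonal":
                         (front_b - front_e) / diag,
                     "v_max_emi": float(v_faces.max()),
                     "v_max_bidomain": float(sb["V"].max())}
    return ComparisonReport(cell_length_um, rg_factor, max(snapshot_times),
                            {"wavefronts": fronts},
                            extras={"mesh_extent_um": (Lx, Ly), "dt": dt})
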