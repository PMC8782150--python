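"""Membrane and gap-junction current models, and stimulus protocols.

Any object implementing the :class:`MembraneModel` contract can be plugged
into both the cell-based and the homogenized solver.  The contract is small:
a resting potential, a gating-state dimension, the ionic current density
I_ion(v, gates, t) in uA/cm^2, and the gating right-hand side used for the
forward-Euler gating update.  At the rest point the ionic current and the
gating derivatives must vanish, so an unstimulated resting tissue stays at
rest in either solver.

Units everywhere: mV, ms, uA/cm^2, kOhm cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MembraneModel:
    """Contract for membrane kinetics; subclasses override the three methods."""

    resting_potential: float = -80.0
    n_gates: int = 0

    def initial_gates(self, n: int) -> np.ndarray:
        return np.zeros((n, self.n_gates))

    def I_ion(self, v: np.ndarray, gates: np.ndarray, t: float) -> np.ndarray:
        raise NotImplementedError

    def gating_rhs(self, v: np.ndarray, gates: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class PassiveMembrane(MembraneModel):
    """Linear leak membrane: I_ion = (v - v0)/R_m.

    ``R_m``: specific membrane resistance (kOhm cm^2, default 5);
    ``v0``: resting potential (mV, default -80).
    """

    R_m: float = 5.0
    v0: float = -80.0

    def __post_init__(self) -> None:
        if not self.R_m > 0:
            raise ValueError("R_m must be positive")
        self.resting_potential = self.v0
        self.n_gates = 0

    def I_ion(self, v, gates, t):
        return passive_ionic_current(v, self)

    def gating_rhs(self, v, gates):
        return gates  # empty


def passive_ionic_current(v, params: PassiveMembrane):
    """Leak current density (v - v0)/R_m in uA/cm^2 (mV / kOhm cm^2)."""
    return (np.asarray(v) - params.v0) / params.R_m


def gap_junction_current(w, R_g: float):
    """Passive gap-junction current density I_gap = w / R_g (uA/cm^2).

    ``w`` is the intracellular potential jump across the disc (mV) and
    ``R_g`` the specific disc resistance (kOhm cm^2).
    """
    if not R_g > 0:
        raise ValueError("R_g must be positive")
    return np.asarray(w) / R_g


@dataclass(frozen=True)
class StimulusProtocol:
    """Box-region, box-time membrane stimulus.

    The stimulated region is an interval from the domain's left edge along x
    (``x_extent_um``), optionally restricted in y (``y_extent_um``) for
    corner stimuli on 2D grids.  ``amplitude`` in uA/cm^2 (negative =
    depolarizing inward current), ``start``/``duration`` in ms; an unbounded
    stimulus uses ``duration=np.inf``.
    """

    x_extent_um: float
    amplitude: float
    start: float = 0.0
    duration: float = np.inf
    y_extent_um: float | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration

    def region_mask(self, points_um: np.ndarray) -> np.ndarray:
        """Boolean mask of stimulated locations; points shape (n, dim), um."""
        pts = np.atleast_2d(points_um)
        mask = pts[:, 0] <= self.x_extent_um
        if self.y_extent_um is not None and pts.shape[1] > 1:
            mask &= pts[:, 1] <= self.y_extent_um
        return mask


def stimulus_current(points_um: np.ndarray, t: float,
                     protocol: StimulusProtocol | None) -> np.ndarray:
    """Stimulus current density at each location at time ``t`` (uA/cm^2)."""
    pts = np.atleast_2d(points_um)
    out = np.zeros(pts.shape[0])
    if protocol is not None and protocol.active(t):
        out[protocol.region_mask(pts)] = protocol.amplitude
    return out


@dataclass
class SurrogateActiveModel(MembraneModel):
    """Reduced three-current excitable membrane (two gating variables).

    A minimal surrogate for a full ionic model, in physiological units, in
    the spirit of reduced three-current formulations:

    * a linear leak ``g_leak (v - v_rest)`` setting the subthreshold input
      resistance (default matches the 5 kOhm cm^2 passive membrane),
    * a fast sodium-like inward current ``g_act m_inf(v) h (v - v_peak)``
      with instantaneous steep activation
      ``m_inf = 1/(1 + exp(-(v-v_half_m)/k_m))`` and a slow inactivation
      gate h (``h_inf = 1/(1 + exp((v-v_half_h)/k_h))``, time constant
      ``tau_h``) that terminates the plateau,
    * a repolarizing recovery current ``g_rec s (v - v_rest)/span`` with
      ``ds/dt = eps ((v - v_rest)/span - s)``, span = v_peak - v_rest,
      which removes any depolarized equilibrium.

    The inward current is rest-corrected so that I_ion is exactly zero at
    (v_rest, h = h_inf(v_rest), s = 0), making rest an exact equilibrium of
    both solvers.  Defaults give an emergent firing threshold near -60 mV,
    an upstroke of several hundred mV/ms crossing -20 mV, a peak near
    +19 mV and an action-potential duration of roughly 9 ms.
    """

    v_rest: float = -80.0
    v_peak: float = 20.0
    g_leak: float = 0.2    # mS/cm^2
    g_act: float = 12.0    # mS/cm^2
    v_half_m: float = -45.0  # mV, activation midpoint
    k_m: float = 3.0       # mV, activation slope
    v_half_h: float = -55.0  # mV, inactivation midpoint
    k_h: float = 5.0       # mV, inactivation slope
    tau_h: float = 10.0    # ms
    g_rec: float = 500.0   # uA/cm^2 at s = 1, v = v_peak
    eps: float = 0.07      # 1/ms

    def __post_init__(self) -> None:
        self.resting_potential = self.v_rest
        self.n_gates = 2  # gates[..., 0] = h, gates[..., 1] = s
        self._h_rest = self._h_inf(self.v_rest)
        self._i_rest = (self.g_act * self._m_inf(self.v_rest)
                        * self._h_rest * (self.v_rest - self.v_peak))

    def _m_inf(self, v):
        return 1.0 / (1.0 + np.exp(-(v - self.v_half_m) / self.k_m))

    def _h_inf(self, v):
        return 1.0 / (1.0 + np.exp((v - self.v_half_h) / self.k_h))

    def initial_gates(self, n: int) -> np.ndarray:
        gates = np.zeros((n, 2))
        gates[:, 0] = self._h_rest
        return gates

    def I_ion(self, v, gates, t):
        v = np.asarray(v, dtype=float)
        h = np.asarray(gates)[..., 0]
        s = np.asarray(gates)[..., 1]
        span = self.v_peak - self.v_rest
        leak = self.g_leak * (v - self.v_rest)
        inward = (self.g_act * self._m_inf(v) * h * (v - self.v_peak)
                  - self._i_rest)
        recovery = self.g_rec * s * (v - self.v_rest) / span
        return leak + inward + recovery

    def gating_rhs(self, v, gates):
        v = np.asarray(v, dtype=float)
        h = np.asarray(gates)[..., 0]
        s = np.asarray(gates)[..., 1]
        span = self.v_peak - self.v_rest
        dh = (self._h_inf(v) - h) / self.tau_h
        ds = self.eps * ((v - self.v_rest) / span - s)
        return np.stack([dh, ds], axis=-1)


def surrogate_active_model(**kwargs) -> SurrogateActiveModel:
    """Bundled excitable membrane satisfying the :class:`MembraneModel` contract."""
    return SurrogateActiveModel(**kwargs)
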