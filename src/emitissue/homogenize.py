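"""Bidomain parameters from cell-scale geometry.

The homogenized tissue description needs a surface-to-volume ratio chi, an
intracellular conductivity tensor M_i and an extracellular tensor M_e.  All
three follow from integrated measures of the cell-collection mesh
(:class:`~emitissue.geometry.MeshMetrics`) and the cell-scale physical
parameters:

* ``chi = A_Gamma / V_Omega`` — membrane area per unit tissue volume.
* Cross-sectional area fractions are volume fractions:
  ``A_bar_i = V_Omega_i / V_Omega`` identically for every axis.
* The averaged intracellular conductivity per axis d lumps the gap-junction
  resistance in series with the cytoplasm such that the *total* intracellular
  resistance of the tissue block is preserved:

      sigma_bar_i^d = sigma_i / (1 + sigma_i R_g V_Omega_i / (delta_d^2 A_j^d)),

  with delta_d = L_d/(N_d - 1) the disc spacing.  The defining property is
  the resistor-network identity

      L_d / (sigma_bar_i^d A_bar_i * cross_area) = R_c^d + R_j^d,

  where R_c is the cytoplasmic resistance and R_j the series resistance of
  the N_d - 1 disc planes; :func:`resistor_network_total_resistance` computes
  the right-hand side independently and is used as the verification oracle.
* Tensor entries: ``sigma_tilde_i^d = A_bar_i * sigma_bar_i^d`` and
  ``sigma_tilde_e^d = A_bar_e * sigma_e`` (the extracellular space has no
  discs, so its tensor is isotropic).

Anisotropy arises only through the per-axis disc geometry: the ratio of two
axes' sigma_bar values is governed by delta^2 A_j per axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import EMIParameters, MeshMetrics


@dataclass(frozen=True)
class BidomainParameters:
    """Homogenized tissue parameters.

    ``sigma_tilde_i``/``sigma_tilde_e``: per-axis effective conductivities
    (mS/cm), i.e. the diagonals of the tensors M_i and M_e; ``chi``: membrane
    surface-to-volume ratio (1/cm); ``C_m``: specific membrane capacitance
    (uF/cm^2).
    """

    sigma_tilde_i: tuple[float, float, float]
    sigma_tilde_e: tuple[float, float, float]
    chi: float
    C_m: float

    @property
    def M_i(self) -> np.ndarray:
        return np.diag(self.sigma_tilde_i)

    @property
    def M_e(self) -> np.ndarray:
        return np.diag(self.sigma_tilde_e)


def surface_to_volume(metrics: MeshMetrics) -> float:
    """chi = total membrane area / total tissue volume (1/cm)."""
    if not metrics.V_Omega > 0:
        raise ValueError("domain volume must be positive")
    return metrics.A_Gamma / metrics.V_Omega


def area_fractions(metrics: MeshMetrics) -> tuple[float, float]:
    """(A_bar_i, A_bar_e): average cross-sectional area fractions.

    Equal to the volume fractions, identically for all three axes.
    """
    if not metrics.V_Omega > 0:
        raise ValueError("domain volume must be positive")
    a_i = metrics.V_Omega_i / metrics.V_Omega
    return a_i, 1.0 - a_i


def avg_intracellular_conductivity(metrics: MeshMetrics,
                                   params: EMIParameters,
                                   axis: int) -> float:
    """Averaged intracellular conductivity sigma_bar_i along ``axis`` (mS/cm).

    Lumps cytoplasm and gap junctions in series so the total intracellular
    resistance matches the cell-based model.  With a single cell along the
    axis there are no discs and sigma_bar_i = sigma_i exactly.
    """
    n = metrics.N(axis)
    if n == 1:
        return params.sigma_i
    a_j = metrics.A_j(axis)
    if not a_j > 0:
        raise ValueError(
            f"axis {axis}: {n} cells but zero disc area; intracellular "
            "resistance is infinite (conduction impossible)")
    delta = metrics.L(axis) / (n - 1)
    term = params.sigma_i * params.R_g * metrics.V_Omega_i / (delta ** 2 * a_j)
    return params.sigma_i / (1.0 + term)


def bidomain_conductivities(metrics: MeshMetrics,
                            params: EMIParameters) -> BidomainParameters:
    """Full homogenized parameter set from mesh metrics and cell parameters."""
    a_i, a_e = area_fractions(metrics)
    sig_i = tuple(a_i * avg_intracellular_conductivity(metrics, params, d)
                  for d in range(3))
    sig_e = (a_e * params.sigma_e,) * 3
    return BidomainParameters(sig_i, sig_e, surface_to_volume(metrics),
                              params.C_m)


def resistor_network_total_resistance(metrics: MeshMetrics,
                                      params: EMIParameters,
                                      axis: int) -> float:
    """Total intracellular resistance along ``axis`` (kOhm), cell-based route.

    R = R_c + R_j with the cytoplasmic path R_c = L/(sigma_i A_bar_i A_perp)
    and the gap-junction path R_j = (N-1) R_g / (N_perp A_j_single), where
    A_j_single is the area of one disc.  Serves as the independent oracle for
    the homogenized resistance L/(sigma_bar_i A_bar_i A_perp).
    """
    a_i, _ = area_fractions(metrics)
    perp = [d for d in range(3) if d != axis]
    cross_area = metrics.L(perp[0]) * metrics.L(perp[1])
    r_c = metrics.L(axis) / (params.sigma_i * a_i * cross_area)
    n = metrics.N(axis)
    if n == 1:
        return r_c
    a_j_total = metrics.A_j(axis)
    if not a_j_total > 0:
        raise ValueError("no disc area along a multi-cell axis")
    n_perp = metrics.N(perp[0]) * metrics.N(perp[1])
    a_j_single = a_j_total / ((n - 1) * n_perp)
    r_j = (n - 1) * params.R_g / (n_perp * a_j_single)
    return r_c + r_j


def homogenized_total_resistance(metrics: MeshMetrics,
                                 params: EMIParameters,
                                 axis: int) -> float:
    """Total intracellular resistance along ``axis`` (kOhm), averaged route."""
    a_i, _ = area_fractions(metrics)
    perp = [d for d in range(3) if d != axis]
    cross_area = metrics.L(perp[0]) * metrics.L(perp[1])
    sigma_bar = avg_intracellular_conductivity(metrics, params, axis)
    return metrics.L(axis) / (sigma_bar * a_i * cross_area)


def audit(metrics: MeshMetrics, params: EMIParameters) -> dict:
    """Intermediate homogenization quantities for inspection/serialization."""
    a_i, a_e = area_fractions(metrics)
    out = {"A_bar_i": a_i, "A_bar_e": a_e,
           "chi_per_cm": surface_to_volume(metrics)}
    for d, name in enumerate("xyz"):
        out[f"sigma_bar_i_{name}"] = avg_intracellular_conductivity(
            metrics, params, d)
    bp = bidomain_conductivities(metrics, params)
    for d, name in enumerate("xyz"):
        out[f"sigma_tilde_i_{name}"] = bp.sigma_tilde_i[d]
        out[f"sigma_tilde_e_{name}"] = bp.sigma_tilde_e[d]
    return out
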