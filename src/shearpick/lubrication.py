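"""Axisymmetric thin-film (Reynolds) solver for arbitrary gap profiles.

Stokes flow in a thin axisymmetric gap ``h(r)`` with a volumetric sink ``Q``
at the centre satisfies, under the locally parabolic (lubrication) closure:

    continuity:   q(r) = Q / (2 pi r)          (flux per unit circumference)
    momentum:     dp/dr = 12 mu q / h^3
    wall shear:   tau(r) = 6 mu q / h^2 = 3 mu Q / (pi r h^2)

The solver evaluates these on a radial grid, integrating the pressure by
trapezoid quadrature from the open rim (gauge p = 0) inward, and reports a
mass-conservation residual.  It is the numerical cross-check for the
closed-form design identities in :mod:`shearpick.ptms_design` and plays the
role a full CFD run would on the desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .flow_core import FluidProperties, ULS_TO_M3S, UM_TO_M
from .ptms_design import PTMSGeometry, contour_height, nominal_wss

__all__ = ["GapProfile", "SolverResult", "solve_radial", "compare_closed_form", "pump_pressure"]


@dataclass(frozen=True)
class GapProfile:
    """Gap height h(r) in um over the annulus [r_inner, r_outer] (um)."""

    height: Callable[[np.ndarray], np.ndarray]
    r_inner: float
    r_outer: float

    def __post_init__(self) -> None:
        if not (0 < self.r_inner < self.r_outer):
            raise ValueError(
                f"need 0 < r_inner < r_outer, got {self.r_inner}, {self.r_outer}"
            )

    @classmethod
    def from_geometry(cls, geom: PTMSGeometry) -> "GapProfile":
        """The designed contour sqrt(r0/r) h0."""
        return cls(lambda r: contour_height(geom, r), geom.bore_radius, geom.r0)

    @classmethod
    def flat(cls, h0: float, r_inner: float, r_outer: float) -> "GapProfile":
        """Uniform gap — an *unshaped* pin, for which tau falls off as 1/r."""
        return cls(lambda r: np.full_like(np.asarray(r, float), h0), r_inner, r_outer)

    @classmethod
    def from_table(cls, r_um: np.ndarray, h_um: np.ndarray) -> "GapProfile":
        r_um = np.asarray(r_um, float)
        h_um = np.asarray(h_um, float)
        return cls(lambda r: np.interp(r, r_um, h_um), float(r_um[0]), float(r_um[-1]))


@dataclass
class SolverResult:
    """Solved thin-film fields on a radial grid.

    ``flux`` is the per-circumference flux q(r) = Q/(2 pi r) in m^2/s;
    ``pressure`` is gauge (0 at the rim, suction negative); ``tau`` in Pa;
    ``residual`` is the worst relative mass-conservation defect
    max_r |2 pi r h vbar - Q| / Q.
    """

    radii: np.ndarray
    gap: np.ndarray
    flux: np.ndarray
    pressure: np.ndarray
    tau: np.ndarray
    flow_rate: float
    residual: float


def solve_radial(
    profile: GapProfile,
    flow_rate: float,
    fluid: FluidProperties,
    n_grid: int = 2048,
) -> SolverResult:
    """Solve the radial thin-film equations for aspiration at ``flow_rate`` (ul/s)."""
    if not math.isfinite(flow_rate) or flow_rate < 0:
        raise ValueError(f"flow_rate must be finite and >= 0, got {flow_rate!r}")
    if n_grid < 16:
        raise ValueError(f"n_grid must be >= 16, got {n_grid}")

    radii = np.geomspace(profile.r_inner, profile.r_outer, n_grid)
    h_um = np.asarray(profile.height(radii), dtype=float)
    if not np.all(np.isfinite(h_um)) or np.any(h_um <= 0):
        raise ValueError("gap profile must be positive and finite on the grid")

    r = radii * UM_TO_M
    h = h_um * UM_TO_M
    q_si = flow_rate * ULS_TO_M3S
    mu = fluid.viscosity

    flux = q_si / (2.0 * np.pi * r)
    tau = 6.0 * mu * flux / h**2
    dpdr = 12.0 * mu * flux / h**3
    pressure = np.zeros(n_grid)
    seg = 0.5 * (dpdr[1:] + dpdr[:-1]) * np.diff(r)
    pressure[:-1] = -(seg[::-1].cumsum()[::-1])

    if q_si > 0:
        vbar = flux / h  # mean velocity across the gap
        residual = float(np.abs(2.0 * np.pi * r * h * vbar - q_si).max() / q_si)
    else:
        residual = 0.0

    return SolverResult(
        radii=radii,
        gap=h_um,
        flux=flux,
        pressure=pressure,
        tau=tau,
        flow_rate=flow_rate,
        residual=residual,
    )


def compare_closed_form(
    result: SolverResult,
    geom: PTMSGeometry,
    flow_rate: float,
    fluid: FluidProperties,
) -> float:
    """Max relative deviation of the solved tau from the constant design value.

    For the designed contour this is grid plumbing (both sides are the same
    algebra) and sits at machine precision; for a perturbed gap it measures
    how far the field departs from design.
    """
    if result.flow_rate != flow_rate:
        raise ValueError("result was solved at a different flow rate")
    if not (
        math.isclose(result.radii[0], geom.bore_radius)
        and math.isclose(result.radii[-1], geom.r0)
    ):
        raise ValueError("result grid does not span the geometry's annulus")
    tau_nom = nominal_wss(geom, flow_rate, fluid)
    if tau_nom == 0:
        return float(np.abs(result.tau).max())
    return float(np.abs(result.tau - tau_nom).max() / tau_nom)


def pump_pressure(result: SolverResult) -> float:
    """Suction magnitude the pump must supply at the bore, Pa: |p(r_inner)|."""
    return float(abs(result.pressure[0]))
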