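"""Design calculus for the constant-shear aspiration pin (PTMS).

A pin held a small standoff ``h0`` above the culture surface and aspirating at
flow rate ``Q`` drives a radially converging thin-film flow.  Under the
lubrication (locally parabolic) closure the wall shear stress at radius ``r``
under a gap profile ``h(r)`` is

    tau(r) = 3 mu Q / (pi r h(r)^2).

Machining the pin tip to the contour ``h(r) = sqrt(r0/r) h0`` makes
``r h(r)^2 = r0 h0^2`` constant, so tau is spatially uniform and equal to the
nominal value ``3 mu Q / (pi r0 h0^2)`` everywhere over the annulus between
the aspiration bore ``r_i`` and the rim ``r0`` — the property that lets one
shear level address every cell under the footprint at once.

This module provides the contour, the nominal-shear and flow-sizing closed
forms, the perturbed field when the whole pin is offset vertically by
``delta``, uniformity/coverage metrics over the pi r0^2 footprint, and a CSV
contour export for manufacturing hand-off.

All radii and gaps are um, flow rates ul/s, stresses Pa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow_core import FluidProperties, ULS_TO_M3S, UM_TO_M

__all__ = [
    "PTMSGeometry",
    "OffsetScenario",
    "ShearField",
    "PUMP_MAX_WSS_PA",
    "contour_height",
    "nominal_wss",
    "required_flow",
    "wss_profile",
    "sensitivity_scan",
    "coverage_metrics",
    "export_contour",
]

#: Upper edge of the shear range the displacement pump can hold on the plate, Pa.
PUMP_MAX_WSS_PA = 1000.0

DEFAULT_N_GRID = 2048


@dataclass(frozen=True)
class PTMSGeometry:
    """Pin-tip geometry: rim radius ``r0``, standoff ``h0``, bore radius ``bore_radius`` (um)."""

    r0: float = 500.0
    h0: float = 50.0
    bore_radius: float = 150.0

    def __post_init__(self) -> None:
        if not (0 < self.bore_radius < self.r0):
            raise ValueError(
                f"need 0 < bore_radius < r0, got bore_radius={self.bore_radius}, r0={self.r0}"
            )
        if self.h0 <= 0:
            raise ValueError(f"h0 must be positive, got {self.h0}")
        if self.h0 / self.r0 > 0.2:
            warnings.warn(
                f"h0/r0 = {self.h0 / self.r0:.3f} > 0.2: lubrication (thin-film) "
                "closure is questionable for such a thick gap",
                stacklevel=2,
            )

    def radial_grid(self, n: int = DEFAULT_N_GRID) -> np.ndarray:
        """Log-spaced radii from the bore to the rim (um); resolves the steep inner contour."""
        if n < 2:
            raise ValueError("need at least 2 grid points")
        return np.geomspace(self.bore_radius, self.r0, n)


@dataclass(frozen=True)
class OffsetScenario:
    """Vertical offset of the whole pin from nominal standoff, um.

    Positive ``delta`` moves the pin away from the surface (gap widens);
    negative narrows it.  The gap must stay open: ``h0 + delta > 0`` (the gap
    is smallest at the rim).
    """

    delta: float = 0.0

    def gap(self, geom: PTMSGeometry, r: np.ndarray | float) -> np.ndarray | float:
        return contour_height(geom, r) + self.delta

    def validate(self, geom: PTMSGeometry) -> None:
        if geom.h0 + self.delta <= 0:
            raise ValueError(
                f"offset delta={self.delta} um closes the gap (h0={geom.h0} um at the rim)"
            )


@dataclass
class ShearField:
    """Radial shear-stress and pressure field under the pin.

    Attributes
    ----------
    radii : ndarray
        Radial grid, um.
    tau : ndarray
        Wall shear stress tau(r), Pa.
    pressure : ndarray
        Gauge pressure p(r), Pa, zero at the rim; negative (suction) inside.
    gradient : ndarray
        Analytic radial gradient d tau/dr, Pa/m.  For the designed contour at
        offset ``delta`` the gap family obeys ``h + 2 r h' = delta``, hence
        ``d tau/dr = -3 mu Q delta / (pi r^2 h^3)`` — identically zero when
        ``delta = 0``.
    flow_rate : float
        Aspiration flow rate, ul/s.
    nominal_wss : float
        Design shear 3 mu Q / (pi r0 h0^2), Pa.
    max_rel_variation : float
        max_r |tau(r) - nominal| / nominal.
    coverage_fraction : float
        Fraction of the pi r0^2 footprint within the tolerance band of
        nominal (bore disc counted as non-covered).
    """

    radii: np.ndarray
    tau: np.ndarray
    pressure: np.ndarray
    gradient: np.ndarray
    flow_rate: float
    nominal_wss: float
    max_rel_variation: float
    coverage_fraction: float
    geometry: PTMSGeometry = field(repr=False, default_factory=PTMSGeometry)
    offset: OffsetScenario = field(repr=False, default_factory=OffsetScenario)
    coverage_tol: float = 0.05


def contour_height(geom: PTMSGeometry, r):
    """Gap height h(r) = sqrt(r0/r) h0 of the designed contour, um.

    Valid on the annulus bore_radius <= r <= r0.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < geom.bore_radius) or np.any(r_arr > geom.r0):
        raise ValueError(
            f"radius outside the contour domain [{geom.bore_radius}, {geom.r0}] um"
        )
    h = np.sqrt(geom.r0 / r_arr) * geom.h0
    return float(h) if np.isscalar(r) else h


def nominal_wss(geom: PTMSGeometry, flow_rate: float, fluid: FluidProperties) -> float:
    """Design wall shear stress 3 mu Q / (pi r0 h0^2), Pa (Q in ul/s)."""
    if not math.isfinite(flow_rate) or flow_rate < 0:
        raise ValueError(f"flow_rate must be finite and >= 0, got {flow_rate!r}")
    q = flow_rate * ULS_TO_M3S
    r0 = geom.r0 * UM_TO_M
    h0 = geom.h0 * UM_TO_M
    return 3.0 * fluid.viscosity * q / (math.pi * r0 * h0 * h0)


def required_flow(geom: PTMSGeometry, target_wss: float, fluid: FluidProperties) -> float:
    """Flow rate (ul/s) that produces ``target_wss`` (Pa) under the designed contour.

    Exact inverse of :func:`nominal_wss`; warns above the pump envelope.
    """
    if not math.isfinite(target_wss) or target_wss < 0:
        raise ValueError(f"target WSS must be finite and >= 0, got {target_wss!r}")
    if target_wss > PUMP_MAX_WSS_PA:
        warnings.warn(
            f"target WSS {target_wss} Pa exceeds the pump envelope "
            f"(0 to {PUMP_MAX_WSS_PA:.0f} Pa)",
            stacklevel=2,
        )
    r0 = geom.r0 * UM_TO_M
    h0 = geom.h0 * UM_TO_M
    q = target_wss * math.pi * r0 * h0 * h0 / (3.0 * fluid.viscosity)
    return q / ULS_TO_M3S


def wss_profile(
    geom: PTMSGeometry,
    flow_rate: float,
    fluid: FluidProperties,
    offset: OffsetScenario | None = None,
    n_grid: int = DEFAULT_N_GRID,
    coverage_tol: float = 0.05,
) -> ShearField:
    """Shear and pressure field under the (possibly offset) designed contour.

    tau(r) = 3 mu Q / (pi r (sqrt(r0/r) h0 + delta)^2); pressure by trapezoid
    integration of dp/dr = 12 mu q / h^3 inward from p(r0) = 0.
    """
    offset = offset or OffsetScenario()
    offset.validate(geom)
    if not math.isfinite(flow_rate) or flow_rate < 0:
        raise ValueError(f"flow_rate must be finite and >= 0, got {flow_rate!r}")

    radii = geom.radial_grid(n_grid)
    r_si = radii * UM_TO_M
    h_si = np.asarray(offset.gap(geom, radii)) * UM_TO_M
    if np.any(h_si <= 0):
        raise ValueError("gap closes (h <= 0) somewhere on the grid")
    q_si = flow_rate * ULS_TO_M3S
    mu = fluid.viscosity

    tau = 3.0 * mu * q_si / (np.pi * r_si * h_si**2)
    # analytic gradient of tau for the contour-plus-offset gap family:
    # h + 2 r h' = delta  =>  dtau/dr = -3 mu Q delta / (pi r^2 h^3)
    delta_si = offset.delta * UM_TO_M
    gradient = -3.0 * mu * q_si * delta_si / (np.pi * r_si**2 * h_si**3)

    # suction pressure: dp/dr = 12 mu q / h^3 with q = Q/(2 pi r) (inward flux)
    dpdr = 12.0 * mu * q_si / (2.0 * np.pi * r_si * h_si**3)
    p = np.zeros_like(radii)
    # integrate from the rim (p=0) inward
    seg = 0.5 * (dpdr[1:] + dpdr[:-1]) * np.diff(r_si)
    p[:-1] = -(seg[::-1].cumsum()[::-1])

    tau_nom = nominal_wss(geom, flow_rate, fluid)
    if tau_nom > 0:
        rel = np.abs(tau - tau_nom) / tau_nom
        max_rel = float(rel.max())
    else:
        max_rel = 0.0

    fld = ShearField(
        radii=radii,
        tau=tau,
        pressure=p,
        gradient=gradient,
        flow_rate=flow_rate,
        nominal_wss=tau_nom,
        max_rel_variation=max_rel,
        coverage_fraction=0.0,
        geometry=geom,
        offset=offset,
        coverage_tol=coverage_tol,
    )
    fld.coverage_fraction = coverage_metrics(fld, coverage_tol)
    return fld


def coverage_metrics(fld: ShearField, tol: float = 0.05) -> float:
    """Fraction of the pi r0^2 footprint where tau is within ``tol`` of nominal.

    Area-weighted over the annulus; the bore disc (r < bore_radius) counts as
    non-covered.  For the unperturbed design this is 1 - (r_i/r0)^2.
    """
    if not 0 <= tol < 1:
        raise ValueError(f"tolerance must be in [0, 1), got {tol}")
    if fld.radii.size < 2:
        raise ValueError("shear field grid is empty or degenerate")
    if fld.nominal_wss == 0:
        return 0.0
    within = np.abs(fld.tau - fld.nominal_wss) / fld.nominal_wss <= tol
    # annular band between consecutive grid radii counts iff both edges are within
    band_ok = within[1:] & within[:-1]
    band_area = fld.radii[1:] ** 2 - fld.radii[:-1] ** 2  # pi cancels
    covered = float(band_area[band_ok].sum())
    return covered / fld.geometry.r0**2


def sensitivity_scan(
    geom: PTMSGeometry,
    flow_rate: float,
    fluid: FluidProperties,
    offsets,
    n_grid: int = DEFAULT_N_GRID,
) -> pd.DataFrame:
    """Shear-uniformity response to vertical pin offsets.

    Returns one row per offset with the worst-case relative variation over the
    annulus and the signed relative change at the rim, where the perturbation
    is largest: tau(r0)/tau_nom = 1/(1 + delta/h0)^2, so a positive offset
    (wider gap) lowers the shear and a negative one raises it, with the
    negative branch the stronger of the two.
    """
    rows = []
    for delta in offsets:
        fld = wss_profile(geom, flow_rate, fluid, OffsetScenario(float(delta)), n_grid)
        rim_rel_change = float((fld.tau[-1] - fld.nominal_wss) / fld.nominal_wss)
        rows.append(
            {
                "delta_um": float(delta),
                "max_rel_variation": fld.max_rel_variation,
                "rim_rel_change": rim_rel_change,
            }
        )
    return pd.DataFrame(rows)


def export_contour(geom: PTMSGeometry, path, n_points: int = 256) -> pd.DataFrame:
    """Write the machining contour (r_um, h_um) to CSV and return it.

    Radii run monotonically from the bore to the rim; heights follow
    :func:`contour_height` and round-trip through the CSV bit-exactly at
    double precision (written with 17 significant digits).
    """
    if n_points < 2:
        raise ValueError("need at least 2 contour points")
    r = geom.radial_grid(n_points)
    df = pd.DataFrame({"r_um": r, "h_um": contour_height(geom, r)})
    df.to_csv(path, index=False, float_format="%.17g")
    return df
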