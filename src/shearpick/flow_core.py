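"""Parallel-plate Poiseuille flow primitives.

Laminar flow between two plates separated by a gap ``h`` has a parabolic
velocity profile ``V(y) = V_max (1 - 4 y^2 / h^2)`` (``y`` measured from
mid-gap), mean velocity ``(2/3) V_max``, and exerts a wall shear stress
``WSS = 6 Q mu / (h^2 w)`` on each plate for a channel of width ``w``
carrying volumetric flow ``Q``.  These relations are the basis both of the
parallel-plate flow chamber (PPFC) used to characterise colony detachment
and of the thin-film design calculus in :mod:`shearpick.ptms_design`.

Public API uses lab units (mm, um, ul/s, Pa, Pa.s); everything is converted
to SI internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "FluidProperties",
    "PlateChannel",
    "ParabolicProfile",
    "WATER_VISCOSITY_PA_S",
    "plate_wss",
    "plate_flow_for_wss",
    "parabolic_velocity",
    "mean_velocity",
    "profile_wall_shear",
]

# unit conversion factors to SI
MM_TO_M = 1e-3
UM_TO_M = 1e-6
ULS_TO_M3S = 1e-9

#: Dynamic viscosity of water at ~20 degC, Pa.s.  Culture medium is
#: water-like; use :class:`FluidProperties` to override.
WATER_VISCOSITY_PA_S = 1.0e-3


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid, characterised by its dynamic viscosity ``mu`` in Pa.s."""

    viscosity: float = WATER_VISCOSITY_PA_S

    def __post_init__(self) -> None:
        if not (math.isfinite(self.viscosity) and self.viscosity > 0):
            raise ValueError(f"viscosity must be positive and finite, got {self.viscosity!r}")


@dataclass(frozen=True)
class PlateChannel:
    """Rectangular flow-chamber lumen; dimensions in mm.

    The plate-shear formula assumes the channel is much wider than tall, so a
    warning (not an error) is emitted when ``width/height < 5``.
    """

    length: float = 30.0
    width: float = 3.5
    height: float = 0.25

    def __post_init__(self) -> None:
        for name in ("length", "width", "height"):
            v = _require_finite(name, getattr(self, name))
            if v <= 0:
                raise ValueError(f"channel {name} must be positive, got {v}")
        if self.width / self.height < 5:
            warnings.warn(
                f"width/height = {self.width / self.height:.2f} < 5: the wide-channel "
                "shear formula WSS = 6 Q mu / (h^2 w) loses accuracy",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ParabolicProfile:
    """Symmetric parabolic velocity profile across a gap.

    Parameters
    ----------
    gap : float
        Plate separation h0 in um.
    vmax : float
        Centreline (maximum) velocity in m/s.
    """

    gap: float
    vmax: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gap) and self.gap > 0):
            raise ValueError(f"gap must be positive, got {self.gap!r}")
        _require_finite("vmax", self.vmax)


def plate_wss(flow_rate: float, channel: PlateChannel, fluid: FluidProperties) -> float:
    """Wall shear stress in a parallel-plate channel, Pa.

    Implements ``WSS = 6 Q mu / (h^2 w)`` with ``flow_rate`` in ul/s and the
    channel dimensions in mm.

    >>> plate_wss(4739.6, PlateChannel(30, 3.5, 0.25), FluidProperties())
    130.00...
    """
    flow_rate = _require_finite("flow_rate", flow_rate)
    if flow_rate < 0:
        raise ValueError(f"flow_rate must be >= 0, got {flow_rate}")
    q_si = flow_rate * ULS_TO_M3S
    h = channel.height * MM_TO_M
    w = channel.width * MM_TO_M
    return 6.0 * q_si * fluid.viscosity / (h * h * w)


def plate_flow_for_wss(target: float, channel: PlateChannel, fluid: FluidProperties) -> float:
    """Flow rate (ul/s) producing a target wall shear stress (Pa).

    Exact inverse of :func:`plate_wss`: round-trips to 1e-12 relative.
    """
    target = _require_finite("target", target)
    if target < 0:
        raise ValueError(f"target WSS must be >= 0, got {target}")
    h = channel.height * MM_TO_M
    w = channel.width * MM_TO_M
    q_si = target * h * h * w / (6.0 * fluid.viscosity)
    return q_si / ULS_TO_M3S


def parabolic_velocity(profile: ParabolicProfile, y: float) -> float:
    """Velocity at transverse position ``y`` (um from mid-gap), m/s.

    ``V(y) = V_max (1 - 4 y^2 / h0^2)``; zero at the walls (no slip).
    """
    y = _require_finite("y", y)
    half = profile.gap / 2.0
    if abs(y) > half:
        raise ValueError(f"|y| = {abs(y)} um lies outside the half-gap {half} um")
    return profile.vmax * (1.0 - 4.0 * y * y / (profile.gap * profile.gap))


def mean_velocity(profile: ParabolicProfile) -> float:
    """Gap-averaged velocity, m/s; equals (2/3) V_max for a parabola."""
    return 2.0 / 3.0 * profile.vmax


def profile_wall_shear(profile: ParabolicProfile, fluid: FluidProperties) -> float:
    """Shear stress on the wall, Pa: ``4 mu V_max / h0``."""
    return 4.0 * fluid.viscosity * profile.vmax / (profile.gap * UM_TO_M)
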