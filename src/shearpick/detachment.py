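"""Stochastic simulator of shear-threshold lineage selection.

A somatic-reprogramming colony is a layered mixture of cell types with very
different adhesion strengths: neural progenitors (NPCs) and pre-neurons sit
stacked on top and let go at low wall shear stress (median critical WSS
~124 Pa), iPSCs form a strongly adherent bottom monolayer (~248 Pa), and the
parental urine-derived cells (UCs) cling hardest (~744 Pa).  Exposing the
colony to a calibrated shear pulse therefore acts as a tunable sieve.

Model
-----
Each cell carries a critical WSS drawn log-normally around its lineage
median.  During an exposure step at stress ``tau`` for time ``t`` a cell
detaches with probability

    P = 1 - exp(-k * t * max(0, tau/tau_c - 1)**m)

i.e. nothing happens below the cell's threshold and the hazard grows with
the relative excess stress.  Stacking shields: a cell is only exposed to the
flow once no retained cell sits above it in its (x, y) neighbourhood, so a
step sweeps the colony top-down until no further cell comes loose.

Protocols
---------
* single run — harvest everything detached by one 500 Pa pulse;
* dual run — discard the 250 Pa detachate (the weakly adherent stacked
  NPC/pre-neuron layers), then harvest the 500 Pa detachate, which is
  enriched in iPSCs;
* negative selection — repeated low-WSS passes whose *retained* population
  is the product.

Common random numbers: each cell draws one uniform per exposure step, so
with a fixed seed the detached set is monotone in tau, t and pass count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .purity_stats import CompositionTable

__all__ = [
    "LINEAGES",
    "REPROGRAMMING_COMPOSITION",
    "AdhesionModel",
    "ExposureStep",
    "Colony",
    "SelectionOutcome",
    "make_colony",
    "apply_exposure",
    "run_protocol",
    "single_run_protocol",
    "dual_run_protocol",
    "negative_selection",
    "selected_area_curve",
    "onset_wss",
    "fit_log_logistic",
]

LINEAGES = ("iPSC", "NPC", "pre-neuron-1", "pre-neuron-2", "cell-cycle", "other")

#: Cell-type make-up of a manually picked reprogramming colony: NPCs dominate,
#: iPSCs are a <5% minority.
REPROGRAMMING_COMPOSITION = {
    "iPSC": 0.048,
    "NPC": 0.565,
    "pre-neuron-1": 0.125,
    "pre-neuron-2": 0.054,
    "cell-cycle": 0.195,
    "other": 0.013,
}

_NPC_MEDIAN = 124.0
_IPSC_MEDIAN = 248.0
_UC_MEDIAN = 744.0
# pre-neurons share the NPC threshold; cell-cycle and the uncharacterised
# remainder sit at the NPC/iPSC geometric mean
_MID_MEDIAN = math.sqrt(_NPC_MEDIAN * _IPSC_MEDIAN)

PUMP_MAX_WSS_PA = 1000.0


@dataclass(frozen=True)
class AdhesionModel:
    """Per-lineage critical-WSS distributions and detachment kinetics.

    ``medians`` are the lineage median critical stresses in Pa; per-cell
    thresholds are log-normal around them with log-scale dispersion
    ``sigma``.  ``k`` (1/s) and ``m`` set the excess-stress hazard
    ``k t ((tau/tau_c - 1)+)**m``.
    """

    medians: dict[str, float] = field(
        default_factory=lambda: {
            "NPC": _NPC_MEDIAN,
            "iPSC": _IPSC_MEDIAN,
            "UC": _UC_MEDIAN,
            "pre-neuron-1": _NPC_MEDIAN,
            "pre-neuron-2": _NPC_MEDIAN,
            "cell-cycle": _MID_MEDIAN,
            "other": _MID_MEDIAN,
        }
    )
    sigma: float = 0.15
    k: float = 1.0
    m: float = 1.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.medians.values()):
            raise ValueError("all median critical stresses must be positive")
        if self.sigma < 0 or self.k <= 0 or self.m <= 0:
            raise ValueError("need sigma >= 0, k > 0, m > 0")

    def sample_critical_wss(self, lineages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        med = np.array([self.medians[l] for l in lineages])
        if self.sigma == 0:
            return med
        return med * np.exp(self.sigma * rng.standard_normal(med.size))

    def detach_probability(self, tau: float, duration: float, tau_c: np.ndarray) -> np.ndarray:
        excess = np.clip(tau / tau_c - 1.0, 0.0, None)
        return 1.0 - np.exp(-self.k * duration * excess**self.m)


@dataclass(frozen=True)
class ExposureStep:
    """One shear pulse: stress ``wss`` (Pa) for ``duration`` (s).

    ``collect=True`` marks the detachate of this step as harvested material.
    Stresses above the pump envelope are allowed (simulation can explore
    beyond hardware) but warn.
    """

    wss: float
    duration: float = 1.0
    collect: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.wss) or self.wss < 0:
            raise ValueError(f"wss must be finite and >= 0, got {self.wss!r}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration!r}")
        if self.wss > PUMP_MAX_WSS_PA:
            warnings.warn(
                f"WSS {self.wss} Pa exceeds the pump envelope (0 to {PUMP_MAX_WSS_PA:.0f} Pa)",
                stacklevel=2,
            )


@dataclass
class Colony:
    """Synthetic colony: one row per cell (x, y um; layer; lineage; critical_wss Pa)."""

    cells: pd.DataFrame
    radius: float
    seed: int
    adhesion: AdhesionModel = field(default_factory=AdhesionModel)
    shield_pitch: float = 20.0  # (x, y) neighbourhood size for stacking, um

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def composition(self, label: str = "colony") -> CompositionTable:
        counts = self.cells["lineage"].value_counts().to_dict()
        return CompositionTable.from_counts(counts, label=label)


@dataclass
class SelectionOutcome:
    """Result of one or more exposure steps applied to a colony.

    ``detached`` and ``retained`` partition the initial population;
    ``harvested`` is the fraction kept as product (collect-flagged
    detachates, or the retained population for negative selection).
    """

    colony: Colony
    steps: list[ExposureStep]
    detached: pd.DataFrame
    retained: pd.DataFrame
    harvested: pd.DataFrame
    step_detached: list[pd.DataFrame]
    compositions: dict[str, CompositionTable]
    selected_area_um2: float

    def harvested_fraction(self, lineage: str) -> float:
        if len(self.harvested) == 0:
            return 0.0
        return float((self.harvested["lineage"] == lineage).mean())


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(_seedseq(seed))


def make_colony(
    composition: dict[str, float] | None = None,
    n_cells: int = 1000,
    radius: float = 500.0,
    layering: float = 0.8,
    adhesion: AdhesionModel | None = None,
    seed: int = 0,
    layer_probs=(0.5, 0.3, 0.2),
    shield_pitch: float = 20.0,
) -> Colony:
    """Build a layered synthetic colony.

    Lineages are assigned multinomially from ``composition`` (default: the
    reprogramming-colony mixture).  Layer 0 is the surface-attached
    monolayer; ``layering`` in [0, 1] boosts the probability that an iPSC
    sits in layer 0 (0 = no bias, 1 = all iPSCs at the bottom), emulating
    the observed bottom-layer distribution of pluripotent cells under
    stacked NPC/pre-neuron multilayers.
    """
    composition = dict(composition or REPROGRAMMING_COMPOSITION)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 <= layering <= 1:
        raise ValueError("layering must lie in [0, 1]")
    s = sum(composition.values())
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"composition fractions must sum to 1 +/- 1e-6, got {s}")
    adhesion = adhesion or AdhesionModel()
    rng = _rng(seed)

    names = list(composition)
    counts = rng.multinomial(n_cells, [composition[k] for k in names])
    lineage = np.repeat(names, counts)
    rng.shuffle(lineage)

    # uniform positions on the disc
    rr = radius * np.sqrt(rng.random(n_cells))
    th = 2.0 * np.pi * rng.random(n_cells)
    x, y = rr * np.cos(th), rr * np.sin(th)

    base = np.asarray(layer_probs, float)
    base = base / base.sum()
    ipsc_probs = base.copy()
    ipsc_probs[0] = base[0] + layering * (1.0 - base[0])
    if base[0] < 1.0:
        ipsc_probs[1:] = base[1:] * (1.0 - ipsc_probs[0]) / (1.0 - base[0])
    u = rng.random(n_cells)
    is_ipsc = lineage == "iPSC"
    layer = np.where(
        is_ipsc,
        np.searchsorted(np.cumsum(ipsc_probs), u),
        np.searchsorted(np.cumsum(base), u),
    ).astype(int)
    layer = np.clip(layer, 0, len(base) - 1)
    if not np.any(layer == 0):  # a colony always has a surface-attached layer
        layer[0] = 0

    tau_c = adhesion.sample_critical_wss(lineage, rng)

    cells = pd.DataFrame(
        {"x": x, "y": y, "layer": layer, "lineage": lineage, "critical_wss": tau_c}
    )
    return Colony(cells=cells, radius=radius, seed=seed, adhesion=adhesion, shield_pitch=shield_pitch)


def _exposure_mask(
    cells: pd.DataFrame,
    step: ExposureStep,
    adhesion: AdhesionModel,
    rng: np.random.Generator,
    pitch: float,
) -> np.ndarray:
    """Boolean mask of cells detached by one step (top-down shielded sweeps)."""
    n = len(cells)
    if n == 0:
        return np.zeros(0, bool)
    layer = cells["layer"].to_numpy()
    tau_c = cells["critical_wss"].to_numpy()
    bx = np.floor(cells["x"].to_numpy() / pitch).astype(np.int64)
    by = np.floor(cells["y"].to_numpy() / pitch).astype(np.int64)
    _, bin_code = np.unique(bx * 1_000_003 + by, return_inverse=True)
    n_bins = bin_code.max() + 1

    p = adhesion.detach_probability(step.wss, step.duration, tau_c)
    u = rng.random(n)  # one draw per cell per step (common random numbers)

    retained = np.ones(n, bool)
    tested = np.zeros(n, bool)
    while True:
        top = np.full(n_bins, -1, dtype=np.int64)
        np.maximum.at(top, bin_code[retained], layer[retained])
        exposed = retained & (layer == top[bin_code]) & ~tested
        if not exposed.any():
            break
        tested[exposed] = True
        detach = exposed & (u < p)
        if not detach.any():
            break
        retained[detach] = False
    return ~retained


def apply_exposure(colony: Colony, step: ExposureStep, seed: int = 0) -> SelectionOutcome:
    """Apply a single shear pulse; detachate is the harvested fraction."""
    return run_protocol(colony, [replace(step, collect=True)], seed=seed)


def run_protocol(
    colony: Colony,
    protocol: list[ExposureStep],
    seed: int = 0,
    harvest: str = "collected",
) -> SelectionOutcome:
    """Apply the steps in order to the evolving retained population.

    ``harvest='collected'`` pools the detachates of collect-flagged steps
    (positive selection); ``harvest='retained'`` keeps the survivors
    (negative selection).
    """
    if not protocol:
        raise ValueError("protocol must contain at least one exposure step")
    if harvest not in ("collected", "retained"):
        raise ValueError(f"unknown harvest mode {harvest!r}")
    ss = _seedseq(seed)
    child = ss.spawn(len(protocol))

    current = colony.cells
    step_detached: list[pd.DataFrame] = []
    for stp, cs in zip(protocol, child):
        mask = _exposure_mask(current, stp, colony.adhesion, np.random.default_rng(cs), colony.shield_pitch)
        step_detached.append(current[mask])
        current = current[~mask]

    detached = pd.concat(step_detached) if step_detached else colony.cells.iloc[:0]
    retained = current
    if harvest == "collected":
        picked = [d for stp, d in zip(protocol, step_detached) if stp.collect]
        harvested = pd.concat(picked) if picked else colony.cells.iloc[:0]
    else:
        harvested = retained

    area_per_cell = np.pi * colony.radius**2 / colony.n_cells
    compositions = {"initial": colony.composition("initial")}
    for name, df in (("detached", detached), ("retained", retained), ("harvested", harvested)):
        if len(df):
            compositions[name] = CompositionTable.from_counts(
                df["lineage"].value_counts().to_dict(), label=name
            )
    for i, d in enumerate(step_detached):
        if len(d):
            compositions[f"step{i}_detached"] = CompositionTable.from_counts(
                d["lineage"].value_counts().to_dict(), label=f"step{i}_detached"
            )

    return SelectionOutcome(
        colony=colony,
        steps=list(protocol),
        detached=detached,
        retained=retained,
        harvested=harvested,
        step_detached=step_detached,
        compositions=compositions,
        selected_area_um2=float(len(harvested) * area_per_cell),
    )


def single_run_protocol(wss: float = 500.0, duration: float = 1.0) -> list[ExposureStep]:
    """Conventional single pulse: harvest everything detached at ``wss``."""
    return [ExposureStep(wss, duration, collect=True)]


def dual_run_protocol(
    discard_wss: float = 250.0, harvest_wss: float = 500.0, duration: float = 1.0
) -> list[ExposureStep]:
    """Discard the low-stress detachate, then harvest the high-stress one."""
    return [
        ExposureStep(discard_wss, duration, collect=False),
        ExposureStep(harvest_wss, duration, collect=True),
    ]


def negative_selection(
    colony: Colony, wss: float = 250.0, passes: int = 3, seed: int = 0
) -> SelectionOutcome:
    """Repeated low-WSS passes; the retained population is the product."""
    if passes < 0:
        raise ValueError("passes must be >= 0")
    if passes == 0:
        empty = colony.cells.iloc[:0]
        return SelectionOutcome(
            colony=colony,
            steps=[],
            detached=empty,
            retained=colony.cells,
            harvested=colony.cells,
            step_detached=[],
            compositions={
                "initial": colony.composition("initial"),
                "retained": colony.composition("retained"),
                "harvested": colony.composition("harvested"),
            },
            selected_area_um2=float(np.pi * colony.radius**2),
        )
    protocol = [ExposureStep(wss, 1.0, collect=False) for _ in range(passes)]
    return run_protocol(colony, protocol, seed=seed, harvest="retained")


def selected_area_curve(
    lineage: str,
    adhesion: AdhesionModel | None = None,
    wss_grid=None,
    duration: float = 1.0,
    n_rep: int = 50,
    seed: int = 0,
    n_cells: int = 400,
    radius: float = 500.0,
) -> pd.DataFrame:
    """Mean detached-area fraction vs applied WSS for a homogeneous monolayer.

    For each replicate a fresh single-lineage monolayer colony is built and
    swept over ``wss_grid`` with common random numbers, so every replicate's
    curve (and hence the mean) is monotone non-decreasing in tau.  Returns a
    DataFrame with columns ``wss`` and ``area_fraction``.
    """
    adhesion = adhesion or AdhesionModel()
    if wss_grid is None:
        wss_grid = np.linspace(0.0, 2.0 * adhesion.medians[lineage], 21)
    wss_grid = np.asarray(wss_grid, float)
    if wss_grid.size == 0:
        raise ValueError("wss_grid must not be empty")

    ss = _seedseq(seed)
    fractions = np.zeros((n_rep, wss_grid.size))
    for i, cs in enumerate(ss.spawn(n_rep)):
        colony_seed, exposure_seed = cs.spawn(2)
        colony = make_colony(
            composition={lineage: 1.0},
            n_cells=n_cells,
            radius=radius,
            layering=0.0,
            adhesion=adhesion,
            seed=colony_seed,
            layer_probs=(1.0,),  # monolayer
        )
        tau_c = colony.cells["critical_wss"].to_numpy()
        u = np.random.default_rng(exposure_seed).random(n_cells)
        for j, tau in enumerate(wss_grid):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # grids may probe past the pump envelope
                p = adhesion.detach_probability(tau, duration, tau_c)
            fractions[i, j] = float((u < p).mean())
    return pd.DataFrame({"wss": wss_grid, "area_fraction": fractions.mean(axis=0)})


def onset_wss(curve: pd.DataFrame, level: float = 0.01) -> float:
    """First grid stress where the selected-area fraction exceeds ``level``.

    The operational "selection threshold" of a lineage; NaN if never reached.
    """
    above = curve[curve["area_fraction"] > level]
    return float(above["wss"].iloc[0]) if len(above) else float("nan")


def fit_log_logistic(
    curve: pd.DataFrame,
    adhesion: AdhesionModel | None = None,
    duration: float = 1.0,
) -> dict[str, float]:
    """Fit a log-logistic sigmoid to a selected-area curve and back out the median.

    The sigmoid ``F(tau) = 1 / (1 + (tau/alpha)^-beta)`` places its midpoint
    ``alpha`` at the 50% detachment stress.  Under the excess-stress hazard
    that midpoint sits above the critical-WSS median by a known kinetic
    factor: P = 0.5 when ``k t (tau/median - 1)^m = ln 2``, i.e.
    ``tau_50 = median (1 + (ln2/(k t))^(1/m))``.  The returned
    ``median_estimate`` divides alpha by that factor (duration is taken from
    the curve's construction, default 1 s).
    """
    adhesion = adhesion or AdhesionModel()
    tau = curve["wss"].to_numpy()
    f = curve["area_fraction"].to_numpy()
    ok = tau > 0
    if ok.sum() < 3:
        raise ValueError("need at least 3 positive-stress points to fit")

    def model(t, alpha, beta):
        return 1.0 / (1.0 + (t / alpha) ** (-beta))

    alpha0 = float(np.interp(0.5, f[ok], tau[ok])) if f.max() > 0.5 else float(tau[ok].max())
    popt, _ = curve_fit(
        model, tau[ok], f[ok], p0=[alpha0, 4.0], bounds=([1e-6, 0.1], [1e6, 100.0]), maxfev=20000
    )
    alpha, beta = float(popt[0]), float(popt[1])
    kinetic = 1.0 + (math.log(2.0) / (adhesion.k * duration)) ** (1.0 / adhesion.m)
    return {"alpha": alpha, "beta": beta, "median_estimate": alpha / kinetic}
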