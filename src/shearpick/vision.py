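"""Synthetic plate images, colony segmentation, qualification, pick lists.

The selection robot needs (x, y) stage targets for colonies that are safe to
aspirate: large enough, not two colonies merged into one blob, far enough
from neighbours that the pin footprint (radius r0) plus a clearance ring
touches nothing else, and clear of the well edge.  This module generates
seeded synthetic bright-field-like plates with known ground truth, segments
colonies (Gaussian smoothing, Otsu threshold, hole filling, connected
components), applies the qualification rules, and emits a serpentine-ordered
pick list in stage micrometres.

Coordinate convention: image origin at the top-left pixel centre, x
rightward (columns), y downward (rows), 0-based; stage frame = pixel
coordinates scaled by ``pixel_size`` plus a configurable offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "PlateImage",
    "ColonyRecord",
    "QualificationRules",
    "PickList",
    "generate_plate_image",
    "read_image",
    "write_image",
    "segment_colonies",
    "qualify_colonies",
    "make_picklist",
]

DEFAULT_PIXEL_SIZE = 3.25  # um per pixel
_U16_MAX = 65535


@dataclass
class PlateImage:
    """16-bit grayscale plate view with its spatial calibration."""

    intensity: np.ndarray  # uint16, shape (rows, cols)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    well_center_px: tuple[float, float] | None = None  # (x, y)
    well_radius_um: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.intensity.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.intensity.shape}")
        if self.well_center_px is None:
            rows, cols = self.intensity.shape
            self.well_center_px = ((cols - 1) / 2.0, (rows - 1) / 2.0)
        if self.well_radius_um is None:
            rows, cols = self.intensity.shape
            self.well_radius_um = 0.48 * min(rows, cols) * self.pixel_size


@dataclass
class ColonyRecord:
    """One segmented colony with geometry and qualification status."""

    label: int
    centroid_px: tuple[float, float]  # (x, y)
    centroid_um: tuple[float, float]
    area_um2: float
    equivalent_diameter_um: float
    solidity: float
    qualified: bool | None = None
    reasons: list[str] = field(default_factory=list)

    @property
    def radius_um(self) -> float:
        return self.equivalent_diameter_um / 2.0


@dataclass(frozen=True)
class QualificationRules:
    """Pickability rules; lengths in um.

    A colony qualifies iff its area lies in [min_area, max_area], its
    solidity is at least ``solidity_min`` (low solidity flags merged
    colonies), every other colony is at least ``2*footprint_radius +
    clearance`` away edge-to-edge, and its own edge clears the well wall by
    ``edge_margin`` (default footprint radius + 100 um).

    ``solidity_min`` defaults to 0.9: the union of two equal discs has
    solidity between ~0.88 (tangent) and 1 (coincident), so a threshold
    must sit above 0.88 to catch weakly fused colony pairs while isolated
    noisy discs measure >= 0.97.
    """

    min_area_um2: float = 1.0e4
    max_area_um2: float = 1.5e6
    footprint_radius: float = 500.0
    clearance: float = 200.0
    edge_margin: float = 600.0
    solidity_min: float = 0.9


@dataclass
class PickList:
    """Ordered stage targets for the picking arm."""

    targets: pd.DataFrame  # columns id, x_um, y_um
    footprint_radius: float
    clearance: float

    def min_separation(self) -> float:
        xy = self.targets[["x_um", "y_um"]].to_numpy()
        if len(xy) < 2:
            return math.inf
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        return float(d[np.triu_indices(len(xy), 1)].min())


def generate_plate_image(
    n_colonies: int = 6,
    radius_range: tuple[float, float] = (150.0, 350.0),
    seed: int = 0,
    noise: float = 0.005,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    shape: tuple[int, int] = (2048, 2048),
    min_edge_separation_um: float = 400.0,
    background: int = 8000,
    contrast: int = 14000,
    max_attempts: int = 2000,
) -> tuple[PlateImage, pd.DataFrame]:
    """Seeded synthetic plate: textured bright discs on a darker background.

    Returns the image and a ground-truth table (x_px, y_px, x_um, y_um,
    radius_um).  Colony centres are rejection-sampled inside the well so
    that edge-to-edge separations are at least ``min_edge_separation_um``;
    exceeding ``max_attempts`` raises a generation error.
    """
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, cols = shape
    img = np.full(shape, float(background))
    img += rng.normal(0.0, noise * _U16_MAX, size=shape)

    well_center = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    well_radius_um = 0.48 * min(rows, cols) * pixel_size

    placed: list[tuple[float, float, float]] = []  # x_um, y_um, r_um
    attempts = 0
    while len(placed) < n_colonies:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_colonies} colonies after {max_attempts} attempts"
            )
        r_um = rng.uniform(*radius_range)
        max_c = well_radius_um - r_um - 2 * pixel_size
        if max_c <= 0:
            raise RuntimeError("colony radius exceeds the well")
        rad = max_c * math.sqrt(rng.random())
        th = 2 * math.pi * rng.random()
        cx_um = well_center[0] * pixel_size + rad * math.cos(th)
        cy_um = well_center[1] * pixel_size + rad * math.sin(th)
        ok = all(
            math.hypot(cx_um - px, cy_um - py) - r_um - pr >= min_edge_separation_um
            for px, py, pr in placed
        )
        if ok:
            placed.append((cx_um, cy_um, r_um))

    for cx_um, cy_um, r_um in placed:
        cx_px, cy_px = cx_um / pixel_size, cy_um / pixel_size
        r_px = r_um / pixel_size
        # paint only the bounding box of the colony
        x0 = max(0, int(cx_px - r_px) - 3)
        x1 = min(cols, int(cx_px + r_px) + 4)
        y0 = max(0, int(cy_px - r_px) - 3)
        y1 = min(rows, int(cy_px + r_px) + 4)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - cx_px, yy - cy_px)
        # soft 2-px edge so segmentation sees a realistic (not aliased) rim
        disc = np.clip((r_px - dist) / 2.0 + 0.5, 0.0, 1.0)
        texture = 1.0 + 0.08 * rng.standard_normal(size=disc.shape)
        img[y0:y1, x0:x1] += contrast * disc * texture

    img = np.clip(img, 0, _U16_MAX).astype(np.uint16)
    image = PlateImage(
        intensity=img,
        pixel_size=pixel_size,
        well_center_px=well_center,
        well_radius_um=well_radius_um,
        seed=seed,
    )
    truth = pd.DataFrame(
        [
            {
                "x_px": cx / pixel_size,
                "y_px": cy / pixel_size,
                "x_um": cx,
                "y_um": cy,
                "radius_um": r,
            }
            for cx, cy, r in placed
        ],
        columns=["x_px", "y_px", "x_um", "y_um", "radius_um"],
    )
    return image, truth


def write_image(image: PlateImage, path) -> None:
    """Write the 16-bit grayscale image as PNG or TIFF (by extension)."""
    iio.imwrite(path, image.intensity)


def read_image(path, pixel_size: float = DEFAULT_PIXEL_SIZE, **kwargs) -> PlateImage:
    """Read a 16-bit grayscale PNG/TIFF into a :class:`PlateImage`."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr[..., 0]
    return PlateImage(intensity=arr.astype(np.uint16), pixel_size=pixel_size, **kwargs)


def segment_colonies(
    image: PlateImage,
    smooth_sigma_px: float = 2.0,
    min_area_um2: float = 5.0e3,
    min_contrast: float = 2000.0,
) -> list[ColonyRecord]:
    """Detect colonies: smooth, Otsu-threshold, fill holes, label, filter.

    Returns one record per connected component larger than ``min_area_um2``.
    A foreground/background mean-intensity contrast below ``min_contrast``
    counts (the situation on a blank plate, where Otsu would split noise) is
    treated as "no colonies".
    """
    arr = np.asarray(image.intensity)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    sm = gaussian(arr.astype(float), sigma=smooth_sigma_px, preserve_range=True)
    thr = threshold_otsu(sm)
    mask = sm > thr
    if not mask.any() or mask.all():
        return []
    if sm[mask].mean() - sm[~mask].mean() < min_contrast:
        return []
    mask = ndimage.binary_fill_holes(mask)
    labels = sk_label(mask)
    min_px = max(1, int(round(min_area_um2 / image.pixel_size**2)))

    records = []
    for prop in regionprops(labels):
        if prop.area < min_px:
            continue
        cy, cx = prop.centroid  # row, col
        records.append(
            ColonyRecord(
                label=int(prop.label),
                centroid_px=(float(cx), float(cy)),
                centroid_um=(float(cx) * image.pixel_size, float(cy) * image.pixel_size),
                area_um2=float(prop.area) * image.pixel_size**2,
                equivalent_diameter_um=float(prop.equivalent_diameter_area) * image.pixel_size,
                solidity=float(prop.solidity),
            )
        )
    return records


def qualify_colonies(
    records: list[ColonyRecord],
    image: PlateImage,
    rules: QualificationRules | None = None,
) -> list[ColonyRecord]:
    """Flag each record as pickable or not; reasons list every failed rule.

    Rule identifiers: ``area-small``, ``area-large``, ``merged`` (low
    solidity), ``proximity`` (another colony inside the footprint +
    clearance ring), ``well-edge``.
    """
    rules = rules or QualificationRules()
    if image.well_radius_um is not None and image.well_radius_um <= rules.footprint_radius:
        raise ValueError(
            f"well radius {image.well_radius_um} um must exceed the footprint "
            f"radius {rules.footprint_radius} um"
        )
    wx = image.well_center_px[0] * image.pixel_size
    wy = image.well_center_px[1] * image.pixel_size
    min_sep = 2.0 * rules.footprint_radius + rules.clearance

    for i, rec in enumerate(records):
        reasons = []
        if rec.area_um2 < rules.min_area_um2:
            reasons.append("area-small")
        if rec.area_um2 > rules.max_area_um2:
            reasons.append("area-large")
        if rec.solidity < rules.solidity_min:
            reasons.append("merged")
        for j, other in enumerate(records):
            if j == i:
                continue
            gap = (
                math.hypot(
                    rec.centroid_um[0] - other.centroid_um[0],
                    rec.centroid_um[1] - other.centroid_um[1],
                )
                - rec.radius_um
                - other.radius_um
            )
            if gap < min_sep:
                reasons.append("proximity")
                break
        if image.well_radius_um is not None:
            edge_clear = (
                image.well_radius_um
                - math.hypot(rec.centroid_um[0] - wx, rec.centroid_um[1] - wy)
                - rec.radius_um
            )
            if edge_clear < rules.edge_margin:
                reasons.append("well-edge")
        rec.reasons = reasons
        rec.qualified = not reasons
    return records


def make_picklist(
    records: list[ColonyRecord],
    image: PlateImage,
    stage_offset: tuple[float, float] = (0.0, 0.0),
    band_height_um: float = 1000.0,
    rules: QualificationRules | None = None,
    path=None,
) -> PickList:
    """Stage targets for the qualified colonies, serpentine-ordered.

    Pixel centroids are converted to stage um (``px * pixel_size + offset``)
    and sorted into horizontal bands of ``band_height_um``, alternating the
    x-direction per band to minimise arm travel.  If ``path`` is given the
    list is written as CSV with columns ``id,x_um,y_um`` (coordinate
    convention documented in ``#`` header lines).
    """
    rules = rules or QualificationRules()
    picked = [r for r in records if r.qualified is not False]
    rows = [
        {
            "id": r.label,
            "x_um": r.centroid_px[0] * image.pixel_size + stage_offset[0],
            "y_um": r.centroid_px[1] * image.pixel_size + stage_offset[1],
        }
        for r in picked
    ]
    df = pd.DataFrame(rows, columns=["id", "x_um", "y_um"])
    if len(df):
        band = np.floor(df["y_um"].to_numpy() / band_height_um).astype(int)
        df["_band"] = band
        df["_x_key"] = np.where(band % 2 == 0, df["x_um"], -df["x_um"])
        df = df.sort_values(["_band", "_x_key"]).drop(columns=["_band", "_x_key"])
        df = df.reset_index(drop=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write("# stage frame: image origin top-left, x rightward, y downward\n")
            fh.write(
                f"# x_um = x_px * {image.pixel_size} + {stage_offset[0]}; "
                f"y_um = y_px * {image.pixel_size} + {stage_offset[1]}\n"
            )
            df.to_csv(fh, index=False)
    return PickList(targets=df, footprint_radius=rules.footprint_radius, clearance=rules.clearance)
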