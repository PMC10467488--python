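"""Fluorophore-chip well classification and detection-sensitivity surfaces.

The chip holds radial rings of wells of graded diameters, each ring
spanning a fixed fluorophore concentration series with one zero-
concentration control well.  Device images of the chip (optionally under
tissue-mimicking thin films of increasing thickness) are analyzed by:

1. projecting the physical chip layout into pixel ROIs (``build_mask``),
2. classifying every well as SAT / FL / NFL — saturated if its mean ROI
   luminance reaches a threshold, otherwise fluorescent if its Delta E 2000
   against the same-size control well exceeds a threshold
   (``classify_well`` / ``classify_image``),
3. aggregating calls across film depths into a sensitivity surface over
   (well diameter, concentration, depth) with derived detection minima
   (``sensitivity_surface``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

from .color import ROI, delta_e_2000, normalize_image, relative_luminance, roi_mask, roi_mean_color, srgb_to_lab, srgb_to_xyY

__all__ = [
    "DEFAULT_CONCENTRATIONS",
    "ChipLayout",
    "Registration",
    "WellROI",
    "ClassifierConfig",
    "WellCall",
    "SensitivitySurface",
    "build_mask",
    "classify_well",
    "classify_image",
    "sensitivity_surface",
    "estimate_registration_center",
]

#: Default fluorophore concentration series per angular position, ug/mL
#: (decreasing clockwise; the final zero is the control well).
DEFAULT_CONCENTRATIONS = (450.0, 300.0, 180.0, 120.0, 80.0, 55.0, 40.0, 25.0, 16.0, 0.0)

#: Default ring geometry: (well diameter um, ring radius um).  Ring radii
#: are package defaults chosen so wells never overlap and the chip fits a
#: 50.8 mm wafer; override via ``ChipLayout(rings=...)`` to match a mold.
DEFAULT_RINGS = ((100.0, 4000.0), (250.0, 8000.0), (500.0, 12000.0),
                 (1000.0, 16000.0), (5000.0, 20500.0))


@dataclass(frozen=True)
class ChipLayout:
    """Geometric model of the fluorophore chip.

    ``rings`` lists (well diameter um, ring radius um) from the chip
    center; every ring holds ``wells_per_ring`` wells at equal angular
    spacing, all wells of a given size equidistant from the center.
    Angular position ``j`` holds ``concentrations[j]`` in every ring
    (radial concentration columns), with exactly one zero-concentration
    control per ring.
    """

    rings: tuple[tuple[float, float], ...] = DEFAULT_RINGS
    wells_per_ring: int = 10
    chip_thickness_um: float = 2000.0
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS

    def __post_init__(self) -> None:
        if len(self.concentrations) != self.wells_per_ring:
            raise ValueError("need one concentration per angular position")
        if sum(1 for c in self.concentrations if c == 0.0) != 1:
            raise ValueError("exactly one zero-concentration control per ring")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        for d, r in self.rings:
            if d <= 0 or r <= 0:
                raise ValueError("well diameters and ring radii must be > 0")
        # wells within a ring must not touch: chord spacing > well diameter
        for d, r in self.rings:
            chord = 2.0 * r * math.sin(math.pi / self.wells_per_ring)
            if chord <= d:
                raise ValueError(
                    f"{d:g} um wells at ring radius {r:g} um would overlap"
                )

    @property
    def control_index(self) -> int:
        return self.concentrations.index(0.0)

    @property
    def extent_um(self) -> float:
        """Radius of the smallest circle containing all wells."""
        return max(r + d / 2.0 for d, r in self.rings)


@dataclass(frozen=True)
class Registration:
    """Mapping from chip coordinates (um) to image pixels."""

    center_row: float
    center_col: float
    um_per_px: float
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px scale must be > 0")


@dataclass(frozen=True)
class WellROI:
    """One chip well projected into the image."""

    ring_diameter_um: float
    angular_index: int
    concentration: float
    roi: ROI
    is_control: bool


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for the SAT / FL / NFL decision.

    ``y_sat`` is the relative-luminance saturation threshold (xyY Y, in
    (0, 1]); ``delta_e_fl`` the Delta E 2000 threshold against the control
    well above which a non-saturated well is called fluorescent.  Both are
    unprinted device-specific settings; the defaults (near-full-scale
    luminance, a few just-noticeable differences) must be reported with any
    result.  ``sat_on_max`` evaluates saturation on the maximum pixel
    luminance in the ROI instead of the ROI mean.
    """

    y_sat: float = 0.98
    delta_e_fl: float = 3.0
    sat_on_max: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.y_sat <= 1.0:
            raise ValueError("y_sat must lie in (0, 1]")
        if self.delta_e_fl <= 0:
            raise ValueError("delta_e_fl must be > 0")


@dataclass(frozen=True)
class WellCall:
    """Per-well classification with the evidence used."""

    well: WellROI
    call: str  # "SAT" | "FL" | "NFL"
    y_well: float
    delta_e_vs_control: float | None
    depth_um: float = 0.0


@dataclass
class SensitivitySurface:
    """Call table over (well diameter, concentration, depth) plus detection minima."""

    calls: pd.DataFrame  # columns: ring_diameter_um, angular_index, concentration, depth_um, y_well, delta_e, call
    y_sat: float
    delta_e_fl: float

    def min_detectable_concentration(self) -> pd.DataFrame:
        """Per (diameter, depth): the smallest nonzero concentration with a
        detected (non-NFL) call; NaN if nothing was detected."""
        det = self.calls[(self.calls["call"] != "NFL") & (self.calls["concentration"] > 0)]
        out = (
            det.groupby(["ring_diameter_um", "depth_um"])["concentration"]
            .min()
            .rename("min_detectable_concentration")
            .reset_index()
        )
        grid = self.calls[["ring_diameter_um", "depth_um"]].drop_duplicates()
        return grid.merge(out, how="left", on=["ring_diameter_um", "depth_um"])

    def max_detectable_depth(self) -> pd.DataFrame:
        """Per (diameter, concentration > 0): the deepest film at which the
        well was still detected; NaN if never detected."""
        det = self.calls[(self.calls["call"] != "NFL") & (self.calls["concentration"] > 0)]
        out = (
            det.groupby(["ring_diameter_um", "concentration"])["depth_um"]
            .max()
            .rename("max_detectable_depth")
            .reset_index()
        )
        grid = self.calls[self.calls["concentration"] > 0][
            ["ring_diameter_um", "concentration"]
        ].drop_duplicates()
        return grid.merge(out, how="left", on=["ring_diameter_um", "concentration"])

    def to_summary(self) -> dict:
        return {
            "thresholds": {"y_sat": self.y_sat, "delta_e_fl": self.delta_e_fl},
            "n_wells": int(len(self.calls)),
            "call_counts": self.calls["call"].value_counts().to_dict(),
            "min_detectable_concentration": self.min_detectable_concentration().to_dict(
                orient="records"
            ),
            "max_detectable_depth": self.max_detectable_depth().to_dict(orient="records"),
        }


def well_centers_um(layout: ChipLayout, rotation_deg: float = 0.0) -> list[tuple[float, float, int, float]]:
    """Physical (x um, y um, angular index, ring diameter) for every well.

    Angular index increases clockwise starting at twelve o'clock (matching
    a concentration series loaded clockwise); x is to the right, y up.
    """
    out = []
    step = 360.0 / layout.wells_per_ring
    for diameter, ring_radius in layout.rings:
        for j in range(layout.wells_per_ring):
            theta = math.radians(90.0 - j * step + rotation_deg)
            out.append((ring_radius * math.cos(theta), ring_radius * math.sin(theta), j, diameter))
    return out


def build_mask(
    layout: ChipLayout,
    image_shape: tuple[int, int],
    registration: Registration,
    *,
    roi_shrink: float = 0.8,
) -> list[WellROI]:
    """Project the chip layout into deterministic pixel ROIs.

    ROI radius is the projected well radius scaled by ``roi_shrink`` (< 1
    keeps the ROI clear of well edges and point-spread blur).  Wells whose
    full projected extent falls outside the image raise a ``ValueError``
    listing every offender.
    """
    if not 0.0 < roi_shrink <= 1.0:
        raise ValueError("roi_shrink must lie in (0, 1]")
    h, w = image_shape[:2]
    wells: list[WellROI] = []
    offenders: list[str] = []
    for x_um, y_um, j, diameter in well_centers_um(layout, registration.rotation_deg):
        row = registration.center_row - y_um / registration.um_per_px
        col = registration.center_col + x_um / registration.um_per_px
        well_radius_px = (diameter / 2.0) / registration.um_per_px
        if (
            row - well_radius_px < 0
            or row + well_radius_px > h - 1
            or col - well_radius_px < 0
            or col + well_radius_px > w - 1
        ):
            offenders.append(f"ring {diameter:g} um, index {j}")
            continue
        conc = layout.concentrations[j]
        wells.append(
            WellROI(
                ring_diameter_um=diameter,
                angular_index=j,
                concentration=conc,
                roi=ROI(row, col, well_radius_px * roi_shrink,
                        label=f"d{diameter:g}um_i{j}"),
                is_control=(j == layout.control_index),
            )
        )
    if offenders:
        raise ValueError(
            "wells project outside the image: " + "; ".join(offenders)
        )
    return wells


def classify_well(
    image: np.ndarray,
    well: WellROI,
    control: WellROI,
    cfg: ClassifierConfig,
    *,
    depth_um: float = 0.0,
) -> WellCall:
    """Three-way SAT / FL / NFL call for one well.

    Saturation is decided first on the xyY luminance of the ROI mean color
    (or the maximum pixel luminance with ``cfg.sat_on_max``); non-saturated
    wells are called FL when their Delta E 2000 against the mean color of
    the same-size control well exceeds ``cfg.delta_e_fl``, else NFL.
    Control wells run through the same rule (and come out NFL on
    well-formed data).
    """
    if not control.is_control:
        raise ValueError("reference well is not a control well")
    if control.ring_diameter_um != well.ring_diameter_um:
        raise ValueError(
            "control well ring size does not match the well under test "
            f"({control.ring_diameter_um:g} vs {well.ring_diameter_um:g} um)"
        )
    mean_color = roi_mean_color(image, well.roi)
    y_mean = relative_luminance(mean_color)
    if cfg.sat_on_max:
        img = normalize_image(image)
        mask = roi_mask(img.shape[:2], well.roi)
        # per-pixel xyY luminance; linearization is monotone per channel but
        # luminance mixes channels, so compute it exactly
        from skimage import color as _skc

        y_gate = float(_skc.rgb2xyz(img[mask].reshape(-1, 1, 3))[:, 0, 1].max())
    else:
        y_gate = y_mean
    if y_gate >= cfg.y_sat:
        return WellCall(well=well, call="SAT", y_well=y_mean,
                        delta_e_vs_control=None, depth_um=depth_um)
    de = delta_e_2000(
        srgb_to_lab(mean_color), srgb_to_lab(roi_mean_color(image, control.roi))
    )
    call = "FL" if de > cfg.delta_e_fl else "NFL"
    return WellCall(well=well, call=call, y_well=y_mean,
                    delta_e_vs_control=de, depth_um=depth_um)


def classify_image(
    image: np.ndarray,
    wells: Sequence[WellROI],
    cfg: ClassifierConfig,
    *,
    depth_um: float = 0.0,
) -> list[WellCall]:
    """Classify every well in one image against its ring's control well."""
    controls: dict[float, WellROI] = {}
    for w in wells:
        if w.is_control:
            if w.ring_diameter_um in controls:
                raise ValueError(
                    f"multiple control wells for ring {w.ring_diameter_um:g} um"
                )
            controls[w.ring_diameter_um] = w
    missing = {w.ring_diameter_um for w in wells} - set(controls)
    if missing:
        raise ValueError(f"missing control well for ring(s): {sorted(missing)}")
    return [
        classify_well(image, w, controls[w.ring_diameter_um], cfg, depth_um=depth_um)
        for w in wells
    ]


def calls_to_frame(calls: Sequence[WellCall]) -> pd.DataFrame:
    rows = [
        {
            "ring_diameter_um": c.well.ring_diameter_um,
            "angular_index": c.well.angular_index,
            "concentration": c.well.concentration,
            "depth_um": c.depth_um,
            "y_well": c.y_well,
            "delta_e": np.nan if c.delta_e_vs_control is None else c.delta_e_vs_control,
            "call": c.call,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)


def sensitivity_surface(
    image_series: Sequence[tuple[float, np.ndarray]],
    layout: ChipLayout,
    cfg: ClassifierConfig,
    registration: Registration,
    *,
    roi_shrink: float = 0.8,
) -> SensitivitySurface:
    """Classify a depth series of chip images and build the sensitivity surface.

    One shared ROI mask is built from the first image (constant phantom /
    device geometry across the series) and reused for every depth.  Depths
    must be strictly increasing.
    """
    if len(image_series) == 0:
        raise ValueError("empty image series")
    depths = [d for d, _ in image_series]
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing (no duplicates)")
    first_image = image_series[0][1]
    wells = build_mask(layout, first_image.shape[:2], registration, roi_shrink=roi_shrink)
    all_calls: list[WellCall] = []
    for depth, image in image_series:
        all_calls.extend(classify_image(image, wells, cfg, depth_um=depth))
    return SensitivitySurface(
        calls=calls_to_frame(all_calls), y_sat=cfg.y_sat, delta_e_fl=cfg.delta_e_fl
    )


def estimate_registration_center(
    image: np.ndarray,
    layout: ChipLayout,
    um_per_px: float,
) -> tuple[Registration, float]:
    """Best-effort chip-center estimate from the bright outer-ring wells.

    Segments bright blobs of roughly the area of the largest wells, then
    fits a circle through their centroids (linear Kasa fit) — the blob
    centroids of the outer ring lie on a circle of known radius around the
    chip center.  Scale must be known and rotation is not estimated (a
    symmetric ring leaves it ambiguous without a fiducial).  Returns the
    registration and the RMS residual (px) of blob-centroid distances
    against the expected ring radius.
    """
    img = normalize_image(image)
    lum = 0.2126 * img[..., 0] + 0.7152 * img[..., 1] + 0.0722 * img[..., 2]
    bg = float(np.median(lum))
    thresh = bg + max(0.02, 0.1 * (float(lum.max()) - bg))
    labels = _skmeasure.label(lum >= thresh)
    props = _skmeasure.regionprops(labels)
    big_d, big_r = max(layout.rings, key=lambda ring: ring[0])
    expected_area = math.pi * (big_d / 2.0 / um_per_px) ** 2
    blobs = [p for p in props if p.area >= 0.5 * expected_area]
    blobs.sort(key=lambda p: p.area, reverse=True)
    blobs = blobs[: layout.wells_per_ring]
    if len(blobs) < 3:
        raise ValueError(
            "need at least 3 bright outer-ring wells to fit the chip center "
            f"(found {len(blobs)})"
        )
    pts = np.array([p.centroid for p in blobs])
    # Kasa circle fit: |p - c|^2 = R^2  ->  2*c.p + (R^2 - |c|^2) = |p|^2
    a_mat = np.column_stack([2.0 * pts[:, 0], 2.0 * pts[:, 1], np.ones(len(pts))])
    rhs = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    center = sol[:2]
    radii = np.sqrt(((pts - center) ** 2).sum(axis=1))
    rms = float(np.sqrt(np.mean((radii - big_r / um_per_px) ** 2)))
    reg = Registration(center_row=float(center[0]), center_col=float(center[1]),
                       um_per_px=um_per_px)
    return reg, rms
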