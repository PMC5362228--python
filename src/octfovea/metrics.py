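"""Magnification-corrected thickness profiles and foveal sampling.

Thickness is an axial measurement and is therefore taken at the nominal
axial scale; ocular magnification affects only the lateral geometry. The
lateral scale is corrected with Bennett's formula, q = 0.01306 (x - 1.82)
with x the axial length in mm, applied in ratio form against the
instrument's assumed model eye: a shorter-than-reference eye images a
smaller retinal patch per pixel, so its corrected lateral scale is smaller
than nominal and a fixed 0.5-mm eccentricity maps to more pixels.

The foveal center is the minimum of the (smoothed) total-thickness profile
within the region where the inner retinal layers (NFL, GCL+IPL, INL, OPL)
are absent; central values are averaged over the horizontal and vertical
meridians, and peripheral values are sampled 0.5 mm from the center in the
nasal, temporal, superior and inferior quadrants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import INNER_LAYERS, LAYERS, OUTER_LAYERS, QUADRANTS, BScan
from .segmentation import BoundarySet

__all__ = [
    "BENNETT_SLOPE",
    "BENNETT_OFFSET_MM",
    "OpticalBiometry",
    "MagnificationModel",
    "LayerThicknessProfile",
    "FovealSample",
    "bennett_factor",
    "corrected_lateral_scale",
    "boundaries_to_thickness",
    "profile_from_scan",
    "find_foveal_center",
    "sample_fovea",
]

#: Constants of Bennett's ocular magnification formula q = 0.01306 (x - 1.82).
BENNETT_SLOPE = 0.01306
BENNETT_OFFSET_MM = 1.82

#: Default model-eye axial length assumed by the instrument (mm).
DEFAULT_REFERENCE_AXIAL_LENGTH = 23.95

_SANITY_BAND_MM = (15.0, 40.0)


@dataclass
class OpticalBiometry:
    """Per-eye optical biometry relevant to magnification."""

    axial_length: float  # mm
    eye: str = "OD"


def bennett_factor(biometry: OpticalBiometry | float) -> float:
    """Ocular magnification factor q = 0.01306 (axial_length - 1.82).

    Accepts an :class:`OpticalBiometry` or a bare axial length in mm.
    Warns (but computes) outside the physiological 15-40 mm band.
    """
    x = biometry.axial_length if isinstance(biometry, OpticalBiometry) else float(biometry)
    if x <= 0:
        raise ValueError(f"axial length must be positive, got {x}")
    if not _SANITY_BAND_MM[0] < x < _SANITY_BAND_MM[1]:
        warnings.warn(
            f"axial length {x} mm outside the physiological band {_SANITY_BAND_MM}",
            stacklevel=2,
        )
    return BENNETT_SLOPE * (x - BENNETT_OFFSET_MM)


def corrected_lateral_scale(
    nominal_scale: float,
    biometry: OpticalBiometry | float,
    reference_axial_length: float = DEFAULT_REFERENCE_AXIAL_LENGTH,
) -> float:
    """Relative Bennett correction of the lateral pixel scale.

    corrected = nominal * q(axial_length) / q(reference_axial_length),
    where the reference is the model-eye axial length the instrument assumed
    when it reported ``nominal_scale``.
    """
    if nominal_scale <= 0:
        raise ValueError("nominal_scale must be positive")
    if reference_axial_length <= BENNETT_OFFSET_MM:
        raise ValueError(
            f"reference axial length must exceed {BENNETT_OFFSET_MM} mm, "
            f"got {reference_axial_length}"
        )
    return nominal_scale * bennett_factor(biometry) / bennett_factor(reference_axial_length)


@dataclass
class MagnificationModel:
    """Resolved magnification correction for one eye."""

    q: float
    reference_axial_length: float
    nominal_lateral_scale: float
    corrected_lateral_scale: float

    @classmethod
    def from_biometry(
        cls,
        biometry: OpticalBiometry | float,
        nominal_lateral_scale: float,
        reference_axial_length: float = DEFAULT_REFERENCE_AXIAL_LENGTH,
    ) -> "MagnificationModel":
        return cls(
            q=bennett_factor(biometry),
            reference_axial_length=reference_axial_length,
            nominal_lateral_scale=nominal_lateral_scale,
            corrected_lateral_scale=corrected_lateral_scale(
                nominal_lateral_scale, biometry, reference_axial_length
            ),
        )


@dataclass
class LayerThicknessProfile:
    """Per-column layer thicknesses (μm) along one meridian.

    ``layers`` maps each of the eight layer names to a per-column thickness
    array; ``total`` is their exact sum (equivalently (B9 - B1) times the
    axial scale). ``lateral_um`` is the magnification-corrected lateral
    position of each column, origin at column 0.
    """

    layers: dict[str, np.ndarray]
    total: np.ndarray
    lateral_um: np.ndarray
    lateral_scale: float
    meridian: str = "horizontal"
    eye: str = "OD"
    positive_column_direction: str = "nasal"

    @property
    def width(self) -> int:
        return self.total.size

    def inner_thickness(self) -> np.ndarray:
        """Combined NFL + GCL+IPL + INL + OPL thickness per column."""
        return sum(self.layers[name] for name in INNER_LAYERS)

    def value_at(self, column: int, layer: str) -> float:
        arr = self.total if layer == "total" else self.layers[layer]
        return float(arr[column])


def boundaries_to_thickness(
    boundaries: BoundarySet,
    axial_scale: float,
    lateral_scale_corrected: float,
    *,
    meridian: str = "horizontal",
    eye: str = "OD",
    positive_column_direction: str = "nasal",
) -> LayerThicknessProfile:
    """Convert nine boundary rows to eight layer thickness profiles.

    Layer k thickness(x) = (B(k+1)(x) - Bk(x)) * axial_scale; the total is
    the telescoping sum (B9 - B1) * axial_scale.
    """
    rows = boundaries.rows_array()
    if np.any(np.diff(rows, axis=0) < 0):
        raise ValueError("boundary set violates the B1 <= ... <= B9 ordering")
    thick = np.diff(rows, axis=0) * axial_scale
    layers = {name: thick[i] for i, name in enumerate(LAYERS)}
    return LayerThicknessProfile(
        layers=layers,
        total=(rows[-1] - rows[0]) * axial_scale,
        lateral_um=np.arange(rows.shape[1], dtype=float) * lateral_scale_corrected,
        lateral_scale=lateral_scale_corrected,
        meridian=meridian,
        eye=eye,
        positive_column_direction=positive_column_direction,
    )


def profile_from_scan(
    scan: BScan,
    boundaries: BoundarySet,
    reference_axial_length: float = DEFAULT_REFERENCE_AXIAL_LENGTH,
    magnification: bool = True,
) -> LayerThicknessProfile:
    """Thickness profile for a segmented scan, with its metadata attached.

    Applies the relative Bennett correction to the lateral scale when the
    scan carries an axial length and ``magnification`` is enabled.
    """
    scale = scan.lateral_scale
    if magnification and scan.axial_length_mm is not None:
        scale = corrected_lateral_scale(scale, scan.axial_length_mm, reference_axial_length)
    return boundaries_to_thickness(
        boundaries,
        scan.axial_scale,
        scale,
        meridian=scan.meridian,
        eye=scan.eye,
        positive_column_direction=scan.positive_column_direction,
    )


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + values.size]
    return out


def find_foveal_center(
    profile: LayerThicknessProfile,
    inner_absence_threshold: float = 5.0,
    smooth_window: int = 5,
    plateau_tol_um: float = 1.0,
    refine_halfwidth: int = 20,
) -> int:
    """Column index of the foveal center.

    The center is the argmin of the smoothed total-thickness profile,
    restricted to columns where the smoothed combined inner-layer thickness
    falls below ``inner_absence_threshold`` (μm) — i.e. where the inner
    retinal layers are absent. The pit floor is nearly flat, so everything
    within ``plateau_tol_um`` of the minimum counts as the minimal plateau
    and its median column seeds the estimate; because the floor is locally
    quadratic, a parabola fitted to the smoothed total over
    ``refine_halfwidth`` columns on each side then refines the estimate to
    its vertex (set ``refine_halfwidth=0`` to disable). A flat minimal
    plateau with symmetric surroundings resolves to its median column.
    """
    total = _moving_average(profile.total, smooth_window)
    inner = _moving_average(profile.inner_thickness(), smooth_window)
    candidates = np.flatnonzero(inner < inner_absence_threshold)
    if candidates.size == 0:
        raise ValueError(
            "no foveal pit found: the inner-layer thickness never falls below "
            f"{inner_absence_threshold} μm"
        )
    vals = total[candidates]
    plateau = candidates[vals <= vals.min() + plateau_tol_um]
    center = int(np.floor(np.median(plateau)))
    if refine_halfwidth > 0:
        lo = max(0, center - refine_halfwidth)
        hi = min(profile.width, center + refine_halfwidth + 1)
        if hi - lo >= 5:
            a, b, _ = np.polyfit(np.arange(lo, hi), total[lo:hi], 2)
            if a > 0:
                vertex = float(np.clip(-b / (2.0 * a), candidates.min(), candidates.max()))
                center = int(round(vertex))
    return center


@dataclass
class FovealSample:
    """Central and 0.5-mm peripheral thicknesses for one eye.

    ``central`` holds the total plus the four outer layers (the inner layers
    are absent at the center by definition), each the mean of the horizontal
    and vertical meridian values at their respective centers. ``peripheral``
    maps each quadrant to all eight layers plus the total.
    """

    central: dict[str, float]
    peripheral: dict[str, dict[str, float]]
    center_columns: dict[str, int] = field(default_factory=dict)
    eye: str = "OD"

    def to_long(self, subject_id: str = "", group: str = "") -> pd.DataFrame:
        """Long-format rows: subject, eye, group, region, layer, thickness_um."""
        records = [
            {"subject_id": subject_id, "eye": self.eye, "group": group,
             "region": "central", "layer": layer, "thickness_um": value}
            for layer, value in self.central.items()
        ]
        for quadrant, values in self.peripheral.items():
            records.extend(
                {"subject_id": subject_id, "eye": self.eye, "group": group,
                 "region": quadrant, "layer": layer, "thickness_um": value}
                for layer, value in values.items()
            )
        return pd.DataFrame.from_records(records)


def _directed_column(profile: LayerThicknessProfile, center: int, offset_px: int,
                     quadrant: str) -> int:
    positive = profile.positive_column_direction == quadrant
    column = center + offset_px if positive else center - offset_px
    if not 0 <= column < profile.width:
        raise ValueError(
            f"eccentricity reaches column {column}, outside the scan, for the "
            f"{quadrant} quadrant"
        )
    return column


def sample_fovea(
    horizontal: LayerThicknessProfile,
    vertical: LayerThicknessProfile,
    eccentricity_um: float = 500.0,
    eye: str | None = None,
    inner_absence_threshold: float = 5.0,
    smooth_window: int = 5,
) -> FovealSample:
    """Sample central and quadrant thicknesses from the two meridian profiles.

    The peripheral offset is ``eccentricity_um`` divided by each profile's
    corrected lateral scale, rounded to the nearest column. Nasal/temporal
    come from the horizontal profile, superior/inferior from the vertical,
    with the direction taken from each profile's declared
    ``positive_column_direction``.
    """
    if horizontal.meridian != "horizontal" or vertical.meridian != "vertical":
        raise ValueError("expected one horizontal and one vertical profile")
    eye = eye or horizontal.eye
    centers = {
        "horizontal": find_foveal_center(horizontal, inner_absence_threshold, smooth_window),
        "vertical": find_foveal_center(vertical, inner_absence_threshold, smooth_window),
    }
    central = {
        layer: 0.5
        * (
            horizontal.value_at(centers["horizontal"], layer)
            + vertical.value_at(centers["vertical"], layer)
        )
        for layer in ("total",) + OUTER_LAYERS
    }
    peripheral: dict[str, dict[str, float]] = {}
    for quadrant in QUADRANTS:
        profile = horizontal if quadrant in ("nasal", "temporal") else vertical
        center = centers[profile.meridian]
        offset_px = int(round(eccentricity_um / profile.lateral_scale))
        column = _directed_column(profile, center, offset_px, quadrant)
        peripheral[quadrant] = {
            layer: profile.value_at(column, layer) for layer in ("total",) + LAYERS
        }
    return FovealSample(central=central, peripheral=peripheral, center_columns=centers, eye=eye)
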