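"""Shared naming conventions and the B-scan container.

Boundary and layer names follow the standard SD-OCT nomenclature for the
nine detectable interfaces and the eight intra-retinal layers between them:

===========  =====================================  =========================
boundary     interface                              layer below the boundary
===========  =====================================  =========================
B1 (ILM)     vitreous / NFL                         NFL
B2           NFL / GCL+IPL                          GCL+IPL
B3           IPL / INL                              INL
B4           INL / OPL                              OPL
B5           OPL / HFL+ONL                          HFL+ONL
B6 (ELM)     HFL+ONL / MEZ                          MEZ
B7           MEZ / OS                               OS
B8           OS / IZ+RPE                            IZ+RPE
B9 (BrM)     IZ+RPE / choroid                       —
===========  =====================================  =========================

Row coordinates are pixel indices increasing downward (toward the choroid);
a boundary row value of ``r`` means the intensity transition is centred on
sample index ``r`` of the image column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The eight intra-retinal layers, inner to outer.
LAYERS: tuple[str, ...] = (
    "NFL",
    "GCL+IPL",
    "INL",
    "OPL",
    "HFL+ONL",
    "MEZ",
    "OS",
    "IZ+RPE",
)

#: The four inner layers that vanish at the foveal center.
INNER_LAYERS: tuple[str, ...] = LAYERS[:4]

#: The four outer layers analysed at the foveal center.
OUTER_LAYERS: tuple[str, ...] = LAYERS[4:]

#: The nine boundaries, inner to outer.
BOUNDARIES: tuple[str, ...] = ("B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B9")

#: Peripheral sampling quadrants at 0.5 mm eccentricity.
QUADRANTS: tuple[str, ...] = ("nasal", "temporal", "superior", "inferior")

#: All sampling regions of the foveal analysis.
REGIONS: tuple[str, ...] = ("central",) + QUADRANTS

EYES: tuple[str, ...] = ("OD", "OS")
MERIDIANS: tuple[str, ...] = ("horizontal", "vertical")
GROUPS: tuple[str, ...] = ("amblyopic", "fellow", "control")


@dataclass
class BScan:
    """One cross-sectional OCT image with its acquisition metadata.

    Parameters
    ----------
    image
        2-D intensity grid, rows = depth (vitreous at the top), columns =
        lateral position.
    eye
        ``"OD"`` (right) or ``"OS"`` (left).
    meridian
        ``"horizontal"`` or ``"vertical"``.
    axial_scale, lateral_scale
        Nominal instrument scales in μm/pixel. The lateral scale is the one
        affected by ocular magnification; the axial scale is not.
    axial_length_mm
        Subject's axial length, input to Bennett's magnification formula.
    positive_column_direction
        Anatomical direction of increasing column index: ``"nasal"`` or
        ``"temporal"`` for horizontal scans, ``"superior"`` or ``"inferior"``
        for vertical scans. This is declared metadata, never inferred from
        pixels.
    """

    image: np.ndarray
    eye: str = "OD"
    meridian: str = "horizontal"
    axial_scale: float = 3.87
    lateral_scale: float = 5.7
    axial_length_mm: float | None = None
    positive_column_direction: str = "nasal"
    scan_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("BScan image must be 2-D (depth x lateral)")
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        if self.meridian not in MERIDIANS:
            raise ValueError(f"meridian must be one of {MERIDIANS}, got {self.meridian!r}")
        if self.axial_scale <= 0 or self.lateral_scale <= 0:
            raise ValueError("scales must be positive")
        valid = ("nasal", "temporal") if self.meridian == "horizontal" else ("superior", "inferior")
        if self.positive_column_direction not in valid:
            raise ValueError(
                f"positive_column_direction for a {self.meridian} scan must be one of "
                f"{valid}, got {self.positive_column_direction!r}"
            )

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def metadata(self) -> dict:
        """Sidecar metadata as a JSON-serialisable dict."""
        return {
            "eye": self.eye,
            "meridian": self.meridian,
            "axial_scale": self.axial_scale,
            "lateral_scale": self.lateral_scale,
            "axial_length_mm": self.axial_length_mm,
            "positive_column_direction": self.positive_column_direction,
            "scan_id": self.scan_id,
            "seed": self.seed,
        }
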