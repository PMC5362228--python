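"""Synthetic SD-OCT B-scan phantoms and synthetic three-group cohorts.

The phantom is a layered retinal cross-section: ten intensity compartments
(vitreous, the eight intra-retinal layers, choroid) separated by nine
boundaries, a Gaussian foveal depression in which the four inner layers
(NFL, GCL+IPL, INL, OPL) vanish, Gaussian optical blur, and first-order
multiplicative speckle (mean-one gamma factor). Ground-truth boundary
positions are returned at sub-pixel precision, so segmentation accuracy can
be measured without any real data.

The cohort generator draws per-eye thickness, biometry and acuity values
from configurable group-wise Gaussian distributions; by default these are
the published reference distributions in :mod:`octfovea.reference`
(18 eyes per group). Amblyopic and fellow eyes of a subject are generated
pairwise with a configurable interocular correlation of the thickness
deviations; control subjects are independent (one analysed eye each).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from . import reference as ref
from .core import EYES, GROUPS, LAYERS, MERIDIANS, BScan
from .segmentation import BoundarySet

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_bscan",
    "generate_cohort",
    "cohort_to_long",
]

#: Default mean gray levels for the 10 compartments (vitreous, 8 layers,
#: choroid). Contrast polarity alternates the way it does on real SD-OCT:
#: bright NFL, dark INL and HFL+ONL, bright ELM..MEZ band, dark OS, very
#: bright IZ+RPE, moderately bright choroid (EDI).
DEFAULT_INTENSITIES: tuple[float, ...] = (20, 170, 75, 45, 120, 70, 150, 50, 160, 120)

_DEFAULT_AXIAL_SCALE = 3.87  # μm/px, typical for the instrument class
_DEFAULT_LATERAL_SCALE = 5.7  # μm/px
_DEFAULT_TOP_ROW = 220.0


def _default_base_rows() -> tuple[float, ...]:
    """Peripheral boundary rows mimicking the reference control nasal layer means."""
    thick_um = [ref.THICKNESS_REFERENCE["control"]["nasal"][layer][0] for layer in LAYERS]
    offsets_px = np.cumsum([0.0] + thick_um) / _DEFAULT_AXIAL_SCALE
    return tuple(_DEFAULT_TOP_ROW + offsets_px)


@dataclass
class PhantomSpec:
    """Declarative description of one synthetic B-scan.

    ``base_boundary_rows`` are the nine boundary row positions (pixels,
    sub-pixel allowed) of the flat periphery, inner to outer. ``pit_depth``
    is the drop of the inner surface (B1) at the pit center in μm; inside
    the pit, boundaries B1–B5 coalesce so the inner-layer thickness is
    exactly zero at ``pit_center_column``. ``pit_radius`` is the lateral
    extent of the depression in μm (the Gaussian profile has
    sigma = pit_radius / 3, i.e. the pit has essentially decayed at the
    stated radius). ``noise_level`` is the speckle contrast (coefficient of
    variation of the multiplicative gamma factor).
    """

    image_height: int = 496
    image_width: int = 512
    axial_scale: float = _DEFAULT_AXIAL_SCALE
    lateral_scale: float = _DEFAULT_LATERAL_SCALE
    eye: str = "OD"
    meridian: str = "horizontal"
    base_boundary_rows: tuple[float, ...] = field(default_factory=_default_base_rows)
    pit_depth: float = 81.79
    pit_radius: float = 750.0
    pit_center_column: int | None = None
    layer_intensities: tuple[float, ...] = DEFAULT_INTENSITIES
    min_contrast: float = 10.0
    noise_level: float = 0.1
    blur_sigma: float = 0.8  # ~3 μm PSF sigma at 3.87 μm/px axial sampling
    axial_length_mm: float = 23.95
    seed: int = 0

    @property
    def center_column(self) -> int:
        return self.image_width // 2 if self.pit_center_column is None else self.pit_center_column

    def validate(self) -> None:
        if self.image_height < 3 or self.image_width < 3:
            raise ValueError("image must be at least 3 x 3 pixels")
        if self.axial_scale <= 0 or self.lateral_scale <= 0:
            raise ValueError("pixel scales must be positive")
        if self.eye not in EYES or self.meridian not in MERIDIANS:
            raise ValueError("invalid eye or meridian")
        rows = np.asarray(self.base_boundary_rows, dtype=float)
        if rows.shape != (9,):
            raise ValueError("base_boundary_rows must hold 9 values")
        if not np.all(np.diff(rows) > 0):
            raise ValueError("base_boundary_rows must be strictly increasing")
        if rows[0] < 0 or rows[-1] >= self.image_height:
            raise ValueError("base_boundary_rows must lie within [0, image_height)")
        intens = np.asarray(self.layer_intensities, dtype=float)
        if intens.shape != (10,):
            raise ValueError("layer_intensities must hold 10 values")
        if np.min(np.abs(np.diff(intens))) < self.min_contrast:
            raise ValueError(
                f"adjacent compartment intensities must differ by at least {self.min_contrast}"
            )
        if not 0.0 <= self.noise_level < 1.0:
            raise ValueError("noise_level must be in [0, 1)")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be non-negative")
        if self.pit_depth < 0 or self.pit_radius <= 0:
            raise ValueError("pit_depth must be >= 0 and pit_radius > 0")
        if not 0 <= self.center_column < self.image_width:
            raise ValueError("pit_center_column outside the image")
        if self.pit_depth > 0:
            pit_row = rows[0] + self.pit_depth / self.axial_scale
            if pit_row > rows[5]:
                raise ValueError(
                    "pit_depth pushes the coalesced inner boundaries below the ELM "
                    f"(pit row {pit_row:.1f} > B6 row {rows[5]:.1f})"
                )
            if pit_row >= self.image_height:
                raise ValueError("pit_depth pushes boundaries outside the image")

    def ground_truth_rows(self) -> np.ndarray:
        """Sub-pixel boundary rows (9, width) implied by the geometry alone."""
        rows = np.asarray(self.base_boundary_rows, dtype=float)
        truth = np.tile(rows[:, None], (1, self.image_width))
        if self.pit_depth > 0:
            x = np.arange(self.image_width, dtype=float)
            sigma_px = self.pit_radius / self.lateral_scale / 3.0
            profile = np.exp(-0.5 * ((x - self.center_column) / sigma_px) ** 2)
            pit_row = rows[0] + self.pit_depth / self.axial_scale
            for i in range(5):  # B1..B5 coalesce toward the pit floor
                truth[i] = rows[i] + profile * (pit_row - rows[i])
        return truth


def _render(truth: np.ndarray, intensities: np.ndarray, height: int) -> np.ndarray:
    """Anti-aliased compartment fill.

    A boundary at row coordinate r centres the intensity transition on
    sample index r, so the rendered gradient peaks exactly at the stored
    ground-truth position.
    """
    width = truth.shape[1]
    tops = np.vstack([np.full(width, -1.0), truth])
    bottoms = np.vstack([truth, np.full(width, height + 1.0)])
    r = np.arange(height, dtype=float)[:, None]
    image = np.zeros((height, width))
    for k in range(10):
        cover = np.clip(np.minimum(bottoms[k], r + 0.5) - np.maximum(tops[k], r - 0.5), 0.0, 1.0)
        image += intensities[k] * cover
    return image


def generate_bscan(spec: PhantomSpec) -> tuple[BScan, BoundarySet]:
    """Render one phantom B-scan and return it with its ground truth.

    Rendering order: compartment fill (anti-aliased at the sub-pixel
    boundaries), Gaussian blur of ``blur_sigma``, then multiplicative
    speckle — a mean-one gamma factor with coefficient of variation
    ``noise_level``. Identical spec and seed give bit-identical output.
    """
    spec.validate()
    truth = spec.ground_truth_rows()
    image = _render(truth, np.asarray(spec.layer_intensities, dtype=float), spec.image_height)
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.blur_sigma, mode="nearest")
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        shape = 1.0 / spec.noise_level**2
        image = image * rng.gamma(shape, 1.0 / shape, size=image.shape)
    if spec.meridian == "horizontal":
        direction = "nasal" if spec.eye == "OD" else "temporal"
    else:
        direction = "superior"
    scan = BScan(
        image=image,
        eye=spec.eye,
        meridian=spec.meridian,
        axial_scale=spec.axial_scale,
        lateral_scale=spec.lateral_scale,
        axial_length_mm=spec.axial_length_mm,
        positive_column_direction=direction,
        seed=spec.seed,
    )
    return scan, BoundarySet.from_array(truth)


# --------------------------------------------------------------------------
# cohorts


def _group_params_from_reference() -> tuple[dict, dict]:
    means = {g: ref.reference_means(g) for g in GROUPS}
    sds = {g: ref.reference_sds(g) for g in GROUPS}
    return means, sds


@dataclass
class CohortSpec:
    """Declarative description of a synthetic three-group cohort.

    ``group_means`` / ``group_sds`` map group name -> measurement key ->
    value, where measurement keys are the flat ``<region>_<layer>`` thickness
    names plus ``refraction_d``, ``axial_length_mm`` and ``va_logmar``. The
    defaults are the published reference distributions.
    ``paired_eye_correlation`` is the correlation between the amblyopic-eye
    and fellow-eye thickness deviations of one subject. ``age_effect``
    (μm/year) and ``sex_effect`` (μm, added for boys) are optional linear
    covariate slopes applied to every thickness measurement.
    """

    n_per_group: int = ref.N_PER_GROUP
    group_means: dict[str, dict[str, float]] = None  # type: ignore[assignment]
    group_sds: dict[str, dict[str, float]] = None  # type: ignore[assignment]
    age_mean: float = ref.AGE_MEAN
    age_sd: float = ref.AGE_SD
    age_range: tuple[float, float] = ref.AGE_RANGE
    sex_proportion: float = ref.SEX_PROPORTION_MALE
    paired_eye_correlation: float = 0.7
    age_effect: float = 0.0
    sex_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_means is None or self.group_sds is None:
            means, sds = _group_params_from_reference()
            if self.group_means is None:
                self.group_means = means
            if self.group_sds is None:
                self.group_sds = sds

    def validate(self) -> None:
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be >= 0")
        if not -1.0 <= self.paired_eye_correlation <= 1.0:
            raise ValueError("|paired_eye_correlation| must be <= 1")
        if not 0.0 <= self.sex_proportion <= 1.0:
            raise ValueError("sex_proportion must be in [0, 1]")
        if self.age_sd < 0:
            raise ValueError("age_sd must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min <= max")
        for g in GROUPS:
            if g not in self.group_means or g not in self.group_sds:
                raise ValueError(f"missing distribution parameters for group {g!r}")
        all_keys = set().union(*(self.group_means[g] for g in GROUPS))
        for g in GROUPS:
            for k in sorted(all_keys):
                if k not in self.group_means[g]:
                    raise ValueError(f"missing mean for group {g!r}, measurement {k!r}")
                if k not in self.group_sds[g]:
                    raise ValueError(f"missing sd for group {g!r}, measurement {k!r}")
                if self.group_sds[g][k] < 0:
                    raise ValueError(f"negative sd for group {g!r}, measurement {k!r}")

    def measurement_keys(self) -> list[str]:
        """Measurement keys common to all three configured groups."""
        keys = list(self.group_means[GROUPS[0]])
        return [k for k in keys if all(k in self.group_means[g] for g in GROUPS)]

    def thickness_keys(self) -> list[str]:
        return [k for k in self.measurement_keys() if not k.endswith(("_d", "_mm", "_logmar"))]


_BIOMETRY_KEYS = ("refraction_d", "axial_length_mm", "va_logmar")
_MIN_THICKNESS_UM = 0.1  # thicknesses are physical lengths; floor Gaussian draws


def _draw_ages(rng: np.random.Generator, spec: CohortSpec, n: int) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if spec.age_sd == 0:
        return np.clip(np.full(n, spec.age_mean), *spec.age_range)
    lo, hi = spec.age_range
    a, b = (lo - spec.age_mean) / spec.age_sd, (hi - spec.age_mean) / spec.age_sd
    return sps.truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng)


def cohort_columns(spec: CohortSpec | None = None) -> list[str]:
    """Full cohort-table column schema, in order."""
    keys = spec.thickness_keys() if spec is not None else ref.thickness_keys()
    return [
        "subject_id",
        "group",
        "eye",
        "age",
        "sex",
        "sphere",
        "cylinder",
        "spherical_equivalent",
        "axial_length_mm",
        "va_logmar",
    ] + keys


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Generate a seeded synthetic cohort table (one row per analysed eye).

    Amblyopic and fellow rows of one subject share subject id, age and sex;
    their thickness deviations are correlated with
    ``spec.paired_eye_correlation``. Control subjects contribute one
    (left-eye) row each and are independent. Thickness draws are floored at
    0.1 μm; biometry and acuity are unrestricted Gaussians. Generated
    refractions are reported as spherical equivalents (``sphere`` carries
    the value, ``cylinder`` is zero).
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    thick_keys = spec.thickness_keys()
    columns = cohort_columns(spec)
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in columns})[columns]

    rho = spec.paired_eye_correlation
    ages_amb = _draw_ages(rng, spec, n)
    sex_amb = np.where(rng.random(n) < spec.sex_proportion, "M", "F")
    amb_eye = np.where(rng.random(n) < 0.5, "OD", "OS")
    fellow_eye = np.where(amb_eye == "OD", "OS", "OD")
    ages_ctl = _draw_ages(rng, spec, n)
    sex_ctl = np.where(rng.random(n) < spec.sex_proportion, "M", "F")

    rows: dict[str, dict[str, np.ndarray]] = {g: {} for g in GROUPS}
    for key in thick_keys:
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        z_ctl = rng.standard_normal(n)
        z_fellow = rho * z1 + math.sqrt(max(0.0, 1.0 - rho**2)) * z2
        for g, z in (("amblyopic", z1), ("fellow", z_fellow), ("control", z_ctl)):
            vals = spec.group_means[g][key] + spec.group_sds[g][key] * z
            age = ages_ctl if g == "control" else ages_amb
            sex = sex_ctl if g == "control" else sex_amb
            vals = vals + spec.age_effect * (age - spec.age_mean) + spec.sex_effect * (sex == "M")
            rows[g][key] = np.maximum(vals, _MIN_THICKNESS_UM)
    for key in _BIOMETRY_KEYS:
        for g in GROUPS:
            rows[g][key] = spec.group_means[g][key] + spec.group_sds[g][key] * rng.standard_normal(n)

    frames = []
    subj_amb = [f"S{i + 1:03d}" for i in range(n)]
    subj_ctl = [f"C{i + 1:03d}" for i in range(n)]
    for g in GROUPS:
        d = {
            "subject_id": subj_ctl if g == "control" else subj_amb,
            "group": g,
            "eye": {"amblyopic": amb_eye, "fellow": fellow_eye}.get(g, np.full(n, "OS")),
            "age": ages_ctl if g == "control" else ages_amb,
            "sex": sex_ctl if g == "control" else sex_amb,
            "sphere": rows[g]["refraction_d"],
            "cylinder": np.zeros(n),
            "spherical_equivalent": rows[g]["refraction_d"],
            "axial_length_mm": rows[g]["axial_length_mm"],
            "va_logmar": rows[g]["va_logmar"],
        }
        d.update({k: rows[g][k] for k in thick_keys})
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)[columns]


def cohort_to_long(cohort: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide thickness columns into the long analysis format.

    Returns one row per (subject, group, region, layer) with columns
    ``subject_id, group, eye, age, sex, region, layer, thickness_um``.
    """
    id_cols = ["subject_id", "group", "eye", "age", "sex"]
    value_cols = [c for c in cohort.columns if "_" in c and c.split("_", 1)[0] in
                  ("central", "nasal", "temporal", "superior", "inferior")]
    long = cohort.melt(id_vars=id_cols, value_vars=value_cols,
                       var_name="measurement", value_name="thickness_um")
    split = long["measurement"].str.split("_", n=1, expand=True)
    long["region"] = split[0]
    long["layer"] = split[1]
    return long.drop(columns="measurement")[id_cols + ["region", "layer", "thickness_um"]]
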