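"""Published reference distributions for a pediatric anisometropic-amblyopia cohort.

These are the group-level means and standard deviations (18 eyes per group:
amblyopic, fellow, age-matched control) for magnification-corrected foveal
layer thicknesses sampled at the foveal center and at 0.5 mm in the four
quadrants, together with the baseline biometry (spherical-equivalent
refraction, axial length, visual acuity). They parameterise the default
synthetic cohort generator and serve as worked-example inputs for the
group-comparison utilities.

Thickness units are μm; refraction is in diopters (spherical equivalent),
axial length in mm, acuity in logMAR.
"""

from __future__ import annotations

import pandas as pd

from .core import GROUPS, LAYERS, REGIONS

#: group -> region -> layer (or "total") -> (mean, sd), thickness in μm.
THICKNESS_REFERENCE: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "amblyopic": {
        "central": {
            "total": (133.58, 8.16),
            "HFL+ONL": (65.11, 8.19),
            "MEZ": (16.80, 1.15),
            "OS": (26.56, 1.13),
            "IZ+RPE": (25.09, 1.83),
        },
        "nasal": {
            "total": (224.95, 9.92),
            "NFL": (18.26, 1.68),
            "GCL+IPL": (43.16, 5.67),
            "INL": (20.08, 2.55),
            "OPL": (12.76, 2.65),
            "HFL+ONL": (65.81, 5.54),
            "MEZ": (16.29, 1.01),
            "OS": (24.05, 1.38),
            "IZ+RPE": (24.51, 1.84),
        },
        "temporal": {
            "total": (216.87, 11.88),
            "NFL": (16.93, 1.60),
            "GCL+IPL": (38.25, 5.57),
            "INL": (19.13, 3.76),
            "OPL": (20.02, 10.26),
            "HFL+ONL": (59.19, 11.48),
            "MEZ": (16.22, 1.08),
            "OS": (23.87, 2.00),
            "IZ+RPE": (24.23, 3.50),
        },
        "superior": {
            "total": (229.06, 9.45),
            "NFL": (16.66, 3.27),
            "GCL+IPL": (48.27, 6.88),
            "INL": (25.27, 3.35),
            "OPL": (22.46, 8.67),
            "HFL+ONL": (52.13, 14.20),
            "MEZ": (16.98, 2.59),
            "OS": (23.38, 1.54),
            "IZ+RPE": (23.88, 2.56),
        },
        "inferior": {
            "total": (230.76, 9.86),
            "NFL": (17.48, 2.81),
            "GCL+IPL": (50.76, 5.67),
            "INL": (25.54, 1.82),
            "OPL": (16.94, 3.48),
            "HFL+ONL": (55.77, 7.59),
            "MEZ": (16.78, 2.34),
            "OS": (23.15, 2.18),
            "IZ+RPE": (24.30, 2.60),
        },
    },
    "fellow": {
        "central": {
            "total": (132.85, 9.48),
            "HFL+ONL": (64.46, 9.11),
            "MEZ": (17.11, 1.73),
            "OS": (26.02, 1.04),
            "IZ+RPE": (25.25, 1.52),
        },
        "nasal": {
            "total": (217.78, 11.43),
            "NFL": (17.15, 1.82),
            "GCL+IPL": (39.91, 6.77),
            "INL": (20.52, 2.57),
            "OPL": (15.99, 6.77),
            "HFL+ONL": (60.17, 8.43),
            "MEZ": (16.32, 1.45),
            "OS": (23.54, 1.60),
            "IZ+RPE": (24.15, 2.33),
        },
        "temporal": {
            "total": (213.39, 10.93),
            "NFL": (16.50, 2.29),
            "GCL+IPL": (38.95, 6.07),
            "INL": (18.75, 3.18),
            "OPL": (13.74, 5.04),
            "HFL+ONL": (61.60, 6.74),
            "MEZ": (16.53, 0.74),
            "OS": (23.32, 2.17),
            "IZ+RPE": (23.97, 2.95),
        },
        "superior": {
            "total": (221.44, 14.40),
            "NFL": (17.77, 3.75),
            "GCL+IPL": (47.85, 6.03),
            "INL": (23.93, 3.12),
            "OPL": (21.37, 6.61),
            "HFL+ONL": (46.18, 13.84),
            "MEZ": (17.67, 3.63),
            "OS": (22.74, 1.28),
            "IZ+RPE": (23.90, 1.72),
        },
        "inferior": {
            "total": (221.78, 11.48),
            "NFL": (18.09, 2.50),
            "GCL+IPL": (46.59, 5.93),
            "INL": (23.54, 3.66),
            "OPL": (19.97, 8.37),
            "HFL+ONL": (49.37, 9.23),
            "MEZ": (17.46, 3.70),
            "OS": (22.86, 1.48),
            "IZ+RPE": (23.85, 2.73),
        },
    },
    "control": {
        "central": {
            "total": (133.31, 6.31),
            "HFL+ONL": (66.58, 6.49),
            "MEZ": (15.96, 0.85),
            "OS": (25.86, 0.92),
            "IZ+RPE": (24.90, 1.76),
        },
        "nasal": {
            "total": (215.10, 12.36),
            "NFL": (16.38, 2.31),
            "GCL+IPL": (38.81, 7.14),
            "INL": (20.77, 3.14),
            "OPL": (12.57, 3.89),
            "HFL+ONL": (62.63, 6.00),
            "MEZ": (16.29, 1.52),
            "OS": (22.84, 2.00),
            "IZ+RPE": (24.82, 2.08),
        },
        "temporal": {
            "total": (208.22, 11.15),
            "NFL": (15.57, 2.32),
            "GCL+IPL": (36.80, 6.17),
            "INL": (19.44, 3.17),
            "OPL": (17.10, 9.83),
            "HFL+ONL": (56.02, 13.56),
            "MEZ": (16.52, 1.28),
            "OS": (22.98, 2.50),
            "IZ+RPE": (23.80, 2.62),
        },
        "superior": {
            "total": (221.17, 10.71),
            "NFL": (17.41, 4.72),
            "GCL+IPL": (47.15, 7.05),
            "INL": (22.81, 2.90),
            "OPL": (23.71, 6.92),
            "HFL+ONL": (47.52, 8.39),
            "MEZ": (16.76, 1.48),
            "OS": (22.42, 3.77),
            "IZ+RPE": (23.98, 3.05),
        },
        "inferior": {
            "total": (219.90, 12.51),
            "NFL": (18.63, 4.45),
            "GCL+IPL": (45.88, 8.29),
            "INL": (22.40, 3.68),
            "OPL": (18.36, 5.78),
            "HFL+ONL": (52.86, 8.97),
            "MEZ": (16.08, 1.29),
            "OS": (22.26, 3.01),
            "IZ+RPE": (23.43, 3.32),
        },
    },
}

#: group -> variable -> (mean, sd). Refraction is spherical equivalent (D).
BIOMETRY_REFERENCE: dict[str, dict[str, tuple[float, float]]] = {
    "amblyopic": {
        "refraction_d": (4.44, 1.57),
        "axial_length_mm": (21.77, 0.68),
        "va_logmar": (0.48, 0.19),
    },
    "fellow": {
        "refraction_d": (0.75, 0.98),
        "axial_length_mm": (23.17, 0.75),
        "va_logmar": (0.00, 0.01),
    },
    "control": {
        "refraction_d": (0.00, 0.29),
        "axial_length_mm": (22.97, 0.69),
        "va_logmar": (0.01, 0.03),
    },
}

#: Subject ages in years: mean, sd and the study inclusion band.
AGE_MEAN, AGE_SD = 7.8, 1.9
AGE_RANGE: tuple[float, float] = (5.0, 12.0)

#: Fraction of boys among amblyopic subjects (14 of 18).
SEX_PROPORTION_MALE = 14.0 / 18.0

#: Eyes per group in the reference study.
N_PER_GROUP = 18


def measurement_key(region: str, layer: str) -> str:
    """Canonical flat column name for one thickness cell, e.g. ``nasal_NFL``."""
    return f"{region}_{layer}"


def thickness_keys() -> list[str]:
    """All thickness measurement keys in canonical (region, layer) order."""
    keys = []
    for region in REGIONS:
        layers = ("total", "HFL+ONL", "MEZ", "OS", "IZ+RPE") if region == "central" else ("total",) + LAYERS
        keys.extend(measurement_key(region, layer) for layer in layers)
    return keys


def reference_means(group: str) -> dict[str, float]:
    """Flat {measurement key: mean} map for one group (thickness + biometry)."""
    out = {
        measurement_key(region, layer): ms[0]
        for region, cells in THICKNESS_REFERENCE[group].items()
        for layer, ms in cells.items()
    }
    out.update({k: v[0] for k, v in BIOMETRY_REFERENCE[group].items()})
    return out


def reference_sds(group: str) -> dict[str, float]:
    """Flat {measurement key: sd} map for one group (thickness + biometry)."""
    out = {
        measurement_key(region, layer): ms[1]
        for region, cells in THICKNESS_REFERENCE[group].items()
        for layer, ms in cells.items()
    }
    out.update({k: v[1] for k, v in BIOMETRY_REFERENCE[group].items()})
    return out


def reference_report() -> pd.DataFrame:
    """Reference group means/SDs as a comparison-report-shaped table.

    One row per (region, layer-or-total) outcome with ``mean_<group>`` and
    ``sd_<group>`` columns — the same layout :func:`octfovea.stats.compare_all`
    produces, so it can be fed to
    :func:`octfovea.stats.group_mean_difference` directly.
    """
    rows = []
    for region in REGIONS:
        for layer in THICKNESS_REFERENCE["control"][region]:
            row: dict[str, object] = {"region": region, "layer": layer}
            for group in GROUPS:
                m, s = THICKNESS_REFERENCE[group][region][layer]
                row[f"mean_{group}"] = m
                row[f"sd_{group}"] = s
            rows.append(row)
    return pd.DataFrame(rows)
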