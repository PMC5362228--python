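"""End-to-end orchestration: simulate (or load) → segment → measure → compare.

A single declarative :class:`PipelineConfig` drives the whole analysis and
every stochastic stage derives its seed from the one global seed, so a run
is reproducible byte-for-byte at the CSV level.

Two input routes exist:

* ``simulate`` — generate a synthetic cohort; optionally also render
  per-eye phantom B-scans from each row's drawn thicknesses, segment them
  and measure the foveal samples (the full image route). Without images the
  drawn thickness values feed the statistics directly.
* ``inputs`` — load user-supplied B-scans (TIFF/PNG + JSON sidecar) and a
  cohort CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from ._version import __version__ as _pkg_version
from .core import GROUPS, LAYERS, QUADRANTS
from .metrics import profile_from_scan, sample_fovea
from .phantom import CohortSpec, PhantomSpec, cohort_to_long, generate_bscan, generate_cohort
from .segmentation import SegmentationConfig, segment_layers
from .stats import PAIRS, baseline_compare, compare_all, correlate

__all__ = ["PipelineConfig", "RunReport", "ConfigError", "run_pipeline"]

logger = logging.getLogger("octfovea")


class ConfigError(ValueError):
    """Configuration schema violation, reported with the offending field path."""


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    Exactly one of ``simulate`` / ``inputs`` must be enabled. The nested
    dicts override the corresponding dataclass defaults
    (:class:`~octfovea.phantom.CohortSpec`,
    :class:`~octfovea.segmentation.SegmentationConfig`).
    """

    seed: int = 0
    output_dir: str = "octfovea_out"
    simulate: dict | None = field(default_factory=dict)
    inputs: dict | None = None
    segmentation: dict = field(default_factory=dict)
    magnification: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one input source required: simulate xor inputs")
        if self.simulate is not None:
            cohort = self.simulate.get("cohort", {})
            n = cohort.get("n_per_group", CohortSpec().n_per_group)
            if n < 1:
                raise ConfigError("simulate.cohort.n_per_group: must be >= 1")
        else:
            for key in ("cohort_csv",):
                if key not in self.inputs:
                    raise ConfigError(f"inputs.{key}: required when loading data")
        ref_al = self.magnification.get("reference_axial_length", 23.95)
        if ref_al <= 1.82:
            raise ConfigError("magnification.reference_axial_length: must exceed 1.82 mm")

    def segmentation_config(self) -> SegmentationConfig:
        cfg = SegmentationConfig(**self.segmentation)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """What a pipeline run produced: counts, warnings and the file manifest."""

    version: str
    config: dict
    counts: dict[str, int]
    warnings: list[str]
    manifest: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


def _scan_seed(global_seed: int, index: int) -> int:
    return (global_seed * 100_003 + 7 * index + 1) % (2**31)


def _phantom_from_row(row: pd.Series, meridian: str, seed: int, images_cfg: dict) -> PhantomSpec:
    """Phantom geometry for one eye-row: flank layer thicknesses are the mean
    of the row's two opposite quadrants along the meridian."""
    q1, q2 = ("nasal", "temporal") if meridian == "horizontal" else ("superior", "inferior")
    thick = [(row[f"{q1}_{l}"] + row[f"{q2}_{l}"]) / 2.0 for l in LAYERS]
    axial_scale = images_cfg.get("axial_scale", 3.87)
    top = images_cfg.get("top_row", 220.0)
    rows = tuple(top + np.cumsum([0.0] + thick) / axial_scale)
    peripheral_total = (row[f"{q1}_total"] + row[f"{q2}_total"]) / 2.0
    pit_depth = max(5.0, peripheral_total - row["central_total"])
    return PhantomSpec(
        axial_scale=axial_scale,
        eye=row["eye"],
        meridian=meridian,
        base_boundary_rows=rows,
        pit_depth=pit_depth,
        noise_level=images_cfg.get("noise_level", 0.1),
        axial_length_mm=row["axial_length_mm"],
        seed=seed,
    )


def _measure_scans(
    scans: dict[str, "object"],
    row_meta: dict,
    seg_cfg: SegmentationConfig,
    magnification: dict,
    out_dir: Path,
    manifest: list[str],
) -> pd.DataFrame:
    enabled = magnification.get("enabled", True)
    ref_al = magnification.get("reference_axial_length", 23.95)
    profiles = {}
    for meridian, scan in scans.items():
        boundaries = segment_layers(scan, seg_cfg)
        path = out_dir / "boundaries" / f"{row_meta['subject_id']}_{row_meta['group']}_{meridian}.csv"
        fio.write_boundaries(boundaries, path)
        manifest.append(str(path.relative_to(out_dir)))
        profiles[meridian] = profile_from_scan(
            scan, boundaries, reference_axial_length=ref_al, magnification=enabled
        )
    sample = sample_fovea(profiles["horizontal"], profiles["vertical"])
    return sample.to_long(subject_id=row_meta["subject_id"], group=row_meta["group"])


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis and write every artifact under ``output_dir``."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    warnings_log: list[str] = []
    counts: dict[str, int] = {}
    seg_cfg = config.segmentation_config()

    # ---- stage 1: obtain cohort (+ optionally scans) -----------------------
    if config.simulate is not None:
        cohort_kwargs = dict(config.simulate.get("cohort", {}))
        cohort_kwargs.setdefault("seed", _scan_seed(config.seed, 0))
        cohort = generate_cohort(CohortSpec(**cohort_kwargs))
        images_cfg = config.simulate.get("images", {})
        use_images = bool(images_cfg.get("enabled", False))
    else:
        cohort = fio.read_table(config.inputs["cohort_csv"], "cohort")
        images_cfg = {}
        use_images = False
    counts["cohort_rows"] = len(cohort)
    logger.info("cohort: %d eye rows", len(cohort))

    # ---- stage 2+3: segment & measure (image route) or melt directly ------
    if use_images:
        long_parts = []
        for idx, row in cohort.reset_index(drop=True).iterrows():
            scans = {}
            for j, meridian in enumerate(("horizontal", "vertical")):
                spec = _phantom_from_row(row, meridian, _scan_seed(config.seed, 2 * idx + j + 1), images_cfg)
                scan, _truth = generate_bscan(spec)
                scans[meridian] = scan
            long_parts.append(
                _measure_scans(scans, row, seg_cfg, config.magnification, out_dir, manifest)
            )
        long = pd.concat(long_parts, ignore_index=True)
        long = long.merge(cohort[["subject_id", "group", "age", "sex"]], on=["subject_id", "group"])
        counts["scans_segmented"] = 2 * len(cohort)
    else:
        long = cohort_to_long(cohort)
        counts["scans_segmented"] = 0
    counts["thickness_rows"] = len(long)
    thickness_path = fio.write_table(
        long[fio.THICKNESS_COLUMNS + [c for c in ("age", "sex") if c in long.columns]],
        out_dir / "thickness.csv",
        "thickness",
    )
    manifest.append(thickness_path.name)
    cohort_path = fio.write_table(cohort, out_dir / "cohort.csv", "cohort")
    manifest.append(cohort_path.name)

    # ---- stage 4: statistics ----------------------------------------------
    if "age" not in long.columns:
        long = long.merge(cohort[["subject_id", "group", "age", "sex"]], on=["subject_id", "group"])
    report = compare_all(long)
    report_path = fio.write_table(report, out_dir / "report.csv", "report")
    manifest.append(report_path.name)
    counts["outcomes_compared"] = len(report)

    baselines = pd.DataFrame(
        [
            {"variable": var, "group_1": g1, "group_2": g2, **baseline_compare(cohort, var, g1, g2)}
            for var in ("SE", "AL", "VA")
            for (g1, g2) in PAIRS
        ]
    )
    baselines_path = out_dir / "baselines.csv"
    with open(baselines_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# octfovea-schema: baselines/v1\n")
        baselines.to_csv(fh, index=False, float_format=fio.FLOAT_FORMAT, lineterminator="\n")
    manifest.append(baselines_path.name)

    corr_group = config.stats.get("correlation_group", "amblyopic")
    wide = long.pivot_table(
        index=["subject_id", "group"], columns=["region", "layer"], values="thickness_um"
    )
    corr_rows = []
    sub = cohort[cohort["group"] == corr_group].set_index("subject_id")
    va_diff = None
    if {"amblyopic", "fellow"} <= set(cohort["group"]):
        va = cohort.pivot_table(index="subject_id", columns="group", values="va_logmar")
        if {"amblyopic", "fellow"} <= set(va.columns):
            va_diff = (va["amblyopic"] - va["fellow"]).rename("va_interocular_diff")
    if len(sub) >= 3:
        grp_wide = wide.xs(corr_group, level="group")
        predictors = {
            "axial_length_mm": sub["axial_length_mm"],
            "spherical_equivalent": sub["spherical_equivalent"],
        }
        if va_diff is not None and corr_group == "amblyopic":
            predictors["va_interocular_diff"] = va_diff
        for (region, layer) in grp_wide.columns:
            y = grp_wide[(region, layer)]
            for name, x in predictors.items():
                joined = pd.concat([x, y], axis=1, join="inner").dropna()
                if len(joined) < 3 or joined.iloc[:, 0].std() == 0 or joined.iloc[:, 1].std() == 0:
                    warnings_log.append(f"correlation skipped: {name} vs {region} {layer}")
                    continue
                res = correlate(joined.iloc[:, 0], joined.iloc[:, 1], name, f"{region}_{layer}")
                corr_rows.append({"x": res.x, "y": res.y, "r": res.r, "p": res.p, "n": res.n})
    correlations = pd.DataFrame(corr_rows, columns=["x", "y", "r", "p", "n"])
    corr_path = fio.write_table(correlations, out_dir / "correlations.csv", "correlations")
    manifest.append(corr_path.name)
    counts["correlations"] = len(correlations)

    report_obj = RunReport(
        version=_pkg_version,
        config=dataclasses.asdict(config),
        counts=counts,
        warnings=warnings_log,
        manifest=sorted(manifest) + ["run_report.json"],
        )
    (out_dir / "run_report.json").write_text(report_obj.to_json())
    logger.info("pipeline complete: %s", counts)
    return report_obj
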