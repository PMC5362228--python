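"""File round-tripping: B-scans with JSON sidecars, schema-checked CSVs.

All tabular outputs are UTF-8, dot-decimal CSVs with a one-line schema
comment header (``# octfovea-schema: <name>/v1``) so files are diff-able
and language-neutral. Floats are written at fixed precision; readers
validate the column schema and name any missing column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import BOUNDARIES, BScan
from .segmentation import BoundarySet

__all__ = [
    "SchemaError",
    "write_bscan",
    "read_bscan",
    "write_boundaries",
    "read_boundaries",
    "write_table",
    "read_table",
    "THICKNESS_COLUMNS",
    "REPORT_COLUMNS",
]

FLOAT_FORMAT = "%.6f"

THICKNESS_COLUMNS = ["subject_id", "eye", "group", "region", "layer", "thickness_um"]
REPORT_COLUMNS = ["region", "layer", "mean_amblyopic", "mean_fellow", "mean_control"]
CORRELATION_COLUMNS = ["x", "y", "r", "p", "n"]

_SCHEMAS: dict[str, list[str]] = {
    "boundaries": ["column"] + list(BOUNDARIES),
    "thickness": THICKNESS_COLUMNS,
    "cohort": ["subject_id", "group", "eye", "age", "sex"],
    "report": REPORT_COLUMNS,
    "correlations": CORRELATION_COLUMNS,
}


class SchemaError(ValueError):
    """A CSV did not match its declared column schema."""


def write_bscan(scan: BScan, image_path: str | Path) -> Path:
    """Write a B-scan as 8-bit grayscale TIFF/PNG plus a JSON sidecar.

    The sidecar path is the image path with a ``.json`` suffix; it carries
    eye, meridian, scales, axial length and the column-direction convention.
    Returns the sidecar path.
    """
    image_path = Path(image_path)
    img = np.clip(np.round(scan.image), 0, 255).astype(np.uint8)
    if image_path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(image_path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(image_path, img)
    sidecar = image_path.with_suffix(image_path.suffix + ".json")
    sidecar.write_text(json.dumps(scan.metadata(), indent=2, sort_keys=True) + "\n")
    return sidecar


def read_bscan(image_path: str | Path) -> BScan:
    """Read a B-scan image and its JSON sidecar back into a :class:`BScan`."""
    image_path = Path(image_path)
    sidecar = image_path.with_suffix(image_path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    if image_path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(image_path)
    else:
        import imageio.v3 as iio

        img = iio.imread(image_path)
    meta = json.loads(sidecar.read_text())
    return BScan(
        image=np.asarray(img, dtype=float),
        eye=meta["eye"],
        meridian=meta["meridian"],
        axial_scale=meta["axial_scale"],
        lateral_scale=meta["lateral_scale"],
        axial_length_mm=meta.get("axial_length_mm"),
        positive_column_direction=meta["positive_column_direction"],
        scan_id=meta.get("scan_id", ""),
        seed=meta.get("seed"),
    )


def write_table(frame: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Write a schema-tagged CSV (UTF-8, dot-decimal, LF line endings)."""
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    _validate(frame.columns, schema)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# octfovea-schema: {schema}/v1\n")
        frame.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a schema-tagged CSV."""
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    frame = pd.read_csv(path, comment="#")
    _validate(frame.columns, schema)
    return frame


def _validate(columns, schema: str) -> None:
    missing = [c for c in _SCHEMAS[schema] if c not in set(columns)]
    if missing:
        raise SchemaError(
            f"CSV does not match schema {schema!r}: missing column(s) "
            + ", ".join(repr(c) for c in missing)
        )


def write_boundaries(boundaries: BoundarySet, path: str | Path) -> Path:
    """Write a boundary set as a CSV of sub-pixel rows per column."""
    return write_table(boundaries.to_frame(), path, "boundaries")


def read_boundaries(path: str | Path) -> BoundarySet:
    """Read a boundary-set CSV back into a :class:`BoundarySet`."""
    return BoundarySet.from_frame(read_table(path, "boundaries"))
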