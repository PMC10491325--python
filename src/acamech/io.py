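"""File readers and writers.

Myograph cycles travel as delimited text with unit-bearing column names
(``pressure_mmHg, outer_diameter_mm, axial_force_mN``) plus a JSON sidecar
holding the specimen metadata (lengths, ring perimeters, axial stretch).
Units live in the column names and are validated, never guessed — the
mmHg/kPa boundary is the likeliest silent-failure point in this pipeline.
Images travel as TIFF (multi-page for z-stacks) or PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ParseError
from .mechanics import MyographRecording, ReferenceGeometry, radii_from_perimeters

MYOGRAPH_COLUMNS = ("pressure_mmHg", "outer_diameter_mm", "axial_force_mN")


def read_myograph_csv(path: str | Path) -> tuple[MyographRecording, ReferenceGeometry]:
    """Read one cycle (CSV) and its metadata sidecar (same stem, .json).

    The sidecar must provide ``L_mm``, ``l_mm``, ``outer_perimeter_mm`` and
    ``inner_perimeter_mm``; malformed files raise :class:`ParseError` naming
    the offending column or row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"{path}: unreadable CSV ({exc})") from exc
    for col in MYOGRAPH_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    for col in MYOGRAPH_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {bad[0]}")
        df[col] = vals
    if (df["outer_diameter_mm"] <= 0).any():
        row = df.index[df["outer_diameter_mm"] <= 0][0]
        raise ParseError(f"{path}: non-positive outer diameter at row {row}")

    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ParseError(f"{path}: metadata sidecar {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    for key in ("L_mm", "l_mm", "outer_perimeter_mm", "inner_perimeter_mm"):
        if key not in meta:
            raise ParseError(f"{sidecar}: missing metadata key {key!r}")

    rec = MyographRecording(
        pressure=df["pressure_mmHg"].to_numpy(),
        outer_diameter=df["outer_diameter_mm"].to_numpy(),
        axial_force=df["axial_force_mN"].to_numpy(),
        stretched_length=float(meta["l_mm"]),
        cycle_label=str(meta.get("cycle_label", "unlabeled")),
    )
    geom = radii_from_perimeters(
        float(meta["outer_perimeter_mm"]),
        float(meta["inner_perimeter_mm"]),
        float(meta["L_mm"]),
    )
    return rec, geom


def write_myograph_csv(
    path: str | Path,
    rec: MyographRecording,
    geom: ReferenceGeometry,
    outer_perimeter_mm: float | None = None,
    inner_perimeter_mm: float | None = None,
) -> None:
    """Write a cycle and its sidecar; inverse of :func:`read_myograph_csv`."""
    path = Path(path)
    pd.DataFrame(
        {
            "pressure_mmHg": rec.pressure,
            "outer_diameter_mm": rec.outer_diameter,
            "axial_force_mN": rec.axial_force,
        }
    ).to_csv(path, index=False)
    meta = {
        "L_mm": geom.L,
        "l_mm": rec.stretched_length,
        "outer_perimeter_mm": outer_perimeter_mm or 2 * np.pi * geom.Ro,
        "inner_perimeter_mm": inner_perimeter_mm or 2 * np.pi * geom.Ri,
        "lambda_z": rec.stretched_length / geom.L,
        "cycle_label": rec.cycle_label,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_image(path: str | Path) -> np.ndarray:
    """Read TIFF/PNG as grayscale; multi-page TIFF returns a (Z, H, W) stack.

    RGB inputs are rejected rather than silently collapsed — select or
    convert the signal channel upstream.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and path.suffix.lower() not in (".tif", ".tiff"):
        raise ParseError(
            f"{path}: RGB(A) image; convert to single-channel grayscale first"
        )
    if arr.ndim not in (2, 3):
        raise ParseError(f"{path}: expected 2D image or 3D stack, got ndim={arr.ndim}")
    return arr


def write_image(path: str | Path, arr: np.ndarray) -> None:
    """Write a 2D image or 3D stack; float arrays go to TIFF as float32."""
    path = Path(path)
    arr = np.asarray(arr)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = arr.astype(np.float32) if arr.dtype.kind == "f" else arr
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        if arr.ndim != 2:
            raise ValueError("PNG output supports 2D images only")
        if arr.dtype.kind == "f":
            arr = np.clip(arr, 0, 1)
            arr = (arr * 65535).round().astype(np.uint16)
        Image.fromarray(arr).save(path)
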