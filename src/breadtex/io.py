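"""File I/O for the standard interchange formats.

Curves travel as CSV with header ``time_min,torque_nm,temp_c``; colour
readings as CSV with header ``group,replicate,L,a,b``; images as 8-bit
PNG, label masks as 16-bit PNG; all floats are serialized with 12
significant digits so write/read round-trips are lossless well past 1e-9.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio

from breadtex.mixolab import TorqueCurve

__all__ = [
    "CURVE_COLUMNS",
    "COLOR_COLUMNS",
    "read_curve_csv",
    "write_curve_csv",
    "read_color_csv",
    "write_color_csv",
    "write_image_png",
    "write_label_mask_png",
    "read_label_mask_png",
]

CURVE_COLUMNS = ("time_min", "torque_nm", "temp_c")
COLOR_COLUMNS = ("group", "replicate", "L", "a", "b")

_FLOAT_FMT = "%.12g"


def read_curve_csv(path: str | Path) -> TorqueCurve:
    """Parse a torque-curve CSV, with named, line-numbered errors.

    Expects exactly the header ``time_min,torque_nm,temp_c``; time must be
    strictly increasing and every cell numeric.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        missing = [c for c in CURVE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}; header was {header}")
        idx = {c: header.index(c) for c in CURVE_COLUMNS}
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            parsed = []
            for col in CURVE_COLUMNS:
                cell = row[idx[col]]
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric value {cell!r} in column {col!r}"
                    ) from None
            rows.append(parsed)
    if len(rows) < 2:
        raise ValueError(f"{path}: a curve needs at least 2 samples, found {len(rows)}")
    data = np.array(rows, dtype=float)
    time = data[:, 0]
    bad = np.flatnonzero(np.diff(time) <= 0)
    if bad.size:
        raise ValueError(f"{path}: line {int(bad[0]) + 3}: time not increasing")
    return TorqueCurve(time=time, torque=data[:, 1], temperature=data[:, 2])


def write_curve_csv(curve: TorqueCurve, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CURVE_COLUMNS)
        for t, tq, tc in zip(curve.time, curve.torque, curve.temperature):
            writer.writerow([_FLOAT_FMT % t, _FLOAT_FMT % tq, _FLOAT_FMT % tc])


def read_color_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in COLOR_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("L", "a", "b"):
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise ValueError(f"{path}: column {col!r} must be numeric")
    return frame[list(COLOR_COLUMNS)]


def write_color_csv(frame: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image))


def write_label_mask_png(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("label mask exceeds 16-bit range")
    write_image_png(mask.astype(np.uint16), path)


def read_label_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path))
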