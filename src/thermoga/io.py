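"""Readers and writers for the plain-text formats the tool consumes.

* Temperature matrices: whitespace-delimited numeric grids, one file per
  breast (the dialect of public thermography archives); optional masks as
  0/1 text grids of the same shape or single-channel PNG images.
* Feature tables: CSV with a header; first column ``exam_id``, last column
  ``class`` in {cancer, no_cancer}, feature columns in between.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import Dataset
from .roi import LABELS, RoiMatrix


def read_temperature_matrix(
    path, mask_path=None, side: str = "left"
) -> RoiMatrix:
    """Parse a whitespace-delimited temperature grid into a ROI.

    The grid must be rectangular; a ragged or non-numeric file raises a
    parse error naming the offending line.  Without a mask file, the whole
    rectangle is treated as tissue.
    """
    path = Path(path)
    rows = []
    width: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                row = [float(t) for t in tokens]
            except ValueError as exc:
                bad = next(t for t in tokens if not _is_number(t))
                raise ValueError(
                    f"{path}: non-numeric token {bad!r} on line {lineno}"
                ) from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}: ragged grid — line {lineno} has {len(row)} "
                    f"values, expected {width}"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty temperature grid")
    values = np.asarray(rows, dtype=float)
    mask = read_mask(mask_path, values.shape) if mask_path else None
    return RoiMatrix(values=values, mask=mask, side=side)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_mask(path, expected_shape) -> np.ndarray:
    """Read a binary mask from a 0/1 text grid or a single-channel PNG."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        mask = arr > 0
    else:
        mask = np.loadtxt(path).astype(bool)
    if mask.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: mask shape {mask.shape} != ROI shape {tuple(expected_shape)}"
        )
    return mask


def write_temperature_matrix(roi: RoiMatrix, path) -> None:
    np.savetxt(path, roi.values, fmt="%.6f")


def write_feature_table(data: Dataset, path) -> None:
    """Write the CSV dialect: exam_id, feature columns, class."""
    frame = pd.DataFrame(data.features, columns=list(data.column_names))
    frame.insert(0, "exam_id", list(data.exam_ids))
    frame["class"] = data.labels()
    frame.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> Dataset:
    """Read the CSV dialect back into a :class:`Dataset`."""
    frame = pd.read_csv(path)
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: empty feature table")
    if "class" not in frame.columns:
        raise ValueError(f"{path}: missing 'class' column")
    bad = sorted(set(frame["class"]) - set(LABELS))
    if bad:
        raise ValueError(
            f"{path}: unknown class token(s) {bad}; allowed: {list(LABELS)}"
        )
    if frame.columns[0] == "exam_id":
        exam_ids = [str(e) for e in frame["exam_id"]]
        feature_cols = [c for c in frame.columns[1:] if c != "class"]
    else:
        exam_ids = [f"exam_{i}" for i in range(frame.shape[0])]
        feature_cols = [c for c in frame.columns if c != "class"]
    return Dataset.from_labels(
        features=frame[feature_cols].to_numpy(dtype=float),
        labels=list(frame["class"]),
        column_names=feature_cols,
        exam_ids=exam_ids,
    )


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
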