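"""Region-of-interest containers for breast thermograms.

A thermographic exam provides one temperature matrix per breast (in °C),
pre-segmented so that only breast tissue carries meaningful values.  The
segmentation is encoded as a binary mask of the same shape; where no mask is
supplied the whole rectangle is treated as tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MIN_MASK_CELLS = 16

LABEL_CANCER = "cancer"
LABEL_NO_CANCER = "no_cancer"
LABELS = (LABEL_CANCER, LABEL_NO_CANCER)


@dataclass(frozen=True)
class RoiMatrix:
    """A single-breast temperature grid with its tissue mask.

    Parameters
    ----------
    values : ndarray of float, shape (H, W)
        Skin temperatures in °C.  Entries outside the mask may hold any
        finite or non-finite value; they never enter a computation.
    mask : ndarray of bool, shape (H, W)
        True where the pixel belongs to breast tissue.
    side : {"left", "right"}
    """

    values: np.ndarray
    mask: np.ndarray
    side: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("ROI values must be a 2-D grid")
        mask = self.mask
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        mask = np.asarray(mask).astype(bool)
        if mask.shape != values.shape:
            raise ValueError(
                f"mask shape {mask.shape} != values shape {values.shape}"
            )
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if int(mask.sum()) == 0:
            raise ValueError("empty ROI: mask selects no pixels")
        if int(mask.sum()) < MIN_MASK_CELLS:
            raise ValueError(
                f"ROI mask has {int(mask.sum())} active cells; need >= {MIN_MASK_CELLS}"
            )
        if not np.all(np.isfinite(values[mask])):
            raise ValueError("non-finite temperature inside mask")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        """Temperatures of tissue pixels, flattened row-major."""
        return self.values[self.mask]


@dataclass(frozen=True)
class RoiPair:
    """Both breasts of one exam, with an optional diagnosis label."""

    left: RoiMatrix
    right: RoiMatrix
    label: Optional[str] = None
    exam_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.left.side != "left" or self.right.side != "right":
            raise ValueError("RoiPair sides must be (left, right)")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"label must be one of {LABELS}, got {self.label!r}"
            )

    @property
    def breasts(self) -> tuple:
        return (self.left, self.right)
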