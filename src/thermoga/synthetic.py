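"""Seeded synthetic inputs with the statistical structure the method assumes.

Two generators cover the two entry points of the pipeline:

* :func:`make_roi_pairs` emulates a two-class static-thermography study:
  each exam is a pair of baseline-temperature breast matrices with camera
  noise, and "cancer" exams carry a localized hot spot (a 2-D Gaussian
  temperature bump) on one breast — the vascularization/metabolism
  asymmetry the features are designed to pick up.  Defaults follow a
  balanced 40 + 40 exam study.

* :func:`make_feature_table` builds class-conditional Gaussian feature
  tables with a known informative subset: informative columns differ in
  mean by ``effect_size`` pooled standard deviations, the rest are pure
  noise.  The ground-truth column set is returned for recovery benchmarks.

Both are pure functions of their spec (the seed included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .evaluation import Dataset
from .roi import LABEL_CANCER, LABEL_NO_CANCER, RoiMatrix, RoiPair


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study.

    Image parameters (°C unless noted): ``baseline_temp`` is the healthy
    skin temperature; cancer exams add a radially decaying hot spot of
    amplitude ``hotspot_amplitude`` and scale ``hotspot_radius`` pixels;
    ``noise_sd`` is i.i.d. Gaussian camera noise.  Table parameters:
    ``n_features`` columns of which ``n_informative`` differ between the
    classes by ``effect_size`` pooled standard deviations.
    """

    n_exams: int = 80
    class_balance: float = 0.5
    image_shape: Tuple[int, int] = (64, 64)
    baseline_temp: float = 33.0
    hotspot_amplitude: float = 2.0
    hotspot_radius: float = 8.0
    hotspot_side: str = "random"
    noise_sd: float = 0.1
    n_features: int = 50
    n_informative: int = 10
    effect_size: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exams < 2:
            raise ValueError("need at least 2 exams")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if self.hotspot_amplitude < 0:
            raise ValueError("hotspot amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.image_shape) < 16:
            raise ValueError(
                "image_shape too small for the LTP/wavelet stages (min 16)"
            )
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.hotspot_side not in ("random", "left", "right"):
            raise ValueError("hotspot_side must be random, left or right")


def _class_labels(spec: SynthSpec) -> List[str]:
    n_cancer = int(round(spec.class_balance * spec.n_exams))
    n_cancer = min(max(n_cancer, 1), spec.n_exams - 1)
    return [LABEL_CANCER] * n_cancer + [LABEL_NO_CANCER] * (
        spec.n_exams - n_cancer
    )


def _hotspot(shape, center, amplitude, radius) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    r2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return amplitude * np.exp(-r2 / (2.0 * radius**2))


def make_roi_pairs(spec: SynthSpec) -> List[RoiPair]:
    """Generate one labeled :class:`RoiPair` per exam.

    The hot-spot center is drawn uniformly inside the central half of the
    affected breast; its parameters are recorded in ``pair.meta`` as ground
    truth.  Class order is fixed (cancer exams first), matching the label
    list exactly — reproducible under the spec's seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    h, w = spec.image_shape
    pairs: List[RoiPair] = []
    for i, label in enumerate(_class_labels(spec)):
        breasts = {}
        for side in ("left", "right"):
            values = spec.baseline_temp + spec.noise_sd * rng.standard_normal((h, w))
            breasts[side] = values
        meta: dict = {}
        if label == LABEL_CANCER:
            if spec.hotspot_side == "random":
                side = "left" if rng.random() < 0.5 else "right"
            else:
                side = spec.hotspot_side
            center = (
                float(rng.uniform(h / 4, 3 * h / 4)),
                float(rng.uniform(w / 4, 3 * w / 4)),
            )
            breasts[side] = breasts[side] + _hotspot(
                (h, w), center, spec.hotspot_amplitude, spec.hotspot_radius
            )
            meta = {
                "hotspot_side": side,
                "hotspot_center": center,
                "hotspot_amplitude": spec.hotspot_amplitude,
                "hotspot_radius": spec.hotspot_radius,
            }
        pairs.append(
            RoiPair(
                left=RoiMatrix(values=breasts["left"], mask=None, side="left"),
                right=RoiMatrix(values=breasts["right"], mask=None, side="right"),
                label=label,
                exam_id=f"synth_{i:04d}",
                meta=meta,
            )
        )
    return pairs


def make_feature_table(spec: SynthSpec) -> Tuple[Dataset, np.ndarray]:
    """Two-class Gaussian feature table plus the informative column indices.

    All columns are unit-variance Gaussians; for the informative subset the
    cancer-class mean is shifted by ``effect_size`` (pooled sd = 1).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 12]))
    labels = _class_labels(spec)
    y = np.array([1 if lab == LABEL_CANCER else 0 for lab in labels])
    X = rng.standard_normal((spec.n_exams, spec.n_features))
    informative = np.sort(
        rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    )
    X[np.ix_(y == 1, informative)] += spec.effect_size
    data = Dataset.from_labels(
        features=X,
        labels=labels,
        column_names=[f"synth_feat_{j}" for j in range(spec.n_features)],
        exam_ids=[f"synth_{i:04d}" for i in range(spec.n_exams)],
    )
    return data, informative
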