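"""Texture features of breast thermograms.

Four extractor families are combined into six named feature groups:

* **GLCM** — gray-level co-occurrence statistics (contrast, dissimilarity,
  homogeneity, energy, correlation, ASM) at four directions, distance 1,
  over 256 temperature quantization levels.
* **LTP spectra** — local ternary patterns with a dead-zone threshold ``t``
  (°C); "spectrum k" is the binary map of interior pixels whose
  8-neighborhood produced exactly ``k`` "hotter than center + t" codes.
* **Fractal trio** — Higuchi, Petrosian and Hurst estimators applied to the
  row-major flattening of a spectrum map (see :mod:`thermoga.fractal`).
* **Wavelet–fractal** — single-level Daubechies (db1..db8) decomposition of
  each spectrum map; the fractal trio of the flattened approximation band.

Per exam, each group concatenates the left-breast fragment then the
right-breast fragment, yielding the fixed dimensionalities 384 / 48 / 48 /
60 / 18 / 148 for the six named groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pywt

from .fractal import fractal_trio
from .roi import RoiMatrix, RoiPair

GLCM_LEVELS = 256
GLCM_DESCRIPTORS = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "energy",
    "correlation",
    "asm",
)
GLCM_ANGLES = (0, 45, 90, 135)
# (row, col) offset of the second pixel of a pair, distance 1, in the
# image convention of scikit-image (row axis pointing down); symmetric
# accumulation makes each offset equivalent to its negation.
_ANGLE_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}

# 8-neighborhood in fixed clockwise order starting at the top-left corner;
# the position in this tuple is the bit index of the LTP code.
NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

DEFAULT_LTP_THRESHOLD = 0.1  # °C; typical thermal-camera sensitivity
DEFAULT_WAVELETS = tuple(f"db{i}" for i in range(1, 9))
LTP_HIST_BINS = 25


# ---------------------------------------------------------------------------
# quantization and GLCM


def quantize(roi: RoiMatrix, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Min–max quantize masked temperatures to ``levels`` integer levels.

    Per-breast scaling removes absolute temperature offsets between exams.
    A constant ROI maps entirely to level 0.  Pixels outside the mask are
    assigned level 0 but are excluded from all pair counts.
    """
    values = roi.values
    masked = roi.masked_values()
    vmin, vmax = masked.min(), masked.max()
    q = np.zeros(values.shape, dtype=np.int64)
    if vmax > vmin:
        scaled = (values - vmin) / (vmax - vmin) * levels
        q_in = np.clip(np.floor(scaled), 0, levels - 1).astype(np.int64)
        q[roi.mask] = q_in[roi.mask]
    return q


def glcm_matrix(roi: RoiMatrix, angle: int, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix at one direction.

    Only pixel pairs with both endpoints inside the mask contribute.
    """
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {GLCM_ANGLES}, got {angle}")
    q = quantize(roi, levels)
    mask = roi.mask
    dr, dc = _ANGLE_OFFSETS[angle]
    h, w = q.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a = q[r0, c0]
    b = q[r1, c1]
    valid = mask[r0, c0] & mask[r1, c1]
    codes = a[valid] * levels + b[valid]
    counts = np.bincount(codes, minlength=levels * levels).reshape(levels, levels)
    counts = counts + counts.T  # symmetric accumulation
    total = counts.sum()
    if total == 0:
        return np.zeros((levels, levels), dtype=float)
    return counts / total


def glcm_descriptors(p: np.ndarray) -> dict:
    """The six Haralick-style descriptors of a normalized GLCM.

    Correlation of a zero-variance matrix is defined as 0.
    """
    levels = p.shape[0]
    i = np.arange(levels, dtype=float)
    diff = i[:, None] - i[None, :]
    asm = float((p * p).sum())
    out = {
        "contrast": float((p * diff**2).sum()),
        "dissimilarity": float((p * np.abs(diff)).sum()),
        "homogeneity": float((p / (1.0 + diff**2)).sum()),
        "energy": float(np.sqrt(asm)),
        "asm": asm,
    }
    pi = p.sum(axis=1)
    mu = float((pi * i).sum())
    var = float((pi * (i - mu) ** 2).sum())
    if var <= 0:
        out["correlation"] = 0.0
    else:
        out["correlation"] = float(
            (p * (i[:, None] - mu) * (i[None, :] - mu)).sum() / var
        )
    return out


def glcm_features(roi: RoiMatrix) -> Tuple[np.ndarray, List[str]]:
    """24 GLCM values: 6 descriptors x 4 directions, deterministic order.

    Order: for each angle (0, 45, 90, 135), the six descriptors
    (contrast, dissimilarity, homogeneity, energy, correlation, ASM).
    """
    values, names = [], []
    for angle in GLCM_ANGLES:
        desc = glcm_descriptors(glcm_matrix(roi, angle))
        for d in GLCM_DESCRIPTORS:
            values.append(desc[d])
            names.append(f"glcm_{d}_a{angle}")
    return np.asarray(values), names


# ---------------------------------------------------------------------------
# local ternary patterns


def _ltp_codes(roi: RoiMatrix, t: float):
    """Per-interior-pixel LTP code counts and polarity byte codes.

    Returns (plus_count, minus_count, upper_code, lower_code, interior),
    all full-shape arrays; ``interior`` marks masked pixels that are not on
    the image border.  Neighbors outside the mask contribute the neutral
    code 0.
    """
    if t <= 0:
        raise ValueError("LTP threshold t must be > 0")
    v = roi.values
    m = roi.mask
    h, w = v.shape
    if h < 3 or w < 3:
        raise ValueError("ROI smaller than 3x3: LTP undefined")
    center = v[1:-1, 1:-1]
    plus = np.zeros(center.shape, dtype=np.int64)
    minus = np.zeros(center.shape, dtype=np.int64)
    upper = np.zeros(center.shape, dtype=np.int64)
    lower = np.zeros(center.shape, dtype=np.int64)
    # values outside the mask may be non-finite; neutralize them so the
    # comparisons below never see them
    v_safe = np.where(m, v, 0.0)
    for bit, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        nb = v_safe[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc]
        nb_mask = m[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc]
        hot = (nb > center + t) & nb_mask
        cold = (nb < center - t) & nb_mask
        plus += hot
        minus += cold
        upper |= hot.astype(np.int64) << bit
        lower |= cold.astype(np.int64) << bit
    interior = np.zeros(v.shape, dtype=bool)
    interior[1:-1, 1:-1] = m[1:-1, 1:-1]
    pad = lambda a: np.pad(a, 1)  # noqa: E731  back to full shape
    return pad(plus), pad(minus), pad(upper), pad(lower), interior


def ltp_spectrum_maps(roi: RoiMatrix, t: float = DEFAULT_LTP_THRESHOLD) -> List[np.ndarray]:
    """The nine LTP spectrum maps (k = 0..8) of one breast.

    Map ``k`` is a full-shape binary array marking interior masked pixels
    whose 8-neighborhood produced exactly ``k`` "+1" codes.  The maps
    partition the interior: every interior pixel belongs to exactly one.
    """
    plus, _, _, _, interior = _ltp_codes(roi, t)
    return [((plus == k) & interior).astype(np.uint8) for k in range(9)]


def ltp_polarity_histograms(
    roi: RoiMatrix, t: float = DEFAULT_LTP_THRESHOLD, bins: int = LTP_HIST_BINS
) -> Tuple[np.ndarray, List[str]]:
    """Upper- and lower-polarity LTP code histograms (2 x ``bins`` values).

    The 8-bit upper (resp. lower) code of each interior pixel collects the
    "+1" (resp. "-1") comparisons as bits; each code distribution over
    [0, 256) is binned into ``bins`` equal-width bins and normalized to
    frequencies.
    """
    _, _, upper, lower, interior = _ltp_codes(roi, t)
    n = int(interior.sum())
    if n == 0:
        raise ValueError("ROI has no interior masked pixels")
    values, names = [], []
    for pol_name, codes in (("upper", upper), ("lower", lower)):
        hist, _ = np.histogram(codes[interior], bins=bins, range=(0, 256))
        values.append(hist / n)
        names.extend(f"ltphist_{pol_name}_{b}" for b in range(bins))
    return np.concatenate(values), names


def interior_bbox(roi: RoiMatrix) -> Tuple[slice, slice]:
    """Bounding box of interior masked pixels (image border excluded)."""
    interior = np.zeros(roi.shape, dtype=bool)
    interior[1:-1, 1:-1] = roi.mask[1:-1, 1:-1]
    if not interior.any():
        raise ValueError("ROI has no interior masked pixels")
    rows = np.flatnonzero(interior.any(axis=1))
    cols = np.flatnonzero(interior.any(axis=0))
    return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)


# ---------------------------------------------------------------------------
# fractal composites


def ltp_fractal_features(
    roi: RoiMatrix,
    spectra: Sequence[int],
    t: float = DEFAULT_LTP_THRESHOLD,
) -> Tuple[np.ndarray, List[str]]:
    """Fractal trio of each requested spectrum map, flattened row-major.

    Maps are cropped to the interior bounding box before flattening, so a
    constant ROI yields a constant spectrum-0 series (Petrosian exactly 1).
    """
    maps = ltp_spectrum_maps(roi, t)
    rs, cs = interior_bbox(roi)
    values, names = [], []
    for k in spectra:
        if not 0 <= k <= 8:
            raise ValueError(f"undefined LTP spectrum index {k}")
        series = maps[k][rs, cs].astype(float).ravel()
        trio = fractal_trio(series)
        values.extend(trio)
        names.extend(f"ltpfrac_s{k}_{f}" for f in ("higuchi", "petrosian", "hurst"))
    return np.asarray(values), names


def wavelet_fractal_features(
    roi: RoiMatrix,
    spectra: Sequence[int] = tuple(range(8)),
    wavelets: Sequence[str] = DEFAULT_WAVELETS,
    t: float = DEFAULT_LTP_THRESHOLD,
) -> Tuple[np.ndarray, List[str]]:
    """Fractal trio of the approximation band of each (spectrum, wavelet).

    Single-level 2-D Daubechies decomposition of each cropped spectrum map;
    the approximation coefficients are flattened row-major and summarized by
    the fractal trio.  Order: spectrum, then wavelet, then
    (higuchi, petrosian, hurst) — 3 x len(spectra) x len(wavelets) values.
    """
    maps = ltp_spectrum_maps(roi, t)
    rs, cs = interior_bbox(roi)
    values, names = [], []
    for k in spectra:
        if not 0 <= k <= 8:
            raise ValueError(f"undefined LTP spectrum index {k}")
        cropped = maps[k][rs, cs].astype(float)
        for wav in wavelets:
            approx, _ = pywt.dwt2(cropped, wav)
            trio = fractal_trio(approx.ravel())
            values.extend(trio)
            names.extend(
                f"wavfrac_s{k}_{wav}_{f}"
                for f in ("higuchi", "petrosian", "hurst")
            )
    return np.asarray(values), names


# ---------------------------------------------------------------------------
# feature groups


@dataclass(frozen=True)
class FeatureGroup:
    """A named recipe of extractor components applied to both breasts.

    ``components`` is a tuple of component descriptors, each one of
    ``("glcm",)``, ``("ltp_fractal", spectra)``,
    ``("wavelet_fractal", spectra, wavelets)`` or ``("ltp_hist", bins)``.
    ``expected_length`` is the total dimensionality over the two breasts.
    """

    name: str
    components: tuple
    expected_length: int

    @staticmethod
    def _component_length(comp: tuple) -> int:
        kind = comp[0]
        if kind == "glcm":
            return len(GLCM_DESCRIPTORS) * len(GLCM_ANGLES)
        if kind == "ltp_fractal":
            return 3 * len(comp[1])
        if kind == "wavelet_fractal":
            return 3 * len(comp[1]) * len(comp[2])
        if kind == "ltp_hist":
            return 2 * comp[1]
        raise ValueError(f"unknown component kind {kind!r}")

    @classmethod
    def from_components(cls, name: str, components: Iterable[tuple]) -> "FeatureGroup":
        components = tuple(tuple(c) for c in components)
        length = 2 * sum(cls._component_length(c) for c in components)
        return cls(name=name, components=components, expected_length=length)


def named_groups() -> dict:
    """The six standard feature groups with their fixed dimensionalities."""
    all8 = tuple(range(8))
    groups = [
        FeatureGroup.from_components(
            "fractals_wavelets_8ltp", [("wavelet_fractal", all8, DEFAULT_WAVELETS)]
        ),  # 3 fractals x 8 wavelets x 8 spectra x 2 breasts = 384
        FeatureGroup.from_components("fractals_8ltp", [("ltp_fractal", all8)]),  # 48
        FeatureGroup.from_components("glcm", [("glcm",)]),  # 48
        FeatureGroup.from_components(
            "fractals_2ltp_glcm", [("ltp_fractal", (0, 4)), ("glcm",)]
        ),  # 12 + 48 = 60
        FeatureGroup.from_components("fractals_3ltp", [("ltp_fractal", (0, 3, 6))]),  # 18
        FeatureGroup.from_components(
            "glcm_8ltp", [("ltp_hist", LTP_HIST_BINS), ("glcm",)]
        ),  # 100 + 48 = 148
    ]
    return {g.name: g for g in groups}


GROUP_NAMES = tuple(named_groups().keys())


@dataclass(frozen=True)
class FeatureVector:
    group: str
    values: np.ndarray
    column_names: tuple

    def __post_init__(self) -> None:
        if len(self.values) != len(self.column_names):
            raise ValueError("values/column_names length mismatch")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("duplicate column names")


def get_group(group) -> FeatureGroup:
    if isinstance(group, FeatureGroup):
        return group
    try:
        return named_groups()[group]
    except KeyError:
        raise ValueError(
            f"unknown feature group {group!r}; known: {GROUP_NAMES}"
        ) from None


def _breast_fragment(roi: RoiMatrix, group: FeatureGroup, t: float):
    values, names = [], []
    for comp in group.components:
        kind = comp[0]
        if kind == "glcm":
            v, n = glcm_features(roi)
        elif kind == "ltp_fractal":
            v, n = ltp_fractal_features(roi, comp[1], t=t)
        elif kind == "wavelet_fractal":
            v, n = wavelet_fractal_features(roi, comp[1], comp[2], t=t)
        elif kind == "ltp_hist":
            v, n = ltp_polarity_histograms(roi, t=t, bins=comp[1])
        else:
            raise ValueError(f"unknown component kind {kind!r}")
        values.append(v)
        names.extend(f"{roi.side}_{x}" for x in n)
    return np.concatenate(values), names


def compute_group(
    pair: RoiPair, group, t: float = DEFAULT_LTP_THRESHOLD
) -> FeatureVector:
    """Feature vector of one exam for a named or user-defined group.

    Left-breast fragment first, then right, each fragment following the
    recipe's component order.
    """
    group = get_group(group)
    lv, ln = _breast_fragment(pair.left, group, t)
    rv, rn = _breast_fragment(pair.right, group, t)
    values = np.concatenate([lv, rv])
    names = tuple(ln + rn)
    if len(values) != group.expected_length:
        raise AssertionError(
            f"group {group.name}: got {len(values)} values, "
            f"expected {group.expected_length}"
        )
    return FeatureVector(group=group.name, values=values, column_names=names)


def extract_table(
    pairs: Sequence[RoiPair], group, t: float = DEFAULT_LTP_THRESHOLD
):
    """Row-per-exam feature table for a list of labeled exams.

    Returns a :class:`thermoga.evaluation.Dataset`; row order follows the
    input order.
    """
    from .evaluation import Dataset  # local import to avoid a cycle

    if len(pairs) == 0:
        raise ValueError("empty table: no exams given")
    group = get_group(group)
    rows, labels, exam_ids = [], [], []
    columns = None
    for pair in pairs:
        if pair.label is None:
            raise ValueError(f"exam {pair.exam_id!r} has no label")
        fv = compute_group(pair, group, t)
        if columns is None:
            columns = fv.column_names
        elif fv.column_names != columns:
            raise ValueError("inconsistent feature columns across exams")
        rows.append(fv.values)
        labels.append(pair.label)
        exam_ids.append(pair.exam_id)
    return Dataset.from_labels(
        features=np.vstack(rows),
        labels=labels,
        column_names=list(columns),
        exam_ids=exam_ids,
    )
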