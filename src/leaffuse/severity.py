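"""Greenness-index severity scoring of nutrient deficiency from a leaf image.

The pipeline quantifies chlorosis in five steps:

1. **Segmentation** — the leaf is separated from the background with an
   excess-green index (2G − R − B), Otsu thresholding, morphological
   opening, and largest-connected-component selection.
2. **Symptom detection** — the image is converted to HSV and pixels in
   the yellow band (inside the leaf mask) are counted as symptomatic.
3. **Degree of Severity (DoS)** — symptomatic area / total leaf area.
4. **Channel trimming** — for each RGB channel, an intensity window
   centred at the channel mean grows by one unit per side until it covers
   at least 90% of the leaf pixels; the mean of the in-window values is
   the trimmed channel value (GCV), robust to intensity outliers.
5. **Greenness Index** — GI = G / (R + G + B + 1e−6) on the trimmed,
   unit-normalized channel values.  Because raw GI is bounded by 1, the
   severity thresholds (0.95 / 1.05) are applied to the ratio of the
   leaf's GI to a healthy-reference GI.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, opening as binary_opening

from .data_pipeline import validate_image

__all__ = [
    "ChannelStats",
    "LeafMask",
    "SeverityConfig",
    "SeverityReport",
    "classify_severity",
    "compute_gi",
    "degree_of_severity",
    "detect_symptoms",
    "score_image",
    "segment_leaf",
    "trim_channel_window",
]

GI_EPSILON = 1e-6


@dataclass(frozen=True)
class SeverityConfig:
    """Thresholds and colour bands for the severity pipeline.

    ``hsv_yellow_lower/upper`` are (hue°, saturation, value) with hue on a
    0–360° scale and saturation/value in [0, 1].  ``reference_gi`` is the
    greenness index of a healthy reference leaf; ``gi_low``/``gi_high``
    apply to the ratio gi / reference_gi.  The three DoS bands
    (mild < 0.10 ≤ moderate < 0.30 ≤ severe) are package defaults, not
    literature values.
    """

    p_threshold: float = 0.9
    gi_low: float = 0.95
    gi_high: float = 1.05
    epsilon: float = GI_EPSILON
    hsv_yellow_lower: tuple[float, float, float] = (40.0, 0.25, 0.25)
    hsv_yellow_upper: tuple[float, float, float] = (70.0, 1.0, 1.0)
    reference_gi: float | None = None
    dos_mild: float = 0.10
    dos_severe: float = 0.30
    opening_radius: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.gi_low >= self.gi_high:
            raise ValueError("gi_low must be below gi_high")
        if not 0.0 <= self.dos_mild <= self.dos_severe <= 1.0:
            raise ValueError("DoS bands must satisfy 0 <= mild <= severe <= 1")


@dataclass
class LeafMask:
    """Binary leaf mask plus an empty-segmentation flag."""

    mask: np.ndarray  # H x W bool
    empty: bool = False

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class ChannelStats:
    """Trimmed-window summary of one colour channel inside the leaf."""

    channel: str  # "R", "G" or "B"
    mean: float
    window: tuple[int, int]
    coverage: float
    gcv: float  # trimmed channel value, 0-255 scale

    @property
    def gcv_normalized(self) -> float:
        return self.gcv / 255.0


@dataclass
class SeverityReport:
    gi: float
    gi_ratio: float | None
    dos: float
    label: str
    dos_label: str
    channel_stats: dict[str, ChannelStats]
    leaf_area: int
    symptom_area: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def segment_leaf(img: np.ndarray, opening_radius: int = 2) -> LeafMask:
    """Segment the leaf from the background.

    Excess-green index (2G − R − B) + Otsu threshold + morphological
    opening + largest connected component.  An image with no detectable
    foreground yields an empty mask with the ``empty`` flag set, not an
    exception.
    """
    img = validate_image(img)
    rgb = img.astype(float)
    exg = 2.0 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]
    if np.ptp(exg) < 1e-9:  # constant field: Otsu undefined
        return LeafMask(mask=np.zeros(img.shape[:2], dtype=bool), empty=True)
    thr = threshold_otsu(exg)
    mask = exg > thr
    if opening_radius > 0:
        mask = binary_opening(mask, disk(opening_radius))
    if not mask.any():
        return LeafMask(mask=mask, empty=True)
    labels = cc_label(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0  # background
    mask = labels == int(sizes.argmax())
    return LeafMask(mask=mask, empty=False)


def detect_symptoms(
    img: np.ndarray, leaf: LeafMask, cfg: SeverityConfig = SeverityConfig()
) -> np.ndarray:
    """Binary mask of chlorotic (yellow) pixels inside the leaf.

    Yellow is detected in HSV space between the configured lower and upper
    bounds; pixels outside the leaf mask are never symptomatic.
    """
    img = validate_image(img)
    if leaf.mask.shape != img.shape[:2]:
        raise ValueError("leaf mask shape does not match image")
    if not leaf.mask.any():
        return np.zeros_like(leaf.mask)
    hsv = rgb2hsv(img)  # h, s, v all in [0, 1]
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    lo_h, lo_s, lo_v = cfg.hsv_yellow_lower
    hi_h, hi_s, hi_v = cfg.hsv_yellow_upper
    yellow = (
        (hue >= lo_h) & (hue <= hi_h)
        & (sat >= lo_s) & (sat <= hi_s)
        & (val >= lo_v) & (val <= hi_v)
    )
    return yellow & leaf.mask


def degree_of_severity(symptoms: np.ndarray, leaf: LeafMask) -> float:
    """DoS = symptomatic area / total leaf area.

    NaN (with no exception) when the leaf mask is empty, mirroring the
    flagged-empty segmentation convention.
    """
    if leaf.area == 0:
        return float("nan")
    overlap = symptoms & leaf.mask
    return float(overlap.sum()) / leaf.area


def trim_channel_window(values: np.ndarray, p_threshold: float = 0.9,
                        channel: str = "?") -> ChannelStats:
    """Grow an intensity window around the channel mean to ≥ p coverage.

    The window starts at the rounded mean ``[X, X]`` and expands by one
    intensity unit per side per iteration (clamped to [0, 255]) until the
    fraction of values inside it reaches ``p_threshold``; the trimmed
    channel value (GCV) is the mean of the in-window values.  Coverage is
    non-decreasing and the loop always terminates because the window is
    bounded by the full intensity range.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty channel value list")
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in (0, 1]")
    mean = float(values.mean())
    x = int(min(255, max(0, math.floor(mean + 0.5))))  # round half up
    lo = hi = x
    n = values.size
    while True:
        inside = (values >= lo) & (values <= hi)
        coverage = inside.sum() / n
        if coverage >= p_threshold or (lo == 0 and hi == 255):
            break
        lo = max(0, lo - 1)
        hi = min(255, hi + 1)
    gcv = float(values[inside].mean()) if inside.any() else float(x)
    return ChannelStats(channel=channel, mean=mean, window=(lo, hi),
                        coverage=float(coverage), gcv=gcv)


def compute_gi(stats_r: ChannelStats, stats_g: ChannelStats,
               stats_b: ChannelStats, epsilon: float = GI_EPSILON) -> float:
    """Greenness Index GI = G / (R + G + B + ε) on unit-normalized GCVs."""
    r = stats_r.gcv_normalized
    g = stats_g.gcv_normalized
    b = stats_b.gcv_normalized
    return g / (r + g + b + epsilon)


def classify_severity(
    gi_ratio: float | None, dos: float, cfg: SeverityConfig = SeverityConfig()
) -> tuple[str, str]:
    """Map the GI ratio and DoS to severity labels.

    Returns ``(gi_label, dos_label)``: the GI label follows the two
    thresholds on gi/reference (above ``gi_high`` → "high", below
    ``gi_low`` → "minor", between → "none"); the DoS label is the
    three-band mild/moderate/severe reading of the symptomatic-area
    fraction.
    """
    if gi_ratio is None or math.isnan(gi_ratio):
        gi_label = "unknown"
    elif gi_ratio > cfg.gi_high:
        gi_label = "high"
    elif gi_ratio < cfg.gi_low:
        gi_label = "minor"
    else:
        gi_label = "none"
    if math.isnan(dos):
        dos_label = "unknown"
    elif dos < cfg.dos_mild:
        dos_label = "mild"
    elif dos < cfg.dos_severe:
        dos_label = "moderate"
    else:
        dos_label = "severe"
    return gi_label, dos_label


def score_image(
    img: np.ndarray,
    cfg: SeverityConfig = SeverityConfig(),
    reference_img: np.ndarray | None = None,
) -> SeverityReport:
    """Full severity pipeline for one image.

    ``reference_img`` (a healthy leaf) or ``cfg.reference_gi`` provides
    the denominator for the GI ratio; with neither, the GI ratio and its
    label are left undefined and flagged.
    """
    img = validate_image(img)
    flags: list[str] = []
    leaf = segment_leaf(img, opening_radius=cfg.opening_radius)
    if leaf.empty:
        flags.append("empty_leaf_mask")
        empty_stats = {
            c: ChannelStats(channel=c, mean=float("nan"), window=(0, 0),
                            coverage=0.0, gcv=float("nan"))
            for c in "RGB"
        }
        return SeverityReport(
            gi=float("nan"), gi_ratio=None, dos=float("nan"),
            label="unknown", dos_label="unknown", channel_stats=empty_stats,
            leaf_area=0, symptom_area=0, flags=flags,
        )
    symptoms = detect_symptoms(img, leaf, cfg)
    dos = degree_of_severity(symptoms, leaf)
    stats = {
        c: trim_channel_window(img[..., i][leaf.mask], cfg.p_threshold, channel=c)
        for i, c in enumerate("RGB")
    }
    gi = compute_gi(stats["R"], stats["G"], stats["B"], cfg.epsilon)

    reference_gi = cfg.reference_gi
    if reference_img is not None:
        ref_report = score_image(reference_img, cfg=SeverityConfig(
            p_threshold=cfg.p_threshold,
            hsv_yellow_lower=cfg.hsv_yellow_lower,
            hsv_yellow_upper=cfg.hsv_yellow_upper,
            opening_radius=cfg.opening_radius,
        ))
        if "empty_leaf_mask" in ref_report.flags:
            flags.append("reference_segmentation_failed")
        else:
            reference_gi = ref_report.gi
    gi_ratio = gi / reference_gi if reference_gi else None
    if gi_ratio is None:
        flags.append("no_reference_gi")
    gi_label, dos_label = classify_severity(gi_ratio, dos, cfg)
    return SeverityReport(
        gi=gi, gi_ratio=gi_ratio, dos=dos, label=gi_label, dos_label=dos_label,
        channel_stats=stats, leaf_area=leaf.area, symptom_area=int(symptoms.sum()),
        flags=flags,
    )
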