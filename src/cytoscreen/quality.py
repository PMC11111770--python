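"""Thumbnail standardization and heuristic slide-quality assessment.

The assessment mirrors a two-branch QC model interface: a binary
acceptable/problematic summary plus per-issue severities for blur,
incomplete scan and low cellularity. The baseline here is deterministic
image heuristics; a learned model can be plugged in behind the same
:class:`QualityReport` contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Union

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.transform import resize

THUMBNAIL_SHORT_EDGE = 1000

#: brightness above which a pixel counts as blank background (gray in [0, 1])
_BLANK_LEVEL = 0.92
#: sharpness scale calibrating blur severity to [0, 1]
_SHARPNESS_SCALE = 2e-4
_QC_GRID = 8  # blocks per axis for the blank-region (incomplete scan) check


@dataclass(frozen=True)
class QCThresholds:
    blur: float = 0.5
    incomplete_scan: float = 0.3
    low_cellularity: float = 0.5


@dataclass
class QualityReport:
    acceptable: bool
    issues: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps({"acceptable": self.acceptable, "issues": self.issues}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def standardize_thumbnail(image: np.ndarray) -> np.ndarray:
    """Resize so the short edge is exactly 1000 px, preserving aspect ratio.

    The long edge is rounded to the nearest integer; upscaling is
    permitted. Idempotent: an already standardized thumbnail is returned
    unchanged.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB raster")
    h, w = arr.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("empty image")
    short = min(h, w)
    if short == THUMBNAIL_SHORT_EDGE:
        return arr.copy()
    scale = THUMBNAIL_SHORT_EDGE / short
    new_h = THUMBNAIL_SHORT_EDGE if h == short else int(round(h * scale))
    new_w = THUMBNAIL_SHORT_EDGE if w == short else int(round(w * scale))
    out = resize(
        arr.astype(np.float64),
        (new_h, new_w, 3),
        order=1,
        anti_aliasing=scale < 1.0,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def blur_severity(gray: np.ndarray) -> float:
    """Blur score in [0, 1] from a normalized local-contrast statistic.

    Uses the variance of the Laplacian response relative to the global
    gray-level variance; heavier Gaussian blur suppresses the Laplacian
    energy faster than the global contrast, so severity grows with blur.
    """
    # pre-smooth so 8-bit quantization noise cannot dominate the tail;
    # normalize by mean brightness (blur-invariant), keeping the statistic
    # monotone in applied blur
    smoothed = ndimage.gaussian_filter(gray, 1.0)
    lap = ndimage.laplace(smoothed)
    denom = float(gray.mean()) ** 2 + 1e-12
    sharpness = float(lap.var()) / denom
    return float(np.exp(-sharpness / _SHARPNESS_SCALE))


def _tissue_mask(gray: np.ndarray) -> np.ndarray:
    return gray < _BLANK_LEVEL


def incomplete_scan_severity(gray: np.ndarray) -> float:
    """Fraction of coarse image blocks that contain essentially no tissue."""
    mask = _tissue_mask(gray)
    h, w = mask.shape
    ys = np.linspace(0, h, _QC_GRID + 1, dtype=int)
    xs = np.linspace(0, w, _QC_GRID + 1, dtype=int)
    blank_blocks = 0
    for i in range(_QC_GRID):
        for j in range(_QC_GRID):
            block = mask[ys[i] : ys[i + 1], xs[j] : xs[j + 1]]
            if block.size == 0 or block.mean() < 0.01:
                blank_blocks += 1
    return blank_blocks / (_QC_GRID * _QC_GRID)


def low_cellularity_severity(gray: np.ndarray) -> float:
    """1 minus the tissue-pixel fraction."""
    return float(1.0 - _tissue_mask(gray).mean())


def assess_quality(
    thumbnail: np.ndarray, thresholds: QCThresholds = QCThresholds()
) -> QualityReport:
    """Heuristic quality report for a standardized RGB thumbnail.

    A slide is acceptable iff every issue severity is at or below its
    threshold.
    """
    arr = np.asarray(thumbnail)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB raster")
    gray = rgb2gray(arr)  # floats in [0, 1]
    issues = {
        "blur": blur_severity(gray),
        "incomplete_scan": incomplete_scan_severity(gray),
        "low_cellularity": low_cellularity_severity(gray),
    }
    acceptable = (
        issues["blur"] <= thresholds.blur
        and issues["incomplete_scan"] <= thresholds.incomplete_scan
        and issues["low_cellularity"] <= thresholds.low_cellularity
    )
    return QualityReport(acceptable=acceptable, issues=issues)
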