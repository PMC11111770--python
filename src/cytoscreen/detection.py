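"""Patch-detector contract, simulated detector, and slide-level aggregation.

A real detection model's per-patch output can be ingested through the
same :class:`PatchDetection` records (see :mod:`cytoscreen.io`); the
:class:`SimulatedDetector` stands in for it by sampling detections from
a statistical profile attached to latent slide/patch descriptors, so
every downstream stage can be exercised without a trained network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import PatchGrade, SlideGrade, SlideRecord
from .tiling import Box, to_slide_coords

DEFAULT_DEDUP_IOU = 0.5

#: typical abnormal-cell bounding-box edge in px at 40x (about 10-20 um)
_MIN_CELL_PX, _MAX_CELL_PX = 40, 80


@dataclass(frozen=True)
class PatchDetection:
    """One detected abnormal cell."""

    grade: PatchGrade
    confidence: float
    box: Box
    epithelium_score: float = 1.0  # 1 = squamous, 0 = glandular

    def __post_init__(self) -> None:
        object.__setattr__(self, "grade", PatchGrade.from_label(self.grade))
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if not (0.0 <= self.epithelium_score <= 1.0):
            raise ValueError("epithelium_score must be in [0, 1]")
        x0, y0, x1, y1 = self.box
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"box must have positive area, got {self.box}")


@dataclass
class SlideDetectionSet:
    """All detections of one slide, in slide coordinates."""

    slide: SlideRecord
    detections: List[PatchDetection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two (x0, y0, x1, y1) boxes."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def _clip_box(box: Box, width: int, height: int) -> Box:
    x0 = min(max(box[0], 0.0), width - 1.0)
    y0 = min(max(box[1], 0.0), height - 1.0)
    x1 = min(max(box[2], x0 + 1e-9), float(width))
    y1 = min(max(box[3], y0 + 1e-9), float(height))
    return (x0, y0, x1, y1)


def aggregate_detections(
    patch_outputs: Iterable[Tuple[Tuple[int, int], Sequence[PatchDetection]]],
    slide: SlideRecord,
    dedup_iou: float = DEFAULT_DEDUP_IOU,
) -> SlideDetectionSet:
    """Merge per-patch detections into one deduplicated slide-level set.

    ``patch_outputs`` yields (patch origin, detections-in-patch-coords)
    pairs. Boxes are translated to slide coordinates and clipped to the
    slide bounds; within each grade, overlapping duplicates (IoU >
    ``dedup_iou``) are suppressed keeping the higher-confidence box
    (greedy non-maximum suppression).
    """
    translated: List[PatchDetection] = []
    for origin, dets in patch_outputs:
        for det in dets:
            box = _clip_box(to_slide_coords(det.box, origin), slide.width_px, slide.height_px)
            translated.append(replace(det, box=box))

    kept: List[PatchDetection] = []
    for grade in PatchGrade:
        group = [d for d in translated if d.grade is grade]
        # high confidence first; deterministic tie-break by box origin
        group.sort(key=lambda d: (-d.confidence, d.box[1], d.box[0]))
        chosen: List[PatchDetection] = []
        for det in group:
            if all(iou(det.box, c.box) <= dedup_iou for c in chosen):
                chosen.append(det)
        kept.extend(chosen)
    return SlideDetectionSet(slide=slide, detections=kept)


def top_k_per_class(
    ds: SlideDetectionSet, k: int = 20
) -> Dict[PatchGrade, List[PatchDetection]]:
    """Up to ``k`` highest-confidence detections per class, for review.

    Sorted by confidence descending; ties broken by (y, x) of the box
    origin ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: Dict[PatchGrade, List[PatchDetection]] = {}
    for grade in PatchGrade:
        group = sorted(
            (d for d in ds if d.grade is grade),
            key=lambda d: (-d.confidence, d.box[1], d.box[0]),
        )
        out[grade] = group[:k]
    return out


@dataclass
class DetectorProfile:
    """Statistical behaviour of a (simulated) patch detector.

    ``rates`` gives, per true slide grade, the mean number of abnormal
    cells of each patch class on a slide (Poisson). Emitted class labels
    pass through ``confusion`` (rows = true class, in PatchGrade order).
    Confidences are Beta-distributed, with separate parameters for
    detections of true cells and for false positives; ``fp_rate`` is the
    expected number of false positives per slide on NILM tissue.
    """

    rates: Mapping[SlideGrade, Mapping[PatchGrade, float]]
    confusion: np.ndarray
    tp_conf: Tuple[float, float] = (8.0, 2.0)
    fp_conf: Tuple[float, float] = (2.0, 8.0)
    fp_rate: float = 0.5

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=np.float64)
        n = len(PatchGrade)
        if self.confusion.shape != (n, n):
            raise ValueError(f"confusion must be {n}x{n}")
        if np.any(self.confusion < 0) or not np.allclose(self.confusion.sum(axis=1), 1.0):
            raise ValueError("confusion rows must be nonnegative and sum to 1")
        for grade_rates in self.rates.values():
            if any(r < 0 for r in grade_rates.values()):
                raise ValueError("Poisson rates must be nonnegative")
        if min(self.tp_conf) <= 0 or min(self.fp_conf) <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be nonnegative")


@dataclass(frozen=True)
class LatentPatch:
    """Ground-truth inventory attached to one synthetic patch.

    ``true_cells`` lists the patch classes of the abnormal cells present;
    ``fp_mean`` is the expected false-positive count for this patch.
    """

    patch_size_px: int
    true_cells: Tuple[PatchGrade, ...] = ()
    fp_mean: float = 0.0


_GRADE_INDEX = {g: i for i, g in enumerate(PatchGrade)}
_GRADES = tuple(PatchGrade)


def _sample_box(rng: np.random.Generator, width: float, height: float) -> Box:
    w = float(rng.uniform(_MIN_CELL_PX, _MAX_CELL_PX))
    h = float(rng.uniform(_MIN_CELL_PX, _MAX_CELL_PX))
    w, h = min(w, width), min(h, height)
    x0 = float(rng.uniform(0, max(width - w, 1e-9)))
    y0 = float(rng.uniform(0, max(height - h, 1e-9)))
    return (x0, y0, x0 + w, y0 + h)


def _epithelium_score(grade: PatchGrade, rng: np.random.Generator) -> float:
    # glandular cells score low, squamous high
    if grade is PatchGrade.AGC:
        return float(rng.beta(2.0, 8.0))
    return float(rng.beta(8.0, 2.0))


def sample_detections(
    profile: DetectorProfile,
    true_cells: Sequence[PatchGrade],
    fp_mean: float,
    width: float,
    height: float,
    rng: np.random.Generator,
) -> List[PatchDetection]:
    """Draw detections for a region holding ``true_cells`` abnormal cells."""
    dets: List[PatchDetection] = []
    a_tp, b_tp = profile.tp_conf
    a_fp, b_fp = profile.fp_conf
    for cell in true_cells:
        row = profile.confusion[_GRADE_INDEX[cell]]
        emitted = _GRADES[int(rng.choice(len(_GRADES), p=row))]
        conf = float(np.clip(rng.beta(a_tp, b_tp), 0.0, 1.0))
        dets.append(
            PatchDetection(
                grade=emitted,
                confidence=conf,
                box=_sample_box(rng, width, height),
                epithelium_score=_epithelium_score(emitted, rng),
            )
        )
    n_fp = int(rng.poisson(fp_mean)) if fp_mean > 0 else 0
    for _ in range(n_fp):
        emitted = _GRADES[int(rng.integers(len(_GRADES)))]
        conf = float(np.clip(rng.beta(a_fp, b_fp), 0.0, 1.0))
        dets.append(
            PatchDetection(
                grade=emitted,
                confidence=conf,
                box=_sample_box(rng, width, height),
                epithelium_score=_epithelium_score(emitted, rng),
            )
        )
    return dets


class SimulatedDetector:
    """Detector plug-in that samples from a :class:`DetectorProfile`.

    ``detect`` consumes :class:`LatentPatch` descriptors (the latent
    truth attached to synthetic patches) instead of pixel rasters.
    Deterministic for a fixed seed.
    """

    def __init__(self, profile: DetectorProfile, seed: int = 0) -> None:
        self.profile = profile
        self._rng = np.random.default_rng(seed)

    def detect(self, patch: LatentPatch) -> List[PatchDetection]:
        if not isinstance(patch, LatentPatch):
            raise TypeError("SimulatedDetector consumes LatentPatch descriptors")
        size = float(patch.patch_size_px)
        return sample_detections(
            self.profile, patch.true_cells, patch.fp_mean, size, size, self._rng
        )
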