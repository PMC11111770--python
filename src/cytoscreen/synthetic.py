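"""Generators for every input the pipeline needs.

Grade-conditioned synthetic slide detection profiles, two-stain
Beer-Lambert RGB images with known ground truth for the stain
augmentation oracle, fixture cohorts whose prevalences mirror a
screening population, and simulated reader / AI-assisted-reader arms.
All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .core import PatchGrade, RiskStratum, SlideGrade, SlideRecord, stratum_membership
from .detection import (
    DetectorProfile,
    PatchDetection,
    SlideDetectionSet,
    sample_detections,
)
from .stain import DEFAULT_BACKGROUND, DEFAULT_EPS

#: Reference H and E absorbance vectors (unit norm) for image synthesis.
REFERENCE_H = np.array([0.65, 0.70, 0.29]) / np.linalg.norm([0.65, 0.70, 0.29])
REFERENCE_E = np.array([0.07, 0.99, 0.11]) / np.linalg.norm([0.07, 0.99, 0.11])

#: Training-mix slide-grade prevalences used by the bundled demo cohort
#: (enriched for lesions, as screening model-development sets are).
DEMO_PREVALENCES: Dict[SlideGrade, float] = {
    SlideGrade.NILM: 0.724,
    SlideGrade.ASC_US: 0.078,
    SlideGrade.LSIL: 0.107,
    SlideGrade.HSIL_PLUS: 0.077,
    SlideGrade.AGC: 0.014,
}

_DEFAULT_SLIDE_PX = 20000


def default_detector_profile() -> DetectorProfile:
    """A learnable but non-trivial simulated detector.

    Grade-conditioned abnormal-cell rates are separated by >= 4x between
    adjacent grades; the class-confusion matrix leaks 10% of mass to
    morphologically adjacent classes; true-cell confidences follow
    Beta(8, 2) and false positives Beta(2, 8) with 0.5 expected false
    positives per slide.
    """
    zero = {g: 0.0 for g in PatchGrade}
    rates: Dict[SlideGrade, Dict[PatchGrade, float]] = {
        SlideGrade.NILM: dict(zero),
        SlideGrade.ASC_US: {**zero, PatchGrade.ASC_US: 8.0},
        SlideGrade.LSIL: {**zero, PatchGrade.ASC_US: 2.0, PatchGrade.LSIL: 10.0},
        SlideGrade.HSIL_PLUS: {
            **zero,
            PatchGrade.LSIL: 2.0,
            PatchGrade.ASC_H: 4.0,
            PatchGrade.HSIL: 10.0,
            PatchGrade.SCC: 1.0,
        },
        SlideGrade.AGC: {**zero, PatchGrade.AGC: 8.0},
    }
    n = len(PatchGrade)
    confusion = np.full((n, n), 0.1 / (n - 1))
    np.fill_diagonal(confusion, 0.9)
    return DetectorProfile(rates=rates, confusion=confusion)


@dataclass
class CohortConfig:
    """Recipe for one synthetic slide cohort."""

    n_slides: int
    prevalences: Mapping[SlideGrade, float] = field(
        default_factory=lambda: dict(DEMO_PREVALENCES)
    )
    profile: DetectorProfile = field(default_factory=default_detector_profile)
    seed: int = 0
    slide_px: int = _DEFAULT_SLIDE_PX
    pixel_size_um: float = 0.2529

    def __post_init__(self) -> None:
        if self.n_slides < 1:
            raise ValueError("n_slides must be >= 1")
        total = sum(self.prevalences.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.prevalences.values()):
            raise ValueError("prevalences must be nonnegative and sum to 1")


def generate_cohort(
    cfg: CohortConfig,
) -> Tuple[List[SlideDetectionSet], List[SlideGrade]]:
    """Sample a cohort of slide detection sets with known true grades.

    Per slide: the true grade is drawn from the prevalence vector;
    abnormal-cell counts per patch class from the grade-conditioned
    Poisson rates; each cell's emitted class passes through the
    confusion matrix; confidences come from the profile's Beta
    distributions; boxes fall uniformly within the slide bounds.
    """
    rng = np.random.default_rng(cfg.seed)
    grades = list(cfg.prevalences.keys())
    probs = np.array([cfg.prevalences[g] for g in grades], dtype=np.float64)
    probs = probs / probs.sum()

    slides: List[SlideDetectionSet] = []
    truths: List[SlideGrade] = []
    for i in range(cfg.n_slides):
        grade = grades[int(rng.choice(len(grades), p=probs))]
        record = SlideRecord(
            slide_id=f"synthetic-{cfg.seed}-{i:05d}",
            width_px=cfg.slide_px,
            height_px=cfg.slide_px,
            pixel_size_um=cfg.pixel_size_um,
            true_grade=grade,
        )
        cells: List[PatchGrade] = []
        for cls in PatchGrade:
            count = int(rng.poisson(cfg.profile.rates[grade][cls]))
            cells.extend([cls] * count)
        dets = sample_detections(
            cfg.profile,
            cells,
            cfg.profile.fp_rate,
            float(cfg.slide_px),
            float(cfg.slide_px),
            rng,
        )
        slides.append(SlideDetectionSet(slide=record, detections=dets))
        truths.append(grade)
    return slides, truths


def generate_stain_image(
    shape: Tuple[int, int] = (96, 96),
    stain_vectors: Optional[np.ndarray] = None,
    concentrations: Optional[np.ndarray] = None,
    max_concentration: Tuple[float, float] = (1.2, 1.0),
    seed: int = 0,
    background_intensity: float = DEFAULT_BACKGROUND,
    eps: float = DEFAULT_EPS,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthesize a two-stain Beer-Lambert RGB image with known truth.

    Returns (rgb uint8 raster, stain_vectors (3, 2), concentrations
    (h, w, 2)). Pixel RGB = background * exp(-stains @ conc) - eps,
    quantized to 8 bits. Concentrations default to independent uniforms
    on [0, max_concentration].
    """
    if stain_vectors is None:
        stain_vectors = np.column_stack([REFERENCE_H, REFERENCE_E])
    stain_vectors = np.asarray(stain_vectors, dtype=np.float64)
    if stain_vectors.shape != (3, 2):
        raise ValueError("stain_vectors must be (3, 2) columns [H, E]")
    norms = np.linalg.norm(stain_vectors, axis=0)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("stain vectors must be unit norm")
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = np.stack(
            [
                rng.uniform(0.0, max_concentration[0], size=shape),
                rng.uniform(0.0, max_concentration[1], size=shape),
            ],
            axis=-1,
        )
    concentrations = np.asarray(concentrations, dtype=np.float64)
    sda = concentrations @ stain_vectors.T  # (h, w, 3)
    rgb = background_intensity * np.exp(-sda) - eps
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return rgb, stain_vectors, concentrations


@dataclass
class ReaderProfile:
    """Behavioural model of a cytopathologist reader.

    ``sensitivity``/``specificity`` give the unassisted binary-call
    operating point per risk stratum. In the assisted arm, an
    AI-positive slide becomes a final positive with probability
    ``confirmation_prob``; an AI-negative slide that is truly positive
    is independently caught with probability ``independent_catch_prob``,
    and a truly negative AI-negative slide stays negative.
    """

    sensitivity: Mapping[RiskStratum, float]
    specificity: Mapping[RiskStratum, float]
    confirmation_prob: float = 1.0
    independent_catch_prob: float = 0.5

    def __post_init__(self) -> None:
        for m in (self.sensitivity, self.specificity):
            if any(not 0.0 <= v <= 1.0 for v in m.values()):
                raise ValueError("per-stratum probabilities must be in [0, 1]")
        if not (0.0 <= self.confirmation_prob <= 1.0):
            raise ValueError("confirmation_prob must be in [0, 1]")
        if not (0.0 <= self.independent_catch_prob <= 1.0):
            raise ValueError("independent_catch_prob must be in [0, 1]")

    @classmethod
    def uniform(
        cls,
        sensitivity: float,
        specificity: float,
        confirmation_prob: float = 1.0,
        independent_catch_prob: float = 0.5,
    ) -> "ReaderProfile":
        return cls(
            sensitivity={s: sensitivity for s in RiskStratum},
            specificity={s: specificity for s in RiskStratum},
            confirmation_prob=confirmation_prob,
            independent_catch_prob=independent_catch_prob,
        )


def simulate_reader_arms(
    truth: Sequence[Union[str, SlideGrade]],
    ai_predictions: Sequence[Union[str, SlideGrade]],
    rp: ReaderProfile,
    stratum: RiskStratum,
    seed: int = 0,
) -> Tuple[List[bool], List[bool]]:
    """Simulate unassisted and AI-assisted binary reader calls.

    Returns (reader_calls, assisted_calls) as stratum-positive booleans.
    """
    if len(truth) != len(ai_predictions):
        raise ValueError("truth and ai_predictions must have equal length")
    rng = np.random.default_rng(seed)
    sens = rp.sensitivity[stratum]
    spec = rp.specificity[stratum]
    reader_calls: List[bool] = []
    assisted_calls: List[bool] = []
    for t, ai in zip(truth, ai_predictions):
        t_pos = stratum_membership(t, stratum)
        ai_pos = stratum_membership(ai, stratum)
        if t_pos:
            reader_calls.append(bool(rng.random() < sens))
        else:
            reader_calls.append(bool(rng.random() >= spec))
        if ai_pos:
            assisted_calls.append(bool(rng.random() < rp.confirmation_prob))
        elif t_pos:
            assisted_calls.append(bool(rng.random() < rp.independent_catch_prob))
        else:
            assisted_calls.append(False)
    return reader_calls, assisted_calls
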