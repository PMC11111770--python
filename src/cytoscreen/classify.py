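"""Slide-level feature extraction and random-forest TBS grading.

Each slide's detection set is reduced to a fixed-length vector of
per-class confidence statistics (max, mean, SD and confidence-interval
bin proportions, optionally raw counts and a glandular fraction), which
a random forest maps to one of the five slide report categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .core import SEVERITY_ORDER, PatchGrade, RiskStratum, SlideGrade
from .detection import SlideDetectionSet

DEFAULT_N_BINS = 10
DEFAULT_RF_SEED = 20140101
DEFAULT_N_TREES = 500


def default_bins(n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equal-width confidence bin edges on [0, 1] (last bin right-closed).

    Edges are computed as i / n so that round decimals like 0.6 compare
    equal to their edge (linspace accumulates one-ulp errors there).
    """
    return np.arange(n_bins + 1) / n_bins


def _grade_key(grade: PatchGrade) -> str:
    return grade.value.replace("-", "_")


def feature_names(
    bins: Optional[np.ndarray] = None,
    include_counts: bool = True,
    include_glandular: bool = True,
) -> List[str]:
    """Stable header names matching :func:`extract_features` layout."""
    bins = default_bins() if bins is None else np.asarray(bins)
    n_bins = len(bins) - 1
    names: List[str] = []
    for grade in PatchGrade:
        key = _grade_key(grade)
        names += [f"{key}_max_conf", f"{key}_mean_conf", f"{key}_std_conf"]
        names += [f"{key}_bin_{i:02d}" for i in range(n_bins)]
    if include_counts:
        names += [f"{_grade_key(g)}_count" for g in PatchGrade]
    if include_glandular:
        names.append("glandular_fraction")
    return names


@dataclass(frozen=True)
class SlideFeatureVector:
    """Fixed-length per-slide feature vector with its header names."""

    values: np.ndarray
    names: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names length mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _validate_bins(bins: np.ndarray) -> np.ndarray:
    bins = np.asarray(bins, dtype=np.float64)
    if bins.ndim != 1 or len(bins) < 2:
        raise ValueError("bins must be a 1-D array of at least 2 edges")
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if bins[0] != 0.0 or bins[-1] != 1.0:
        raise ValueError("bin edges must span [0, 1]")
    return bins


def extract_features(
    ds: SlideDetectionSet,
    bins: Optional[np.ndarray] = None,
    include_counts: bool = True,
    include_glandular: bool = True,
) -> SlideFeatureVector:
    """Compute the slide feature vector from a detection set.

    Per patch class: maximum, mean and (population) standard deviation
    of the detection confidences, plus the proportion of that class's
    detections falling in each confidence bin. Classes with no
    detections contribute zeros. Order-independent and deterministic.
    """
    bins = _validate_bins(default_bins() if bins is None else bins)
    n_bins = len(bins) - 1
    blocks: List[np.ndarray] = []
    counts: List[float] = []
    for grade in PatchGrade:
        confs = np.array([d.confidence for d in ds if d.grade is grade])
        counts.append(float(len(confs)))
        if len(confs) == 0:
            blocks.append(np.zeros(3 + n_bins))
            continue
        hist, _ = np.histogram(confs, bins=bins)
        stats = np.array([confs.max(), confs.mean(), confs.std()])
        blocks.append(np.concatenate([stats, hist / len(confs)]))
    values = np.concatenate(blocks)
    if include_counts:
        values = np.concatenate([values, counts])
    if include_glandular:
        scores = np.array([d.epithelium_score for d in ds])
        gland = float((1.0 - scores).mean()) if len(scores) else 0.0
        values = np.append(values, gland)
    return SlideFeatureVector(
        values=values,
        names=tuple(feature_names(bins, include_counts, include_glandular)),
    )


def feature_matrix(features: Sequence[SlideFeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame with stable headers."""
    if not features:
        raise ValueError("no feature vectors given")
    names = features[0].names
    for f in features:
        if f.names != names:
            raise ValueError("inconsistent feature layouts")
    return pd.DataFrame(np.vstack([f.values for f in features]), columns=list(names))


@dataclass
class SlideClassifier:
    """Random forest over slide feature vectors with TBS class labels."""

    estimator: RandomForestClassifier
    feature_names: Tuple[str, ...]
    classes: Tuple[SlideGrade, ...]
    seed: int
    oob_accuracy: Optional[float] = None

    def save(self, path: Union[str, Path]) -> None:
        joblib.dump(
            {
                "format_version": 1,
                "estimator": self.estimator,
                "feature_names": list(self.feature_names),
                "classes": [g.value for g in self.classes],
                "seed": self.seed,
                "oob_accuracy": self.oob_accuracy,
            },
            path,
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SlideClassifier":
        payload = joblib.load(path)
        return cls(
            estimator=payload["estimator"],
            feature_names=tuple(payload["feature_names"]),
            classes=tuple(SlideGrade.from_label(c) for c in payload["classes"]),
            seed=payload["seed"],
            oob_accuracy=payload.get("oob_accuracy"),
        )


def train_slide_classifier(
    features: Sequence[SlideFeatureVector],
    labels: Sequence[SlideGrade],
    n_trees: int = DEFAULT_N_TREES,
    max_features: Union[str, float] = "sqrt",
    seed: int = DEFAULT_RF_SEED,
    **rf_kwargs,
) -> SlideClassifier:
    """Fit the slide-grade random forest. Reproducible given ``seed``."""
    if len(features) != len(labels):
        raise ValueError("features and labels length mismatch")
    labels = [SlideGrade.from_label(lbl) for lbl in labels]
    if len(set(labels)) < 2:
        raise ValueError("training requires at least 2 distinct slide grades")
    X = feature_matrix(features).to_numpy()
    y = np.array([g.value for g in labels])
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        oob_score=True,
        **rf_kwargs,
    )
    rf.fit(X, y)
    return SlideClassifier(
        estimator=rf,
        feature_names=features[0].names,
        classes=tuple(SlideGrade.from_label(c) for c in rf.classes_),
        seed=seed,
        oob_accuracy=float(rf.oob_score_),
    )


@dataclass(frozen=True)
class SlidePrediction:
    grade: SlideGrade
    probabilities: Dict[SlideGrade, float]
    abnormality_score: float  # 1 - P(NILM)

    def stratum_score(self, stratum: RiskStratum) -> float:
        """Sum of member-grade probabilities for a risk stratum."""
        return sum(self.probabilities.get(g, 0.0) for g in stratum.slide_members)


def predict_slide_grade(
    model: SlideClassifier, fv: SlideFeatureVector
) -> SlidePrediction:
    """Predict the slide grade; ties resolve toward the more severe grade."""
    if fv.names != model.feature_names:
        raise ValueError("feature layout does not match the fitted model")
    proba = model.estimator.predict_proba(fv.values.reshape(1, -1))[0]
    probs = {g: 0.0 for g in SlideGrade}
    probs.update(dict(zip(model.classes, map(float, proba))))
    best = max(probs.items(), key=lambda kv: (kv[1], SEVERITY_ORDER[kv[0]]))[0]
    return SlidePrediction(
        grade=best,
        probabilities=probs,
        abnormality_score=1.0 - probs[SlideGrade.NILM],
    )


def feature_importances(
    model: SlideClassifier, k: int = 20
) -> List[Tuple[str, float]]:
    """Top-``k`` features by impurity importance, descending."""
    check_is_fitted(model.estimator)
    if k < 1:
        raise ValueError("k must be >= 1")
    imp = model.estimator.feature_importances_
    order = np.argsort(-imp, kind="stable")[:k]
    return [(model.feature_names[i], float(imp[i])) for i in order]
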