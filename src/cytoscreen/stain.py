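"""Stain-space color augmentation for H&E-stained patch images.

Pipeline: RGB -> stain-density-absorbance (SDA, i.e. optical density)
space, Macenko SVD/percentile-angle estimation of the 3x3 stain
component matrix, per-image H/E component distribution fitting over a
training set, and bounded uniform perturbation of the H and/or E
components with reconstruction back to RGB.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

DEFAULT_BACKGROUND = 255.0
DEFAULT_EPS = 1.0
DEFAULT_BETA = 0.15  # SDA-magnitude threshold selecting tissue pixels
DEFAULT_ALPHA = 1.0  # percentile for robust extreme angles

PERTURBATION_TARGETS = ("H", "E", "both", "neither")


class DegenerateStainWarning(UserWarning):
    """Raised (as a warning) when too few tissue pixels support estimation."""


class UnstableStainWarning(UserWarning):
    """Raised when the second stain direction is poorly determined."""


def rgb_to_sda(
    image: np.ndarray,
    background_intensity: float = DEFAULT_BACKGROUND,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Transform an RGB raster in [0, 255] to SDA (optical density) space.

    Per channel: sda = -ln((I + eps) / background_intensity). ``eps``
    keeps the log finite at I = 0.
    """
    if background_intensity <= 0:
        raise ValueError("background_intensity must be positive")
    arr = np.asarray(image, dtype=np.float64)
    return -np.log((arr + eps) / background_intensity)


def sda_to_rgb(
    sda: np.ndarray,
    background_intensity: float = DEFAULT_BACKGROUND,
    eps: float = DEFAULT_EPS,
    clip: bool = True,
) -> np.ndarray:
    """Invert :func:`rgb_to_sda`; returns a float array (not quantized)."""
    if background_intensity <= 0:
        raise ValueError("background_intensity must be positive")
    rgb = background_intensity * np.exp(-np.asarray(sda, dtype=np.float64)) - eps
    if clip:
        rgb = np.clip(rgb, 0.0, 255.0)
    return rgb


def _as_pixels(sda: np.ndarray) -> np.ndarray:
    arr = np.asarray(sda, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.reshape(-1, arr.shape[-1])
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) pixel array or (h, w, 3) raster")
    return arr


def _clip_unit(v: np.ndarray) -> np.ndarray:
    """Force nonnegative entries and unit Euclidean norm."""
    v = np.where(v < 0, 0.0, v)
    n = np.linalg.norm(v)
    if n == 0:
        return v
    return v / n


def estimate_stain_matrix_macenko(
    sda: np.ndarray,
    beta: float = DEFAULT_BETA,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Estimate a 3x3 stain component matrix from SDA pixels (Macenko).

    Tissue pixels (SDA magnitude > ``beta``) are projected onto the
    plane of the top two right singular vectors; the stain vectors are
    taken at the ``alpha`` / ``100 - alpha`` percentile extreme angles.
    Columns are unit-norm absorbance vectors ordered (H, E, residual),
    H being the vector with the larger blue-channel absorbance. The
    residual column is the normalized cross product of H and E.

    A raster with fewer than 2 tissue pixels yields an identity fallback
    matrix with a :class:`DegenerateStainWarning`; a single-stain raster
    yields a well-defined first vector and an :class:`UnstableStainWarning`.
    """
    pixels = _as_pixels(sda)
    mask = np.linalg.norm(pixels, axis=1) > beta
    tissue = pixels[mask]
    if tissue.shape[0] < 2:
        warnings.warn(
            "fewer than 2 pixels above the SDA threshold; "
            "returning identity fallback stain matrix",
            DegenerateStainWarning,
            stacklevel=2,
        )
        return np.eye(3)

    _, s, vt = np.linalg.svd(tissue, full_matrices=False)
    plane = vt[:2]  # rows span the dominant stain plane
    # Orient basis vectors so the bulk of tissue projects positively.
    proj = tissue @ plane.T
    for j in range(2):
        if proj[:, j].sum() < 0:
            plane[j] = -plane[j]
            proj[:, j] = -proj[:, j]

    # quantization noise alone gives a ratio ~1e-3; real two-stain wedges >~0.1
    if s[0] > 0 and s[1] / s[0] < 0.02:
        warnings.warn(
            "second stain direction is numerically unstable (single-stain input?)",
            UnstableStainWarning,
            stacklevel=2,
        )

    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi_min, phi_max = np.percentile(phi, [alpha, 100.0 - alpha])
    v_min = plane.T @ np.array([np.cos(phi_min), np.sin(phi_min)])
    v_max = plane.T @ np.array([np.cos(phi_max), np.sin(phi_max)])
    v_min, v_max = _clip_unit(v_min), _clip_unit(v_max)

    # H absorbs more in the blue channel than E.
    if v_min[2] >= v_max[2]:
        h, e = v_min, v_max
    else:
        h, e = v_max, v_min
    residual = np.cross(h, e)
    if residual.sum() < 0:
        residual = -residual
    residual = _clip_unit(residual)
    if np.linalg.norm(residual) == 0:
        residual = _clip_unit(np.array([1.0, 1.0, 1.0]) - h)
    return np.column_stack([h, e, residual])


@dataclass
class StainModel:
    """Fitted stain matrix plus per-image H/E component distributions.

    ``mu``/``sigma`` are across-image mean and SD of the per-image mean
    concentration magnitudes; the bounds are across-image min and max.
    """

    stain_matrix: np.ndarray
    mu_H: float
    mu_E: float
    sigma_H: float
    sigma_E: float
    lower_H: float
    upper_H: float
    lower_E: float
    upper_E: float
    background_intensity: float = DEFAULT_BACKGROUND
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=np.float64)
        if self.stain_matrix.shape != (3, 3):
            raise ValueError("stain_matrix must be 3x3")
        if self.sigma_H < 0 or self.sigma_E < 0:
            raise ValueError("sigma must be nonnegative")
        if self.lower_H > self.upper_H or self.lower_E > self.upper_E:
            raise ValueError("lower bound exceeds upper bound")

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = asdict(self)
        payload["stain_matrix"] = self.stain_matrix.tolist()
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "StainModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        payload["stain_matrix"] = np.asarray(payload["stain_matrix"])
        return cls(**payload)


@dataclass(frozen=True)
class PerturbationDraw:
    """One sampled augmentation: which component(s) move and by how much."""

    target: str  # one of PERTURBATION_TARGETS
    delta_H: float
    delta_E: float

    def __post_init__(self) -> None:
        if self.target not in PERTURBATION_TARGETS:
            raise ValueError(f"target must be one of {PERTURBATION_TARGETS}")


def _concentrations(image: np.ndarray, model: StainModel) -> np.ndarray:
    """Per-pixel (3, n) stain concentrations via the model's matrix."""
    sda = rgb_to_sda(image, model.background_intensity, model.eps)
    pixels = _as_pixels(sda)
    return np.linalg.solve(model.stain_matrix, pixels.T)


def fit_stain_distribution(
    images: Sequence[np.ndarray],
    beta: float = DEFAULT_BETA,
    alpha: float = DEFAULT_ALPHA,
    background_intensity: float = DEFAULT_BACKGROUND,
    eps: float = DEFAULT_EPS,
) -> StainModel:
    """Fit a :class:`StainModel` over a training set of RGB rasters.

    The stain matrix is estimated once from the pooled SDA pixels of all
    images; each image then contributes its mean H and E concentration
    magnitudes, from which the across-image mean, SD (population), and
    min/max bounds are taken.
    """
    images = list(images)
    if len(images) < 2:
        raise ValueError("need at least 2 images to fit a stain distribution")
    pooled = np.concatenate(
        [_as_pixels(rgb_to_sda(im, background_intensity, eps)) for im in images]
    )
    matrix = estimate_stain_matrix_macenko(pooled, beta=beta, alpha=alpha)

    means = np.empty((len(images), 2))
    partial = StainModel(
        matrix, 0, 0, 0, 0, 0, 0, 0, 0, background_intensity, eps
    )
    for i, im in enumerate(images):
        conc = _concentrations(im, partial)
        means[i] = conc[0].mean(), conc[1].mean()

    mu = means.mean(axis=0)
    sigma = means.std(axis=0)  # population SD
    lo = means.min(axis=0)
    hi = means.max(axis=0)
    return StainModel(
        stain_matrix=matrix,
        mu_H=float(mu[0]),
        mu_E=float(mu[1]),
        sigma_H=float(sigma[0]),
        sigma_E=float(sigma[1]),
        lower_H=float(lo[0]),
        upper_H=float(hi[0]),
        lower_E=float(lo[1]),
        upper_E=float(hi[1]),
        background_intensity=background_intensity,
        eps=eps,
    )


def draw_perturbation(model: StainModel, rng: np.random.Generator) -> PerturbationDraw:
    """Sample a perturbation: uniform target choice, deltas in [-2s, 2s]."""
    target = PERTURBATION_TARGETS[int(rng.integers(len(PERTURBATION_TARGETS)))]
    d_h = float(rng.uniform(-2.0 * model.sigma_H, 2.0 * model.sigma_H))
    d_e = float(rng.uniform(-2.0 * model.sigma_E, 2.0 * model.sigma_E))
    if target == "H":
        d_e = 0.0
    elif target == "E":
        d_h = 0.0
    elif target == "neither":
        d_h = d_e = 0.0
    return PerturbationDraw(target=target, delta_H=d_h, delta_E=d_e)


def apply_perturbation(
    image: np.ndarray, model: StainModel, draw: PerturbationDraw
) -> np.ndarray:
    """Shift the image's H/E components by the draw's deltas and rebuild RGB.

    The shift is a global additive change to the per-image component
    magnitude (the mean per-pixel concentration), clamped so the realized
    magnitude stays within the model's fitted [lower, upper] bounds. A
    zero delta leaves the component untouched.
    """
    arr = np.asarray(image)
    conc = _concentrations(arr, model)

    for idx, delta, lo, hi in (
        (0, draw.delta_H, model.lower_H, model.upper_H),
        (1, draw.delta_E, model.lower_E, model.upper_E),
    ):
        if delta == 0.0:
            continue
        m = conc[idx].mean()
        effective = float(np.clip(m + delta, lo, hi)) - m
        conc[idx] += effective

    sda = (model.stain_matrix @ conc).T.reshape(arr.shape)
    rgb = sda_to_rgb(sda, model.background_intensity, model.eps)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def perturb_stains(
    image: np.ndarray,
    model: StainModel,
    rng: np.random.Generator,
    draw: Optional[PerturbationDraw] = None,
) -> np.ndarray:
    """Randomly perturb the H and/or E stain components of an RGB raster.

    Either the H component, the E component, both, or neither is
    selected (uniformly); the selected components receive additive
    shifts drawn uniformly from [-2 sigma, 2 sigma], clamped to the
    fitted bounds. Bit-reproducible for a fixed ``rng`` state.
    """
    if draw is None:
        draw = draw_perturbation(model, rng)
    return apply_perturbation(image, model, draw)


def component_magnitudes(image: np.ndarray, model: StainModel) -> tuple[float, float]:
    """Per-image mean H and E concentration magnitudes under the model."""
    conc = _concentrations(image, model)
    return float(conc[0].mean()), float(conc[1].mean())


def angular_error_deg(v: np.ndarray, w: np.ndarray) -> float:
    """Angle in degrees between two stain vectors (sign-insensitive)."""
    v = np.asarray(v, float) / np.linalg.norm(v)
    w = np.asarray(w, float) / np.linalg.norm(w)
    c = np.clip(abs(float(v @ w)), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))
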