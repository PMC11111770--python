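import numpy as np
import pytest

from cytoscreen.detection import DetectorProfile
from cytoscreen.synthetic import CohortConfig, generate_cohort, generate_stain_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """120 synthetic slides with known grades (session-scoped for speed)."""
    cfg = CohortConfig(n_slides=120, seed=7)
    slides, truths = generate_cohort(cfg)
    return slides, truths


@pytest.fixture(scope="session")
def stain_pair():
    """Two seeded Beer-Lambert images with shared ground-truth vectors."""
    img_a, vecs, conc_a = generate_stain_image(seed=11)
    img_b, _, conc_b = generate_stain_image(seed=12)
    return (img_a, img_b), vecs, (conc_a, conc_b)


def dense_tissue_thumbnail(seed: int = 0, shape=(400, 600)) -> np.ndarray:
    """Sharp, fully tissue-covered synthetic RGB thumbnail."""
    rng = np.random.default_rng(seed)
    h, w = shape
    base = np.full((h, w, 3), 200.0)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(250):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(4, 14)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 < r**2
        base[mask] = rng.uniform(60, 160, 3)
    base += rng.normal(0, 3, base.shape)
    return np.clip(base, 0, 255).astype(np.uint8)


@pytest.fixture
def tissue_thumbnail():
    return dense_tissue_thumbnail()


@pytest.fixture
def identity_confusion_profile():
    """Detector profile with a perfectly diagonal class-confusion matrix."""
    from cytoscreen.synthetic import default_detector_profile

    profile = default_detector_profile()
    return DetectorProfile(
        rates=profile.rates,
        confusion=np.eye(6),
        tp_conf=profile.tp_conf,
        fp_conf=profile.fp_conf,
        fp_rate=0.0,
    )
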