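import numpy as np
import pytest

import histofuse as hf
from histofuse.patches import PreprocessConfig
from histofuse.pipeline import detector_training_patches

DETECT_PP = PreprocessConfig(enabled_steps=("background_subtract", "edge_enhance"))


class BrownnessStub:
    """Deterministic stand-in for a trained model: scores a patch by the
    red-minus-blue excess at the center of its inner crop.  Pure function of
    the pixels, so scan invariances can be tested without training."""

    class config:
        threshold = 0.5

    def predict_proba_arrays(self, inner: np.ndarray, outer: np.ndarray) -> np.ndarray:
        center = inner[:, :, 12:20, 12:20]
        brown = (center[:, 0] - center[:, 2]).mean(axis=(1, 2))
        return np.clip(brown * 2.0 + 0.5, 0.0, 1.0).astype(np.float64)


@pytest.fixture(scope="session")
def stub_model():
    return BrownnessStub()


@pytest.fixture(scope="session")
def patch_pool():
    """Labeled bifocal patches from six synthetic slides (shared pool)."""
    return detector_training_patches(n_slides=6, seed=0, preprocess=DETECT_PP)


@pytest.fixture(scope="session")
def split_pool():
    """The round-vs-{ramified, negative} benchmark: plain center-dot and
    background annotations on raw color patches, shuffled into a 500-train /
    200-test split."""
    from histofuse.annotations import annotations_from_ground_truth
    from histofuse.patches import extract_dataset

    raw = PreprocessConfig(enabled_steps=())
    pool = []
    for i in range(6):
        slide = hf.generate_slide(
            512, 512, {"round_positive": 40, "ramified_positive": 35,
                       "negative": 25}, "Iba1", seed=101 * (i + 1))
        dots = annotations_from_ground_truth(slide, n_background=30, seed=i)
        pool += extract_dataset(slide.image, dots, raw)
    idx = np.random.default_rng(0).permutation(len(pool))
    return [pool[i] for i in idx[:500]], [pool[i] for i in idx[500:700]]


@pytest.fixture(scope="session")
def learnability_model(split_pool):
    """Model trained under the benchmark conditions: the 500 training
    patches plus two augmented copies each (augmentation is part of the
    training recipe)."""
    from histofuse.patches import augment

    train_p, test_p = split_pool
    aug = (train_p
           + [augment(p, seed=1000 + i) for i, p in enumerate(train_p)]
           + [augment(p, seed=5000 + i) for i, p in enumerate(train_p)])
    return hf.train(aug, test_p, hf.ClassifierConfig(seed=0))


@pytest.fixture(scope="session")
def detection_model(patch_pool):
    """Detector trained on the larger pool, for whole-slide scanning."""
    idx = np.random.default_rng(1).permutation(len(patch_pool))
    train_p = [patch_pool[i] for i in idx[:1500]]
    val_p = [patch_pool[i] for i in idx[1500:1800]]
    return hf.train(train_p, val_p, hf.ClassifierConfig(epochs=22, seed=0))


@pytest.fixture(scope="session")
def calibrated_detector(detection_model):
    """(model, preprocess, threshold) with the detection threshold picked by
    F1 on a separate validation slide."""
    cal = hf.generate_slide(
        512, 512,
        {"round_positive": 20, "ramified_positive": 10, "negative": 12},
        "Iba1", seed=901)
    hm = hf.scan(cal.image, detection_model, stride=10, preprocess=DETECT_PP)
    gt = np.array([(c.x, c.y) for c in cal.cells
                   if c.phenotype == "round_positive"])
    t = hf.calibrate_threshold(hm, gt)
    return detection_model, DETECT_PP, t
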