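"""Shared fixtures: small synthetic benchmarks and a trained detector.

Everything is generated programmatically at test time; the heavier
artifacts (the 3-domain benchmark and a detector trained on its clean
images) are session-scoped so the whole suite trains once.
"""

import numpy as np
import pytest

import dynacolor as dc

BENCH_SEED = 1
DETECTOR_STEPS = 600
GAINS = (0.6, 1.0, 1.5)


def make_benchmark(seed: int, gains=GAINS, images_per_domain: int = 12):
    """3-domain 64x64 benchmark with pure-gain degradations, clip on."""
    cfg = dc.SceneConfig(height=64, width=64, n_objects=(4, 8))
    domains = [(cfg, dc.DegradationParams(a=a, b=0.0, domain=f"a{a}"))
               for a in gains]
    return dc.generate_benchmark(domains, images_per_domain, seed=seed)


def clean_view(samples):
    """Samples re-pointed at their clean (undegraded) images."""
    return [dc.Sample(image=s.clean_image, boxes=s.boxes, domain=s.domain,
                      image_id=s.image_id, split=s.split) for s in samples]


def train_clean_detector(bench, seed: int) -> dc.ToyDetector:
    det, _ = dc.train_detector(
        clean_view(bench.train),
        dc.TrainConfig(steps=DETECTOR_STEPS, lr=0.1, batch_size=4,
                       seed=seed))
    return det


@pytest.fixture(scope="session")
def benchmark3():
    return make_benchmark(BENCH_SEED)


@pytest.fixture(scope="session")
def clean_detector(benchmark3):
    """Detector trained on the clean images of the 3-domain benchmark."""
    return train_clean_detector(benchmark3, BENCH_SEED)


@pytest.fixture
def scene64():
    cfg = dc.SceneConfig(height=64, width=64, n_objects=(5, 5))
    return dc.generate_scene(cfg, np.random.default_rng(7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
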