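import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cocompart as cc
from cocompart.pipeline import PipelineConfig, analyze_scene

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_scene_config():
    """Noise-free, blur-free scene: ground truth equals the rendered image."""
    return cc.SceneConfig(seed=7, psf=None, poisson_noise=False,
                          gaussian_noise_sd=0.0, background=0.0)


@pytest.fixture(scope="session")
def clean_scene(clean_scene_config):
    return cc.generate_scene(clean_scene_config)


@pytest.fixture(scope="session")
def default_scene():
    """A realistic rendered scene (blur + noise) with 25% co-localization."""
    cfg = cc.SceneConfig(seed=11, coloc=((("NALP3", "LC3"), 0.25),))
    return cfg, cc.generate_scene(cfg)


@pytest.fixture(scope="session")
def analyzed_scene(default_scene):
    """Feature table + pixel colocalization of the default scene."""
    cfg, (channels, gt) = default_scene
    pipe = PipelineConfig(deconvolve=False)
    table, coloc = analyze_scene(channels, "n.t.",
                                 {"NALP3": "LC3", "LC3": "NALP3"}, pipe)
    return cfg, gt, table, coloc


def random_label_volume(rng, shape=(8, 24, 24), n_blobs=5, max_r=3):
    """Small random label volume of non-overlapping boxes for oracle tests."""
    labels = np.zeros(shape, dtype=np.int32)
    k = 0
    for _ in range(n_blobs):
        size = rng.integers(1, max_r + 1, size=3)
        lo = [rng.integers(0, s - sz) for s, sz in zip(shape, size)]
        sl = tuple(slice(l, l + sz) for l, sz in zip(lo, size))
        if (labels[sl] == 0).all():
            k += 1
            labels[sl] = k
    return labels, k
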