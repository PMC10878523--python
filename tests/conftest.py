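"""Shared fixtures: small synthetic scenes and one full benchmark run.

The expensive products (a default benchmark run and a noiseless run) are
session-scoped so the acceptance tests and the module tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from firehist.pipeline import PipelineConfig, evaluate_against_truth, run
from firehist.synthetic import FireSpec, SceneConfig


BENCHMARK_SEED = 11


def small_scene_config(**overrides) -> SceneConfig:
    """A fast 60x60 scene with a shorter archive and smaller fires."""
    defaults = dict(
        rows=60, cols=60,
        start=(2000, 1), end=(2022, 12),
        fires=(
            FireSpec(2014, 9, 8.0),
            FireSpec(2017, 10, 30.0, overlap=0.2),
            FireSpec(2019, 10, 60.0, overlap=0.6),
            FireSpec(2021, 10, 90.0, overlap=0.6),
        ),
        n_footprints=600,
        seed=7,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def benchmark_ctx():
    """Full default pipeline run on the 100x100, 37-year noisy benchmark."""
    cfg = PipelineConfig(seed=BENCHMARK_SEED)
    cfg.scene.seed = BENCHMARK_SEED
    ctx = run(cfg)
    ctx["config"] = cfg
    ctx["evaluation"] = evaluate_against_truth(ctx)
    return ctx


@pytest.fixture(scope="session")
def noiseless_ctx():
    """Full pipeline run with zero noise and no missing data."""
    cfg = PipelineConfig(seed=BENCHMARK_SEED + 1)
    cfg.scene.seed = BENCHMARK_SEED + 1
    cfg.scene.noise_sd = 0.0
    cfg.scene.missing_prob = 0.0
    ctx = run(cfg)
    ctx["config"] = cfg
    return ctx


@pytest.fixture(scope="session")
def small_scene():
    """Landscape + noiseless archive + truth for the small scene."""
    from firehist.synthetic import generate_landscape, simulate_archive

    cfg = small_scene_config(noise_sd=0.0, missing_prob=0.0)
    land, zones = generate_landscape(cfg)
    bands, truth = simulate_archive(cfg, (land, zones))
    return cfg, bands, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
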