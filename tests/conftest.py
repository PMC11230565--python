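"""Shared fixtures: a fast 16 kHz synthetic setup and a trained model.

Unit-test scenes run at a reduced 16 kHz sample rate so the suite stays
fast; the physics being tested (framing, gating, band energies, feature
shapes) is rate-agnostic.
"""

from __future__ import annotations

import numpy as np
import pytest

from deepscan import (
    CalibrationSpec,
    FeatureParams,
    PipelineConfig,
    SceneSpec,
    build_training_set,
    init_network,
    simulate_corpus,
    train,
)
from deepscan.synthetic import ChorusSpec

FS = 16_000.0


@pytest.fixture
def cal_zero() -> CalibrationSpec:
    """Calibration with correction factor S = 0 (raw dB re full scale)."""
    return CalibrationSpec(hydrophone_sensitivity=0.0, gain=0.0, v_adc=1.0)


@pytest.fixture
def cal_default() -> CalibrationSpec:
    return CalibrationSpec()


@pytest.fixture(scope="session")
def fast_template() -> SceneSpec:
    return SceneSpec(sample_rate=FS, chorus=ChorusSpec(enabled=True))


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def trained_model(pipeline_config):
    """A classifier trained on a small seeded 16 kHz corpus."""
    template = SceneSpec(
        duration=60.0, sample_rate=FS, chorus=ChorusSpec(enabled=True)
    )
    items, _ = simulate_corpus(14, 0.5, template=template, seed=311)
    scenes = [(it.render(), it.truth) for it in items]
    fp = pipeline_config.features
    data = build_training_set(scenes, fp, negatives_per_positive=10, seed=311)
    model = init_network(input_dim=fp.input_dim, seed=311)
    return train(model, data, seed=311)
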