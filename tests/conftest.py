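"""Shared fixtures.

The expensive fixtures are the trained desk-scale classifiers (200
synthetic records, 10 CPU epochs each).  They are session-scoped so the
whole suite pays each training cost once: the standard-phenotype model for
classification checks, and the two P-wave-contrast models used by the
localization analyses.
"""

from __future__ import annotations

import pytest

from ecgxai.experiments import pwave_contrast_configs, train_desk_model
from ecgxai.model import ModelConfig
from ecgxai.synth import SynthConfig, afib_config, synth_record


@pytest.fixture(scope="session")
def desk_study():
    """Standard-phenotype dataset (f-waves, pronounced T, irregular RR)
    with a trained desk classifier and a true holdout split."""
    return train_desk_model(SynthConfig(), afib_config())


@pytest.fixture(scope="session")
def desk_dataset(desk_study):
    return desk_study.records, desk_study.truths


@pytest.fixture(scope="session")
def desk_split(desk_study):
    return desk_study.train_idx, desk_study.test_idx


@pytest.fixture(scope="session")
def trained_desk_model(desk_study):
    return desk_study.model, desk_study.history


@pytest.fixture(scope="session")
def timing_contrast_model():
    """Model trained on the P-wave-contrast dataset with the generator's
    default RR-timing contrast (for the interval-ranking analysis)."""
    normal_base, afib_base = pwave_contrast_configs("default")
    study = train_desk_model(normal_base, afib_base)
    return study.model, afib_base


@pytest.fixture(scope="session")
def pwave_dominant_model():
    """Model trained with minimized timing contrast so P-wave absence is
    the dominant cue (for the Grad-CAM localization analysis)."""
    normal_base, afib_base = pwave_contrast_configs("minimal")
    study = train_desk_model(normal_base, afib_base)
    return study.model, afib_base


@pytest.fixture()
def normal_record():
    record, truth = synth_record(SynthConfig(seed=11), record_id="normal_fixture")
    return record, truth


@pytest.fixture()
def afib_record():
    record, truth = synth_record(afib_config(seed=12), record_id="afib_fixture")
    return record, truth


@pytest.fixture()
def tiny_model_config():
    """A model small enough for per-test training and gradient checks."""
    return ModelConfig(
        n_blocks=2,
        base_channels=4,
        kernel_size=5,
        downsample_every=1,
        max_channels=8,
        stem_stride=1,
        stem_pool=2,
        seed=0,
    )
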