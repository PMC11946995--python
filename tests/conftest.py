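"""Shared fixtures: small study designs and feature configurations.

Training-based tests run on deliberately reduced problem sizes (fewer sweeps,
coarser spectrograms, narrow network widths) so the whole suite fits a
single-CPU run; the reduced settings are defined here in one place.
"""

from __future__ import annotations

import numpy as np
import pytest

from vibroscrew.excitation import ExcitationConfig, generate_sweep
from vibroscrew.features import FeatureConfig
from vibroscrew.model import desk_scale_config
from vibroscrew.simulate import ConditionEffect, StudyDesign, in_memory_dataset


@pytest.fixture(scope="session")
def default_sweep():
    return generate_sweep(ExcitationConfig())


@pytest.fixture(scope="session")
def small_feature_config():
    """Coarse 64 x 55 log-mel front end: full sweep bandwidth and duration,
    reduced mel/time resolution."""
    return FeatureConfig(n_mels=64, hop=1024)


@pytest.fixture(scope="session")
def small_model_config():
    return desk_scale_config(input_shape=(64, 55))


@pytest.fixture(scope="session")
def tiny_separable_dataset():
    """3 specimens x 2 screws x 2 conditions x 8 sweeps at full contrast."""
    design = StudyDesign(n_specimens=3, sweeps_per_screw=8, master_seed=5)
    manifest, recordings = in_memory_dataset(design, ConditionEffect(separation=1.0))
    return manifest, recordings
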