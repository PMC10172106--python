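import numpy as np
import pytest

from greylung.roi import ImageFrame
from greylung.synth import (DEFAULT_SCHEDULE, GeneratorConfig, LambTruth,
                            VenegasParams, make_lamb_truth)


@pytest.fixture
def schedule():
    return DEFAULT_SCHEDULE


@pytest.fixture
def noiseless_config():
    return GeneratorConfig(noise_sigma_range=(0.0, 0.0))


@pytest.fixture
def truth():
    """One deterministic lamb with default generator settings."""
    return make_lamb_truth(seed=42)


@pytest.fixture
def noiseless_truth(noiseless_config):
    return make_lamb_truth(seed=42, config=noiseless_config)


def manual_truth(noise_sigma=0.0, echo_baseline=40.0, echo_gain=2.0,
                 weights=(0.25, 0.40, 0.35), fraction=0.45,
                 inflation=VenegasParams(2, 28, 22, 3),
                 deflation=None, region="dependent", seed=7):
    """Hand-assembled ground truth for oracle-style checks."""
    if deflation is None:
        deflation = VenegasParams(inflation.a, inflation.b,
                                  inflation.c - 6, inflation.d)
    return LambTruth(
        lamb_id="manual", region_imaged=region,
        inflation_params=inflation, deflation_params=deflation,
        regional_weights=dict(zip(("ventral", "central", "dorsal"), weights)),
        right_whole_fraction=fraction, echo_baseline=echo_baseline,
        echo_gain=echo_gain, noise_sigma=noise_sigma, seed=seed,
    )


@pytest.fixture
def make_truth():
    return manual_truth


def frame_from(pixels, spacing=0.02, meta=None):
    return ImageFrame(pixels=np.asarray(pixels, dtype=np.uint8),
                      pixel_spacing_mm=spacing, meta=meta or {})


@pytest.fixture
def make_frame():
    return frame_from
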