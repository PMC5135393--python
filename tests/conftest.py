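import numpy as np
import pytest

from laminafp import SyntheticConfig, generate_fp_recording


@pytest.fixture
def clean_recording():
    """Noise-free control HB recording with the sink at 100 um."""
    cfg = SyntheticConfig(sink_center_um=100.0, modality="HB", noise_sd=0.0)
    rec, truth = generate_fp_recording(cfg)
    return rec, truth


@pytest.fixture
def clean_rgc_recording():
    """Noise-free control RGC recording with the sink at 50 um."""
    cfg = SyntheticConfig(sink_center_um=50.0, modality="RGC", noise_sd=0.0)
    rec, truth = generate_fp_recording(cfg)
    return rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
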