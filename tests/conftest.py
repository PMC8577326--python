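import numpy as np
import pytest

from neommr.paradigm import BlockConfig, generate_block
from neommr.simulate import (
    ErpTemplateParams,
    MmrEffectParams,
    NoiseParams,
    block_config_for,
    simulate_subject,
)


@pytest.fixture(scope="session")
def default_block():
    """One full-size roving-standard block (default configuration)."""
    return generate_block(BlockConfig(seed=123))


@pytest.fixture(scope="session")
def tiny_block():
    """A short durational block (2 occurrences per train length)."""
    return generate_block(block_config_for("durational", seed=7, occurrences_per_length=2))


@pytest.fixture(scope="session")
def silent_params():
    """Deterministic simulation: no noise, no artifacts, no subject effects."""
    return dict(
        erp=ErpTemplateParams(subject_gain_sd=0.0),
        mmr=MmrEffectParams(
            base_early_uv=0.0, base_late_uv=0.0,
            asymmetry_early_uv=0.0, asymmetry_late_uv=0.0, subject_sd_uv=0.0,
        ),
        noise=NoiseParams(rms_uv=0.0, artifact_rate=0.0),
    )


@pytest.fixture(scope="session")
def noise_free_recording(tiny_block, silent_params):
    """Noise-free speech-domain recording of the tiny durational block."""
    return simulate_subject(
        tiny_block, seed=3, domain="speech", dimension="durational", **silent_params
    )
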