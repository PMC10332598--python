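import numpy as np
import pytest

from vocrep.config import SpectrogramConfig
from vocrep.synth import RepertoireSpec, UnitTypeSpec, render_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """32x32 spectrogram config (k_f = k_t = 1): cheap but full-pipeline-valid."""
    return SpectrogramConfig(fs=32_000, nfft=256, T=0.05, n_mels=32, n_time=32,
                             k_f=1, k_t=1)


@pytest.fixture(scope="session")
def two_type_dataset(tmp_path_factory):
    """A rendered 2-type, high-SNR repertoire: WAV + annotation table."""
    spec = RepertoireSpec(
        types=[
            UnitTypeSpec("low", contour="constant", f_start=3000, f_end=3000,
                         n_harmonics=2, duration_mean=0.04, duration_sd=0.004),
            UnitTypeSpec("high", contour="chirp", f_start=8000, f_end=11000,
                         n_harmonics=1, duration_mean=0.04, duration_sd=0.004),
        ],
        fs=32_000, jitter=0.02, snr_db=30.0, seed=7,
    )
    out = tmp_path_factory.mktemp("two_type")
    table = render_dataset(spec, n_per_type=30, out_dir=out, seed=7)
    return out, table
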