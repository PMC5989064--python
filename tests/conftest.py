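import numpy as np
import pytest

from pyrpeak.io_formats import EcgRecord
from pyrpeak.rpeak_detector import DetectorConfig
from pyrpeak.synthetic_ecg import SyntheticSpec, generate_clean_ecg


@pytest.fixture
def default_cfg() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture
def make_clean():
    """Factory for seeded clean synthetic records."""

    def _make(duration_s=60.0, fs=360.0, heart_rate_bpm=60.0,
              rr_jitter_frac=0.05, seed=0, **kw):
        spec = SyntheticSpec(
            duration_s=duration_s, fs=fs, heart_rate_bpm=heart_rate_bpm,
            rr_jitter_frac=rr_jitter_frac, seed=seed, **kw,
        )
        rec, truth = generate_clean_ecg(spec)
        return spec, rec, truth

    return _make


@pytest.fixture
def flat_record() -> EcgRecord:
    return EcgRecord("flat", np.zeros(360 * 30), 360.0)


def assert_refractory(peaks, fs, refractory_ms=250.0):
    """Suite-wide guarantee: no two detections closer than the refractory gap."""
    idx = np.asarray(peaks.peak_samples)
    if idx.size > 1:
        min_gap = int(round(refractory_ms * fs / 1000.0))
        assert np.diff(idx).min() >= min_gap
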