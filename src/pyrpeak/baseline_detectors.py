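"""Energy-based QRS detection in the Pan–Tompkins tradition.

Stages: causal bandpass (QRS energy band, default 5–15 Hz) → first
difference → squaring → moving-window integration → per-window adaptive
threshold → refractory enforcement.  Parameterization follows the jQRS
operating point: detector threshold 0.6 of the running amplitude estimate,
15-second analysis windows, 150-ms refractory period and a 7-sample
integration window.  Included as a comparison detector; the amplitude
estimate used by the adaptive threshold is the integrated signal's maximum
within the current analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_formats import EcgRecord
from .rpeak_detector import DetectorConfig, RPeakList, refractory_filter

__all__ = ["BaselineConfig", "pan_tompkins_detect"]


@dataclass(frozen=True)
class BaselineConfig:
    band_low_hz: float = 5.0
    band_high_hz: float = 15.0
    detector_threshold: float = 0.6
    window_s: float = 15.0
    refractory_ms: float = 150.0
    integration_samples: int = 7
    refine_window_ms: float = 80.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if not 0 < self.detector_threshold < 1:
            raise ValueError("detector_threshold must be in (0, 1)")
        if self.integration_samples < 1:
            raise ValueError("integration_samples must be >= 1")


def _causal_bandpass(y: np.ndarray, fs: float, cfg: BaselineConfig) -> np.ndarray:
    nyq = fs / 2.0
    if cfg.band_high_hz >= nyq:
        raise ValueError(
            f"band_high_hz {cfg.band_high_hz} not below Nyquist {nyq}"
        )
    sos = sps.butter(
        3, [cfg.band_low_hz / nyq, cfg.band_high_hz / nyq],
        btype="band", output="sos",
    )
    return sps.sosfilt(sos, y)


def pan_tompkins_detect(
    record: EcgRecord, cfg: BaselineConfig | None = None
) -> RPeakList:
    """Detect R peaks with the bandpass/derivative/square/integrate chain.

    Candidates are runs of the integrated energy above
    ``detector_threshold x max(integrated energy in the current window)``;
    each run is refined to the bandpassed-signal maximum of magnitude within
    ``refine_window_ms`` and the refractory rule keeps the larger of any two
    detections closer than ``refractory_ms``.
    """
    cfg = cfg or BaselineConfig()
    y = record.samples
    fs = record.fs
    if y.size < 2 * cfg.integration_samples:
        raise ValueError("record too short for integration window")
    bp = _causal_bandpass(y, fs, cfg)
    deriv = np.empty_like(bp)
    deriv[0] = 0.0
    deriv[1:] = np.diff(bp) * fs
    energy = deriv * deriv
    kernel = np.ones(cfg.integration_samples) / cfg.integration_samples
    integ = np.convolve(energy, kernel)[: y.size]

    win = max(1, int(round(cfg.window_s * fs)))
    refine = max(1, int(round(cfg.refine_window_ms * fs / 1000.0)))
    peaks: list[int] = []
    amps: list[float] = []
    for start in range(0, y.size, win):
        chunk = integ[start : start + win]
        peak_level = float(chunk.max(initial=0.0))
        if peak_level <= 0:
            continue
        thr = cfg.detector_threshold * peak_level
        above = chunk > thr
        padded = np.concatenate([[False], above, [False]])
        edges = np.diff(padded.astype(np.int8))
        for s in np.flatnonzero(edges == 1):
            a = start + int(s)
            b = min(y.size, a + refine + 1)
            p = a + int(np.argmax(np.abs(bp[a:b])))
            peaks.append(p)
            amps.append(float(np.abs(bp[p])))

    # Refinement can map neighbouring runs onto the same or out-of-order
    # samples; keep one entry per sample, in time order.
    uniq: dict[int, float] = {}
    for p, a in zip(peaks, amps):
        uniq[p] = max(a, uniq.get(p, 0.0))
    ordered = sorted(uniq)
    rcfg = DetectorConfig(refractory_ms=cfg.refractory_ms)
    kept_p, kept_a = refractory_filter(
        np.asarray(ordered, dtype=np.int64),
        np.asarray([uniq[p] for p in ordered], dtype=float),
        rcfg,
        fs,
    )
    return RPeakList(
        record_id=record.record_id,
        fs=fs,
        peak_samples=kept_p,
        amplitudes=kept_a,
    )
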