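"""Seeded synthetic single-lead ECG with injectable artifacts.

The generator produces annotated ECG-like traces so every detector stage can
be verified against exact ground truth.  Each beat is a sum of Gaussian bumps
(P, R, T); the Gaussian R bump makes the true apex analytically known, and
the annotation marks exactly that sample.  Morphological realism beyond that
(QT adaptation, Q/S notches, AF f-waves) is deliberately out of scope.

Artifact classes mirror the failure modes a wearable/Holter recording
exhibits: low-frequency wander from sudden movement, monotonic electrical
drift, sub-1-Hz respiratory oscillation, 50/60/100 Hz powerline pickup,
isolated low- and high-frequency electrical spikes, inverted lead polarity,
enlarged T waves, and premature (PVC/PAC-like) ectopic beats.  Spikes are
placed at least 250 ms from every true beat, so the reference annotations are
unchanged by their injection; premature beats are genuine beats and *do*
update the annotations.

All generation is a pure function of the spec dataclasses and their seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .io_formats import (
    BeatAnnotations,
    EcgRecord,
    write_record_csv,
    write_truth_csv,
)

__all__ = [
    "SyntheticSpec",
    "ArtifactSpec",
    "ARTIFACT_KINDS",
    "generate_clean_ecg",
    "inject_artifact",
    "generate_dataset",
    "dataset_from_manifest",
]

ARTIFACT_KINDS = (
    "movement_wander",
    "drift",
    "respiration",
    "powerline",
    "spike_lowfreq",
    "spike_highfreq",
    "invert_polarity",
    "enlarged_t",
    "pvc",
    "pac",
)

#: Minimum clearance (s) between an injected spike and any true R apex, so a
#: detector honouring a 250-ms refractory period sees an unambiguous truth.
SPIKE_CLEARANCE_S = 0.250

# Default artifact magnitudes (mV, or events for pvc/pac).  These are the
# study conditions of the synthetic suite: amplitudes on the order of, or
# exceeding, a 1-mV R peak for baseline disturbances, and modest counts of
# isolated events per minute of signal.
DEFAULT_MAGNITUDES = {
    "movement_wander": 2.0,
    "drift": 1.5,
    "respiration": 0.5,
    "powerline": 0.1,
    "spike_lowfreq": 2.0,
    "spike_highfreq": 1.5,
    "invert_polarity": 1.0,
    "enlarged_t": 0.6,
    "pvc": 4.0,
    "pac": 4.0,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a clean synthetic record.

    ``rr_jitter_frac`` is the fractional standard deviation of the RR
    intervals (Gaussian, truncated at +-3 sigma); 0 gives a metronomic
    rhythm.  Amplitudes are in millivolts, widths in milliseconds.
    """

    duration_s: float = 60.0
    fs: float = 360.0
    heart_rate_bpm: float = 60.0
    rr_jitter_frac: float = 0.05
    qrs_width_ms: float = 80.0
    r_amplitude_mV: float = 1.0
    p_amplitude_mV: float = 0.15
    t_amplitude_mV: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        if not 20 <= self.heart_rate_bpm <= 240:
            raise ValueError("heart_rate_bpm must be in [20, 240]")
        if not 0 <= self.rr_jitter_frac < 1:
            raise ValueError("rr_jitter_frac must be in [0, 1)")
        for a in (self.r_amplitude_mV, self.p_amplitude_mV,
                  self.t_amplitude_mV):
            if a < 0:
                raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact to superimpose on (or splice into) a record.

    ``magnitude`` is in mV for additive kinds, the number of ectopic events
    for ``pvc``/``pac``, and ignored for ``invert_polarity``.  ``None`` picks
    the kind's default.  ``start_s``/``end_s`` bound the affected interval
    (default: whole record).
    """

    kind: str
    magnitude: float | None = None
    frequency_hz: float | None = None
    start_s: float | None = None
    end_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.magnitude is not None and self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.kind == "respiration" and self.frequency_hz is not None:
            if not 0 < self.frequency_hz < 1:
                raise ValueError("respiration frequency must be < 1 Hz")
        if self.kind == "powerline" and self.frequency_hz is not None:
            if self.frequency_hz not in (50.0, 60.0, 100.0):
                raise ValueError("powerline frequency must be 50, 60 or 100")

    def resolved_magnitude(self) -> float:
        if self.magnitude is not None:
            return self.magnitude
        return DEFAULT_MAGNITUDES[self.kind]


# ---------------------------------------------------------------------------
# Clean signal
# ---------------------------------------------------------------------------


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _beat_waveform(
    t: np.ndarray,
    r_time: float,
    rr_before: float,
    rr_after: float,
    spec: SyntheticSpec,
    r_scale: float = 1.0,
    width_scale: float = 1.0,
    with_p: bool = True,
) -> np.ndarray:
    """P + R + T Gaussian bumps for one beat centred at ``r_time`` seconds."""
    sigma_r = width_scale * spec.qrs_width_ms / 6000.0  # +-3 sigma = QRS width
    y = r_scale * spec.r_amplitude_mV * _gauss(t, r_time, sigma_r)
    if with_p and spec.p_amplitude_mV > 0:
        p_off = min(0.180, 0.30 * rr_before)
        y += spec.p_amplitude_mV * _gauss(t, r_time - p_off, 0.025)
    if spec.t_amplitude_mV > 0:
        t_off = min(0.250, 0.45 * rr_after)
        y += spec.t_amplitude_mV * _gauss(t, r_time + t_off, 0.060)
    return y


def _t_offset(rr_after: float) -> float:
    return min(0.250, 0.45 * rr_after)


def generate_clean_ecg(
    spec: SyntheticSpec,
) -> tuple[EcgRecord, BeatAnnotations]:
    """Generate an artifact-free annotated record.

    Beats start at half an RR interval into the record, so a 60-s record at
    60 bpm with zero jitter contains exactly 60 beats one second apart.  Each
    annotation is the integer sample of its R apex.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    base_rr = 60.0 / spec.heart_rate_bpm

    beat_times: list[float] = []
    t = 0.5 * base_rr
    while t < spec.duration_s:
        beat_times.append(t)
        eps = float(np.clip(rng.normal(0.0, spec.rr_jitter_frac), -0.3, 0.3)) \
            if spec.rr_jitter_frac > 0 else 0.0
        t += base_rr * (1.0 + eps)
    beat_samples = np.round(np.asarray(beat_times) * fs).astype(np.int64)
    beat_samples = beat_samples[beat_samples < n]
    beat_times_snapped = beat_samples / fs

    tt = np.arange(n) / fs
    y = np.zeros(n)
    m = beat_samples.size
    for k in range(m):
        r_time = beat_times_snapped[k]
        rr_before = (
            r_time - beat_times_snapped[k - 1] if k > 0 else base_rr
        )
        rr_after = (
            beat_times_snapped[k + 1] - r_time if k + 1 < m else base_rr
        )
        # Only evaluate near the beat to keep generation O(n).
        lo = max(0, int((r_time - 0.6) * fs))
        hi = min(n, int((r_time + 0.6) * fs) + 1)
        y[lo:hi] += _beat_waveform(
            tt[lo:hi], r_time, rr_before, rr_after, spec
        )
    record = EcgRecord(
        record_id=f"synth-{spec.seed}", samples=y, fs=fs, lead_name="synth"
    )
    truth = BeatAnnotations(beat_samples, ["N"] * m)
    return record, truth


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------


def _interval_samples(
    art: ArtifactSpec, n: int, fs: float
) -> tuple[int, int]:
    lo = 0 if art.start_s is None else int(round(art.start_s * fs))
    hi = n if art.end_s is None else int(round(art.end_s * fs))
    if not 0 <= lo < hi <= n:
        raise ValueError(f"artifact interval [{lo}, {hi}) outside record")
    return lo, hi


def _place_clear_of_beats(
    rng: np.random.Generator,
    n_events: int,
    lo: int,
    hi: int,
    beat_samples: np.ndarray,
    fs: float,
    max_tries: int = 2000,
) -> np.ndarray:
    """Draw event samples >= SPIKE_CLEARANCE_S from every beat and each other."""
    clearance = int(round(SPIKE_CLEARANCE_S * fs))
    placed: list[int] = []
    for _ in range(max_tries):
        if len(placed) == n_events:
            break
        cand = int(rng.integers(lo, hi))
        if beat_samples.size and np.min(np.abs(beat_samples - cand)) <= clearance:
            continue
        if placed and min(abs(p - cand) for p in placed) <= 2 * clearance:
            continue
        placed.append(cand)
    if len(placed) < n_events:
        raise ValueError(
            "could not place spikes with 250-ms clearance from beats"
        )
    return np.sort(np.asarray(placed, dtype=np.int64))


def _insert_ectopic(
    record: EcgRecord,
    truth: BeatAnnotations,
    art: ArtifactSpec,
    spec_like: SyntheticSpec,
    kind: str,
) -> tuple[EcgRecord, BeatAnnotations]:
    """Insert premature beats between existing beats, updating the truth.

    The ectopic apex lands at 62% of the local RR interval, leaving both
    neighbouring gaps comfortably above the 250-ms physiological minimum at
    resting heart rates.  PVCs are wide and tall without a P wave; PACs keep
    a near-normal narrow morphology.
    """
    rng = np.random.default_rng(art.seed)
    fs = record.fs
    n = record.samples.size
    lo, hi = _interval_samples(art, n, fs)
    n_events = int(round(art.resolved_magnitude()))
    beats = truth.beat_samples
    gaps = [
        k
        for k in range(beats.size - 1)
        if lo <= beats[k] and beats[k + 1] <= hi
        and (beats[k + 1] - beats[k]) * 0.38 / fs > 0.30
    ]
    if len(gaps) < n_events:
        raise ValueError("not enough room for premature beats")
    chosen = sorted(rng.choice(len(gaps), size=n_events, replace=False))
    y = record.samples.copy()
    tt = np.arange(n) / fs
    new_beats = list(map(int, beats))
    new_labels = list(truth.beat_labels)
    for gi in chosen:
        k = gaps[gi]
        rr = (beats[k + 1] - beats[k]) / fs
        apex = int(round(beats[k] + 0.62 * rr * fs))
        r_time = apex / fs
        wlo = max(0, int((r_time - 0.6) * fs))
        whi = min(n, int((r_time + 0.6) * fs) + 1)
        if kind == "pvc":
            y[wlo:whi] += _beat_waveform(
                tt[wlo:whi], r_time, 0.62 * rr, 0.38 * rr, spec_like,
                r_scale=1.3, width_scale=1.8, with_p=False,
            )
            label = "V"
        else:
            y[wlo:whi] += _beat_waveform(
                tt[wlo:whi], r_time, 0.62 * rr, 0.38 * rr, spec_like,
                r_scale=0.95, width_scale=1.0, with_p=True,
            )
            label = "A"
        pos = int(np.searchsorted(new_beats, apex))
        new_beats.insert(pos, apex)
        new_labels.insert(pos, label)
    rec = EcgRecord(record.record_id, y, fs, record.lead_name)
    return rec, BeatAnnotations(
        np.asarray(new_beats, dtype=np.int64), new_labels,
        list(truth.exclusion_intervals),
    )


def inject_artifact(
    record: EcgRecord,
    truth: BeatAnnotations,
    art: ArtifactSpec,
    morphology: SyntheticSpec | None = None,
) -> tuple[EcgRecord, BeatAnnotations]:
    """Superimpose one artifact; returns a new (record, truth) pair.

    Additive disturbances (wander, drift, respiration, powerline, spikes,
    enlarged T) and polarity inversion never change the annotation list;
    ``pvc``/``pac`` insert genuine annotated beats.  ``morphology`` supplies
    beat-shape parameters for the ectopic/enlarged-T kinds (defaults to the
    generator defaults).
    """
    fs = record.fs
    n = record.samples.size
    spec_like = morphology or SyntheticSpec()
    if art.kind in ("pvc", "pac"):
        return _insert_ectopic(record, truth, art, spec_like, art.kind)

    rng = np.random.default_rng(art.seed)
    lo, hi = _interval_samples(art, n, fs)
    mag = art.resolved_magnitude()
    y = record.samples.copy()
    t = np.arange(n) / fs

    if art.kind == "invert_polarity":
        y[lo:hi] = -y[lo:hi]
    elif art.kind == "movement_wander":
        # Sudden-movement baseline excursions: smooth tanh steps (~0.3 s
        # transitions) at random instants, amplitudes up to `mag` mV.
        n_steps = max(2, int((hi - lo) / fs / 10.0))
        centers = rng.uniform(lo / fs, hi / fs, size=n_steps)
        amps = mag * rng.uniform(0.5, 1.0, size=n_steps)
        signs = rng.choice([-1.0, 1.0], size=n_steps)
        add = np.zeros(n)
        for c, a, s in zip(centers, amps, signs):
            add += s * a * 0.5 * (1.0 + np.tanh((t - c) / 0.15))
        add -= add[lo]
        y[lo:hi] += add[lo:hi]
    elif art.kind == "drift":
        ramp = np.linspace(0.0, mag, hi - lo)
        y[lo:hi] += ramp
    elif art.kind == "respiration":
        f = art.frequency_hz if art.frequency_hz is not None else 0.3
        phase = rng.uniform(0, 2 * np.pi)
        y[lo:hi] += mag * np.sin(2 * np.pi * f * t[lo:hi] + phase)
    elif art.kind == "powerline":
        f = art.frequency_hz if art.frequency_hz is not None else 50.0
        phase = rng.uniform(0, 2 * np.pi)
        y[lo:hi] += mag * np.sin(2 * np.pi * f * t[lo:hi] + phase)
    elif art.kind == "spike_lowfreq":
        # Slow transients: ~1-s-wide bumps (sigma 0.25 s), isolated from
        # beats — the baseline-excursion class the detrending stage removes.
        pos = _place_clear_of_beats(rng, 3, lo, hi, truth.beat_samples, fs)
        for p in pos:
            y += mag * _gauss(t, p / fs, 0.25)
    elif art.kind == "spike_highfreq":
        # Near-impulse transients one sample wide.
        pos = _place_clear_of_beats(rng, 3, lo, hi, truth.beat_samples, fs)
        y[pos] += mag
    elif art.kind == "enlarged_t":
        # Raise each beat's T bump by `mag` mV (default brings T to ~0.85 of
        # a 1-mV R peak, the known T-misdetection regime).
        beats = truth.beat_samples
        for k in range(beats.size):
            if not lo <= beats[k] < hi:
                continue
            rr_after = (
                (beats[k + 1] - beats[k]) / fs
                if k + 1 < beats.size
                else 60.0 / spec_like.heart_rate_bpm
            )
            c = beats[k] / fs + _t_offset(rr_after)
            wlo = max(0, int((c - 0.45) * fs))
            whi = min(n, int((c + 0.45) * fs) + 1)
            y[wlo:whi] += mag * _gauss(t[wlo:whi], c, 0.070)
    else:  # pragma: no cover - guarded by ArtifactSpec validation
        raise ValueError(f"unknown artifact kind {art.kind!r}")

    rec = EcgRecord(record.record_id, y, fs, record.lead_name)
    return rec, BeatAnnotations(
        truth.beat_samples.copy(), list(truth.beat_labels),
        list(truth.exclusion_intervals),
    )


# ---------------------------------------------------------------------------
# Dataset plumbing
# ---------------------------------------------------------------------------


def _apply_all(
    spec: SyntheticSpec, arts: list[ArtifactSpec]
) -> tuple[EcgRecord, BeatAnnotations]:
    rec, truth = generate_clean_ecg(spec)
    for art in arts:
        rec, truth = inject_artifact(rec, truth, art, morphology=spec)
    return rec, truth


def generate_dataset(
    specs: list[tuple[SyntheticSpec, list[ArtifactSpec]]],
    out_dir: str | Path,
) -> dict:
    """Write records + truth CSVs + a JSON manifest; returns the manifest.

    The manifest records every spec field, so ``dataset_from_manifest``
    regenerates bit-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (spec, arts) in enumerate(specs):
        rec, truth = _apply_all(spec, arts)
        rec_id = f"rec{i:03d}"
        rec = replace_id(rec, rec_id)
        write_record_csv(rec, out / f"{rec_id}.csv")
        write_truth_csv(truth, out / f"{rec_id}.truth.csv")
        entries.append(
            {
                "id": rec_id,
                "fs": spec.fs,
                "seed": spec.seed,
                "spec": asdict(spec),
                "artifacts": [asdict(a) for a in arts],
            }
        )
    manifest = {"records": entries}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def replace_id(rec: EcgRecord, new_id: str) -> EcgRecord:
    return EcgRecord(new_id, rec.samples, rec.fs, rec.lead_name)


def dataset_from_manifest(manifest: dict, out_dir: str | Path) -> None:
    """Regenerate a dataset's files from its manifest (determinism check)."""
    specs = []
    for entry in manifest["records"]:
        spec = SyntheticSpec(**entry["spec"])
        arts = [ArtifactSpec(**a) for a in entry["artifacts"]]
        specs.append((spec, arts))
    generate_dataset(specs, out_dir)
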