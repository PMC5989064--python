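"""Reading and writing single-lead ECG records, annotations and detections.

Two on-disk dialects are supported:

* WFDB (PhysioNet waveform database): ``.hea`` headers, ``.dat`` signals in
  format 212 (two 12-bit samples packed in three bytes, the MIT-BIH layout)
  or format 16, and MIT ``.atr``-style annotation streams.  The codec here is
  a compact, self-contained implementation of those formats.
* Plain text: one sample per line (CSV), which requires an explicit sampling
  rate, and CSV detection tables.

Sample indices are 0-based everywhere; times in seconds are ``index / fs``;
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EcgRecord",
    "BeatAnnotations",
    "BEAT_SYMBOLS",
    "read_record",
    "read_annotations",
    "write_detections",
    "write_record_csv",
    "write_record_wfdb",
    "write_annotations_wfdb",
    "read_detections_csv",
]


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class EcgRecord:
    """A uniformly sampled single-lead voltage series.

    Parameters
    ----------
    record_id : str
        Identifier (file stem for on-disk records).
    samples : ndarray
        Voltage in millivolts.
    fs : float
        Sampling rate in Hz, > 0.
    lead_name : str, optional
        Lead label from the source header, if any.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    lead_name: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def time_axis(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class BeatAnnotations:
    """Reference beat locations plus rhythm intervals excluded from scoring.

    ``beat_samples`` are strictly increasing 0-based indices of annotated
    beats; ``beat_labels`` the per-beat symbol codes; ``exclusion_intervals``
    half-open ``[start, end)`` sample intervals (e.g. ventricular-flutter
    episodes) that evaluation removes from both reference and test streams.
    """

    beat_samples: np.ndarray
    beat_labels: list[str] = field(default_factory=list)
    exclusion_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_samples = np.asarray(self.beat_samples, dtype=np.int64)
        if self.beat_samples.size and np.any(np.diff(self.beat_samples) <= 0):
            raise ValueError("beat_samples must be strictly increasing")
        if not self.beat_labels:
            self.beat_labels = ["N"] * int(self.beat_samples.size)
        if len(self.beat_labels) != self.beat_samples.size:
            raise ValueError("beat_labels length mismatch")
        for s, e in self.exclusion_intervals:
            if not s < e:
                raise ValueError(f"empty exclusion interval [{s}, {e})")

    @property
    def n_beats(self) -> int:
        return int(self.beat_samples.size)


# ---------------------------------------------------------------------------
# MIT annotation code table
# ---------------------------------------------------------------------------

# Standard MIT annotation codes <-> display symbols.
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}

#: Beat-class symbols (normal + ectopic); non-beat artifact/rhythm symbols
#: such as ``~ | + [ ] !`` are excluded.
BEAT_SYMBOLS = frozenset(
    ["N", "L", "R", "B", "A", "a", "J", "S", "V", "r",
     "F", "e", "j", "n", "E", "/", "f", "Q"]
)

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


# ---------------------------------------------------------------------------
# WFDB header / signal codec
# ---------------------------------------------------------------------------


def _parse_header(hea_path: Path) -> dict:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty WFDB header: {hea_path}")
    rec = lines[0].split()
    if len(rec) < 2:
        raise ValueError(f"unparseable WFDB record line: {lines[0]!r}")
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samp = int(rec[3]) if len(rec) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        if len(f) < 2:
            raise ValueError(f"unparseable WFDB signal line: {ln!r}")
        fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = f[2] if len(f) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain_s, base_s = gain_part.split("(")
            gain = float(gain_s)
            baseline = int(base_s.rstrip(")"))
        else:
            gain = float(gain_part)
            baseline = None
        if gain == 0:
            gain = 200.0
        adc_zero = int(f[4]) if len(f) > 4 else 0
        desc = " ".join(f[8:]) if len(f) > 8 else None
        signals.append(
            {
                "file": f[0],
                "fmt": fmt,
                "gain": gain,
                "baseline": baseline if baseline is not None else adc_zero,
                "desc": desc,
            }
        )
    return {"name": name, "n_sig": n_sig, "fs": fs, "n_samp": n_samp,
            "signals": signals}


def _unpack_212(raw: bytes, n_values: int) -> np.ndarray:
    """Decode WFDB format 212: two 12-bit two's-complement samples / 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_tri = b.size // 3
    b = b[: n_tri * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_tri, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096
    return out[:n_values]


def _pack_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if np.any((v < -2048) | (v > 2047)):
        raise ValueError("format 212 samples must fit in 12 bits")
    if v.size % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v).astype(np.uint32)
    s0, s1 = v[0::2], v[1::2]
    tri = np.empty((s0.size, 3), dtype=np.uint8)
    tri[:, 0] = s0 & 0xFF
    tri[:, 1] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
    tri[:, 2] = s1 & 0xFF
    return tri.tobytes()


def _read_wfdb(path: Path, channel: int) -> EcgRecord:
    hea_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(hea_path)
    hdr = _parse_header(hea_path)
    if not 0 <= channel < hdr["n_sig"]:
        raise IndexError(
            f"channel {channel} out of range for {hdr['n_sig']}-signal record"
        )
    sig = hdr["signals"][channel]
    dat_path = hea_path.parent / sig["file"]
    raw = dat_path.read_bytes()
    n_sig = hdr["n_sig"]
    fmt = sig["fmt"]
    if fmt == 212:
        total = hdr["n_samp"] * n_sig if hdr["n_samp"] else (len(raw) // 3) * 2
        flat = _unpack_212(raw, total)
    elif fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        if hdr["n_samp"]:
            flat = flat[: hdr["n_samp"] * n_sig]
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    adc = flat[channel::n_sig]
    mv = (adc - sig["baseline"]) / sig["gain"]
    return EcgRecord(
        record_id=hdr["name"],
        samples=mv,
        fs=hdr["fs"],
        lead_name=sig["desc"],
    )


def write_record_wfdb(
    record: EcgRecord,
    path: str | Path,
    gain: float = 200.0,
    fmt: int = 212,
) -> None:
    """Write ``record`` as a WFDB ``.hea`` + ``.dat`` pair (format 212 or 16).

    Millivolt samples are quantized to ADC units with the given gain and a
    zero baseline, so a read-back reproduces them to within ``1/(2*gain)`` mV.
    """
    path = Path(path)
    base = path.with_suffix("")
    adc = np.rint(record.samples * gain).astype(np.int32)
    if fmt == 212:
        payload = _pack_212(adc)
    elif fmt == 16:
        payload = adc.astype("<i2").tobytes()
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    (base.parent / (base.name + ".dat")).write_bytes(payload)
    fs = record.fs
    fs_str = f"{fs:g}"
    lead = record.lead_name or "ECG"
    hea = (
        f"{base.name} 1 {fs_str} {record.samples.size}\n"
        f"{base.name}.dat {fmt} {gain:g}(0)/mV 12 0 0 0 0 {lead}\n"
    )
    (base.parent / (base.name + ".hea")).write_text(hea)


# ---------------------------------------------------------------------------
# MIT annotation codec
# ---------------------------------------------------------------------------


def _read_mit_annotations(path: Path) -> list[tuple[int, str, str | None]]:
    """Decode an MIT annotation stream to (sample, symbol, aux) triples."""
    raw = path.read_bytes()
    words = np.frombuffer(raw[: len(raw) - len(raw) % 2], dtype="<u2")
    out: list[tuple[int, str, str | None]] = []
    t = 0
    i = 0
    n = words.size
    while i < n:
        w = int(words[i])
        code, tfield = w >> 10, w & 0x3FF
        i += 1
        if code == 0 and tfield == 0:
            break
        if code == _SKIP:
            if i + 1 >= n:
                raise ValueError("truncated SKIP in annotation stream")
            interval = (int(words[i]) << 16) | int(words[i + 1])
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            i += 2
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            n_bytes = tfield
            start = 2 * i
            aux = raw[start : start + n_bytes].decode("latin-1").rstrip("\x00")
            i += (n_bytes + 1) // 2
            if out:
                s, sym, _ = out[-1]
                out[-1] = (s, sym, aux)
            continue
        t += tfield
        sym = _CODE_TO_SYMBOL.get(code)
        if sym is None:
            raise ValueError(f"unknown annotation code {code}")
        out.append((t, sym, None))
    return out


def _write_mit_annotations(
    annots: list[tuple[int, str, str | None]], path: Path
) -> None:
    buf = bytearray()
    prev = 0
    for sample, sym, aux in annots:
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"no MIT code for symbol {sym!r}")
        delta = sample - prev
        if delta < 0:
            raise ValueError("annotations must be sorted by sample")
        if delta > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        if aux:
            data = aux.encode("latin-1")
            buf += struct.pack("<H", (_AUX << 10) | len(data))
            buf += data
            if len(data) % 2:
                buf += b"\x00"
        prev = sample
    buf += struct.pack("<H", 0)
    path.write_bytes(bytes(buf))


def read_annotations(
    path: str | Path,
    beat_label_set: frozenset[str] | set[str] = BEAT_SYMBOLS,
) -> BeatAnnotations:
    """Read an MIT annotation file, keeping only beat-class annotations.

    Ventricular-flutter episodes — delimited either by ``[``/``]`` markers or
    by rhythm-change ``+`` annotations whose aux string starts a ``(VFL``
    rhythm — become half-open ``exclusion_intervals``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    triples = _read_mit_annotations(path)
    beats: list[int] = []
    labels: list[str] = []
    intervals: list[tuple[int, int]] = []
    open_start: int | None = None
    end_sample = triples[-1][0] + 1 if triples else 0
    for sample, sym, aux in triples:
        if sym in beat_label_set:
            beats.append(sample)
            labels.append(sym)
        elif sym == "[":
            if open_start is None:
                open_start = sample
        elif sym == "]":
            if open_start is not None:
                intervals.append((open_start, sample + 1))
                open_start = None
        elif sym == "+" and aux:
            rhythm = aux.lstrip("\x00")
            if rhythm.startswith("(VFL"):
                if open_start is None:
                    open_start = sample
            elif open_start is not None:
                intervals.append((open_start, sample))
                open_start = None
    if open_start is not None:
        intervals.append((open_start, max(end_sample, open_start + 1)))
    return BeatAnnotations(
        beat_samples=np.asarray(beats, dtype=np.int64),
        beat_labels=labels,
        exclusion_intervals=intervals,
    )


def write_annotations_wfdb(ann: BeatAnnotations, path: str | Path) -> None:
    """Write beats (and flutter intervals as ``[``/``]``) to an MIT stream."""
    events: list[tuple[int, int, str, str | None]] = []
    for s, sym in zip(ann.beat_samples, ann.beat_labels):
        events.append((int(s), 1, sym, None))
    for start, end in ann.exclusion_intervals:
        events.append((int(start), 0, "[", None))
        events.append((int(end) - 1, 2, "]", None))
    events.sort(key=lambda e: (e[0], e[1]))
    _write_mit_annotations([(s, sym, aux) for s, _, sym, aux in events],
                           Path(path))


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def _read_csv_samples(path: Path) -> np.ndarray:
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for ln_no, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            token = line.split(",")[0]
            try:
                values.append(float(token))
            except ValueError:
                if ln_no == 0:  # optional header row
                    continue
                raise ValueError(f"unparseable CSV line {ln_no + 1}: {line!r}")
    return np.asarray(values, dtype=float)


def write_record_csv(record: EcgRecord, path: str | Path) -> None:
    np.savetxt(path, record.samples, fmt="%.9g")


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def read_record(
    path: str | Path,
    format: str = "wfdb",
    fs_override: float | None = None,
    channel: int = 0,
) -> EcgRecord:
    """Read an ECG record into millivolt samples.

    For WFDB, gain and baseline from the header are applied and ``fs`` comes
    from the header (``fs_override`` wins if given).  CSV streams carry no
    rate, so ``fs_override`` is required.
    """
    path = Path(path)
    if format == "wfdb":
        rec = _read_wfdb(path, channel)
        if fs_override is not None:
            rec = EcgRecord(rec.record_id, rec.samples, fs_override,
                            rec.lead_name)
        return rec
    if format == "csv":
        if fs_override is None:
            raise ValueError("fs_override is required for CSV input")
        if not path.exists():
            raise FileNotFoundError(path)
        if channel != 0:
            raise IndexError("CSV records are single-channel")
        return EcgRecord(
            record_id=path.stem, samples=_read_csv_samples(path),
            fs=fs_override,
        )
    raise ValueError(f"unknown format {format!r}")


def write_detections(peaks, path: str | Path, format: str = "csv") -> None:
    """Write detected R peaks.

    ``csv``: rows of ``sample_index,time_s,amplitude_mV`` (header always
    written, so an empty detection list yields a header-only file).
    ``wfdb_ann``: an MIT annotation stream of ``N`` beats, round-trippable to
    identical sample indices.
    """
    path = Path(path)
    idx = np.asarray(peaks.peak_samples, dtype=np.int64)
    amps = np.asarray(peaks.amplitudes, dtype=float)
    if format == "csv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample_index,time_s,amplitude_mV\n")
            for s, a in zip(idx, amps):
                fh.write(f"{int(s)},{s / peaks.fs:.9g},{a:.9g}\n")
    elif format == "wfdb_ann":
        _write_mit_annotations([(int(s), "N", None) for s in idx], path)
    else:
        raise ValueError(f"unknown detections format {format!r}")


def read_detections_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a detections CSV back to (sample_indices, amplitudes)."""
    idx: list[int] = []
    amps: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("sample_index"):
            raise ValueError("not a detections CSV")
        for line in fh:
            if not line.strip():
                continue
            s, _, a = line.strip().split(",")
            idx.append(int(s))
            amps.append(float(a))
    return np.asarray(idx, dtype=np.int64), np.asarray(amps, dtype=float)


def read_truth_csv(path: str | Path) -> BeatAnnotations:
    """Read a truth CSV (``sample_index,label`` rows) from the generator."""
    beats: list[int] = []
    labels: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("sample_index"):
                continue
            s, lab = line.split(",")
            beats.append(int(s))
            labels.append(lab)
    return BeatAnnotations(np.asarray(beats, dtype=np.int64), labels)


def write_truth_csv(ann: BeatAnnotations, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_index,label\n")
        for s, lab in zip(ann.beat_samples, ann.beat_labels):
            fh.write(f"{int(s)},{lab}\n")


def load_manifest(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
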