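"""Beat-by-beat scoring of detections against reference annotations.

A detected peak within 150 ms of an unmatched reference beat is a true
positive; a detection with no reference beat in that window is a false
positive; a reference beat with no detection is a false negative.  Matching
is one-to-one and performed in a single chronological sweep: each test peak
is paired with the earliest still-unmatched reference beat inside its
window.  Because every test peak's admissible reference beats form a
contiguous span of the sorted reference list, this greedy sweep attains the
maximum possible number of pairs (it is the classic greedy for convex
bipartite matching).

Summary statistics: Se = TP/(TP+FN), PPV = TP/(TP+FP), F1 = harmonic mean of
the two, and FN/FP rates expressed as fractions of the reference-annotation
count (note the FP rate can exceed 1 under that denominator).  Rhythm
episodes with no discernible sinus beats — ventricular flutter — are excised
from both streams before matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BeatAnnotations
from .rpeak_detector import RPeakList

__all__ = [
    "MatchResult",
    "DetectionStats",
    "exclude_intervals",
    "match_beats",
    "detection_stats",
    "summarize_groups",
]

DEFAULT_MATCH_WINDOW_MS = 150.0


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    n_ref: int
    matched_pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.tp + self.fn != self.n_ref:
            raise ValueError("tp + fn must equal n_ref")
        if self.tp != len(self.matched_pairs):
            raise ValueError("tp must equal number of matched pairs")


@dataclass(frozen=True)
class DetectionStats:
    """Summary fractions in [0, 1]; ``ppv``/``f1`` are None when undefined."""

    se: float | None
    ppv: float | None
    f1: float | None
    fn_rate: float
    fp_rate: float


def exclude_intervals(
    ref: BeatAnnotations,
    test: RPeakList,
    intervals: list[tuple[int, int]] | None = None,
) -> tuple[BeatAnnotations, RPeakList]:
    """Drop reference beats and test peaks inside excluded rhythm episodes.

    ``intervals`` defaults to the reference's own ``exclusion_intervals``.
    Intervals must be sorted and non-overlapping, half-open ``[start, end)``;
    removal is symmetric (both streams), so spurious detections during an
    excluded episode are not penalized.
    """
    if intervals is None:
        intervals = list(ref.exclusion_intervals)
    intervals = sorted(intervals)
    for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("exclusion intervals overlap")

    def keep(samples: np.ndarray) -> np.ndarray:
        mask = np.ones(samples.size, dtype=bool)
        for s, e in intervals:
            mask &= ~((samples >= s) & (samples < e))
        return mask

    ref_mask = keep(ref.beat_samples)
    test_mask = keep(test.peak_samples)
    new_ref = BeatAnnotations(
        ref.beat_samples[ref_mask],
        [lab for lab, k in zip(ref.beat_labels, ref_mask) if k],
        [],
    )
    new_test = RPeakList(
        record_id=test.record_id,
        fs=test.fs,
        peak_samples=test.peak_samples[test_mask],
        amplitudes=test.amplitudes[test_mask],
        polarity_flipped=list(test.polarity_flipped),
    )
    return new_ref, new_test


def match_beats(
    ref: BeatAnnotations,
    test: RPeakList,
    window_ms: float = DEFAULT_MATCH_WINDOW_MS,
) -> MatchResult:
    """One-to-one chronological matching within ``window_ms``.

    Walks test peaks in time order, pairing each with the earliest unmatched
    reference beat within the window; leftover test peaks are false
    positives, leftover reference beats false negatives.
    """
    window = window_ms * test.fs / 1000.0
    r = np.asarray(ref.beat_samples, dtype=np.int64)
    t = np.asarray(test.peak_samples, dtype=np.int64)
    pairs: list[tuple[int, int]] = []
    j = 0  # first unmatched reference index
    for tk in t:
        while j < r.size and r[j] < tk - window:
            j += 1
        if j < r.size and abs(int(r[j]) - int(tk)) <= window:
            pairs.append((int(r[j]), int(tk)))
            j += 1
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=int(t.size) - tp,
        fn=int(r.size) - tp,
        n_ref=int(r.size),
        matched_pairs=tuple(pairs),
    )


def detection_stats(m: MatchResult) -> DetectionStats:
    """Se, PPV, F1 and reference-normalized FN/FP rates for one record."""
    if m.n_ref == 0:
        raise ValueError("no reference beats: statistics undefined")
    se = m.tp / (m.tp + m.fn)
    ppv = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else None
    if ppv is not None and (ppv + se) > 0:
        f1 = 2.0 * ppv * se / (ppv + se)
    else:
        f1 = None
    return DetectionStats(
        se=se,
        ppv=ppv,
        f1=f1,
        fn_rate=m.fn / m.n_ref,
        fp_rate=m.fp / m.n_ref,
    )


def summarize_groups(
    per_record_stats: list[tuple[str, str, DetectionStats]],
) -> pd.DataFrame:
    """Unweighted per-record means of each statistic by group, plus overall.

    Returns a DataFrame indexed by group label (with a final ``Total`` row)
    and columns ``fn_rate, fp_rate, se, ppv, f1, n_records``.  Records with
    an undefined statistic are omitted from that statistic's mean.
    """
    if not per_record_stats:
        raise ValueError("no records to summarize")
    rows = [
        {
            "record_id": rid,
            "group": grp,
            "fn_rate": st.fn_rate,
            "fp_rate": st.fp_rate,
            "se": st.se,
            "ppv": st.ppv,
            "f1": st.f1,
        }
        for rid, grp, st in per_record_stats
    ]
    df = pd.DataFrame(rows)
    cols = ["fn_rate", "fp_rate", "se", "ppv", "f1"]
    by_group = df.groupby("group")[cols].mean()
    by_group["n_records"] = df.groupby("group").size()
    total = df[cols].mean().to_frame().T
    total["n_records"] = len(df)
    total.index = pd.Index(["Total"], name="group")
    out = pd.concat([by_group, total])
    out["n_records"] = out["n_records"].astype(int)
    return out
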