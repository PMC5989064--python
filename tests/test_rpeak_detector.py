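"""Detector stages and end-to-end invariants on synthetic ground truth."""

import numpy as np
import pytest

from pyrpeak.detrending import DetrendConfig, Segment, fit_baseline_residual, segment_stream
from pyrpeak.io_formats import EcgRecord
from pyrpeak.rpeak_detector import (
    DetectorConfig,
    correct_polarity,
    detect_r_peaks,
    find_candidates,
    refine_peaks,
    refractory_filter,
    smooth_derivative,
)
from pyrpeak.synthetic_ecg import ArtifactSpec, inject_artifact

from conftest import assert_refractory


def _segment(samples, fs=360.0):
    return Segment("t", 0, np.asarray(samples, dtype=float), fs)


class TestSmoothDerivative:
    @pytest.mark.parametrize("fs,expected", [(256.0, 5), (360.0, 7),
                                             (500.0, 10), (100.0, 2)])
    def test_kernel_length_tracks_sampling_rate(self, fs, expected):
        assert DetectorConfig().kernel_samples(fs) == expected

    def test_constant_segment_gives_zero(self):
        out = smooth_derivative(_segment(np.full(1000, 2.5)), DetectorConfig())
        assert np.max(np.abs(out)) == 0.0
        assert out.size == 1000

    def test_ramp_recovers_slope_away_from_edges(self):
        fs = 360.0
        t = np.arange(2000) / fs
        out = smooth_derivative(_segment(1.0 * t, fs), DetectorConfig())
        np.testing.assert_allclose(out[20:], 1.0, atol=1e-9)

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError):
            smooth_derivative(_segment(np.zeros(5)), DetectorConfig())


class TestPolarity:
    def _clean_segment(self, make_clean, invert=False):
        _, rec, _ = make_clean(duration_s=15, rr_jitter_frac=0.0)
        samples = -rec.samples if invert else rec.samples
        seg = _segment(samples)
        return fit_baseline_residual(seg, DetrendConfig())

    def test_upright_segment_not_flipped(self, make_clean):
        _, flipped = correct_polarity(self._clean_segment(make_clean),
                                      DetectorConfig())
        assert flipped is False

    def test_inverted_segment_flipped_back(self, make_clean):
        seg = self._clean_segment(make_clean, invert=True)
        out, flipped = correct_polarity(seg, DetectorConfig())
        assert flipped is True
        np.testing.assert_array_equal(out.samples, -seg.samples)

    def test_flat_segment_reports_unflipped(self):
        _, flipped = correct_polarity(_segment(np.zeros(1000)),
                                      DetectorConfig())
        assert flipped is False

    def test_exact_tie_does_not_flip(self):
        # Two upright and two inverted bumps: votes split evenly.
        fs = 360.0
        t = np.arange(int(8 * fs)) / fs
        y = np.zeros(t.size)
        for c, sign in [(1.0, 1), (3.0, -1), (5.0, 1), (7.0, -1)]:
            y += sign * np.exp(-0.5 * ((t - c) / 0.013) ** 2)
        _, flipped = correct_polarity(_segment(y, fs), DetectorConfig())
        assert flipped is False


class TestCandidates:
    def test_zero_signal_no_candidates(self):
        seg = _segment(np.zeros(1000))
        deriv = smooth_derivative(seg, DetectorConfig())
        assert find_candidates(deriv, seg, DetectorConfig()).size == 0

    def test_clean_15s_segment_one_candidate_per_beat(self, make_clean):
        _, rec, truth = make_clean(duration_s=15, heart_rate_bpm=60,
                                   rr_jitter_frac=0.0)
        seg = fit_baseline_residual(
            segment_stream(rec, DetrendConfig())[0], DetrendConfig()
        )
        cfg = DetectorConfig()
        cands = find_candidates(smooth_derivative(seg, cfg), seg, cfg)
        assert cands.size == truth.n_beats == 15

    def test_amplitude_scaling_leaves_candidates_unchanged(self, make_clean):
        _, rec, _ = make_clean(duration_s=15)
        cfg = DetectorConfig()
        seg = fit_baseline_residual(
            segment_stream(rec, DetrendConfig())[0], DetrendConfig()
        )
        big = _segment(seg.samples * 250.0)
        c1 = find_candidates(smooth_derivative(seg, cfg), seg, cfg)
        c2 = find_candidates(smooth_derivative(big, cfg), big, cfg)
        np.testing.assert_array_equal(c1, c2)


class TestRefinePeaks:
    def test_candidate_maps_to_gaussian_apex(self):
        fs = 360.0
        t = np.arange(720) / fs
        apex = 360
        y = np.exp(-0.5 * ((t - t[apex]) / 0.013) ** 2)
        peaks, amps = refine_peaks(np.array([apex - 10]), _segment(y, fs),
                                   DetectorConfig())
        assert peaks.size == 1 and abs(int(peaks[0]) - apex) <= 1
        assert amps[0] == pytest.approx(1.0, abs=1e-3)

    def test_duplicate_candidates_collapse(self):
        fs = 360.0
        t = np.arange(720) / fs
        y = np.exp(-0.5 * ((t - 1.0) / 0.013) ** 2)
        peaks, _ = refine_peaks(np.array([350, 355]), _segment(y, fs),
                                DetectorConfig())
        assert peaks.size == 1

    def test_monotonic_ramp_candidate_dropped(self):
        y = np.linspace(0, 1, 720)
        peaks, _ = refine_peaks(np.array([100]), _segment(y), DetectorConfig())
        assert peaks.size == 0


class TestRefractoryFilter:
    def test_close_pair_keeps_higher_amplitude(self):
        fs = 360.0
        p, a = refractory_filter(np.array([0, 72]), np.array([1.0, 0.5]),
                                 DetectorConfig(), fs)
        assert p.tolist() == [0] and a.tolist() == [1.0]

    def test_spaced_peaks_untouched(self):
        fs = 360.0
        peaks = np.array([0, 108, 216])  # 300-ms spacing
        p, _ = refractory_filter(peaks, np.ones(3), DetectorConfig(), fs)
        assert p.tolist() == peaks.tolist()

    def test_amplitude_tie_keeps_earlier(self):
        p, _ = refractory_filter(np.array([0, 10]), np.array([1.0, 1.0]),
                                 DetectorConfig(), 360.0)
        assert p.tolist() == [0]

    def test_matches_bruteforce_elimination(self):
        # Independent oracle: naive repeated scan applying the stated rule.
        def oracle(peaks, amps, min_gap):
            peaks, amps = list(peaks), list(amps)
            while True:
                best = None
                for i in range(len(peaks) - 1):
                    gap = peaks[i + 1] - peaks[i]
                    if gap < min_gap and (best is None or gap < best[1]):
                        best = (i, gap)
                if best is None:
                    return peaks, amps
                i = best[0]
                j = i if amps[i + 1] > amps[i] else i + 1
                peaks.pop(j)
                amps.pop(j)

        rng = np.random.default_rng(42)
        cfg = DetectorConfig()
        fs = 360.0
        min_gap = cfg.refractory_samples(fs)
        for _ in range(1000):
            n = int(rng.integers(0, 13))
            peaks = np.unique(rng.integers(0, 1200, size=n))
            amps = np.round(rng.uniform(0, 2, size=peaks.size), 2)
            got_p, got_a = refractory_filter(peaks, amps, cfg, fs)
            exp_p, exp_a = oracle(peaks, amps, min_gap)
            assert got_p.tolist() == exp_p
            assert got_a.tolist() == exp_a


class TestDetectEndToEnd:
    def test_clean_record_perfect_recovery(self, make_clean):
        from pyrpeak.evaluation import detection_stats, match_beats

        _, rec, truth = make_clean(duration_s=300, heart_rate_bpm=75, seed=1)
        peaks = detect_r_peaks(rec)
        assert_refractory(peaks, rec.fs)
        stats = detection_stats(match_beats(truth, peaks))
        assert stats.se == 1.0 and stats.ppv == 1.0

    def test_polarity_inversion_gives_identical_peaks(self, make_clean):
        _, rec, _ = make_clean(duration_s=60, seed=2)
        p1 = detect_r_peaks(rec)
        p2 = detect_r_peaks(EcgRecord(rec.record_id, -rec.samples, rec.fs))
        np.testing.assert_array_equal(p1.peak_samples, p2.peak_samples)
        assert any(p2.polarity_flipped)

    def test_amplitude_scaling_gives_identical_peaks(self, make_clean):
        _, rec, _ = make_clean(duration_s=60, seed=3)
        p1 = detect_r_peaks(rec)
        p2 = detect_r_peaks(EcgRecord(rec.record_id, 13.0 * rec.samples,
                                      rec.fs))
        np.testing.assert_array_equal(p1.peak_samples, p2.peak_samples)

    def test_highfreq_spikes_do_not_add_peaks(self, make_clean):
        spec, rec, truth = make_clean(duration_s=60, seed=4)
        noisy, _ = inject_artifact(
            rec, truth, ArtifactSpec(kind="spike_highfreq", seed=5),
            morphology=spec,
        )
        p1 = detect_r_peaks(rec)
        p2 = detect_r_peaks(noisy)
        np.testing.assert_array_equal(p1.peak_samples, p2.peak_samples)

    def test_shift_robustness_rr_preserved(self, make_clean):
        _, rec, _ = make_clean(duration_s=60, seed=6)
        base_rr = np.diff(detect_r_peaks(rec).peak_samples)
        for delay_s in (0.5, 1.0, 2.0):
            pad = np.zeros(int(delay_s * rec.fs))
            shifted = EcgRecord(rec.record_id,
                                np.concatenate([pad, rec.samples]), rec.fs)
            rr = np.diff(detect_r_peaks(shifted).peak_samples)
            assert rr.size == base_rr.size
            assert np.max(np.abs(rr - base_rr)) <= 1

    def test_record_too_short_raises(self):
        with pytest.raises(ValueError):
            detect_r_peaks(EcgRecord("r", np.zeros(30), 360.0))
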