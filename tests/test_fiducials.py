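"""Fiducial detector against brute-force oracles and synthetic ground truth."""

import dataclasses

import numpy as np
import pytest

import detect_ecg as d
from detect_ecg.errors import NoBeatsError
from detect_ecg.fiducials import (DetectorConfig, detect_r_peaks, locate_pt,
                                  locate_qrs_onset_offset, locate_qs)
from detect_ecg.segmenter import Segment
from detect_ecg.synthcohort import synthesize_recording

FS = 200.0


def _seg(x, fs=FS, sid="s"):
    return Segment(sid, np.asarray(x, dtype=float), fs, 0, "blind")


def _gauss(n, center, amp, sigma_samples):
    i = np.arange(n)
    return amp * np.exp(-0.5 * ((i - center) / sigma_samples) ** 2)


def brute_force_r_peaks(x, frac):
    """Oracle: all strict interior local maxima >= frac * max(x)."""
    t = frac * x.max()
    return [i for i in range(1, x.size - 1)
            if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] >= t]


class TestDetectRPeaks:
    def test_two_suprathreshold_bumps(self):
        x = _gauss(600, 100, 1.0, 4) + _gauss(600, 400, 0.9, 4)
        seg = _seg(x)
        peaks = detect_r_peaks(seg)
        assert list(peaks) == [100, 400] == brute_force_r_peaks(x, 0.66)

    def test_subthreshold_bump_eliminated(self):
        x = _gauss(600, 100, 1.0, 4) + _gauss(600, 400, 0.5, 4)
        peaks = detect_r_peaks(_seg(x))
        assert list(peaks) == [100] == brute_force_r_peaks(x, 0.66)

    def test_constant_segment_raises(self):
        with pytest.raises(NoBeatsError):
            detect_r_peaks(_seg(np.zeros(600)))

    def test_close_peaks_merged_keeping_larger(self):
        # 20 samples apart = 0.1 s < min_rr 0.25 s
        x = _gauss(600, 100, 0.9, 3) + _gauss(600, 120, 1.0, 3)
        peaks = detect_r_peaks(_seg(x))
        assert list(peaks) == [120]

    def test_merge_disabled_at_zero_min_rr(self):
        x = _gauss(600, 100, 0.9, 3) + _gauss(600, 120, 1.0, 3)
        cfg = DetectorConfig(min_rr_s=1e-9)
        assert list(detect_r_peaks(_seg(x), cfg)) == [100, 120]

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=600).cumsum()  # smooth-ish random walk
        x -= x.min()
        counts = []
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
            try:
                counts.append(detect_r_peaks(_seg(x), DetectorConfig(
                    r_threshold_fraction=frac)).size)
            except NoBeatsError:
                counts.append(0)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestLocateQS:
    def test_troughs_found_next_to_r(self):
        n = 600
        x = (_gauss(n, 300, 1.0, 3) - _gauss(n, 285, 0.15, 2)
             - _gauss(n, 315, 0.25, 2))
        q, s = locate_qs(_seg(x), 300)
        assert abs(q - 285) <= 1 and abs(s - 315) <= 1

    def test_symmetric_beat_symmetric_qs(self):
        n = 600
        x = (_gauss(n, 300, 1.0, 3) - _gauss(n, 280, 0.2, 2)
             - _gauss(n, 320, 0.2, 2))
        q, s = locate_qs(_seg(x), 300)
        assert 300 - q == s - 300

    def test_monotone_ramp_rejects_beat(self):
        # strictly increasing through the whole window: no extremum
        x = np.linspace(0, 1, 600)
        assert locate_qs(_seg(x), 300) is None

    def test_strict_maximum_mode_skips_troughs(self):
        n = 600
        x = (_gauss(n, 300, 1.0, 3) - _gauss(n, 290, 0.2, 2)
             + _gauss(n, 284, 0.1, 2) - _gauss(n, 310, 0.2, 2)
             + _gauss(n, 316, 0.1, 2))
        cfg = DetectorConfig(qs_mode="maximum")
        q, s = locate_qs(_seg(x), 300, cfg)
        assert abs(q - 284) <= 1 and abs(s - 316) <= 1


class TestOnsetOffset:
    def test_linear_ramp_tie_goes_to_far_edge(self):
        x = np.arange(600) / 64.0  # exactly representable: chord slopes tie
        onset, offset = locate_qrs_onset_offset(_seg(x), 300, 320)
        w = int(round(0.04 * FS))  # 8 candidate samples
        assert onset == 300 - w
        assert offset == 320 + w

    def test_kink_before_q_wins_slope_search(self):
        # flat until sample 295 then steep drop into Q at 300
        x = np.zeros(600)
        x[295:301] = np.linspace(0, -0.5, 6)
        x[301:] = -0.5
        x += _gauss(600, 305, 1.0, 2)  # R peak to the right, irrelevant here
        onset, _ = locate_qrs_onset_offset(_seg(x), 300, 310)
        # brute-force argmax of |x[q]-x[t]|/(q-t) over the 8-sample window
        w = int(round(0.04 * FS))
        cands = np.arange(300 - w, 300)
        slopes = np.abs(x[300] - x[cands]) / (300 - cands)
        assert onset == cands[np.argmax(slopes)]

    def test_window_clipped_by_edge_rejects(self):
        x = np.linspace(0, 1, 600)
        assert locate_qrs_onset_offset(_seg(x), 3, 598) is None

    def test_search_window_has_8_candidates_at_200hz(self):
        assert int(round(DetectorConfig().slope_window_s * FS)) == 8


class TestLocatePT:
    def _beat_segment(self, p_amp=0.15, t_amp=0.3):
        n = 600
        x = (_gauss(n, 300, 1.0, 3) - _gauss(n, 293, 0.1, 2)
             - _gauss(n, 307, 0.2, 2)
             + _gauss(n, 264, p_amp, 5) + _gauss(n, 350, t_amp, 10))
        return _seg(x)

    def test_p_and_t_found_near_truth(self):
        seg = self._beat_segment()
        q, s = locate_qs(seg, 300)
        onset, offset = locate_qrs_onset_offset(seg, q, s)
        p, t = locate_pt(seg, onset, offset)
        assert p is not None and abs(p - 264) <= 3
        assert t is not None and abs(t - 350) <= 3

    def test_zero_p_amplitude_absent(self):
        seg = self._beat_segment(p_amp=0.0)
        q, s = locate_qs(seg, 300)
        onset, offset = locate_qrs_onset_offset(seg, q, s)
        p, _ = locate_pt(seg, onset, offset)
        assert p is None

    def test_clipped_window_gives_absent(self):
        seg = self._beat_segment()
        p, t = locate_pt(seg, 10, 590)  # windows overrun both edges
        assert p is None and t is None


class TestAnnotateSegment:
    def test_zero_noise_three_beat_segment(self, clean_morphology):
        rec, truth = synthesize_recording(clean_morphology, 4.0, FS, seed=2)
        seg = Segment("ref", rec.samples[:600], FS, 0, "blind")
        beats = d.annotate_segment(seg)
        in_seg = truth.r_indices[truth.r_indices < 600]
        assert len(beats) == len(in_seg)
        for b in beats:
            assert (b.qrs_onset_index < b.q_index < b.r_index
                    < b.s_index < b.qrs_offset_index)
            if b.p_index is not None:
                assert b.p_index < b.qrs_onset_index
            if b.t_index is not None:
                assert b.t_index > b.qrs_offset_index

    def test_single_beat_segment(self, clean_morphology):
        rec, _ = synthesize_recording(clean_morphology, 4.0, FS, seed=2)
        seg = Segment("ref", rec.samples[100:400], FS, 100, "blind")
        beats = d.annotate_segment(seg)
        assert len(beats) == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_ordering_invariant_on_noisy_segments(self, seed):
        morph = d.sample_morphology(f"n{seed}", np.random.default_rng(seed))
        morph = dataclasses.replace(morph, heart_rate_jitter_sd=3.0)
        rec, _ = synthesize_recording(morph, 10.0, FS, seed=seed,
                                      noise=d.MODERATE_NOISE)
        for start in (0, 600, 1200):
            seg = Segment(morph.subject_id, rec.samples[start:start + 600],
                          FS, start, "blind")
            try:
                beats = d.annotate_segment(seg)
            except NoBeatsError:
                continue
            for b in beats:
                assert (b.qrs_onset_index < b.q_index < b.r_index
                        < b.s_index < b.qrs_offset_index)
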