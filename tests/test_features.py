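"""Feature arithmetic, set projection and IQR outlier filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import detect_ecg as d
from detect_ecg.errors import InvalidArgumentError
from detect_ecg.features import (BASE_FEATURES, DURATION_FEATURES, FEATURE_NAMES,
                                 OutlierSpec, SegmentRejection, compute_fences,
                                 feature_columns, passes_quality,
                                 qrs_amplitude_stats)
from detect_ecg.fiducials import BeatAnnotation
from detect_ecg.segmenter import Segment

FS = 200.0


def _beat(r=100, q_off=5, s_off=5, r_amp=1.0, q_amp=-0.1, s_amp=-0.2,
          p=None, t=None, p_amp=0.15, t_amp=0.3):
    return BeatAnnotation(
        r_index=r, r_amp=r_amp,
        q_index=r - q_off, q_amp=q_amp,
        s_index=r + s_off, s_amp=s_amp,
        qrs_onset_index=r - q_off - 8, qrs_onset_amp=-0.02,
        qrs_offset_index=r + s_off + 8, qrs_offset_amp=-0.03,
        p_index=p, p_amp=p_amp if p is not None else None,
        t_index=t, t_amp=t_amp if t is not None else None)


def _segment(n=600):
    return Segment("s", np.zeros(n), FS, 0, "blind")


class TestExtractFeatures:
    def test_qrs_amplitude_is_r_minus_s(self):
        vec = d.extract_features([_beat(r_amp=1.0, s_amp=-0.2)], _segment(), "g")
        assert vec.values[FEATURE_NAMES.index("qrs_amplitude_mv")] == pytest.approx(1.2)

    def test_r_wave_duration_from_qs_times(self):
        # S at 625, Q at 605 -> 20 samples at 200 Hz = 100 ms
        b = _beat(r=615, q_off=10, s_off=10)
        vec = d.extract_features([b], _segment(700), "g")
        assert vec.values[FEATURE_NAMES.index("r_wave_duration_ms")] == pytest.approx(100.0)

    def test_identical_beats_zero_std(self):
        beats = [_beat(r=100), _beat(r=300)]
        vec = d.extract_features(beats, _segment(), "g")
        for name in ("std_q_amp_mv", "std_r_amp_mv", "std_s_amp_mv"):
            assert vec.values[FEATURE_NAMES.index(name)] == 0.0

    def test_qrs_stats_emit_exactly_six_values(self):
        assert qrs_amplitude_stats([_beat(), _beat(r=300)]).shape == (6,)

    def test_rr_interval_requires_two_beats(self):
        vec1 = d.extract_features([_beat(r=100)], _segment(), "g")
        assert np.isnan(vec1.values[FEATURE_NAMES.index("rr_interval_ms")])
        vec2 = d.extract_features([_beat(r=100), _beat(r=300)], _segment(), "g")
        assert vec2.values[FEATURE_NAMES.index("rr_interval_ms")] == pytest.approx(1000.0)

    def test_pp_interval_from_consecutive_p(self):
        beats = [_beat(r=100, p=60), _beat(r=300, p=260)]
        vec = d.extract_features(beats, _segment(), "g")
        assert vec.values[FEATURE_NAMES.index("mean_pp_interval_ms")] == pytest.approx(1000.0)

    def test_zero_beats_rejected_with_reason(self):
        out = d.extract_features([], _segment(), "g")
        assert isinstance(out, SegmentRejection) and out.reason == "no_beats"

    def test_duration_features_scale_with_fs_amplitudes_do_not(self):
        beats = [_beat(r=100, p=60, t=160), _beat(r=300, p=260, t=360)]
        seg_a = Segment("s", np.zeros(600), 200.0, 0, "blind")
        seg_b = Segment("s", np.zeros(600), 400.0, 0, "blind")
        va = d.extract_features(beats, seg_a, "g").values
        vb = d.extract_features(beats, seg_b, "g").values
        for i, name in enumerate(FEATURE_NAMES):
            if not np.isfinite(va[i]):
                continue
            if name in DURATION_FEATURES:
                assert va[i] == pytest.approx(2 * vb[i])
            else:
                assert va[i] == pytest.approx(vb[i])


class TestFeatureSets:
    def _vec(self):
        return d.FeatureVector("s", "g", np.arange(22, dtype=float))

    def test_base_has_9_slots(self):
        assert d.select_feature_set(self._vec(), "base").shape == (9,)
        assert len(BASE_FEATURES) == 9

    def test_full_has_22_slots(self):
        assert d.select_feature_set(self._vec(), "full").shape == (22,)
        assert len(FEATURE_NAMES) == 22

    def test_base_is_prefix_of_full(self):
        v = self._vec()
        np.testing.assert_array_equal(d.select_feature_set(v, "base"),
                                      d.select_feature_set(v, "full")[:9])
        assert feature_columns("base") == feature_columns("full")[:9]

    def test_quality_gate_full_needs_pt_slots(self):
        vals = np.arange(22, dtype=float)
        vals[FEATURE_NAMES.index("mean_p_amp_mv")] = np.nan
        vec = d.FeatureVector("s", "g", vals)
        assert passes_quality(vec, "base")
        assert not passes_quality(vec, "full")


def _table(columns):
    df = pd.DataFrame(columns)
    df.insert(0, "segment_id", [f"g{i}" for i in range(len(df))])
    df.insert(0, "subject_id", "s")
    return df


class TestIqrFilter:
    def test_degenerate_iqr_removes_single_outlier(self):
        # {0,0,0,0,10}: Q1=Q3=0 (linear interpolation), fences [0,0]
        t = _table({"f": [0.0, 0.0, 0.0, 0.0, 10.0]})
        kept, report = d.iqr_filter(t, OutlierSpec(fence_multiplier=0.5))
        assert report["fences"]["f"] == (0.0, 0.0)
        assert len(kept) == 4
        assert report["n_removed"] == 1
        assert report["removals"][0]["value"] == 10.0

    def test_constant_column_removes_nothing(self):
        t = _table({"f": [3.0] * 6})
        kept, report = d.iqr_filter(t)
        assert len(kept) == 6 and report["n_removed"] == 0

    def test_huge_multiplier_removes_nothing(self):
        rng = np.random.default_rng(0)
        t = _table({"f": rng.normal(size=50), "g": rng.normal(size=50)})
        kept, _ = d.iqr_filter(t, OutlierSpec(fence_multiplier=1e9))
        assert len(kept) == 50

    def test_partition_into_retained_and_removed(self):
        rng = np.random.default_rng(1)
        t = _table({"f": rng.standard_cauchy(40)})
        kept, report = d.iqr_filter(t)
        removed_ids = {r["row_id"] for r in report["removals"]}
        assert len(kept) + len(removed_ids) == len(t)
        assert set(kept.index).isdisjoint(removed_ids)
        assert set(kept.index) | removed_ids == set(t.index)

    def test_frozen_fences_are_idempotent(self):
        rng = np.random.default_rng(2)
        t = _table({"f": rng.standard_cauchy(60)})
        spec = OutlierSpec()
        kept, report = d.iqr_filter(t, spec)
        again, report2 = d.iqr_filter(kept, spec, fences=report["fences"])
        assert report2["n_removed"] == 0
        pd.testing.assert_frame_equal(again, kept)

    def test_refit_pass_removes_subset_of_retained(self):
        rng = np.random.default_rng(3)
        t = _table({"f": rng.standard_cauchy(60)})
        kept, _ = d.iqr_filter(t)
        kept2, _ = d.iqr_filter(kept)
        assert set(kept2.index) <= set(kept.index)

    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=40),
           st.floats(0, 5), st.floats(0, 5))
    def test_monotone_in_fence_multiplier(self, values, m1, dm):
        t = _table({"f": values})
        k_small, _ = d.iqr_filter(t, OutlierSpec(fence_multiplier=m1))
        k_large, _ = d.iqr_filter(t, OutlierSpec(fence_multiplier=m1 + dm))
        assert set(k_small.index) <= set(k_large.index)

    def test_quantile_mode_trims_extremes_only(self):
        vals = list(range(1000))
        t = _table({"f": [float(v) for v in vals]})
        kept, report = d.iqr_filter(t, OutlierSpec(mode="quantile"))
        # 0.5% per tail of 1000 ordered values: 5 below Q(0.005)=4.995,
        # 5 above Q(0.995)=994.005
        assert report["n_removed"] == 10
        assert len(kept) == 990

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidArgumentError):
            d.iqr_filter(_table({"f": []}))

    def test_fences_fitted_on_train_apply_to_test(self):
        train = _table({"f": [0.0, 1.0, 2.0, 3.0, 4.0]})
        test = _table({"f": [2.0, 50.0]})
        fences = compute_fences(train, OutlierSpec(fence_multiplier=0.5))
        kept, report = d.iqr_filter(test, fences=fences)
        assert list(kept["f"]) == [2.0] and report["n_removed"] == 1
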