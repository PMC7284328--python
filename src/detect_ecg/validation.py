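"""Ground-truth validation of the fiducial detector on synthetic cohorts.

Measures how often the detector recovers the generator's analytic wave
positions.  R recovery is scored for every true apex falling inside a blind
segment; Q/S/P/T are scored per matched beat, and P/T only where the full
search window fits inside the segment (a clipped window makes the wave
undetectable by construction, not a detector failure).
"""

from __future__ import annotations

import numpy as np

from .errors import NoBeatsError
from .fiducials import DetectorConfig, annotate_segment, detect_r_peaks
from .segmenter import segment_blind


def fiducial_recovery(cohort, cfg: DetectorConfig = DetectorConfig(),
                      window_s: float = 3.0,
                      r_tol: int = 2, wave_tol: int = 3) -> dict:
    """Recovery rates of R (±r_tol samples) and Q/S/P/T (±wave_tol).

    ``cohort`` is a list of (EcgRecording, GroundTruth) pairs as produced by
    :func:`detect_ecg.sample_cohort`.  Returns per-wave dicts with ``hit``,
    ``total`` and ``rate``.
    """
    hit = {w: 0 for w in "RQSPT"}
    total = {w: 0 for w in "RQSPT"}
    for rec, truth in cohort:
        fs = rec.fs
        pw = int(round(cfg.p_search_window_s * fs))
        tw = int(round(cfg.t_search_window_s * fs))
        for seg in segment_blind(rec, window_s):
            lo, hi = seg.start_index, seg.start_index + seg.n_samples
            try:
                r_peaks = detect_r_peaks(seg, cfg)
            except NoBeatsError:
                r_peaks = np.empty(0, dtype=int)
            beats = annotate_segment(seg, cfg)
            beat_r = np.array([b.r_index for b in beats], dtype=int)
            for bi, r_global in enumerate(truth.r_indices):
                if not lo <= r_global < hi:
                    continue
                r_true = r_global - lo
                total["R"] += 1
                if r_peaks.size and np.abs(r_peaks - r_true).min() <= r_tol:
                    hit["R"] += 1
                if not beat_r.size:
                    continue
                k = int(np.argmin(np.abs(beat_r - r_true)))
                if abs(beat_r[k] - r_true) > r_tol:
                    continue
                b = beats[k]
                checks = [("Q", b.q_index, True),
                          ("S", b.s_index, True),
                          ("P", b.p_index, b.qrs_onset_index - pw >= 0),
                          ("T", b.t_index, b.qrs_offset_index + 1 + tw <= hi - lo)]
                for wave, detected, searchable in checks:
                    if not searchable:
                        continue
                    true_idx = truth.wave_indices(wave)[bi] - lo
                    if not 0 <= true_idx < hi - lo:
                        continue
                    total[wave] += 1
                    if detected is not None and abs(detected - true_idx) <= wave_tol:
                        hit[wave] += 1
    return {w: {"hit": hit[w], "total": total[w],
                "rate": hit[w] / total[w] if total[w] else np.nan}
            for w in "RQSPT"}
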