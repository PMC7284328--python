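"""Fiducial-point detection within a 3-s segment.

Detection order mirrors how the features are later assembled:

1. **R peaks** — all strict local maxima at or above a fraction (default 66%)
   of the per-segment maximum; peaks closer than a refractory interval are
   merged keeping the larger.
2. **Q and S** — the first local extremum scanning backward resp. forward
   from each R peak inside a short search window.  The literal published
   recipe says "first local maximum"; physiologically Q and S are troughs,
   so the default accepts an extremum of either polarity and a
   strict-maximum mode is kept behind ``qs_mode="maximum"``.
3. **QRS onset/offset** — within a 40-ms window walking away from Q (resp.
   S), the sample maximizing the chord slope |x[q] − x[t]| / |q − t|;
   slope ties resolve to the window's far edge.
4. **P and T** — the most relevant local extremum (largest absolute
   deviation from the window median) in a search window before the onset /
   after the offset; absent when the window is clipped or contains no
   extremum.

Beats that fail any sub-locator are dropped; a segment with no surviving
R peak is rejected outright.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import InvalidArgumentError, NoBeatsError
from .segmenter import Segment


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    r_threshold_fraction: float = 0.66
    qs_search_window_s: float = 0.1
    slope_window_s: float = 0.04
    p_search_window_s: float = 0.2
    t_search_window_s: float = 0.4
    min_rr_s: float = 0.25   # refractory merge guard; 0 disables (literal recipe)
    qs_mode: str = "extremum"  # "extremum" | "maximum"
    #: Minimum |deviation from window median| for a P/T candidate (mV); filters
    #: the vanishing numerical extrema a flat window otherwise produces.
    pt_relevance_floor_mv: float = 0.02

    def __post_init__(self):
        if not 0 < self.r_threshold_fraction < 1:
            raise InvalidArgumentError("r_threshold_fraction must be in (0, 1)")
        for name in ("qs_search_window_s", "slope_window_s",
                     "p_search_window_s", "t_search_window_s"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.min_rr_s < 0:
            raise InvalidArgumentError("min_rr_s must be >= 0")
        if self.qs_mode not in ("extremum", "maximum"):
            raise InvalidArgumentError(f"unknown qs_mode {self.qs_mode!r}")


@dataclasses.dataclass(frozen=True)
class BeatAnnotation:
    """Fiducial indices and amplitudes of one beat (indices into the segment)."""

    r_index: int
    r_amp: float
    q_index: int
    q_amp: float
    s_index: int
    s_amp: float
    qrs_onset_index: int
    qrs_onset_amp: float
    qrs_offset_index: int
    qrs_offset_amp: float
    p_index: int | None = None
    p_amp: float | None = None
    t_index: int | None = None
    t_amp: float | None = None

    def __post_init__(self):
        ok = (self.qrs_onset_index < self.q_index < self.r_index
              < self.s_index < self.qrs_offset_index)
        if not ok:
            raise InvalidArgumentError(
                "fiducial ordering violated: onset < Q < R < S < offset required")
        if self.p_index is not None and self.p_index >= self.qrs_onset_index:
            raise InvalidArgumentError("P must precede QRS onset")
        if self.t_index is not None and self.t_index <= self.qrs_offset_index:
            raise InvalidArgumentError("T must follow QRS offset")


def _strict_local_maxima(x: np.ndarray) -> np.ndarray:
    """Interior strict local maxima; boundary samples never qualify."""
    if x.size < 3:
        return np.empty(0, dtype=int)
    core = (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])
    return np.flatnonzero(core) + 1


def detect_r_peaks(segment: Segment, cfg: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """R peaks: strict local maxima >= threshold × segment max, refractory-merged."""
    x = segment.samples
    if np.all(x == x[0]):
        raise NoBeatsError("constant segment: no beats")
    thresh = cfg.r_threshold_fraction * float(x.max())
    cand = [i for i in _strict_local_maxima(x) if x[i] >= thresh]
    if not cand:
        raise NoBeatsError("no local maximum reaches the R threshold")
    min_gap = int(round(cfg.min_rr_s * segment.fs))
    kept: list[int] = []
    for i in cand:
        if kept and i - kept[-1] < min_gap:
            if x[i] > x[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    return np.asarray(kept, dtype=int)


def _first_extremum(x: np.ndarray, start: int, stop: int, step: int,
                    mode: str) -> int | None:
    """First interior index from ``start`` towards ``stop`` that is a local
    extremum (or strict maximum when mode="maximum")."""
    i = start
    while i != stop:
        if 1 <= i <= x.size - 2:
            is_max = x[i] > x[i - 1] and x[i] > x[i + 1]
            is_min = x[i] < x[i - 1] and x[i] < x[i + 1]
            if (mode == "maximum" and is_max) or (mode == "extremum" and (is_max or is_min)):
                return i
        i += step
    return None


def locate_qs(segment: Segment, r_index: int,
              cfg: DetectorConfig = DetectorConfig()) -> tuple[int, int] | None:
    """First local extremum backward (Q) and forward (S) of the R peak.

    Returns None (beat rejected) when either window holds no extremum.
    """
    x = segment.samples
    w = int(round(cfg.qs_search_window_s * segment.fs))
    q = _first_extremum(x, r_index - 1, max(r_index - w, 0) - 1, -1, cfg.qs_mode)
    s = _first_extremum(x, r_index + 1, min(r_index + w, x.size - 1) + 1, +1, cfg.qs_mode)
    if q is None or s is None:
        return None
    return q, s


def locate_qrs_onset_offset(segment: Segment, q_index: int, s_index: int,
                            cfg: DetectorConfig = DetectorConfig()
                            ) -> tuple[int, int] | None:
    """Maximum-chord-slope search within ``slope_window_s`` of Q and S.

    Onset candidates are [q − w, q); offset candidates are (s, s + w].  Ties
    resolve to the window's far edge.  Returns None when either window is
    clipped by the segment boundary.
    """
    x = segment.samples
    w = int(round(cfg.slope_window_s * segment.fs))
    if q_index - w < 0 or s_index + w > x.size - 1:
        return None
    on_t = np.arange(q_index - w, q_index)
    on_slopes = np.abs(x[q_index] - x[on_t]) / (q_index - on_t)
    onset = int(on_t[np.argmax(on_slopes)])  # first occurrence = earliest = far edge
    off_t = np.arange(s_index + 1, s_index + w + 1)
    off_slopes = np.abs(x[off_t] - x[s_index]) / (off_t - s_index)
    rev = off_slopes[::-1]
    offset = int(off_t[off_t.size - 1 - np.argmax(rev)])  # far edge on ties
    return onset, offset


def locate_pt(segment: Segment, onset_index: int, offset_index: int,
              cfg: DetectorConfig = DetectorConfig()
              ) -> tuple[int | None, int | None]:
    """Most relevant extremum before the onset (P) and after the offset (T).

    Relevance is the absolute deviation from the window median.  A wave is
    absent (None) when its window is clipped by the segment edge or contains
    no local extremum.
    """
    x = segment.samples

    def most_relevant(lo: int, hi: int) -> int | None:
        if lo < 0 or hi > x.size or hi - lo < 3:
            return None
        window = x[lo:hi]
        ext = _strict_local_maxima(window)
        ext_min = _strict_local_maxima(-window)
        idx = np.concatenate([ext, ext_min])
        if idx.size == 0:
            return None
        baseline = float(np.median(window))
        best = idx[np.argmax(np.abs(window[idx] - baseline))]
        if abs(window[best] - baseline) < cfg.pt_relevance_floor_mv:
            return None
        return lo + int(best)

    pw = int(round(cfg.p_search_window_s * segment.fs))
    tw = int(round(cfg.t_search_window_s * segment.fs))
    p = most_relevant(onset_index - pw, onset_index)
    t = most_relevant(offset_index + 1, offset_index + 1 + tw)
    return p, t


def annotate_segment(segment: Segment,
                     cfg: DetectorConfig = DetectorConfig()) -> list[BeatAnnotation]:
    """Full per-beat annotation; beats failing any sub-locator are dropped."""
    x = segment.samples
    beats = []
    for r in detect_r_peaks(segment, cfg):
        qs = locate_qs(segment, int(r), cfg)
        if qs is None:
            continue
        q, s = qs
        onoff = locate_qrs_onset_offset(segment, q, s, cfg)
        if onoff is None:
            continue
        onset, offset = onoff
        if not onset < q < r < s < offset:
            continue
        p, t = locate_pt(segment, onset, offset, cfg)
        if p is not None and p >= onset:
            p = None
        if t is not None and t <= offset:
            t = None
        beats.append(BeatAnnotation(
            r_index=int(r), r_amp=float(x[r]),
            q_index=q, q_amp=float(x[q]),
            s_index=s, s_amp=float(x[s]),
            qrs_onset_index=onset, qrs_onset_amp=float(x[onset]),
            qrs_offset_index=offset, qrs_offset_amp=float(x[offset]),
            p_index=p, p_amp=None if p is None else float(x[p]),
            t_index=t, t_amp=None if t is None else float(x[t])))
    return beats
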