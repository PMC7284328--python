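"""Blind fixed-length segmentation and random-window augmentation.

Segmentation is *blind*: the recording is cut into equal windows (default
3 s) without locating heartbeats first; the QRS complex is only found later,
during feature extraction.  Augmentation enlarges a subject's segment set by
drawing window start offsets uniformly at random (with replacement, windows
may overlap), turning the 20 blind segments of a 60-s recording into an
arbitrary number — 80 by default.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._seeds import derive_seed
from .errors import InvalidArgumentError
from .ioformats import EcgRecording

DEFAULT_WINDOW_S = 3.0
DEFAULT_N_AUGMENT = 80
#: Only the first minute of each recording feeds the default pipeline.
DEFAULT_USE_SECONDS = 60.0


@dataclasses.dataclass(frozen=True)
class Segment:
    """A fixed-duration window of a source recording.

    ``samples`` equals the source slice ``[start_index, start_index + len)``;
    ``origin`` records whether it came from the blind grid or augmentation.
    """

    subject_id: str
    samples: np.ndarray
    fs: float
    start_index: int
    origin: str  # "blind" | "augmented"

    @property
    def n_samples(self) -> int:
        return self.samples.size


def _window_len(recording: EcgRecording, window_s: float) -> int:
    length = int(round(window_s * recording.fs))
    if length <= 0:
        raise InvalidArgumentError("window_s must be positive")
    if recording.samples.size < length:
        raise InvalidArgumentError(
            f"recording of {recording.samples.size} samples shorter than one "
            f"{window_s}-s window ({length} samples)")
    return length


def segment_blind(recording: EcgRecording,
                  window_s: float = DEFAULT_WINDOW_S) -> list[Segment]:
    """Non-overlapping contiguous windows from offset 0; trailing partial dropped."""
    length = _window_len(recording, window_s)
    n = recording.samples.size // length
    return [Segment(recording.subject_id,
                    recording.samples[i * length:(i + 1) * length].copy(),
                    recording.fs, i * length, "blind")
            for i in range(n)]


def augment_random_windows(recording: EcgRecording,
                           n_segments: int = DEFAULT_N_AUGMENT,
                           window_s: float = DEFAULT_WINDOW_S,
                           seed: int = 0) -> list[Segment]:
    """Draw ``n_segments`` windows with uniformly random starts (replacement).

    The per-subject RNG stream is derived from (seed, subject_id) so draws are
    reproducible independently of cohort ordering.
    """
    if n_segments < 0:
        raise InvalidArgumentError("n_segments must be >= 0")
    length = _window_len(recording, window_s)
    rng = np.random.default_rng(derive_seed(seed, "augment", recording.subject_id))
    starts = rng.integers(0, recording.samples.size - length + 1, size=n_segments)
    return [Segment(recording.subject_id,
                    recording.samples[s:s + length].copy(),
                    recording.fs, int(s), "augmented")
            for s in starts]
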