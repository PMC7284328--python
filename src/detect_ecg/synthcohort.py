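"""Seeded synthetic multi-subject ECG cohorts with known beat locations.

Each subject is a sum-of-Gaussians beat template: five localized bumps (P, Q,
R, S, T) at fixed time offsets relative to the R apex, repeated at a
heart-rate-controlled period with optional per-beat jitter, plus additive
baseline wander, power-line and broadband noise.  The generator records the
analytic position of every wave of every beat as ground truth, so fiducial
detection and feature extraction can be validated exactly on zero-noise
cohorts.

The model deliberately omits the U wave, pathological rhythms and multi-lead
geometry: it exists to make subjects mutually distinguishable through the
same P-QRS-T morphology parameters the downstream feature extractor measures.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._seeds import derive_seed
from .errors import InvalidArgumentError
from .ioformats import EcgRecording, write_recording_csv

WAVES = ("P", "Q", "R", "S", "T")

#: Physiological heart-rate range enforced everywhere (beats/min).
HR_MIN, HR_MAX = 40.0, 208.0


@dataclasses.dataclass(frozen=True)
class SubjectMorphology:
    """Per-subject beat shape and rhythm parameters.

    wave_amplitudes : mV per wave; R > 0, Q and S <= 0 (standard-lead polarity).
    wave_widths     : Gaussian sigma per wave, seconds.
    wave_offsets    : wave-apex time relative to the R apex, seconds; R is 0
                      and offsets are strictly ordered P < Q < R < S < T.
    mean_heart_rate : beats/min, within [40, 208].
    heart_rate_jitter_sd : per-beat instantaneous-rate jitter, beats/min.
    amplitude_jitter_sd  : per-beat multiplicative amplitude jitter, fraction.
    """

    subject_id: str
    wave_amplitudes: dict
    wave_widths: dict
    wave_offsets: dict
    mean_heart_rate: float
    heart_rate_jitter_sd: float = 0.0
    amplitude_jitter_sd: float = 0.0

    def __post_init__(self):
        for w in WAVES:
            for d in (self.wave_amplitudes, self.wave_widths, self.wave_offsets):
                if w not in d:
                    raise InvalidArgumentError(f"missing wave {w!r} in morphology")
        if self.wave_amplitudes["R"] <= 0:
            raise InvalidArgumentError("R amplitude must be > 0")
        if self.wave_amplitudes["Q"] > 0 or self.wave_amplitudes["S"] > 0:
            raise InvalidArgumentError("Q and S amplitudes must be <= 0")
        if not (HR_MIN <= self.mean_heart_rate <= HR_MAX):
            raise InvalidArgumentError(
                f"mean_heart_rate {self.mean_heart_rate} outside [{HR_MIN}, {HR_MAX}]")
        off = [self.wave_offsets[w] for w in WAVES]
        if self.wave_offsets["R"] != 0.0 or not all(a < b for a, b in zip(off, off[1:])):
            raise InvalidArgumentError(
                "wave offsets must satisfy P < Q < R(=0) < S < T")


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Additive noise mixture: baseline wander (< 0.5 Hz), power line, broadband."""

    baseline_wander_amp: float = 0.0   # mV
    baseline_wander_freq: float = 0.33  # Hz, must stay < 0.5
    powerline_amp: float = 0.0         # mV
    powerline_freq: float = 50.0       # Hz (50 or 60)
    broadband_sd: float = 0.0          # mV

    def __post_init__(self):
        if min(self.baseline_wander_amp, self.powerline_amp, self.broadband_sd) < 0:
            raise InvalidArgumentError("noise amplitudes must be >= 0")
        if not 0 < self.baseline_wander_freq < 0.5:
            raise InvalidArgumentError("baseline wander frequency must be < 0.5 Hz")


#: A moderate acquisition-noise level used by the scenario experiments.
MODERATE_NOISE = NoiseSpec(baseline_wander_amp=0.10, powerline_amp=0.05,
                           broadband_sd=0.08)

ZERO_NOISE = NoiseSpec()


@dataclasses.dataclass
class GroundTruth:
    """Analytic per-beat wave positions (sample indices), aligned across arrays.

    Indices point at the analytic wave-offset positions, not post-noise
    argmaxes; exact-recovery assertions therefore use zero-noise cohorts.
    """

    subject_id: str
    r_indices: np.ndarray
    p_indices: np.ndarray
    q_indices: np.ndarray
    s_indices: np.ndarray
    t_indices: np.ndarray

    def wave_indices(self, wave: str) -> np.ndarray:
        return getattr(self, f"{wave.lower()}_indices")

    @property
    def n_beats(self) -> int:
        return self.r_indices.size


# Per-subject parameter ranges (uniform draws).  Amplitudes/widths/offsets are
# textbook lead-II orders of magnitude; the spread is what makes subjects
# mutually distinguishable.
DEFAULT_RANGES = {
    "amp": {"P": (0.10, 0.25), "Q": (-0.20, -0.05), "R": (0.80, 1.60),
            "S": (-0.35, -0.10), "T": (0.20, 0.45)},
    "width": {"P": (0.020, 0.030), "Q": (0.008, 0.012), "R": (0.010, 0.016),
              "S": (0.008, 0.014), "T": (0.040, 0.060)},
    "offset": {"P": (-0.21, -0.16), "Q": (-0.042, -0.030), "R": (0.0, 0.0),
               "S": (0.030, 0.042), "T": (0.22, 0.30)},
    "mean_heart_rate": (55.0, 90.0),
    "heart_rate_jitter_sd": 1.5,   # bpm
    "amplitude_jitter_sd": 0.02,   # fraction
}


def sample_morphology(subject_id: str, rng: np.random.Generator,
                      ranges: dict = DEFAULT_RANGES,
                      heart_rate_jitter_sd: float | None = None,
                      amplitude_jitter_sd: float | None = None) -> SubjectMorphology:
    """Draw one subject's morphology from the per-subject parameter ranges."""
    amps = {w: rng.uniform(*ranges["amp"][w]) for w in WAVES}
    widths = {w: rng.uniform(*ranges["width"][w]) for w in WAVES}
    offsets = {w: rng.uniform(*ranges["offset"][w]) for w in WAVES}
    hr = rng.uniform(*ranges["mean_heart_rate"])
    return SubjectMorphology(
        subject_id=subject_id,
        wave_amplitudes=amps, wave_widths=widths, wave_offsets=offsets,
        mean_heart_rate=hr,
        heart_rate_jitter_sd=(ranges["heart_rate_jitter_sd"]
                              if heart_rate_jitter_sd is None else heart_rate_jitter_sd),
        amplitude_jitter_sd=(ranges["amplitude_jitter_sd"]
                             if amplitude_jitter_sd is None else amplitude_jitter_sd),
    )


def render_beat(morphology: SubjectMorphology, fs: float) -> np.ndarray:
    """Render one jitter-free beat as a sample sequence.

    The beat spans [min offset − 4 max width, max offset + 4 max width] so all
    bumps decay essentially to zero inside the returned array.
    """
    if fs <= 0:
        raise InvalidArgumentError("fs must be > 0")
    wmax = max(morphology.wave_widths.values())
    t0 = min(morphology.wave_offsets.values()) - 4 * wmax
    t1 = max(morphology.wave_offsets.values()) + 4 * wmax
    t = np.arange(int(round(t0 * fs)), int(round(t1 * fs)) + 1) / fs
    out = np.zeros_like(t)
    for w in WAVES:
        a = morphology.wave_amplitudes[w]
        if a == 0.0:
            continue
        mu, sig = morphology.wave_offsets[w], morphology.wave_widths[w]
        out += a * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return out


def _beat_times(morphology: SubjectMorphology, duration: float,
                rng: np.random.Generator) -> np.ndarray:
    """Successive R-apex times with truncated per-beat heart-rate jitter."""
    times = []
    t = 0.35  # leave room for the first beat's P wave
    while t < duration:
        times.append(t)
        hr = morphology.mean_heart_rate
        if morphology.heart_rate_jitter_sd > 0:
            hr = hr + rng.normal(0.0, morphology.heart_rate_jitter_sd)
        hr = float(np.clip(hr, HR_MIN, HR_MAX))
        t += 60.0 / hr
    return np.asarray(times)


def synthesize_recording(morphology: SubjectMorphology, duration: float, fs: float,
                         seed: int, noise: NoiseSpec = ZERO_NOISE
                         ) -> tuple[EcgRecording, GroundTruth]:
    """Render one subject's recording plus analytic ground truth."""
    if duration <= 0 or fs < 100:
        raise InvalidArgumentError("need duration > 0 and fs >= 100 Hz")
    if duration < 60.0 / HR_MIN:
        raise InvalidArgumentError("duration shorter than one beat at HR=40")
    rng = np.random.default_rng(derive_seed(seed, "subject", morphology.subject_id))
    n = int(round(duration * fs))
    x = np.zeros(n)
    t_axis = np.arange(n) / fs

    r_times = _beat_times(morphology, duration, rng)
    truth_rows = {w: [] for w in WAVES}
    kept = []
    for rt in r_times:
        scale = 1.0
        if morphology.amplitude_jitter_sd > 0:
            scale = 1.0 + rng.normal(0.0, morphology.amplitude_jitter_sd)
        idx = {w: int(round((rt + morphology.wave_offsets[w]) * fs)) for w in WAVES}
        for w in WAVES:
            a = morphology.wave_amplitudes[w] * scale
            mu = rt + morphology.wave_offsets[w]
            sig = morphology.wave_widths[w]
            lo = max(0, int((mu - 5 * sig) * fs))
            hi = min(n, int((mu + 5 * sig) * fs) + 1)
            if lo < hi and a != 0.0:
                x[lo:hi] += a * np.exp(-0.5 * ((t_axis[lo:hi] - mu) / sig) ** 2)
        if all(0 <= idx[w] < n for w in WAVES):  # ground truth: fully contained beats
            kept.append(idx)
    for idx in kept:
        for w in WAVES:
            truth_rows[w].append(idx[w])

    if noise.baseline_wander_amp > 0:
        x += noise.baseline_wander_amp * np.sin(
            2 * np.pi * noise.baseline_wander_freq * t_axis + rng.uniform(0, 2 * np.pi))
    if noise.powerline_amp > 0:
        x += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t_axis + rng.uniform(0, 2 * np.pi))
    if noise.broadband_sd > 0:
        x += rng.normal(0.0, noise.broadband_sd, size=n)

    rec = EcgRecording(morphology.subject_id, x, fs,
                       provenance=f"synth:seed={seed}")
    truth = GroundTruth(
        subject_id=morphology.subject_id,
        **{f"{w.lower()}_indices": np.asarray(truth_rows[w], dtype=int) for w in WAVES})
    return rec, truth


def sample_cohort(n_subjects: int, duration: float, fs: float, seed: int,
                  noise: NoiseSpec = ZERO_NOISE,
                  ranges: dict = DEFAULT_RANGES
                  ) -> list[tuple[EcgRecording, GroundTruth]]:
    """Generate a seeded cohort of mutually distinguishable subjects.

    Same (seed, parameters) always yields bit-identical recordings.
    """
    if n_subjects <= 0:
        raise InvalidArgumentError("n_subjects must be positive")
    cohort = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        rng = np.random.default_rng(derive_seed(seed, "morph", sid))
        morph = sample_morphology(sid, rng, ranges)
        cohort.append(synthesize_recording(morph, duration, fs, seed, noise))
    return cohort


def write_cohort(cohort, outdir, fs: float, duration: float, seed: int) -> Path:
    """Write one CSV per subject, a manifest JSON and a ground-truth CSV.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    gt_lines = ["subject_id,beat_index,wave,sample_index"]
    for rec, truth in cohort:
        fname = f"{rec.subject_id}.csv"
        write_recording_csv(rec, outdir / fname)
        manifest.append({"subject_id": rec.subject_id, "file": fname,
                         "fs": fs, "duration": duration, "seed": seed})
        for b in range(truth.n_beats):
            for w in WAVES:
                gt_lines.append(f"{rec.subject_id},{b},{w},{truth.wave_indices(w)[b]}")
    (outdir / "ground_truth.csv").write_text("\n".join(gt_lines) + "\n")
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath
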