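"""Readers and writers for the signal, feature-table and report formats.

Conventions used by every module in the package:

* sample indexing is 0-based and windows are half-open ``[start, start+len)``;
* CSV files are comma-separated, ``.`` decimal, UTF-8, LF line endings;
* amplitudes are in millivolts, sampling rates in Hz.

WFDB support is a minimal reader for ``.hea`` headers plus format-16 (16-bit
little-endian two's-complement) ``.dat`` signal files — the subset needed to
load a single ECG channel from a PhysioNet-style record.  Everything else in
the pipeline runs on plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError


@dataclasses.dataclass
class EcgRecording:
    """One subject's single-channel ECG trace.

    Parameters
    ----------
    subject_id : str
        Opaque subject label.
    samples : ndarray
        Ordered voltage samples in mV.
    fs : float
        Sampling rate in Hz, > 0.
    provenance : str
        Free-text processing history (source file, applied filters).
    """

    subject_id: str
    samples: np.ndarray
    fs: float
    provenance: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be > 0, got {self.fs}")
        if self.samples.size == 0:
            raise InvalidArgumentError("recording has no samples")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise FormatError(f"non-finite sample at index {bad}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def first_seconds(self, seconds: float) -> "EcgRecording":
        """Return the leading ``seconds`` of the recording (all of it if shorter)."""
        n = min(self.samples.size, int(round(seconds * self.fs)))
        return EcgRecording(self.subject_id, self.samples[:n].copy(), self.fs,
                            self.provenance + f"|first_{seconds}s")


def read_recording_csv(path, fs: float, subject_id: str) -> EcgRecording:
    """Load a two-column (sample_index, amplitude_mV) CSV with a header row."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns, found {df.shape[1]}")
    amp = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(amp))
    if bad.size:
        # +2: 1 for the header line, 1 for 1-based file rows
        raise FormatError(f"{path}: non-numeric or non-finite value at file row {bad[0] + 2}")
    return EcgRecording(subject_id, amp, fs, provenance=f"csv:{path.name}")


def write_recording_csv(recording: EcgRecording, path) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_index,amplitude_mV\n")
        for i, v in enumerate(recording.samples):
            fh.write(f"{i},{float(v)!r}\n")


# ---------------------------------------------------------------------------
# WFDB (.hea + .dat, format 16)
# ---------------------------------------------------------------------------

def read_recording_wfdb(header_path, channel_name: str) -> EcgRecording:
    """Read one channel of a WFDB record into physical units (mV assumed).

    Supports single-.dat records in format 16.  Physical value is
    ``(adc - baseline) / gain`` with gain defaulting to 200 ADU/mV and
    baseline defaulting to the ADC zero, per the WFDB header spec.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"no such file: {header_path}")
    lines = [ln.strip() for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec = lines[0].split()
    if len(rec) < 4:
        raise FormatError(f"{header_path}: malformed record line {rec!r}")
    n_sig, fs, n_samp = int(rec[1]), float(rec[2]), int(rec[3])
    sig_lines = lines[1:1 + n_sig]

    channels = []
    for ln in sig_lines:
        f = ln.split()
        fname, fmt = f[0], f[1]
        gain_field = f[2] if len(f) > 2 else "200"
        adc_zero = int(f[4]) if len(f) > 4 else 0
        desc = " ".join(f[8:]) if len(f) > 8 else ""
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain_s, base_s = gain_part.rstrip(")").split("(")
            gain, baseline = float(gain_s), int(base_s)
        else:
            gain, baseline = float(gain_part), adc_zero
        if gain == 0:
            gain = 200.0
        channels.append(dict(fname=fname, fmt=fmt, gain=gain,
                             baseline=baseline, desc=desc))

    names = [c["desc"] for c in channels]
    try:
        idx = names.index(channel_name)
    except ValueError:
        raise FormatError(
            f"channel {channel_name!r} not in record; available: {names}") from None

    ch = channels[idx]
    if ch["fmt"].split("x")[0] != "16":
        raise FormatError(f"unsupported WFDB signal format {ch['fmt']!r} (only 16)")
    dat_path = header_path.parent / ch["fname"]
    if not dat_path.exists():
        raise FormatError(f"signal file missing: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    per_frame = len(channels)
    raw = raw[: (raw.size // per_frame) * per_frame].reshape(-1, per_frame)
    adc = raw[:n_samp, idx].astype(float)
    physical = (adc - ch["baseline"]) / ch["gain"]
    return EcgRecording(subject_id=rec[0], samples=physical, fs=fs,
                        provenance=f"wfdb:{header_path.name}:{channel_name}")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

KEY_COLUMNS = ["subject_id", "segment_id"]


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table (key columns first) as CSV."""
    cols = [c for c in KEY_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in KEY_COLUMNS]
    table[cols].to_csv(path, index=False, lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    vals = df[value_cols].to_numpy(dtype=float)
    if vals.size and not np.all(np.isfinite(vals)):
        r, c = np.argwhere(~np.isfinite(vals))[0]
        raise FormatError(f"{path}: non-finite value at row {r} column {value_cols[c]}")
    return df


def write_report_json(report: dict, path) -> None:
    """Serialize a report dict deterministically (sorted keys, repr floats)."""
    with open(path, "w", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
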