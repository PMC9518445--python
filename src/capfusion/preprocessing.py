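"""Resampling to 100 Hz, per-recording standardization, and epoch windowing.

The classifier consumes one-second epochs of 100 samples per channel, so any
recording sampled above 100 Hz is first low-pass filtered with a zero-phase
Chebyshev type I filter (order 8, 0.05 dB passband ripple, cutoff 0.8 of the
target Nyquist) and decimated.  Non-integer ratios (e.g. 512 -> 100 Hz) use
rational polyphase resampling with the equivalent anti-aliasing cutoff.
Signals are then standardized per channel (zero mean, unit variance) and cut
into sliding windows of T consecutive epochs; the label of a window is the
label of its last epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .synthetic_data import Recording

__all__ = [
    "TARGET_FS",
    "INPUT_POINTS",
    "EpochWindow",
    "resample_to_100hz",
    "standardize",
    "preprocess_recording",
    "make_windows",
    "windows_to_arrays",
    "read_edf_recording",
    "parse_cap_annotations",
]

TARGET_FS = 100.0
INPUT_POINTS = 100  # samples per one-second epoch at 100 Hz

# Anti-aliasing filter of the decimation stage: Chebyshev type I, order 8,
# 0.05 dB passband ripple, cutoff 0.8x the post-decimation Nyquist.
_CHEB_ORDER = 8
_CHEB_RIPPLE_DB = 0.05
_CHEB_CUTOFF = 0.8


@dataclass(frozen=True)
class EpochWindow:
    """T consecutive one-second epochs for every channel, labeled by the last."""

    data: np.ndarray  # (n_channels, T, INPUT_POINTS)
    label: int
    subject_id: str
    epoch_index: int


def resample_to_100hz(signal: np.ndarray, fs: float) -> np.ndarray:
    """Filtered decimation of ``signal`` from ``fs`` down to 100 Hz.

    Integer reduction factors use zero-phase Chebyshev-I filtering followed by
    keeping every s-th sample; non-integer ratios fall back to polyphase
    rational resampling.  Output length is floor(len * 100 / fs).
    """
    signal = np.asarray(signal, dtype=np.float64)
    if fs < TARGET_FS:
        raise ValueError(f"fs={fs} Hz < {TARGET_FS} Hz: upsampling is not supported")
    out_len = int(np.floor(len(signal) * TARGET_FS / fs))
    if fs == TARGET_FS:
        return signal[:out_len].copy()
    ratio = Fraction(fs / TARGET_FS).limit_denominator(1000)
    if ratio.denominator == 1:
        s = ratio.numerator
        sos = sps.cheby1(
            _CHEB_ORDER, _CHEB_RIPPLE_DB, _CHEB_CUTOFF / s, output="sos"
        )
        filtered = sps.sosfiltfilt(sos, signal)
        return filtered[::s][:out_len].copy()
    up, down = ratio.denominator, ratio.numerator
    return sps.resample_poly(signal, up, down)[:out_len].copy()


def standardize(signal: np.ndarray) -> np.ndarray:
    """Subtract the mean and divide by the standard deviation."""
    signal = np.asarray(signal, dtype=np.float64)
    sd = signal.std()
    if sd == 0 or np.ptp(signal) == 0:
        raise ValueError("cannot standardize a constant (zero-variance) signal")
    return (signal - signal.mean()) / sd


def preprocess_recording(rec: Recording) -> Recording:
    """Resample every channel to 100 Hz and standardize per channel."""
    channels = [standardize(resample_to_100hz(ch, rec.fs)) for ch in rec.signals]
    signals = np.vstack(channels)
    n_seconds = int(signals.shape[1] // TARGET_FS)
    return Recording(
        subject_id=rec.subject_id,
        signals=signals,
        fs=TARGET_FS,
        labels=rec.labels[:n_seconds],
        channel_names=rec.channel_names,
        group=rec.group,
        events=rec.events,
    )


def make_windows(rec: Recording, time_steps: int) -> list[EpochWindow]:
    """Sliding windows of ``time_steps`` epochs; the first T-1 epochs yield none.

    Window i (0-based epoch index, i in [T-1, N-1]) contains the raw samples
    [100*(i-T+1), 100*(i+1)) of every channel and carries label ``labels[i]``.
    """
    if time_steps < 1:
        raise ValueError("time_steps must be >= 1")
    if rec.fs != TARGET_FS:
        raise ValueError("recording must be resampled to 100 Hz first")
    n_epochs = len(rec.labels)
    T, I = time_steps, INPUT_POINTS
    windows = []
    for i in range(T - 1, n_epochs):
        start = (i - T + 1) * I
        data = rec.signals[:, start : (i + 1) * I].reshape(rec.n_channels, T, I)
        windows.append(
            EpochWindow(
                data=data,
                label=int(rec.labels[i]),
                subject_id=rec.subject_id,
                epoch_index=i,
            )
        )
    return windows


def windows_to_arrays(windows: list[EpochWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (X, y): X is (N, n_channels, T, I), y is (N,)."""
    if not windows:
        raise ValueError("no windows to stack")
    X = np.stack([w.data for w in windows])
    y = np.array([w.label for w in windows], dtype=np.int8)
    return X, y


# ---------------------------------------------------------------------------
# real-data path: EDF signals + CAP Sleep Database text annotations


def read_edf_recording(
    path: str | Path,
    annotation_path: str | Path | None = None,
    channels: tuple[str, ...] = ("Fp2-F4", "F4-C4", "C4-A1"),
    subject_id: str | None = None,
) -> Recording:
    """Load selected channels of an EDF file, optionally with A-phase labels.

    Requires ``mne`` (optional dependency).  Channel names are matched
    case-insensitively after stripping separators, so "Fp2-F4" finds "FP2-F4".
    """
    import mne  # local import: optional dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")

    def norm(name: str) -> str:
        return name.replace("-", "").replace("_", "").replace(" ", "").lower()

    available = {norm(ch): ch for ch in raw.ch_names}
    picks = []
    for ch in channels:
        key = norm(ch)
        if key not in available:
            raise KeyError(f"channel {ch!r} not found in {raw.ch_names}")
        picks.append(available[key])
    data = raw.get_data(picks=picks)
    fs = float(raw.info["sfreq"])
    n_seconds = int(data.shape[1] // fs)
    if annotation_path is not None:
        meas_date = raw.info.get("meas_date")
        start = None
        if meas_date is not None:
            start = meas_date.hour * 3600 + meas_date.minute * 60 + meas_date.second
        labels = parse_cap_annotations(
            Path(annotation_path).read_text(), n_seconds, recording_start_s=start
        )
    else:
        labels = np.zeros(n_seconds, dtype=np.int8)
    return Recording(
        subject_id=subject_id or Path(path).stem,
        signals=data,
        fs=fs,
        labels=labels,
        channel_names=channels,
    )


def parse_cap_annotations(
    text: str, n_seconds: int, recording_start_s: int | None = None
) -> np.ndarray:
    """Per-second binary labels from a CAP Sleep Database annotation file.

    The scorer files are delimited text with an header row naming at least
    ``Time [hh:mm:ss]``, ``Event`` and ``Duration[s]`` columns; rows whose
    event is an A phase (``MCAP-A1``/``A2``/``A3``) mark every second from
    onset for the stated duration.  ``recording_start_s`` is the clock time
    (seconds after midnight) of sample 0; if omitted, the first annotation
    row defines time zero.
    """
    labels = np.zeros(n_seconds, dtype=np.int8)
    header: list[str] | None = None
    rows: list[tuple[int, int]] = []  # (onset clock seconds, duration)
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        sep = "\t" if "\t" in line else None
        parts = [p.strip() for p in (line.split(sep) if sep else line.split())]
        if header is None:
            joined = line.lower()
            if "event" in joined and "duration" in joined:
                header = [p.lower() for p in line.split("\t")]
            continue
        if len(parts) < 3:
            continue
        time_idx = next(
            (k for k, h in enumerate(header) if h.startswith("time")), None
        )
        event_idx = next((k for k, h in enumerate(header) if h == "event"), None)
        dur_idx = next(
            (k for k, h in enumerate(header) if h.startswith("duration")), None
        )
        if time_idx is None or event_idx is None or dur_idx is None:
            continue
        try:
            hh, mm, ss = (int(v) for v in parts[time_idx].split(":"))
            duration = int(round(float(parts[dur_idx])))
        except (ValueError, IndexError):
            continue
        event = parts[event_idx].upper()
        if not any(tag in event for tag in ("A1", "A2", "A3")):
            continue
        rows.append((hh * 3600 + mm * 60 + ss, duration))
    if not rows:
        return labels
    if recording_start_s is None:
        recording_start_s = rows[0][0]
    for clock, duration in rows:
        onset = clock - recording_start_s
        if onset < 0:  # annotation crosses midnight relative to start
            onset += 24 * 3600
        lo = max(0, onset)
        hi = min(n_seconds, onset + duration)
        if lo < hi:
            labels[lo:hi] = 1
    return labels
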