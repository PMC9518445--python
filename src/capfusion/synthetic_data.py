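"""Seeded generator of CAP-like multichannel EEG recordings.

Real CAP (cyclic alternating pattern) scoring marks transient brain-activation
events — A phases, 2–60 s long — on a per-second basis in NREM sleep EEG.
This module emulates the statistical skeleton of that problem so the whole
pipeline (preprocessing, fusion classifier, architecture search, evaluation,
robustness sweeps) is testable without polysomnography data:

* background activity is correlated 1/f^beta colored noise per channel, built
  from a shared latent source (cross-channel correlation) plus independent
  per-channel noise;
* activation events are amplitude bursts (gain > 1) of duration drawn from
  [2, 60] s, placed without overlap and with >= 2 s gaps, until a target
  per-second label prevalence is reached;
* a second is labeled 1 when an event overlaps at least half of it.

Cohorts are split into an "FND-like" half (subjects free of neurological
disorders: lower A-phase prevalence) and an "SDP-like" half (sleep-disorder
patients: higher prevalence), mirroring the population structure the
evaluation protocols stratify on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Recording",
    "GeneratorParams",
    "EventPlacementError",
    "generate_recording",
    "generate_cohort",
    "save_recording",
    "load_recording",
    "save_generator_params",
    "load_generator_params",
]

CHANNEL_NAMES = ("Fp2-F4", "F4-C4", "C4-A1")

# Cohort prevalence factors: ratio of each group's mean A-phase time to the
# population mean (FND 3235.63 s, SDP 4764.75 s, pooled 4000.19 s).
FND_PREVALENCE_FACTOR = 3235.63 / 4000.19
SDP_PREVALENCE_FACTOR = 4764.75 / 4000.19


class EventPlacementError(RuntimeError):
    """Requested prevalence cannot be reached with non-overlapping events."""


@dataclass
class Recording:
    """A multichannel signal with per-second binary A-phase labels."""

    subject_id: str
    signals: np.ndarray  # (n_channels, n_samples)
    fs: float
    labels: np.ndarray  # (n_seconds,), values in {0, 1}
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    group: str | None = None  # "FND" | "SDP" | None
    events: tuple[tuple[float, float], ...] = ()  # (start_s, end_s) per event

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n_seconds = int(self.signals.shape[1] // self.fs)
        if len(self.labels) != n_seconds:
            raise ValueError(
                f"labels length {len(self.labels)} != floor(samples/fs) = {n_seconds}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signals.shape[1] / self.fs


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 6
    duration_s: float = 600.0
    fs: float = 100.0
    prevalence: float = 0.15
    event_duration_range_s: tuple[float, float] = (2.0, 60.0)
    event_visibility: tuple[bool, bool, bool] = (True, True, True)
    background_spectrum_exponent: float = 1.0
    inter_channel_correlation: float = 0.5
    event_amplitude_gain: float = 3.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.event_duration_range_s
        if not (2.0 <= lo <= hi <= 60.0):
            raise ValueError("event durations must lie within [2, 60] s")
        if not (0.0 <= self.prevalence < 0.5):
            raise ValueError("prevalence must be in [0, 0.5)")
        if not (100.0 <= self.fs <= 512.0):
            raise ValueError("fs must be in [100, 512] Hz")
        if not (0.0 <= self.inter_channel_correlation <= 1.0):
            raise ValueError("inter_channel_correlation must be in [0, 1]")


def _colored_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Unit-variance noise with a 1/f^beta power spectrum (FFT shaping)."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]  # avoid division by zero at DC
    spectrum *= freqs ** (-beta / 2.0)
    x = np.fft.irfft(spectrum, n)
    return (x - x.mean()) / x.std()


def _label_seconds(start: float, end: float, n_seconds: int) -> np.ndarray:
    """Indices of whole seconds that the event [start, end) overlaps >= 50%."""
    first = max(0, int(np.floor(start)))
    last = min(n_seconds - 1, int(np.ceil(end)) - 1)
    secs = np.arange(first, last + 1)
    overlap = np.minimum(end, secs + 1.0) - np.maximum(start, secs.astype(float))
    return secs[overlap >= 0.5]


def _place_events(
    rng: np.random.Generator, params: GeneratorParams, n_seconds: int
) -> list[tuple[float, float]]:
    """Non-overlapping events with >= 2 s gaps until target prevalence."""
    target = params.prevalence * n_seconds
    if target <= 0:
        return []
    events: list[tuple[float, float]] = []
    covered = 0
    lo, hi = params.event_duration_range_s
    attempts = 0
    max_attempts = 20000
    while covered < target:
        attempts += 1
        if attempts > max_attempts:
            raise EventPlacementError(
                f"could not reach prevalence {params.prevalence} in "
                f"{params.duration_s:.0f} s with non-overlapping [{lo}, {hi}] s "
                f"events and 2 s gaps after {max_attempts} attempts"
            )
        # cap the draw near the remaining need so total coverage lands close
        # to the target instead of overshooting by up to a whole max event
        remaining = target - covered
        dur = rng.uniform(lo, min(hi, max(lo + 1.0, remaining + 1.0)))
        if dur > params.duration_s:
            continue
        start = rng.uniform(0.0, params.duration_s - dur)
        end = start + dur
        # enforce a 2 s guard band around existing events
        if any(start < e + 2.0 and end > s - 2.0 for s, e in events):
            continue
        events.append((start, end))
        covered += len(_label_seconds(start, end, n_seconds))
    return sorted(events)


def generate_recording(params: GeneratorParams, subject_index: int) -> Recording:
    """One synthetic recording; deterministic for fixed (seed, subject_index)."""
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, subject_index)))
    n_samples = int(round(params.duration_s * params.fs))
    n_seconds = int(np.floor(n_samples / params.fs))
    beta = params.background_spectrum_exponent
    rho = params.inter_channel_correlation

    shared = _colored_noise(rng, n_samples, beta)
    signals = np.empty((len(CHANNEL_NAMES), n_samples))
    for c in range(len(CHANNEL_NAMES)):
        own = _colored_noise(rng, n_samples, beta)
        signals[c] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own

    events = _place_events(rng, params, n_seconds)
    labels = np.zeros(n_seconds, dtype=np.int8)
    t = np.arange(n_samples) / params.fs
    for start, end in events:
        labels[_label_seconds(start, end, n_seconds)] = 1
        in_event = (t >= start) & (t < end)
        for c, visible in enumerate(params.event_visibility):
            if visible:
                signals[c, in_event] *= params.event_amplitude_gain

    return Recording(
        subject_id=f"S{subject_index:02d}",
        signals=signals,
        fs=params.fs,
        labels=labels,
        channel_names=CHANNEL_NAMES,
        events=tuple(events),
    )


def generate_cohort(params: GeneratorParams) -> list[Recording]:
    """An even-sized cohort, half FND-like and half SDP-like.

    SDP-like subjects use a higher event prevalence than FND-like ones
    (sleep-disorder patients spend more time in A phase), so group-stratified
    splits are meaningful downstream.
    """
    if params.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if params.n_subjects % 2:
        raise ValueError("n_subjects must be even (half FND-like, half SDP-like)")
    half = params.n_subjects // 2
    recordings = []
    for i in range(params.n_subjects):
        group = "FND" if i < half else "SDP"
        factor = FND_PREVALENCE_FACTOR if group == "FND" else SDP_PREVALENCE_FACTOR
        rec = generate_recording(
            replace(params, prevalence=min(params.prevalence * factor, 0.499)), i
        )
        rec.group = group
        recordings.append(rec)
    return recordings


# ---------------------------------------------------------------------------
# flat-file container: NPZ signals + one-label-per-line text + YAML metadata


def save_recording(rec: Recording, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / f"{rec.subject_id}_signals.npz", signals=rec.signals)
    np.savetxt(directory / f"{rec.subject_id}_labels.txt", rec.labels, fmt="%d")
    meta = {
        "subject_id": rec.subject_id,
        "fs": float(rec.fs),
        "channel_names": list(rec.channel_names),
        "group": rec.group,
        "events": [[float(s), float(e)] for s, e in rec.events],
    }
    with open(directory / f"{rec.subject_id}_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_recording(directory: str | Path, subject_id: str) -> Recording:
    directory = Path(directory)
    with open(directory / f"{subject_id}_meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    signals = np.load(directory / f"{subject_id}_signals.npz")["signals"]
    labels = np.loadtxt(directory / f"{subject_id}_labels.txt", dtype=int)
    return Recording(
        subject_id=meta["subject_id"],
        signals=signals,
        fs=meta["fs"],
        labels=np.atleast_1d(labels),
        channel_names=tuple(meta["channel_names"]),
        group=meta.get("group"),
        events=tuple((s, e) for s, e in meta.get("events", [])),
    )


def save_generator_params(params: GeneratorParams, path: str | Path) -> None:
    data = {
        "n_subjects": params.n_subjects,
        "duration_s": params.duration_s,
        "fs": params.fs,
        "prevalence": params.prevalence,
        "event_duration_range_s": list(params.event_duration_range_s),
        "event_visibility": list(params.event_visibility),
        "background_spectrum_exponent": params.background_spectrum_exponent,
        "inter_channel_correlation": params.inter_channel_correlation,
        "event_amplitude_gain": params.event_amplitude_gain,
        "seed": params.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def load_generator_params(path: str | Path) -> GeneratorParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["event_duration_range_s"] = tuple(data["event_duration_range_s"])
    data["event_visibility"] = tuple(bool(v) for v in data["event_visibility"])
    return GeneratorParams(**data)
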