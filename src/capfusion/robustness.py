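"""Test-time robustness protocols: channel loss and additive white Gaussian
noise.

Models are always trained on clean, complete recordings; only the test-time
inputs are perturbed.  Channel loss substitutes each lost channel's signal
with one of the still-working channels (with all ten possible loss/replacement
scenarios over three channels enumerable); noise contamination adds white
Gaussian noise at a requested SNR to the standardized signals the model
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from itertools import combinations

import numpy as np
import pandas as pd

from .encoding import ModelConfig
from .evaluation import loo_evaluate, roc_auc
from .fusion_model import TrainingHyperparams, predict_scores
from .preprocessing import make_windows, preprocess_recording, windows_to_arrays
from .synthetic_data import Recording

__all__ = [
    "PerturbationScenario",
    "apply_channel_loss",
    "enumerate_scenarios",
    "add_awgn",
    "robustness_sweep",
    "DEFAULT_SNR_GRID_DB",
]

DEFAULT_SNR_GRID_DB = (-20.0, -10.0, -5.0, 0.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class PerturbationScenario:
    """One test-time perturbation: channel substitution or noise injection."""

    kind: str  # "channel_loss" | "awgn"
    lost_channels: tuple[int, ...] = ()
    replacement_assignment: dict = field(default_factory=dict)  # lost -> working
    snr_db: float | None = None

    def __post_init__(self):
        if self.kind not in ("channel_loss", "awgn"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "awgn":
            if self.snr_db is None or not (-20.0 <= self.snr_db <= 20.0):
                raise ValueError("snr_db must lie in [-20, 20] dB")

    @property
    def label(self) -> str:
        if self.kind == "awgn":
            return f"awgn_{self.snr_db:+.0f}dB"
        if not self.lost_channels:
            return "all_channels"
        repl = ",".join(f"{k}->{v}" for k, v in sorted(self.replacement_assignment.items()))
        return f"lost_{repl}"

    @property
    def n_working(self) -> int:
        return 3 - len(self.lost_channels)


def apply_channel_loss(rec: Recording, scenario: PerturbationScenario) -> Recording:
    """Substitute each lost channel's signal with its assigned working channel."""
    lost = set(scenario.lost_channels)
    working = [c for c in range(rec.n_channels) if c not in lost]
    if not working:
        raise ValueError("at least one channel must remain working")
    signals = rec.signals.copy()
    for lost_ch in lost:
        source = scenario.replacement_assignment[lost_ch]
        if source in lost:
            raise ValueError(f"replacement channel {source} is itself lost")
        signals[lost_ch] = rec.signals[source]
    return Recording(
        subject_id=rec.subject_id,
        signals=signals,
        fs=rec.fs,
        labels=rec.labels,
        channel_names=rec.channel_names,
        group=rec.group,
        events=rec.events,
    )


def enumerate_scenarios(n_channels: int = 3) -> list[PerturbationScenario]:
    """All channel-loss scenarios: 1 clean + 6 one-lost + 3 two-lost = 10."""
    channels = range(n_channels)
    scenarios = [PerturbationScenario(kind="channel_loss")]
    for lost in channels:  # one lost channel, replaced by either survivor
        for source in channels:
            if source != lost:
                scenarios.append(
                    PerturbationScenario(
                        kind="channel_loss",
                        lost_channels=(lost,),
                        replacement_assignment={lost: source},
                    )
                )
    for pair in combinations(channels, 2):  # two lost, both take the survivor
        survivor = next(c for c in channels if c not in pair)
        scenarios.append(
            PerturbationScenario(
                kind="channel_loss",
                lost_channels=pair,
                replacement_assignment={c: survivor for c in pair},
            )
        )
    return scenarios


def add_awgn(
    signal: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    """Add white Gaussian noise with power = signal_power / 10^(snr/10)."""
    signal = np.asarray(signal, dtype=np.float64)
    power = float(np.mean(signal**2))
    if power == 0:
        raise ValueError("cannot set an SNR against a zero-power signal")
    noise_sd = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    return signal + noise_sd * rng.standard_normal(signal.shape)


def _perturb(rec: Recording, scenario: PerturbationScenario, rng) -> Recording:
    if scenario.kind == "channel_loss":
        return apply_channel_loss(rec, scenario)
    signals = np.vstack([add_awgn(ch, scenario.snr_db, rng) for ch in rec.signals])
    return Recording(
        subject_id=rec.subject_id,
        signals=signals,
        fs=rec.fs,
        labels=rec.labels,
        channel_names=rec.channel_names,
        group=rec.group,
        events=rec.events,
    )


def robustness_sweep(
    config: ModelConfig,
    cohort: list[Recording],
    hp: TrainingHyperparams,
    scenarios: list[PerturbationScenario],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """LOO-style AUC per scenario: train clean per cycle, test perturbed.

    Returns one row per (scenario, held-out subject) with the test AUC, from
    which quartile summaries (violin/box data) can be taken directly.
    """
    results, models = loo_evaluate(config, cohort, hp, rng, return_models=True)
    preprocessed = {rec.subject_id: preprocess_recording(rec) for rec in cohort}
    rows = []
    for scenario in scenarios:
        for rec, model in zip(cohort, models):
            clean = preprocessed[rec.subject_id]
            perturbed = _perturb(clean, scenario, rng)
            X, y = windows_to_arrays(make_windows(perturbed, config.time_steps))
            auc = roc_auc(predict_scores(model, (X, None)), y)
            rows.append(
                {
                    "scenario": scenario.label,
                    "kind": scenario.kind,
                    "n_working": scenario.n_working if scenario.kind == "channel_loss" else 3,
                    "snr_db": scenario.snr_db,
                    "subject_id": rec.subject_id,
                    "auc": auc,
                }
            )
    return pd.DataFrame(rows)
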