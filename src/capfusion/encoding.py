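"""15-bit architecture genome: decoding table, validity rules, and repair.

Both optimizers search the same space of bit strings.  Each genome decodes to
a full fusion-classifier configuration: which EEG channels to fuse, the
recurrent depth/direction/width, dropout, and the optional dense layers.  The
all-zero channel mask is invalid (a classifier with no input), which leaves
7/8 of the 2^15 patterns — 28,672 distinct configurations.

The decoding table ships as a machine-readable YAML file so it can be audited
or swapped for a different option grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "N_BITS",
    "CHANNEL_NAMES",
    "ACTIVATIONS",
    "ModelConfig",
    "DecodingTable",
    "InvalidGenomeError",
    "default_table",
    "load_decoding_table",
    "decode",
    "encode",
    "repair",
    "random_genome",
    "count_valid_configurations",
]

N_BITS = 15
CHANNEL_NAMES = ("Fp2-F4", "F4-C4", "C4-A1")
ACTIVATIONS = ("tanh", "sigmoid", "relu", "selu")


class InvalidGenomeError(ValueError):
    """Raised when a bit pattern does not decode to a usable architecture."""


@dataclass(frozen=True)
class ModelConfig:
    """Decoded architecture parameters of the fusion classifier."""

    channel_mask: tuple[bool, bool, bool]
    time_steps: int
    n_recurrent_layers: int
    recurrent_type: str  # "unidirectional" | "bidirectional"
    hidden_units: int
    dropout: float
    dense_size: int  # 0 = no dense layers
    dense_activation: str

    @property
    def n_channels(self) -> int:
        return sum(self.channel_mask)

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(i for i, on in enumerate(self.channel_mask) if on)

    @property
    def bidirectional(self) -> bool:
        return self.recurrent_type == "bidirectional"


@dataclass(frozen=True)
class DecodingTable:
    """Maps bit fields of the genome to architecture option values."""

    time_steps: tuple[int, ...] = (5, 10, 15, 25)
    n_recurrent_layers: tuple[int, ...] = (1, 2)
    recurrent_type: tuple[str, ...] = ("unidirectional", "bidirectional")
    hidden_units: tuple[int, ...] = (50, 100, 150, 200)
    dropout: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
    dense_size: tuple[int, ...] = (0, 100, 200, 300)
    dense_activation: tuple[str, ...] = ACTIVATIONS
    channel_names: tuple[str, ...] = CHANNEL_NAMES


def load_decoding_table(path: str | Path) -> DecodingTable:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    opts = spec["options"]
    return DecodingTable(
        time_steps=tuple(opts["time_steps"]),
        n_recurrent_layers=tuple(opts["n_recurrent_layers"]),
        recurrent_type=tuple(opts["recurrent_type"]),
        hidden_units=tuple(opts["hidden_units"]),
        dropout=tuple(opts["dropout"]),
        dense_size=tuple(opts["dense_size"]),
        dense_activation=tuple(opts["dense_activation"]),
        channel_names=tuple(opts["channel_names"]),
    )


def default_table() -> DecodingTable:
    """The packaged decoding table (identical to the dataclass defaults)."""
    with resources.as_file(
        resources.files("capfusion") / "data" / "decoding_table.yaml"
    ) as path:
        return load_decoding_table(path)


def _check_bits(genome) -> np.ndarray:
    bits = np.asarray(genome, dtype=int)
    if bits.shape != (N_BITS,) or not np.isin(bits, (0, 1)).all():
        raise InvalidGenomeError(f"genome must be {N_BITS} bits of 0/1, got {genome!r}")
    return bits


def _field_value(bits: np.ndarray) -> int:
    """Binary value of a bit field, most-significant bit first."""
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    return value


def decode(genome, table: DecodingTable | None = None) -> ModelConfig:
    """Decode a 15-bit genome into a :class:`ModelConfig`.

    Raises :class:`InvalidGenomeError` on the all-zero channel mask.
    """
    table = table or DecodingTable()
    bits = _check_bits(genome)
    mask = tuple(bool(b) for b in bits[0:3])
    if not any(mask):
        raise InvalidGenomeError("channel mask 000: at least one channel is required")
    return ModelConfig(
        channel_mask=mask,
        time_steps=table.time_steps[_field_value(bits[3:5])],
        n_recurrent_layers=table.n_recurrent_layers[_field_value(bits[5:6])],
        recurrent_type=table.recurrent_type[_field_value(bits[6:7])],
        hidden_units=table.hidden_units[_field_value(bits[7:9])],
        dropout=table.dropout[_field_value(bits[9:11])],
        dense_size=table.dense_size[_field_value(bits[11:13])],
        dense_activation=table.dense_activation[_field_value(bits[13:15])],
    )


def _field_bits(options, value, width: int, name: str) -> list[int]:
    try:
        idx = list(options).index(value)
    except ValueError:
        raise ValueError(f"{name}={value!r} is not one of the options {options}") from None
    return [(idx >> (width - 1 - k)) & 1 for k in range(width)]


def encode(config: ModelConfig, table: DecodingTable | None = None) -> np.ndarray:
    """Inverse of :func:`decode`: genome bits for a configuration."""
    table = table or DecodingTable()
    if not any(config.channel_mask):
        raise ValueError("configuration selects no channels")
    bits = [int(b) for b in config.channel_mask]
    bits += _field_bits(table.time_steps, config.time_steps, 2, "time_steps")
    bits += _field_bits(table.n_recurrent_layers, config.n_recurrent_layers, 1, "n_recurrent_layers")
    bits += _field_bits(table.recurrent_type, config.recurrent_type, 1, "recurrent_type")
    bits += _field_bits(table.hidden_units, config.hidden_units, 2, "hidden_units")
    bits += _field_bits(table.dropout, config.dropout, 2, "dropout")
    bits += _field_bits(table.dense_size, config.dense_size, 2, "dense_size")
    bits += _field_bits(table.dense_activation, config.dense_activation, 2, "dense_activation")
    return np.array(bits, dtype=int)


def repair(genome, rng: np.random.Generator) -> np.ndarray:
    """Make a genome valid: an empty channel mask gets one random channel bit."""
    bits = _check_bits(genome).copy()
    if not bits[0:3].any():
        bits[rng.integers(0, 3)] = 1
    return bits


def random_genome(rng: np.random.Generator) -> np.ndarray:
    """Uniform random *valid* genome (mask 000 rejected by repair)."""
    return repair(rng.integers(0, 2, size=N_BITS), rng)


def count_valid_configurations(table: DecodingTable | None = None) -> int:
    """Enumerate all 2^15 bit patterns and count those that decode."""
    table = table or DecodingTable()
    count = 0
    for value in range(2**N_BITS):
        bits = [(value >> (N_BITS - 1 - k)) & 1 for k in range(N_BITS)]
        try:
            decode(bits, table)
        except InvalidGenomeError:
            continue
        count += 1
    return count
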