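"""Per-channel recurrent feature extraction, feature-level fusion, and the
softmax classification head.

Each selected EEG channel feeds its own LSTM branch (1-2 layers, optionally
bidirectional).  For time step t and cell c the gates are

    F = sigmoid(U_F x_t + W_F h_{t-1} + b_F)      (forget)
    I = sigmoid(U_I x_t + W_I h_{t-1} + b_I)      (input)
    O = sigmoid(U_O x_t + W_O h_{t-1} + b_O)      (output)
    s_t = F * s_{t-1} + I * tanh(U x_t + W h_{t-1} + b)
    h_t = tanh(s_t) * O

The last cell's output h (per direction) is the branch feature vector; an
optional dense layer of size S transforms it.  A concatenation node fuses the
branch features into f = [f_1 ... f_n]; if the per-branch dense layer is
present, a second dense layer with the same configuration transforms f.  A
2-unit softmax layer produces the class probabilities, and cost-sensitive
(class-weighted) cross-entropy with Adam performs the training.

"Hidden units" counts units per direction, so a bidirectional branch outputs
2H features.  This reading is pinned by the published parameter counts of the
two optimizer-selected architectures (934,202 and 723,602), which the closed
form below reproduces exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from . import _nn
from ._nn import Adam, Tensor
from .encoding import ModelConfig
from .preprocessing import INPUT_POINTS, EpochWindow, windows_to_arrays

__all__ = [
    "TrainingHyperparams",
    "FusionModel",
    "build_model",
    "count_parameters",
    "parameter_count_formula",
    "compute_class_weights",
    "train",
    "predict_scores",
    "select_threshold",
]

_ACTIVATIONS = {
    "tanh": _nn.tanh,
    "sigmoid": _nn.sigmoid,
    "relu": _nn.relu,
    "selu": _nn.selu,
}


@dataclass
class TrainingHyperparams:
    """Fixed training constants; only the epoch budget is situational."""

    learning_rate: float = 0.001
    batch_size: int = 1024
    class_weights: tuple[float, float] | None = None  # None -> from the data
    max_training_epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class FusionModel:
    """The wired network: branches, fusion node, dense layers, softmax head."""

    def __init__(self, config: ModelConfig, input_points: int = INPUT_POINTS, seed: int = 0):
        self.config = config
        self.input_points = input_points
        self.seed = seed
        self.params: list[Tensor] = []
        self.param_names: list[str] = []
        self._rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)))
        self._build()

    # -- construction ------------------------------------------------------

    def _weight(self, name: str, shape: tuple[int, ...]) -> Tensor:
        """Glorot-uniform initialized trainable tensor."""
        if len(shape) == 1:
            data = np.zeros(shape)
        else:
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            data = self._rng.uniform(-limit, limit, size=shape)
        t = Tensor(data, requires_grad=True)
        self.params.append(t)
        self.param_names.append(name)
        return t

    def _lstm_params(self, name: str, in_dim: int, H: int) -> dict:
        # combined gate order: [F, I, O, G]
        return {
            "U": self._weight(f"{name}.U", (in_dim, 4 * H)),
            "W": self._weight(f"{name}.W", (H, 4 * H)),
            "b": self._weight(f"{name}.b", (4 * H,)),
        }

    def _build(self):
        cfg = self.config
        H, S = cfg.hidden_units, cfg.dense_size
        n_dir = 2 if cfg.bidirectional else 1
        self.branches = []
        for ch in cfg.channels:
            layers = []
            in_dim = self.input_points
            for layer in range(cfg.n_recurrent_layers):
                directions = [
                    self._lstm_params(f"ch{ch}.l{layer}.d{d}", in_dim, H)
                    for d in range(n_dir)
                ]
                layers.append(directions)
                in_dim = n_dir * H  # stacked layer consumes the full sequence
            branch = {"layers": layers}
            if S > 0:
                branch["dense_W"] = self._weight(f"ch{ch}.dense.W", (n_dir * H, S))
                branch["dense_b"] = self._weight(f"ch{ch}.dense.b", (S,))
            self.branches.append(branch)
        fused_width = cfg.n_channels * (S if S > 0 else n_dir * H)
        if S > 0:
            self.fusion_dense_W = self._weight("fusion.dense.W", (fused_width, S))
            self.fusion_dense_b = self._weight("fusion.dense.b", (S,))
            out_in = S
        else:
            self.fusion_dense_W = None
            self.fusion_dense_b = None
            out_in = fused_width
        self.out_W = self._weight("out.W", (out_in, 2))
        self.out_b = self._weight("out.b", (2,))

    # -- forward pass ------------------------------------------------------

    @staticmethod
    def _run_direction(seq: list[Tensor], p: dict, H: int) -> list[Tensor]:
        """One LSTM direction over a sequence; returns the per-step outputs."""
        B = seq[0].shape[0]
        h = Tensor(np.zeros((B, H)))
        s = Tensor(np.zeros((B, H)))
        outs = []
        for x_t in seq:
            z = _nn.add(_nn.add(_nn.matmul(x_t, p["U"]), _nn.matmul(h, p["W"])), p["b"])
            f = _nn.sigmoid(_nn.cols(z, 0, H))
            i = _nn.sigmoid(_nn.cols(z, H, 2 * H))
            o = _nn.sigmoid(_nn.cols(z, 2 * H, 3 * H))
            g = _nn.tanh(_nn.cols(z, 3 * H, 4 * H))
            s = _nn.add(_nn.mul(f, s), _nn.mul(i, g))
            h = _nn.mul(_nn.tanh(s), o)
            outs.append(h)
        return outs

    def _dropout(self, x: Tensor, train: bool, rng) -> Tensor:
        p = self.config.dropout
        if not train or p <= 0:
            return x
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return _nn.mul(x, Tensor(mask))

    def forward(self, X: np.ndarray, train: bool = False, rng=None) -> Tensor:
        """Logits for a batch X of shape (B, n_recorded_channels, T, I).

        X carries every recorded channel; the model reads only the channels
        its configuration selects.
        """
        cfg = self.config
        H = cfg.hidden_units
        if rng is None:
            rng = self._rng
        features = []
        for ch, branch in zip(cfg.channels, self.branches):
            seq = [Tensor(X[:, ch, t, :]) for t in range(cfg.time_steps)]
            for directions in branch["layers"]:
                fwd = self._run_direction(seq, directions[0], H)
                if cfg.bidirectional:
                    bwd = self._run_direction(seq[::-1], directions[1], H)
                    seq = [
                        _nn.concat([fwd[t], bwd[len(seq) - 1 - t]], axis=1)
                        for t in range(len(seq))
                    ]
                else:
                    seq = fwd
            feat = self._dropout(seq[-1], train, rng)  # last cell's output
            if cfg.dense_size > 0:
                act = _ACTIVATIONS[cfg.dense_activation]
                feat = act(_nn.add(_nn.matmul(feat, branch["dense_W"]), branch["dense_b"]))
                feat = self._dropout(feat, train, rng)
            features.append(feat)
        fused = _nn.concat(features, axis=1) if len(features) > 1 else features[0]
        if self.fusion_dense_W is not None:
            act = _ACTIVATIONS[cfg.dense_activation]
            fused = act(_nn.add(_nn.matmul(fused, self.fusion_dense_W), self.fusion_dense_b))
            fused = self._dropout(fused, train, rng)
        return _nn.add(_nn.matmul(fused, self.out_W), self.out_b)


def build_model(config: ModelConfig, input_points: int = INPUT_POINTS, seed: int = 0) -> FusionModel:
    """Cold-start a fusion network from a decoded configuration."""
    return FusionModel(config, input_points=input_points, seed=seed)


def count_parameters(model: FusionModel) -> int:
    """Total number of trainable scalars in the built network."""
    return int(sum(p.data.size for p in model.params))


def parameter_count_formula(config: ModelConfig, input_points: int = INPUT_POINTS) -> int:
    """Closed-form trainable-parameter count of the wired architecture.

    For one recurrent layer:
        n * dir * 4(H(I+H) + H)                       recurrent branches
      + [S>0] * ( n*(dir*H + 1)*S + (n*S + 1)*S )     dense layers
      + (out_in + 1) * 2                              softmax head
    with out_in = S if S > 0 else n*dir*H.  Stacked second layers consume
    dir*H-wide inputs: 4(H(dir*H + H) + H) per direction per channel.
    """
    n = config.n_channels
    H = config.hidden_units
    S = config.dense_size
    d = 2 if config.bidirectional else 1
    I = input_points
    total = n * d * 4 * (H * (I + H) + H)
    if config.n_recurrent_layers == 2:
        total += n * d * 4 * (H * (d * H + H) + H)
    if S > 0:
        total += n * (d * H + 1) * S + (n * S + 1) * S
        out_in = S
    else:
        out_in = n * d * H
    total += (out_in + 1) * 2
    return total


def compute_class_weights(labels: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency weights w_c = N / (2 * N_c); balanced data -> (1, 1)."""
    labels = np.asarray(labels)
    n = len(labels)
    n1 = int(labels.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute class weights")
    return (n / (2.0 * n0), n / (2.0 * n1))


def train(
    model: FusionModel,
    windows: list[EpochWindow] | tuple[np.ndarray, np.ndarray],
    hp: TrainingHyperparams,
) -> list[float]:
    """Class-weighted Adam training; returns the per-epoch mean loss trace."""
    if isinstance(windows, tuple):
        X, y = windows
    else:
        if not windows:
            raise ValueError("empty training set")
        X, y = windows_to_arrays(windows)
    if len(X) == 0:
        raise ValueError("empty training set")
    weights = hp.class_weights or compute_class_weights(y)
    w = np.where(y == 1, weights[1], weights[0]).astype(np.float64)
    rng = np.random.default_rng(np.random.SeedSequence((hp.seed, 0x7121)))
    opt = Adam(model.params, lr=hp.learning_rate)
    losses = []
    n = len(X)
    for _ in range(hp.max_training_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            opt.zero_grad()
            logits = model.forward(X[idx], train=True, rng=rng)
            loss = _nn.weighted_softmax_cross_entropy(logits, y[idx], w[idx])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    return losses


def predict_scores(
    model: FusionModel, windows: list[EpochWindow] | tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Softmax probability of the positive ("A") class per window."""
    if isinstance(windows, tuple):
        X = windows[0]
    else:
        X, _ = windows_to_arrays(windows)
    scores = []
    for start in range(0, len(X), 4096):
        logits = model.forward(X[start : start + 4096], train=False)
        scores.append(_nn.softmax(logits.data)[:, 1])
    return np.concatenate(scores)


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-optimal cutoff: the score threshold maximizing Youden's J.

    J = Sen + Spe - 1 = TPR - FPR over the training ROC; the decision rule is
    ``score >= threshold``.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to choose a threshold")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    thr = thresholds[best]
    if np.isinf(thr):  # sklearn's sentinel above the top score
        thr = float(np.max(scores)) + 1.0
    return float(thr)
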