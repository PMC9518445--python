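"""Fusion network wiring, parameter counts, training and thresholding."""

import numpy as np
import pytest

from capfusion import _nn
from capfusion.encoding import ModelConfig, decode, random_genome
from capfusion.evaluation import roc_auc
from capfusion.fusion_model import (
    TrainingHyperparams,
    build_model,
    compute_class_weights,
    count_parameters,
    parameter_count_formula,
    predict_scores,
    select_threshold,
    train,
)
from capfusion.preprocessing import make_windows, preprocess_recording, windows_to_arrays

GA_CFG = decode([1, 1, 1, 0, 1, 0, 1, 0, 1, 1, 0, 1, 1, 0, 1])
PSO_CFG = decode([1, 1, 1, 1, 1, 0, 1, 0, 1, 0, 0, 1, 0, 1, 0])


def _mono_config(**over):
    base = dict(
        channel_mask=(True, False, False),
        time_steps=2,
        n_recurrent_layers=1,
        recurrent_type="unidirectional",
        hidden_units=8,
        dropout=0.0,
        dense_size=0,
        dense_activation="tanh",
    )
    base.update(over)
    return ModelConfig(**base)


def test_parameter_count_ga_architecture():
    model = build_model(GA_CFG)
    assert count_parameters(model) == 934_202
    assert parameter_count_formula(GA_CFG) == 934_202


def test_parameter_count_pso_architecture():
    model = build_model(PSO_CFG)
    assert count_parameters(model) == 723_602
    assert parameter_count_formula(PSO_CFG) == 723_602


def test_parameter_count_single_channel_closed_form():
    cfg = _mono_config(hidden_units=100)
    assert parameter_count_formula(cfg) == 4 * (100 * 200 + 100) + 101 * 2 == 80_602
    assert count_parameters(build_model(cfg)) == 80_602


def test_closed_form_matches_counter_on_random_configs():
    rng = np.random.default_rng(17)
    for _ in range(100):
        cfg = decode(random_genome(rng))
        assert count_parameters(build_model(cfg)) == parameter_count_formula(cfg)


def test_branch_widths():
    uni = build_model(_mono_config())
    X = np.zeros((2, 3, 2, 100))
    assert uni.forward(X).shape == (2, 2)
    assert uni.out_W.shape == (8, 2)  # H feeds the softmax directly when S=0
    bi = build_model(_mono_config(recurrent_type="bidirectional"))
    assert bi.out_W.shape == (16, 2)  # 2H for a bidirectional branch


def test_class_weights():
    assert compute_class_weights(np.array([0, 1] * 10)) == (1.0, 1.0)
    w = compute_class_weights(np.array([0] * 80 + [1] * 20))
    assert w == (0.625, 2.5)
    with pytest.raises(ValueError):
        compute_class_weights(np.zeros(10))


def test_weighted_loss_balances_trivial_predictors():
    """With inverse-frequency weights, all-majority and all-minority
    predictors incur the same loss on imbalanced data."""
    y = np.array([0] * 80 + [1] * 20)
    w0, w1 = compute_class_weights(y)
    w = np.where(y == 1, w1, w0)
    logit_majority = np.tile([3.0, -3.0], (100, 1))
    logit_minority = np.tile([-3.0, 3.0], (100, 1))
    loss_maj = float(_nn.weighted_softmax_cross_entropy(_nn.Tensor(logit_majority), y, w).data)
    loss_min = float(_nn.weighted_softmax_cross_entropy(_nn.Tensor(logit_minority), y, w).data)
    assert loss_maj == pytest.approx(loss_min, rel=1e-12)


def test_scaled_class_weights_scale_gradients():
    cfg = _mono_config()
    X = np.random.default_rng(0).standard_normal((8, 3, 2, 100))
    y = np.array([0, 1] * 4)
    grads = []
    for scale in (1.0, 3.0):
        model = build_model(cfg, seed=5)
        w = scale * np.where(y == 1, 2.0, 0.5)
        loss = _nn.weighted_softmax_cross_entropy(model.forward(X), y, w)
        loss.backward()
        grads.append(np.concatenate([p.grad.ravel() for p in model.params]))
    assert np.allclose(grads[1], 3.0 * grads[0])


def test_softmax_scores_normalized_and_argmax_consistent():
    model = build_model(_mono_config(recurrent_type="bidirectional"), seed=2)
    X = np.random.default_rng(1).standard_normal((32, 3, 2, 100))
    logits = model.forward(X)
    probs = _nn.softmax(logits.data)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    scores = predict_scores(model, (X, None))
    assert np.array_equal(np.argmax(probs, axis=1) == 1, scores >= 0.5)
    assert ((scores >= 0) & (scores <= 1)).all()


def test_untrained_model_scores_near_half():
    model = build_model(_mono_config(hidden_units=16), seed=3)
    X = np.random.default_rng(2).standard_normal((200, 3, 2, 100))
    assert abs(predict_scores(model, (X, None)).mean() - 0.5) < 0.1


def test_training_learns_separable_synthetic_data(tiny_cohort, tiny_config):
    rec = preprocess_recording(tiny_cohort[0])
    X, y = windows_to_arrays(make_windows(rec, tiny_config.time_steps))
    model = build_model(tiny_config, seed=1)
    hp = TrainingHyperparams(max_training_epochs=10, seed=1)
    losses = train(model, (X, y), hp)
    assert losses[-1] < losses[0]
    assert roc_auc(predict_scores(model, (X, None)), y) > 0.95


def test_training_is_deterministic(tiny_cohort, tiny_config):
    rec = preprocess_recording(tiny_cohort[1])
    X, y = windows_to_arrays(make_windows(rec, tiny_config.time_steps))
    hp = TrainingHyperparams(max_training_epochs=2, seed=9)
    traces = []
    for _ in range(2):
        model = build_model(tiny_config, seed=9)
        traces.append(train(model, (X, y), hp))
    assert traces[0] == traces[1]


def test_train_rejects_empty_windows():
    model = build_model(_mono_config(), seed=0)
    with pytest.raises(ValueError):
        train(model, [], TrainingHyperparams())


def test_select_threshold_separable():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    thr = select_threshold(scores, labels)
    pred = scores >= thr
    assert (pred == labels.astype(bool)).all()


def test_select_threshold_matches_exhaustive_scan():
    rng = np.random.default_rng(8)
    for _ in range(20):
        scores = rng.random(60)
        labels = (rng.random(60) < 0.3).astype(int)
        if labels.sum() in (0, 60):
            continue
        thr = select_threshold(scores, labels)

        def youden(t):
            pred = scores >= t
            sen = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spe = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            return sen + spe - 1

        best_j = max(youden(t) for t in np.concatenate([scores, [scores.max() + 1]]))
        assert youden(thr) == pytest.approx(best_j, abs=1e-12)


def test_select_threshold_null_scores_give_small_j():
    rng = np.random.default_rng(12)
    js = []
    for _ in range(50):
        scores = rng.random(400)
        labels = (rng.random(400) < 0.5).astype(int)
        thr = select_threshold(scores, labels)
        pred = scores >= thr
        sen = (pred & (labels == 1)).sum() / max((labels == 1).sum(), 1)
        spe = (~pred & (labels == 0)).sum() / max((labels == 0).sum(), 1)
        js.append(sen + spe - 1)
    # the optimum of an independent ROC is positively biased but small
    assert 0 <= np.mean(js) < 0.15


def test_select_threshold_requires_both_classes():
    with pytest.raises(ValueError):
        select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))
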