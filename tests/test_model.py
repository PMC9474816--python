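"""The survival network: loss, curves, batching, splitting, training."""

import dataclasses
import math

import numpy as np
import pytest

import icusurv as iu
from icusurv.data_model import CohortIndex, DOMAINS
from icusurv.labels import SurvivalLabel, WindowSpec, make_labels
from icusurv.model import (
    ModelConfig,
    SEARCH_SPACE,
    SequenceBatch,
    assemble_batch,
    build_model,
    discrete_survival_loss,
    fit_padding_lengths,
    make_cv_folds,
    random_search,
    sample_config,
    split_by_birthday,
    survival_curve,
    train,
)
from icusurv.tokenization import PAD_INDEX, TokenizedAdmission, Vocabulary, slot_layout
from .conftest import make_admission


# ------------------------------------------------------------------- the loss
def case_wise_loss(p, s, f):
    """Independent oracle dispatching the three per-window cases: survived →
    −log p, died → −log(1−p), after death/censoring → 0."""
    total = 0.0
    for pi, si, fi in zip(p, s, f):
        if si:
            total -= math.log(pi)
        elif fi:
            total -= math.log(1.0 - pi)
    return total


def test_loss_death_in_window_two():
    label = SurvivalLabel((1, 0, 0, 0, 0, 0), (0, 1, 0, 0, 0, 0))
    p = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4)
    expected = -math.log(0.9) - math.log(0.2)
    assert discrete_survival_loss(p, label) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(1.7148, abs=5e-5)


def test_loss_ignores_windows_after_censoring():
    label = SurvivalLabel((1, 0, 0, 0, 0, 0), (0, 0, 0, 0, 0, 0))
    base = discrete_survival_loss((0.9, 0.5, 0.5, 0.5, 0.5, 0.5), label)
    other = discrete_survival_loss((0.9, 0.01, 0.99, 0.2, 0.8, 0.5), label)
    assert base == pytest.approx(other) == pytest.approx(-math.log(0.9))


def test_loss_perfect_survivor_tends_to_zero():
    label = SurvivalLabel((1,) * 6, (0,) * 6)
    assert discrete_survival_loss((1.0 - 1e-7,) * 6, label) < 1e-5


def test_loss_length_mismatch():
    with pytest.raises(ValueError):
        discrete_survival_loss((0.5, 0.5), SurvivalLabel((1, 0, 0), (0, 1, 0)))


def _random_label(rng, n=6):
    kind = rng.integers(3)
    if kind == 0:  # death in window k
        k = int(rng.integers(n))
        s = [1] * k + [0] * (n - k)
        f = [0] * n
        f[k] = 1
    elif kind == 1:  # censored after k survived windows
        k = int(rng.integers(n + 1))
        s = [1] * k + [0] * (n - k)
        f = [0] * n
    else:  # survivor of everything
        s, f = [1] * n, [0] * n
    return SurvivalLabel(tuple(s), tuple(f))


def test_loss_matches_case_wise_oracle():
    rng = np.random.default_rng(42)
    for _ in range(2000):
        p = rng.uniform(0.001, 0.999, size=6)
        lb = _random_label(rng)
        assert abs(
            discrete_survival_loss(p, lb) - case_wise_loss(p, lb.surv_s, lb.surv_f)
        ) < 1e-10


# ------------------------------------------------------------ survival curves
@pytest.mark.parametrize(
    "cond, expected",
    [
        ((0.9, 0.8), (0.9, 0.72)),
        ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)),
        ((0.5, 0.5, 0.5), (0.5, 0.25, 0.125)),
    ],
)
def test_survival_curve_examples(cond, expected):
    assert survival_curve(cond) == pytest.approx(expected)


def test_survival_curve_nonincreasing():
    rng = np.random.default_rng(0)
    for _ in range(50):
        s = survival_curve(rng.uniform(0.01, 0.999, size=6))
        assert np.all(np.diff(s) <= 0)


# -------------------------------------------------------- batches and padding
def _toy_vocabs():
    return {
        d: Vocabulary(d, {"a": 2, "b": 3, "c": 4} if d in ("lab", "chart") else {"a": 2})
        for d in DOMAINS
    }


def _tokenized(aid, lab_tokens, baseline_h=0.0):
    slots = slot_layout(baseline_h)
    idx = {d: [[] for _ in slots] for d in DOMAINS}
    idx["lab"][-1] = list(lab_tokens)
    return TokenizedAdmission(aid, slots, idx, age_years=70.0, hospital_los_days=1.0)


def test_assemble_batch_pads_and_truncates():
    pad = {d: 1 for d in DOMAINS} | {"lab": 5}
    batch = assemble_batch(
        [_tokenized("A1", [2, 3, 4]), _tokenized("A2", [2, 3, 4, 2, 3, 4, 2, 3]),
         _tokenized("A3", [])],
        pad,
    )
    lab = batch.indices["lab"][:, -1, :]
    assert lab[0].tolist() == [2, 3, 4, PAD_INDEX, PAD_INDEX]
    # truncation keeps the most recent (last) five tokens
    assert lab[1].tolist() == [2, 3, 4, 2, 3, 4, 2, 3][-5:]
    assert lab[2].tolist() == [PAD_INDEX] * 5


def test_fit_padding_lengths_percentile_of_positive_counts():
    toks = [_tokenized("A1", [2] * 4), _tokenized("A2", [2]), _tokenized("A3", [])]
    pad = fit_padding_lengths(toks, 95.0)
    assert pad["lab"] == 4  # 95th pct of positive counts {4, 1}
    assert pad["chart"] == 1  # empty domain floors at 1


# ------------------------------------------------------------------ the model
def _small_config(**kw):
    base = dict(hidden_units=8, dropout=0.0, recurrent_dropout=0.0, l2=0.0,
                epochs=5, batch_size=8, learning_rate=0.05, seed=3,
                use_static=False)
    base.update(kw)
    return ModelConfig(**base)


def test_embedding_width_matches_formula():
    vocabs = _toy_vocabs()
    vocabs["lab"] = Vocabulary("lab", {f"t{i}": i + 2 for i in range(10_000)})
    m = build_model(_small_config(), vocabs, {d: 1 for d in DOMAINS})
    assert m.embed_dims["lab"] == 60
    assert m.embeddings["lab"].data.shape == (10_002, 60)


def test_all_pad_input_gives_valid_probabilities():
    m = build_model(_small_config(), _toy_vocabs(), {d: 1 for d in DOMAINS})
    batch = assemble_batch([_tokenized("A1", []), _tokenized("A2", [])],
                           {d: 1 for d in DOMAINS})
    p = m.predict(batch)
    assert p.shape == (2, 6)
    assert np.all((p > 0) & (p < 1))
    # identical inputs → identical outputs in inference mode
    assert np.array_equal(p[0], p[1])


@pytest.mark.parametrize("cell", ["gru", "lstm"])
def test_model_gradients_match_finite_differences(cell):
    """End-to-end gradient check of the full network incl. embeddings."""
    from .test_autodiff import numerical_grad

    vocabs = _toy_vocabs()
    pad = {d: 1 for d in DOMAINS} | {"lab": 2}
    cfg = _small_config(recurrent_cell=cell, hidden_units=3)
    m = build_model(cfg, vocabs, pad, (np.array([70.0, 1.0]), np.array([10.0, 2.0])))
    labels = [
        make_labels(3.0, True, cfg.windows),
        make_labels(400.0, False, cfg.windows),
    ]
    batch = assemble_batch([_tokenized("A1", [2, 3]), _tokenized("A2", [4])],
                           pad, labels)
    loss = m.loss_tensor(batch)
    loss.backward()
    for p in (m.embeddings["lab"], m.Wx[0], m.Wh[-1], m.b[0], m.W_out, m.b_out):
        num = numerical_grad(lambda: float(m.loss_tensor(batch).data), p)
        assert np.allclose(p.grad, num, atol=1e-6)


def test_loss_tensor_matches_public_loss():
    vocabs = _toy_vocabs()
    pad = {d: 1 for d in DOMAINS} | {"lab": 2}
    cfg = _small_config()
    m = build_model(cfg, vocabs, pad)
    labels = [make_labels(10.0, True, cfg.windows), make_labels(50.0, False, cfg.windows)]
    batch = assemble_batch([_tokenized("A1", [2]), _tokenized("A2", [3])], pad, labels)
    graph = float(m.loss_tensor(batch).data)
    preds = m.predict(batch)
    manual = np.mean([discrete_survival_loss(preds[i], labels[i]) for i in range(2)])
    assert graph == pytest.approx(manual, rel=1e-9)


def _separable_batch(n=60, seed=0):
    """Token 2 ⇒ early death, token 3 ⇒ survivor: linearly separable."""
    rng = np.random.default_rng(seed)
    toks, labels = [], []
    for i in range(n):
        sick = i % 2 == 0
        toks.append(_tokenized(f"A{i}", [2 if sick else 3]))
        t = float(rng.uniform(0.1, 0.9)) if sick else 400.0
        labels.append(make_labels(t, sick, WindowSpec()))
    return assemble_batch(toks, {d: 1 for d in DOMAINS}, labels)


def test_training_reduces_loss_on_separable_cohort():
    batch = _separable_batch()
    cfg = _small_config(epochs=15)
    m = build_model(cfg, _toy_vocabs(), {d: 1 for d in DOMAINS})
    hist = train(m, batch, None, cfg)
    assert hist["train_loss"][-1] < hist["train_loss"][0] * 0.5
    p = m.predict(batch)
    assert p[0, 0] < p[1, 0]  # sick admission gets lower window-1 survival


def test_training_is_deterministic_under_seed():
    batch = _separable_batch()
    losses = []
    for _ in range(2):
        cfg = _small_config(epochs=4, dropout=0.2, recurrent_dropout=0.2)
        m = build_model(cfg, _toy_vocabs(), {d: 1 for d in DOMAINS})
        hist = train(m, batch, None, cfg)
        losses.append(hist["train_loss"])
    assert losses[0] == losses[1]


def test_divergence_aborts_with_diagnostic():
    batch = _separable_batch(n=8)
    cfg = _small_config(epochs=2)
    m = build_model(cfg, _toy_vocabs(), {d: 1 for d in DOMAINS})
    m.W_out.data[:] = np.nan  # corrupted state must abort, not loop silently
    with pytest.raises(FloatingPointError, match="diverged"):
        train(m, batch, None, cfg)


# ------------------------------------------------------- splitting and search
def test_split_by_birthday_is_patient_level():
    cohort = CohortIndex([
        make_admission("A1", "P1", birth_day=3),
        make_admission("A2", "P1", birth_day=3),
        make_admission("A3", "P2", birth_day=7),
    ])
    tr, te = split_by_birthday(cohort)
    assert [a.admission_id for a in te] == ["A1", "A2"]
    assert [a.admission_id for a in tr] == ["A3"]


def test_cv_folds_partition_patients():
    cohort = CohortIndex(
        [make_admission(f"A{i}{j}", f"P{i}") for i in range(10) for j in range(i % 3 + 1)]
    )
    folds = make_cv_folds(cohort, k=5, seed=1)
    assert len(folds) == 5
    assert sum(len(f.by_patient) for f in folds) == 10
    seen = [set(f.by_patient) for f in folds]
    for i in range(5):
        for j in range(i + 1, 5):
            assert not seen[i] & seen[j]
    again = make_cv_folds(cohort, k=5, seed=1)
    assert [sorted(f.by_patient) for f in folds] == [sorted(f.by_patient) for f in again]


def test_sampled_configs_stay_in_ranges():
    rng = np.random.default_rng(0)
    base = _small_config()
    for _ in range(50):
        cfg = sample_config(rng, base)
        assert cfg.recurrent_cell in SEARCH_SPACE["recurrent_cell"]
        assert SEARCH_SPACE["hidden_units"][0] <= cfg.hidden_units <= SEARCH_SPACE["hidden_units"][1]
        assert SEARCH_SPACE["l2"][0] <= cfg.l2 <= SEARCH_SPACE["l2"][1]
        assert SEARCH_SPACE["dropout"][0] <= cfg.dropout <= SEARCH_SPACE["dropout"][1]
        assert 0.2 <= cfg.embedding_coefficient <= 2.0


def test_random_search_budget_one_returns_single_sample():
    batch = _separable_batch(n=20)
    val = _separable_batch(n=10, seed=1)
    base = _small_config(epochs=1)
    best, log = random_search(1, [(batch, val)], _toy_vocabs(),
                              {d: 1 for d in DOMAINS}, base, seed=5)
    assert len(log) == 1
    assert dataclasses.asdict(best) == log[0]["config"]


def test_config_range_validation():
    with pytest.raises(ValueError):
        ModelConfig(hidden_units=1000).validate()
    with pytest.raises(ValueError):
        ModelConfig(recurrent_cell="rnn").validate()
    with pytest.raises(ValueError):
        ModelConfig(baseline_h=12.0).validate()
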