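"""Recurrent multi-label discrete-time survival model.

Architecture: each data domain has its own entity-embedding space whose width
is ``D = 6·alpha·V^(1/4)``. Within a time slot, the embedded token vectors of
a domain are concatenated (padded/truncated to a per-domain length set by the
padding percentile of training slot counts), then the seven domain blocks are
concatenated into one slot vector. The slot sequence — six coarse
pre-baseline bins followed by hourly post-admission slots — feeds a recurrent
sub-model (LSTM or GRU). Its final state, concatenated with standardized age
and pre-ICU hospital length of stay, passes through a dense layer with one
sigmoid output node per prediction window. Node i is the conditional
probability of surviving window i given survival so far; cumulative survival
is the running product.

The training criterion is the censoring-aware negative log-likelihood

    -l = -sum_i [ log(1 + s_i (p_i - 1)) + log(1 - f_i p_i) ]

where p_i is the predicted conditional survival of window i and (s, f) the
survive/fail indicators: a window after death or censoring contributes
exactly zero, so only subjects at risk in a window back-propagate loss there.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Parameter, Tensor
from .data_model import DOMAINS, CohortIndex
from .labels import SurvivalLabel, WindowSpec, labels_to_arrays
from .tokenization import PAD_INDEX, TokenizedAdmission, Vocabulary, embedding_size

_EPS = 1e-7


@dataclass
class ModelConfig:
    """Hyperparameters; ranges follow the tuned search space."""

    recurrent_cell: str = "gru"            # {"lstm", "gru"}
    hidden_units: int = 128                # [128, 384]
    recurrent_dropout: float = 0.1         # [0.1, 0.8]
    dropout: float = 0.1                   # [0.1, 0.8]
    l2: float = 1e-4                       # [0.0001, 0.1]
    embedding_coefficient: float = 1.0     # alpha, [0.2, 2]
    padding_percentile: float = 95.0       # [90, 98]
    baseline_h: float = 0.0                # {0, 24, 48, 72}
    windows: WindowSpec = field(default_factory=WindowSpec)
    seed: int = 0
    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 1e-3
    patience: int = 5                      # early-stopping patience (epochs)
    use_static: bool = True

    def validate(self) -> None:
        checks = [
            (self.recurrent_cell in ("lstm", "gru"), "recurrent_cell"),
            (1 <= self.hidden_units <= 384, "hidden_units"),
            # tuned range is [0.1, 0.8] (see SEARCH_SPACE); 0 switches the
            # regularizer off, e.g. for intercept-only likelihood checks
            (0.0 <= self.recurrent_dropout <= 0.8, "recurrent_dropout"),
            (0.0 <= self.dropout <= 0.8, "dropout"),
            (0.0 <= self.l2 <= 0.1, "l2"),
            (0.2 <= self.embedding_coefficient <= 2.0, "embedding_coefficient"),
            (90.0 <= self.padding_percentile <= 98.0, "padding_percentile"),
            (self.baseline_h in (0.0, 24.0, 48.0, 72.0), "baseline_h"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"config field {name} out of range")


#: Uniform sampling ranges of the random hyperparameter search.
SEARCH_SPACE = {
    "recurrent_cell": ("lstm", "gru"),
    "hidden_units": (128, 384),
    "recurrent_dropout": (0.1, 0.8),
    "dropout": (0.1, 0.8),
    "l2": (1e-4, 0.1),
    "embedding_coefficient": (0.2, 2.0),
    "padding_percentile": (90.0, 98.0),
}


@dataclass
class SequenceBatch:
    """Dense integer token arrays per domain plus statics and labels."""

    indices: dict[str, np.ndarray]        # domain -> (B, T, L_d) int
    static: np.ndarray                    # (B, 2): age_years, hospital_los_days
    admission_ids: list[str]
    surv_s: np.ndarray | None = None      # (B, n)
    surv_f: np.ndarray | None = None

    def __len__(self) -> int:
        return self.static.shape[0]

    def take(self, idx) -> "SequenceBatch":
        idx = np.asarray(idx)
        return SequenceBatch(
            indices={d: a[idx] for d, a in self.indices.items()},
            static=self.static[idx],
            admission_ids=[self.admission_ids[i] for i in idx],
            surv_s=None if self.surv_s is None else self.surv_s[idx],
            surv_f=None if self.surv_f is None else self.surv_f[idx],
        )


@dataclass(frozen=True)
class HazardPrediction:
    """Per-window conditional survival probabilities for one admission."""

    surv_pred: tuple[float, ...]

    def __post_init__(self):
        assert all(0.0 < p < 1.0 for p in self.surv_pred)

    @property
    def hazard(self) -> tuple[float, ...]:
        return tuple(1.0 - p for p in self.surv_pred)


def survival_curve(pred) -> np.ndarray:
    """Cumulative survival S_k = prod_{i<=k} surv_pred_i (nonincreasing)."""
    p = np.asarray(pred.surv_pred if isinstance(pred, HazardPrediction) else pred, dtype=float)
    return np.cumprod(p, axis=-1)


def fit_padding_lengths(
    tokenized: list[TokenizedAdmission], padding_percentile: float
) -> dict[str, int]:
    """Per-domain slot length L_d: the padding percentile of the positive
    per-(admission, slot) token counts in training data, ceiling, minimum 1."""
    lengths: dict[str, int] = {}
    for d in DOMAINS:
        counts = [len(sl) for ta in tokenized for sl in ta.indices[d] if sl]
        if counts:
            lengths[d] = max(1, int(math.ceil(np.percentile(counts, padding_percentile))))
        else:
            lengths[d] = 1
    return lengths


def assemble_batch(
    tokenized: list[TokenizedAdmission],
    pad_lengths: dict[str, int],
    labels: list[SurvivalLabel] | None = None,
) -> SequenceBatch:
    """Pad/truncate token lists to dense arrays. Truncation keeps the most
    recent tokens within a slot; unused positions hold PAD."""
    B = len(tokenized)
    T = len(tokenized[0].slots) if B else 0
    indices = {}
    for d in DOMAINS:
        L = pad_lengths[d]
        arr = np.full((B, T, L), PAD_INDEX, dtype=np.int64)
        for b, ta in enumerate(tokenized):
            for t, toks in enumerate(ta.indices[d]):
                if toks:
                    tail = toks[-L:]
                    arr[b, t, : len(tail)] = tail
        indices[d] = arr
    static = np.array([[ta.age_years, ta.hospital_los_days] for ta in tokenized], dtype=float)
    s = f = None
    if labels is not None:
        s, f = labels_to_arrays(labels)
    return SequenceBatch(indices, static, [ta.admission_id for ta in tokenized], s, f)


def discrete_survival_loss(surv_pred, label: SurvivalLabel) -> float:
    """Censoring-aware negative log-likelihood of one admission.

    ``-l = -sum_i [log(1 + s_i (p_i - 1)) + log(1 - f_i p_i)]`` with p clipped
    to [eps, 1-eps]. Windows after death or censoring (s_i = f_i = 0)
    contribute exactly zero.
    """
    p = np.clip(np.asarray(surv_pred, dtype=float), _EPS, 1.0 - _EPS)
    s = np.asarray(label.surv_s, dtype=float)
    f = np.asarray(label.surv_f, dtype=float)
    if p.shape != s.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {s.shape}")
    ll = np.log1p(s * (p - 1.0)) + np.log1p(-(f * p))
    return float(-ll.sum())


class SurvivalRNN:
    """The predictor: per-domain embeddings → recurrent sub-model → sigmoid
    output nodes. All weights (embeddings included) train jointly."""

    def __init__(
        self,
        config: ModelConfig,
        vocabularies: dict[str, Vocabulary],
        pad_lengths: dict[str, int],
        static_stats: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        config.validate()
        if config.use_static and static_stats is None:
            raise ValueError(
                "use_static=True requires training-set static_stats "
                "(see static_statistics); unstandardized age/LOS saturate the head"
            )
        self.config = config
        self.pad_lengths = dict(pad_lengths)
        self.vocab_sizes = {d: v.size for d, v in vocabularies.items()}
        self.embed_dims = {
            d: embedding_size(V, config.embedding_coefficient)
            for d, V in self.vocab_sizes.items()
        }
        self.static_stats = static_stats  # (mean, sd) of (age, LOS) on train
        self.n_windows = config.windows.n
        self._rng = np.random.default_rng(config.seed)
        self._build()

    # -- parameters -------------------------------------------------------
    def _glorot(self, fan_in: int, fan_out: int) -> Parameter:
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        return Parameter(self._rng.uniform(-limit, limit, size=(fan_in, fan_out)))

    def _build(self) -> None:
        cfg = self.config
        H = cfg.hidden_units
        self.embeddings = {
            d: Parameter(self._rng.normal(0.0, 0.05, size=(self.vocab_sizes[d] + 2,
                                                           self.embed_dims[d])))
            for d in DOMAINS
        }
        F = sum(self.pad_lengths[d] * self.embed_dims[d] for d in DOMAINS)
        self.input_dim = F
        n_gates = 3 if cfg.recurrent_cell == "gru" else 4
        self.Wx = [self._glorot(F, H) for _ in range(n_gates)]
        self.Wh = [self._glorot(H, H) for _ in range(n_gates)]
        self.b = [Parameter(np.zeros(H)) for _ in range(n_gates)]
        if cfg.recurrent_cell == "lstm":
            self.b[1].data[:] = 1.0  # forget-gate bias
        head_in = H + (2 if cfg.use_static else 0)
        self.W_out = self._glorot(head_in, self.n_windows)
        self.b_out = Parameter(np.zeros(self.n_windows))

    def parameters(self) -> list[Parameter]:
        ps = list(self.embeddings.values()) + self.Wx + self.Wh + self.b
        return ps + [self.W_out, self.b_out]

    def _weight_parameters(self) -> list[Parameter]:
        """Parameters subject to L2 (weights, not biases or embeddings)."""
        return self.Wx + self.Wh + [self.W_out]

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, d in zip(self.parameters(), state):
            p.data = d.copy()

    # -- forward ----------------------------------------------------------
    def _slot_input(self, batch: SequenceBatch, t: int) -> Tensor:
        parts = []
        for d in DOMAINS:
            idx = batch.indices[d][:, t, :]              # (B, L)
            emb = self.embeddings[d].take_rows(idx)      # (B, L, D)
            B, L, D = emb.shape
            parts.append(emb.reshape(B, L * D))
        return Tensor.concat(parts, axis=-1)

    def _standardized_static(self, batch: SequenceBatch) -> np.ndarray:
        mean, sd = self.static_stats if self.static_stats is not None else (
            np.zeros(2), np.ones(2))
        return (batch.static - mean) / np.maximum(sd, 1e-8)

    def forward(self, batch: SequenceBatch, training: bool = False) -> Tensor:
        cfg = self.config
        B = len(batch)
        T = next(iter(batch.indices.values())).shape[1]
        H = cfg.hidden_units
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        rec_mask = None
        if training and cfg.recurrent_dropout > 0:
            keep = 1.0 - cfg.recurrent_dropout
            rec_mask = (self._rng.random((B, H)) < keep) / keep  # variational
        for t in range(T):
            x = self._slot_input(batch, t)
            h_in = h * rec_mask if rec_mask is not None else h
            if cfg.recurrent_cell == "gru":
                z = (x @ self.Wx[0] + h_in @ self.Wh[0] + self.b[0]).sigmoid()
                r = (x @ self.Wx[1] + h_in @ self.Wh[1] + self.b[1]).sigmoid()
                n = (x @ self.Wx[2] + (r * h_in) @ self.Wh[2] + self.b[2]).tanh()
                h = (1.0 - z) * n + z * h
            else:
                i = (x @ self.Wx[0] + h_in @ self.Wh[0] + self.b[0]).sigmoid()
                f = (x @ self.Wx[1] + h_in @ self.Wh[1] + self.b[1]).sigmoid()
                o = (x @ self.Wx[2] + h_in @ self.Wh[2] + self.b[2]).sigmoid()
                g = (x @ self.Wx[3] + h_in @ self.Wh[3] + self.b[3]).tanh()
                c = f * c + i * g
                h = o * c.tanh()
        if training and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            h = h * ((self._rng.random((B, H)) < keep) / keep)
        if cfg.use_static:
            h = Tensor.concat([h, Tensor(self._standardized_static(batch))], axis=-1)
        logits = h @ self.W_out + self.b_out
        return logits.sigmoid()  # conditional survival per window

    def predict(self, batch: SequenceBatch, chunk: int = 1024) -> np.ndarray:
        """Deterministic inference (dropout off): (B, n) conditional survival."""
        outs = []
        for start in range(0, len(batch), chunk):
            sub = batch.take(np.arange(start, min(start + chunk, len(batch))))
            outs.append(self.forward(sub, training=False).data)
        return np.vstack(outs) if outs else np.zeros((0, self.n_windows))

    def predict_survival(self, batch: SequenceBatch) -> np.ndarray:
        """Cumulative survival curves S at the window edges, (B, n)."""
        return np.cumprod(self.predict(batch), axis=1)

    # -- training ---------------------------------------------------------
    def loss_tensor(self, batch: SequenceBatch, training: bool = False) -> Tensor:
        """Mean per-admission negative log-likelihood (+ L2) as a graph node.

        Uses the algebraically equivalent masked form
        ``-l = -sum_i [s_i log p_i + f_i log(1-p_i)]`` (s and f are 0/1 and
        never both 1, so this matches the closed form exactly).
        """
        p = self.forward(batch, training=training).clip(_EPS, 1.0 - _EPS)
        s = np.asarray(batch.surv_s, dtype=float)
        f = np.asarray(batch.surv_f, dtype=float)
        ll = Tensor(s) * p.log() + Tensor(f) * (1.0 - p).log()
        loss = -ll.sum() * (1.0 / len(batch))
        if self.config.l2 > 0:
            reg = None
            for w in self._weight_parameters():
                sq = (w * w).sum()
                reg = sq if reg is None else reg + sq
            loss = loss + self.config.l2 * reg
        return loss


def build_model(
    config: ModelConfig,
    vocabularies: dict[str, Vocabulary],
    pad_lengths: dict[str, int],
    static_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> SurvivalRNN:
    """Construct the predictor from a validated config and fitted state."""
    return SurvivalRNN(config, vocabularies, pad_lengths, static_stats)


def static_statistics(batch: SequenceBatch) -> tuple[np.ndarray, np.ndarray]:
    """Training-set mean/sd of the static features (age, LOS)."""
    return batch.static.mean(axis=0), batch.static.std(axis=0)


def train(
    model: SurvivalRNN,
    train_batch: SequenceBatch,
    val_batch: SequenceBatch | None = None,
    config: ModelConfig | None = None,
) -> dict:
    """Seeded minibatch Adam with early stopping on validation loss.

    Returns a history dict with per-epoch train/val losses; the model is left
    at the best validation checkpoint (or final epoch without validation).
    Diverging (non-finite) loss aborts with a diagnostic.
    """
    cfg = config or model.config
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val = math.inf
    best_state = None
    stale = 0
    n = len(train_batch)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sub = train_batch.take(order[start : start + cfg.batch_size])
            loss = model.loss_tensor(sub, training=True)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(sub)
        history["train_loss"].append(epoch_loss / n)
        if val_batch is not None:
            val_loss = float(model.loss_tensor(val_batch, training=False).data)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val, best_state, stale = val_loss, model.get_state(), 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_state is not None:
        model.set_state(best_state)
    return history


def split_by_birthday(cohort: CohortIndex) -> tuple[CohortIndex, CohortIndex]:
    """Patient-level hold-out split: patients born in the first six days of a
    month go to the test set (≈20%), the rest to training. All admissions of
    a patient land on the same side."""
    train, test = [], []
    for adm in cohort:
        (test if adm.birth_day_of_month <= 6 else train).append(adm)
    return cohort.subset(train), cohort.subset(test)


def make_cv_folds(cohort: CohortIndex, k: int = 5, seed: int = 0) -> list[CohortIndex]:
    """Patient-level cross-validation folds: a seeded shuffle of patients
    split into k near-equal groups; all admissions of a patient share a fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    patients = sorted(cohort.by_patient)
    rng.shuffle(patients)
    folds = []
    for chunk in np.array_split(np.asarray(patients, dtype=object), k):
        adms = [a for p in chunk for a in cohort.by_patient[p]]
        folds.append(cohort.subset(adms))
    return folds


def sample_config(rng: np.random.Generator, base: ModelConfig) -> ModelConfig:
    """Draw one configuration uniformly from the search space."""
    cfg = dataclasses.replace(
        base,
        recurrent_cell=SEARCH_SPACE["recurrent_cell"][rng.integers(2)],
        hidden_units=int(rng.integers(SEARCH_SPACE["hidden_units"][0],
                                      SEARCH_SPACE["hidden_units"][1] + 1)),
        recurrent_dropout=float(rng.uniform(*SEARCH_SPACE["recurrent_dropout"])),
        dropout=float(rng.uniform(*SEARCH_SPACE["dropout"])),
        l2=float(np.exp(rng.uniform(*np.log(SEARCH_SPACE["l2"])))),
        embedding_coefficient=float(rng.uniform(*SEARCH_SPACE["embedding_coefficient"])),
        padding_percentile=float(rng.uniform(*SEARCH_SPACE["padding_percentile"])),
    )
    return cfg


def random_search(
    budget: int,
    folds: list[tuple[SequenceBatch, SequenceBatch]],
    vocabularies: dict[str, Vocabulary],
    pad_lengths: dict[str, int],
    base: ModelConfig,
    seed: int = 0,
) -> tuple[ModelConfig, list[dict]]:
    """Minimal random hyperparameter search: sample ``budget`` configs, score
    each by mean cross-validation validation loss, return the best (ties go
    to the earliest sample) plus a full log."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    best = None
    for trial in range(budget):
        cfg = sample_config(rng, base)
        losses = []
        for tr, va in folds:
            m = build_model(cfg, vocabularies, pad_lengths, static_statistics(tr))
            train(m, tr, va, cfg)
            losses.append(float(m.loss_tensor(va).data))
        mean_loss = float(np.mean(losses))
        log.append({"trial": trial, "config": dataclasses.asdict(cfg),
                    "fold_losses": losses, "mean_val_loss": mean_loss})
        if best is None or mean_loss < best[0]:
            best = (mean_loss, cfg)
    return best[1], log
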