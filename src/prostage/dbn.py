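"""Restricted Boltzmann machines stacked into a deep belief network classifier.

One network per predictor.  Each network stacks three logistic-unit RBMs of
the same width as its input (9 for PSA bits, 9 for Gleason flags, 8 for
clinical T flags), pretrained greedily with contrastive divergence, then
fine-tuned end-to-end by backpropagation through a two-unit logistic head.

The two head outputs score organ-confined (OCD) and non-organ-confined
(NOCD) disease independently; they are deliberately *not* softmax-normalised,
so the shortfall 1 - (p_OCD + p_NOCD) survives to the evidence-fusion stage
as unassigned belief mass.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .data import Label

__all__ = [
    "RBMParams",
    "DBNClassifier",
    "TrainingConfig",
    "hidden_activation",
    "visible_activation",
    "cd_update",
    "init_rbm",
    "pretrain",
    "finetune",
    "train_dbn",
    "predict_proba",
    "save_classifier",
    "load_classifier",
]


@dataclass(frozen=True)
class RBMParams:
    """Parameters of one RBM layer: ``weights`` is visible_dim x hidden_dim."""

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        vb = np.asarray(self.visible_bias, dtype=float)
        hb = np.asarray(self.hidden_bias, dtype=float)
        if w.ndim != 2 or vb.shape != (w.shape[0],) or hb.shape != (w.shape[1],):
            raise ValueError("inconsistent RBM parameter shapes")
        if not (np.isfinite(w).all() and np.isfinite(vb).all() and np.isfinite(hb).all()):
            raise ValueError("RBM parameters must be finite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "visible_bias", vb)
        object.__setattr__(self, "hidden_bias", hb)

    @property
    def visible_dim(self) -> int:
        return self.weights.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs for unsupervised pretraining and supervised fine-tuning.

    ``pretrain_epochs`` counts epochs *per RBM layer* by default; set
    ``epoch_allocation="total"`` to spread the budget across the stack
    instead.  ``freeze_stack`` restricts backpropagation to the head.
    """

    pretrain_epochs: int = 100
    finetune_epochs: int = 1000
    pretrain_lr: float = 0.1
    finetune_lr: float = 0.1
    batch_size: int = 32
    cd_steps: int = 1
    seed: int = 0
    n_layers: int = 3
    epoch_allocation: str = "per_layer"  # or "total"
    freeze_stack: bool = False

    def __post_init__(self) -> None:
        if self.pretrain_epochs < 0 or self.finetune_epochs < 0:
            raise ValueError("epoch counts must be nonnegative")
        if self.pretrain_lr <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1 or self.cd_steps < 1 or self.n_layers < 1:
            raise ValueError("batch_size, cd_steps and n_layers must be >= 1")
        if self.epoch_allocation not in ("per_layer", "total"):
            raise ValueError("epoch_allocation must be 'per_layer' or 'total'")


@dataclass(frozen=True)
class DBNClassifier:
    """A pretrained RBM stack with a two-output logistic classification head.

    Output unit 0 scores OCD, unit 1 scores NOCD.
    """

    rbm_layers: tuple[RBMParams, ...]
    head_weights: np.ndarray
    head_bias: np.ndarray
    feature_name: str
    config: TrainingConfig | None = None
    training_loss: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        hw = np.asarray(self.head_weights, dtype=float)
        hb = np.asarray(self.head_bias, dtype=float)
        layers = tuple(self.rbm_layers)
        for a, b in zip(layers, layers[1:]):
            if a.hidden_dim != b.visible_dim:
                raise ValueError("RBM layer dimensions do not chain")
        if layers and hw.shape != (layers[-1].hidden_dim, 2):
            raise ValueError("head must map the top hidden layer to 2 outputs")
        if hb.shape != (2,):
            raise ValueError("head bias must have length 2")
        object.__setattr__(self, "rbm_layers", layers)
        object.__setattr__(self, "head_weights", hw)
        object.__setattr__(self, "head_bias", hb)

    @property
    def visible_dim(self) -> int:
        return self.rbm_layers[0].visible_dim


def _as_batch(v: np.ndarray, dim: int, what: str) -> tuple[np.ndarray, bool]:
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    if single:
        v = v[None, :]
    if v.ndim != 2 or v.shape[1] != dim:
        raise ValueError(f"{what}: expected vectors of length {dim}, got shape {v.shape}")
    return v, single


def hidden_activation(rbm: RBMParams, v: np.ndarray) -> np.ndarray:
    """P(h=1 | v): elementwise logistic of ``v @ W + hidden_bias``."""
    vb, single = _as_batch(v, rbm.visible_dim, "hidden_activation")
    p = expit(vb @ rbm.weights + rbm.hidden_bias)
    return p[0] if single else p


def visible_activation(rbm: RBMParams, h: np.ndarray) -> np.ndarray:
    """P(v=1 | h): elementwise logistic of ``h @ W.T + visible_bias``."""
    hb, single = _as_batch(h, rbm.hidden_dim, "visible_activation")
    p = expit(hb @ rbm.weights.T + rbm.visible_bias)
    return p[0] if single else p


def init_rbm(visible_dim: int, hidden_dim: int, rng: np.random.Generator) -> RBMParams:
    """Small Gaussian weights (sd 0.01), zero biases."""
    return RBMParams(
        weights=rng.normal(0.0, 0.01, size=(visible_dim, hidden_dim)),
        visible_bias=np.zeros(visible_dim),
        hidden_bias=np.zeros(hidden_dim),
    )


def cd_update(
    rbm: RBMParams,
    batch: np.ndarray,
    lr: float,
    cd_steps: int = 1,
    rng: np.random.Generator | None = None,
) -> RBMParams:
    """One contrastive-divergence (CD-k) gradient step on a mini-batch.

    Positive phase uses the data and hidden probabilities; the negative phase
    runs ``cd_steps`` Gibbs alternations with *sampled* binary hidden states
    and mean-field visible probabilities.  Deterministic under a fixed rng.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    batch, _ = _as_batch(batch, rbm.visible_dim, "cd_update")
    if batch.shape[0] == 0:
        raise ValueError("cd_update requires a non-empty batch")
    if lr < 0:
        raise ValueError("learning rate must be nonnegative")

    n = batch.shape[0]
    h_pos = expit(batch @ rbm.weights + rbm.hidden_bias)
    v_neg = batch
    h_prob = h_pos
    for _ in range(cd_steps):
        h_sample = (rng.random(h_prob.shape) < h_prob).astype(float)
        v_neg = expit(h_sample @ rbm.weights.T + rbm.visible_bias)
        h_prob = expit(v_neg @ rbm.weights + rbm.hidden_bias)

    dw = (batch.T @ h_pos - v_neg.T @ h_prob) / n
    dvb = (batch - v_neg).mean(axis=0)
    dhb = (h_pos - h_prob).mean(axis=0)
    return RBMParams(
        weights=rbm.weights + lr * dw,
        visible_bias=rbm.visible_bias + lr * dvb,
        hidden_bias=rbm.hidden_bias + lr * dhb,
    )


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _layer_epochs(config: TrainingConfig) -> list[int]:
    if config.epoch_allocation == "per_layer":
        return [config.pretrain_epochs] * config.n_layers
    base, extra = divmod(config.pretrain_epochs, config.n_layers)
    return [base + (1 if i < extra else 0) for i in range(config.n_layers)]


def pretrain(
    data: np.ndarray,
    dims: Sequence[int] | None = None,
    config: TrainingConfig = TrainingConfig(),
) -> list[RBMParams]:
    """Greedy layer-wise unsupervised pretraining of the RBM stack.

    Layer 1 trains on the raw encoded vectors; each subsequent layer trains
    on the previous layer's hidden activation probabilities.  ``dims`` gives
    the hidden widths (default: input width repeated, matching the design of
    one equal-width RBM per input node).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("pretrain requires a non-empty 2-D data matrix")
    if dims is None:
        dims = [data.shape[1]] * config.n_layers
    dims = list(dims)
    if len(dims) != config.n_layers:
        raise ValueError(f"expected {config.n_layers} hidden widths, got {len(dims)}")

    rng = np.random.default_rng(config.seed)
    stack: list[RBMParams] = []
    layer_input = data
    for hidden_dim, epochs in zip(dims, _layer_epochs(config)):
        rbm = init_rbm(layer_input.shape[1], hidden_dim, rng)
        for _ in range(epochs):
            for idx in _minibatches(layer_input.shape[0], config.batch_size, rng):
                rbm = cd_update(rbm, layer_input[idx], config.pretrain_lr, config.cd_steps, rng)
        stack.append(rbm)
        layer_input = hidden_activation(rbm, layer_input)
    return stack


def _forward(stack: Sequence[RBMParams], head_w: np.ndarray, head_b: np.ndarray, x: np.ndarray):
    """Deterministic probability propagation; returns all layer activations."""
    activations = [x]
    a = x
    for rbm in stack:
        a = expit(a @ rbm.weights + rbm.hidden_bias)
        activations.append(a)
    out = expit(a @ head_w + head_b)
    return activations, out


def _one_hot_targets(labels: Sequence[Label]) -> np.ndarray:
    t = np.zeros((len(labels), 2))
    for i, lab in enumerate(labels):
        t[i, 0 if lab == Label.OCD else 1] = 1.0
    return t


def finetune(
    stack: Sequence[RBMParams],
    data: np.ndarray,
    labels: Sequence[Label],
    config: TrainingConfig = TrainingConfig(),
    feature_name: str = "initial_psa",
) -> DBNClassifier:
    """Supervised fine-tuning: attach a 2-unit logistic head and backpropagate.

    Minimises the summed binary cross-entropy of the two head units against
    one-hot OCD/NOCD targets.  By default gradients flow through every RBM
    layer; set ``config.freeze_stack`` to train the head alone.  With
    ``finetune_epochs=0`` the head is left at its random initialisation and
    the stack is returned untouched.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or len(data) != len(labels) or len(labels) == 0:
        raise ValueError("finetune requires matching non-empty data and labels")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    weights = [np.array(r.weights) for r in stack]
    biases = [np.array(r.hidden_bias) for r in stack]
    top_dim = stack[-1].hidden_dim if stack else data.shape[1]
    head_w = rng.normal(0.0, 0.01, size=(top_dim, 2))
    head_b = np.zeros(2)
    targets = _one_hot_targets(list(labels))

    losses: list[float] = []
    for _ in range(config.finetune_epochs):
        epoch_loss = 0.0
        for idx in _minibatches(len(data), config.batch_size, rng):
            x, t = data[idx], targets[idx]
            acts = [x]
            a = x
            for w, b in zip(weights, biases):
                a = expit(a @ w + b)
                acts.append(a)
            y = expit(a @ head_w + head_b)

            eps = 1e-12
            epoch_loss += float(-(t * np.log(y + eps) + (1 - t) * np.log(1 - y + eps)).sum())

            n = len(idx)
            delta = (y - t) / n  # d(mean summed BCE)/d(head logits)
            g_head_w = acts[-1].T @ delta
            g_head_b = delta.sum(axis=0)
            if not config.freeze_stack:
                da = delta @ head_w.T
                grads_w, grads_b = [], []
                for k in range(len(weights) - 1, -1, -1):
                    dz = da * acts[k + 1] * (1 - acts[k + 1])
                    grads_w.append(acts[k].T @ dz)
                    grads_b.append(dz.sum(axis=0))
                    da = dz @ weights[k].T
                for k, (gw, gb) in enumerate(zip(reversed(grads_w), reversed(grads_b))):
                    weights[k] -= config.finetune_lr * gw
                    biases[k] -= config.finetune_lr * gb
            head_w -= config.finetune_lr * g_head_w
            head_b -= config.finetune_lr * g_head_b
        losses.append(epoch_loss / len(data))

    new_stack = tuple(
        replace(r, weights=w, hidden_bias=b) for r, w, b in zip(stack, weights, biases)
    )
    return DBNClassifier(
        rbm_layers=new_stack,
        head_weights=head_w,
        head_bias=head_b,
        feature_name=feature_name,
        config=config,
        training_loss=tuple(losses),
    )


def train_dbn(
    data: np.ndarray,
    labels: Sequence[Label],
    config: TrainingConfig = TrainingConfig(),
    feature_name: str = "initial_psa",
) -> DBNClassifier:
    """Pretrain the stack and fine-tune the full network in one call."""
    stack = pretrain(data, None, config)
    return finetune(stack, data, labels, config, feature_name)


def predict_proba(model: DBNClassifier, x: np.ndarray) -> np.ndarray:
    """Per-unit logistic scores (p_OCD, p_NOCD) for one vector or a batch.

    Probabilities are propagated deterministically (no sampling); the two
    outputs each lie in [0, 1] but need not sum to 1.
    """
    xb, single = _as_batch(x, model.visible_dim, "predict_proba")
    _, out = _forward(model.rbm_layers, model.head_weights, model.head_bias, xb)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# serialization — a self-describing JSON archive with bit-exact round-trip

def _array_to_json(a: np.ndarray) -> dict:
    return {"shape": list(a.shape), "data": [v.hex() for v in a.ravel()]}


def _array_from_json(d: dict) -> np.ndarray:
    return np.array([float.fromhex(v) for v in d["data"]], dtype=float).reshape(d["shape"])


def save_classifier(model: DBNClassifier, path: str | Path) -> None:
    """Serialise to JSON; float64 values are stored as hex for exactness."""
    doc = {
        "format": "prostage-dbn",
        "version": 1,
        "feature_name": model.feature_name,
        "layers": [
            {
                "weights": _array_to_json(r.weights),
                "visible_bias": _array_to_json(r.visible_bias),
                "hidden_bias": _array_to_json(r.hidden_bias),
            }
            for r in model.rbm_layers
        ],
        "head_weights": _array_to_json(model.head_weights),
        "head_bias": _array_to_json(model.head_bias),
        "config": asdict(model.config) if model.config else None,
        "training_loss": list(model.training_loss),
    }
    Path(path).write_text(json.dumps(doc))


def load_classifier(path: str | Path) -> DBNClassifier:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "prostage-dbn":
        raise ValueError(f"{path} is not a DBN classifier archive")
    return DBNClassifier(
        rbm_layers=tuple(
            RBMParams(
                weights=_array_from_json(l["weights"]),
                visible_bias=_array_from_json(l["visible_bias"]),
                hidden_bias=_array_from_json(l["hidden_bias"]),
            )
            for l in doc["layers"]
        ),
        head_weights=_array_from_json(doc["head_weights"]),
        head_bias=_array_from_json(doc["head_bias"]),
        feature_name=doc["feature_name"],
        config=TrainingConfig(**doc["config"]) if doc["config"] else None,
        training_loss=tuple(doc.get("training_loss", ())),
    )
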