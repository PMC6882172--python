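"""Stacked residual big blocks with attention, dropout and a softmax head.

The network consumes one dimer's ordered pair-feature matrix (L x 18) as a
sequence of length L and emits per-pair interface probabilities (L x 2,
class 1 = interface).  Architecture: inverted input dropout -> stacked LSTM
layers paired into residual big blocks (inverted dropout on every
non-recurrent layer-to-layer feed; recurrent connections and the residual
shortcut are never dropped) -> additive self-attention over the sequence ->
per-position dense layer with softmax.

The attention scores each timestep with e_t = v . tanh(A h_t), normalizes
with a softmax over timesteps, and rescales the sequence by T * w_t so that
a uniform weighting is the identity and per-position outputs are preserved.

All gradients are hand-derived (see :mod:`ppilstm.recurrent`); training uses
Adam by default with plain SGD available.  Cross-entropy is weighted by
inverse class frequency by default to cope with the extreme interface /
non-interface imbalance; pass ``class_weight=None`` for the plain loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import recurrent as R
from .exceptions import ConfigurationError, TrainingError, ValidationError

__all__ = [
    "softmax",
    "categorical_crossentropy",
    "AttentionParams",
    "attention_forward",
    "NetworkConfig",
    "TrainingConfig",
    "OutputHead",
    "NetworkParams",
    "init_network",
    "model_forward",
    "model_backward",
    "sequence_loss",
    "train_model",
    "evaluate_scores",
    "grid_search_layers_units",
    "GridSearchResult",
]

PROB_FLOOR = 1e-12   # floor inside the log of the cross-entropy


# ---------------------------------------------------------------------------
# Softmax and cross-entropy
# ---------------------------------------------------------------------------

def softmax(z) -> np.ndarray:
    """Shift-invariant softmax: sigma(z)_j = exp(z_j) / sum_k exp(z_k),
    computed as exp(z - logsumexp(z)) along the last axis."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValidationError("softmax of an empty vector")
    if not np.all(np.isfinite(z)):
        raise ValidationError("softmax input contains non-finite entries")
    return np.exp(z - logsumexp(z, axis=-1, keepdims=True))


def categorical_crossentropy(p_true, q_est) -> float:
    """H(p, q) = -sum_j p_j ln q_j (natural log), with q floored at 1e-12.

    Equals H(p) + D_KL(p || q), i.e. it is minimized (at the entropy of p)
    exactly when the estimate matches the true distribution.
    """
    p = np.asarray(p_true, dtype=float)
    q = np.asarray(q_est, dtype=float)
    if p.shape != q.shape:
        raise ValidationError(f"distribution length mismatch: {p.shape} vs {q.shape}")
    for name, v in (("p_true", p), ("q_est", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValidationError(f"{name} does not sum to 1 (sum={v.sum()!r})")
    return float(-(p * np.log(np.maximum(q, PROB_FLOOR))).sum())


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """Additive self-attention scoring weights: ``score_map`` (a x n) and
    scoring vector ``v`` (length a), giving e_t = v . tanh(score_map h_t)."""

    score_map: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.score_map = np.asarray(self.score_map, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.score_map.ndim != 2 or self.v.shape != (self.score_map.shape[0],):
            raise ConfigurationError("attention score_map must be (a, n) with v of length a")

    def named_arrays(self) -> dict[str, np.ndarray]:
        return {"score_map": self.score_map, "v": self.v}


@dataclass
class _AttentionCache:
    hidden: np.ndarray   # (T, n)
    u: np.ndarray        # (T, a) tanh(A h_t)
    weights: np.ndarray  # (T,)


def attention_forward(hidden_sequence, params: AttentionParams,
                      return_cache: bool = False):
    """Score, normalize and reweight a hidden sequence.

    Returns ``(weights, reweighted)`` where ``weights`` is the softmax of the
    per-timestep energies (nonnegative, summing to 1) and
    ``reweighted[t] = T * weights[t] * hidden[t]`` — an all-equal weighting
    leaves the sequence unchanged.
    """
    H = np.asarray(hidden_sequence, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValidationError("hidden_sequence must be a non-empty (T, n) matrix")
    if H.shape[1] != params.score_map.shape[1]:
        raise ValidationError("hidden width does not match attention score_map")
    u = np.tanh(H @ params.score_map.T)            # (T, a)
    energies = u @ params.v                        # (T,)
    weights = softmax(energies)
    reweighted = H.shape[0] * weights[:, None] * H
    if return_cache:
        return weights, reweighted, _AttentionCache(hidden=H, u=u, weights=weights)
    return weights, reweighted


def _attention_backward(cache: _AttentionCache, params: AttentionParams, d_out):
    """Gradients of the attention output w.r.t. its weights and its input."""
    H, u, w = cache.hidden, cache.u, cache.weights
    T = H.shape[0]
    d_hidden = T * w[:, None] * d_out
    d_w = T * np.einsum("ti,ti->t", d_out, H)          # dL/dw_t
    d_e = w * (d_w - float(w @ d_w))                    # softmax Jacobian
    d_v = u.T @ d_e
    d_pre = (1.0 - u ** 2) * params.v[None, :] * d_e[:, None]   # (T, a)
    d_A = d_pre.T @ H
    d_hidden = d_hidden + d_pre @ params.score_map
    return {"score_map": d_A, "v": d_v}, d_hidden


# ---------------------------------------------------------------------------
# Configuration and parameter containers
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``layers`` LSTM layers are arranged as ``layers // 2`` residual big
    blocks (an odd final layer stands alone without a shortcut).  Dropout
    rates follow the study defaults: 0.15 on the input features, 0.6 on
    non-recurrent connections between stacked layers.
    """

    layers: int = 4
    units: int = 8
    input_size: int = 18
    dropout_in: float = 0.15
    dropout_mid: float = 0.6
    attention: bool = True
    classes: int = 2
    attention_dim: Optional[int] = None
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.layers < 2:
            raise ConfigurationError("need at least 2 LSTM layers")
        if self.units < 1:
            raise ConfigurationError("need at least 1 unit per layer")
        for name in ("dropout_in", "dropout_mid"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ConfigurationError(f"{name}={r} must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "layers", "units", "input_size", "dropout_in", "dropout_mid",
            "attention", "classes", "attention_dim", "init_scale", "seed")}


@dataclass
class TrainingConfig:
    """Optimization hyperparameters (the original study does not state its
    optimizer; Adam is the default here, plain SGD is available)."""

    optimizer: str = "adam"
    learning_rate: float = 0.01
    epochs: int = 100
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    clip_threshold: Optional[float] = None
    class_weight: Optional[str] = "balanced"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ConfigurationError("learning rate must be nonnegative")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class OutputHead:
    """Per-position dense layer (units -> K) followed by a softmax."""

    weights: np.ndarray   # (n, K)
    bias: np.ndarray      # (K,)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.bias.shape != (self.weights.shape[1],):
            raise ConfigurationError("head bias length must equal class count")

    def named_arrays(self) -> dict[str, np.ndarray]:
        return {"weights": self.weights, "bias": self.bias}


@dataclass
class NetworkParams:
    config: NetworkConfig
    layers: list
    attention: Optional[AttentionParams]
    head: OutputHead
    # optional per-feature z-score scaler fitted on the training set; raw
    # physicochemical features span very different magnitudes (areas in
    # tens of A^2, ratios, pKa units) and would saturate the gates otherwise
    feature_mean: Optional[np.ndarray] = None
    feature_std: Optional[np.ndarray] = None

    def named_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.named_arrays().items():
                out[f"layer{i}.{k}"] = v
        if self.attention is not None:
            for k, v in self.attention.named_arrays().items():
                out[f"attention.{k}"] = v
        for k, v in self.head.named_arrays().items():
            out[f"head.{k}"] = v
        return out


def init_network(config: NetworkConfig) -> NetworkParams:
    """Seeded uniform U(-scale, scale) initialization of the whole network."""
    rng = np.random.default_rng(config.seed)
    layers = []
    in_size = config.input_size
    for _ in range(config.layers):
        layers.append(R.init_lstm_layer(in_size, config.units, rng,
                                        scale=config.init_scale))
        in_size = config.units
    attention = None
    if config.attention:
        a = config.attention_dim or config.units
        attention = AttentionParams(
            score_map=rng.uniform(-config.init_scale, config.init_scale,
                                  size=(a, config.units)),
            v=rng.uniform(-config.init_scale, config.init_scale, size=a))
    head = OutputHead(
        weights=rng.uniform(-config.init_scale, config.init_scale,
                            size=(config.units, config.classes)),
        bias=np.zeros(config.classes))
    return NetworkParams(config=config, layers=layers, attention=attention, head=head)


# ---------------------------------------------------------------------------
# Forward / backward through the whole network
# ---------------------------------------------------------------------------

@dataclass
class _ModelCache:
    masks: Optional[list]
    stack_trace: R.StackTrace
    attn_cache: Optional[_AttentionCache]
    attended: np.ndarray
    probs: np.ndarray


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> Optional[np.ndarray]:
    if rate <= 0.0:
        return None
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(float) / keep


def model_forward(params: NetworkParams, dimer_matrix, train_mode: bool = False,
                  rng: "int | np.random.Generator | None" = None,
                  return_cache: bool = False):
    """Map an L x 18 pair-feature matrix to L x 2 class probabilities.

    In evaluation mode (default) the pass is deterministic and applies no
    dropout rescaling (inverted dropout is used at train time).  In train
    mode the dropout masks are drawn from ``rng`` (a seed or Generator), so
    a fixed seed replays identical masks.
    """
    cfg = params.config
    X = np.asarray(dimer_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != cfg.input_size:
        raise ValidationError(
            f"dimer matrix must be (L, {cfg.input_size}), got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("dimer matrix contains non-finite values")
    if params.feature_mean is not None:
        X = (X - params.feature_mean) / params.feature_std
    T = X.shape[0]

    masks = None
    if train_mode and (cfg.dropout_in > 0 or cfg.dropout_mid > 0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        masks = [_dropout_mask(rng, (T, cfg.input_size), cfg.dropout_in)]
        for _ in range(1, cfg.layers):
            masks.append(_dropout_mask(rng, (T, cfg.units), cfg.dropout_mid))

    st = R.stack_forward(params.layers, X, residual=True, masks=masks)
    if params.attention is not None:
        _, attended, attn_cache = attention_forward(st.output, params.attention,
                                                    return_cache=True)
    else:
        attended, attn_cache = st.output, None
    logits = attended @ params.head.weights + params.head.bias
    probs = softmax(logits)
    if return_cache:
        return probs, _ModelCache(masks=masks, stack_trace=st,
                                  attn_cache=attn_cache, attended=attended,
                                  probs=probs)
    return probs


def model_backward(params: NetworkParams, cache: _ModelCache,
                   dlogits) -> dict[str, np.ndarray]:
    """Hand-derived backward pass given dL/dlogits per position; returns a
    gradient dict keyed like :meth:`NetworkParams.named_arrays`."""
    dlogits = np.asarray(dlogits, dtype=float)
    grads: dict[str, np.ndarray] = {}
    grads["head.weights"] = cache.attended.T @ dlogits
    grads["head.bias"] = dlogits.sum(axis=0)
    d_attended = dlogits @ params.head.weights.T
    if params.attention is not None:
        attn_grads, d_hidden = _attention_backward(cache.attn_cache,
                                                   params.attention, d_attended)
        for k, v in attn_grads.items():
            grads[f"attention.{k}"] = v
    else:
        d_hidden = d_attended
    per_layer, _ = R.stack_backward(params.layers, cache.stack_trace, d_hidden,
                                    residual=True, masks=cache.masks)
    for i, g in enumerate(per_layer):
        for k, v in g.items():
            grads[f"layer{i}.{k}"] = v
    return grads


def sequence_loss(probs: np.ndarray, labels: np.ndarray,
                  class_weight: Optional[str] = None
                  ) -> tuple[float, np.ndarray]:
    """Mean (optionally class-weighted) cross-entropy over the sequence and
    its gradient with respect to the logits (softmax + CE combined)."""
    labels = np.asarray(labels, dtype=int)
    T, K = probs.shape
    onehot = np.eye(K)[labels]
    if class_weight == "balanced":
        counts = np.bincount(labels, minlength=K).astype(float)
        w_class = np.where(counts > 0, T / (np.count_nonzero(counts) * np.maximum(counts, 1)), 0.0)
        w = w_class[labels]
    else:
        w = np.ones(T)
    norm = w.sum()
    logq = np.log(np.maximum(probs, PROB_FLOOR))
    loss = float(-(w[:, None] * onehot * logq).sum() / norm)
    dlogits = (w[:, None] * (probs - onehot)) / norm
    return loss, dlogits


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _as_examples(dataset) -> list:
    """Normalize a dataset into (id, matrix, labels, tnrp) tuples.  Accepts
    DimerPairSet-like objects (with .dimer_id/.matrix()/.labels()/.tnrp) or
    plain (matrix, labels) tuples."""
    out = []
    for i, item in enumerate(dataset):
        if hasattr(item, "matrix") and hasattr(item, "labels"):
            out.append((getattr(item, "dimer_id", f"dimer{i}"),
                        np.asarray(item.matrix(), dtype=float),
                        np.asarray(item.labels(), dtype=int),
                        int(getattr(item, "tnrp", len(item.labels())))))
        else:
            X, y = item
            X = np.asarray(X, dtype=float)
            y = np.asarray(y, dtype=int)
            out.append((f"dimer{i}", X, y, len(y)))
    return out


def _validation_mean_accuracy_order(params, examples) -> float:
    """Mean RFPP/TNRP (as a fraction) over dimers, in evaluation mode."""
    from .metrics import rank_pairs
    vals = []
    for _, X, y, tnrp in examples:
        probs = model_forward(params, X)
        rep = rank_pairs(probs[:, 1], y, tnrp=tnrp)
        rfpp = min(rep.rfpp, tnrp)  # sentinel (no positive) counts as worst
        vals.append(rfpp / tnrp)
    return float(np.mean(vals)) if vals else float("nan")


@dataclass
class TrainResult:
    params: NetworkParams
    best_params: NetworkParams
    history: pd.DataFrame


def train_model(config: NetworkConfig, training: TrainingConfig,
                train_set, validation_set=None,
                params: Optional[NetworkParams] = None) -> TrainResult:
    """Minimize the per-dimer mean cross-entropy with Adam (or SGD).

    One dimer is one training sequence; each epoch visits every training
    dimer in a seeded shuffled order and applies one parameter update per
    dimer.  The checkpoint with the best validation mean accuracy order is
    retained alongside the final parameters.
    """
    train_examples = _as_examples(train_set)
    if not train_examples:
        raise ValidationError("empty training set")
    val_examples = _as_examples(validation_set) if validation_set else []

    if params is None:
        params = init_network(config)
    if training.standardize and params.feature_mean is None:
        stacked = np.vstack([X for _, X, _, _ in train_examples])
        params.feature_mean = stacked.mean(axis=0)
        params.feature_std = np.maximum(stacked.std(axis=0), 1e-8)
    arrays = params.named_arrays()
    rng = np.random.default_rng(training.seed)

    m = {k: np.zeros_like(v) for k, v in arrays.items()}
    v2 = {k: np.zeros_like(va) for k, va in arrays.items()}
    step = 0
    best_val = np.inf
    best_params = copy.deepcopy(params)
    rows = []
    for epoch in range(1, training.epochs + 1):
        order = rng.permutation(len(train_examples))
        losses = []
        for idx in order:
            _, X, y, _ = train_examples[idx]
            probs, cache = model_forward(params, X, train_mode=True, rng=rng,
                                         return_cache=True)
            loss, dlogits = sequence_loss(probs, y,
                                          class_weight=training.class_weight)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or enable gradient clipping")
            losses.append(loss)
            grads = model_backward(params, cache, dlogits)
            if training.clip_threshold is not None:
                total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
                if total > training.clip_threshold:
                    scale = training.clip_threshold / total
                    grads = {k: g * scale for k, g in grads.items()}
            step += 1
            if training.optimizer == "adam":
                b1, b2 = training.beta1, training.beta2
                for k, arr in arrays.items():
                    g = grads[k]
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v2[k] = b2 * v2[k] + (1 - b2) * g * g
                    mhat = m[k] / (1 - b1 ** step)
                    vhat = v2[k] / (1 - b2 ** step)
                    arr -= training.learning_rate * mhat / (np.sqrt(vhat) + training.adam_eps)
            else:
                for k, arr in arrays.items():
                    arr -= training.learning_rate * grads[k]
        val_metric = (_validation_mean_accuracy_order(params, val_examples)
                      if val_examples else np.nan)
        if val_examples and val_metric < best_val:
            best_val = val_metric
            best_params = copy.deepcopy(params)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_mean_accuracy_order": val_metric})
    if not val_examples:
        best_params = copy.deepcopy(params)
    return TrainResult(params=params, best_params=best_params,
                       history=pd.DataFrame(rows))


def evaluate_scores(params: NetworkParams, dataset) -> list:
    """Score every dimer in evaluation mode; returns (id, scores, labels,
    tnrp) tuples with scores = predicted interface probability per pair."""
    out = []
    for did, X, y, tnrp in _as_examples(dataset):
        probs = model_forward(params, X)
        out.append((did, probs[:, 1], y, tnrp))
    return out


# ---------------------------------------------------------------------------
# Two-stage grid search over layer and unit counts
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    ranked: list                 # [((layers, units), mean_accuracy_order), ...] ascending
    best: tuple                  # (layers, units)
    table: pd.DataFrame          # dimers as rows, configs as columns, mean row last


def grid_search_layers_units(layer_candidates: Sequence[int],
                             unit_candidates: Sequence[int],
                             data: dict, training: TrainingConfig,
                             base_config: Optional[NetworkConfig] = None,
                             objective: Optional[Callable] = None
                             ) -> GridSearchResult:
    """Coarse-then-neighborhood search over depth, then width.

    Stage 1 sweeps ``layer_candidates`` at the first unit count; stage 2
    refines the immediate neighbors of the best depth; stage 3 sweeps
    ``unit_candidates`` at the best depth.  Configurations are ranked by
    mean validation accuracy order (lower is better).  ``objective`` may
    inject a scoring function (layers, units) -> mean accuracy order (or
    (mean, per-dimer list)) in place of actual training — used for testing
    the search logic itself.
    """
    if not layer_candidates or not unit_candidates:
        raise ValidationError("candidate lists must be non-empty")
    if objective is None and (not data or not data.get("train")):
        raise ValidationError("empty data")
    base = base_config or NetworkConfig()

    val_ids = [e[0] for e in _as_examples(data.get("validation", []))] if data else []
    scores: dict[tuple, tuple] = {}

    def evaluate(layers: int, units: int):
        key = (layers, units)
        if key in scores:
            return scores[key][0]
        if objective is not None:
            res = objective(layers, units)
            mean, per_dimer = res if isinstance(res, tuple) else (res, None)
        else:
            cfg = NetworkConfig(layers=layers, units=units,
                                input_size=base.input_size,
                                dropout_in=base.dropout_in,
                                dropout_mid=base.dropout_mid,
                                attention=base.attention,
                                init_scale=base.init_scale, seed=base.seed)
            tr = train_model(cfg, training, data["train"], data.get("validation"))
            ex = _as_examples(data.get("validation") or data["train"])
            from .metrics import rank_pairs
            per_dimer = []
            for _, X, y, tnrp in ex:
                probs = model_forward(tr.best_params, X)
                rep = rank_pairs(probs[:, 1], y, tnrp=tnrp)
                per_dimer.append(min(rep.rfpp, tnrp) / tnrp)
            mean = float(np.mean(per_dimer))
        scores[key] = (float(mean), per_dimer)
        return float(mean)

    units0 = unit_candidates[0]
    stage1 = {m: evaluate(m, units0) for m in layer_candidates}
    best_m = min(stage1, key=stage1.get)
    for m in (best_m - 1, best_m + 1):
        if m >= 2 and m not in stage1:
            evaluate(m, units0)
    best_m = min((k for k in scores if k[1] == units0),
                 key=lambda k: scores[k][0])[0]
    for n in unit_candidates:
        evaluate(best_m, n)

    ranked = sorted(((k, v[0]) for k, v in scores.items()), key=lambda kv: kv[1])
    best = ranked[0][0]

    columns = {}
    n_dimers = max((len(v[1]) for v in scores.values() if v[1] is not None),
                   default=0)
    index = val_ids if len(val_ids) == n_dimers and n_dimers else [
        f"dimer{i}" for i in range(n_dimers)]
    for key, (mean, per_dimer) in sorted(scores.items()):
        col = f"layer_{key[0]}_unit_{key[1]}"
        vals = per_dimer if per_dimer is not None else [np.nan] * n_dimers
        columns[col] = list(vals) + [mean]
    table = pd.DataFrame(columns, index=index + ["mean"])
    return GridSearchResult(ranked=ranked, best=best, table=table)
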