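"""Attention-based multiple-instance learning (AB-MIL) regression.

A patient is a *bag* of tile embeddings with a single patient-level target
vector (the 30 signature scores). A learnable attention module assigns a
softmax-normalized weight to every tile; the weighted sum of tile embeddings
is a patient-level representation fed to a per-signature MLP head.

Two configurations:

* ``single_task`` — one attention module and one MLP head per signature;
* ``multi_task`` — one *shared* attention module per functional group of
  signatures, separate MLP heads per signature within the group.

Training follows a robust-regression recipe: Huber loss (δ = 1), AdamW
(lr 1e-4, weight decay 1e-4), batch size 1 with gradient accumulation over
8 bags, at most 40 epochs with early stopping after 10 epochs without
validation improvement. Targets are z-scored per signature on the training
cohort and de-scaled at prediction time.

The implementation is pure NumPy and fully deterministic under a fixed
seed — same seed, same training log, bit for bit.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bags import TileBag

Params = dict[str, np.ndarray]


@dataclass
class ABMILConfig:
    """Hyperparameters of the AB-MIL regressor."""

    input_dim: int
    attention_hidden_dim: int = 384
    mlp_hidden_dim: int = 256
    mode: str = "multi_task"  # "multi_task" | "single_task"
    attention_kind: str = "gated"  # "gated" | "plain"
    loss_delta: float = 1.0
    lr: float = 1e-4
    weight_decay: float = 1e-4
    grad_accum_batches: int = 8
    max_epochs: int = 40
    patience: int = 10
    val_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.weight_decay <= 0:
            raise ValueError("lr and weight_decay must be positive")
        if self.loss_delta <= 0:
            raise ValueError("Huber delta must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.mode not in ("multi_task", "single_task"):
            raise ValueError(f"unknown mode {self.mode!r}")


def huber_loss(y, yhat, delta: float = 1.0) -> float:
    """Huber loss: ½r² for |r| ≤ δ, δ|r| − ½δ² beyond; mean over elements."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("non-finite residuals")
    a = np.abs(r)
    out = np.where(a <= delta, 0.5 * r**2, delta * a - 0.5 * delta**2)
    return float(np.mean(out))


def _huber_grad(r: np.ndarray, delta: float) -> np.ndarray:
    """d(huber)/dr, elementwise."""
    return np.clip(r, -delta, delta)


def _init_head_params(rng: np.random.Generator, cfg: ABMILConfig) -> Params:
    """One attention module (gated or plain)."""
    d, D = cfg.input_dim, cfg.attention_hidden_dim
    s = np.sqrt(6.0 / (d + D))
    p = {
        "Wv": rng.uniform(-s, s, (d, D)),
        "bv": np.zeros(D),
        "w": rng.uniform(-np.sqrt(6.0 / (D + 1)), np.sqrt(6.0 / (D + 1)), D),
    }
    if cfg.attention_kind == "gated":
        p["Wu"] = rng.uniform(-s, s, (d, D))
        p["bu"] = np.zeros(D)
    return p


def _init_mlp_params(rng: np.random.Generator, cfg: ABMILConfig) -> Params:
    """One signature output head: input -> hidden (ReLU) -> scalar."""
    d, H = cfg.input_dim, cfg.mlp_hidden_dim
    s1 = np.sqrt(6.0 / (d + H))
    return {
        "W1": rng.uniform(-s1, s1, (d, H)),
        "b1": np.zeros(H),
        "w2": rng.uniform(-np.sqrt(6.0 / (H + 1)), np.sqrt(6.0 / (H + 1)), H),
        "b2": np.zeros(1),
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def attention_weights(bag_x: np.ndarray, head: Params, kind: str = "gated") -> np.ndarray:
    """Softmax attention weights over the tiles of one bag.

    Permutation-equivariant: reordering rows of ``bag_x`` reorders the
    weights identically.
    """
    X = np.asarray(bag_x, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("bag must be a non-empty (n_tiles, dim) matrix")
    if not np.isfinite(X).all():
        raise ValueError("bag contains non-finite embeddings")
    V = np.tanh(X @ head["Wv"] + head["bv"])
    if kind == "gated":
        U = _sigmoid(X @ head["Wu"] + head["bu"])
        scores = (V * U) @ head["w"]
    else:
        scores = V @ head["w"]
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


def aggregate(bag_x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Attention-weighted sum of tile embeddings -> one slide-level vector."""
    X = np.asarray(bag_x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != X.shape[0]:
        raise ValueError("weights length must match number of tiles")
    return w @ X


@dataclass
class TrainedModel:
    """A fitted AB-MIL regressor (attention heads + per-signature MLPs + scaling)."""

    config: ABMILConfig
    signature_names: tuple[str, ...]
    groups: dict[str, tuple[str, ...]]  # head label -> member signatures
    attention_params: dict[str, Params]  # head label -> params
    head_params: dict[str, Params]       # signature -> params
    target_mean: np.ndarray
    target_sd: np.ndarray
    training_log: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as f:
            pickle.dump(self, f)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path, "rb") as f:
            return pickle.load(f)


def _build_groups(
    signature_names: Sequence[str],
    groups: Mapping[str, Sequence[str]] | None,
    mode: str,
) -> dict[str, tuple[str, ...]]:
    names = list(signature_names)
    if mode == "single_task":
        return {n: (n,) for n in names}
    if groups is None:
        raise ValueError("multi_task mode requires a group partition")
    out: dict[str, tuple[str, ...]] = {}
    seen: list[str] = []
    for label, members in groups.items():
        mem = tuple(m for m in names if m in set(members))
        if not mem:
            raise ValueError(f"group {label!r} has no member signatures")
        out[label] = mem
        seen.extend(mem)
    if sorted(seen) != sorted(names):
        raise ValueError("groups must partition the signature set exactly")
    return out


def _forward_group(X: np.ndarray, att: Params, heads: list[Params], kind: str):
    """Forward pass of one attention head + its signature heads; returns cache."""
    V_pre = X @ att["Wv"] + att["bv"]
    V = np.tanh(V_pre)
    if kind == "gated":
        U = _sigmoid(X @ att["Wu"] + att["bu"])
        G = V * U
    else:
        U = None
        G = V
    s = G @ att["w"]
    s = s - s.max()
    e = np.exp(s)
    p = e / e.sum()
    h = p @ X
    outs, caches = [], []
    for hp in heads:
        z_pre = h @ hp["W1"] + hp["b1"]
        z = np.maximum(z_pre, 0.0)
        yhat = float(z @ hp["w2"] + hp["b2"][0])
        outs.append(yhat)
        caches.append((z_pre, z))
    return np.array(outs), {"V": V, "U": U, "G": G, "p": p, "h": h, "heads": caches}


def _backward_group(
    X: np.ndarray,
    att: Params,
    heads: list[Params],
    cache: dict,
    g_out: np.ndarray,
    kind: str,
    g_att: Params,
    g_heads: list[Params],
) -> None:
    """Accumulate gradients for one group given d(loss)/d(yhat_j) = g_out."""
    p, h = cache["p"], cache["h"]
    dh = np.zeros_like(h)
    for hp, gh, (z_pre, z), gy in zip(heads, g_heads, cache["heads"], g_out):
        dz = (gy * hp["w2"]) * (z_pre > 0)
        gh["w2"] += gy * z
        gh["b2"] += gy
        gh["W1"] += np.outer(h, dz)
        gh["b1"] += dz
        dh += hp["W1"] @ dz
    dp = X @ dh
    ds = p * (dp - p @ dp)
    G, V, U = cache["G"], cache["V"], cache["U"]
    g_att["w"] += G.T @ ds
    dG = np.outer(ds, att["w"])
    if kind == "gated":
        dV = dG * U
        dU = dG * V
        dB = dU * U * (1.0 - U)
        g_att["Wu"] += X.T @ dB
        g_att["bu"] += dB.sum(axis=0)
    else:
        dV = dG
    dA = dV * (1.0 - V**2)
    g_att["Wv"] += X.T @ dA
    g_att["bv"] += dA.sum(axis=0)


class _AdamW:
    """Decoupled weight-decay Adam over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, w in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            wd = 0.0 if k.rsplit("/", 1)[-1].startswith("b") else self.wd  # no decay on biases
            w -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + wd * w)


def _flatten_params(model: TrainedModel) -> dict[str, np.ndarray]:
    flat = {}
    for label, p in model.attention_params.items():
        for k, v in p.items():
            flat[f"att/{label}/{k}"] = v
    for sig, p in model.head_params.items():
        for k, v in p.items():
            flat[f"head/{sig}/{k}"] = v
    return flat


def _bag_loss_and_grads(model: TrainedModel, X: np.ndarray, y_scaled: np.ndarray,
                        grads: dict[str, np.ndarray] | None) -> float:
    """Loss (and, if grads given, accumulated gradients) for one bag."""
    cfg = model.config
    names = model.signature_names
    idx = {n: i for i, n in enumerate(names)}
    total = 0.0
    m_total = len(names)
    for label, members in model.groups.items():
        att = model.attention_params[label]
        heads = [model.head_params[s] for s in members]
        outs, cache = _forward_group(X, att, heads, cfg.attention_kind)
        y = np.array([y_scaled[idx[s]] for s in members])
        r = y - outs
        a = np.abs(r)
        d = cfg.loss_delta
        total += float(np.sum(np.where(a <= d, 0.5 * r**2, d * a - 0.5 * d**2)))
        if grads is not None:
            g_out = -_huber_grad(r, d) / m_total  # d(mean huber)/d(yhat)
            g_att = {k: grads[f"att/{label}/{k}"] for k in att}
            g_heads = [{k: grads[f"head/{s}/{k}"] for k in model.head_params[s]} for s in members]
            _backward_group(X, att, heads, cache, g_out, cfg.attention_kind, g_att, g_heads)
    return total / m_total


def train_abmil(
    train_bags: Sequence[TileBag],
    train_profiles: pd.DataFrame,
    config: ABMILConfig,
    groups: Mapping[str, Sequence[str]] | None = None,
    val_bags: Sequence[TileBag] | None = None,
    val_profiles: pd.DataFrame | None = None,
) -> TrainedModel:
    """Fit the AB-MIL regressor.

    ``train_profiles`` is a samples x signatures DataFrame indexed by patient
    id. Targets are z-scored per signature on the training cohort; the stats
    are stored in the model and undone at prediction. When no explicit
    validation set is given, a seeded ``val_frac`` split of the training
    patients is held out for early stopping. The model state from the best
    validation epoch is returned.
    """
    cfg = config
    if len(train_bags) == 0:
        raise ValueError("empty training set")
    names = tuple(train_profiles.columns)
    group_map = _build_groups(names, groups, cfg.mode)
    rng = np.random.default_rng(cfg.seed)

    if val_bags is None:
        n_val = max(1, int(round(cfg.val_frac * len(train_bags))))
        if len(train_bags) - n_val < 1:
            raise ValueError("training set too small to split off validation patients")
        order = rng.permutation(len(train_bags))
        val_idx = set(order[:n_val].tolist())
        val_bags = [b for i, b in enumerate(train_bags) if i in val_idx]
        train_bags = [b for i, b in enumerate(train_bags) if i not in val_idx]
        val_profiles = train_profiles.loc[[b.patient_id for b in val_bags]]
        train_profiles = train_profiles.loc[[b.patient_id for b in train_bags]]
    elif val_profiles is None or len(val_bags) == 0:
        raise ValueError("val_bags given without val_profiles (or empty)")

    for b in list(train_bags) + list(val_bags):
        if b.dim != cfg.input_dim:
            raise ValueError(f"bag {b.patient_id}: dim {b.dim} != config.input_dim {cfg.input_dim}")

    mu = train_profiles.mean(axis=0).to_numpy()
    sd = train_profiles.std(axis=0, ddof=0).to_numpy()
    sd = np.where(sd > 1e-12, sd, 1.0)

    model = TrainedModel(
        config=cfg,
        signature_names=names,
        groups=group_map,
        attention_params={g: _init_head_params(rng, cfg) for g in group_map},
        head_params={s: _init_mlp_params(rng, cfg) for s in names},
        target_mean=mu,
        target_sd=sd,
    )
    flat = _flatten_params(model)
    opt = _AdamW(flat, lr=cfg.lr, weight_decay=cfg.weight_decay)

    y_train = {b.patient_id: (train_profiles.loc[b.patient_id].to_numpy() - mu) / sd for b in train_bags}
    y_val = {b.patient_id: (val_profiles.loc[b.patient_id].to_numpy() - mu) / sd for b in val_bags}
    xs_train = {b.patient_id: b.embeddings.astype(np.float64) for b in train_bags}
    xs_val = {b.patient_id: b.embeddings.astype(np.float64) for b in val_bags}

    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_bags))
        grads = {k: np.zeros_like(v) for k, v in flat.items()}
        n_acc = 0
        train_loss = 0.0
        for j, i in enumerate(order):
            b = train_bags[i]
            train_loss += _bag_loss_and_grads(model, xs_train[b.patient_id], y_train[b.patient_id], grads)
            n_acc += 1
            if n_acc == cfg.grad_accum_batches or j == len(order) - 1:
                for k in grads:
                    grads[k] /= n_acc
                opt.step(grads)
                for k in grads:
                    grads[k][...] = 0.0
                n_acc = 0
        train_loss /= len(train_bags)
        val_loss = sum(
            _bag_loss_and_grads(model, xs_val[b.patient_id], y_val[b.patient_id], None)
            for b in val_bags
        ) / len(val_bags)
        model.training_log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in flat.items()}
            model.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_state is not None:
        for k, v in flat.items():
            v[...] = best_state[k]
    return model


def predict_signatures(model: TrainedModel, bag: TileBag):
    """Predict all signature scores for one bag, plus per-head attention maps.

    Returns ``(scores, attention)`` where ``scores`` is a pandas Series over
    the signature names in canonical order (de-scaled to the training-target
    scale) and ``attention`` maps each head label to its per-tile weight
    vector aligned with ``bag.coords``.
    """
    cfg = model.config
    if bag.dim != cfg.input_dim:
        raise ValueError(f"bag dim {bag.dim} != model input dim {cfg.input_dim}")
    X = bag.embeddings.astype(np.float64)
    idx = {n: i for i, n in enumerate(model.signature_names)}
    raw = np.zeros(len(model.signature_names))
    attention: dict[str, np.ndarray] = {}
    for label, members in model.groups.items():
        att = model.attention_params[label]
        heads = [model.head_params[s] for s in members]
        outs, cache = _forward_group(X, att, heads, cfg.attention_kind)
        attention[label] = cache["p"]
        for s, v in zip(members, outs):
            raw[idx[s]] = v
    scores = raw * model.target_sd + model.target_mean
    return pd.Series(scores, index=list(model.signature_names), name=bag.patient_id), attention


def predict_profile(model: TrainedModel, bags: Sequence[TileBag]) -> pd.DataFrame:
    """Predict a full cohort profile (samples x signatures)."""
    rows = [predict_signatures(model, b)[0] for b in bags]
    return pd.DataFrame(rows)


def evaluate_pearson_ci(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-signature Pearson r with percentile-bootstrap confidence intervals.

    Patients are resampled with replacement ``n_boot`` times; the CI is the
    percentile interval of the resampled correlations. Zero-variance columns
    yield NaN.
    """
    if pred.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    truth = truth.loc[pred.index, pred.columns]
    P = pred.to_numpy(dtype=float)
    T = truth.to_numpy(dtype=float)
    n = P.shape[0]
    rng = np.random.default_rng(seed)

    def _cols_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        den = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, (a * b).sum(axis=0) / den, np.nan)

    r = _cols_r(P, T)
    boots = np.empty((n_boot, P.shape[1]))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[i] = _cols_r(P[idx], T[idx])
    alpha = (1.0 - level) / 2.0
    lo = np.nanpercentile(boots, 100 * alpha, axis=0)
    hi = np.nanpercentile(boots, 100 * (1 - alpha), axis=0)
    return pd.DataFrame({"r": r, "ci_low": lo, "ci_high": hi}, index=pred.columns)
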