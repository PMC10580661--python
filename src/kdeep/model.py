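"""KDeep predictor architectures: CNN-BiLSTM and CNN-attention-BiLSTM.

The layer sequence is

    conv(n_filters, filter_width, valid padding) -> ReLU -> maxpool ->
    dropout -> [additive attention] -> BiLSTM -> dropout ->
    dense(ReLU) -> dense(sigmoid)

operating on encoded strands of shape (rows, input_cols).  Valid (no)
convolution padding is used so that a filter of width F scanning S encoded
rows visits exactly P = S - F + 1 sites.  Outputs are independent sigmoids,
one per target, trained with binary cross-entropy and Adam.

The network is implemented directly in numpy with hand-derived gradients;
the test suite verifies every path against central-difference numerical
gradients.  Padded rows (variable-length batches) are excluded from
convolution sites, pooling, attention and the BiLSTM through the validity
mask.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class ModelConfig:
    """Hyperparameters of a KDeep/KDeep+ model.

    ``use_attention=True`` selects the KDeep+ variant: a single-head additive
    attention block over pooled positions, inserted between the CNN stack and
    the BiLSTM, whose softmax scores are retrievable for heatmaps.
    """

    n_filters: int = 16
    filter_width: int = 16
    pool_size: int = 13
    dropout_cnn: float = 0.2
    dropout_lstm: float = 0.5
    lstm_units: int = 32
    dense_units: int = 128
    n_outputs: int = 1
    use_attention: bool = False
    input_cols: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be >= 1")
        if not (0 <= self.dropout_cnn < 1 and 0 <= self.dropout_lstm < 1):
            raise ValueError("dropout rates must lie in [0, 1)")
        for name in ("n_filters", "filter_width", "pool_size", "lstm_units", "dense_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @classmethod
    def dna(cls, n_outputs: int = 919, **overrides) -> "ModelConfig":
        """DNA-scale configuration: 320 first-layer kernels, 320 LSTM units."""
        base = dict(n_filters=320, lstm_units=320, n_outputs=n_outputs)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def rna(cls, **overrides) -> "ModelConfig":
        """RNA-scale configuration (single binding target)."""
        base = dict(n_filters=16, lstm_units=32, n_outputs=1)
        base.update(overrides)
        return cls(**base)


class KDeepModel:
    """A built (possibly trained) predictor with inspectable first-layer filters."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params = _init_params(config)
        self.training_log: list[dict] = []

    @property
    def first_layer_filters(self) -> np.ndarray:
        """First-layer convolution kernels, shape (n_filters, F, input_cols)."""
        cfg = self.config
        return (
            self.params["Wc"]
            .reshape(cfg.filter_width, cfg.input_cols, cfg.n_filters)
            .transpose(2, 0, 1)
            .copy()
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _init_params(cfg: ModelConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    F, C, K, H = cfg.filter_width, cfg.input_cols, cfg.n_filters, cfg.lstm_units
    params = {
        "Wc": _glorot(rng, F * C, K, (F * C, K)),
        "bc": np.zeros(K),
    }
    if cfg.use_attention:
        A = K  # attention hidden width tied to the filter count
        params["Wa"] = _glorot(rng, K, A, (K, A))
        params["ba"] = np.zeros(A)
        params["va"] = _glorot(rng, A, 1, (A,))
    for d in ("f", "b"):
        params[f"Wx_{d}"] = _glorot(rng, K, 4 * H, (K, 4 * H))
        params[f"Wh_{d}"] = _glorot(rng, H, 4 * H, (H, 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        params[f"b_{d}"] = b
    params["W1"] = _glorot(rng, 2 * H, cfg.dense_units, (2 * H, cfg.dense_units))
    params["b1"] = np.zeros(cfg.dense_units)
    params["W2"] = _glorot(rng, cfg.dense_units, cfg.n_outputs, (cfg.dense_units, cfg.n_outputs))
    params["b2"] = np.zeros(cfg.n_outputs)
    return params


def build_model(config: ModelConfig) -> KDeepModel:
    """Construct an untrained model with seed-deterministic initialization."""
    return KDeepModel(config)


def count_trainable_parameters(model: KDeepModel) -> int:
    """Exact number of free parameters across all layers."""
    return int(sum(p.size for p in model.params.values()))


def parameter_breakdown(model: KDeepModel) -> dict[str, int]:
    """Per-parameter-array sizes, for closed-form auditing."""
    return {name: int(p.size) for name, p in model.params.items()}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _lstm_forward(x, step_mask, Wx, Wh, b, reverse: bool):
    """One LSTM direction over (B, T, K) inputs; masked steps carry state."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    order = range(T - 1, -1, -1) if reverse else range(T)
    steps = []
    for t in order:
        m = step_mask[:, t : t + 1].astype(float)
        z = x[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        steps.append(dict(t=t, m=m, i=i, f=f, g=g, o=o, c_prev=c, h_prev=h, c_new=c_new))
        h = m * h_new + (1 - m) * h
        c = m * c_new + (1 - m) * c
    return h, steps


def _lstm_backward(dh_final, steps, x, Wx, Wh):
    """BPTT for one direction; returns (dx, dWx, dWh, db)."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dx = np.zeros_like(x)
    dh = dh_final.copy()
    dc = np.zeros((B, H))
    for st in reversed(steps):
        t, m = st["t"], st["m"]
        i, f, g, o = st["i"], st["f"], st["g"], st["o"]
        c_new, c_prev, h_prev = st["c_new"], st["c_prev"], st["h_prev"]
        dh_new = dh * m
        dh_carry = dh * (1 - m)
        dc_new = dc * m + dh_new * o * (1 - np.tanh(c_new) ** 2)
        dc_carry = dc * (1 - m)
        tanh_c = np.tanh(c_new)
        do = dh_new * tanh_c
        di = dc_new * g
        df = dc_new * c_prev
        dg = dc_new * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
            axis=1,
        )
        dWx += x[:, t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ Wx.T
        dh = dz @ Wh.T + dh_carry
        dc = dc_new * f + dc_carry
    return dx, dWx, dWh, db


def _forward(params, cfg: ModelConfig, X, mask, train: bool = False, drop_rng=None):
    """Full forward pass; returns (probabilities, cache-for-backward)."""
    B, S, C = X.shape
    F, K, pool = cfg.filter_width, cfg.n_filters, cfg.pool_size
    lengths = mask.sum(axis=1)
    if S < F or lengths.min() < F:
        raise ValueError(
            f"filter width {F} exceeds the encoded row count of some strand "
            f"(min valid rows {int(lengths.min())})"
        )
    P = S - F + 1
    # conv via im2col: (B, P, F*C) @ (F*C, K)
    Xw = sliding_window_view(X, F, axis=1).transpose(0, 1, 3, 2).reshape(B, P, F * C)
    pre = Xw @ params["Wc"] + params["bc"]
    act = np.maximum(pre, 0.0)
    site_mask = (np.arange(P)[None, :] + F) <= lengths[:, None]
    T = P // pool
    if T < 1:
        raise ValueError(f"pool_size {pool} exceeds the {P} convolution sites")
    a4 = np.where(site_mask[:, : T * pool, None], act[:, : T * pool], -np.inf).reshape(
        B, T, pool, K
    )
    pool_arg = a4.argmax(axis=2)
    pooled_raw = np.take_along_axis(a4, pool_arg[:, :, None, :], axis=2)[:, :, 0, :]
    step_mask = site_mask[:, : T * pool].reshape(B, T, pool).any(axis=2)
    pooled = np.where(step_mask[:, :, None], pooled_raw, 0.0)

    if train and cfg.dropout_cnn > 0:
        keep1 = (drop_rng.random(pooled.shape) >= cfg.dropout_cnn) / (1 - cfg.dropout_cnn)
    else:
        keep1 = None
    h = pooled if keep1 is None else pooled * keep1

    alpha = tt = None
    if cfg.use_attention:
        u = h @ params["Wa"] + params["ba"]
        tt = np.tanh(u)
        e = tt @ params["va"]
        e = np.where(step_mask, e, -np.inf)
        e = e - e.max(axis=1, keepdims=True)
        w = np.exp(e)
        alpha = w / w.sum(axis=1, keepdims=True)
        h_seq = h * alpha[:, :, None]
    else:
        h_seq = h

    hf, steps_f = _lstm_forward(
        h_seq, step_mask, params["Wx_f"], params["Wh_f"], params["b_f"], reverse=False
    )
    hb, steps_b = _lstm_forward(
        h_seq, step_mask, params["Wx_b"], params["Wh_b"], params["b_b"], reverse=True
    )
    hcat = np.concatenate([hf, hb], axis=1)

    if train and cfg.dropout_lstm > 0:
        keep2 = (drop_rng.random(hcat.shape) >= cfg.dropout_lstm) / (1 - cfg.dropout_lstm)
    else:
        keep2 = None
    hd = hcat if keep2 is None else hcat * keep2

    z1 = hd @ params["W1"] + params["b1"]
    r1 = np.maximum(z1, 0.0)
    z2 = r1 @ params["W2"] + params["b2"]
    y = _sigmoid(z2)
    cache = dict(
        Xw=Xw, pre=pre, site_mask=site_mask, pool_arg=pool_arg, step_mask=step_mask,
        pooled=pooled, keep1=keep1, h=h, alpha=alpha, tt=tt, h_seq=h_seq,
        steps_f=steps_f, steps_b=steps_b, hcat=hcat, keep2=keep2, hd=hd,
        z1=z1, r1=r1, y=y, T=T, P=P,
    )
    return y, cache


def _backward(params, cfg: ModelConfig, cache, dz2):
    """Gradients of the loss w.r.t. every parameter, given dL/dz2."""
    grads = {}
    r1, hd, z1 = cache["r1"], cache["hd"], cache["z1"]
    grads["W2"] = r1.T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    dz1 = (dz2 @ params["W2"].T) * (z1 > 0)
    grads["W1"] = hd.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    dhd = dz1 @ params["W1"].T
    dhcat = dhd if cache["keep2"] is None else dhd * cache["keep2"]

    H = cfg.lstm_units
    h_seq = cache["h_seq"]
    dxf, grads["Wx_f"], grads["Wh_f"], grads["b_f"] = _lstm_backward(
        dhcat[:, :H], cache["steps_f"], h_seq, params["Wx_f"], params["Wh_f"]
    )
    dxb, grads["Wx_b"], grads["Wh_b"], grads["b_b"] = _lstm_backward(
        dhcat[:, H:], cache["steps_b"], h_seq, params["Wx_b"], params["Wh_b"]
    )
    dh_seq = dxf + dxb

    h, alpha, tt = cache["h"], cache["alpha"], cache["tt"]
    if cfg.use_attention:
        dh = dh_seq * alpha[:, :, None]
        dalpha = (dh_seq * h).sum(axis=2)
        de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        grads["va"] = np.einsum("bt,bta->a", de, tt)
        du = de[:, :, None] * params["va"] * (1 - tt ** 2)
        grads["Wa"] = np.einsum("btk,bta->ka", h, du)
        grads["ba"] = du.sum(axis=(0, 1))
        dh = dh + du @ params["Wa"].T
    else:
        dh = dh_seq

    dpooled = dh if cache["keep1"] is None else dh * cache["keep1"]
    dpooled = dpooled * cache["step_mask"][:, :, None]

    B, T, P = dh.shape[0], cache["T"], cache["P"]
    pool, K = cfg.pool_size, cfg.n_filters
    da4 = np.zeros((B, T, pool, K))
    np.put_along_axis(da4, cache["pool_arg"][:, :, None, :], dpooled[:, :, None, :], axis=2)
    dact = np.zeros((B, P, K))
    dact[:, : T * pool] = da4.reshape(B, T * pool, K)
    dpre = dact * (cache["pre"] > 0)
    grads["Wc"] = np.einsum("bpf,bpk->fk", cache["Xw"], dpre)
    grads["bc"] = dpre.sum(axis=(0, 1))
    return grads


def _bce(y: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    yc = np.clip(y, eps, 1 - eps)
    return float(-(labels * np.log(yc) + (1 - labels) * np.log(1 - yc)).mean())


def predict(model: KDeepModel, X, mask, batch_size: int = 512) -> np.ndarray:
    """Deterministic inference (dropout disabled); scores in [0, 1]."""
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if X.shape[:2] != mask.shape:
        raise ValueError(f"tensor {X.shape} and mask {mask.shape} are inconsistent")
    if X.shape[2] != model.config.input_cols:
        raise ValueError(
            f"encoded column count {X.shape[2]} != config.input_cols "
            f"{model.config.input_cols}"
        )
    outs = []
    for start in range(0, X.shape[0], batch_size):
        y, _ = _forward(
            model.params, model.config, X[start : start + batch_size],
            mask[start : start + batch_size], train=False,
        )
        outs.append(y)
    return np.concatenate(outs, axis=0)


def attention_scores(model: KDeepModel, X, mask) -> np.ndarray:
    """Per-strand attention weights over pooled positions (rows sum to 1)."""
    if not model.config.use_attention:
        raise ValueError("model was built without attention (use_attention=False)")
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    _, cache = _forward(model.params, model.config, X, mask, train=False)
    return cache["alpha"]


def train(
    model: KDeepModel,
    X,
    mask,
    labels,
    epochs: int = 10,
    batch_size: int = 64,
    learning_rate: float = 1e-3,
    validation_fraction: float = 0.1,
    patience: int = 5,
) -> KDeepModel:
    """Train in place with Adam on binary cross-entropy.

    A validation split (seeded from the model config) is monitored each
    epoch; the best-validation parameters are restored at the end, and
    training stops early after ``patience`` epochs without improvement.
    Raises on NaN loss or on shape inconsistencies before training starts.
    """
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if labels.shape[0] == 1 and X.shape[0] != 1:
        labels = labels.T
    if labels.shape != (X.shape[0], model.config.n_outputs):
        raise ValueError(
            f"labels {labels.shape} incompatible with {X.shape[0]} strands and "
            f"{model.config.n_outputs} outputs"
        )
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")

    rng = np.random.default_rng(model.config.seed + 7919)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = int(round(validation_fraction * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("validation fraction leaves no training data")

    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_loss = np.inf
    best_params = copy.deepcopy(model.params)
    stale = 0

    def monitored_loss() -> float:
        idx = val_idx if n_val > 0 else tr_idx
        y = predict(model, X[idx], mask[idx])
        return _bce(y, labels[idx])

    for epoch in range(epochs):
        order = rng.permutation(tr_idx)
        train_losses = []
        for start in range(0, len(order), batch_size):
            batch = order[start : start + batch_size]
            y, cache = _forward(
                model.params, model.config, X[batch], mask[batch],
                train=True, drop_rng=rng,
            )
            loss = _bce(y, labels[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            train_losses.append(loss)
            dz2 = (y - labels[batch]) / y.size
            grads = _backward(model.params, model.config, cache, dz2)
            step += 1
            for k, g in grads.items():
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                mhat = m_state[k] / (1 - beta1 ** step)
                vhat = v_state[k] / (1 - beta2 ** step)
                model.params[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps)
        mon = monitored_loss()
        model.training_log.append(
            dict(
                epoch=epoch,
                train_loss=float(np.mean(train_losses)),
                val_loss=mon if n_val > 0 else None,
                monitored_loss=mon,
            )
        )
        if mon < best_loss - 1e-6:
            best_loss = mon
            best_params = copy.deepcopy(model.params)
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    model.params = best_params
    return model


def save_model(model: KDeepModel, path: str | Path) -> None:
    """Persist config, weights and training log to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "config.json", "w") as fh:
        json.dump(asdict(model.config), fh, indent=2)
    np.savez(path / "weights.npz", **model.params)
    with open(path / "training_log.json", "w") as fh:
        json.dump(model.training_log, fh)


def load_model(path: str | Path) -> KDeepModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    cfg_file = path / "config.json"
    if not cfg_file.exists():
        raise FileNotFoundError(f"no model at {path} (missing config.json)")
    with open(cfg_file) as fh:
        config = ModelConfig(**json.load(fh))
    model = KDeepModel(config)
    with np.load(path / "weights.npz") as data:
        model.params = {k: data[k].copy() for k in data.files}
    log_file = path / "training_log.json"
    if log_file.exists():
        with open(log_file) as fh:
            model.training_log = json.load(fh)
    return model
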