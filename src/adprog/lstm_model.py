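"""Shifted many-to-one LSTM network for next-visit stage prediction.

A 2-layer LSTM (100 hidden units per layer by default) consumes a
patient's N encoded visit rows — each carrying the months to the following
visit, the last carrying the user-chosen prediction horizon — and a
softmax head over the layer-2 hidden state at the last real step emits a
probability vector over the five Global CDR stages of the (N+1)-th visit.

The cell follows the standard gate equations: forget/input/output gates
are logistic in W.[h_prev, x] + b, the candidate cell is tanh of the same
form, the cell state is f*C_prev + i*C_tilde, and h = o*tanh(C). Training
minimises a cross-entropy loss with L2 weight regularization; the default
loss sums the binary-style term -(y log p + (1-y) log(1-p)) over all five
softmax components (the study's printed form), with standard categorical
cross-entropy available as a variant. Forward, backward (BPTT) and the
adaptive-moment optimizer are implemented in numpy; gradients are
validated against central finite differences in the test suite.

Padded steps are masked: the hidden and cell states carry through masked
steps unchanged, so the readout is exactly the state at the last real
visit and pad rows can never change a prediction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import EncodedDataset
from .schema import N_STAGES, decode_stage

EPS = 1e-12

LOSS_VARIANTS = ("binary_ce", "categorical_ce")

#: Parameter keys carrying weight matrices (regularized); biases are not.
_GATES = ("Wf", "Wi", "Wc", "Wo")
_BIASES = ("bf", "bi", "bc", "bo")


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are the package's fixture values."""

    hidden: int = 100
    lam: float = 1e-4
    learning_rate: float = 1e-3
    lr_decay: float = 0.95  # exponential decay per epoch
    ema_decay: float = 0.99  # moving average of parameters for evaluation
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    loss_variant: str = "binary_ce"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0 < self.lr_decay <= 1 or not 0 <= self.ema_decay < 1:
            raise ValueError("decay factors out of range")
        if self.loss_variant not in LOSS_VARIANTS:
            raise ValueError(f"loss_variant must be one of {LOSS_VARIANTS}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def init_params(input_width: int, hidden: int = 100, n_layers: int = 2,
                n_classes: int = N_STAGES, seed: int = 0) -> dict[str, np.ndarray]:
    """Initialise gate/head tensors uniformly in +-1/sqrt(fan_in)."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    d = input_width
    for layer in range(n_layers):
        fan_in = hidden + d
        bound = 1.0 / np.sqrt(fan_in)
        for g, b in zip(_GATES, _BIASES):
            params[f"l{layer}_{g}"] = rng.uniform(-bound, bound, (hidden, fan_in))
            params[f"l{layer}_{b}"] = np.zeros(hidden)
        d = hidden
    bound = 1.0 / np.sqrt(hidden)
    params["head_W"] = rng.uniform(-bound, bound, (n_classes, hidden))
    params["head_b"] = np.zeros(n_classes)
    return params


def n_layers_of(params: dict[str, np.ndarray]) -> int:
    return len({k.split("_")[0] for k in params if k.startswith("l")})


def weight_keys(params: dict[str, np.ndarray]) -> list[str]:
    """Keys of regularized tensors: gate and head weight matrices only."""
    return [k for k in params if any(k.endswith(g) for g in _GATES)] + ["head_W"]


# ---------------------------------------------------------------------------
# Forward
# ---------------------------------------------------------------------------


def lstm_cell_forward(x: np.ndarray, h_prev: np.ndarray, C_prev: np.ndarray,
                      cell: dict[str, np.ndarray]):
    """One LSTM cell step; returns (h, C) and the backprop cache.

    ``cell`` maps Wf/Wi/Wc/Wo to (H x (H+D)) matrices and bf/bi/bc/bo to
    length-H biases; ``x`` is (B, D), states are (B, H).
    """
    if x.shape[1] + h_prev.shape[1] != cell["Wf"].shape[1]:
        raise ValueError(
            f"input width {x.shape[1]} + hidden {h_prev.shape[1]} does not "
            f"match gate fan-in {cell['Wf'].shape[1]}"
        )
    a = np.concatenate([h_prev, x], axis=1)
    f = _sigmoid(a @ cell["Wf"].T + cell["bf"])
    i = _sigmoid(a @ cell["Wi"].T + cell["bi"])
    g = np.tanh(a @ cell["Wc"].T + cell["bc"])
    o = _sigmoid(a @ cell["Wo"].T + cell["bo"])
    C = f * C_prev + i * g
    tC = np.tanh(C)
    h = o * tC
    cache = (a, f, i, g, o, C_prev, tC)
    return h, C, cache


def _layer_params(params: dict[str, np.ndarray], layer: int) -> dict[str, np.ndarray]:
    return {k: params[f"l{layer}_{k}"] for k in _GATES + _BIASES}


def forward_pass(X: np.ndarray, mask: np.ndarray, params: dict[str, np.ndarray]):
    """Run the full network; returns (probs, caches, h_final)."""
    if X.ndim != 3:
        raise ValueError("X must be (batch, steps, width)")
    B, T, _ = X.shape
    if T == 0 or mask.sum() == 0:
        raise ValueError("empty sequence batch")
    L = n_layers_of(params)
    H = params["l0_Wf"].shape[0]
    caches: list[list] = [[] for _ in range(L)]
    h = [np.zeros((B, H)) for _ in range(L)]
    C = [np.zeros((B, H)) for _ in range(L)]
    for t in range(T):
        m = mask[:, t][:, None]
        inp = X[:, t, :]
        for layer in range(L):
            cell = _layer_params(params, layer)
            h_full, C_full, cache = lstm_cell_forward(inp, h[layer], C[layer], cell)
            # masked steps carry state through unchanged
            h_new = m * h_full + (1 - m) * h[layer]
            C_new = m * C_full + (1 - m) * C[layer]
            caches[layer].append((cache, m, h[layer], C[layer]))
            h[layer], C[layer] = h_new, C_new
            inp = h[layer]
    logits = h[L - 1] @ params["head_W"].T + params["head_b"]
    probs = softmax(logits)
    return probs, caches, h[L - 1]


def network_forward(X: np.ndarray, mask: np.ndarray,
                    params: dict[str, np.ndarray]) -> np.ndarray:
    """Probability vectors over the five stages for each patient in X."""
    probs, _, _ = forward_pass(X, mask, params)
    return probs


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def loss_with_l2(probs: np.ndarray, y: np.ndarray, params: dict[str, np.ndarray],
                 lam: float, variant: str = "binary_ce") -> float:
    """Summed cross-entropy over the batch plus lambda * sum of squared weights.

    ``binary_ce`` sums -(y log p + (1-y) log(1-p)) over all five components;
    ``categorical_ce`` sums -y log p. Probabilities are clamped to
    [EPS, 1-EPS] inside the logs.
    """
    if variant not in LOSS_VARIANTS:
        raise ValueError(f"unknown loss variant {variant!r}")
    p = np.clip(probs, EPS, 1.0 - EPS)
    if variant == "binary_ce":
        data = -np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    else:
        data = -np.sum(y * np.log(p))
    reg = sum(float(np.sum(params[k] ** 2)) for k in weight_keys(params))
    return float(data + lam * reg)


def _dlogits(probs: np.ndarray, y: np.ndarray, variant: str) -> np.ndarray:
    if variant == "categorical_ce":
        return probs - y
    # binary_ce: dL/dp then through the softmax Jacobian
    p = np.clip(probs, EPS, 1.0 - EPS)
    dLdp = -(y / p) + (1.0 - y) / (1.0 - p)
    inner = np.sum(dLdp * probs, axis=1, keepdims=True)
    return probs * (dLdp - inner)


# ---------------------------------------------------------------------------
# Backward (BPTT)
# ---------------------------------------------------------------------------


def _cell_backward(dh_out, dC_out, cache, m, cell):
    """Backprop one masked cell step; returns (dh_prev, dC_prev, dx, grads)."""
    a, f, i, g, o, C_prev, tC = cache
    H = f.shape[1]
    dh_full = dh_out * m
    dh_prev = dh_out * (1 - m)
    dC_full = dC_out * m
    dC_prev = dC_out * (1 - m)

    do = dh_full * tC
    dC_full = dC_full + dh_full * o * (1.0 - tC ** 2)
    df = dC_full * C_prev
    dC_prev = dC_prev + dC_full * f
    di = dC_full * g
    dg = dC_full * i

    dzf = df * f * (1.0 - f)
    dzi = di * i * (1.0 - i)
    dzg = dg * (1.0 - g ** 2)
    dzo = do * o * (1.0 - o)

    grads = {
        "Wf": dzf.T @ a, "Wi": dzi.T @ a, "Wc": dzg.T @ a, "Wo": dzo.T @ a,
        "bf": dzf.sum(0), "bi": dzi.sum(0), "bc": dzg.sum(0), "bo": dzo.sum(0),
    }
    da = dzf @ cell["Wf"] + dzi @ cell["Wi"] + dzg @ cell["Wc"] + dzo @ cell["Wo"]
    dh_prev = dh_prev + da[:, :H]
    dx = da[:, H:]
    return dh_prev, dC_prev, dx, grads


def loss_and_grads(X: np.ndarray, mask: np.ndarray, y: np.ndarray,
                   params: dict[str, np.ndarray], lam: float,
                   variant: str = "binary_ce"):
    """Loss and analytic gradients for one batch; rejects non-finite grads."""
    probs, caches, h_final = forward_pass(X, mask, params)
    loss = loss_with_l2(probs, y, params, lam, variant)
    B, T, _ = X.shape
    L = n_layers_of(params)

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dlogits = _dlogits(probs, y, variant)
    grads["head_W"] = dlogits.T @ h_final
    grads["head_b"] = dlogits.sum(0)

    dh = [np.zeros_like(h_final) for _ in range(L)]
    dC = [np.zeros_like(h_final) for _ in range(L)]
    dh[L - 1] = dlogits @ params["head_W"]
    for t in range(T - 1, -1, -1):
        dx_upper = None
        for layer in range(L - 1, -1, -1):
            cache, m, _, _ = caches[layer][t]
            if dx_upper is not None:
                dh[layer] = dh[layer] + dx_upper
            cell = _layer_params(params, layer)
            dh[layer], dC[layer], dx_upper, g = _cell_backward(
                dh[layer], dC[layer], cache, m, cell)
            for k, v in g.items():
                grads[f"l{layer}_{k}"] += v

    for k in weight_keys(params):
        grads[k] += 2.0 * lam * params[k]
    for k, v in grads.items():
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite gradient in {k}")
    return loss, grads, probs


def numeric_gradient(X, mask, y, params, lam, variant, key, index,
                     eps: float = 1e-5) -> float:
    """Central finite difference of the loss wrt one parameter coordinate."""
    p = {k: v.copy() for k, v in params.items()}
    flat = p[key].reshape(-1)
    flat[index] += eps
    probs, _, _ = forward_pass(X, mask, p)
    up = loss_with_l2(probs, y, p, lam, variant)
    flat[index] -= 2 * eps
    probs, _, _ = forward_pass(X, mask, p)
    down = loss_with_l2(probs, y, p, lam, variant)
    return (up - down) / (2 * eps)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    params: dict[str, np.ndarray]       # raw final parameters
    ema_params: dict[str, np.ndarray]   # evaluation parameters
    history: list[dict]                 # per-epoch loss / accuracy
    config: TrainConfig


def fit(dataset: EncodedDataset, config: TrainConfig) -> FitResult:
    """Train with adaptive-moment updates, lr decay and parameter averaging.

    Deterministic given the config seed: initialisation, batch order and
    every update are driven by one generator. Aborts with the history so
    far if the loss becomes non-finite.
    """
    if dataset.y is None:
        raise ValueError("dataset has no targets; supply ground truth")
    X, mask, y = dataset.X, dataset.mask, dataset.y
    n = X.shape[0]
    params = init_params(X.shape[2], hidden=config.hidden, seed=config.seed)
    ema = {k: v.copy() for k, v in params.items()}
    m1 = {k: np.zeros_like(v) for k, v in params.items()}
    m2 = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        lr = config.learning_rate * config.lr_decay ** epoch
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            try:
                loss, grads, probs = loss_and_grads(
                    X[idx], mask[idx], y[idx], params,
                    config.lam, config.loss_variant)
            except FloatingPointError:
                return FitResult(params, ema, history, config)
            if not np.isfinite(loss):
                return FitResult(params, ema, history, config)
            total_loss += loss
            correct += int((probs.argmax(1) == y[idx].argmax(1)).sum())
            step += 1
            for k in params:
                m1[k] = beta1 * m1[k] + (1 - beta1) * grads[k]
                m2[k] = beta2 * m2[k] + (1 - beta2) * grads[k] ** 2
                mhat = m1[k] / (1 - beta1 ** step)
                vhat = m2[k] / (1 - beta2 ** step)
                params[k] -= lr * mhat / (np.sqrt(vhat) + adam_eps)
                ema[k] = config.ema_decay * ema[k] + (1 - config.ema_decay) * params[k]
        history.append({
            "epoch": epoch,
            "loss": total_loss / n,
            "accuracy": correct / n,
        })
    return FitResult(params=params, ema_params=ema, history=history,
                     config=config)


def predict_stage_indices(dataset: EncodedDataset,
                          params: dict[str, np.ndarray],
                          batch_size: int = 256) -> np.ndarray:
    """Argmax stage indices; ties resolve toward the lower stage."""
    out = []
    for start in range(0, dataset.n_patients, batch_size):
        probs = network_forward(dataset.X[start: start + batch_size],
                                dataset.mask[start: start + batch_size], params)
        out.append(probs.argmax(axis=1))
    return np.concatenate(out)


def predict_next_stage(dataset: EncodedDataset, params: dict[str, np.ndarray]):
    """Predicted Global CDR values and probability matrix for a dataset."""
    probs = network_forward(dataset.X, dataset.mask, params)
    indices = probs.argmax(axis=1)
    stages = np.array([decode_stage(int(i)) for i in indices])
    return stages, probs


def make_lstm_builder(config: TrainConfig | None = None,
                      include_time_intervals: bool = True):
    """Model builder for the cross-validation harness.

    Returns ``builder(train_visits, train_truth, schema, seed)`` which fits
    the preprocessing pipeline and the network on the training patients and
    yields ``predict(test_visits, test_truth) -> stage values`` ordered by
    patient id.
    """
    from .preprocess import PreprocessPipeline

    base = config or TrainConfig()

    def builder(train_visits, train_truth, schema, seed):
        cfg = TrainConfig(**{**asdict(base), "seed": seed})
        pipeline = PreprocessPipeline.fit(train_visits, schema)
        train_ds = pipeline.encode(train_visits, train_truth,
                                   include_time_intervals=include_time_intervals)
        result = fit(train_ds, cfg)

        def predict(test_visits, test_truth):
            test_ds = pipeline.encode(test_visits, test_truth,
                                      include_time_intervals=include_time_intervals)
            stages, _ = predict_next_stage(test_ds, result.ema_params)
            return stages

        return predict

    return builder


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(path: str | Path, result: FitResult, schema_json: str) -> None:
    """Write parameters (npz) plus a JSON sidecar with config and schema hash."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "params.npz", **result.params)
    np.savez(path / "ema_params.npz", **result.ema_params)
    meta = {
        "config": asdict(result.config),
        "schema_sha256": hashlib.sha256(schema_json.encode()).hexdigest(),
        "history": result.history,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(path: str | Path) -> FitResult:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    params = dict(np.load(path / "params.npz"))
    ema = dict(np.load(path / "ema_params.npz"))
    return FitResult(params=params, ema_params=ema,
                     history=meta["history"],
                     config=TrainConfig(**meta["config"]))
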