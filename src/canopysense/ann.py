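"""Feed-forward 10-20-4 regression network trained by Levenberg-Marquardt.

One sigmoid hidden layer (20 neurons) and a linear output layer map the
scaled E-nose vector to the four physiological targets (TWSI, Ig, CTD, LAI):

    y_hat = W2 . sigma(W1 x + b1) + b2,     sigma(z) = 1 / (1 + exp(-z))

Training minimises the sum of squared residuals with damped Gauss-Newton
steps: solve (J'J + mu I) delta = J'e, where J is the Jacobian of the
residuals with respect to all weights.  mu shrinks after an accepted step
(guaranteeing per-epoch descent on the training set) and grows after a
rejected one.  Training stops at the epoch cap, on mu overflow, or after a
run of consecutive validation-MSE increases; the best-validation weights are
returned.  Goodness of fit is reported as the MSE over all outputs and the
Pearson correlation between flattened predictions and targets (one pooled R
per stage; per-output values are also logged).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .features import ScaledDataset, INPUT_ORDER, TARGET_ORDER

log = logging.getLogger(__name__)

DEFAULT_HIDDEN = 20
DEFAULT_MU0 = 1e-3
DEFAULT_MU_FACTOR = 10.0
DEFAULT_MU_MAX = 1e10
DEFAULT_MAX_EPOCHS = 1000
DEFAULT_VAL_FAIL_LIMIT = 6
INIT_HALF_WIDTH = 0.5


class TrainingError(RuntimeError):
    """The damped normal equations stayed singular with mu at its cap."""


@dataclass
class NetworkModel:
    w1: np.ndarray  # (hidden, in)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (out, hidden)
    b2: np.ndarray  # (out,)
    seed: Optional[int] = None
    training_log: list = field(default_factory=list)  # (epoch, mse_train, mse_val)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.w1.shape[1], self.w1.shape[0], self.w2.shape[0]

    def n_params(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size


@dataclass
class FitReport:
    mse_train: float
    mse_val: float
    mse_test: float
    r_train: float
    r_val: float
    r_test: float
    n_train: int
    n_val: int
    n_test: int
    epochs_run: int
    mse_extra: Optional[float] = None
    r_extra: Optional[float] = None
    n_extra: Optional[int] = None
    r_per_output: Optional[dict] = None


def init_network(
    n_in: int = len(INPUT_ORDER),
    n_hidden: int = DEFAULT_HIDDEN,
    n_out: int = len(TARGET_ORDER),
    seed: int = 0,
) -> NetworkModel:
    """Seeded uniform [-0.5, 0.5] initialisation of all weights and biases."""
    if min(n_in, n_hidden, n_out) < 1:
        raise ValueError("layer sizes must be positive")
    rng = np.random.default_rng(seed)
    u = lambda *shape: rng.uniform(-INIT_HALF_WIDTH, INIT_HALF_WIDTH, shape)
    return NetworkModel(
        w1=u(n_hidden, n_in), b1=u(n_hidden), w2=u(n_out, n_hidden), b2=u(n_out),
        seed=seed,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def forward(model: NetworkModel, inputs: np.ndarray) -> np.ndarray:
    """Network predictions for an (n, n_in) input matrix."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != model.w1.shape[1]:
        raise ValueError(
            f"input width {X.shape[1]} != network input size {model.w1.shape[1]}"
        )
    a = _sigmoid(X @ model.w1.T + model.b1)
    return a @ model.w2.T + model.b2


def _pack(model: NetworkModel) -> np.ndarray:
    return np.concatenate(
        [model.w1.ravel(), model.b1, model.w2.ravel(), model.b2]
    )


def _unpack(vec: np.ndarray, shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    n_in, n_h, n_out = shape
    i = 0
    w1 = vec[i : i + n_h * n_in].reshape(n_h, n_in); i += n_h * n_in
    b1 = vec[i : i + n_h]; i += n_h
    w2 = vec[i : i + n_out * n_h].reshape(n_out, n_h); i += n_out * n_h
    b2 = vec[i : i + n_out]
    return w1, b1, w2, b2


def _with_params(model: NetworkModel, vec: np.ndarray) -> NetworkModel:
    w1, b1, w2, b2 = _unpack(vec, model.shape)
    return NetworkModel(w1=w1, b1=b1, w2=w2, b2=b2, seed=model.seed,
                        training_log=model.training_log)


def residual_jacobian(
    model: NetworkModel, X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residual vector e = vec(y_hat - y) and its Jacobian w.r.t. all weights.

    Rows of J are ordered (sample, output) row-major; columns follow the
    packing order w1, b1, w2, b2.
    """
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    n, n_in = X.shape
    n_h = model.w1.shape[0]
    n_out = model.w2.shape[0]
    a = _sigmoid(X @ model.w1.T + model.b1)  # (n, h)
    yhat = a @ model.w2.T + model.b2
    e = (yhat - Y).ravel()
    s = a * (1.0 - a)  # sigmoid derivative, (n, h)
    P = model.n_params()
    J = np.empty((n, n_out, P))
    # d/dW1[h, j] = W2[o, h] * s[i, h] * X[i, j]
    chain = s[:, None, :] * model.w2[None, :, :]  # (n, o, h)
    J[:, :, : n_h * n_in] = (chain[:, :, :, None] * X[:, None, None, :]).reshape(
        n, n_out, n_h * n_in
    )
    ofs = n_h * n_in
    J[:, :, ofs : ofs + n_h] = chain  # d/db1
    ofs += n_h
    # d/dW2[o', h'] = a[i, h'] iff o' == o
    w2_block = np.zeros((n, n_out, n_out, n_h))
    idx = np.arange(n_out)
    w2_block[:, idx, idx, :] = a[:, None, :]
    J[:, :, ofs : ofs + n_out * n_h] = w2_block.reshape(n, n_out, n_out * n_h)
    ofs += n_out * n_h
    J[:, :, ofs:] = np.eye(n_out)[None, :, :]  # d/db2
    return e, J.reshape(n * n_out, P)


def evaluate(model: NetworkModel, inputs: np.ndarray, targets: np.ndarray) -> tuple[float, float]:
    """Mean squared error and pooled Pearson R over all n x 4 entries."""
    X = np.atleast_2d(inputs)
    Y = np.atleast_2d(targets)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("row-count mismatch")
    if X.shape[0] == 0:
        raise ValueError("empty evaluation set")
    pred = forward(model, X)
    mse = float(np.mean((pred - Y) ** 2))
    return mse, _pearson(pred.ravel(), Y.ravel())


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return 0.0
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def per_output_r(model: NetworkModel, X: np.ndarray, Y: np.ndarray) -> dict[str, float]:
    pred = forward(model, X)
    return {
        name: _pearson(pred[:, j], Y[:, j]) for j, name in enumerate(TARGET_ORDER[: Y.shape[1]])
    }


def train_lm(
    model: NetworkModel,
    dataset: ScaledDataset,
    mu0: float = DEFAULT_MU0,
    mu_factor: float = DEFAULT_MU_FACTOR,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    val_fail_limit: int = DEFAULT_VAL_FAIL_LIMIT,
    mu_max: float = DEFAULT_MU_MAX,
    extra: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> tuple[NetworkModel, FitReport]:
    """Levenberg-Marquardt training with validation-based early stopping.

    ``dataset`` must already carry train/val/test split labels.  ``extra``
    optionally supplies a second untouched (inputs, targets) hold-out whose
    metrics are reported alongside the three split stages.
    """
    Xtr, Ytr = dataset.subset("train")
    Xva, Yva = dataset.subset("val")
    Xte, Yte = dataset.subset("test")
    if len(Xtr) == 0:
        raise ValueError("dataset has no training rows; split it first")
    n_resid = Ytr.size

    w = _pack(model)
    P = w.size
    mu = mu0
    model.training_log = []

    def sse(vec: np.ndarray) -> float:
        m = _with_params(model, vec)
        return float(np.sum((forward(m, Xtr) - Ytr) ** 2))

    def val_mse(vec: np.ndarray) -> float:
        if len(Xva) == 0:
            return float("nan")
        m = _with_params(model, vec)
        return float(np.mean((forward(m, Xva) - Yva) ** 2))

    best_w = w.copy()
    best_val = val_mse(w)
    val_fails = 0
    epochs_run = 0

    for epoch in range(1, max_epochs + 1):
        cur = _with_params(model, w)
        e, J = residual_jacobian(cur, Xtr, Ytr)
        sse_cur = float(e @ e)
        JtJ = J.T @ J
        Jte = J.T @ e
        accepted = False
        while mu <= mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(P), Jte)
            except np.linalg.LinAlgError:
                mu *= mu_factor
                if mu > mu_max:
                    raise TrainingError("normal equations singular with mu at cap")
                continue
            w_new = w - delta
            if sse(w_new) < sse_cur:
                accepted = True
                mu = max(mu / mu_factor, 1e-20)
                break
            mu *= mu_factor
        if not accepted:
            log.info("mu overflow at epoch %d; stopping", epoch)
            break
        w = w_new
        epochs_run = epoch
        mse_tr = sse(w) / n_resid
        mse_va = val_mse(w)
        model.training_log.append((epoch, mse_tr, mse_va))
        if np.isnan(mse_va) or mse_va < best_val or np.isnan(best_val):
            best_val, best_w, val_fails = mse_va, w.copy(), 0
        else:
            val_fails += 1
            if val_fails >= val_fail_limit:
                log.info("early stop: %d consecutive validation increases", val_fails)
                break
        if mse_tr < 1e-14:
            break

    final = _with_params(model, best_w)
    mse_tr, r_tr = evaluate(final, Xtr, Ytr)
    mse_va, r_va = evaluate(final, Xva, Yva) if len(Xva) else (float("nan"),) * 2
    mse_te, r_te = evaluate(final, Xte, Yte) if len(Xte) else (float("nan"),) * 2
    report = FitReport(
        mse_train=mse_tr, mse_val=mse_va, mse_test=mse_te,
        r_train=r_tr, r_val=r_va, r_test=r_te,
        n_train=len(Xtr), n_val=len(Xva), n_test=len(Xte),
        epochs_run=epochs_run,
        r_per_output=per_output_r(final, Xtr, Ytr),
    )
    if extra is not None:
        Xx, Yx = extra
        report.mse_extra, report.r_extra = evaluate(final, Xx, Yx)
        report.n_extra = len(np.atleast_2d(Xx))
    return final, report


def save_model(model: NetworkModel, path: str | Path, metadata: Optional[dict] = None) -> None:
    """Serialise a model (architecture, weights, seed, scaling metadata) to JSON."""
    doc = {
        "architecture": list(model.shape),
        "activation": {"hidden": "logistic", "output": "identity"},
        "input_order": list(INPUT_ORDER),
        "target_order": list(TARGET_ORDER),
        "seed": model.seed,
        "weights": {
            "w1": model.w1.tolist(), "b1": model.b1.tolist(),
            "w2": model.w2.tolist(), "b2": model.b2.tolist(),
        },
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> NetworkModel:
    doc = json.loads(Path(path).read_text())
    w = doc["weights"]
    return NetworkModel(
        w1=np.array(w["w1"]), b1=np.array(w["b1"]),
        w2=np.array(w["w2"]), b2=np.array(w["b2"]),
        seed=doc.get("seed"),
    )
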