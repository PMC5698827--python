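"""Deep stacking network classifier with closed-form upper weights.

A deep stacking network (DSN) is a stack of simple modules, each a
single-hidden-layer perceptron: linear input, sigmoid hidden layer,
linear output.  Module m receives the raw feature vector concatenated
with the outputs of all previous modules (plus a constant bias row).
For a fixed lower weight matrix W the hidden activations are
H = sigma(W^T X), and the upper weights minimizing the total squared
error E = ||U^T H - T||^2 have the ridge-stabilized closed form

    U = (H H^T + eps I)^{-1} H T^T.

The lower weights of the bottom module are initialized from a
Bernoulli-Bernoulli restricted Boltzmann machine trained by contrastive
divergence on the (min-max scaled) inputs; upper modules start from
symmetric fan-in-scaled uniform noise.  Each module's W is optionally
fine-tuned by batch gradient descent on E(W) with U eliminated through
the closed form (U is refit after every step); steps that would increase
E are halved, so E never increases.

With U* = U(W) the minimizer, the objective actually descended is the
ridge objective J(W) = ||U*^T H - T||^2 + eps ||U*||^2, whose exact
gradient (envelope theorem: dJ/dU = 0 at U*) is

    dJ/dW = 2 X [ (U* (Y - T)) o H o (1 - H) ]^T,

where o is the elementwise product.  For eps -> 0 this is the gradient
of E itself.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, softmax

MODEL_FORMAT_VERSION = 1

LABELS = ("noncoding", "coding")  # column order of one-hot targets; coding = class 1


@dataclasses.dataclass
class RbmConfig:
    cd_steps: int = 1
    epochs: int = 10
    learning_rate: float = 0.1
    batch_size: int = 100


@dataclasses.dataclass
class FineTuneConfig:
    enabled: bool = True
    learning_rate: float = 1e-3
    epochs: int = 20


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters of DSN training.

    ``hidden_units`` is the per-module hidden layer width L;
    ``ridge_eps`` stabilizes the closed-form solve for U.
    """

    n_modules: int = 3
    hidden_units: int = 128
    rbm: RbmConfig = dataclasses.field(default_factory=RbmConfig)
    fine_tune: FineTuneConfig = dataclasses.field(default_factory=FineTuneConfig)
    ridge_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1 or self.hidden_units < 1:
            raise ValueError("n_modules and hidden_units must be positive")
        if self.ridge_eps < 0:
            raise ValueError("ridge_eps must be >= 0")
        if self.fine_tune.enabled and self.fine_tune.learning_rate <= 0:
            raise ValueError("fine-tune learning rate must be > 0 when enabled")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["rbm"] = RbmConfig(**d["rbm"])
        d["fine_tune"] = FineTuneConfig(**d["fine_tune"])
        return cls(**d)


@dataclasses.dataclass
class Scaler:
    """Per-dimension affine maps fitted on training features.

    ``mean``/``std`` z-standardize the network input; ``lo``/``span``
    min-max scale to [0, 1] for the Bernoulli RBM.
    """

    mean: np.ndarray
    std: np.ndarray
    lo: np.ndarray
    span: np.ndarray

    @classmethod
    def fit(cls, X_raw: np.ndarray) -> "Scaler":
        mean = X_raw.mean(axis=0)
        std = X_raw.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        lo = X_raw.min(axis=0)
        span = X_raw.max(axis=0) - lo
        span = np.where(span > 0, span, 1.0)
        return cls(mean, std, lo, span)

    def zscore(self, X_raw: np.ndarray) -> np.ndarray:
        return (X_raw - self.mean) / self.std

    def unit(self, X_raw: np.ndarray) -> np.ndarray:
        return np.clip((X_raw - self.lo) / self.span, 0.0, 1.0)


@dataclasses.dataclass
class DsnModuleParams:
    W: np.ndarray  # (D_m + 1) x L, bias row last
    U: np.ndarray  # L x C


@dataclasses.dataclass
class DsnModel:
    modules: list[DsnModuleParams]
    scaler: Scaler
    d_raw: int
    n_classes: int
    config: TrainConfig
    feature_groups: tuple[str, ...] = ("orfc", "mcu", "mau", "zcps", "zcpd")
    version: int = MODEL_FORMAT_VERSION


def sigmoid(z: np.ndarray) -> np.ndarray:
    return expit(z)


def stack_input(X_raw: np.ndarray, previous_outputs: Sequence[np.ndarray]) -> np.ndarray:
    """Form a module's input: raw columns, prior outputs, then a bias row.

    ``X_raw`` is D x N (samples in columns); each previous output is
    C x N.  The result is (D + m*C + 1) x N for m previous modules.
    """
    n = X_raw.shape[1]
    blocks = [X_raw]
    for Y in previous_outputs:
        if Y.shape[1] != n:
            raise ValueError(f"stacked output has {Y.shape[1]} columns, expected {n}")
        blocks.append(Y)
    blocks.append(np.ones((1, n)))
    return np.vstack(blocks)


def fit_upper_weights(H: np.ndarray, T: np.ndarray, ridge_eps: float = 1e-8) -> np.ndarray:
    """Closed-form upper weights U = (H H^T + eps I)^{-1} H T^T."""
    L = H.shape[0]
    A = H @ H.T + ridge_eps * np.eye(L)
    return np.linalg.solve(A, H @ T.T)


def module_error(W: np.ndarray, X_m: np.ndarray, T: np.ndarray, ridge_eps: float) -> tuple[float, np.ndarray]:
    """Total squared error of a module with U refit in closed form."""
    H = sigmoid(W.T @ X_m)
    U = fit_upper_weights(H, T, ridge_eps)
    E = float(np.sum((U.T @ H - T) ** 2))
    return E, U


def error_gradient(W: np.ndarray, X_m: np.ndarray, T: np.ndarray, ridge_eps: float) -> np.ndarray:
    """Gradient of the module error with U eliminated via the closed form."""
    with np.errstate(over="ignore"):
        Z = W.T @ X_m
    if not np.all(np.isfinite(Z)):
        raise FloatingPointError(
            f"non-finite pre-activation (|W|max={np.abs(W).max():.3g}, "
            f"|X|max={np.abs(X_m).max():.3g})"
        )
    H = sigmoid(Z)
    U = fit_upper_weights(H, T, ridge_eps)
    R = U.T @ H - T  # C x N residual
    G = (U @ R) * H * (1.0 - H)  # L x N
    grad = 2.0 * X_m @ G.T
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError(
            f"non-finite gradient (|W|max={np.abs(W).max():.3g}, |H|max={np.abs(H).max():.3g})"
        )
    return grad


def fine_tune_W(
    W: np.ndarray,
    X_m: np.ndarray,
    T: np.ndarray,
    learning_rate: float,
    epochs: int,
    ridge_eps: float = 1e-8,
    max_halvings: int = 12,
) -> np.ndarray:
    """Batch gradient descent on the module error, refitting U each step.

    A step that would increase the error is retried with a halved step
    size (up to ``max_halvings`` times, then the epoch is skipped), so
    the error is non-increasing across accepted steps.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be > 0")
    W = W.copy()
    E, _ = module_error(W, X_m, T, ridge_eps)
    eta = learning_rate
    for _ in range(epochs):
        grad = error_gradient(W, X_m, T, ridge_eps)
        for _ in range(max_halvings + 1):
            W_new = W - eta * grad
            E_new, _ = module_error(W_new, X_m, T, ridge_eps)
            if E_new <= E:
                W, E = W_new, E_new
                break
            eta /= 2.0
    return W


def train_rbm(
    X01: np.ndarray,
    hidden_units: int,
    config: RbmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Train a Bernoulli-Bernoulli RBM by contrastive divergence (CD-k).

    ``X01`` is D x N with entries in [0, 1], interpreted as Bernoulli
    probabilities.  Returns a (D + 1) x L weight matrix: the learned
    visible-to-hidden weights with the hidden bias folded into a final
    bias row, ready to serve as a DSN module's lower weights W.
    """
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    if not np.all(np.isfinite(X01)):
        raise ValueError("RBM input contains non-finite values")
    D, N = X01.shape
    L = hidden_units
    W = rng.normal(0.0, 0.01, size=(D, L))
    b_h = np.zeros(L)
    b_v = np.zeros(D)
    lr = config.learning_rate
    for _ in range(config.epochs):
        order = rng.permutation(N)
        for i in range(0, N, config.batch_size):
            V0 = X01[:, order[i : i + config.batch_size]]
            B = V0.shape[1]
            Ph0 = expit(W.T @ V0 + b_h[:, None])
            Vk, Phk = V0, Ph0
            for _ in range(config.cd_steps):
                Hk = (rng.random(Phk.shape) < Phk).astype(float)
                Pv = expit(W @ Hk + b_v[:, None])
                Vk = Pv  # mean-field reconstruction
                Phk = expit(W.T @ Vk + b_h[:, None])
            W += lr * ((V0 @ Ph0.T) - (Vk @ Phk.T)) / B
            b_h += lr * (Ph0.mean(axis=1) - Phk.mean(axis=1))
            b_v += lr * (V0.mean(axis=1) - Vk.mean(axis=1))
    return np.vstack([W, b_h[None, :]])


def rbm_reconstruction_error(X01: np.ndarray, W_with_bias: np.ndarray) -> float:
    """Mean-field one-step reconstruction MSE of an RBM weight matrix."""
    W = W_with_bias[:-1]
    b_h = W_with_bias[-1]
    Ph = expit(W.T @ X01 + b_h[:, None])
    V = expit(W @ Ph)
    return float(np.mean((V - X01) ** 2))


def _random_W(rng: np.random.Generator, d_in: int, hidden_units: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (d_in + hidden_units))
    return rng.uniform(-bound, bound, size=(d_in, hidden_units))


def one_hot(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    """C x N one-hot target matrix in :data:`LABELS` row order."""
    labels = np.asarray(labels)
    T = np.zeros((len(LABELS), len(labels)))
    for i, lab in enumerate(LABELS):
        T[i, labels == lab] = 1.0
    if not np.all(T.sum(axis=0) == 1):
        unknown = sorted(set(labels.tolist()) - set(LABELS))
        raise ValueError(f"unknown labels: {unknown}")
    return T


def train_dsn(
    X_raw: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    config: TrainConfig | None = None,
) -> DsnModel:
    """Train a DSN on raw feature rows (n_samples x d_raw) and labels.

    Fits the input scaler; initializes the bottom module's W from an RBM
    trained on the min-max scaled features and upper modules' W from
    symmetric fan-in-scaled uniform noise; per module solves U in closed
    form, optionally fine-tunes W, and stacks the module output onto the
    input of the next module.  Deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    X_raw = np.asarray(X_raw, dtype=float)
    labels = np.asarray(labels)
    if X_raw.ndim != 2 or X_raw.shape[0] != len(labels):
        raise ValueError("X_raw must be (n_samples, d_raw) matching labels")
    if len(set(labels.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    scaler = Scaler.fit(X_raw)
    T = one_hot(labels)
    X = scaler.zscore(X_raw).T  # D x N
    d_raw = X.shape[0]
    n_classes = len(LABELS)

    modules: list[DsnModuleParams] = []
    outputs: list[np.ndarray] = []
    for m in range(config.n_modules):
        X_m = stack_input(X, outputs)
        d_in = X_m.shape[0]
        if m == 0:
            W_rbm = train_rbm(scaler.unit(X_raw).T, config.hidden_units, config.rbm, rng)
            # RBM sees only the raw features; zero rows for bias row mismatch
            W = np.zeros((d_in, config.hidden_units))
            W[:d_raw] = W_rbm[:d_raw]
            W[-1] = W_rbm[-1]  # hidden bias -> bias row
        else:
            # warm start from the previous module: shared input rows keep
            # their weights, the C new rows (previous module's output)
            # start near zero.  At initialization the module then matches
            # the previous module's error, and fine-tuning/refitting can
            # only improve it — this is what makes stacking monotone in
            # practice; fully random W regularly starts worse than the
            # RBM-initialized, fine-tuned bottom module.
            W_prev = modules[-1].W
            W = np.zeros((d_in, config.hidden_units))
            W[: W_prev.shape[0] - 1] = W_prev[:-1]
            W[-1] = W_prev[-1]
            n_new = d_in - W_prev.shape[0]
            W[W_prev.shape[0] - 1 : W_prev.shape[0] - 1 + n_new] = rng.normal(
                0.0, 0.01, size=(n_new, config.hidden_units)
            )
        if config.fine_tune.enabled:
            W = fine_tune_W(
                W,
                X_m,
                T,
                config.fine_tune.learning_rate,
                config.fine_tune.epochs,
                config.ridge_eps,
            )
        H = sigmoid(W.T @ X_m)
        U = fit_upper_weights(H, T, config.ridge_eps)
        modules.append(DsnModuleParams(W=W, U=U))
        outputs.append(U.T @ H)
    return DsnModel(
        modules=modules,
        scaler=scaler,
        d_raw=d_raw,
        n_classes=n_classes,
        config=config,
    )


def forward(model: DsnModel, X_raw: np.ndarray) -> np.ndarray:
    """Propagate raw feature rows through the stack; final C x N output."""
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.ndim != 2 or X_raw.shape[1] != model.d_raw:
        raise ValueError(
            f"expected (n_samples, {model.d_raw}) features, got {X_raw.shape}"
        )
    X = model.scaler.zscore(X_raw).T
    outputs: list[np.ndarray] = []
    Y = np.empty((model.n_classes, X.shape[1]))
    for params in model.modules:
        X_m = stack_input(X, outputs)
        H = sigmoid(params.W.T @ X_m)
        Y = params.U.T @ H
        outputs.append(Y)
    return Y


def predict(model: DsnModel, X_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and softmax-normalized scores for feature rows.

    Returns ``(labels, scores)`` where ``scores`` is n_samples x C in
    :data:`LABELS` column order and ``labels`` the argmax class names.
    """
    Y = forward(model, X_raw)
    scores = softmax(Y, axis=0).T
    labels = np.array([LABELS[i] for i in np.argmax(Y, axis=0)])
    return labels, scores


def save_model(model: DsnModel, path: str | Path) -> None:
    """Serialize a model to a single ``.npz`` container."""
    meta = {
        "format_version": model.version,
        "d_raw": model.d_raw,
        "n_classes": model.n_classes,
        "n_modules": len(model.modules),
        "feature_groups": list(model.feature_groups),
        "config": model.config.to_dict(),
    }
    arrays = {
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        "scaler_mean": model.scaler.mean,
        "scaler_std": model.scaler.std,
        "scaler_lo": model.scaler.lo,
        "scaler_span": model.scaler.span,
    }
    for i, params in enumerate(model.modules):
        arrays[f"W{i}"] = params.W
        arrays[f"U{i}"] = params.U
    np.savez(path, **arrays)


def load_model(path: str | Path) -> DsnModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {meta['format_version']} "
                f"(this build reads version {MODEL_FORMAT_VERSION})"
            )
        scaler = Scaler(
            mean=data["scaler_mean"],
            std=data["scaler_std"],
            lo=data["scaler_lo"],
            span=data["scaler_span"],
        )
        modules = [
            DsnModuleParams(W=data[f"W{i}"], U=data[f"U{i}"])
            for i in range(meta["n_modules"])
        ]
    return DsnModel(
        modules=modules,
        scaler=scaler,
        d_raw=meta["d_raw"],
        n_classes=meta["n_classes"],
        config=TrainConfig.from_dict(meta["config"]),
        feature_groups=tuple(meta["feature_groups"]),
        version=meta["format_version"],
    )
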