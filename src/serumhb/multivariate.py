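"""Multivariate calibration of Hb from (R, G, B, intensity).

Two models are implemented from first principles:

* partial least squares regression with NIPALS factor extraction and
  deflation (single-response PLS1 on autoscaled predictors), and
* a 4-7-1 multilayer feed-forward network with sigmoidal units trained by
  backpropagation with momentum.

The network trains with per-pattern (incremental) weight updates in a fixed
data order, which keeps the whole procedure deterministic for a given seed
while converging within the 500-epoch cap at the small published learning
rate; full-batch updates at the same rate do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "PLSModel",
    "ANNSpec",
    "ANNModel",
    "pls_fit",
    "pls_predict",
    "select_n_lf",
    "sigmoid",
    "ann_init",
    "ann_train",
    "ann_predict",
]

PREDICTOR_NAMES = ("r_mean", "g_mean", "b_mean", "intensity")


# ---------------------------------------------------------------------------
# PLSR (NIPALS, single response)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    n_lf: int
    x_weights: np.ndarray      # p x a
    x_loadings: np.ndarray     # p x a
    y_loadings: np.ndarray     # a
    scores: np.ndarray         # n x a
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    explained_x_variance: np.ndarray  # cumulative %, length a
    explained_y_variance: np.ndarray  # cumulative %, length a

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector on the autoscaled X / scaled y domain."""
        w, p, q = self.x_weights, self.x_loadings, self.y_loadings
        return w @ np.linalg.solve(p.T @ w, q)


def pls_fit(X, y, n_lf: int) -> PLSModel:
    """NIPALS extraction of ``n_lf`` latent factors with deflation.

    Predictors are autoscaled (z-score) and the response centred and scaled
    internally; explained X- and Y-variances are recorded cumulatively.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one response per row")
    n, p = X.shape
    if not (1 <= n_lf <= p):
        raise ValueError(f"n_lf must lie in [1, {p}]")
    if n < n_lf + 2:
        raise ValueError("too few samples for the requested factor count")
    x_sd = X.std(axis=0, ddof=1)
    for j, sd in enumerate(x_sd):
        if sd == 0.0:
            name = PREDICTOR_NAMES[j] if j < len(PREDICTOR_NAMES) else f"column {j}"
            raise ValueError(f"zero-variance predictor: {name}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if y_sd == 0.0:
        y_sd = 1.0
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd

    ssx_total = float(np.sum(Xs**2))
    ssy_total = float(np.sum(ys**2))
    Xd, yd = Xs.copy(), ys.copy()
    W = np.zeros((p, n_lf))
    P = np.zeros((p, n_lf))
    Q = np.zeros(n_lf)
    T = np.zeros((n, n_lf))
    evx = np.zeros(n_lf)
    evy = np.zeros(n_lf)
    for a in range(n_lf):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0.0:
            # residual response orthogonal to residual X: keep a null factor
            W[:, a] = 0.0
            evx[a] = evx[a - 1] if a else 0.0
            evy[a] = evy[a - 1] if a else 0.0
            continue
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        pvec = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - q * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, pvec, q, t
        evx[a] = 100.0 * (1.0 - np.sum(Xd**2) / ssx_total) if ssx_total else 0.0
        evy[a] = 100.0 * (1.0 - np.sum(yd**2) / ssy_total) if ssy_total else 0.0
    return PLSModel(
        n_lf=n_lf,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        explained_x_variance=evx,
        explained_y_variance=evy,
    )


def pls_predict(model: PLSModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"expected {model.x_mean.size} predictor columns, got {X.shape[1]}"
        )
    Xs = (X - model.x_mean) / model.x_sd
    return model.y_mean + model.y_sd * (Xs @ model.coefficients)


def select_n_lf(X, y, max_lf: int = 4, n_folds: int = 10, tolerance: float = 0.05,
                seed: int = 0) -> int:
    """Smallest factor count whose cross-validated RMSE is within
    ``tolerance`` (fractional) of the global minimum.

    A warning is raised when even the best model does no better than
    predicting the training mean (pure-noise response).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if max_lf > X.shape[1]:
        raise ValueError("max_lf cannot exceed the predictor count")
    k = min(n_folds, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    press = np.zeros(max_lf)
    press_mean = 0.0
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        press_mean += float(np.sum((y[fold] - y[mask].mean()) ** 2))
        for a in range(1, max_lf + 1):
            model = pls_fit(X[mask], y[mask], n_lf=a)
            press[a - 1] += float(np.sum((y[fold] - pls_predict(model, X[fold])) ** 2))
    rmse = np.sqrt(press / n)
    baseline = np.sqrt(press_mean / n)
    if rmse.min() >= 0.95 * baseline:
        warnings.warn(
            "response is not predictable from the colour variables "
            "(cross-validated RMSE no better than the mean model)",
            stacklevel=2,
        )
    # absolute slack keeps the rule stable when all RMSEs are numerically zero
    threshold = (1.0 + tolerance) * rmse.min() + 1e-8 * max(float(np.std(y)), 1.0)
    return int(np.argmax(rmse <= threshold)) + 1


# ---------------------------------------------------------------------------
# MLF-ANN (4-7-1, sigmoid, backpropagation with momentum)
# ---------------------------------------------------------------------------

def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)), numerically stable for large |x|."""
    return expit(x)


@dataclass(frozen=True)
class ANNSpec:
    layer_sizes: tuple[int, int, int] = (4, 7, 1)
    learning_rate: float = 0.2
    momentum: float = 0.5
    max_epochs: int = 500
    init_range: float = 3.0
    seed: int = 42
    stop_tolerance: float = 1e-7
    target_low: float = 0.1
    target_high: float = 0.9

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        if self.max_epochs < 1:
            raise ValueError("at least one epoch is required")


@dataclass
class ANNModel:
    spec: ANNSpec
    weights: list[np.ndarray] = field(default_factory=list)  # [W1, b1, W2, b2]
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None
    y_min: float = 0.0
    y_max: float = 1.0
    training_rmse_trace: list[float] = field(default_factory=list)
    trained: bool = False

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights)


def ann_init(spec: ANNSpec) -> ANNModel:
    """Uniform random weights and biases in [-init_range, +init_range],
    deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    d, h, o = spec.layer_sizes
    lim = spec.init_range
    weights = [
        rng.uniform(-lim, lim, size=(h, d)),
        rng.uniform(-lim, lim, size=h),
        rng.uniform(-lim, lim, size=(o, h)),
        rng.uniform(-lim, lim, size=o),
    ]
    return ANNModel(spec=spec, weights=weights)


def _scale_inputs(model: ANNModel, X: np.ndarray) -> np.ndarray:
    span = np.where(model.x_max > model.x_min, model.x_max - model.x_min, 1.0)
    return (X - model.x_min) / span


def _forward_scaled(weights, Xs: np.ndarray) -> np.ndarray:
    W1, b1, W2, b2 = weights
    hidden = expit(Xs @ W1.T + b1)
    return expit(hidden @ W2.T + b2).ravel()


def _pattern_gradients(weights, x: np.ndarray, target: float):
    """Backprop gradients of the half-squared error for one pattern."""
    W1, b1, W2, b2 = weights
    a1 = expit(W1 @ x + b1)
    out = expit(W2 @ a1 + b2)
    err = out - target
    d2 = err * out * (1.0 - out)
    g_w2 = d2[:, None] * a1[None, :]
    g_b2 = d2
    d1 = (W2.T @ d2) * a1 * (1.0 - a1)
    g_w1 = d1[:, None] * x[None, :]
    g_b1 = d1
    return [g_w1, g_b1, g_w2, g_b2]


def ann_train(model: ANNModel, X, y) -> ANNModel:
    """Backpropagation with momentum, per-pattern updates in data order.

    Inputs are min-max scaled to [0, 1] and targets to [target_low,
    target_high] (fitted on the training data only).  Training stops at
    max_epochs or when the epoch RMSE stops improving by stop_tolerance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one target per row")
    if X.shape[1] != model.spec.layer_sizes[0]:
        raise ValueError(
            f"expected {model.spec.layer_sizes[0]} predictor columns, got {X.shape[1]}"
        )
    spec = model.spec
    model.x_min = X.min(axis=0)
    model.x_max = X.max(axis=0)
    model.y_min = float(y.min())
    model.y_max = float(y.max())
    span = model.y_max - model.y_min
    if span == 0.0:
        span = 1.0
    Xs = _scale_inputs(model, X)
    ys = spec.target_low + (spec.target_high - spec.target_low) * (y - model.y_min) / span

    weights = model.weights
    velocity = [np.zeros_like(w) for w in weights]
    eta, mom = spec.learning_rate, spec.momentum
    trace: list[float] = []
    prev_rmse = np.inf
    for epoch in range(spec.max_epochs):
        for i in range(Xs.shape[0]):
            grads = _pattern_gradients(weights, Xs[i], ys[i])
            for j in range(len(weights)):
                velocity[j] = mom * velocity[j] - eta * grads[j]
                weights[j] += velocity[j]
        rmse = float(np.sqrt(np.mean((_forward_scaled(weights, Xs) - ys) ** 2)))
        if not np.isfinite(rmse):
            raise RuntimeError(f"training diverged (non-finite loss at epoch {epoch})")
        trace.append(rmse)
        if abs(prev_rmse - rmse) < spec.stop_tolerance:
            break
        prev_rmse = rmse
    model.training_rmse_trace = trace
    model.trained = True
    return model


def ann_predict(model: ANNModel, X) -> np.ndarray:
    if not model.trained:
        raise ValueError("the network has not been trained")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.spec.layer_sizes[0]:
        raise ValueError(
            f"expected {model.spec.layer_sizes[0]} predictor columns, got {X.shape[1]}"
        )
    out = _forward_scaled(model.weights, _scale_inputs(model, X))
    spec = model.spec
    frac = (out - spec.target_low) / (spec.target_high - spec.target_low)
    return model.y_min + frac * (model.y_max - model.y_min)
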