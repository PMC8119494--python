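"""Wavelet neural network (WNN) regression core, plus a sigmoid-MLP baseline.

The WNN is a two-layer network whose hidden nodes ("wavelons") are
translated/dilated Mexican-hat wavelets combined multiplicatively over the
inputs, with an additional direct linear input->output connection and output
biases:

    y_hat_j = sum_i  psi_i(x) w_out[i,j] + sum_k x_k w_dir[k,j] + b_j
    psi_i(x) = prod_k psi( (x_k - xi[k,i]) / sigma[k,i] )
    psi(z)   = (1 - z^2) exp(-z^2 / 2)

Training minimizes the cost

    L = (1/N) sum_p || y_p - y_hat_p ||^2

by full-batch gradient descent with momentum, stopping at a cost floor or
an epoch cap. Translations are initialized at the per-input data midpoints
and dilations proportionally to the per-input data range (capped at 1), so
every input falls inside the wavelet's active support; biases start at the
target means; weights start uniformly in a small symmetric range.

Hidden-layer size is chosen by the minimum prediction-risk principle: the
candidate count whose trained network attains the smallest held-out mean
squared error wins (ties go to the smaller network).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from functools import singledispatch

import numpy as np

_EPS_DILATION = 1e-3


@dataclasses.dataclass
class WNNParameters:
    """All trainable parameters of the wavelet network.

    Shapes: ``w_direct`` (n_in, n_out), ``w_out`` (n_hidden, n_out),
    ``xi``/``sigma`` (n_in, n_hidden) translations/dilations, ``bias`` (n_out,).
    """

    w_direct: np.ndarray
    w_out: np.ndarray
    xi: np.ndarray
    sigma: np.ndarray
    bias: np.ndarray

    def validate(self) -> None:
        k, j = self.w_direct.shape
        i = self.w_out.shape[0]
        if self.w_out.shape != (i, j) or self.xi.shape != (k, i) \
                or self.sigma.shape != (k, i) or self.bias.shape != (j,):
            raise ValueError("inconsistent parameter shapes")
        for name in ("w_direct", "w_out", "xi", "sigma", "bias"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.sigma <= 0):
            raise ValueError("dilations must be strictly positive")

    def arrays(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def copy(self) -> "WNNParameters":
        return WNNParameters(**{k: v.copy() for k, v in self.arrays().items()})


@dataclasses.dataclass
class MLPParameters:
    """Sigmoid-MLP baseline: one hidden layer, linear output, no direct path."""

    w_in: np.ndarray      # (n_in, n_hidden)
    b_hidden: np.ndarray  # (n_hidden,)
    w_out: np.ndarray     # (n_hidden, n_out)
    bias: np.ndarray      # (n_out,)

    def arrays(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def copy(self) -> "MLPParameters":
        return MLPParameters(**{k: v.copy() for k, v in self.arrays().items()})


@dataclasses.dataclass
class TrainingConfig:
    """Training/optimizer settings (defaults match the reference protocol:
    5 hidden nodes, 50 epochs, cost floor 1e-5)."""

    epochs: int = 50
    cost_floor: float = 1e-5
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0
    n_hidden: int = 5
    dilation_scale: float = 0.25
    init_weight_range: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.cost_floor <= 0:
            raise ValueError("cost floor must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")


@dataclasses.dataclass
class TrainingTrace:
    costs: list[float]
    stop_reason: str  # "cost_floor" | "epoch_cap"


class TrainingDivergence(RuntimeError):
    def __init__(self, message: str, trace: TrainingTrace):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# wavelet primitives

def mexican_hat(z):
    """Mexican-hat mother wavelet psi(z) = (1 - z^2) exp(-z^2/2)."""
    z = np.asarray(z, dtype=float)
    out = (1.0 - z * z) * np.exp(-0.5 * z * z)
    return out if out.ndim else float(out)


def mexican_hat_deriv(z):
    """d/dz of the Mexican hat: z (z^2 - 3) exp(-z^2/2)."""
    z = np.asarray(z, dtype=float)
    out = z * (z * z - 3.0) * np.exp(-0.5 * z * z)
    return out if out.ndim else float(out)


def wavelon_input(x_k: float, xi: float, sigma: float) -> float:
    """Translated/dilated wavelon argument z = (x_k - xi) / sigma."""
    if sigma == 0:
        raise ValueError("dilation must be non-zero")
    return (x_k - xi) / sigma


def wavelon_activation(x: np.ndarray, xi_col: np.ndarray, sigma_col: np.ndarray) -> float:
    """One wavelon's activation: the product of Mexican hats over all inputs."""
    x = np.asarray(x, dtype=float)
    if x.shape != xi_col.shape or x.shape != sigma_col.shape:
        raise ValueError("input/translation/dilation lengths must match")
    if np.any(sigma_col == 0):
        raise ValueError("dilation must be non-zero")
    z = (x - xi_col) / sigma_col
    return float(np.prod(mexican_hat(z)))


# ---------------------------------------------------------------------------
# forward / cost / gradients (arrays are (n_features, n_samples))

def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


@singledispatch
def forward(params, x: np.ndarray) -> np.ndarray:
    raise TypeError(f"unsupported parameter type {type(params)!r}")


@forward.register
def _(params: WNNParameters, x: np.ndarray) -> np.ndarray:
    squeeze = np.asarray(x).ndim == 1
    xb = _as_batch(x)
    if xb.shape[0] != params.w_direct.shape[0]:
        raise ValueError("input dimension mismatch")
    z = (xb[:, None, :] - params.xi[:, :, None]) / params.sigma[:, :, None]
    psi = np.prod(mexican_hat(z), axis=0)                     # (n_hidden, n)
    yhat = params.w_out.T @ psi + params.w_direct.T @ xb + params.bias[:, None]
    return yhat[:, 0] if squeeze else yhat


@forward.register
def _(params: MLPParameters, x: np.ndarray) -> np.ndarray:
    squeeze = np.asarray(x).ndim == 1
    xb = _as_batch(x)
    if xb.shape[0] != params.w_in.shape[0]:
        raise ValueError("input dimension mismatch")
    h = _sigmoid(params.w_in.T @ xb + params.b_hidden[:, None])
    yhat = params.w_out.T @ h + params.bias[:, None]
    return yhat[:, 0] if squeeze else yhat


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * a))


def cost(y: np.ndarray, y_hat: np.ndarray) -> float:
    """L = (1/N) sum_p ||y_p - y_hat_p||^2 (sum over output coordinates,
    mean over samples)."""
    y, y_hat = _as_batch(y), _as_batch(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("target/prediction shape mismatch")
    r = y - y_hat
    return float(np.sum(r * r) / y.shape[1])


@singledispatch
def gradients(params, x: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    raise TypeError(f"unsupported parameter type {type(params)!r}")


@gradients.register
def _(params: WNNParameters, x: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    xb, yb = _as_batch(x), _as_batch(y)
    n = xb.shape[1]
    z = (xb[:, None, :] - params.xi[:, :, None]) / params.sigma[:, :, None]
    psi_k = mexican_hat(z)                                    # (K, I, n)
    psi = np.prod(psi_k, axis=0)                              # (I, n)
    yhat = params.w_out.T @ psi + params.w_direct.T @ xb + params.bias[:, None]
    r2 = 2.0 * (yhat - yb) / n                                # dL/dyhat (J, n)

    g_bias = r2.sum(axis=1)
    g_wdir = xb @ r2.T
    g_wout = psi @ r2.T
    g_psi = params.w_out @ r2                                 # dL/dpsi (I, n)

    # product over inputs excluding k, via shifted cumulative products
    fwd = np.ones_like(psi_k)
    np.cumprod(psi_k[:-1], axis=0, out=fwd[1:])
    bwd = np.ones_like(psi_k)
    np.cumprod(psi_k[:0:-1], axis=0, out=bwd[-2::-1])
    excl = fwd * bwd                                          # (K, I, n)

    dz = g_psi[None, :, :] * excl * mexican_hat_deriv(z)      # dL/dz (K, I, n)
    inv_sigma = 1.0 / params.sigma[:, :, None]
    g_xi = -(dz * inv_sigma).sum(axis=2)
    g_sigma = -(dz * z * inv_sigma).sum(axis=2)
    return {"w_direct": g_wdir, "w_out": g_wout, "xi": g_xi,
            "sigma": g_sigma, "bias": g_bias}


@gradients.register
def _(params: MLPParameters, x: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    xb, yb = _as_batch(x), _as_batch(y)
    n = xb.shape[1]
    h = _sigmoid(params.w_in.T @ xb + params.b_hidden[:, None])
    yhat = params.w_out.T @ h + params.bias[:, None]
    r2 = 2.0 * (yhat - yb) / n
    g_h = (params.w_out @ r2) * h * (1.0 - h)
    return {
        "w_in": xb @ g_h.T,
        "b_hidden": g_h.sum(axis=1),
        "w_out": h @ r2.T,
        "bias": r2.sum(axis=1),
    }


# ---------------------------------------------------------------------------
# initialization

def init_params(
    x_train: np.ndarray,
    y_train: np.ndarray,
    n_hidden: int,
    seed: int = 0,
    dilation_scale: float = 0.25,
    init_weight_range: float = 0.1,
) -> WNNParameters:
    """Heuristic WNN initialization from the training data.

    Translations sit at the per-input midpoints 0.5*(min + max); dilations
    are ``dilation_scale`` times the per-input range, clipped to
    (1e-3, 1], so training samples fall within the wavelet's active
    support; biases equal the per-output target means; both weight blocks
    are uniform in +/- ``init_weight_range``.
    """
    xb, yb = _as_batch(x_train), _as_batch(y_train)
    if xb.shape[1] < 1:
        raise ValueError("empty training set")
    if n_hidden < 1:
        raise ValueError("need at least one hidden node")
    mk = xb.max(axis=1)
    nk = xb.min(axis=1)
    if np.any(mk == nk):
        warnings.warn(
            "constant input row(s): dilation floored at 1e-3", RuntimeWarning
        )
    xi = np.repeat((0.5 * (nk + mk))[:, None], n_hidden, axis=1)
    sigma = np.repeat(
        np.clip(dilation_scale * (mk - nk), _EPS_DILATION, 1.0)[:, None],
        n_hidden, axis=1,
    )
    rng = np.random.default_rng(seed)
    n_in, n_out = xb.shape[0], yb.shape[0]
    r = init_weight_range
    params = WNNParameters(
        w_direct=rng.uniform(-r, r, size=(n_in, n_out)),
        w_out=rng.uniform(-r, r, size=(n_hidden, n_out)),
        xi=xi,
        sigma=sigma,
        bias=yb.mean(axis=1),
    )
    params.validate()
    return params


def init_mlp_params(
    x_train: np.ndarray,
    y_train: np.ndarray,
    n_hidden: int,
    seed: int = 0,
    init_weight_range: float = 0.1,
) -> MLPParameters:
    """Matched-convention MLP initialization: small uniform weights, output
    bias at the target means."""
    xb, yb = _as_batch(x_train), _as_batch(y_train)
    if n_hidden < 1:
        raise ValueError("need at least one hidden node")
    rng = np.random.default_rng(seed)
    n_in, n_out = xb.shape[0], yb.shape[0]
    r = init_weight_range
    return MLPParameters(
        w_in=rng.uniform(-r, r, size=(n_in, n_hidden)),
        b_hidden=rng.uniform(-r, r, size=n_hidden),
        w_out=rng.uniform(-r, r, size=(n_hidden, n_out)),
        bias=yb.mean(axis=1),
    )


# ---------------------------------------------------------------------------
# training

def train(params, x_train, y_train, config: TrainingConfig):
    """Full-batch gradient descent with momentum.

    Per epoch: record the cost, stop if it reached the floor, else update
    every parameter with velocity = momentum*velocity - lr*gradient.
    Returns (trained params, TrainingTrace); raises TrainingDivergence with
    the trace attached if the cost becomes non-finite.
    """
    params = params.copy()
    xb, yb = _as_batch(x_train), _as_batch(y_train)
    velocity = {k: np.zeros_like(v) for k, v in params.arrays().items()}
    costs: list[float] = []
    for _epoch in range(1, config.epochs + 1):
        level = cost(yb, forward(params, xb))
        costs.append(level)
        if not np.isfinite(level):
            raise TrainingDivergence(
                "training diverged (non-finite cost)",
                TrainingTrace(costs=costs, stop_reason="diverged"),
            )
        if level <= config.cost_floor:
            return params, TrainingTrace(costs=costs, stop_reason="cost_floor")
        grads = gradients(params, xb, yb)
        for name, g in grads.items():
            velocity[name] = config.momentum * velocity[name] - config.learning_rate * g
            arr = getattr(params, name)
            setattr(params, name, arr + velocity[name])
    return params, TrainingTrace(costs=costs, stop_reason="epoch_cap")


def prediction_risk(params, x_test: np.ndarray, y_test: np.ndarray) -> float:
    """Held-out mean squared error (same functional form as the cost)."""
    xb, yb = _as_batch(x_test), _as_batch(y_test)
    if xb.shape[1] == 0:
        raise ValueError("empty test set")
    return cost(yb, forward(params, xb))


def select_hidden_nodes(
    x: np.ndarray,
    y: np.ndarray,
    candidates: list[int],
    config: TrainingConfig,
    train_fraction: float = 0.7,
) -> int:
    """Pick the hidden-node count with minimum prediction risk.

    One WNN is trained per candidate (same split and seed for all), scored
    on the held-out portion; ties break toward fewer nodes.
    """
    if not candidates:
        raise ValueError("no candidate hidden-node counts")
    xb, yb = _as_batch(x), _as_batch(y)
    n = xb.shape[1]
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    tr, te = order[:n_train], order[n_train:]
    best_nodes, best_risk = None, np.inf
    for n_hidden in sorted(candidates):
        params = init_params(
            xb[:, tr], yb[:, tr], n_hidden, seed=config.seed,
            dilation_scale=config.dilation_scale,
            init_weight_range=config.init_weight_range,
        )
        fitted, _ = train(params, xb[:, tr], yb[:, tr], config)
        risk = prediction_risk(fitted, xb[:, te], yb[:, te])
        if risk < best_risk:
            best_nodes, best_risk = n_hidden, risk
    return best_nodes


def mlp_baseline(x, y, config: TrainingConfig):
    """Train the sigmoid-MLP baseline under the same optimizer and budget."""
    params = init_mlp_params(
        x, y, config.n_hidden, seed=config.seed,
        init_weight_range=config.init_weight_range,
    )
    return train(params, x, y, config)


# ---------------------------------------------------------------------------
# serialization

_FORMAT_VERSION = 1


def params_to_json(params) -> str:
    kind = "wnn" if isinstance(params, WNNParameters) else "mlp"
    payload = {
        "format_version": _FORMAT_VERSION,
        "kind": kind,
        "arrays": {
            k: {"shape": list(v.shape), "values": v.ravel().tolist()}
            for k, v in params.arrays().items()
        },
    }
    return json.dumps(payload)


def params_from_json(text: str):
    payload = json.loads(text)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported parameter file version")
    arrays = {
        k: np.array(v["values"], dtype=float).reshape(v["shape"])
        for k, v in payload["arrays"].items()
    }
    cls = WNNParameters if payload["kind"] == "wnn" else MLPParameters
    return cls(**arrays)
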