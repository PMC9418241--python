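"""Mean-field variational Bayesian neural network (Bayes by Backprop).

The classifier is a fully connected net with logistic-sigmoid hidden layers
and a softmax output.  Instead of point weights it maintains a factorized
Gaussian posterior q(w|delta) = prod_j N(w_j | mu_j, sigma_j^2) over every
weight and bias, with sigma = softplus(rho) so the scale stays positive
under unconstrained optimization.  Training minimizes the Monte-Carlo
negative ELBO

    L = (1/n) sum_i  kl_scale * [log q(w_i|delta) - log p(w_i)]  -  log p(batch | w_i)

over reparameterized draws w_i = mu + sigma * eps_i, eps_i ~ N(0, I), with a
standard-normal prior p(w) and categorical likelihood.  Gradients are
derived analytically (numpy, no autograd): for the reparameterized draw the
log q term's total mu-gradient cancels exactly and its rho-gradient is
-softplus'(rho)/sigma, while prior and likelihood gradients flow through
the draw via d w / d mu = 1 and d w / d rho = eps * softplus'(rho).

Point-estimate baselines for comparison: an L2-regularized DNN with Xavier
initialization (same activations), and sklearn multinomial logistic
regression.  All three are trained with Adam (the DNN/BNN use the Adam
implemented here) and are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .data import LabeledDataset

__all__ = [
    "PriorSpec",
    "VariationalParams",
    "WeightSample",
    "TrainConfig",
    "BNNModel",
    "DNNModel",
    "LogRegModel",
    "init_variational",
    "sample_weights",
    "forward",
    "elbo_loss",
    "train_bnn",
    "train_dnn_baseline",
    "train_logreg_baseline",
    "save_model",
    "load_model",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_PROB_FLOOR = 1e-12  # probabilities clipped here before log-likelihood


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class PriorSpec:
    """Standard-normal prior over every weight and bias: w_j ~ N(0, 1)."""

    mean: float = 0.0
    variance: float = 1.0

    def __post_init__(self) -> None:
        if self.mean != 0.0 or self.variance != 1.0:
            raise ValueError("the prior is fixed at N(0, 1)")


@dataclass
class VariationalParams:
    """Location (mu) and raw scale (rho) arrays per layer; sigma = softplus(rho)."""

    layer_sizes: tuple[int, ...]
    w_mu: list[np.ndarray]
    w_rho: list[np.ndarray]
    b_mu: list[np.ndarray]
    b_rho: list[np.ndarray]

    def arrays(self) -> list[np.ndarray]:
        return [*self.w_mu, *self.b_mu, *self.w_rho, *self.b_rho]

    def n_layers(self) -> int:
        return len(self.layer_sizes) - 1

    def copy(self) -> "VariationalParams":
        return VariationalParams(
            self.layer_sizes,
            [a.copy() for a in self.w_mu],
            [a.copy() for a in self.w_rho],
            [a.copy() for a in self.b_mu],
            [a.copy() for a in self.b_rho],
        )


@dataclass
class WeightSample:
    """Concrete weight/bias arrays for all layers (one posterior draw)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by the BNN and the point-estimate DNN.

    n_mc is the number of Monte-Carlo posterior draws per loss evaluation;
    kl_scale weights the complexity term per mini-batch (None means
    kl_multiplier/number_of_batches; with the default multiplier of 1 this
    is the standard mini-batch ELBO weighting).  kl_multiplier < 1 gives a
    tempered posterior, which cross-validation favours when the training
    set is small relative to the weight count.  l2_strength applies to the
    baselines only.
    """

    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 128
    n_mc: int = 1
    kl_scale: float | None = None
    kl_multiplier: float = 1.0
    l2_strength: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.n_mc < 1:
            raise ValueError("epochs, batch_size and n_mc must all be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.kl_scale is not None and self.kl_scale < 0:
            raise ValueError("kl_scale must be >= 0")
        if self.kl_multiplier < 0:
            raise ValueError("kl_multiplier must be >= 0")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be >= 0")


@dataclass
class BNNModel:
    params: VariationalParams
    prior: PriorSpec
    class_names: tuple[str, ...]
    feature_genes: tuple[str, ...]
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.params.layer_sizes[-1] != len(self.class_names):
            raise ValueError("output width must equal the number of classes")
        if self.params.layer_sizes[0] != len(self.feature_genes):
            raise ValueError("input width must equal the number of feature genes")


@dataclass
class DNNModel:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    class_names: tuple[str, ...]
    feature_genes: tuple[str, ...]
    loss_history: list[float] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return forward(WeightSample(self.weights, self.biases), X)


@dataclass
class LogRegModel:
    estimator: LogisticRegression
    class_names: tuple[str, ...]
    feature_genes: tuple[str, ...]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities with columns in class_names order."""
        raw = self.estimator.predict_proba(np.asarray(X, dtype=float))
        cols = {c: j for j, c in enumerate(self.estimator.classes_)}
        out = np.zeros((raw.shape[0], len(self.class_names)))
        for i, c in enumerate(self.class_names):
            if c in cols:
                out[:, i] = raw[:, cols[c]]
        return out


# ---------------------------------------------------------------------------
# numerics


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def softplus_inv(y: float) -> float:
    return float(np.log(np.expm1(y)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# variational machinery


def init_variational(
    layer_sizes: Sequence[int],
    seed: int,
    mu_sd: float = 0.1,
    init_sigma: float = 0.05,
) -> VariationalParams:
    """Normal initialization of locations; scales start near ``init_sigma``."""
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least an input and an output layer")
    if any(s < 1 for s in sizes):
        raise ValueError("all layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    rho0 = softplus_inv(init_sigma)
    w_mu, w_rho, b_mu, b_rho = [], [], [], []
    for d_in, d_out in zip(sizes[:-1], sizes[1:]):
        w_mu.append(rng.normal(0.0, mu_sd, size=(d_in, d_out)))
        b_mu.append(rng.normal(0.0, mu_sd, size=d_out))
        w_rho.append(np.full((d_in, d_out), rho0))
        b_rho.append(np.full(d_out, rho0))
    return VariationalParams(sizes, w_mu, w_rho, b_mu, b_rho)


def _draw_eps(params: VariationalParams, rng: np.random.Generator):
    w_eps = [rng.standard_normal(a.shape) for a in params.w_mu]
    b_eps = [rng.standard_normal(a.shape) for a in params.b_mu]
    return w_eps, b_eps


def _realize(params: VariationalParams, w_eps, b_eps) -> WeightSample:
    weights = [mu + softplus(rho) * e for mu, rho, e in zip(params.w_mu, params.w_rho, w_eps)]
    biases = [mu + softplus(rho) * e for mu, rho, e in zip(params.b_mu, params.b_rho, b_eps)]
    return WeightSample(weights, biases)


def sample_weights(params: VariationalParams, rng: np.random.Generator) -> WeightSample:
    """One reparameterized posterior draw w = mu + softplus(rho) * eps."""
    w_eps, b_eps = _draw_eps(params, rng)
    return _realize(params, w_eps, b_eps)


def forward(weights: WeightSample, X: np.ndarray) -> np.ndarray:
    """Class probabilities: sigmoid hidden layers, softmax output layer."""
    a = np.asarray(X, dtype=float)
    if a.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if a.shape[1] != weights.weights[0].shape[0]:
        raise ValueError(
            f"feature count {a.shape[1]} does not match input width "
            f"{weights.weights[0].shape[0]}"
        )
    last = len(weights.weights) - 1
    for l, (W, b) in enumerate(zip(weights.weights, weights.biases)):
        z = a @ W + b
        a = softmax(z) if l == last else sigmoid(z)
    return a


def _log_q_minus_log_p(params: VariationalParams, w_eps, b_eps) -> float:
    """log q(w|delta) - log p(w) at the draw defined by the given epsilons."""
    total = 0.0
    for mu, rho, eps in zip(
        params.w_mu + params.b_mu, params.w_rho + params.b_rho, w_eps + b_eps
    ):
        sig = softplus(rho)
        w = mu + sig * eps
        log_q = -0.5 * _LOG_2PI - np.log(sig) - 0.5 * eps**2
        log_p = -0.5 * _LOG_2PI - 0.5 * w**2
        total += float(np.sum(log_q - log_p))
    return total


def _nll_and_grads(sample: WeightSample, X: np.ndarray, y_idx: np.ndarray):
    """Categorical NLL (summed over the batch) and its weight gradients."""
    n_layers = len(sample.weights)
    acts = [np.asarray(X, dtype=float)]
    for l, (W, b) in enumerate(zip(sample.weights, sample.biases)):
        z = acts[-1] @ W + b
        acts.append(softmax(z) if l == n_layers - 1 else sigmoid(z))
    probs = acts[-1]
    n = X.shape[0]
    nll = -float(
        np.sum(np.log(np.clip(probs[np.arange(n), y_idx], _PROB_FLOOR, None)))
    )
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y_idx] = 1.0
    dZ = probs - onehot
    gW: list[np.ndarray] = [np.empty(0)] * n_layers
    gb: list[np.ndarray] = [np.empty(0)] * n_layers
    for l in range(n_layers - 1, -1, -1):
        gW[l] = acts[l].T @ dZ
        gb[l] = dZ.sum(axis=0)
        if l > 0:
            dA = dZ @ sample.weights[l].T
            dZ = dA * acts[l] * (1.0 - acts[l])
    return nll, gW, gb


def _elbo_value_and_grad(
    params: VariationalParams,
    X: np.ndarray,
    y_idx: np.ndarray,
    kl_scale: float,
    eps_draws,
):
    """Loss and gradients for a fixed set of epsilon draws.

    Holding the epsilons fixed makes the loss a deterministic function of
    (mu, rho), which is what the finite-difference gradient check exercises.
    """
    L = params.n_layers()
    g_w_mu = [np.zeros_like(a) for a in params.w_mu]
    g_w_rho = [np.zeros_like(a) for a in params.w_rho]
    g_b_mu = [np.zeros_like(a) for a in params.b_mu]
    g_b_rho = [np.zeros_like(a) for a in params.b_rho]
    total_loss = 0.0
    n_mc = len(eps_draws)
    has_data = X.shape[0] > 0

    for w_eps, b_eps in eps_draws:
        sample = _realize(params, w_eps, b_eps)
        kl_term = _log_q_minus_log_p(params, w_eps, b_eps)
        if has_data:
            nll, gW, gb = _nll_and_grads(sample, X, y_idx)
        else:
            nll = 0.0
            gW = [np.zeros_like(a) for a in params.w_mu]
            gb = [np.zeros_like(a) for a in params.b_mu]
        total_loss += kl_scale * kl_term + nll

        for l in range(L):
            sig_w = softplus(params.w_rho[l])
            sig_b = softplus(params.b_rho[l])
            sp_w = sigmoid(params.w_rho[l])  # softplus'(rho)
            sp_b = sigmoid(params.b_rho[l])
            # d(loss)/dw for terms flowing through the draw: prior + likelihood
            g_w = kl_scale * sample.weights[l] + gW[l]
            g_b = kl_scale * sample.biases[l] + gb[l]
            g_w_mu[l] += g_w  # dw/dmu = 1; log q total mu-derivative is 0
            g_b_mu[l] += g_b
            g_w_rho[l] += g_w * w_eps[l] * sp_w - kl_scale * sp_w / sig_w
            g_b_rho[l] += g_b * b_eps[l] * sp_b - kl_scale * sp_b / sig_b

    inv = 1.0 / n_mc
    grads = (
        [g * inv for g in g_w_mu],
        [g * inv for g in g_w_rho],
        [g * inv for g in g_b_mu],
        [g * inv for g in g_b_rho],
    )
    return total_loss * inv, grads


def elbo_loss(
    params: VariationalParams,
    prior: PriorSpec,
    X: np.ndarray,
    y_idx: np.ndarray,
    n_mc: int,
    kl_scale: float,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo negative ELBO: mean over draws of
    kl_scale*(log q - log p) + categorical NLL of the batch."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    X = np.asarray(X, dtype=float).reshape(-1, params.layer_sizes[0])
    y_idx = np.asarray(y_idx, dtype=int)
    eps_draws = [_draw_eps(params, rng) for _ in range(n_mc)]
    loss, _ = _elbo_value_and_grad(params, X, y_idx, kl_scale, eps_draws)
    return float(loss)


# ---------------------------------------------------------------------------
# Adam


class Adam:
    """Plain Adam over a list of parameter arrays (updated in place)."""

    def __init__(self, arrays: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# training


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_bnn(
    train: LabeledDataset,
    hidden_sizes: Sequence[int] = (250, 95),
    config: TrainConfig = TrainConfig(),
) -> BNNModel:
    """Fit the variational posterior by Bayes by Backprop with Adam."""
    X = train.matrix.values
    y = train.label_indices()
    if len(set(train.labels)) < 2:
        raise ValueError("training data must contain >= 2 classes")
    sizes = (train.matrix.n_genes, *hidden_sizes, train.n_classes)
    params = init_variational(sizes, seed=config.seed)
    rng = np.random.default_rng([config.seed, 1])

    n = X.shape[0]
    n_batches = int(np.ceil(n / config.batch_size))
    kl_scale = (
        config.kl_scale
        if config.kl_scale is not None
        else config.kl_multiplier / n_batches
    )

    opt_arrays = [*params.w_mu, *params.b_mu, *params.w_rho, *params.b_rho]
    opt = Adam(opt_arrays, lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        for idx in _batches(n, config.batch_size, rng):
            eps_draws = [_draw_eps(params, rng) for _ in range(config.n_mc)]
            loss, (g_w_mu, g_w_rho, g_b_mu, g_b_rho) = _elbo_value_and_grad(
                params, X[idx], y[idx], kl_scale, eps_draws
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss ({loss}) at step {opt.t + 1}; "
                    "reduce the learning rate or check the input scale"
                )
            opt.step([*g_w_mu, *g_b_mu, *g_w_rho, *g_b_rho])
            epoch_loss += loss
        history.append(epoch_loss / n_batches)

    return BNNModel(
        params=params,
        prior=PriorSpec(),
        class_names=train.class_names,
        feature_genes=train.matrix.gene_ids,
        loss_history=history,
    )


def _xavier_init(sizes: tuple[int, ...], rng: np.random.Generator):
    weights, biases = [], []
    for d_in, d_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return weights, biases


def train_dnn_baseline(
    train: LabeledDataset,
    config: TrainConfig = TrainConfig(),
    hidden_sizes: Sequence[int] = (250, 55),
) -> DNNModel:
    """Point-estimate baseline: 250-55-C net, L2 penalty, Xavier init, Adam."""
    X = train.matrix.values
    y = train.label_indices()
    if len(set(train.labels)) < 2:
        raise ValueError("training data must contain >= 2 classes")
    sizes = (train.matrix.n_genes, *hidden_sizes, train.n_classes)
    rng = np.random.default_rng([config.seed, 2])
    weights, biases = _xavier_init(sizes, rng)
    sample = WeightSample(weights, biases)

    n = X.shape[0]
    opt = Adam([*weights, *biases], lr=config.learning_rate)
    history: list[float] = []
    n_batches = int(np.ceil(n / config.batch_size))
    lam = config.l2_strength
    for _ in range(config.epochs):
        epoch_loss = 0.0
        for idx in _batches(n, config.batch_size, rng):
            nll, gW, gb = _nll_and_grads(sample, X[idx], y[idx])
            penalty = lam * sum(float(np.sum(W**2)) for W in weights)
            loss = nll + penalty
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss ({loss})")
            gW = [g + 2.0 * lam * W for g, W in zip(gW, weights)]
            opt.step([*gW, *gb])
            epoch_loss += loss
        history.append(epoch_loss / n_batches)

    return DNNModel(
        weights=weights,
        biases=biases,
        class_names=train.class_names,
        feature_genes=train.matrix.gene_ids,
        loss_history=history,
    )


def train_logreg_baseline(
    train: LabeledDataset, config: TrainConfig = TrainConfig()
) -> LogRegModel:
    """L2-regularized multinomial logistic regression (sklearn, lbfgs)."""
    if len(set(train.labels)) < 2:
        raise ValueError("logistic regression needs >= 2 classes in training data")
    C = 1.0 / config.l2_strength if config.l2_strength > 0 else 1e12
    est = LogisticRegression(C=C, max_iter=5000)  # L2 penalty (sklearn default)
    est.fit(train.matrix.values, np.asarray(train.labels))
    return LogRegModel(
        estimator=est,
        class_names=train.class_names,
        feature_genes=train.matrix.gene_ids,
    )


# ---------------------------------------------------------------------------
# serialization (single JSON archive; supports inference on external cohorts)


def save_model(model: BNNModel, path: str | Path) -> None:
    payload = {
        "kind": "bnn",
        "layer_sizes": list(model.params.layer_sizes),
        "class_names": list(model.class_names),
        "feature_genes": list(model.feature_genes),
        "w_mu": [a.tolist() for a in model.params.w_mu],
        "w_rho": [a.tolist() for a in model.params.w_rho],
        "b_mu": [a.tolist() for a in model.params.b_mu],
        "b_rho": [a.tolist() for a in model.params.b_rho],
        "loss_history": model.loss_history,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> BNNModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("kind") != "bnn":
        raise ValueError(f"not a BNN model archive: {path}")
    params = VariationalParams(
        tuple(payload["layer_sizes"]),
        [np.asarray(a, dtype=float) for a in payload["w_mu"]],
        [np.asarray(a, dtype=float) for a in payload["w_rho"]],
        [np.asarray(a, dtype=float) for a in payload["b_mu"]],
        [np.asarray(a, dtype=float) for a in payload["b_rho"]],
    )
    return BNNModel(
        params=params,
        prior=PriorSpec(),
        class_names=tuple(payload["class_names"]),
        feature_genes=tuple(payload["feature_genes"]),
        loss_history=list(payload.get("loss_history", [])),
    )
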