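"""Epistemic uncertainty: Monte-Carlo prediction, filtering, OLS correction.

During inference, weights are repeatedly drawn from the variational
posterior (T = 500 draws by default) and the softmax outputs collected.
The per-sample epistemic uncertainty is the empirical second-moment matrix
of the draws around their mean,

    Xi = (1/T) sum_t (p_t - p_bar)(p_t - p_bar)^T ,

whose diagonal entries are per-class predictive variances; the scalar
uncertainty xi_i is the diagonal entry at the predicted class.  Two uses:

* filtering — discard test predictions whose xi_i is not below the mean
  xi_i of *correct training* predictions (raises accuracy on what is kept,
  at the cost of coverage);
* correction — per class, an OLS fit of logit(mean probability) on sqrt(xi)
  over training samples predicted as that class; at prediction time the
  fitted slope adjusts the mean probability for the uncertainty attached
  to it, without dropping any sample.

The correction has two formula variants (``canonical`` subtracts
beta*sqrt(xi) on the logit scale, matching the regression that produced
beta; ``literal`` applies f^-1(E[p] - beta*xi) with the mean probability
untransformed and xi to the first power) and two application scopes
(``predicted``: each class's coefficients correct the samples predicted as
that class, the population they were fitted on; ``all_classes``: every
class of every sample).  See :func:`apply_correction`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BNNModel, forward, sample_weights

__all__ = [
    "MCPredictions",
    "UncertaintyEstimate",
    "FilterResult",
    "CorrectionModel",
    "CorrectedPredictions",
    "mc_predict",
    "epistemic_matrix",
    "epistemic_scalar",
    "training_uncertainty_threshold",
    "filter_predictions",
    "logit",
    "inv_logit",
    "fit_correction",
    "apply_correction",
]

LOGIT_EPS = 1e-7  # probabilities clipped into [eps, 1-eps] before logit


@dataclass(frozen=True)
class MCPredictions:
    """T x N x C softmax draws with their mean and the implied class calls."""

    draws: np.ndarray
    mean_probs: np.ndarray
    predicted_class: np.ndarray

    @property
    def T(self) -> int:
        return self.draws.shape[0]

    @property
    def n_samples(self) -> int:
        return self.draws.shape[1]

    @property
    def n_classes(self) -> int:
        return self.draws.shape[2]


@dataclass(frozen=True)
class UncertaintyEstimate:
    """Per-sample scalar xi (variance at the predicted class) and all
    per-class diagonal variances."""

    predicted_class: np.ndarray  # (N,) int
    xi: np.ndarray  # (N,) variance at the predicted class
    class_variances: np.ndarray  # (N, C) diagonal of the uncertainty matrix


@dataclass(frozen=True)
class FilterResult:
    threshold: float
    retained: np.ndarray  # (N,) bool
    retained_fraction: float

    @property
    def empty(self) -> bool:
        return not bool(self.retained.any())


@dataclass(frozen=True)
class CorrectionModel:
    """Per-class OLS coefficients of logit(mean prob) ~ alpha + beta*sqrt(xi).

    Classes with fewer than 3 fit points get beta = 0 (alpha = mean
    response, or 0 when the class was never predicted) and are flagged.
    """

    alpha: np.ndarray  # (C,)
    beta: np.ndarray  # (C,)
    sigma2: np.ndarray  # (C,) residual variance
    n_points: np.ndarray  # (C,) int
    flagged: np.ndarray  # (C,) bool — insufficient points for a slope

    @property
    def n_classes(self) -> int:
        return self.alpha.shape[0]


@dataclass(frozen=True)
class CorrectedPredictions:
    probs: np.ndarray  # (N, C), each entry in (0, 1); not renormalized
    corrected_class: np.ndarray  # (N,) int argmax


def mc_predict(
    model: BNNModel, X: np.ndarray, T: int = 500, seed: int = 0
) -> MCPredictions:
    """T posterior weight draws, each pushed through the network."""
    if T < 1:
        raise ValueError("T must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_genes):
        raise ValueError(
            f"features must be aligned to the model's {len(model.feature_genes)} "
            "feature genes (use align_features)"
        )
    rng = np.random.default_rng(seed)
    draws = np.empty((T, X.shape[0], len(model.class_names)))
    for t in range(T):
        draws[t] = forward(sample_weights(model.params, rng), X)
    mean_probs = draws.mean(axis=0)
    return MCPredictions(
        draws=draws,
        mean_probs=mean_probs,
        predicted_class=np.argmax(mean_probs, axis=1),
    )


def epistemic_matrix(mcpred: MCPredictions, sample: int) -> np.ndarray:
    """C x C second-moment matrix of the draws for one sample."""
    if not 0 <= sample < mcpred.n_samples:
        raise IndexError(f"sample index {sample} out of range")
    dev = mcpred.draws[:, sample, :] - mcpred.mean_probs[sample]
    return dev.T @ dev / mcpred.T


def epistemic_scalar(mcpred: MCPredictions) -> UncertaintyEstimate:
    """Per-class draw variances; xi is the variance at the predicted class."""
    dev = mcpred.draws - mcpred.mean_probs[None, :, :]
    class_var = np.mean(dev**2, axis=0)  # (N, C)
    pred = mcpred.predicted_class
    xi = class_var[np.arange(mcpred.n_samples), pred]
    return UncertaintyEstimate(predicted_class=pred, xi=xi, class_variances=class_var)


def training_uncertainty_threshold(
    est: UncertaintyEstimate, y_true: np.ndarray, per_class: bool = False
) -> float | np.ndarray:
    """Mean xi over correctly classified samples (the filtering threshold).

    With ``per_class`` the mean is taken within each predicted class
    (classes with no correct prediction get NaN).
    """
    y_true = np.asarray(y_true, dtype=int)
    correct = est.predicted_class == y_true
    if not correct.any():
        raise ValueError("no correctly classified samples; threshold undefined")
    if not per_class:
        return float(np.mean(est.xi[correct]))
    n_classes = est.class_variances.shape[1]
    out = np.full(n_classes, np.nan)
    for c in range(n_classes):
        mask = correct & (est.predicted_class == c)
        if mask.any():
            out[c] = float(np.mean(est.xi[mask]))
    return out


def filter_predictions(est: UncertaintyEstimate, threshold: float) -> FilterResult:
    """Retain samples with xi strictly below the threshold (boundary drops)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    retained = est.xi < threshold
    return FilterResult(
        threshold=float(threshold),
        retained=retained,
        retained_fraction=float(np.mean(retained)) if retained.size else 0.0,
    )


def logit(p):
    """f(x) = ln(x / (1-x)), with clipping into [eps, 1-eps]."""
    p = np.asarray(p, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("logit requires finite input")
    p = np.clip(p, LOGIT_EPS, 1.0 - LOGIT_EPS)
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out

def inv_logit(z):
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("inv_logit requires finite input")
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return float(out) if out.ndim == 0 else out


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Least-squares intercept/slope/residual variance via normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(y) - 2, 1)
    return float(coef[0]), float(coef[1]), float(resid @ resid / dof)


def fit_correction(
    mean_probs: np.ndarray,
    est: UncertaintyEstimate,
    y_pred: np.ndarray | None = None,
) -> CorrectionModel:
    """Per class c, regress logit(mean prob of c) on sqrt(xi) by OLS over
    training samples predicted as c."""
    mean_probs = np.asarray(mean_probs, dtype=float)
    y_pred = est.predicted_class if y_pred is None else np.asarray(y_pred, dtype=int)
    n_classes = mean_probs.shape[1]
    alpha = np.zeros(n_classes)
    beta = np.zeros(n_classes)
    sigma2 = np.zeros(n_classes)
    n_points = np.zeros(n_classes, dtype=int)
    flagged = np.zeros(n_classes, dtype=bool)
    for c in range(n_classes):
        mask = y_pred == c
        n_points[c] = int(mask.sum())
        response = logit(mean_probs[mask, c])
        if n_points[c] < 3:
            flagged[c] = True
            alpha[c] = float(np.mean(response)) if n_points[c] else 0.0
            continue
        x = np.sqrt(est.xi[mask])
        if np.ptp(x) == 0.0:  # no spread in the regressor: slope unidentifiable
            flagged[c] = True
            alpha[c] = float(np.mean(response))
            continue
        alpha[c], beta[c], sigma2[c] = _ols_line(x, np.asarray(response))
    return CorrectionModel(alpha=alpha, beta=beta, sigma2=sigma2,
                           n_points=n_points, flagged=flagged)


def apply_correction(
    mean_probs: np.ndarray,
    est: UncertaintyEstimate,
    model: CorrectionModel,
    variant: str = "canonical",
    scope: str = "predicted",
) -> CorrectedPredictions:
    """Uncertainty-corrected probabilities.

    Correction formula per (sample, class):

    canonical: p_corr[c] = f^-1( f(E[p_c]) - beta_c * sqrt(xi^(c)) )
    literal:   p_corr[c] = f^-1( E[p_c] - beta_c * xi^(c) )

    ``scope`` controls which entries the formula touches.  The default
    ``predicted`` corrects each sample's predicted-class probability with
    that class's coefficients — the population the class's regression was
    fitted on — and leaves other classes' probabilities at their means, so
    the correction recalibrates the confidence reported with each call.
    ``all_classes`` applies every class's coefficients to every sample;
    this lets corrected calls flip, but because the adjustment
    -beta_c*sqrt(xi) then compares *per-class fit constants* across
    classes, a confusable class pair with asymmetric slopes can collapse
    onto one member.  Both scopes are exposed; see the methods note.
    """
    mean_probs = np.asarray(mean_probs, dtype=float)
    if mean_probs.shape[1] != model.n_classes:
        raise ValueError(
            f"correction model covers {model.n_classes} classes, "
            f"got probabilities for {mean_probs.shape[1]}"
        )
    var = est.class_variances
    if variant == "canonical":
        corrected = inv_logit(logit(mean_probs) - model.beta[None, :] * np.sqrt(var))
    elif variant == "literal":
        corrected = inv_logit(mean_probs - model.beta[None, :] * var)
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    if scope == "predicted":
        probs = mean_probs.copy()
        rows = np.arange(mean_probs.shape[0])
        probs[rows, est.predicted_class] = corrected[rows, est.predicted_class]
    elif scope == "all_classes":
        probs = corrected
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    return CorrectedPredictions(probs=probs, corrected_class=np.argmax(probs, axis=1))
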