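"""Maximum-likelihood fitting of SSD mixtures by expectation–maximization.

The E-step is the usual posterior-responsibility computation done with
log-sum-exp.  The M-step has no closed form for (alpha, beta, b): each
component is updated by bounded quasi-Newton (L-BFGS-B) on unconstrained
reparameterizations — ``log alpha``, softmax-parameterized ``beta`` and
``log b`` — with fully analytic gradients, warm-started from the current
parameters.  The mixing weights have the usual closed-form update.

The observed-data log-likelihood is guaranteed non-decreasing across
iterations (a component update is rejected if the optimizer fails to improve
its expected complete-data objective).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp, softmax
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .ssd import (
    B_MAX,
    B_MIN,
    SSDMixture,
    SSDParams,
    component_log_densities,
    mixture_sample,
    validate_compositions,
    _log_y,
)

__all__ = [
    "FitResult",
    "init_kmeans",
    "e_step",
    "m_step",
    "fit_em",
    "hard_membership",
    "weighted_negloglik",
    "ShiftedScaledDirichletMixture",
]

_LOG_ALPHA_BOUNDS = (np.log(1e-3), np.log(1e4))
_C_BOUNDS = (-30.0, 30.0)
_ALPHA_INIT_CLIP = (0.1, 500.0)


@dataclass
class FitResult:
    """Outcome of one EM run."""

    model: SSDMixture
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------------
# weighted single-component objective on transformed coordinates
# ---------------------------------------------------------------------------

def _pack(theta: SSDParams) -> np.ndarray:
    c = np.log(theta.beta)
    return np.concatenate([np.log(theta.alpha), c - c.mean(), [np.log(theta.b)]])


def _unpack(x: np.ndarray, dim: int) -> tuple[np.ndarray, np.ndarray, float]:
    alpha = np.exp(x[:dim])
    beta = softmax(x[dim : 2 * dim])
    b = float(np.exp(x[-1]))
    return alpha, beta, b


def weighted_negloglik(
    x: np.ndarray, log_y: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative weighted log-likelihood and its gradient in transformed coords.

    ``x`` concatenates ``log alpha`` (D), the softmax logits of ``beta`` (D)
    and ``log b`` (1); ``log_y`` is the (N, D) matrix of log compositions and
    ``w`` a non-negative weight per row (the responsibilities in EM).
    """
    n, dim = log_y.shape
    alpha, beta, b = _unpack(x, dim)
    a_plus = alpha.sum()
    log_beta = np.log(beta)
    u = log_y - log_beta                     # (N, D)
    z = u / b
    log_s = logsumexp(z, axis=1)             # (N,)
    r = softmax(z, axis=1)                   # (N, D)

    w_total = w.sum()
    sw_logy = w @ log_y                      # (D,)
    sw_logs = float(w @ log_s)
    sw_r = w @ r                             # (D,)

    const = gammaln(a_plus) - gammaln(alpha).sum() - (dim - 1) * np.log(b) - (alpha / b) @ log_beta
    f = w_total * const + (alpha / b - 1.0) @ sw_logy - a_plus * sw_logs

    g_alpha = w_total * (digamma(a_plus) - digamma(alpha) - log_beta / b) + sw_logy / b - sw_logs
    g_beta = (-alpha * w_total + a_plus * sw_r) / (b * beta)
    g_b = (
        -w_total * (dim - 1) / b
        - (alpha @ (w @ u)) / b**2
        + a_plus * float(w @ (r * u).sum(axis=1)) / b**2
    )

    grad = np.empty_like(x)
    grad[:dim] = alpha * g_alpha
    grad[dim : 2 * dim] = beta * (g_beta - beta @ g_beta)
    grad[-1] = b * g_b
    return -f, -grad


def _optimize_component(
    theta: SSDParams, log_y: np.ndarray, w: np.ndarray, maxiter: int = 60
) -> tuple[SSDParams, float, bool]:
    """Maximize the weighted log-likelihood of one component by L-BFGS-B.

    Returns (theta_new, objective_gain, ok); on optimizer failure or
    non-improvement the incoming theta is kept.
    """
    dim = theta.dim
    x0 = _pack(theta)
    f0, _ = weighted_negloglik(x0, log_y, w)
    bounds = (
        [_LOG_ALPHA_BOUNDS] * dim
        + [_C_BOUNDS] * dim
        + [(np.log(B_MIN), np.log(B_MAX))]
    )
    res = minimize(
        weighted_negloglik,
        x0,
        args=(log_y, w),
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={"maxiter": maxiter},
    )
    if not np.isfinite(res.fun) or res.fun > f0 - 1e-12:
        return theta, 0.0, False
    alpha, beta, b = _unpack(res.x, dim)
    return SSDParams(alpha, beta, b), f0 - float(res.fun), True


# ---------------------------------------------------------------------------
# EM building blocks
# ---------------------------------------------------------------------------

def _moment_match_alpha(x: np.ndarray) -> np.ndarray:
    """Dirichlet method-of-moments shape from a cluster of compositions.

    Precision comes from the first coordinate's mean/variance; the mean
    vector fixes the direction.  Falls back to precision 2D for degenerate
    clusters.
    """
    dim = x.shape[1]
    mean = x.mean(axis=0)
    mean = mean / mean.sum()
    if x.shape[0] >= 2:
        m1 = x[:, 0].mean()
        v1 = x[:, 0].var()
        precision = m1 * (1.0 - m1) / v1 - 1.0 if v1 > 1e-12 else 2.0 * dim
    else:
        precision = 2.0 * dim
    if not np.isfinite(precision) or precision <= 0:
        precision = 2.0 * dim
    return np.clip(precision * mean, *_ALPHA_INIT_CLIP)


def init_kmeans(data: np.ndarray, n_components: int, seed: int | None = 0) -> SSDMixture:
    """K-means initialization of an SSD mixture.

    Mixing weights are cluster fractions, each location is the renormalized
    cluster mean, b starts at 1 and alpha comes from Dirichlet moment
    matching on the cluster members.
    """
    data = validate_compositions(data, name="data")
    n = data.shape[0]
    if n_components < 1 or n_components > n:
        raise ValueError("need 1 <= n_components <= n_samples")
    rng = np.random.default_rng(seed)
    if n_components == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(
            n_clusters=n_components,
            n_init=5,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        labels = km.fit_predict(data)
    weights = np.empty(n_components)
    comps = []
    for k in range(n_components):
        members = data[labels == k]
        if members.shape[0] == 0:  # re-seed an empty cluster from a random point
            members = data[rng.integers(0, n)][None, :]
        weights[k] = max(members.shape[0], 1)
        mean = members.mean(axis=0)
        comps.append(SSDParams(_moment_match_alpha(members), mean / mean.sum(), 1.0))
    weights /= weights.sum()
    return SSDMixture(weights, tuple(comps))


def e_step(data: np.ndarray, model: SSDMixture) -> np.ndarray:
    """Posterior responsibilities (N, K); every row sums to 1."""
    comp = component_log_densities(data, model) + np.log(model.weights)
    return softmax(comp, axis=1)


def hard_membership(responsibilities: np.ndarray) -> np.ndarray:
    """Hard assignments: argmax of each responsibility row (ties -> lowest index)."""
    return np.argmax(responsibilities, axis=1)


def m_step(
    data: np.ndarray, responsibilities: np.ndarray, model: SSDMixture, maxiter: int = 60
) -> SSDMixture:
    """One M-step: closed-form weights, quasi-Newton component updates."""
    data = validate_compositions(data, name="data")
    z = np.asarray(responsibilities, dtype=float)
    if z.shape != (data.shape[0], model.n_components):
        raise ValueError("responsibility matrix does not match data/model")
    log_y = _log_y(data)
    weights = z.sum(axis=0) / z.shape[0]
    weights = np.clip(weights, 1e-12, None)
    weights /= weights.sum()
    comps = []
    for k, theta in enumerate(model.components):
        w = z[:, k]
        if w.sum() < 1e-12:
            comps.append(theta)
            continue
        theta_new, _, _ = _optimize_component(theta, log_y, w, maxiter=maxiter)
        comps.append(theta_new)
    return SSDMixture(weights, tuple(comps))


def _reinit_component(model: SSDMixture, k: int, data: np.ndarray) -> SSDMixture:
    """Re-seed component k from the worst-fit data point."""
    from .ssd import mixture_log_density_many

    ll = mixture_log_density_many(data, model)
    worst = data[int(np.argmin(ll))]
    dim = model.dim
    comps = list(model.components)
    comps[k] = SSDParams(np.clip(2.0 * dim * worst, *_ALPHA_INIT_CLIP), worst, 1.0)
    w = model.weights.copy()
    w[k] = 1.0 / data.shape[0]
    w /= w.sum()
    return SSDMixture(w, tuple(comps))


def fit_em(
    data: np.ndarray,
    n_components: int,
    *,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = 0,
    m_step_maxiter: int = 60,
) -> FitResult:
    """Fit an SSD mixture by EM from a K-means start.

    Iterates E/M until the relative change in total log-likelihood falls
    below ``tol`` or ``max_iter`` is reached.  Deterministic under a fixed
    seed.  A component whose weight collapses below 1/(2N) is re-seeded once
    from the worst-fit point, then dropped (with a warning) on a second
    collapse; the trace restarts at such an intervention.
    """
    data = validate_compositions(data, name="data")
    n = data.shape[0]
    if n < n_components:
        raise ValueError("need at least as many points as components")
    if np.max(data.max(axis=0) - data.min(axis=0)) < 1e-12:
        raise ValueError("degenerate data: all points identical")

    model = init_kmeans(data, n_components, seed=seed)
    retried: set[int] = set()
    comp_ll = component_log_densities(data, model) + np.log(model.weights)
    loglik = float(logsumexp(comp_ll, axis=1).sum())
    trace = [loglik]
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        z = softmax(comp_ll, axis=1)
        model = m_step(data, z, model, maxiter=m_step_maxiter)

        # component-death handling
        floor = 1.0 / (2.0 * n)
        dead = [k for k, w in enumerate(model.weights) if w < floor]
        intervened = False
        for k in dead:
            if model.n_components == 1:
                break
            if k not in retried:
                retried.add(k)
                model = _reinit_component(model, k, data)
                intervened = True
            else:
                warnings.warn(f"dropping collapsed mixture component {k}")
                keep = [j for j in range(model.n_components) if j != k]
                w = model.weights[keep]
                model = SSDMixture(w / w.sum(), tuple(model.components[j] for j in keep))
                intervened = True
                break

        comp_ll = component_log_densities(data, model) + np.log(model.weights)
        new_loglik = float(logsumexp(comp_ll, axis=1).sum())
        if intervened:
            trace = [new_loglik]
            loglik = new_loglik
            continue
        trace.append(new_loglik)
        if abs(new_loglik - loglik) < tol * (abs(loglik) + 1e-12):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    return FitResult(model, np.asarray(trace), it, converged)


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class ShiftedScaledDirichletMixture(DensityMixin, BaseEstimator):
    """Finite shifted-scaled Dirichlet mixture, scikit-learn style.

    Parameters
    ----------
    n_components : int, default=1
        Number of mixture components K.
    max_iter : int, default=200
        Maximum EM iterations.
    tol : float, default=1e-6
        Relative log-likelihood change below which EM stops.
    random_state : int or None, default=None
        Seed for the K-means initialization; fixing it makes ``fit``
        bit-reproducible.

    Attributes
    ----------
    weights_ : ndarray of shape (K,)
    alphas_ : ndarray of shape (K, D)
    betas_ : ndarray of shape (K, D)
    bs_ : ndarray of shape (K,)
    mixture_ : SSDMixture
    loglik_trace_ : ndarray
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_components: int = 1,
        max_iter: int = 200,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        result = fit_em(
            X,
            self.n_components,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state if self.random_state is not None else 0,
        )
        self.mixture_ = result.model
        self.weights_ = result.model.weights
        self.alphas_ = np.vstack([c.alpha for c in result.model.components])
        self.betas_ = np.vstack([c.beta for c in result.model.components])
        self.bs_ = np.array([c.b for c in result.model.components])
        self.loglik_trace_ = result.loglik_trace
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        return self

    def score_samples(self, X):
        check_is_fitted(self, "mixture_")
        from .ssd import mixture_log_density_many

        return mixture_log_density_many(X, self.mixture_)

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))

    def predict_proba(self, X):
        check_is_fitted(self, "mixture_")
        return e_step(X, self.mixture_)

    def predict(self, X):
        return hard_membership(self.predict_proba(X))

    def sample(self, n_samples: int = 1, seed: int | None = None):
        check_is_fitted(self, "mixture_")
        return mixture_sample(self.mixture_, n_samples, seed)
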