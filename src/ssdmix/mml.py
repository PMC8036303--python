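"""Minimum Message Length (MML) scoring and selection of the component count.

The message length of a fitted K-component SSD mixture on data Y is

    MML = -log p(Theta) - L(Theta, Y) + 1/2 log|F(Theta)| + Np/2 + Np/2 log(1/12)

with Np = K(2D+1) - 1 free parameters, a factorized prior
p(Theta) = p(pi) p(beta) p(b) p(alpha) and a block-diagonal Fisher
information |F| = |F(pi)| prod_j |F(theta_j)|.  The weight block uses the
standard mixture form N^(K-1) / prod_j pi_j; the per-component blocks are
numerically evaluated Hessians of the negative responsibility-weighted
log-likelihood on minimal transformed coordinates (log alpha, additive
log-ratio beta, log b).

The quantization-lattice constant is fixed at 1/12 for every Np (its value
for Np = 1; the asymptotic value 1/(2 pi e) differs by little).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .em import e_step, fit_em
from .ssd import SSDMixture, SSDParams, mixture_log_density_many, validate_compositions, _log_y

__all__ = [
    "LATTICE_K1",
    "LATTICE_ASYMPTOTIC",
    "MMLReport",
    "num_params",
    "log_prior",
    "fisher_info_logdet",
    "message_length",
    "select_k",
]

#: optimal quantization lattice constant for Np = 1 (used for every Np)
LATTICE_K1 = 1.0 / 12.0
#: asymptotic lattice constant 1/(2 pi e), the large-Np limit
LATTICE_ASYMPTOTIC = 1.0 / (2.0 * np.pi * np.e)


def num_params(n_components: int, dim: int) -> int:
    """Free-parameter count Np = K(2D+1) - 1.

    Each component carries alpha (D), beta (D-1 free) and b (1); the weights
    add K-1.
    """
    if n_components < 1 or dim < 2:
        raise ValueError("need K >= 1 and D >= 2")
    return n_components * (2 * dim + 1) - 1


def log_prior(model: SSDMixture, alpha_hat: np.ndarray | None = None) -> float:
    """Log of the factorized parameter prior p(pi) p(beta) p(b) p(alpha).

    Symmetric Dirichlet(1) priors on the weights and each location (densities
    Gamma(K) and Gamma(D)), a constant 1/10 prior on each scale b, and a
    uniform box of width e^6 ||alpha_hat_j|| per shape coordinate, where
    ``alpha_hat`` defaults to the model's own fitted shapes.
    """
    k, d = model.n_components, model.dim
    if alpha_hat is None:
        alpha_hat = np.vstack([c.alpha for c in model.components])
    alpha_hat = np.atleast_2d(np.asarray(alpha_hat, dtype=float))
    norms = np.linalg.norm(alpha_hat, axis=1)
    if np.any(norms <= 0):
        raise ValueError("alpha_hat has a zero-norm row")
    lp = gammaln(k)                      # Dirichlet(1,...,1) on pi
    lp += k * gammaln(d)                 # Dirichlet(1,...,1) on each beta
    lp += k * np.log(0.1)                # p(b) = 1/10 per component
    lp += float(np.sum(-6.0 - np.log(norms)) * d)  # uniform box per alpha coord
    return float(lp)


# ---------------------------------------------------------------------------
# per-component Hessian on minimal coordinates
# ---------------------------------------------------------------------------

def _theta_to_minimal(theta: SSDParams) -> np.ndarray:
    alr = np.log(theta.beta[:-1]) - np.log(theta.beta[-1])
    return np.concatenate([np.log(theta.alpha), alr, [np.log(theta.b)]])


def _minimal_negloglik(x: np.ndarray, log_y: np.ndarray, w: np.ndarray, dim: int) -> float:
    alpha = np.exp(x[:dim])
    logits = np.concatenate([x[dim : 2 * dim - 1], [0.0]])
    beta = np.exp(logits - logsumexp(logits))
    b = float(np.exp(x[-1]))
    a_plus = alpha.sum()
    log_beta = np.log(beta)
    log_s = logsumexp((log_y - log_beta) / b, axis=1)
    w_total = w.sum()
    const = gammaln(a_plus) - gammaln(alpha).sum() - (dim - 1) * np.log(b) - (alpha / b) @ log_beta
    f = w_total * const + (alpha / b - 1.0) @ (w @ log_y) - a_plus * float(w @ log_s)
    return -f


def _fd_hessian(fun, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian with per-coordinate step h(1+|x|)."""
    p = x0.size
    h = rel_step * (1.0 + np.abs(x0))
    hess = np.empty((p, p))
    f0 = fun(x0)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        fpp = fun(x0 + ei)
        fmm = fun(x0 - ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            fa = fun(x0 + ei + ej)
            fb = fun(x0 + ei - ej)
            fc = fun(x0 - ei + ej)
            fd = fun(x0 - ei - ej)
            hess[i, j] = hess[j, i] = (fa - fb - fc + fd) / (4.0 * h[i] * h[j])
    return hess


def component_hessian(theta: SSDParams, data: np.ndarray, w: np.ndarray) -> np.ndarray:
    """FD Hessian of the negative w-weighted log-likelihood at theta.

    Evaluated on the 2D minimal coordinates (log alpha, ALR(beta), log b).
    """
    log_y = _log_y(validate_compositions(data))
    x0 = _theta_to_minimal(theta)
    return _fd_hessian(lambda x: _minimal_negloglik(x, log_y, w, theta.dim), x0)


def fisher_info_logdet(
    model: SSDMixture,
    data: np.ndarray,
    *,
    fisher_pi_form: str = "standard",
    return_details: bool = False,
):
    """log|F(Theta)| = log|F(pi)| + sum_j log|F(theta_j)|.

    ``fisher_pi_form="standard"`` uses N^(K-1)/prod_j pi_j; ``"as_printed"``
    uses N prod_j pi_j.  Non-positive-definite component Hessians are
    regularized by adding a multiple of the identity (at least 1e-6) before
    the determinant; the regularization is flagged in the details.
    """
    data = validate_compositions(data, name="data")
    n = data.shape[0]
    k = model.n_components
    if fisher_pi_form == "standard":
        log_f_pi = (k - 1) * np.log(n) - float(np.log(model.weights).sum())
    elif fisher_pi_form == "as_printed":
        log_f_pi = np.log(n) + float(np.log(model.weights).sum())
    else:
        raise ValueError("fisher_pi_form must be 'standard' or 'as_printed'")

    z = e_step(data, model)
    total = log_f_pi
    regularized = False
    for j, theta in enumerate(model.components):
        hess = component_hessian(theta, data, z[:, j])
        eigvals = np.linalg.eigvalsh(0.5 * (hess + hess.T))
        if eigvals.min() <= 0:
            regularized = True
            hess = hess + (abs(eigvals.min()) + 1e-6) * np.eye(hess.shape[0])
        sign, logdet = np.linalg.slogdet(0.5 * (hess + hess.T))
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError(
                f"component {j}: Hessian singular after regularization"
            )
        total += logdet
    if return_details:
        return float(total), {"log_f_pi": log_f_pi, "regularized": regularized}
    return float(total)


def message_length(
    model: SSDMixture,
    data: np.ndarray,
    *,
    fisher_pi_form: str = "standard",
    return_details: bool = False,
):
    """Two-part message length of (model, data); smaller is better."""
    data = validate_compositions(data, name="data")
    np_ = num_params(model.n_components, model.dim)
    loglik = float(mixture_log_density_many(data, model).sum())
    lp = log_prior(model)
    fisher, details = fisher_info_logdet(
        model, data, fisher_pi_form=fisher_pi_form, return_details=True
    )
    ml = -lp - loglik + 0.5 * fisher + 0.5 * np_ + 0.5 * np_ * np.log(LATTICE_K1)
    if return_details:
        return float(ml), {
            "loglik": loglik,
            "log_prior": lp,
            "fisher_logdet": fisher,
            "Np": np_,
            "regularized": details["regularized"],
        }
    return float(ml)


@dataclass
class MMLReport:
    """Per-K message-length records and the selected component count."""

    records: list[dict] = field(default_factory=list)
    best_k: int = 0

    def to_dict(self) -> dict:
        return {"best_k": self.best_k, "records": self.records}


def select_k(
    data: np.ndarray,
    k_range,
    *,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    fisher_pi_form: str = "standard",
) -> MMLReport:
    """Fit each K in ``k_range`` by EM and pick the minimum message length.

    Every fit shares the same seed policy; ties break toward smaller K.
    """
    data = validate_compositions(data, name="data")
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    if max(ks) > data.shape[0]:
        raise ValueError("max K exceeds the number of data points")
    records = []
    for k in ks:
        try:
            fit = fit_em(data, k, max_iter=max_iter, tol=tol, seed=seed)
            ml, det = message_length(
                data=data, model=fit.model, fisher_pi_form=fisher_pi_form, return_details=True
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            records.append({"K": k, "error": str(exc)})
            continue
        records.append(
            {
                "K": k,
                "message_length": ml,
                "loglik": det["loglik"],
                "log_prior": det["log_prior"],
                "fisher_logdet": det["fisher_logdet"],
                "Np": det["Np"],
                "fitted_components": fit.model.n_components,
                "converged": fit.converged,
                "regularized": det["regularized"],
            }
        )
    scored = [r for r in records if "message_length" in r]
    if not scored:
        raise RuntimeError("all mixture fits failed during model selection")
    best = min(scored, key=lambda r: (r["message_length"], r["K"]))
    return MMLReport(records=records, best_k=int(best["K"]))
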