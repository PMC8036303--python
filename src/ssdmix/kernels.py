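"""Mixture-derived SVM kernels: Fisher, symmetrized-KL, Bhattacharyya.

Three ways of turning fitted generative models into a Gram matrix between
images:

* **Fisher kernel** — every image is scored by the gradient of its bag
  log-likelihood under one shared background mixture (with respect to the
  mixing weights and the shape vectors); the kernel is the inner product of
  the scores after per-coordinate standardization (an identity approximation
  of the Fisher information, with a diagonal-second-moment option).
* **Symmetrized-KL kernel (SKK)** — ``exp(-B * D_sym)`` where ``D_sym`` is
  the two-sided Kullback–Leibler divergence between the two images'
  per-image mixtures, estimated by Monte Carlo.
* **Bhattacharyya kernel (BK)** — the affinity ``integral sqrt(p q)``
  estimated by two-sided importance sampling between per-image mixtures.

Neither MC kernel is guaranteed positive semidefinite; ``ensure_psd``
clips negative eigenvalues before SVM training.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, logsumexp
from sklearn.base import BaseEstimator, TransformerMixin

from .em import e_step, fit_em
from .ssd import (
    FeatureBag,
    SSDMixture,
    mixture_log_density_many,
    mixture_sample,
    validate_compositions,
    _log_y,
)

__all__ = [
    "FisherScore",
    "fisher_score",
    "fisher_kernel_matrix",
    "skl_divergence_mc",
    "bhattacharyya_mc",
    "skk_kernel_matrix",
    "bk_kernel_matrix",
    "ensure_psd",
    "FisherKernel",
    "MixtureDivergenceKernel",
]


# ---------------------------------------------------------------------------
# generic model interface (SSD mixtures and sklearn Gaussian mixtures)
# ---------------------------------------------------------------------------

def _model_logpdf(model, x: np.ndarray) -> np.ndarray:
    if isinstance(model, SSDMixture):
        return mixture_log_density_many(x, model)
    return model.score_samples(x)  # e.g. sklearn GaussianMixture


def _model_sample(model, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(model, SSDMixture):
        return mixture_sample(model, n, rng)
    # seed-controlled ancestral sampling for sklearn GaussianMixture
    counts = rng.multinomial(n, model.weights_)
    parts = []
    for k, c in enumerate(counts):
        if c == 0:
            continue
        cov = model.covariances_[k]
        if cov.ndim == 1:  # diag
            cov = np.diag(cov)
        parts.append(rng.multivariate_normal(model.means_[k], cov, size=int(c)))
    return rng.permutation(np.vstack(parts))


def _model_dim(model) -> int:
    return model.dim if isinstance(model, SSDMixture) else model.means_.shape[1]


def _pair_seed(master_seed: int, id_a, id_b) -> np.random.SeedSequence:
    """Deterministic seed for an unordered pair of image ids."""
    ha = zlib.crc32(str(id_a).encode())
    hb = zlib.crc32(str(id_b).encode())
    lo, hi = sorted((ha, hb))
    return np.random.SeedSequence([int(master_seed) % 2**31, lo, hi])


# ---------------------------------------------------------------------------
# Fisher scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FisherScore:
    """Gradient of a bag's log-likelihood under the background mixture.

    ``grad_pi`` holds the K-1 free weight derivatives (component 1 carries
    the sum constraint); ``grad_alpha`` the K x D shape derivatives.  Both
    are normalized by the bag size.
    """

    grad_pi: np.ndarray
    grad_alpha: np.ndarray

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.grad_pi, self.grad_alpha.ravel()])


def fisher_score(bag: FeatureBag, ref_model: SSDMixture) -> FisherScore:
    """Fisher score of one bag under the shared background mixture.

    The alpha block is the exact gradient of ``sum_i log p(y_i | Theta)``
    with respect to each component's shape vector:
    ``sum_i Z_ij [psi(alpha_j+) - psi(alpha_jd) + (log y_id - log beta_jd)/b_j
    - log sum_d (y_id/beta_jd)^(1/b_j)]``; the weight block is
    ``sum_i (Z_ij/pi_j - Z_i1/pi_1)`` for j = 2..K.
    """
    if bag.dim != ref_model.dim:
        raise ValueError("bag and reference model dimension mismatch")
    y = bag.vectors
    z = e_step(y, ref_model)                       # (N, K)
    pi = ref_model.weights
    grad_pi = (z[:, 1:] / pi[1:] - z[:, [0]] / pi[0]).sum(axis=0)
    log_y = _log_y(y)
    rows = []
    for j, theta in enumerate(ref_model.components):
        u = log_y - np.log(theta.beta)             # (N, D)
        log_s = logsumexp(u / theta.b, axis=1)     # (N,)
        term = (
            digamma(theta.alpha_plus)
            - digamma(theta.alpha)[None, :]
            + u / theta.b
            - log_s[:, None]
        )
        rows.append(z[:, j] @ term)
    grad_alpha = np.vstack(rows)
    n = bag.size
    return FisherScore(grad_pi / n, grad_alpha / n)


def _score_matrix(bags, ref_model) -> np.ndarray:
    return np.vstack([fisher_score(b, ref_model).concatenated for b in bags])


def fisher_kernel_matrix(
    bags,
    ref_model: SSDMixture,
    *,
    information: str = "identity",
    return_ids: bool = False,
):
    """Train Gram matrix of standardized Fisher scores.

    ``information="identity"`` standardizes each score coordinate across the
    bags (zero mean, unit variance) and takes plain inner products;
    ``"diagonal"`` instead scales by the inverse empirical second moment.
    """
    u = _score_matrix(bags, ref_model)
    if information == "identity":
        scale = u.std(axis=0)
        u = (u - u.mean(axis=0)) / np.where(scale > 1e-12, scale, 1.0)
    elif information == "diagonal":
        m2 = np.sqrt((u**2).mean(axis=0))
        u = u / np.where(m2 > 1e-12, m2, 1.0)
    else:
        raise ValueError("information must be 'identity' or 'diagonal'")
    gram = u @ u.T
    gram = 0.5 * (gram + gram.T)
    if return_ids:
        return gram, [b.image_id for b in bags]
    return gram


# ---------------------------------------------------------------------------
# Monte Carlo divergences between mixtures
# ---------------------------------------------------------------------------

def skl_divergence_mc(
    p1,
    p2,
    n_samples: int = 5000,
    seed: int | np.random.SeedSequence | None = 0,
    *,
    one_sided: bool = False,
) -> tuple[float, float]:
    """Symmetrized KL divergence between two mixtures, by Monte Carlo.

    Returns ``(estimate, standard_error)``.  The two-sided form averages
    ``log p1/p2`` under samples of p1 and ``log p2/p1`` under samples of p2;
    ``one_sided=True`` keeps only the first term.
    """
    if _model_dim(p1) != _model_dim(p2):
        raise ValueError("mixtures must share the dimension D")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    x = _model_sample(p1, n_samples, rng)
    t1 = _model_logpdf(p1, x) - _model_logpdf(p2, x)
    est = t1.mean()
    var = t1.var() / n_samples
    if not one_sided:
        z = _model_sample(p2, n_samples, rng)
        t2 = _model_logpdf(p2, z) - _model_logpdf(p1, z)
        est += t2.mean()
        var += t2.var() / n_samples
    return float(est), float(np.sqrt(var))


def bhattacharyya_mc(
    p,
    q,
    n_samples: int = 5000,
    seed: int | np.random.SeedSequence | None = 0,
    *,
    mc_mix_weight: float = 0.5,
) -> tuple[float, float]:
    """Bhattacharyya affinity ``integral sqrt(p q)`` by importance sampling.

    Two-sided estimator: ``w * E_p[sqrt(q/p)] + (1-w) * E_q[sqrt(p/q)]`` with
    mixing weight ``w = mc_mix_weight``.  Returns ``(estimate, SE)``; the
    affinity of a mixture with itself is exactly 1.
    """
    if _model_dim(p) != _model_dim(q):
        raise ValueError("mixtures must share the dimension D")
    if not 0.0 <= mc_mix_weight <= 1.0:
        raise ValueError("mc_mix_weight must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    w = mc_mix_weight
    est, var = 0.0, 0.0
    if w > 0:
        x = _model_sample(p, n_samples, rng)
        t1 = np.exp(0.5 * (_model_logpdf(q, x) - _model_logpdf(p, x)))
        est += w * t1.mean()
        var += w**2 * t1.var() / n_samples
    if w < 1:
        z = _model_sample(q, n_samples, rng)
        t2 = np.exp(0.5 * (_model_logpdf(p, z) - _model_logpdf(q, z)))
        est += (1 - w) * t2.mean()
        var += (1 - w) ** 2 * t2.var() / n_samples
    return float(est), float(np.sqrt(var))


# ---------------------------------------------------------------------------
# kernel matrices between per-image mixtures
# ---------------------------------------------------------------------------

def _combine(models_a, samples_a, models_b, samples_b):
    """Merge the two model sets (deduplicated when they are the same object)."""
    if models_b is models_a and samples_b is samples_a:
        idx_a = idx_b = list(range(len(models_a)))
        return list(models_a), list(samples_a), idx_a, idx_b
    models = list(models_a) + list(models_b)
    samples = list(samples_a) + list(samples_b)
    idx_a = list(range(len(models_a)))
    idx_b = list(range(len(models_a), len(models)))
    return models, samples, idx_a, idx_b


def _divergence_matrix_per_model(models_a, samples_a, models_b, samples_b):
    """(len_a, len_b) matrix of two-sided KL divergences from cached samples."""
    models, samples, idx_a, idx_b = _combine(models_a, samples_a, models_b, samples_b)
    # ll[i, j] = E_{x ~ sample set i}[log model_j(x)]
    ll = np.array([[_model_logpdf(m, s).mean() for m in models] for s in samples])
    d = np.empty((len(idx_a), len(idx_b)))
    for r, i in enumerate(idx_a):
        for c, j in enumerate(idx_b):
            d[r, c] = (ll[i, i] - ll[i, j]) + (ll[j, j] - ll[j, i])
    return d


def _affinity_matrix_per_model(models_a, samples_a, models_b, samples_b, mc_mix_weight):
    """(len_a, len_b) Bhattacharyya affinities from cached samples."""
    models, samples, idx_a, idx_b = _combine(models_a, samples_a, models_b, samples_b)
    w = mc_mix_weight
    # lp[i][:, j]: log model_j at the points of sample set i
    lp = [np.column_stack([_model_logpdf(m, s) for m in models]) for s in samples]
    out = np.empty((len(idx_a), len(idx_b)))
    for r, i in enumerate(idx_a):
        for c, j in enumerate(idx_b):
            t1 = np.exp(0.5 * (lp[i][:, j] - lp[i][:, i])).mean()
            t2 = np.exp(0.5 * (lp[j][:, i] - lp[j][:, j])).mean()
            out[r, c] = w * t1 + (1 - w) * t2
    return out


def skk_kernel_matrix(
    models,
    *,
    B: float = 1.0,
    n_samples: int = 5000,
    seed: int = 0,
    strategy: str = "per_model",
    psd_repair: bool = False,
    one_sided: bool = False,
) -> np.ndarray:
    """Symmetric SKK Gram matrix ``exp(-B * D_sym)`` between per-image models.

    ``strategy="per_model"`` caches one MC sample set per model (symmetry by
    construction, O(M L) draws); ``"per_pair"`` draws with a dedicated seed
    per unordered pair.  The diagonal is exactly 1.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    m = len(models)
    gram = np.ones((m, m))
    if strategy == "per_model":
        rng_children = np.random.SeedSequence(seed).spawn(m)
        samples = [_model_sample(mod, n_samples, np.random.default_rng(s))
                   for mod, s in zip(models, rng_children)]
        models_l = list(models)
        d = _divergence_matrix_per_model(models_l, samples, models_l, samples)
        d = 0.5 * (d + d.T)
        gram = np.exp(-B * d)
    elif strategy == "per_pair":
        for i in range(m):
            for j in range(i + 1, m):
                dv, _ = skl_divergence_mc(
                    models[i], models[j], n_samples, _pair_seed(seed, i, j),
                    one_sided=one_sided,
                )
                gram[i, j] = gram[j, i] = np.exp(-B * dv)
    else:
        raise ValueError("strategy must be 'per_model' or 'per_pair'")
    np.fill_diagonal(gram, 1.0)
    if psd_repair:
        gram = ensure_psd(gram)
    return gram


def bk_kernel_matrix(
    models,
    *,
    n_samples: int = 5000,
    seed: int = 0,
    strategy: str = "per_model",
    mc_mix_weight: float = 0.5,
    psd_repair: bool = False,
) -> np.ndarray:
    """Symmetric Bhattacharyya Gram matrix with unit diagonal."""
    m = len(models)
    if strategy == "per_model":
        rng_children = np.random.SeedSequence(seed).spawn(m)
        samples = [_model_sample(mod, n_samples, np.random.default_rng(s))
                   for mod, s in zip(models, rng_children)]
        models_l = list(models)
        gram = _affinity_matrix_per_model(
            models_l, samples, models_l, samples, mc_mix_weight
        )
        gram = 0.5 * (gram + gram.T)
    elif strategy == "per_pair":
        gram = np.ones((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                bc, _ = bhattacharyya_mc(
                    models[i], models[j], n_samples, _pair_seed(seed, i, j),
                    mc_mix_weight=mc_mix_weight,
                )
                gram[i, j] = gram[j, i] = bc
    else:
        raise ValueError("strategy must be 'per_model' or 'per_pair'")
    np.fill_diagonal(gram, 1.0)
    if psd_repair:
        gram = ensure_psd(gram)
    return gram


def ensure_psd(matrix: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(0.5 * (matrix + matrix.T))
    out = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    out = 0.5 * (out + out.T)
    out[np.diag_indices_from(out)] += jitter
    return out


# ---------------------------------------------------------------------------
# scikit-learn style kernel builders
# ---------------------------------------------------------------------------

class FisherKernel(BaseEstimator, TransformerMixin):
    """Fisher-kernel Gram builder over feature bags.

    ``fit`` pools the training bags' descriptors, fits the background SSD
    mixture and freezes the score standardization; ``transform`` returns the
    Gram block K(X, X_train).
    """

    def __init__(
        self,
        n_components: int = 4,
        information: str = "identity",
        max_iter: int = 100,
        tol: float = 1e-5,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.information = information
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        bags = list(X)
        pooled = np.vstack([b.vectors for b in bags])
        fit = fit_em(
            pooled,
            self.n_components,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )
        self.background_model_ = fit.model
        self.n_train_descriptors_ = pooled.shape[0]
        u = _score_matrix(bags, fit.model)
        if self.information == "identity":
            self.center_ = u.mean(axis=0)
            scale = u.std(axis=0)
        elif self.information == "diagonal":
            self.center_ = np.zeros(u.shape[1])
            scale = np.sqrt((u**2).mean(axis=0))
        else:
            raise ValueError("information must be 'identity' or 'diagonal'")
        self.scale_ = np.where(scale > 1e-12, scale, 1.0)
        self.train_scores_ = (u - self.center_) / self.scale_
        self.train_ids_ = [b.image_id for b in bags]
        return self

    def transform(self, X):
        u = _score_matrix(list(X), self.background_model_)
        u = (u - self.center_) / self.scale_
        return u @ self.train_scores_.T

    def fit_transform(self, X, y=None):
        self.fit(X, y)
        gram = self.train_scores_ @ self.train_scores_.T
        return 0.5 * (gram + gram.T)


class MixtureDivergenceKernel(BaseEstimator, TransformerMixin):
    """SKK or Bhattacharyya Gram builder from per-image mixtures.

    ``fit`` fits one small SSD mixture per training bag (labels are never
    used) and caches a Monte Carlo sample set per model; ``transform`` fits
    models for new bags and returns the affinity block against the training
    models.
    """

    def __init__(
        self,
        kind: str = "skk",
        n_components: int = 2,
        B: float = 1.0,
        n_samples: int = 5000,
        mc_mix_weight: float = 0.5,
        psd_repair: bool = True,
        max_iter: int = 100,
        tol: float = 1e-5,
        random_state: int = 0,
    ):
        self.kind = kind
        self.n_components = n_components
        self.B = B
        self.n_samples = n_samples
        self.mc_mix_weight = mc_mix_weight
        self.psd_repair = psd_repair
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _fit_models(self, bags):
        models, samples = [], []
        for bag in bags:
            child = np.random.SeedSequence(
                [int(self.random_state), zlib.crc32(str(bag.image_id).encode())]
            )
            seeds = child.generate_state(2)
            k = min(self.n_components, bag.size)
            fit = fit_em(
                bag.vectors, k, max_iter=self.max_iter, tol=self.tol,
                seed=int(seeds[0] % 2**31),
            )
            models.append(fit.model)
            samples.append(
                _model_sample(fit.model, self.n_samples, np.random.default_rng(seeds[1]))
            )
        return models, samples

    def fit(self, X, y=None):
        if self.kind not in ("skk", "bhattacharyya"):
            raise ValueError("kind must be 'skk' or 'bhattacharyya'")
        bags = list(X)
        self.models_, self.samples_ = self._fit_models(bags)
        self.train_ids_ = [b.image_id for b in bags]
        return self

    def _block(self, models_a, samples_a, models_b, samples_b):
        if self.kind == "skk":
            d = _divergence_matrix_per_model(models_a, samples_a, models_b, samples_b)
            return np.exp(-self.B * d)
        return _affinity_matrix_per_model(
            models_a, samples_a, models_b, samples_b, self.mc_mix_weight
        )

    def transform(self, X):
        models, samples = self._fit_models(list(X))
        return self._block(models, samples, self.models_, self.samples_)

    def fit_transform(self, X, y=None):
        self.fit(X, y)
        gram = self._block(self.models_, self.samples_, self.models_, self.samples_)
        gram = 0.5 * (gram + gram.T)
        np.fill_diagonal(gram, 1.0)
        if self.psd_repair:
            gram = ensure_psd(gram)
        return gram
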