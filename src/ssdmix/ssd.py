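"""Shifted-scaled Dirichlet (SSD) distribution on the simplex.

The SSD is a three-parameter family on the open unit simplex
``S_D = {y : y_d > 0, sum y_d = 1}`` generalizing the Dirichlet.  A draw is
obtained from a Dirichlet variate ``x ~ Dir(alpha)`` by powering and
perturbing::

    y_d = beta_d * x_d**b / sum_j beta_j * x_j**b

``alpha`` (positive D-vector) is a shape parameter, ``beta`` (a point of the
simplex) a location, and ``b > 0`` a scale.  ``b = 1`` recovers the scaled
Dirichlet; ``b = 1`` with uniform ``beta`` recovers the Dirichlet itself.

All density work is done in log space with log-sum-exp; no raw products of
Gamma functions are ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "SSDParams",
    "SSDMixture",
    "FeatureBag",
    "ssd_log_density",
    "ssd_log_density_many",
    "ssd_sample",
    "mixture_log_density",
    "mixture_log_density_many",
    "mixture_sample",
    "component_log_densities",
    "project_to_simplex",
    "validate_compositions",
    "B_MIN",
    "B_MAX",
    "INTERIOR_CLIP",
]

#: bounds on the scale parameter during estimation; unbounded b makes the
#: likelihood surface flat through the 1/b^(D-1) degeneracy
B_MIN = 0.05
B_MAX = 20.0

#: entries of a composition are clipped to at least this before taking logs
INTERIOR_CLIP = 1e-12

_SIMPLEX_ATOL = 1e-9


def validate_compositions(y: np.ndarray, *, name: str = "y") -> np.ndarray:
    """Validate an (N, D) array (or single D-vector) of simplex points.

    Every entry must be strictly positive and each row must sum to 1 within
    1e-9; D must be at least 2.  Returns the array as float64 with shape
    (N, D).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError(f"{name} must be a vector or matrix with D >= 2 columns")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(y <= 0):
        raise ValueError(f"{name} must be strictly positive (interior of the simplex)")
    sums = y.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > _SIMPLEX_ATOL):
        raise ValueError(f"{name} rows must sum to 1 within {_SIMPLEX_ATOL}")
    return y


@dataclass(frozen=True)
class SSDParams:
    """Parameters (alpha, beta, b) of one shifted-scaled Dirichlet component."""

    alpha: np.ndarray
    beta: np.ndarray
    b: float

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        if alpha.ndim != 1 or alpha.size < 2:
            raise ValueError("alpha must be a vector of length D >= 2")
        if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
            raise ValueError("alpha entries must be positive and finite")
        validate_compositions(beta, name="beta")
        if beta.shape != alpha.shape:
            raise ValueError("alpha and beta must share length D")
        b = float(self.b)
        if not np.isfinite(b) or b <= 0:
            raise ValueError("b must be a positive scalar")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "b", b)

    @property
    def dim(self) -> int:
        return self.alpha.size

    @property
    def alpha_plus(self) -> float:
        """Total concentration, sum of the shape vector."""
        return float(self.alpha.sum())


@dataclass(frozen=True)
class SSDMixture:
    """Finite mixture of K shifted-scaled Dirichlet components."""

    weights: np.ndarray
    components: tuple[SSDParams, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        comps = tuple(self.components)
        if w.ndim != 1 or w.size != len(comps) or w.size < 1:
            raise ValueError("weights must be a vector matching the number of components")
        if np.any(w <= 0):
            raise ValueError("mixing weights must be strictly positive")
        if abs(w.sum() - 1.0) > _SIMPLEX_ATOL:
            raise ValueError("mixing weights must sum to 1 within 1e-9")
        dims = {c.dim for c in comps}
        if len(dims) != 1:
            raise ValueError("all components must share the same dimension D")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "components", comps)

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def dim(self) -> int:
        return self.components[0].dim

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "weights": self.weights.tolist(),
            "components": [
                {"alpha": c.alpha.tolist(), "beta": c.beta.tolist(), "b": c.b}
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SSDMixture":
        comps = tuple(
            SSDParams(np.asarray(c["alpha"]), np.asarray(c["beta"]), float(c["b"]))
            for c in d["components"]
        )
        return cls(np.asarray(d["weights"], dtype=float), comps)


@dataclass(frozen=True)
class FeatureBag:
    """The set of descriptor compositions extracted from one image."""

    image_id: str
    vectors: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = validate_compositions(self.vectors, name="vectors")
        if v.shape[0] < 1:
            raise ValueError("a feature bag must contain at least one vector")
        object.__setattr__(self, "vectors", v)

    @property
    def size(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def _log_y(y: np.ndarray) -> np.ndarray:
    return np.log(np.clip(y, INTERIOR_CLIP, None))


def ssd_log_density_many(y: np.ndarray, theta: SSDParams) -> np.ndarray:
    """Vectorized SSD log density at the rows of ``y`` (shape (N, D))."""
    y = validate_compositions(y)
    if y.shape[1] != theta.dim:
        raise ValueError("dimension mismatch between y and theta")
    alpha, beta, b = theta.alpha, theta.beta, theta.b
    a_plus = theta.alpha_plus
    log_y = _log_y(y)
    log_beta = np.log(beta)
    const = (
        gammaln(a_plus)
        - gammaln(alpha).sum()
        - (theta.dim - 1) * np.log(b)
        - (alpha / b) @ log_beta
    )
    # log sum_d (y_d / beta_d)^(1/b), via log-sum-exp for stability
    log_s = logsumexp((log_y - log_beta) / b, axis=1)
    return const + log_y @ (alpha / b - 1.0) - a_plus * log_s


def ssd_log_density(y: np.ndarray, theta: SSDParams) -> float:
    """SSD log density at one composition ``y``."""
    return float(ssd_log_density_many(np.atleast_2d(y), theta)[0])


def ssd_sample(
    theta: SSDParams, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` compositions from the SSD.

    Ancestral construction: ``x ~ Dir(alpha)``, then
    ``y_d = beta_d x_d^b / sum_j beta_j x_j^b``.  Deterministic under a fixed
    seed.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n == 0:
        return np.empty((0, theta.dim))
    x = rng.dirichlet(theta.alpha, size=n)
    # closure of the powered/perturbed draw, in log space to avoid underflow
    log_t = np.log(theta.beta) + theta.b * _log_y(x)
    y = np.exp(log_t - logsumexp(log_t, axis=1, keepdims=True))
    # guard the open-simplex invariant against floating-point underflow
    y = np.clip(y, INTERIOR_CLIP, None)
    y /= y.sum(axis=1, keepdims=True)
    return y


def component_log_densities(y: np.ndarray, model: SSDMixture) -> np.ndarray:
    """(N, K) matrix of per-component log densities at the rows of ``y``."""
    y = validate_compositions(y)
    return np.column_stack([ssd_log_density_many(y, c) for c in model.components])


def mixture_log_density_many(y: np.ndarray, model: SSDMixture) -> np.ndarray:
    """Mixture log density log sum_k pi_k p(y|theta_k), vectorized over rows."""
    comp = component_log_densities(y, model)
    return logsumexp(comp + np.log(model.weights), axis=1)


def mixture_log_density(y: np.ndarray, model: SSDMixture) -> float:
    return float(mixture_log_density_many(np.atleast_2d(y), model)[0])


def mixture_sample(
    model: SSDMixture, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Ancestral sampling: component by the mixing weights, then ``ssd_sample``."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n == 0:
        return np.empty((0, model.dim))
    counts = rng.multinomial(n, model.weights)
    parts = [
        ssd_sample(comp, int(c), rng)
        for comp, c in zip(model.components, counts)
        if c > 0
    ]
    y = np.vstack(parts)
    perm = rng.permutation(n)
    return y[perm]


def project_to_simplex(v: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Map an arbitrary real vector (or matrix of row vectors) onto the simplex.

    Rows are shifted by ``-min`` if any entry is non-positive, ``epsilon`` is
    added to every entry, and the row is divided by its sum.  With
    ``epsilon=0`` a degenerate all-equal row that shifts to zero raises.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    if v.shape[1] < 2:
        raise ValueError("vectors must have length D >= 2")
    mins = v.min(axis=1, keepdims=True)
    shifted = np.where(mins <= 0, v - mins, v) + epsilon
    sums = shifted.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("degenerate all-equal vector cannot be projected with epsilon=0")
    out = shifted / sums
    if np.any(out <= 0):
        raise ValueError("projection left a zero entry; use epsilon > 0 for interior output")
    return out[0] if single else out
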