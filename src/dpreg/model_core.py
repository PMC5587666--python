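"""Core model types and the truncated stick-breaking normal scale mixture.

The regression model is

    y = W alpha + X beta + eps,    eps_j ~iid N(0, sigma2_e),

where ``y`` holds phenotypes for ``n`` individuals, ``W`` is an n-by-c
covariate matrix (intercept included), and ``X`` is an n-by-p genotype
dosage matrix.  Each SNP effect ``beta_i`` follows a normal scale mixture
whose mixing distribution over the per-SNP variance carries a Dirichlet
process prior with inverse-gamma base ``H`` and concentration ``lambda``.
Under the (truncated) stick-breaking construction the induced prior on
``beta_i`` is a normal mixture

    beta_i ~ sum_k pi_k N(0, sigma2_k),
    pi_k = nu_k prod_{l<k} (1 - nu_l),   nu_k ~ Beta(1, lambda),
    sigma2_k ~ H = InvGamma(a_sigma, b_sigma),

with the last stick forced to one so the K weights sum to one exactly.
Although the untruncated process has infinitely many components, the
posterior occupies finitely many, so a modest truncation with data-driven
occupancy loses nothing in practice.

This module also provides the univariate special case: fitting the
Dirichlet-process scale mixture directly to a sample of observed values
(no genotypes involved), which is how the flexibility of the induced
effect-size prior can be compared against a single normal density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, InvalidParameterError, TruncationError

__all__ = [
    "RegressionData",
    "DPRPrior",
    "MixtureState",
    "EffectState",
    "stick_breaking_weights",
    "mixture_density",
    "sample_prior_effects",
    "PriorEffectDraw",
    "fit_scale_mixture",
    "ScaleMixtureFit",
    "zero_mean_normal_mle",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RegressionData:
    """Phenotype, covariates and (imputed, centered) genotype dosages.

    Parameters
    ----------
    y
        Phenotype vector of length n.
    W
        n-by-c covariate matrix; must contain an all-ones intercept column.
    X
        n-by-p genotype dosage matrix with no missing entries.
    """

    y: np.ndarray
    W: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.W.shape[0] != n or self.X.shape[0] != n:
            raise InvalidParameterError(
                f"row mismatch: y has {n} entries, W {self.W.shape[0]} rows, "
                f"X {self.X.shape[0]} rows"
            )
        if not np.any(np.all(self.W == 1.0, axis=0)):
            raise InvalidParameterError("W must contain an all-ones intercept column")
        if not np.all(np.isfinite(self.y)):
            raise InvalidParameterError("y contains non-finite values")
        if not np.all(np.isfinite(self.X)):
            raise InvalidParameterError("X contains missing/non-finite values; impute first")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def c(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class DPRPrior:
    """Hyper-parameters of the truncated Dirichlet-process prior.

    ``K`` is the truncation level.  ``(a_sigma, b_sigma)`` are the
    shape/rate of the inverse-gamma base distribution H on component
    variances, kept small so H is weakly informative.  ``(a_lambda,
    b_lambda)`` are the shape/rate of the gamma hyper-prior on the
    concentration, which is inferred from the data.  ``(a_e, b_e)`` are the
    shape/rate of the inverse-gamma prior on the residual variance.
    """

    K: int = 4
    a_sigma: float = 0.1
    b_sigma: float = 0.1
    a_lambda: float = 1.0
    b_lambda: float = 1.0
    a_e: float = 0.1
    b_e: float = 0.1

    def __post_init__(self) -> None:
        if self.K < 1:
            raise InvalidParameterError(f"K must be >= 1, got {self.K}")
        for name in ("a_sigma", "b_sigma", "a_lambda", "b_lambda", "a_e", "b_e"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")


@dataclass
class MixtureState:
    """One realisation of the truncated stick-breaking normal mixture."""

    nu: np.ndarray
    pi: np.ndarray
    sigma2: np.ndarray
    lambda_: float

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.nu.shape != self.pi.shape or self.nu.shape != self.sigma2.shape:
            raise InvalidParameterError("nu, pi, sigma2 must have equal length")
        if np.any(self.sigma2 <= 0):
            raise InvalidParameterError("all component variances must be > 0")
        if self.lambda_ <= 0:
            raise InvalidParameterError("concentration lambda must be > 0")
        expected = stick_breaking_weights(self.nu)
        if not np.allclose(self.pi, expected, rtol=0, atol=1e-12):
            raise InvalidParameterError("pi inconsistent with stick proportions nu")

    @classmethod
    def from_nu(cls, nu: np.ndarray, sigma2: np.ndarray, lambda_: float) -> "MixtureState":
        nu = np.asarray(nu, dtype=float)
        return cls(nu=nu, pi=stick_breaking_weights(nu), sigma2=np.asarray(sigma2, float),
                   lambda_=float(lambda_))

    @classmethod
    def from_pi(cls, pi: np.ndarray, sigma2: np.ndarray, lambda_: float) -> "MixtureState":
        """Build a state from mixture weights, back-solving the sticks."""
        pi = np.asarray(pi, dtype=float)
        pi = pi / pi.sum()
        K = pi.shape[0]
        nu = np.empty(K)
        remaining = 1.0
        for k in range(K):
            nu[k] = pi[k] / remaining if remaining > 0 else 1.0
            remaining -= pi[k]
        nu[-1] = 1.0
        nu = np.clip(nu, 1e-15, 1.0)
        return cls(nu=nu, pi=stick_breaking_weights(nu), sigma2=np.asarray(sigma2, float),
                   lambda_=float(lambda_))

    @property
    def K(self) -> int:
        return self.nu.shape[0]


@dataclass
class EffectState:
    """Per-SNP effects and assignments plus covariate/residual parameters."""

    beta: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    sigma2_e: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=int)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.beta.shape != self.gamma.shape:
            raise InvalidParameterError("beta and gamma must have equal length")
        if self.sigma2_e <= 0:
            raise InvalidParameterError("sigma2_e must be > 0")


# ---------------------------------------------------------------------------
# Stick-breaking machinery
# ---------------------------------------------------------------------------

def stick_breaking_weights(nu: np.ndarray) -> np.ndarray:
    """Turn stick proportions into mixture weights.

    ``pi_k = nu_k * prod_{l<k} (1 - nu_l)``.  The final proportion must be
    exactly one (truncation convention), which guarantees the weights sum
    to one.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.ndim != 1 or nu.size == 0:
        raise InvalidParameterError("nu must be a non-empty 1-d array")
    if np.any(nu <= 0) or np.any(nu > 1):
        raise InvalidParameterError("every stick proportion must lie in (0, 1]")
    if nu[-1] != 1.0:
        raise TruncationError("last stick proportion must equal 1 under truncation")
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - nu[:-1])])
    return nu * remaining


def mixture_density(b, state: MixtureState):
    """Density of the normal scale mixture ``sum_k pi_k N(0, sigma2_k)`` at b."""
    b = np.asarray(b, dtype=float)
    dens = np.zeros_like(b, dtype=float)
    for pi_k, s2_k in zip(state.pi, state.sigma2):
        dens += pi_k * np.exp(-0.5 * b * b / s2_k) / math.sqrt(2.0 * math.pi * s2_k)
    return dens if dens.ndim else float(dens)


@dataclass
class PriorEffectDraw:
    """Effects sampled from the prior together with the latent structure."""

    effects: np.ndarray
    assignments: np.ndarray
    mixture: MixtureState


def sample_prior_effects(
    prior: DPRPrior,
    p: int,
    seed: int,
    *,
    lambda_: float | None = None,
    sigma2: np.ndarray | None = None,
    nu: np.ndarray | None = None,
) -> PriorEffectDraw:
    """Draw ``p`` effect sizes from the truncated stick-breaking prior.

    The hierarchy is sampled top-down: concentration from its gamma
    hyper-prior, sticks from Beta(1, lambda), component variances from the
    inverse-gamma base, then assignments and normal effects.  Any of
    ``lambda_``, ``sigma2`` or ``nu`` can be pinned, which is convenient
    when checking occupancy frequencies against the implied weights.
    """
    if p < 1:
        raise InvalidParameterError("p must be >= 1")
    rng = np.random.default_rng(seed)
    K = prior.K
    if lambda_ is None:
        lambda_ = rng.gamma(prior.a_lambda, 1.0 / prior.b_lambda)
    if nu is None:
        nu = np.ones(K)
        if K > 1:
            nu[:-1] = rng.beta(1.0, lambda_, size=K - 1)
    nu = np.asarray(nu, dtype=float)
    if sigma2 is None:
        sigma2 = 1.0 / rng.gamma(prior.a_sigma, 1.0 / prior.b_sigma, size=K)
    sigma2 = np.asarray(sigma2, dtype=float)
    state = MixtureState.from_nu(nu, sigma2, lambda_)
    assignments = rng.choice(K, size=p, p=state.pi)
    effects = rng.standard_normal(p) * np.sqrt(sigma2[assignments])
    return PriorEffectDraw(effects=effects, assignments=assignments, mixture=state)


# ---------------------------------------------------------------------------
# Univariate scale-mixture fitting (prior-flexibility experiment)
# ---------------------------------------------------------------------------

@dataclass
class ScaleMixtureFit:
    """Posterior summary of a Dirichlet-process normal scale mixture fit.

    ``mixture`` holds posterior-mean parameters; ``pi_draws`` /
    ``sigma2_draws`` hold the kept Gibbs draws so the posterior-predictive
    density (the average of per-draw mixture densities) can be evaluated.
    """

    mixture: MixtureState
    pi_draws: np.ndarray
    sigma2_draws: np.ndarray
    lambda_draws: np.ndarray
    n_kept: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_kept = self.pi_draws.shape[0]

    def density(self, b) -> np.ndarray:
        """Posterior-predictive density, averaged over kept draws."""
        b = np.atleast_1d(np.asarray(b, dtype=float))
        dens = np.zeros_like(b)
        for pi, s2 in zip(self.pi_draws, self.sigma2_draws):
            dens += np.sum(
                pi[None, :] * np.exp(-0.5 * b[:, None] ** 2 / s2[None, :])
                / np.sqrt(2.0 * np.pi * s2[None, :]),
                axis=1,
            )
        return dens / self.n_kept

    def log_density(self, b) -> np.ndarray:
        return np.log(np.maximum(self.density(b), 1e-300))


def zero_mean_normal_mle(values: np.ndarray) -> float:
    """Maximum-likelihood variance of a zero-mean normal fit to ``values``."""
    values = np.asarray(values, dtype=float)
    return float(np.mean(values**2))


def fit_scale_mixture(
    values: np.ndarray,
    K: int = 10,
    n_iter: int = 2000,
    seed: int = 0,
    *,
    burn_in: int | None = None,
    prior: DPRPrior | None = None,
) -> ScaleMixtureFit:
    """Gibbs-fit a zero-mean DP normal scale mixture to observed values.

    This is the univariate special case of the regression model: the
    observations play the role of the effect sizes themselves, so the
    sampler alternates component assignments, component variances, sticks
    and the concentration.  The default truncation is larger than the
    regression default because a free-standing density fit typically
    supports more occupied components than a posterior over SNP effects.
    """
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise DegenerateDataError("need at least 2 distinct values to fit a scale mixture")
    if K < 1 or n_iter < 1:
        raise InvalidParameterError("K and n_iter must be >= 1")
    if prior is None:
        prior = DPRPrior(K=K)
    if burn_in is None:
        burn_in = n_iter // 2
    rng = np.random.default_rng(seed)
    m = values.shape[0]
    v2 = values**2

    lambda_ = prior.a_lambda / prior.b_lambda
    # spread initial variances geometrically around the sample scale
    base = max(np.var(values), 1e-12)
    sigma2 = base * np.power(4.0, -np.arange(K, dtype=float))
    nu = np.ones(K)
    if K > 1:
        nu[:-1] = 1.0 / (1.0 + lambda_)
    pi = stick_breaking_weights(nu)

    kept_pi, kept_s2, kept_lam = [], [], []
    for it in range(n_iter):
        # assignments (Gumbel-max over per-component log densities)
        logp = (
            np.log(np.maximum(pi, 1e-300))[None, :]
            - 0.5 * np.log(sigma2)[None, :]
            - 0.5 * v2[:, None] / sigma2[None, :]
        )
        gumbel = -np.log(-np.log(rng.uniform(1e-300, 1.0, size=logp.shape)))
        gamma = np.argmax(logp + gumbel, axis=1)
        counts = np.bincount(gamma, minlength=K)
        ss = np.bincount(gamma, weights=v2, minlength=K)
        # component variances (conjugate inverse-gamma)
        sigma2 = 1.0 / rng.gamma(prior.a_sigma + counts / 2.0,
                                 1.0 / (prior.b_sigma + ss / 2.0))
        # sticks and weights
        if K > 1:
            tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0]])
            nu[:-1] = rng.beta(1.0 + counts[:-1], lambda_ + tail[:-1])
            nu[:-1] = np.clip(nu[:-1], 1e-12, 1.0 - 1e-12)
        pi = stick_breaking_weights(nu)
        # concentration
        if K > 1:
            rate = prior.b_lambda - np.sum(np.maximum(np.log1p(-nu[:-1]), -700.0))
            lambda_ = rng.gamma(prior.a_lambda + K - 1, 1.0 / rate)
        if it >= burn_in:
            kept_pi.append(pi.copy())
            kept_s2.append(sigma2.copy())
            kept_lam.append(lambda_)

    pi_draws = np.array(kept_pi)
    s2_draws = np.array(kept_s2)
    lam_draws = np.array(kept_lam)
    mean_state = MixtureState.from_pi(pi_draws.mean(axis=0), s2_draws.mean(axis=0),
                                      float(lam_draws.mean()))
    return ScaleMixtureFit(mixture=mean_state, pi_draws=pi_draws,
                           sigma2_draws=s2_draws, lambda_draws=lam_draws)
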