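"""Prediction, accuracy metrics, cross-validation and posterior summaries.

Prediction is the plug-in rule ``yhat = W alpha_hat + Xc beta_hat`` with
posterior-mean coefficients and test genotypes centered on *training*
means.  Accuracy is reported as the squared Pearson correlation (R^2)
and the mean squared error, evaluated over repeated random 80/20
train/test splits (Monte Carlo cross-validation).

Posterior summaries cover the proportion of phenotypic variance explained
(PVE, i.e. SNP heritability) and the per-SNP posterior inclusion
probability (PIP): the posterior probability that a SNP belongs to any
mixture component other than the smallest-variance one, which plays the
role of the polygenic background.  Relatedness diagnostics (GRM, effective
number of chromosome segments) round the module out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegeneratePredictionWarning, InvalidParameterError
from .genotype_io import QuantileNormalizer, center_genotypes
from .model_core import DPRPrior, RegressionData

__all__ = [
    "FitSummary",
    "CVReport",
    "predict",
    "r_squared",
    "mse",
    "monte_carlo_cv",
    "pve_from_draws",
    "pip_from_draws",
    "compute_grm",
    "effective_segments",
    "standardize_genotypes",
    "mcmc_backend",
    "vb_backend",
    "ridge_backend",
]


@dataclass
class FitSummary:
    """Backend-agnostic posterior-mean coefficients (plus optional extras)."""

    alpha_mean: np.ndarray
    beta_mean: np.ndarray
    pve: float | None = None
    pip: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Prediction and metrics
# ---------------------------------------------------------------------------

def predict(fit, W_new: np.ndarray, X_new_centered: np.ndarray) -> np.ndarray:
    """Plug-in prediction with posterior-mean coefficients."""
    W_new = np.atleast_2d(np.asarray(W_new, dtype=float))
    X_new = np.atleast_2d(np.asarray(X_new_centered, dtype=float))
    alpha = np.asarray(fit.alpha_mean, dtype=float)
    beta = np.asarray(fit.beta_mean, dtype=float)
    if W_new.shape[1] != alpha.shape[0]:
        raise InvalidParameterError(
            f"W has {W_new.shape[1]} columns but alpha has {alpha.shape[0]} entries"
        )
    if X_new.shape[1] != beta.shape[0]:
        raise InvalidParameterError(
            f"X has {X_new.shape[1]} columns but beta has {beta.shape[0]} entries"
        )
    if W_new.shape[0] != X_new.shape[0]:
        raise InvalidParameterError("W and X row counts differ")
    return W_new @ alpha + X_new @ beta


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared Pearson correlation; 0 (with a warning) for constant yhat."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape or y.size < 2:
        raise InvalidParameterError("y and yhat must share length >= 2")
    if np.var(y) == 0:
        raise InvalidParameterError("observed phenotype has zero variance")
    if np.var(yhat) == 0:
        warnings.warn("constant predictions: reporting R^2 = 0",
                      DegeneratePredictionWarning)
        return 0.0
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r * r)


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise InvalidParameterError("y and yhat must have equal length")
    return float(np.mean((y - yhat) ** 2))


# ---------------------------------------------------------------------------
# Fitting backends
# ---------------------------------------------------------------------------

def mcmc_backend(prior: DPRPrior | None = None, config=None):
    """Gibbs-sampler fitter ``f(y, W, Xc) -> FitSummary``."""
    from .mcmc import MCMCConfig, run_gibbs

    prior = prior or DPRPrior()
    config = config or MCMCConfig(n_iter=1500, thin=5)

    def fit(y, W, Xc):
        draws = run_gibbs(RegressionData(y=y, W=W, X=Xc), prior, config)
        return FitSummary(alpha_mean=draws.alpha_mean, beta_mean=draws.beta_mean,
                          pve=draws.pve_mean, pip=draws.pip)

    return fit


def vb_backend(prior: DPRPrior | None = None, tol: float = 1e-5,
               max_iter: int = 1000):
    """Variational fitter ``f(y, W, Xc) -> FitSummary``."""
    from .vb import run_vb

    prior = prior or DPRPrior()

    def fit(y, W, Xc):
        res = run_vb(RegressionData(y=y, W=W, X=Xc), prior, tol=tol,
                     max_iter=max_iter)
        return FitSummary(alpha_mean=res.alpha_mean, beta_mean=res.beta_mean,
                          pve=res.pve, pip=res.pip)

    return fit


def ridge_backend(shrinkage: float | None = None):
    """Closed-form single-component (K=1) baseline, i.e. a BLUP-style fit.

    ``shrinkage`` is sigma2_e / sigma2_beta; when None it is set from the
    heuristic sigma2_beta = var(y)/(2p), sigma2_e = var(y)/2.
    """

    def fit(y, W, Xc):
        y = np.asarray(y, float)
        Xc = np.asarray(Xc, float)
        p = Xc.shape[1]
        lam = shrinkage if shrinkage is not None else float(p)
        alpha = np.linalg.lstsq(W, y, rcond=None)[0]
        resid = y - W @ alpha
        A = Xc.T @ Xc + lam * np.eye(p)
        beta = np.linalg.solve(A, Xc.T @ resid)
        return FitSummary(alpha_mean=alpha, beta_mean=beta)

    return fit


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-split scores plus the seeded split definitions."""

    r2: np.ndarray
    mse: np.ndarray
    splits: list
    seed: int

    def summary(self) -> dict:
        return {
            "r2_mean": float(np.nanmean(self.r2)),
            "r2_sd": float(np.nanstd(self.r2, ddof=1)) if self.r2.size > 1 else 0.0,
            "mse_mean": float(np.nanmean(self.mse)),
            "mse_sd": float(np.nanstd(self.mse, ddof=1)) if self.mse.size > 1 else 0.0,
            "n_splits": int(self.r2.size),
        }


def monte_carlo_cv(
    y: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    method,
    n_splits: int = 20,
    train_frac: float = 0.8,
    seed: int = 0,
    normalize_phenotype: bool = False,
) -> CVReport:
    """Repeated random train/test splitting with per-split refits.

    All preprocessing parameters (genotype centering means and, when
    requested, the phenotype quantile-normalization map) are learned on
    the training fold only and applied verbatim to the test fold.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n = y.shape[0]
    if n < 10:
        raise InvalidParameterError("need at least 10 samples for cross-validation")
    rng = np.random.default_rng(seed)
    r2s, mses, splits = [], [], []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        tr, te = perm[:n_train], perm[n_train:]
        splits.append((tr.copy(), te.copy()))
        y_tr, y_te = y[tr], y[te]
        if normalize_phenotype:
            qn = QuantileNormalizer().fit(y_tr)
            y_tr = qn.transform(y_tr)
            y_te = qn.transform(y_te)
        Xc_tr, means = center_genotypes(X[tr])
        Xc_te, _ = center_genotypes(X[te], means=means)
        fit = method(y_tr, W[tr], Xc_tr)
        yhat = predict(fit, W[te], Xc_te)
        r2s.append(r_squared(y_te, yhat))
        mses.append(mse(y_te, yhat))
    return CVReport(r2=np.array(r2s), mse=np.array(mses), splits=splits, seed=seed)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def pve_from_draws(pve_draws: np.ndarray) -> dict:
    """Posterior mean, sd and central 95% interval of the PVE trace."""
    pve_draws = np.asarray(pve_draws, dtype=float).ravel()
    if pve_draws.size == 0:
        raise InvalidParameterError("empty PVE trace")
    lo, hi = np.quantile(pve_draws, [0.025, 0.975])
    return {
        "mean": float(pve_draws.mean()),
        "sd": float(pve_draws.std(ddof=1)) if pve_draws.size > 1 else 0.0,
        "ci95": (float(lo), float(hi)),
    }


def pip_from_draws(gamma_draws: np.ndarray, sigma2k_draws: np.ndarray) -> np.ndarray:
    """PIP_i = fraction of draws with gamma_i outside the smallest component.

    The smallest-variance component is identified per draw, so label
    switching along the chain is harmless.
    """
    gamma_draws = np.asarray(gamma_draws)
    sigma2k_draws = np.atleast_2d(np.asarray(sigma2k_draws, dtype=float))
    if sigma2k_draws.shape[1] == 1:
        warnings.warn("K=1: posterior inclusion probabilities are all 0 by definition")
        return np.zeros(gamma_draws.shape[1])
    if gamma_draws.shape[0] != sigma2k_draws.shape[0]:
        raise InvalidParameterError("gamma and sigma2 draws must align draw-wise")
    background = np.argmin(sigma2k_draws, axis=1)
    return np.mean(gamma_draws != background[:, None], axis=0)


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def standardize_genotypes(X: np.ndarray) -> np.ndarray:
    """Center each SNP and scale to unit variance (monomorphic SNPs rejected)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise InvalidParameterError("monomorphic SNP: cannot standardize")
    return (X - X.mean(axis=0)) / sd


def compute_grm(X_std: np.ndarray) -> np.ndarray:
    """Genetic relatedness matrix ``X_s X_s' / p`` from standardized genotypes."""
    X_std = np.atleast_2d(np.asarray(X_std, dtype=float))
    if X_std.shape[1] < 2:
        raise InvalidParameterError("need at least 2 SNPs for a GRM")
    return X_std @ X_std.T / X_std.shape[1]


def effective_segments(grm: np.ndarray) -> float:
    """Effective number of chromosome segments M_e = 1 / var(off-diagonal GRM)."""
    grm = np.asarray(grm, dtype=float)
    n = grm.shape[0]
    off = grm[~np.eye(n, dtype=bool)]
    v = float(np.var(off))
    if v == 0:
        raise InvalidParameterError("off-diagonal GRM variance is zero")
    return 1.0 / v
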