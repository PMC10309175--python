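"""Shared statistical kernels used by every pipeline stage.

Logistic regression (Wald tests), random-intercept linear mixed models,
Benjamini-Hochberg adjustment, the exact upper-tail hypergeometric
probability, and the rank (Mann-Whitney) AUC. Model fitting is delegated
to statsmodels; the thin wrappers here pin down the contracts the rest
of the package relies on (error behaviour, separation flags, boundary
cases) and return plain dataclasses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning


class DegenerateInputError(ValueError):
    """Raised when an input is constant, rank-deficient, or otherwise uninformative."""


@dataclass
class GlmFit:
    """Maximum-likelihood logistic fit.

    coefs/se are ordered as the design columns; ``separated`` flags
    (quasi-)complete separation, in which case the Wald statistics are
    not trustworthy and callers should report the fit as non-converged.
    """

    names: list[str]
    coefs: np.ndarray
    se: np.ndarray
    deviance: float
    loglik: float
    n_obs: int
    converged: bool
    separated: bool

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coefs / self.se

    def coef(self, name: str) -> float:
        return float(self.coefs[self.names.index(name)])


@dataclass
class LmmFit:
    """Random-intercept linear mixed model fit (REML by default)."""

    names: list[str]
    coefs: np.ndarray
    se: np.ndarray
    re_var: float
    resid_var: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coefs / self.se


# coefficient magnitude beyond which a logit fit is treated as separated
_SEPARATION_COEF = 12.0


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """Fit a binary logistic regression by maximum likelihood (IRLS).

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) binary outcome in {0, 1}.
    names : optional column names (defaults to x0..x{p-1}).

    Raises
    ------
    DegenerateInputError
        If ``y`` is single-class/non-binary or ``X`` is rank deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DegenerateInputError("outcome must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("outcome has a single class")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateInputError("design matrix is rank deficient")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=max_iter, tol=tol)

    coefs = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    mu = np.asarray(res.fittedvalues, dtype=float)
    perfect_fit = bool(np.all(np.abs(y - mu) < 1e-6))
    separated = bool(np.max(np.abs(coefs)) > _SEPARATION_COEF or perfect_fit)
    converged = bool(getattr(res, "converged", True)) and not separated
    return GlmFit(
        names=list(names),
        coefs=coefs,
        se=se,
        deviance=float(res.deviance),
        loglik=float(res.llf),
        n_obs=int(X.shape[0]),
        converged=converged,
        separated=separated,
    )


def fit_lmm_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    reml: bool = True,
) -> LmmFit:
    """Fit ``y = X b + u_group + e`` with a scalar random intercept.

    The likelihood is profiled over the variance ratio var_u/var_e:
    given the ratio, the GLS fixed effects and both variances are in
    closed form, so the (RE)ML optimum is a bounded one-dimensional
    search with the zero-variance boundary checked explicitly. When
    every group is a singleton the intercept variance is unidentified
    and the model collapses to ordinary least squares with re_var = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if X.ndim == 1:
        X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateInputError("design matrix is rank deficient")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    uniq, counts = np.unique(groups, return_counts=True)

    if len(uniq) < 2 or counts.max() == 1:
        # unidentified intercept variance: ordinary least squares limit
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(X.shape[0] - X.shape[1], 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        ll = float(
            -0.5 * X.shape[0] * (np.log(2 * np.pi * s2) + 1)
        )
        return LmmFit(
            names=list(names),
            coefs=beta,
            se=np.sqrt(np.diag(cov)),
            re_var=0.0,
            resid_var=s2,
            loglik=ll,
            n_obs=int(X.shape[0]),
            n_groups=int(len(uniq)),
            converged=True,
        )

    # profiled (RE)ML over the variance ratio lambda = var_u / var_e:
    # for fixed lambda the GLS solution and both variances are closed
    # form (V_g^-1 = I - c_g J with c_g = lambda / (1 + lambda n_g)),
    # so a bounded one-dimensional search over log(lambda) suffices and
    # the zero-variance boundary is checked explicitly.
    n, p = X.shape
    _, idx = np.unique(groups, return_inverse=True)
    n_g = np.bincount(idx)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # per-group column sums of X and sums of y
    Sx = np.zeros((len(n_g), p))
    np.add.at(Sx, idx, X)
    Sy = np.bincount(idx, weights=y)

    def profile(lam: float) -> tuple[float, np.ndarray, np.ndarray, float]:
        c = lam / (1.0 + lam * n_g)
        A = XtX - (Sx * c[:, None]).T @ Sx
        b_vec = Xty - Sx.T @ (c * Sy)
        beta = np.linalg.solve(A, b_vec)
        quad = yty - float(c @ Sy**2)
        rss = quad - 2.0 * float(beta @ b_vec) + float(beta @ (A @ beta))
        rss = max(rss, 1e-300)
        dof = (n - p) if reml else n
        s2 = rss / dof
        nll = dof * np.log(s2) + float(np.sum(np.log1p(lam * n_g)))
        if reml:
            sign, logdet = np.linalg.slogdet(A)
            nll += logdet
        return nll, beta, A, s2

    opt = minimize_scalar(
        lambda t: profile(np.exp(t))[0], bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(opt.x))
    nll0, *_ = profile(0.0)
    if nll0 <= opt.fun:
        lam = 0.0
    nll, beta, A, s2 = profile(lam)
    cov = s2 * np.linalg.inv(A)
    dof = (n - p) if reml else n
    loglik = -0.5 * (nll + dof * (np.log(2 * np.pi) + 1))
    return LmmFit(
        names=list(names),
        coefs=beta,
        se=np.sqrt(np.diag(cov)),
        re_var=lam * s2,
        resid_var=float(s2),
        loglik=float(loglik),
        n_obs=int(n),
        n_groups=int(len(uniq)),
        converged=True,
    )


def wald_p(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal p-value, ``2 * (1 - Phi(|z|))``."""
    out = 2.0 * sps.norm.sf(np.abs(z))
    if np.isscalar(z) or np.ndim(z) == 0:
        return float(out)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) drawing n from N with K successes.

    Computed by integer summation of the hypergeometric mass (exact up
    to the final division), so small tail probabilities carry no
    cancellation error.
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError("inconsistent hypergeometric arguments")
    if not 0 <= k <= min(K, n):
        raise ValueError("k must lie in [0, min(K, n)]")
    hi = min(K, n)
    num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, hi + 1))
    return num / math.comb(N, n)


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted one half.

    ``labels`` are 0/1; returns P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("AUC needs both classes present")
    ranks = sps.rankdata(scores)
    r1 = float(np.sum(ranks[labels == 1]))
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
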