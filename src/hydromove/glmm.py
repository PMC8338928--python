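"""Binomial mixed model with random intercepts, plus supporting pieces.

The model is a logistic regression with crossed/nested random intercepts,

    y_i ~ Bernoulli(p_i),  logit(p_i) = x_i' beta + sum_f sigma_f b_{f, g_f(i)},

with one variance parameter per grouping factor and unit-normal scaled
effects ``b``.  Estimation is Laplace-approximated maximum likelihood: for
candidate variance parameters the joint mode of (beta, b) is found by
penalised Newton iterations (PIRLS), the Laplace log-likelihood

    l(y | beta_hat, b_hat) - ||b_hat||^2 / 2 - log det(Z'WZ + I) / 2

is profiled, and the outer log-SD parameters are optimised with Nelder-Mead.
Fixed-effect uncertainty uses the (beta, b) block of the inverse penalised
Hessian at the optimum (Wald z tests).

The continuous covariate enters either linearly or as a degree-2 orthogonal
polynomial basis (the "poly 1"/"poly 2" convention), built with the standard
three-term recurrence so new values can be projected onto the training
basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import norm

LOGIT_RESIDUAL_VARIANCE = np.pi**2 / 3.0


class SeparationError(RuntimeError):
    """Raised when the likelihood diverges (quasi-)complete separation."""


class ConvergenceError(RuntimeError):
    """Raised when the optimiser fails to reach a stable optimum."""


# ---------------------------------------------------------------------------
# Orthogonal polynomial basis


@dataclass
class OrthoPolyBasis:
    """Degree-d orthonormal polynomial columns fitted on a sample.

    Columns have zero mean, unit Euclidean norm and are mutually orthogonal
    on the training sample; the recurrence coefficients are stored so new
    values can be transformed consistently.
    """

    degree: int
    alpha: np.ndarray  # recurrence shifts, length degree
    beta: np.ndarray  # recurrence scales, length degree (beta[0] unused)
    norms: np.ndarray  # column norms, length degree

    @classmethod
    def fit(cls, x, degree: int = 2) -> "OrthoPolyBasis":
        x = np.asarray(x, dtype=float)
        if len(np.unique(x)) <= degree:
            raise ValueError(f"need more than {degree} distinct values")
        alpha = np.zeros(degree)
        beta = np.zeros(degree)
        norms = np.zeros(degree)
        p_prev = np.ones_like(x)
        p_curr = np.ones_like(x)
        for j in range(degree):
            ss = p_curr @ p_curr
            alpha[j] = (x * p_curr) @ p_curr / ss
            if j > 0:
                beta[j] = ss / (p_prev @ p_prev)
            p_next = (x - alpha[j]) * p_curr - (beta[j] * p_prev if j > 0 else 0.0)
            norms[j] = np.sqrt(p_next @ p_next)
            if norms[j] == 0:
                raise ValueError("degenerate polynomial basis")
            p_prev, p_curr = p_curr, p_next
        return cls(degree=degree, alpha=alpha, beta=beta, norms=norms)

    def transform(self, x) -> np.ndarray:
        """Evaluate the basis at new values; shape ``(n, degree)``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        cols = np.empty((len(x), self.degree))
        p_prev = np.ones_like(x)
        p_curr = np.ones_like(x)
        for j in range(self.degree):
            p_next = (x - self.alpha[j]) * p_curr - (self.beta[j] * p_prev if j > 0 else 0.0)
            cols[:, j] = p_next / self.norms[j]
            p_prev, p_curr = p_curr, p_next
        return cols


def ortho_poly(x, degree: int = 2) -> tuple[np.ndarray, OrthoPolyBasis]:
    """Fit-and-transform convenience wrapper."""
    basis = OrthoPolyBasis.fit(x, degree=degree)
    return basis.transform(x), basis


# ---------------------------------------------------------------------------
# Laplace-ML binomial mixed model


@dataclass
class GlmmFit:
    """Fitted logistic mixed model with Wald tests and R² ingredients."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    variances: dict[str, float]
    var_fixed: float  # variance of the fixed-effect linear predictor
    cov_beta: np.ndarray
    converged: bool
    n_obs: int
    laplace_deviance: float
    optimizer: str = "Nelder-Mead over log-SDs; PIRLS inner"
    dropped_factors: list[str] = field(default_factory=list)
    n_outer_evals: int = 0
    marginal_r2: float = float("nan")
    conditional_r2: float = float("nan")
    x_range: tuple[float, float] | None = None

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "z": self.z,
                "p": self.p,
            }
        )


def _indicator(codes: np.ndarray) -> sp.csr_matrix:
    n = len(codes)
    q = codes.max() + 1
    return sp.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q))


def _penalized_mode(y, A, p_fixed, coef0, max_iter=60, tol=1e-9):
    """Newton/PIRLS joint mode of (beta, b); returns (coef, H, penalised ll)."""
    q = A.shape[1] - p_fixed
    pen = np.concatenate([np.zeros(p_fixed), np.ones(q)])
    coef = coef0.copy()
    eta = A @ coef

    def pll(coef, eta):
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * coef @ (pen * coef))

    ll = pll(coef, eta)
    H = None
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = A.T @ (y - mu) - pen * coef
        AW = A.multiply(w[:, None]) if sp.issparse(A) else A * w[:, None]
        H = (A.T @ AW).toarray() if sp.issparse(A) else A.T @ AW
        H[np.diag_indices_from(H)] += pen
        try:
            c = cho_factor(H)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
            raise ConvergenceError("singular penalised Hessian") from exc
        step = cho_solve(c, grad)
        # step halving to guarantee ascent
        t = 1.0
        for _ in range(30):
            new = coef + t * step
            eta_new = A @ new
            ll_new = pll(new, eta_new)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        coef, eta, ll_prev, ll = new, eta_new, ll, ll_new
        # Only the unpenalised (fixed-effect) direction can diverge; log-odds
        # beyond ~100 from the fixed part alone mean the likelihood is
        # running off along a separating direction.
        if np.abs(A[:, :p_fixed] @ coef[:p_fixed]).max() > 100.0:
            raise SeparationError(
                "fixed-effect linear predictor diverging; data may be (quasi-)separated"
            )
        if np.abs(grad).max() < tol * max(1.0, abs(ll)) or abs(ll - ll_prev) < 1e-12:
            break
    return coef, H, ll


def fit_binomial_glmm(
    y,
    X: np.ndarray,
    groups: dict[str, np.ndarray],
    term_names: list[str] | None = None,
    maxfev: int = 600,
) -> GlmmFit:
    """Fit the logistic random-intercept model by Laplace-approximated ML.

    Parameters
    ----------
    y : 0/1 response.
    X : fixed-effect design matrix (include the intercept column).
    groups : mapping of factor name to per-observation level labels; each
        factor gets one random-intercept variance.  Factors with a single
        level are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    if len(np.unique(y)) < 2:
        raise ValueError("response must contain both classes")

    dropped = []
    Zs: list[sp.csr_matrix] = []
    names: list[str] = []
    for name, labels in groups.items():
        codes = pd.factorize(np.asarray(labels))[0]
        if codes.max() < 1:
            warnings.warn(f"random factor {name!r} has a single level; dropped", stacklevel=2)
            dropped.append(name)
            continue
        Zs.append(_indicator(codes))
        names.append(name)
    Z = sp.hstack(Zs).tocsr() if Zs else sp.csr_matrix((n, 0))
    q_per = [z.shape[1] for z in Zs]
    q = Z.shape[1]

    Xs = sp.csr_matrix(X)
    coef_warm = np.zeros(p + q)
    n_evals = 0

    def scale_vector(theta):
        # clamp log-SDs: below exp(-6) a component is numerically zero and
        # the deviance surface is flat, which stalls the simplex search
        theta = np.clip(theta, -6.0, 5.0)
        return np.concatenate(
            [np.full(qf, np.exp(t)) for qf, t in zip(q_per, theta)]
        ) if q else np.zeros(0)

    def neg2_laplace(theta):
        nonlocal coef_warm, n_evals
        n_evals += 1
        s = scale_vector(theta)
        A = sp.hstack([Xs, Z.multiply(s[None, :])]).tocsr() if q else Xs
        coef, H, ll = _penalized_mode(y, A, p, coef_warm)
        coef_warm = coef
        if q:
            sign, logdet = np.linalg.slogdet(H[p:, p:])
            if sign <= 0:  # pragma: no cover - pathological
                raise ConvergenceError("non-positive-definite random-effect Hessian")
        else:
            logdet = 0.0
        return -2.0 * ll + logdet

    if q:
        theta0 = np.full(len(q_per), np.log(0.5))
        res = optimize.minimize(
            neg2_laplace,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 2e-3, "fatol": 5e-4, "maxfev": maxfev},
        )
        theta = np.clip(res.x, -6.0, 5.0)
        converged = bool(res.success)
        if not converged:
            raise ConvergenceError(f"outer optimisation failed: {res.message}")
    else:
        theta = np.zeros(0)
        converged = True

    # Final mode and curvature at the optimum.
    s = scale_vector(theta)
    A = sp.hstack([Xs, Z.multiply(s[None, :])]).tocsr() if q else Xs
    coef, H, ll = _penalized_mode(y, A, p, coef_warm)
    deviance = -2.0 * ll + (np.linalg.slogdet(H[p:, p:])[1] if q else 0.0)
    cov = np.linalg.inv(H)
    beta = coef[:p]
    se = np.sqrt(np.diag(cov)[:p])
    # Every observation fitted at probability 1 means the likelihood has no
    # finite maximum: complete separation.
    mu_hat = expit(A @ coef)
    class_prob = np.where(y > 0.5, mu_hat, 1.0 - mu_hat)
    if class_prob.min() > 1.0 - 1e-6:
        raise SeparationError("all observations perfectly classified; complete separation")
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    variances = {name: float(np.exp(2.0 * t)) for name, t in zip(names, theta)}
    eta_fixed = X @ beta
    fit = GlmmFit(
        terms=list(term_names),
        beta=beta,
        se=se,
        z=z,
        p=pvals,
        variances=variances,
        var_fixed=float(np.var(eta_fixed, ddof=1)) if n > 1 else 0.0,
        cov_beta=cov[:p, :p],
        converged=converged,
        n_obs=n,
        laplace_deviance=float(deviance),
        dropped_factors=dropped,
        n_outer_evals=n_evals,
    )
    fit.marginal_r2, fit.conditional_r2 = r2_nakagawa(fit)
    return fit


def r2_nakagawa(fit: GlmmFit) -> tuple[float, float]:
    """Marginal and conditional R² for a logit-link binomial mixed model.

    marginal = var_f / (var_f + sum(var_random) + pi²/3); the conditional
    version adds the random-intercept variances to the numerator.  The
    distribution-specific variance of the logit link is pi²/3.
    """
    var_f = fit.var_fixed
    var_r = float(sum(fit.variances.values()))
    denom = var_f + var_r + LOGIT_RESIDUAL_VARIANCE
    return var_f / denom, (var_f + var_r) / denom


def predict_response_curve(
    fit: GlmmFit, X_grid: np.ndarray, x_values: np.ndarray | None = None
) -> pd.DataFrame:
    """Population-level predicted probabilities with delta-method 95% CIs.

    Random effects are set to zero; the CI is on the linear predictor and
    mapped through the inverse logit.  Grid rows outside the observed
    covariate range are flagged as extrapolation.
    """
    X_grid = np.atleast_2d(np.asarray(X_grid, dtype=float))
    eta = X_grid @ fit.beta
    var = np.einsum("ij,jk,ik->i", X_grid, fit.cov_beta, X_grid)
    se = np.sqrt(np.maximum(var, 0.0))
    out = pd.DataFrame(
        {
            "eta": eta,
            "prob": expit(eta),
            "prob_lo": expit(eta - 1.96 * se),
            "prob_hi": expit(eta + 1.96 * se),
        }
    )
    if x_values is not None:
        out.insert(0, "x", np.asarray(x_values, dtype=float))
        if fit.x_range is not None:
            lo, hi = fit.x_range
            out["extrapolated"] = (out["x"] < lo) | (out["x"] > hi)
            if out["extrapolated"].any():
                warnings.warn("prediction grid extends beyond observed covariate range",
                              stacklevel=2)
    return out
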