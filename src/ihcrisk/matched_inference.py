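"""Conditional logistic regression for 1:1 matched pairs, from scratch.

For a matched pair with covariates x_case and x_control, conditioning on
the pair containing exactly one case gives the pair likelihood

    P(case is the case | pair) = sigma(beta . d),   d = x_case - x_control,

so the 1:1 conditional likelihood is exactly an intercept-free binary
logistic likelihood on within-pair differences with all outcomes equal
to one:

    l(beta) = sum_i -ln(1 + exp(-beta . d_i)).

Estimation is Newton-Raphson with step halving; the covariance is the
inverse observed information at the optimum.  Wald odds-ratio intervals,
likelihood-ratio tests for nested (including polynomial) models, and
relative-risk curve prediction for quadratic marker models are built on
top of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairDesign",
    "FitResult",
    "LRTResult",
    "SeparationError",
    "NotIdentifiableError",
    "NotConvergedError",
    "pair_loglik",
    "fit_clogit",
    "wald_or_ci",
    "lrt",
    "predict_risk_curve",
]

MAX_ITER = 50
GRAD_TOL = 1e-8
BETA_BOUND = 15.0  # |beta| beyond this during iteration signals separation


class SeparationError(RuntimeError):
    """Complete/quasi-complete separation: the MLE diverges."""


class NotIdentifiableError(ValueError):
    """A covariate has all-zero within-pair differences."""


class NotConvergedError(RuntimeError):
    """Inference requested from a fit that did not converge."""


@dataclass(frozen=True)
class PairDesign:
    """Within-pair difference design: rows are d_i = x_case - x_control."""

    diffs: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.diffs, dtype=float))
        if not np.all(np.isfinite(d)):
            raise ValueError("pair differences must be finite")
        if d.shape[1] != len(self.names):
            raise ValueError("number of covariate names must match columns")
        object.__setattr__(self, "diffs", d)

    @property
    def n_pairs(self) -> int:
        return self.diffs.shape[0]

    @property
    def n_params(self) -> int:
        return self.diffs.shape[1]

    def subset(self, names: list[str]) -> "PairDesign":
        """Design restricted to the named covariates (for nested models)."""
        idx = [self.names.index(n) for n in names]
        return PairDesign(self.diffs[:, idx], list(names))


@dataclass(frozen=True)
class FitResult:
    """Maximum conditional-likelihood fit of one model."""

    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    names: list[str]
    n_pairs: int

    def se(self, j: int) -> float:
        return float(np.sqrt(self.covariance[j, j]))

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of nested conditional-logistic models."""

    statistic: float
    df: int
    p_value: float


def pair_loglik(design: PairDesign, beta: np.ndarray) -> float:
    """Conditional log-likelihood l(beta) = sum_i -ln(1 + exp(-beta . d_i))."""
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    eta = design.diffs @ beta
    return float(-np.sum(np.logaddexp(0.0, -eta)))


def _grad_hess(design: PairDesign, beta: np.ndarray):
    eta = design.diffs @ beta
    p = 1.0 / (1.0 + np.exp(-eta))  # sigma(eta)
    grad = design.diffs.T @ (1.0 - p)
    w = p * (1.0 - p)
    hess = -(design.diffs.T * w) @ design.diffs
    return grad, hess


def fit_clogit(design: PairDesign, beta0: np.ndarray | None = None) -> FitResult:
    """Newton-Raphson maximisation of the pair conditional likelihood.

    Converged when the gradient max-norm drops below 1e-8 (at most 50
    iterations).  Raises :class:`NotIdentifiableError` for a covariate
    with no within-pair variation and :class:`SeparationError` when the
    informative differences for a covariate all share one sign and the
    iterates run away (|beta_j| > 15).
    """
    d = design.diffs
    for j, name in enumerate(design.names):
        if np.all(d[:, j] == 0.0):
            raise NotIdentifiableError(
                f"covariate '{name}' has all-zero within-pair differences"
            )

    beta = np.zeros(design.n_params) if beta0 is None else np.asarray(beta0, float).copy()
    ll = pair_loglik(design, beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, MAX_ITER + 1):
        grad, hess = _grad_hess(design, beta)
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix; model not identifiable"
            ) from exc
        # step halving keeps the likelihood monotone
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_ll = pair_loglik(design, cand)
            if cand_ll >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll = cand, cand_ll
        if np.any(np.abs(beta) > BETA_BOUND):
            runaway = [design.names[j] for j in np.flatnonzero(np.abs(beta) > BETA_BOUND)]
            raise SeparationError(
                f"separation detected: coefficient(s) {runaway} diverging "
                f"(|beta| > {BETA_BOUND:g})"
            )
    else:
        grad, hess = _grad_hess(design, beta)
        converged = bool(np.max(np.abs(grad)) < GRAD_TOL)

    _, hess = _grad_hess(design, beta)
    cov = np.linalg.inv(-hess) if converged else np.full_like(hess, np.nan)
    return FitResult(
        beta=beta,
        covariance=cov,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        names=list(design.names),
        n_pairs=design.n_pairs,
    )


def wald_or_ci(fit: FitResult, j: int | str, level: float = 0.95):
    """Wald odds ratio, confidence interval and two-sided p for one term."""
    if not fit.converged:
        raise NotConvergedError("cannot compute Wald inference from a non-converged fit")
    if isinstance(j, str):
        j = fit.index(j)
    b, se = float(fit.beta[j]), fit.se(j)
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = 2.0 * stats.norm.sf(abs(b) / se) if se > 0 else float("nan")
    return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se)), float(p)


def lrt(full: FitResult, reduced: FitResult) -> LRTResult:
    """Likelihood-ratio chi-square test of nested models on the same pairs.

    Identical models give statistic 0 with p = 1 (df = 0).
    """
    if not set(reduced.names) <= set(full.names):
        raise ValueError("reduced model's covariates must be a subset of full's")
    if full.n_pairs != reduced.n_pairs:
        raise ValueError("models must be fit on the same pairs")
    statistic = 2.0 * (full.loglik - reduced.loglik)
    if statistic < -1e-8:
        raise ValueError(f"negative LRT statistic {statistic}: models not nested?")
    statistic = max(statistic, 0.0)
    df = len(full.names) - len(reduced.names)
    p = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    return LRTResult(float(statistic), df, p)


def predict_risk_curve(
    fit: FitResult,
    marker_grid: np.ndarray,
    marker_mean: float,
    linear_term: str,
    quadratic_term: str | None = None,
) -> np.ndarray:
    """Relative risk over a marker grid, other covariates held at means.

    Returns exp(b_lin*g + b_quad*g^2) normalised to 1 at the sample mean
    of the marker; covariates other than the marker drop out of the
    relative risk when held at their means.
    """
    if linear_term not in fit.names:
        raise ValueError(f"fit has no linear marker term '{linear_term}'")
    g = np.asarray(marker_grid, dtype=float)
    b_lin = fit.beta[fit.index(linear_term)]
    b_quad = fit.beta[fit.index(quadratic_term)] if quadratic_term else 0.0
    log_rr = b_lin * g + b_quad * g**2
    log_rr_ref = b_lin * marker_mean + b_quad * marker_mean**2
    return np.exp(log_rr - log_rr_ref)
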