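"""Conditional and unconditional logistic regression, Wald intervals, LR and trend tests.

Both fits maximise their likelihood directly by Newton-Raphson with
step-halving (the likelihoods are concave, so this is deterministic and
converges in a handful of iterations at epidemiological scale).

For a matched set :math:`s` with one case and members :math:`m`, the
conditional likelihood contribution is

.. math::

    \\ell_s(\\beta) = x_{\\mathrm{case}}'\\beta
        - \\log \\sum_{m \\in s} \\exp(x_m'\\beta),

which conditions away the per-set intercept, so matching factors (age, sex)
and anything constant within a pair drop out of the model. For 1:1 pairs
this is algebraically an intercept-free logistic fit on within-pair
covariate differences; the implementation works on the general one-case
form above and the identity is exercised in the test-suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DomainError, SeparationError, ValidationError

__all__ = [
    "FitResult",
    "fit_conditional_logistic",
    "fit_logistic",
    "wald_or_ci",
    "likelihood_ratio_test",
    "trend_test",
]

GRAD_TOL = 1e-8
MAX_ITER = 100
MAX_ABS_BETA = 15.0


@dataclass
class FitResult:
    """Maximum-likelihood fit: coefficients, covariance and log-likelihood."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int  # matched sets (conditional) or subjects (unconditional)
    model: str  # "conditional_logit" | "logit"
    ll_trace: np.ndarray  # log-likelihood after each Newton step

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    @property
    def columns(self) -> list[str]:
        return list(self.params.index)

    def wald_p(self, column: str) -> float:
        z = self.params[column] / self.bse[column]
        return float(2 * stats.norm.sf(abs(z)))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": self.model,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik": self.loglik,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _as_design(design: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(design)
    if design.isna().to_numpy().any():
        raise ValidationError("design matrix contains missing cells")
    return design


def _check_rank(X: np.ndarray, columns: Sequence[str], context: str) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(
            f"{context}: design matrix is rank deficient "
            f"(rank {rank} < {X.shape[1]} columns {list(columns)})"
        )


def _newton(loglik_grad_hess, p, columns, model, n_obs, beta_scale=None):
    """Maximise a concave log-likelihood by damped Newton iteration.

    ``beta_scale`` carries one spread per covariate so the separation guard
    (|beta_j| * scale_j > 15, i.e. one covariate SD moving the log odds by
    more than 15) is invariant to affine rescaling of the design.
    """
    beta = np.zeros(p)
    if beta_scale is None:
        beta_scale = np.ones(p)
    ll, grad, hess = loglik_grad_hess(beta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"{model}: singular Hessian at iteration {it}") from exc
        # step-halving keeps the log-likelihood monotone
        scale = 1.0
        for _ in range(40):
            candidate = beta + scale * step
            ll_new, grad_new, hess_new = loglik_grad_hess(candidate)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            raise ConvergenceError(f"{model}: step-halving failed at iteration {it}")
        beta, ll, grad, hess = candidate, ll_new, grad_new, hess_new
        trace.append(ll)
        scaled = np.abs(beta) * beta_scale
        if np.max(scaled) > MAX_ABS_BETA:
            worst = columns[int(np.argmax(scaled))]
            raise SeparationError(worst)
    else:
        raise ConvergenceError(f"{model}: no convergence in {MAX_ITER} iterations")
    cov = np.linalg.inv(-hess)
    return beta, cov, ll, converged, it, np.array(trace)


def fit_conditional_logistic(
    design: pd.DataFrame,
    outcome: Sequence[bool] | np.ndarray,
    matched_set: Sequence | np.ndarray,
) -> FitResult:
    """Conditional logistic regression for matched sets with one case each.

    ``design`` holds one row of covariates per subject (no intercept: it is
    not identified), ``outcome`` flags the case in each set, ``matched_set``
    labels the sets. Every set must contain exactly one case and at least one
    control; covariates constant within every set are not identified and
    raise :class:`ValidationError`.
    """
    design = _as_design(design)
    y = np.asarray(outcome, dtype=bool)
    sets = np.asarray(matched_set)
    if not (len(design) == y.size == sets.size):
        raise ValidationError("design, outcome and matched_set lengths differ")
    order = np.argsort(sets, kind="stable")
    X = design.to_numpy(dtype=float)[order]
    y = y[order]
    sets = sets[order]
    starts = np.flatnonzero(np.r_[True, sets[1:] != sets[:-1]])
    ends = np.r_[starts[1:], sets.size]
    sizes = ends - starts
    cases_per_set = np.add.reduceat(y.astype(int), starts)
    if (sizes < 2).any() or (cases_per_set != 1).any():
        bad = sets[starts[(sizes < 2) | (cases_per_set != 1)]][:5]
        raise ValidationError(
            f"each matched set needs exactly 1 case and >=1 control; offending sets: {list(bad)}"
        )
    # identifiability lives in the within-set variation
    set_index = np.repeat(np.arange(starts.size), sizes)
    set_means = np.add.reduceat(X, starts, axis=0) / sizes[:, None]
    X_centered = X - set_means[set_index]
    constant = ~np.any(np.abs(X_centered) > 1e-12, axis=0)
    if constant.any():
        bad_cols = [c for c, flag in zip(design.columns, constant) if flag]
        raise ValidationError(
            f"covariate(s) constant within every matched set (not identified): {bad_cols}"
        )
    _check_rank(X_centered, design.columns, "conditional logistic")
    case_x_sum = X[y].sum(axis=0)

    def llgh(beta: np.ndarray):
        eta = X @ beta
        set_max = np.maximum.reduceat(eta, starts)
        expc = np.exp(eta - set_max[set_index])
        denom = np.add.reduceat(expc, starts)
        ll = float(eta[y].sum() - (np.log(denom) + set_max).sum())
        pi = expc / denom[set_index]
        A = X * pi[:, None]
        S = np.add.reduceat(A, starts, axis=0)  # per-set weighted mean of x
        grad = case_x_sum - S.sum(axis=0)
        hess = -(X.T @ A - S.T @ S)
        return ll, grad, hess

    beta, cov, ll, converged, n_iter, trace = _newton(
        llgh,
        X.shape[1],
        list(design.columns),
        "conditional logistic",
        starts.size,
        beta_scale=X_centered.std(axis=0),
    )
    return FitResult(
        params=pd.Series(beta, index=design.columns),
        cov=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        n_obs=int(starts.size),
        model="conditional_logit",
        ll_trace=trace,
    )


def fit_logistic(
    design: pd.DataFrame,
    outcome: Sequence[bool] | np.ndarray,
    *,
    add_intercept: bool = True,
) -> FitResult:
    """Unconditional maximum-likelihood logistic regression.

    An intercept column ``const`` is prepended unless ``add_intercept=False``
    or the design already contains one.
    """
    design = _as_design(design)
    y = np.asarray(outcome, dtype=float)
    if len(design) != y.size:
        raise ValidationError("design and outcome lengths differ")
    if not (0 < y.sum() < y.size):
        raise ValidationError("outcome needs at least one case and one non-case")
    if add_intercept and "const" not in design.columns:
        design = design.copy()
        design.insert(0, "const", 1.0)
    X = design.to_numpy(dtype=float)
    _check_rank(X, design.columns, "logistic")

    def llgh(beta: np.ndarray):
        eta = X @ beta
        # numerically stable log(1 + e^eta)
        log1pexp = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
        ll = float(y @ eta - log1pexp.sum())
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        hess = -(X.T @ (X * w[:, None]))
        return ll, grad, hess

    beta, cov, ll, converged, n_iter, trace = _newton(
        llgh, X.shape[1], list(design.columns), "logistic", y.size,
        beta_scale=X.std(axis=0),  # zero for the intercept: never flagged itself
    )
    return FitResult(
        params=pd.Series(beta, index=design.columns),
        cov=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        n_obs=int(y.size),
        model="logit",
        ll_trace=trace,
    )


def wald_or_ci(fit: FitResult, column: str, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio with a Wald confidence interval for one coefficient."""
    if not fit.converged:
        raise ConvergenceError("cannot form a Wald interval from a non-converged fit")
    if not 0 < level < 1:
        raise DomainError("confidence level must lie in (0, 1)")
    beta = fit.params[column]
    se = fit.bse[column]
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """LR test of a reduced model nested in a full model.

    Returns ``(statistic, df, p)`` with the statistic ``2(ll_full −
    ll_reduced)`` clipped at zero and ``df`` the column-count difference.
    """
    if not set(reduced.columns) <= set(full.columns):
        raise ValidationError("reduced model columns must be a subset of the full model's")
    if full.model != reduced.model or full.n_obs != reduced.n_obs:
        raise ValidationError("LR test requires the same model family and observations")
    statistic = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = len(full.columns) - len(reduced.columns)
    if df == 0:  # identical models: the test is vacuous
        return statistic, 0, 1.0 if statistic < 1e-10 else 0.0
    return statistic, df, float(stats.chi2.sf(statistic, df))


def trend_test(
    adjust: pd.DataFrame,
    outcome: Sequence[bool] | np.ndarray,
    quartile_labels: Sequence[int] | np.ndarray,
    quartile_medians: Mapping[int, float],
    *,
    matched_set: Sequence | np.ndarray | None = None,
    statistic: str = "wald",
) -> float:
    """Dose-response (trend) p-value across exposure quartiles.

    The categorical exposure is replaced by each subject's quartile median
    as a single continuous covariate, appended to the adjustment columns;
    the model family follows ``matched_set`` (conditional when given). The
    p-value is the Wald test of that coefficient by default, or an LR test
    against the adjustment-only model with ``statistic="lr"``.
    """
    if len(set(quartile_medians.values())) < 2:
        raise DomainError("trend test needs at least two distinct quartile medians")
    labels = np.asarray(quartile_labels)
    score = np.array([quartile_medians[int(q)] for q in labels], dtype=float)
    design = _as_design(adjust).copy()
    design["fiber_trend"] = score
    if matched_set is not None:
        full = fit_conditional_logistic(design, outcome, matched_set)
        if statistic == "lr":
            reduced = fit_conditional_logistic(
                design.drop(columns="fiber_trend"), outcome, matched_set
            )
    else:
        full = fit_logistic(design, outcome)
        if statistic == "lr":
            reduced = fit_logistic(design.drop(columns="fiber_trend"), outcome)
    if statistic == "wald":
        return full.wald_p("fiber_trend")
    if statistic == "lr":
        return likelihood_ratio_test(full, reduced)[2]
    raise DomainError(f"unknown trend statistic {statistic!r}")
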