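"""Baseline-category multinomial logit model of month of birth.

Models the probability that a birth falls in each calendar month as a
function of stratum covariates (country as a factor, year of birth, a
leap-year indicator, and optionally latitude).  With January as the baseline
month, each of the 11 remaining months gets its own linear predictor
``eta_m(x)`` and

    P(month = m | x) = exp(eta_m(x)) / sum_k exp(eta_k(x)),   eta_Jan = 0.

The likelihood is evaluated directly on aggregated per-stratum monthly
counts — fully equivalent to fitting the expanded individual-level records —
and maximized by Newton-Raphson with the analytic gradient and Hessian.
Standard errors come from the inverse observed information.  A
likelihood-ratio test compares nested covariate sets (e.g. with and without
latitude).

Year is centered before entry and leap-year status is a 0/1 indicator; the
country factor uses reference coding with the alphabetically first label as
reference.  Any full-rank coding yields the same fitted probabilities.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .io import MonthOfBirthTable

__all__ = ["MonthLogitModel", "fit_month_logit", "lrt", "predicted_month_probs"]

_KNOWN_COVARIATES = ("country", "year", "leap", "latitude")


@dataclass(frozen=True)
class MonthLogitModel:
    """Fitted baseline-category logit for month of birth.

    ``coef`` and ``se`` have one row per non-baseline month (February..
    December when the baseline is January) and one column per design column
    (intercept first).
    """

    baseline_month: int
    covariates: tuple
    colnames: tuple
    coef: np.ndarray  # (11, p)
    se: np.ndarray  # (11, p)
    log_likelihood: float
    log_likelihood_null: float
    n_obs: float
    country_levels: tuple
    year_center: float
    converged: bool

    @property
    def n_params(self) -> int:
        return int(self.coef.size)

    @property
    def months(self) -> tuple:
        return tuple(m for m in range(1, 13) if m != self.baseline_month)

    @property
    def mcfadden_r2(self) -> float:
        """McFadden pseudo-R^2 against the intercept-only fit."""
        return 1.0 - self.log_likelihood / self.log_likelihood_null

    def summary_frame(self):
        """Per-coefficient estimates, standard errors, z and p as a frame."""
        import pandas as pd

        rows = []
        for i, m in enumerate(self.months):
            for j, name in enumerate(self.colnames):
                est, se = self.coef[i, j], self.se[i, j]
                z = est / se if se > 0 else np.nan
                rows.append(
                    {
                        "month": m,
                        "covariate": name,
                        "estimate": est,
                        "se": se,
                        "z": z,
                        "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def _design_matrix(
    tables: Sequence[MonthOfBirthTable],
    covariates: Sequence[str],
    country_levels: Optional[tuple] = None,
    year_center: Optional[float] = None,
):
    """Stratum design matrix with an always-present intercept column."""
    for c in covariates:
        if c not in _KNOWN_COVARIATES:
            raise ValueError(f"unknown covariate {c!r}; choose from {_KNOWN_COVARIATES}")
    cols = [np.ones(len(tables))]
    names = ["intercept"]
    if "country" in covariates:
        if country_levels is None:
            country_levels = tuple(sorted({t.label for t in tables}))
        for level in country_levels[1:]:
            cols.append(np.array([1.0 if t.label == level else 0.0 for t in tables]))
            names.append(f"country[{level}]")
        for t in tables:
            if t.label not in country_levels:
                raise ValueError(f"unseen country level {t.label!r}")
    else:
        country_levels = ()
    if "year" in covariates:
        years = np.array([float(t.year) for t in tables])
        if year_center is None:
            year_center = float(years.mean())
        cols.append(years - year_center)
        names.append("year")
    else:
        year_center = 0.0
    if "leap" in covariates:
        cols.append(
            np.array(
                [1.0 if (t.year is not None and calendar.isleap(t.year)) else 0.0 for t in tables]
            )
        )
        names.append("leap")
    if "latitude" in covariates:
        lats = [t.latitude for t in tables]
        if any(v is None for v in lats):
            raise ValueError("latitude covariate requested but some tables lack latitude")
        cols.append(np.array(lats, dtype=float))
        names.append("latitude")
    return np.column_stack(cols), tuple(names), country_levels, year_center


def _loglik_grad_hess(beta: np.ndarray, X: np.ndarray, counts: np.ndarray, base: int):
    """Count-weighted multinomial log-likelihood with analytic derivatives.

    ``beta`` is (11, p); the baseline month's linear predictor is fixed at 0.
    """
    S, p = X.shape
    eta = np.zeros((S, 12))
    nonbase = [m for m in range(12) if m != base]
    eta[:, nonbase] = X @ beta.T
    eta -= eta.max(axis=1, keepdims=True)
    expeta = np.exp(eta)
    probs = expeta / expeta.sum(axis=1, keepdims=True)
    N = counts.sum(axis=1)
    ll = float((counts * np.log(probs)).sum())
    resid = counts[:, nonbase] - N[:, None] * probs[:, nonbase]  # (S, 11)
    grad = (resid.T @ X).ravel()  # (11*p,)
    P = probs[:, nonbase]
    H = np.zeros((11 * p, 11 * p))
    for j in range(11):
        for k in range(j, 11):
            w = N * (P[:, j] * (1.0 if j == k else 0.0) - P[:, j] * P[:, k])
            blk = -(X * w[:, None]).T @ X
            H[j * p : (j + 1) * p, k * p : (k + 1) * p] = blk
            if k != j:
                H[k * p : (k + 1) * p, j * p : (j + 1) * p] = blk
    return ll, grad, H, probs


def fit_month_logit(
    tables: Sequence[MonthOfBirthTable],
    covariates: Sequence[str] = ("country", "year", "leap"),
    baseline_month: int = 1,
    max_iter: int = 100,
    grad_tol: float = 1e-6,
) -> MonthLogitModel:
    """Maximum-likelihood fit of the baseline-category month-of-birth logit.

    Accepts aggregated per-stratum counts (one :class:`MonthOfBirthTable`
    per stratum).  Raises on separation — a month empty in every stratum —
    and on failure to reach gradient max-norm below ``grad_tol``.
    """
    if not tables:
        raise ValueError("need at least one table")
    counts = np.vstack([t.counts for t in tables])
    empty = np.flatnonzero(counts.sum(axis=0) == 0)
    if empty.size:
        raise ValueError(
            f"separation: month(s) {[int(m) + 1 for m in empty]} have no births "
            "in any stratum"
        )
    X, names, levels, year_center = _design_matrix(tables, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (too few covariate patterns)")
    base = baseline_month - 1
    p = X.shape[1]
    beta = np.zeros((11, p))
    ll, grad, H, _ = _loglik_grad_hess(beta, X, counts, base)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < grad_tol:
            break
        step = np.linalg.solve(H, -grad).reshape(11, p)
        scale = 1.0
        # acceptance tolerance is relative: near the optimum the log-likelihood
        # plateaus at machine precision on the scale of |ll|
        ll_tol = 1e-10 * (1.0 + abs(ll))
        for _half in range(30):
            trial = beta + scale * step
            ll_new, grad_new, H_new, _ = _loglik_grad_hess(trial, X, counts, base)
            if ll_new >= ll - ll_tol:
                beta, ll, grad, H = trial, ll_new, grad_new, H_new
                break
            scale *= 0.5
        else:
            raise RuntimeError("step halving failed; likelihood not improving")
    converged = bool(np.max(np.abs(grad)) < grad_tol)
    if not converged:
        raise RuntimeError(f"no convergence in {max_iter} Newton iterations")
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(11, p)
    # intercept-only MLE is the pooled proportion vector (closed form)
    pooled = counts.sum(axis=0)
    ll_null = float((pooled * np.log(pooled / pooled.sum())).sum())
    return MonthLogitModel(
        baseline_month=baseline_month,
        covariates=tuple(covariates),
        colnames=names,
        coef=beta,
        se=se,
        log_likelihood=ll,
        log_likelihood_null=ll_null,
        n_obs=float(counts.sum()),
        country_levels=levels,
        year_center=year_center,
        converged=converged,
    )


def lrt(full: MonthLogitModel, reduced: MonthLogitModel) -> float:
    """Likelihood-ratio p-value for nested month-of-birth logits.

    The reduced model's covariates must be a subset of the full model's and
    both must be fitted to the same observations.
    """
    if not set(reduced.covariates) <= set(full.covariates):
        raise ValueError("models are not nested (reduced covariates not a subset)")
    if reduced.n_obs != full.n_obs:
        raise ValueError("models were fitted to different observation totals")
    df = full.n_params - reduced.n_params
    if df == 0:
        return 1.0
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    return float(stats.chi2.sf(stat, df))


def predicted_month_probs(
    model: MonthLogitModel, covariates: Mapping[str, object]
) -> np.ndarray:
    """Predicted 12-month probability vector for one covariate setting.

    ``covariates`` supplies values by name for the model's covariate set,
    e.g. ``{"country": "UK", "year": 1960, "latitude": 52.0}``; the leap
    indicator is derived from the year when the model includes it.
    """
    x = [1.0]
    for name in model.colnames[1:]:
        if name.startswith("country["):
            level = name[len("country[") : -1]
            value = covariates.get("country")
            if value not in model.country_levels:
                raise ValueError(
                    f"unseen country level {value!r}; fitted levels are "
                    f"{model.country_levels}"
                )
            x.append(1.0 if value == level else 0.0)
        elif name == "year":
            x.append(float(covariates["year"]) - model.year_center)
        elif name == "leap":
            if "leap" in covariates:
                x.append(1.0 if covariates["leap"] else 0.0)
            else:
                x.append(1.0 if calendar.isleap(int(covariates["year"])) else 0.0)
        elif name == "latitude":
            x.append(float(covariates["latitude"]))
    x = np.asarray(x)
    eta = np.zeros(12)
    nonbase = [m for m in range(12) if m != model.baseline_month - 1]
    eta[nonbase] = model.coef @ x
    eta -= eta.max()
    expeta = np.exp(eta)
    return expeta / expeta.sum()
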