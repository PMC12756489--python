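"""Logistic regression with odds-ratio inference and calibration.

The core model is an intercept-included multivariable logistic regression of
the binary SR label on per-category lexicon counts, fitted by Newton-Raphson
(iteratively reweighted least squares) on the exact log-likelihood.
Inference is Wald: the covariance is the inverse observed information at the
MLE, confidence intervals are symmetric on the log-odds scale and
exponentiated to the odds-ratio scale, and two-sided p-values come from the
normal reference.  Quasi-complete separation (diverging coefficients with a
vanishing gradient) is detected and flagged rather than silently reported
with meaningless standard errors.

Calibration uses the Hosmer-Lemeshow chi-square over near-equal-size bins of
predicted probability (ties kept together), with ``groups - 2`` degrees of
freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import INTERCEPT, DesignMatrix

__all__ = [
    "ModelError",
    "SeparationError",
    "LogisticFit",
    "PredictorEffect",
    "CalibrationResult",
    "fit_logistic",
    "effects_table",
    "predict_proba",
    "hosmer_lemeshow",
    "calibration_pvalue",
    "benjamini_hochberg",
]

#: absolute bound on any coefficient beyond which the likelihood is treated
#: as divergent (log-odds of ~1e13 per unit count have no finite MLE)
_SEPARATION_BOUND = 30.0
#: a "converged" solution with a coefficient this large is a separated fit
#: whose score merely vanished because the fitted probabilities saturated
_SATURATION_BOUND = 15.0


class ModelError(RuntimeError):
    """Fit failure that is not explained by separation."""


class SeparationError(ModelError):
    """Inference requested on a separation-flagged fit."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    separation_detected: bool
    column_names: list[str]
    n_obs: int

    @property
    def se(self) -> np.ndarray:
        if self.cov is None:
            raise SeparationError("standard errors suppressed: separation detected")
        return np.sqrt(np.diag(self.cov))


@dataclass
class PredictorEffect:
    """One category's odds ratio in one stratum at one chat fraction."""

    category_id: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    stratum: str = "All"
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")
        if min(self.ci_low, self.odds_ratio) <= 0:
            raise ValueError("odds-ratio quantities must be positive")


@dataclass
class CalibrationResult:
    chi2: float
    df: int
    p_value: float
    table: pd.DataFrame  # per-bin observed/expected counts in both classes


def fit_logistic(design: DesignMatrix, max_iter: int = 100,
                 score_tol: float = 1e-8, ll_tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood fit by Newton-Raphson with step halving.

    Convergence when the largest score component falls below ``score_tol``
    or the relative log-likelihood change falls below ``ll_tol``.  A
    non-intercept column that is constant has no identifiable coefficient and
    is rejected up front.  Divergence of any coefficient past +-30 with the
    fit still improving is flagged as quasi-complete separation: the
    coefficients are returned but the covariance (hence any CI) is withheld.
    """
    X, y = design.X, design.y
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ModelError(
            f"outcome must contain both classes, got {classes.tolist()} "
            f"in stratum {design.stratum!r}"
        )
    non_intercept = [j for j, c in enumerate(design.column_names) if c != INTERCEPT]
    const = [design.column_names[j] for j in non_intercept
             if np.ptp(X[:, j]) == 0.0]
    if const:
        raise ModelError(f"constant non-intercept column(s): {const}")

    n, p = X.shape
    beta = np.zeros(p)
    try:
        icol = design.column_names.index(INTERCEPT)
        prev = float(np.mean(y))
        beta[icol] = np.log(prev / (1.0 - prev))
    except ValueError:
        pass
    ll = _log_likelihood(y, X @ beta)

    separation = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _sigmoid(eta)
        score = X.T @ (y - mu)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step halving keeps the likelihood monotone
        new_ll = -np.inf
        for _ in range(30):
            cand = beta + step
            new_ll = _log_likelihood(y, X @ cand)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        rel_change = abs(new_ll - ll) / (abs(ll) + 1.0)
        ll = new_ll
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            separation = True
            break
        if np.max(np.abs(X.T @ (y - _sigmoid(X @ beta)))) < score_tol:
            converged = True
            break
        if rel_change < ll_tol:
            converged = True
            break

    # under quasi-complete separation the score also vanishes (fitted
    # probabilities saturate at the data), so a "converged" solution with a
    # diverged coefficient is separation too
    if converged and np.max(np.abs(beta)) > _SATURATION_BOUND:
        separation, converged = True, False
    if separation:
        return LogisticFit(beta, None, ll, False, it, True,
                           list(design.column_names), n)
    if not converged:
        raise ModelError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(stratum {design.stratum!r})"
        )
    mu = _sigmoid(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return LogisticFit(beta, cov, ll, True, it, False,
                       list(design.column_names), n)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up), monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def effects_table(fit: LogisticFit, alpha: float = 0.05,
                  bh_correction: bool = False, stratum: str | None = None,
                  fraction: float = 1.0) -> list[PredictorEffect]:
    """Odds ratios with Wald 95% (1-alpha) CIs and two-sided p-values.

    The intercept is excluded.  ``significant`` is ``p < alpha`` on the raw
    Wald p-value, or on the Benjamini-Hochberg adjusted p-value when
    ``bh_correction`` is on.
    """
    if fit.separation_detected:
        raise SeparationError(
            "effects unavailable: quasi-complete separation detected"
        )
    if not fit.converged:
        raise ModelError("effects require a converged fit")
    se = fit.se
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    idx = [j for j, c in enumerate(fit.column_names) if c != INTERCEPT]
    z = fit.coef[idx] / se[idx]
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    p_test = benjamini_hochberg(p_raw) if bh_correction else p_raw
    effects = []
    for k, j in enumerate(idx):
        b, s = fit.coef[j], se[j]
        effects.append(PredictorEffect(
            category_id=fit.column_names[j],
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - z_crit * s)),
            ci_high=float(np.exp(b + z_crit * s)),
            p_value=float(p_raw[k]),
            significant=bool(p_test[k] < alpha),
            stratum=stratum or "All",
            fraction=fraction,
        ))
    return effects


def predict_proba(fit: LogisticFit, design: DesignMatrix) -> np.ndarray:
    """Fitted event probabilities logistic(X beta) for each design row."""
    if fit.separation_detected:
        warnings.warn("predictions from a separation-flagged fit are saturated",
                      RuntimeWarning, stacklevel=2)
    if list(design.column_names) != list(fit.column_names):
        raise ModelError(
            f"feature columns {design.column_names} do not match the fit's "
            f"{fit.column_names}"
        )
    return _sigmoid(design.X @ fit.coef)


def calibration_pvalue(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability (the Hosmer-Lemeshow reference)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(chi2, df))


def hosmer_lemeshow(fit: LogisticFit, design: DesignMatrix,
                    groups: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit over probability bins.

    Rows are sorted by predicted probability and split into ``groups``
    near-equal-size bins; rows with tied probabilities always land in the
    same bin.  The statistic sums (observed - expected)^2 / expected over
    both outcome classes in every bin and is referred to chi-square with
    ``groups - 2`` degrees of freedom.
    """
    if groups < 3:
        raise ValueError("need at least 3 groups (df = groups - 2 >= 1)")
    n = design.n_obs
    if n < groups:
        raise ValueError(f"need at least {groups} observations, have {n}")
    p = predict_proba(fit, design)
    order = np.argsort(p, kind="mergesort")
    p_sorted, y_sorted = p[order], design.y[order]

    # near-equal bin boundaries, pushed forward across ties
    bounds = [round(i * n / groups) for i in range(1, groups)]
    adj = []
    for b in bounds:
        while 0 < b < n and p_sorted[b - 1] == p_sorted[b]:
            b += 1
        adj.append(min(b, n))
    edges = [0, *adj, n]

    rows = []
    chi2 = 0.0
    for g in range(groups):
        lo, hi = edges[g], edges[g + 1]
        if lo >= hi:
            raise ValueError(
                f"bin {g} is empty after keeping tied predictions together; "
                "refit with fewer groups"
            )
        obs1 = float(np.sum(y_sorted[lo:hi]))
        exp1 = float(np.sum(p_sorted[lo:hi]))
        obs0 = float(hi - lo) - obs1
        exp0 = float(hi - lo) - exp1
        if exp1 <= 0.0 or exp0 <= 0.0:
            raise ValueError(
                f"bin {g} has zero expected count; refit with fewer groups"
            )
        chi2 += (obs1 - exp1) ** 2 / exp1 + (obs0 - exp0) ** 2 / exp0
        rows.append({"bin": g, "n": hi - lo, "observed_sr": obs1,
                     "expected_sr": exp1, "observed_non_sr": obs0,
                     "expected_non_sr": exp0})
    df = groups - 2
    return CalibrationResult(chi2=chi2, df=df,
                             p_value=calibration_pvalue(chi2, df),
                             table=pd.DataFrame(rows))
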