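"""Logistic risk-factor modelling: univariate screen and stepwise selection.

The design is complete-case: cohort reports (outcome 1) against background
non-cohort reports (outcome 0), with sex (female = 0 / male = 1 — the
reference coding is reported explicitly with every result), age and weight
per unit, indicator columns for the most prevalent comorbidities (taken from
drug indication terms) and for screened drugs.

Fitting is maximum likelihood via iteratively reweighted least squares
(Fisher scoring) with step-halving; selection is forward with backward
pruning, driven by likelihood-ratio tests at a fixed alpha (Wald intervals
are still what gets reported per term, matching the usual OR/CI/p display).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .report_store import CaseReport, Sex, normalize_term

__all__ = [
    "SeparationError",
    "RankDeficiencyError",
    "LogisticFit",
    "RegressionResult",
    "StepwiseResult",
    "fit_logistic",
    "build_design",
    "univariate_screen",
    "stepwise_select",
    "results_to_frame",
]

Z95 = 1.959963984540054
_MAX_ABS_BETA = 15.0
_SCORE_TOL = 1e-8
_DEV_TOL = 1e-10


class SeparationError(RuntimeError):
    """The likelihood is maximized at infinity for some coefficient."""

    def __init__(self, term: str):
        super().__init__(f"complete or quasi-complete separation on term {term!r}")
        self.term = term


class RankDeficiencyError(RuntimeError):
    """The design matrix is rank deficient."""

    def __init__(self, terms: Sequence[str]):
        super().__init__(f"collinear design columns: {list(terms)}")
        self.terms = list(terms)


@dataclass
class LogisticFit:
    terms: list[str]          # includes "(intercept)" first
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    n_obs: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_ci(self, i: int) -> tuple[float, float]:
        s = self.se()[i]
        return math.exp(self.beta[i] - Z95 * s), math.exp(self.beta[i] + Z95 * s)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: sum y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    terms: Sequence[str] | None = None,
    max_iter: int = 100,
    add_intercept: bool = True,
) -> LogisticFit:
    """IRLS maximum-likelihood logistic fit.

    Converges when max |score| < 1e-8 or the relative deviance change is
    below 1e-10. Raises :class:`SeparationError` when a coefficient diverges
    (|beta| > 15 with a non-vanishing score) and :class:`RankDeficiencyError`
    on collinear designs.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns) if terms is None else list(terms)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if terms is None:
            terms = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be 0/1")
    if y.min() == y.max():
        raise ValueError("need at least one outcome of each class")

    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        terms = ["(intercept)", *terms]
    n, p = X.shape

    if np.linalg.matrix_rank(X) < p:
        # name the dependent columns via QR
        _, r = np.linalg.qr(X)
        bad = [terms[j] for j in range(p) if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise RankDeficiencyError(bad or terms)

    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(y, eta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < _SCORE_TOL:
            break
        XtWX = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(XtWX + 1e-12 * np.eye(p), score)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(terms) from exc
        # step-halving keeps the log-likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        eta = X @ beta
        ll_prev, ll = ll, _loglik(y, eta)
        big = np.abs(beta) > _MAX_ABS_BETA
        if np.any(big) and np.max(np.abs(score)) > 1e-4:
            raise SeparationError(terms[int(np.argmax(np.abs(beta)))])
        if abs(ll - ll_prev) < _DEV_TOL * (abs(ll_prev) + 1e-10):
            break

    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    XtWX = X.T @ (X * w[:, None])
    cov = np.linalg.inv(XtWX + 1e-12 * np.eye(p))
    return LogisticFit(terms=list(terms), beta=beta, cov=cov, loglik=ll,
                       n_iter=n_iter, n_obs=n)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_design(
    cohort: Sequence[CaseReport],
    background: Sequence[CaseReport],
    n_comorbidities: int = 20,
    drugs: Sequence[str] | None = None,
    age_center: float = 0.0,
    weight_center: float = 0.0,
) -> pd.DataFrame:
    """Complete-case design frame: outcome + demographics + indicator columns.

    Comorbidity indicators come from the ``n_comorbidities`` most frequent
    normalized indication terms across the background corpus; drug indicators
    from ``drugs`` (normalized names). Reports with missing age, sex or
    weight are dropped. Cohort membership is determined by case_id.
    """
    cohort_ids = {r.case_id for r in cohort}
    complete = [
        r
        for r in background
        if r.age_years is not None and r.weight_kg is not None and r.sex != Sex.UNKNOWN
    ]
    term_counts: Counter = Counter()
    for r in complete:
        for d in r.drugs:
            if d.indication:
                term_counts[normalize_term(d.indication)] += 1
    top_terms = [t for t, _ in term_counts.most_common(n_comorbidities)]

    rows = []
    for r in complete:
        row = {
            "outcome": 1 if r.case_id in cohort_ids else 0,
            "sex_male": 1 if r.sex == Sex.MALE else 0,
            "age_years": r.age_years - age_center,
            "weight_kg": r.weight_kg - weight_center,
        }
        indications = {normalize_term(d.indication) for d in r.drugs if d.indication}
        for t in top_terms:
            row[f"comorbidity:{t}"] = 1 if t in indications else 0
        if drugs:
            names = r.drug_names()
            for dn in drugs:
                row[f"drug:{dn}"] = 1 if dn in names else 0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screening and stepwise selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    term: str
    estimate: float
    or_value: float
    ci: tuple[float, float]
    p_value: float
    stage: str            # "univariate" | "multivariate"
    included: bool = True
    error: str | None = None


@dataclass
class StepwiseResult:
    final_terms: list[str]
    results: list[RegressionResult]
    trace: list[dict] = field(default_factory=list)
    final_fit: LogisticFit | None = None


def _lr_pvalue(ll_full: float, ll_reduced: float, df: int = 1) -> float:
    lr = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(lr, df))


def univariate_screen(
    design: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    outcome: str = "outcome",
) -> list[RegressionResult]:
    """One single-covariate logistic fit per candidate term.

    Terms that fail (separation, rank deficiency) are returned with
    ``error`` set and screening continues.
    """
    y = design[outcome].to_numpy()
    candidates = [c for c in design.columns if c != outcome] if candidates is None else list(candidates)
    null_ll = _null_loglik(y)
    out = []
    for term in candidates:
        try:
            fit = fit_logistic(design[[term]], y)
        except (SeparationError, RankDeficiencyError, ValueError) as exc:
            out.append(
                RegressionResult(term, math.nan, math.nan, (math.nan, math.nan),
                                 math.nan, "univariate", included=False,
                                 error=str(exc))
            )
            continue
        i = fit.terms.index(term)
        out.append(
            RegressionResult(
                term=term,
                estimate=float(fit.beta[i]),
                or_value=math.exp(fit.beta[i]),
                ci=fit.wald_ci(i),
                p_value=_lr_pvalue(fit.loglik, null_ll),
                stage="univariate",
            )
        )
    return out


def _null_loglik(y: np.ndarray) -> float:
    p = y.mean()
    n1 = y.sum()
    n0 = len(y) - n1
    return float(n1 * math.log(p) + n0 * math.log(1 - p))


def stepwise_select(
    design: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    alpha: float = 0.05,
    outcome: str = "outcome",
    max_steps: int = 200,
) -> StepwiseResult:
    """Forward selection with backward pruning on likelihood-ratio tests.

    At each step the candidate with the smallest LR p-value < alpha enters;
    after each addition any included term whose LR p-value rises to >= alpha
    is dropped. The procedure is deterministic for a fixed input and
    candidate order; the trace records every add/drop with its p-value.
    """
    y = design[outcome].to_numpy()
    candidates = (
        [c for c in design.columns if c != outcome] if candidates is None else list(candidates)
    )
    if not candidates:
        raise ValueError("candidates must be non-empty")

    included: list[str] = []
    trace: list[dict] = []

    def loglik_for(terms: list[str]) -> float | None:
        if not terms:
            return _null_loglik(y)
        try:
            return fit_logistic(design[terms], y).loglik
        except (SeparationError, RankDeficiencyError, ValueError):
            return None

    current_ll = _null_loglik(y)
    for _ in range(max_steps):
        changed = False
        # forward step: best addition
        best_term, best_p, best_ll = None, None, None
        for term in candidates:
            if term in included:
                continue
            ll = loglik_for(included + [term])
            if ll is None:
                continue
            p = _lr_pvalue(ll, current_ll)
            if p < alpha and (best_p is None or p < best_p):
                best_term, best_p, best_ll = term, p, ll
        if best_term is not None:
            included.append(best_term)
            current_ll = best_ll
            trace.append({"action": "add", "term": best_term, "p": best_p})
            changed = True

        # backward step: prune any term no longer significant
        while len(included) > 0:
            worst_term, worst_p, worst_ll = None, None, None
            for term in included:
                reduced = [t for t in included if t != term]
                ll_red = loglik_for(reduced)
                if ll_red is None:
                    continue
                p = _lr_pvalue(current_ll, ll_red)
                if worst_p is None or p > worst_p:
                    worst_term, worst_p, worst_ll = term, p, ll_red
            if worst_term is not None and worst_p >= alpha:
                included.remove(worst_term)
                current_ll = worst_ll
                trace.append({"action": "drop", "term": worst_term, "p": worst_p})
                changed = True
            else:
                break

        if not changed:
            break

    results: list[RegressionResult] = []
    final_fit = None
    if included:
        final_fit = fit_logistic(design[included], y)
        for term in included:
            i = final_fit.terms.index(term)
            ll_red = loglik_for([t for t in included if t != term])
            p = _lr_pvalue(final_fit.loglik, ll_red) if ll_red is not None else math.nan
            results.append(
                RegressionResult(
                    term=term,
                    estimate=float(final_fit.beta[i]),
                    or_value=math.exp(final_fit.beta[i]),
                    ci=final_fit.wald_ci(i),
                    p_value=p,
                    stage="multivariate",
                )
            )
    for term in candidates:
        if term not in included:
            results.append(
                RegressionResult(term, math.nan, math.nan, (math.nan, math.nan),
                                 math.nan, "multivariate", included=False)
            )
    return StepwiseResult(final_terms=included, results=results, trace=trace,
                          final_fit=final_fit)


def results_to_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "or": r.or_value,
                "ci_low": r.ci[0],
                "ci_high": r.ci[1],
                "p_value": r.p_value,
                "stage": r.stage,
                "included": r.included,
                "error": r.error or "",
            }
            for r in results
        ]
    )
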