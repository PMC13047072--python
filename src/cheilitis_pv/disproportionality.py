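"""Disproportionality metrics for spontaneous-report signal detection.

Frequentist metrics on the 2x2 table (a, b, c, d):

* ROR  = (a d)/(b c) with the Woolf interval
  exp(ln ROR +/- z sqrt(1/a + 1/b + 1/c + 1/d));
* PRR  = [a/(a+b)] / [c/(c+d)] with
  exp(ln PRR +/- z sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)));
* Pearson chi-square, Yates-corrected by default.

Zero-cell policy: when a > 0 but any of b, c, d is zero, the
Haldane-Anscombe +0.5 correction is applied to all four cells for both the
point estimate and the interval. Pairs with a = 0 get a 0-valued sentinel
estimate and are never flagged.

Bayesian shrinkage follows the DuMouchel gamma-Poisson model: the relative
reporting rate lambda of a cell with observed count n and independence
expectation E is given a two-component gamma mixture prior

    lambda ~ P Gamma(alpha1, beta1) + (1 - P) Gamma(alpha2, beta2)

(shape/rate), so that marginally n is a mixture of negative binomials. The
five hyperparameters are fitted by maximizing the marginal likelihood over
all cells; the posterior for each cell is again a gamma mixture with
shape_i = alpha_i + n, rate_i = beta_i + E and updated weight q. EBGM is the
posterior geometric mean exp(E[ln lambda]) and EB05/EB95 the posterior 5th
and 95th percentiles, found by monotone root-finding on the mixture CDF.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .contingency import CellExpectation, ContingencyTable, build_cell_set, report_exposures
from .report_store import CaseReport

__all__ = [
    "UndefinedResultError",
    "PriorFitError",
    "GammaPoissonPrior",
    "PosteriorMixture",
    "SignalCriteria",
    "SignalRecord",
    "ror",
    "prr",
    "chi_square",
    "fit_prior",
    "ebgm",
    "classify_signal",
    "signal_table",
    "signals_to_frame",
    "write_signals",
    "DEFAULT_PRIOR_START",
]

Z95 = 1.959963984540054


class UndefinedResultError(ValueError):
    """The requested statistic is undefined on this table."""


class PriorFitError(RuntimeError):
    """Hyperparameter optimization failed from every start."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


def _cells_with_policy(table: ContingencyTable) -> tuple[float, float, float, float]:
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a), float(b), float(c), float(d)


def ror(table: ContingencyTable, haldane: bool | None = None) -> tuple[float, float, float]:
    """Reporting odds ratio with 95% Woolf interval.

    ``haldane=True`` forces the +0.5 correction on all cells; ``None`` (the
    default) applies it only when a zero in b, c or d requires it.
    """
    if table.n_total == 0:
        raise UndefinedResultError("all cells zero")
    if table.a == 0:
        return 0.0, 0.0, math.inf
    if haldane:
        a, b, c, d = (table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5)
    else:
        a, b, c, d = _cells_with_policy(table)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se)


def prr(table: ContingencyTable, haldane: bool | None = None) -> tuple[float, float, float]:
    """Proportional reporting ratio with 95% log-scale interval."""
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise UndefinedResultError("a+b and c+d must both be positive")
    if table.a == 0:
        return 0.0, 0.0, math.inf
    if haldane:
        a, b, c, d = (table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5)
    else:
        a, b, c, d = _cells_with_policy(table)
    est = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se)


def chi_square(table: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the 2x2 table (Yates-corrected by default)."""
    if table.n_total == 0:
        raise UndefinedResultError("empty table")
    margins = (table.a + table.b, table.c + table.d, table.a + table.c, table.b + table.d)
    if min(margins) == 0:
        raise UndefinedResultError("a zero margin makes chi-square undefined")
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    stat, _, _, _ = stats.chi2_contingency(obs, correction=yates)
    return float(stat)


# ---------------------------------------------------------------------------
# gamma-Poisson shrinker
# ---------------------------------------------------------------------------

#: Classical starting point for the hyperparameter search.
DEFAULT_PRIOR_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class GammaPoissonPrior:
    """Two-component gamma mixture prior on the relative reporting rate."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_p: float
    loglik: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not (0 < self.mix_p < 1):
            raise ValueError(f"mix_p must lie in (0,1), got {self.mix_p}")

    def canonical(self) -> "GammaPoissonPrior":
        """Order components so component 1 has the smaller prior mean."""
        if self.alpha1 / self.beta1 <= self.alpha2 / self.beta2:
            return self
        return GammaPoissonPrior(
            self.alpha2, self.beta2, self.alpha1, self.beta1, 1 - self.mix_p,
            loglik=self.loglik,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "alpha1": self.alpha1,
                    "beta1": self.beta1,
                    "alpha2": self.alpha2,
                    "beta2": self.beta2,
                    "mix_p": self.mix_p,
                    "loglik": self.loglik,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GammaPoissonPrior":
        d = json.loads(Path(path).read_text())
        return cls(d["alpha1"], d["beta1"], d["alpha2"], d["beta2"], d["mix_p"],
                   loglik=d.get("loglik"))


@dataclass(frozen=True)
class PosteriorMixture:
    """Posterior gamma mixture for one cell's relative reporting rate."""

    q: float
    shape1: float
    rate1: float
    shape2: float
    rate2: float

    def cdf(self, x: float) -> float:
        return self.q * stats.gamma.cdf(x, a=self.shape1, scale=1 / self.rate1) + (
            1 - self.q
        ) * stats.gamma.cdf(x, a=self.shape2, scale=1 / self.rate2)

    def quantile(self, p: float) -> float:
        q1 = stats.gamma.ppf(p, a=self.shape1, scale=1 / self.rate1)
        q2 = stats.gamma.ppf(p, a=self.shape2, scale=1 / self.rate2)
        lo, hi = min(q1, q2), max(q1, q2)
        # F(lo) <= p <= F(hi) analytically; pad the bracket against
        # floating-point slack at the endpoints before root-finding.
        for _ in range(60):
            if self.cdf(lo) <= p:
                break
            lo *= 0.5
        for _ in range(60):
            if self.cdf(hi) >= p:
                break
            hi = hi * 2.0 + 1e-300
        if hi <= lo or self.cdf(hi) - self.cdf(lo) < 1e-15:
            return float(lo)
        return float(optimize.brentq(lambda x: self.cdf(x) - p, lo, hi,
                                     xtol=1e-14, rtol=8.9e-16))


def _log_nb(n: np.ndarray, alpha: float, beta: float, E: np.ndarray) -> np.ndarray:
    """log NB(n; alpha, beta/(beta+E)): marginal of Poisson(lambda E), lambda~Gamma."""
    return (
        special.gammaln(n + alpha)
        - special.gammaln(alpha)
        - special.gammaln(n + 1)
        + alpha * (math.log(beta) - np.log(beta + E))
        + n * (np.log(E) - np.log(beta + E))
    )


def _mixture_loglik(
    params: Sequence[float], n: np.ndarray, E: np.ndarray, truncated: bool
) -> float:
    a1, b1, a2, b2, p = params
    l1 = math.log(p) + _log_nb(n, a1, b1, E)
    l2 = math.log1p(-p) + _log_nb(n, a2, b2, E)
    ll = np.logaddexp(l1, l2)
    if truncated:
        # condition on n >= 1: subtract log(1 - P(0)) per cell
        zero = np.zeros_like(E)
        p0 = np.logaddexp(
            math.log(p) + _log_nb(zero, a1, b1, E),
            math.log1p(-p) + _log_nb(zero, a2, b2, E),
        )
        ll = ll - np.log1p(-np.exp(p0))
    return float(ll.sum())


def prior_loglik(
    prior: GammaPoissonPrior, cells: Sequence[CellExpectation], truncated: bool = False
) -> float:
    n = np.array([c.n for c in cells], dtype=float)
    E = np.array([c.E for c in cells], dtype=float)
    return _mixture_loglik(
        (prior.alpha1, prior.beta1, prior.alpha2, prior.beta2, prior.mix_p),
        n, E, truncated,
    )


_EXTRA_STARTS = (
    (1.0, 1.0, 1.0, 1.0, 0.5),
    (0.5, 0.5, 4.0, 2.0, 0.2),
    (0.1, 0.1, 1.0, 0.5, 0.5),
    (2.0, 2.0, 0.5, 0.1, 0.7),
)


def fit_prior(
    cells: Sequence[CellExpectation],
    starts: Iterable[tuple[float, float, float, float, float]] | None = None,
    truncated: bool = False,
) -> GammaPoissonPrior:
    """Maximum-marginal-likelihood fit of the five hyperparameters.

    Optimizes over (log alpha1, log beta1, log alpha2, log beta2, logit P)
    with L-BFGS-B from several starting points (the classical
    (0.2, 0.1, 2, 4, 1/3) first) and returns the best optimum, with
    components ordered by prior mean. ``truncated=True`` conditions the
    likelihood on n >= 1.
    """
    if len(cells) == 0:
        raise PriorFitError("no cells to fit")
    if len(cells) < 50:
        warnings.warn(
            f"fitting the gamma-Poisson prior on only {len(cells)} cells; "
            "estimates may be unstable",
            stacklevel=2,
        )
    n = np.array([c.n for c in cells], dtype=float)
    E = np.array([c.E for c in cells], dtype=float)
    if np.any(E <= 0):
        raise ValueError("all cells must have E > 0")

    def unpack(theta: np.ndarray) -> tuple[float, float, float, float, float]:
        a1, b1, a2, b2 = np.exp(theta[:4])
        p = 1 / (1 + math.exp(-theta[4]))
        return a1, b1, a2, b2, p

    def neg(theta: np.ndarray) -> float:
        params = unpack(theta)
        with np.errstate(all="ignore"):
            ll = _mixture_loglik(params, n, E, truncated)
        return math.inf if not math.isfinite(ll) else -ll

    starts = list(starts) if starts is not None else [DEFAULT_PRIOR_START, *_EXTRA_STARTS]
    log_bound = math.log(1e5)
    bounds = [(-log_bound, log_bound)] * 4 + [(-12.0, 12.0)]
    best = None
    diagnostics = []
    for s in starts:
        theta0 = np.array([math.log(s[0]), math.log(s[1]), math.log(s[2]),
                           math.log(s[3]), math.log(s[4] / (1 - s[4]))])
        res = optimize.minimize(neg, theta0, method="L-BFGS-B", bounds=bounds)
        diagnostics.append((s, res.success, float(res.fun)))
        if math.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not math.isfinite(best.fun):
        raise PriorFitError("prior fit failed from every start", diagnostics)
    a1, b1, a2, b2, p = unpack(best.x)
    prior = GammaPoissonPrior(a1, b1, a2, b2, p, loglik=-float(best.fun)).canonical()
    start_ll = _mixture_loglik(DEFAULT_PRIOR_START, n, E, truncated)
    if prior.loglik < start_ll - 1e-6:
        raise PriorFitError(
            f"fitted likelihood {prior.loglik:.3f} below the default start "
            f"{start_ll:.3f}",
            diagnostics,
        )
    return prior


def ebgm(
    n: int, E: float, prior: GammaPoissonPrior
) -> tuple[float, float, float, PosteriorMixture]:
    """Posterior geometric mean and 5th/95th percentiles for one cell.

    Returns ``(ebgm, eb05, eb95, posterior)``. EBGM = exp(E[ln lambda | n])
    with E[ln lambda] evaluated through the digamma function on the conjugate
    posterior mixture.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    n_arr = np.array([float(n)])
    E_arr = np.array([float(E)])
    logw1 = math.log(prior.mix_p) + float(_log_nb(n_arr, prior.alpha1, prior.beta1, E_arr)[0])
    logw2 = math.log1p(-prior.mix_p) + float(
        _log_nb(n_arr, prior.alpha2, prior.beta2, E_arr)[0]
    )
    diff = logw2 - logw1
    if diff > 700:
        q = 0.0
    elif diff < -700:
        q = 1.0
    else:
        q = 1.0 / (1.0 + math.exp(diff))
    post = PosteriorMixture(
        q=q,
        shape1=prior.alpha1 + n,
        rate1=prior.beta1 + E,
        shape2=prior.alpha2 + n,
        rate2=prior.beta2 + E,
    )
    mean_log = q * (special.digamma(post.shape1) - math.log(post.rate1)) + (1 - q) * (
        special.digamma(post.shape2) - math.log(post.rate2)
    )
    return math.exp(mean_log), post.quantile(0.05), post.quantile(0.95), post


# ---------------------------------------------------------------------------
# signal records and classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds for the three standard signal rules.

    ror: n >= min_n and ROR CI lower bound > ror_ci_low;
    prr: PRR >= prr_min and chi2 >= chi2_min and n >= min_n;
    ebgm: EB05 > eb05_min.
    """

    min_n: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    eb05_min: float = 2.0


@dataclass(frozen=True)
class SignalRecord:
    drug: str
    event: str
    n: int
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    prr_ci: tuple[float, float]
    chi2: float
    ebgm: float
    eb05: float
    eb95: float
    flags: frozenset[str] = frozenset()


def classify_signal(record: SignalRecord, criteria: SignalCriteria = SignalCriteria()) -> frozenset[str]:
    """Apply the configured signal rules to a completed record."""
    flags = set()
    if record.n >= criteria.min_n and record.ror_ci[0] > criteria.ror_ci_low:
        flags.add("ror_signal")
    if (
        record.n >= criteria.min_n
        and record.prr >= criteria.prr_min
        and record.chi2 >= criteria.chi2_min
    ):
        flags.add("prr_signal")
    if record.n >= 1 and record.eb05 > criteria.eb05_min:
        flags.add("ebgm_signal")
    return frozenset(flags)


def signal_table(
    reports: Sequence[CaseReport],
    min_n: int = 3,
    criteria: SignalCriteria | None = None,
    prior: GammaPoissonPrior | None = None,
    roles: str = "all",
    stratified_cells_override: Sequence[CellExpectation] | None = None,
) -> list[SignalRecord]:
    """Full disproportionality table over all pairs with n >= min_n.

    The shrinker's prior is fitted on all cells with n >= 1 of this corpus
    unless a pre-fitted ``prior`` is supplied. ``stratified_cells_override``
    substitutes stratified (n, E) cells for the crude ones when computing the
    shrinkage metrics (expectations default to crude).
    """
    criteria = criteria or SignalCriteria(min_n=min_n)
    all_cells = build_cell_set(reports, min_n=1, roles=roles)
    if not all_cells:
        return []
    if prior is None:
        prior = fit_prior(all_cells)

    if stratified_cells_override is not None:
        cell_lookup = {(c.drug, c.event): c for c in stratified_cells_override}
    else:
        cell_lookup = {(c.drug, c.event): c for c in all_cells}

    # margins for 2x2 reconstruction
    exposures = report_exposures(reports, roles)
    n_reports = len(exposures)
    drug_margin: Counter = Counter()
    event_margin: Counter = Counter()
    for ds, es in exposures:
        drug_margin.update(ds)
        event_margin.update(es)

    records = []
    for cell in all_cells:
        if cell.n < min_n:
            continue
        a = cell.n
        b = drug_margin[cell.drug] - a
        c = event_margin[cell.event] - a
        d = n_reports - a - b - c
        table = ContingencyTable(a, b, c, d, drug=cell.drug, event=cell.event)
        ror_est, ror_lo, ror_hi = ror(table)
        prr_est, prr_lo, prr_hi = prr(table)
        try:
            chi2_val = chi_square(table)
        except UndefinedResultError:
            chi2_val = 0.0
        shrink_cell = cell_lookup.get((cell.drug, cell.event), cell)
        ebgm_val, eb05_val, eb95_val, _ = ebgm(shrink_cell.n, shrink_cell.E, prior)
        rec = SignalRecord(
            drug=cell.drug,
            event=cell.event,
            n=a,
            ror=ror_est,
            ror_ci=(ror_lo, ror_hi),
            prr=prr_est,
            prr_ci=(prr_lo, prr_hi),
            chi2=chi2_val,
            ebgm=ebgm_val,
            eb05=eb05_val,
            eb95=eb95_val,
        )
        records.append(replace(rec, flags=classify_signal(rec, criteria)))
    records.sort(key=lambda r: (-r.n, r.drug, r.event))
    return records


def signals_to_frame(records: Sequence[SignalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": r.drug,
                "event": r.event,
                "n": r.n,
                "ror": r.ror,
                "ror_ci_low": r.ror_ci[0],
                "ror_ci_high": r.ror_ci[1],
                "prr": r.prr,
                "prr_ci_low": r.prr_ci[0],
                "prr_ci_high": r.prr_ci[1],
                "chi2": r.chi2,
                "ebgm": r.ebgm,
                "eb05": r.eb05,
                "eb95": r.eb95,
                "flags": ";".join(sorted(r.flags)),
            }
            for r in records
        ],
        columns=[
            "drug", "event", "n", "ror", "ror_ci_low", "ror_ci_high",
            "prr", "prr_ci_low", "prr_ci_high", "chi2", "ebgm", "eb05",
            "eb95", "flags",
        ],
    )


def write_signals(records: Sequence[SignalRecord], path: str | Path) -> None:
    signals_to_frame(records).to_csv(path, index=False)
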