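"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's conjugate-posterior algebra: the
posterior of the relative reporting rate is handled as an unnormalized
density prior(lambda) * lambda^n * exp(-lambda E), integrated numerically.
"""

import math

import numpy as np
from scipy import integrate, optimize, stats


def posterior_moments_numeric(n, E, prior):
    """(ebgm, eb05, eb95) by brute-force integration of the posterior mixture."""

    def log_prior(lam):
        p1 = stats.gamma.logpdf(lam, a=prior.alpha1, scale=1 / prior.beta1)
        p2 = stats.gamma.logpdf(lam, a=prior.alpha2, scale=1 / prior.beta2)
        return np.logaddexp(math.log(prior.mix_p) + p1, math.log1p(-prior.mix_p) + p2)

    def log_g(u):
        # density of u = ln(lambda): prior(e^u) * e^(nu) * exp(-e^u E) * e^u;
        # the log substitution removes the lambda -> 0 singularity when a
        # gamma shape is below 1
        u = np.asarray(u, dtype=float)
        lam = np.exp(u)
        return log_prior(lam) + n * u - lam * E + u

    # the u-density left tail decays like exp(min(alpha) * u) when n = 0, so
    # the support must reach far into negative u before truncating
    grid = np.linspace(-600.0, 40.0, 64001)
    lg = np.where(np.isfinite(log_g(grid)), log_g(grid), -np.inf)
    k = float(np.max(lg))
    mode_u = float(grid[int(np.argmax(lg))])
    keep = np.flatnonzero(lg > k - 60.0)
    u_lo = float(grid[max(keep[0] - 1, 0)])
    u_hi = float(grid[min(keep[-1] + 1, len(grid) - 1)])

    def f(u):
        return math.exp(float(log_g(u)) - k)

    pts = [mode_u] if u_lo < mode_u < u_hi else []
    z, _ = integrate.quad(f, u_lo, u_hi, points=pts, limit=400)
    mean_log, _ = integrate.quad(lambda u: u * f(u), u_lo, u_hi, points=pts,
                                 limit=400)
    mean_log /= z

    def cdf_u(u):
        if u <= u_lo:
            return 0.0
        v, _ = integrate.quad(f, u_lo, min(u, u_hi), limit=400)
        return v / z

    def quantile(p):
        u = optimize.brentq(lambda x: cdf_u(x) - p, u_lo, u_hi,
                            xtol=1e-12, rtol=1e-14)
        return math.exp(u)

    return math.exp(mean_log), quantile(0.05), quantile(0.95)


def expand_table(a, b, c, d):
    """0/1 (exposure, outcome) rows realizing the 2x2 table."""
    x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    return x, y


def brute_force_cells(reports, roles="all"):
    """Pair counts by an exhaustive double loop over reports and pairs."""
    from cheilitis_pv.contingency import build_table, report_exposures

    drugs = set()
    events = set()
    for ds, es in report_exposures(reports, roles):
        drugs |= ds
        events |= es
    out = {}
    for dname in sorted(drugs):
        for ename in sorted(events):
            t = build_table(reports, dname, ename, roles=roles)
            if t.a > 0:
                out[(dname, ename)] = t
    return out
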