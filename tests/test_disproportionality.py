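import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cheilitis_pv.contingency import CellExpectation, ContingencyTable
from cheilitis_pv.disproportionality import (
    DEFAULT_PRIOR_START,
    GammaPoissonPrior,
    PriorFitError,
    SignalCriteria,
    SignalRecord,
    UndefinedResultError,
    chi_square,
    classify_signal,
    ebgm,
    fit_prior,
    prior_loglik,
    prr,
    ror,
    signal_table,
)

from _oracles import expand_table, posterior_moments_numeric

WORKED = ContingencyTable(10, 20, 30, 240)

positive_tables = st.tuples(
    st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50)
).map(lambda t: ContingencyTable(*t))


class TestRor:
    def test_symmetric_table_is_null(self):
        est, lo, hi = ror(ContingencyTable(5, 5, 5, 5))
        assert est == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_worked_closed_form(self):
        est, lo, hi = ror(WORKED)
        assert est == pytest.approx(4.0)
        # exp(ln4 - 1.96*sqrt(1/10+1/20+1/30+1/240)) — verified by hand
        assert lo == pytest.approx(1.7119, abs=1e-4)
        assert hi == pytest.approx(9.3463, abs=1e-4)

    def test_all_zero_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            ror(ContingencyTable(0, 0, 0, 0))

    def test_zero_a_gives_sentinel(self):
        est, lo, hi = ror(ContingencyTable(0, 10, 10, 100))
        assert est == 0.0

    def test_zero_b_applies_haldane(self):
        est, _, _ = ror(ContingencyTable(5, 0, 10, 100))
        assert est == pytest.approx((5.5 * 100.5) / (0.5 * 10.5))

    @given(positive_tables)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_transposition_invariance(self, t):
        assert ror(t)[0] == pytest.approx(ror(t.transpose())[0])

    @given(st.tuples(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30),
                     st.integers(1, 30)))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_haldane_changes_estimate_continuously(self, cells):
        t = ContingencyTable(*cells)
        plain = ror(t)[0]
        corrected = ror(t, haldane=True)[0]
        # correction shrinks the log-estimate toward 0 and stays finite
        assert 0 < corrected < math.inf
        big = ContingencyTable(*(c * 1000 for c in cells))
        assert ror(big)[0] == pytest.approx(ror(big, haldane=True)[0], rel=5e-3)

    def test_matches_logistic_fit(self):
        from cheilitis_pv.risk_model import fit_logistic

        x, y = expand_table(10, 20, 30, 240)
        fit = fit_logistic(x, y)
        assert math.exp(fit.beta[1]) == pytest.approx(4.0, rel=1e-6)


class TestPrr:
    def test_symmetric_table_is_null(self):
        assert prr(ContingencyTable(5, 5, 5, 5))[0] == pytest.approx(1.0)

    def test_worked_closed_form(self):
        assert prr(WORKED)[0] == pytest.approx(3.0)

    def test_undefined_when_drug_margin_empty(self):
        with pytest.raises(UndefinedResultError):
            prr(ContingencyTable(0, 0, 10, 10))

    @given(positive_tables)
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_prr_below_ror_when_positive(self, t):
        r, p = ror(t)[0], prr(t)[0]
        if r > 1:
            assert p <= r + 1e-12

    def test_not_transposition_invariant(self):
        t = ContingencyTable(10, 20, 30, 240)
        assert prr(t)[0] != pytest.approx(prr(t.transpose())[0])


class TestChiSquare:
    def test_independent_table_is_zero(self):
        assert chi_square(ContingencyTable(10, 90, 10, 90), yates=False) == pytest.approx(0.0)

    def test_worked_value(self):
        # N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 300*1800^2/(30*270*40*260)
        assert chi_square(WORKED, yates=False) == pytest.approx(11.538461538)

    def test_zero_margin_undefined(self):
        with pytest.raises(UndefinedResultError):
            chi_square(ContingencyTable(0, 0, 5, 5))

    @given(positive_tables)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_yates_never_exceeds_uncorrected(self, t):
        assert chi_square(t, yates=True) <= chi_square(t, yates=False) + 1e-9


def _simulate_cells(prior, n_cells, rng):
    comp = rng.random(n_cells) < prior.mix_p
    lam = np.where(
        comp,
        rng.gamma(prior.alpha1, 1 / prior.beta1, n_cells),
        rng.gamma(prior.alpha2, 1 / prior.beta2, n_cells),
    )
    E = rng.lognormal(0.5, 1.0, n_cells)
    n = rng.poisson(lam * E)
    return [
        CellExpectation(drug=f"d{i}", event="e", n=int(n[i]), E=float(E[i]))
        for i in range(n_cells)
    ]


class TestPriorFit:
    def test_loglik_beats_default_start(self):
        rng = np.random.default_rng(3)
        truth = GammaPoissonPrior(*DEFAULT_PRIOR_START)
        cells = _simulate_cells(truth, 800, rng)
        fitted = fit_prior(cells)
        assert fitted.loglik >= prior_loglik(GammaPoissonPrior(*DEFAULT_PRIOR_START), cells)

    def test_null_cells_concentrate_near_one(self):
        cells = [
            CellExpectation(drug=f"d{i}", event="e", n=200 + (i % 7) - 3, E=200.0)
            for i in range(200)
        ]
        fitted = fit_prior(cells)
        mean = (
            fitted.mix_p * fitted.alpha1 / fitted.beta1
            + (1 - fitted.mix_p) * fitted.alpha2 / fitted.beta2
        )
        assert 0.5 <= mean <= 2.0

    def test_few_cells_warns(self):
        cells = [CellExpectation(drug="d", event="e", n=2, E=1.0)] * 10
        with pytest.warns(UserWarning, match="10 cells"):
            fit_prior(cells)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            GammaPoissonPrior(-1, 1, 1, 1, 0.5)
        with pytest.raises(ValueError):
            GammaPoissonPrior(1, 1, 1, 1, 1.5)


PRIORS = [
    GammaPoissonPrior(0.2, 0.1, 2.0, 4.0, 1 / 3),
    GammaPoissonPrior(1.0, 1.0, 3.0, 1.5, 0.6),
    GammaPoissonPrior(0.5, 0.3, 5.0, 5.0, 0.1),
]


class TestEbgm:
    def test_degenerate_single_component(self):
        prior = GammaPoissonPrior(1.0, 1.0, 2.0, 4.0, 1 - 1e-9)
        g, lo, hi, post = ebgm(0, 1.0, prior)
        # posterior ~ Gamma(1, 2): E[ln lam] = psi(1) - ln 2
        assert g == pytest.approx(math.exp(-0.5772156649 - math.log(2)), rel=1e-6)
        assert lo == pytest.approx(-math.log(0.95) / 2, rel=1e-6)
        assert hi == pytest.approx(-math.log(0.05) / 2, rel=1e-6)

    @pytest.mark.parametrize("n", [0, 1, 10])
    @pytest.mark.parametrize("E", [0.5, 5.0])
    def test_quantile_ordering(self, n, E):
        for prior in PRIORS:
            g, lo, hi, _ = ebgm(n, E, prior)
            assert lo <= g <= hi

    def test_monotone_in_n(self):
        prior = PRIORS[0]
        values = [ebgm(n, 2.0, prior)[0] for n in range(0, 40, 3)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_large_count_shrinkage_vanishes(self):
        g, _, _, _ = ebgm(1000, 100.0, PRIORS[0])
        assert g == pytest.approx(10.0, rel=0.05)

    def test_spot_check_against_numeric_oracle(self):
        prior = PRIORS[1]
        g, lo, hi, _ = ebgm(3, 1.0, prior)
        og, olo, ohi = posterior_moments_numeric(3, 1.0, prior)
        assert g == pytest.approx(og, rel=1e-4)
        assert lo == pytest.approx(olo, rel=1e-4)
        assert hi == pytest.approx(ohi, rel=1e-4)

    def test_nonpositive_e_rejected(self):
        with pytest.raises(ValueError):
            ebgm(1, 0.0, PRIORS[0])


def _record(n=10, ror_lo=2.0, prr_val=5.0, chi2_val=20.0, eb05=3.0):
    return SignalRecord(
        drug="D", event="e", n=n, ror=ror_lo * 2, ror_ci=(ror_lo, ror_lo * 4),
        prr=prr_val, prr_ci=(prr_val / 2, prr_val * 2), chi2=chi2_val,
        ebgm=eb05 * 1.2, eb05=eb05, eb95=eb05 * 2,
    )


class TestClassifySignal:
    def test_fewer_than_three_cases_never_flags_ror(self):
        rec = _record(n=2, ror_lo=50.0)
        assert "ror_signal" not in classify_signal(rec)

    def test_null_table_has_no_flags(self):
        rec = _record(n=100, ror_lo=0.8, prr_val=1.0, chi2_val=0.0, eb05=0.9)
        assert classify_signal(rec) == frozenset()

    def test_default_thresholds(self):
        rec = _record(n=10, ror_lo=1.5, prr_val=2.5, chi2_val=5.0, eb05=2.5)
        assert classify_signal(rec) == {"ror_signal", "prr_signal", "ebgm_signal"}

    def test_thresholds_configurable(self):
        rec = _record(n=10, ror_lo=1.5, prr_val=2.5, chi2_val=5.0, eb05=2.5)
        strict = SignalCriteria(min_n=20, ror_ci_low=2.0, prr_min=5.0,
                                chi2_min=50.0, eb05_min=5.0)
        assert classify_signal(rec, strict) == frozenset()


def test_signal_table_flags_planted_pair(small_corpus):
    reports, truth = small_corpus
    records = signal_table(reports, min_n=3)
    planted = next(r for r in records if r.drug == "DRUG_001" and r.event == "cheilitis")
    assert planted.flags >= {"ror_signal", "prr_signal"}
    assert planted.n == truth.realized_pair_counts[("DRUG_001", "Cheilitis")]
    for rec in records:
        assert rec.ror_ci[0] <= rec.ror <= rec.ror_ci[1]
        assert rec.eb05 <= rec.ebgm <= rec.eb95
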