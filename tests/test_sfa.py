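"""Translog stochastic frontier: design, likelihood, LR tests."""

import numpy as np
import pytest

from ecoeff import sfa, synthetic
from ecoeff.errors import DomainError


def _sim_design(seed=0, **kw):
    panel, truth = synthetic.simulate_panel(n_regions=30, n_years=10, seed=seed, **kw)
    df = panel.data
    t = (df["year"] - df["year"].min() + 1).to_numpy()
    Xd = sfa.translog_design(df[["capital", "labour", "energy"]].to_numpy(), t)
    y = np.log(df["gdp"].to_numpy())
    return y, Xd, df["region"].to_numpy(), df["year"].to_numpy(), truth


def test_translog_unit_inputs_zero_columns():
    d = sfa.translog_design(np.array([[1.0, 1.0, 1.0]]), np.array([0.0]))
    assert d.shape == (1, 15)
    assert d.drop(columns="const").iloc[0].abs().sum() == 0


def test_translog_hand_evaluation():
    d = sfa.translog_design(np.array([[np.e, 1.0, 1.0]]), np.array([1.0])).iloc[0]
    assert d["lnx1"] == pytest.approx(1.0)
    assert d["lnx1_sq"] == pytest.approx(1.0)
    assert d["t_lnx1"] == pytest.approx(1.0)
    assert d["lnx1_lnx2"] == 0.0 and d["lnx2_lnx3"] == 0.0


def test_translog_rejects_nonpositive():
    with pytest.raises(DomainError):
        sfa.translog_design(np.array([[0.0, 1.0, 1.0]]), np.array([1.0]))


def test_fit_recovers_decay_direction_and_te_range():
    y, Xd, regions, years, truth = _sim_design(seed=1, mu=0.5, eta=0.4,
                                               sigma_u2=0.12, sigma_v2=0.08)
    fit = sfa.fit_frontier(y, Xd, regions, years, n_starts=1)
    assert fit.eta > 0
    assert abs(fit.eta - 0.4) < 0.2
    assert ((fit.te["te"] > 0) & (fit.te["te"] <= 1.0)).all()
    # efficiency trends upward on average when eta > 0
    by_year = fit.te.groupby("year")["te"].mean()
    assert by_year.iloc[-1] > by_year.iloc[0]


def test_gamma_identity():
    y, Xd, regions, years, _ = _sim_design(seed=2)
    fit = sfa.fit_frontier(y, Xd, regions, years, n_starts=1)
    assert 0.0 <= fit.gamma <= 1.0
    assert fit.gamma == pytest.approx(
        fit.sigma_u2 / (fit.sigma_u2 + fit.sigma_v2), abs=1e-9)


def test_eta_zero_fix_matches_time_invariant_model():
    y, Xd, regions, years, _ = _sim_design(seed=3, eta=0.0)
    fix_eta = sfa.fit_frontier(y, Xd, regions, years, fix={"eta": 0.0}, n_starts=1)
    # multi-start can only improve on a single start
    fix_eta2 = sfa.fit_frontier(y, Xd, regions, years, fix={"eta": 0.0}, n_starts=3)
    assert fix_eta2.loglik >= fix_eta.loglik - 1e-6
    # freeing eta on data generated with eta=0 cannot hurt the likelihood
    full = sfa.fit_frontier(y, Xd, regions, years, n_starts=3)
    assert full.loglik >= fix_eta2.loglik - 1e-4


def test_gamma_zero_fix_is_ols():
    y, Xd, regions, years, _ = _sim_design(seed=4)
    fit = sfa.fit_frontier(y, Xd, regions, years, fix={"gamma": 0.0})
    beta, *_ = np.linalg.lstsq(np.asarray(Xd), y, rcond=None)
    order = np.lexsort((years, regions))
    np.testing.assert_allclose(fit.beta.to_numpy(), beta, atol=1e-8)
    assert (fit.te["te"] == 1.0).all()


def test_lr_identical_models_and_nonnegativity():
    y, Xd, regions, years, _ = _sim_design(seed=5)
    fit = sfa.fit_frontier(y, Xd, regions, years, n_starts=1)
    res = sfa.lr_test(fit, fit, df=1, hypothesis="self")
    assert res.statistic == 0.0 and res.decision == "fail"


def test_lr_nesting_violation_detected():
    y, Xd, regions, years, _ = _sim_design(seed=6)
    fit = sfa.fit_frontier(y, Xd, regions, years, n_starts=1)
    better = sfa.SFAFit(beta=fit.beta, mu=fit.mu, eta=fit.eta, sigma2=fit.sigma2,
                        gamma=fit.gamma, loglik=fit.loglik + 100.0, te=fit.te,
                        model=fit.model)
    with pytest.raises(DomainError, match="nesting"):
        sfa.lr_test(fit, better, df=1)


def test_hypothesis_battery_on_cobb_douglas_truth():
    """Data generated from a Cobb-Douglas frontier: H1 (no second-order
    terms) should usually NOT be rejected, while H5 (no inefficiency)
    should be rejected when inefficiency is present."""
    y, Xd, regions, years, _ = _sim_design(seed=7, mu=0.5, eta=0.4,
                                           sigma_u2=0.3, sigma_v2=0.05)
    full = sfa.fit_frontier(y, Xd, regions, years, n_starts=3)
    results = {r.hypothesis: r
               for r in sfa.hypothesis_tests(y, Xd, regions, years,
                                             tests=("H1", "H5"), full=full,
                                             n_starts=1)}
    assert results["H1"].df == 10
    assert results["H5"].df == 3 and results["H5"].boundary
    assert results["H5"].statistic > 0
    assert all(r.statistic >= 0 for r in results.values())
    assert results["H5"].decision == "reject"


def test_boundary_mixture_pvalue_smaller_than_plain():
    a = sfa.lr_test.__wrapped__ if hasattr(sfa.lr_test, "__wrapped__") else sfa.lr_test
    full = sfa.SFAFit(beta=None, mu=0, eta=0, sigma2=1, gamma=0.5, loglik=5.0,
                      te=None, model="bc92")
    restr = sfa.SFAFit(beta=None, mu=0, eta=0, sigma2=1, gamma=0.0, loglik=3.0,
                       te=None, model="bc92")
    plain = a(full, restr, df=1).p
    mixed = a(full, restr, df=1, boundary=True).p
    assert mixed == pytest.approx(0.5 * plain)
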