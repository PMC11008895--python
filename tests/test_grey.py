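"""GM(1,1), posterior-variance grading, BP network, hybrid forecaster."""

import numpy as np
import pytest

from ecoeff import grey, synthetic
from ecoeff.errors import ConvergenceError, DegenerateInputError, DomainError


def test_ago_iago_identity():
    x = np.array([3.0, 1.0, 4.0, 1.5])
    np.testing.assert_allclose(grey.iago(grey.ago(x)), x)


def test_gm11_geometric_exactness():
    m = grey.fit_gm11([100.0, 90.0, 81.0, 72.9])
    assert np.exp(-m.a) == pytest.approx(0.9, abs=1e-8)
    assert np.abs(m.relative_errors_pct[1:]).max() < 1e-6
    assert m.fitted[0] == 100.0  # base-year convention


def test_gm11_constant_series_branch():
    m = grey.fit_gm11([5.0, 5.0, 5.0, 5.0])
    np.testing.assert_allclose(m.fitted, 5.0, atol=1e-9)
    assert m.degenerate


def test_gm11_roundtrips_generator():
    s = synthetic.simulate_grey_series(length=10, a=0.04, u=800.0, x1=2000.0)
    m = grey.fit_gm11(s)
    assert m.a == pytest.approx(0.04, abs=1e-8)
    assert m.u == pytest.approx(800.0, abs=1e-5)
    np.testing.assert_allclose(m.fitted, s, rtol=1e-9)


def test_gm11_rejects_bad_series():
    with pytest.raises(DomainError):
        grey.fit_gm11([1.0, 2.0, 3.0])       # too short
    with pytest.raises(DomainError):
        grey.fit_gm11([1.0, -2.0, 3.0, 4.0])  # nonpositive


def test_relative_errors_reported_cells():
    e, mae = grey.relative_errors([15783.0, 15292.0, 14962.0],
                                  [15783.0, 15792.0, 14675.0])
    assert e[0] == 0.0
    assert e[1] == pytest.approx(-3.27)
    assert e[2] == pytest.approx(1.92)
    assert mae == pytest.approx((3.27 + 1.92) / 2, abs=0.011)


def test_relative_errors_identical_series():
    e, mae = grey.relative_errors([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
    assert np.all(e == 0) and mae == 0.0


def test_relative_errors_zero_actual():
    with pytest.raises(DomainError):
        grey.relative_errors([0.0, 1.0], [1.0, 1.0])


@pytest.mark.parametrize("C,P,grade,label", [
    (0.30, 0.96, 1, "Good"),
    (0.66, 0.69, 4, "Unqualified"),
    (0.50, 0.75, 3, "Barely qualified"),   # fails grade-2 strict C bound
    (0.49, 0.81, 2, "Qualified"),
    (0.35, 0.96, 2, "Qualified"),          # C=0.35 fails grade-1 strict bound
])
def test_grade_bands(C, P, grade, label):
    g, lab = grey.grade_from_cp(C, P)
    assert (g, lab) == (grade, label)


def test_grade_function_total():
    rng = np.random.default_rng(0)
    for _ in range(200):
        g, _ = grey.grade_from_cp(rng.uniform(0, 1.2), rng.uniform(0, 1))
        assert g in (1, 2, 3, 4)


def test_posterior_diagnostics_good_fit():
    s = synthetic.simulate_grey_series(length=10, a=0.05, x1=1000.0,
                                       noise_sd=1.0, seed=2)
    d = grey.posterior_diagnostics(grey.fit_gm11(s))
    assert d.C == pytest.approx(d.s2 / d.s1)
    assert d.grade == 1


def test_posterior_diagnostics_degenerate():
    m = grey.fit_gm11([5.0, 5.0, 5.0, 5.0])
    with pytest.raises(DegenerateInputError):
        grey.posterior_diagnostics(m)


def test_bp_learns_linear_map():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 10, (40, 1))
    net = grey.train_bp(x, 3.0 * x + 1.0, grey.BPNetConfig(n_hidden=3))
    assert net.final_mse < 1e-3


def test_bp_seeded_determinism():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1, (10, 2))
    y = x.sum(axis=1, keepdims=True)
    cfg = grey.BPNetConfig(n_hidden=4, max_epochs=200, seed=3)
    n1, n2 = grey.train_bp(x, y, cfg), grey.train_bp(x, y, cfg)
    assert np.array_equal(n1.W1, n2.W1) and np.array_equal(n1.W2, n2.W2)
    assert np.array_equal(n1.b1, n2.b1) and np.array_equal(n1.b2, n2.b2)


def test_bp_input_validation():
    with pytest.raises(DomainError):
        grey.train_bp([[1.0]], [[1.0]])                       # one sample
    with pytest.raises(DegenerateInputError):
        grey.train_bp([[1.0], [1.0]], [[1.0], [2.0]])         # constant feature


def test_bp_divergence_reported():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 1, (20, 1))
    with pytest.raises(ConvergenceError, match="epoch"):
        grey.train_bp(x, 2 * x, grey.BPNetConfig(learning_rate=1e6, max_epochs=50))


def test_hybrid_null_correction_equals_gm():
    s = synthetic.simulate_grey_series(length=12, a=0.03, x1=1000.0)
    h = grey.grey_bp_hybrid(s, window=3)
    np.testing.assert_allclose(h.combined, h.gm.fitted)
    periods, gm_part, corr, combined = grey.forecast(h, 2)
    np.testing.assert_allclose(combined, gm_part)


def test_hybrid_combined_identity():
    s = synthetic.simulate_grey_series(length=12, a=0.03, x1=1000.0,
                                       noise_sd=4.0, seed=5)
    h = grey.grey_bp_hybrid(s, grey.BPNetConfig(seed=7), window=3)
    np.testing.assert_allclose(h.combined - h.gm.fitted, h.corrections, atol=1e-12)


def test_hybrid_beats_plain_gm_in_median():
    gm_mae, hy_mae = [], []
    for s in range(20):
        series = synthetic.simulate_grey_series(length=14, a=0.03, x1=1000.0,
                                                noise_sd=5.0, seed=s)
        h = grey.grey_bp_hybrid(series, grey.BPNetConfig(seed=s), window=3)
        gm_mae.append(np.mean(np.abs(h.gm.relative_errors_pct[1:])))
        hy_mae.append(np.mean(np.abs(h.relative_errors_pct[1:])))
    assert np.median(hy_mae) <= np.median(gm_mae)


def test_hybrid_window_too_large():
    s = synthetic.simulate_grey_series(length=6, a=0.03, x1=100.0)
    with pytest.raises(DomainError, match="window"):
        grey.grey_bp_hybrid(s, window=5)


def test_forecast_geometric_extrapolation():
    m = grey.fit_gm11([100.0, 90.0, 81.0, 72.9])
    _, _, _, combined = grey.forecast(m, 1)
    assert combined[0] == pytest.approx(65.61, abs=1e-4)


def test_forecast_zero_horizon_rejected():
    m = grey.fit_gm11([100.0, 90.0, 81.0, 72.9])
    with pytest.raises(DomainError):
        grey.forecast(m, 0)
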