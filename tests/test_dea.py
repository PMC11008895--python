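"""SBM / super-SBM efficiency scores and the multi-frontier comparison."""

import numpy as np
import pytest

from ecoeff import dea
from ecoeff.errors import DomainError
from oracles import oracle_scores, random_dmus


def _recompute_score(d, r):
    """Objective recomputed from the returned slacks (bad as reduction)."""
    m = d.x.size
    s = d.y_good.size + d.y_bad.size
    num = 1.0 - np.mean(r.input_slacks / d.x)
    den = 1.0 + (np.sum(r.good_output_slacks / d.y_good)
                 + np.sum(r.bad_output_slacks / d.y_bad if d.y_bad.size else 0.0)) / s
    return num / den


def test_identical_dmus_are_efficient():
    dmus = [dea.DMU("a", [1.0, 2.0], [3.0]), dea.DMU("b", [1.0, 2.0], [3.0])]
    for r in dea.sbm_efficiency(dmus):
        assert r.score == pytest.approx(1.0, abs=1e-9)
    for r in dea.super_sbm_efficiency(dmus):
        assert r.score == pytest.approx(1.0, abs=1e-9)


def test_single_slack_closed_form():
    dmus = [dea.DMU("A", [1.0], [1.0]), dea.DMU("B", [2.0], [1.0])]
    res = dea.sbm_efficiency(dmus)
    assert res[0].score == pytest.approx(1.0, abs=1e-9)
    assert res[1].score == pytest.approx(0.5, abs=1e-9)  # 1 - s/x = 1 - 1/2
    sup = dea.super_sbm_efficiency(dmus)
    assert sup[0].score > 1.0
    assert sup[1].score == pytest.approx(0.5, abs=1e-9)


def test_score_self_consistency_with_slacks():
    rng = np.random.default_rng(0)
    dmus = random_dmus(rng, 5, m=2, s1=1, s2=1)
    for d, r in zip(dmus, dea.sbm_efficiency(dmus)):
        assert _recompute_score(d, r) == pytest.approx(r.score, abs=1e-9)


def test_lambdas_sum_to_one():
    rng = np.random.default_rng(1)
    dmus = random_dmus(rng, 5)
    for r in dea.sbm_efficiency(dmus):
        assert sum(r.lambdas.values()) == pytest.approx(1.0, abs=1e-7)


@pytest.mark.parametrize("s2", [0, 1])
def test_units_invariance(s2):
    rng = np.random.default_rng(2)
    dmus = random_dmus(rng, 5, m=2, s1=1, s2=s2)
    base = [r.score for r in dea.super_sbm_efficiency(dmus)]
    scaled = [dea.DMU(d.id, d.x * np.array([1000.0, 0.01]), d.y_good * 7.0,
                      d.y_bad * 3.0 if s2 else d.y_bad) for d in dmus]
    rescored = [r.score for r in dea.super_sbm_efficiency(scaled)]
    np.testing.assert_allclose(base, rescored, atol=1e-7)


def test_monotonicity_dominance():
    rng = np.random.default_rng(3)
    dmus = random_dmus(rng, 5, m=2, s1=1, s2=0)
    base = dea.sbm_efficiency(dmus)[0].score
    better = [dea.DMU(dmus[0].id, dmus[0].x * 0.9, dmus[0].y_good * 1.1,
                      dmus[0].y_bad)] + dmus[1:]
    improved = dea.sbm_efficiency(better)[0].score
    assert improved >= base - 1e-9


def test_nonpositive_data_rejected():
    with pytest.raises(DomainError):
        dea.DMU("bad", [0.0], [1.0])


def test_bad_output_as_input_mode_runs():
    rng = np.random.default_rng(4)
    dmus = random_dmus(rng, 4, m=2, s1=1, s2=1)
    out_mode = [r.score for r in dea.sbm_efficiency(dmus, bad_output_mode="as-output")]
    in_mode = [r.score for r in dea.sbm_efficiency(dmus, bad_output_mode="as-input")]
    assert all(0 < s <= 1 + 1e-9 for s in out_mode + in_mode)


def test_oracle_equivalence_small_instances():
    rng = np.random.default_rng(5)
    for _ in range(4):
        dmus = random_dmus(rng, int(rng.integers(3, 7)), m=2, s1=1, s2=1)
        impl = [r.score for r in dea.super_sbm_efficiency(dmus)]
        orac = oracle_scores(dmus, mode="super")
        np.testing.assert_allclose(impl, orac, atol=1e-6)


def test_frontier_distances_identical_technology():
    base = [dea.DMU(f"d{i}", [float(i + 1)], [float(i + 1)]) for i in range(3)]
    dmus, years = [], []
    for year in (2012, 2013):
        for d in base:
            dmus.append(dea.DMU(f"{d.id}:{year}", d.x, d.y_good))
            years.append(year)
    fd = dea.frontier_distances(dmus, years)
    np.testing.assert_allclose(fd["Dt"], fd["Do"], atol=1e-9)
    np.testing.assert_allclose(fd["Dt"], fd["Dg"], atol=1e-9)


def test_frontier_distances_nesting_and_expansion():
    # year-2 frontier strictly dominates year-1: year-1 units lose under Dg
    dmus = [
        dea.DMU("a:1", [2.0], [1.0]), dea.DMU("b:1", [3.0], [1.0]),
        dea.DMU("a:2", [1.0], [2.0]), dea.DMU("b:2", [1.5], [2.0]),
    ]
    years = [1, 1, 2, 2]
    fd = dea.frontier_distances(dmus, years).set_index("year")
    assert (fd["Dg"] <= fd["Do"] + 1e-9).all()
    assert (fd["Do"] <= fd["Dt"] + 1e-9).all()
    assert fd.loc[1, "Dg"] < fd.loc[1, "Dt"]


def test_frontier_distances_global_dominator():
    dmus = [
        dea.DMU("top:1", [1.0], [5.0]), dea.DMU("x:1", [2.0], [1.0]),
        dea.DMU("top:2", [1.0], [5.0]), dea.DMU("y:2", [3.0], [1.0]),
    ]
    fd = dea.frontier_distances(dmus, [1, 1, 2, 2])
    # the dominating unit is globally efficient, so it scores 1 in each year
    res = dea.sbm_efficiency([dmus[0]], reference=dmus)
    assert res[0].score == pytest.approx(1.0, abs=1e-9)


def test_frontier_distances_flags_thin_years():
    dmus = [dea.DMU("a:1", [1.0], [1.0]), dea.DMU("b:1", [2.0], [1.0]),
            dea.DMU("a:2", [1.0], [1.0])]
    fd = dea.frontier_distances(dmus, [1, 1, 2]).set_index("year")
    assert fd.loc[2, "flag"].startswith("skipped")
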