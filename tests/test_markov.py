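"""State discretization and (spatial) Markov transition matrices."""

import numpy as np
import pandas as pd
import pytest

from ecoeff import markov
from ecoeff.errors import DegenerateInputError, DomainError, IntegrityError


def _panel(regions, years, values):
    return pd.DataFrame({"region": regions, "year": years, "value": values})


def test_discretize_quartiles_of_1_to_8():
    df = _panel([f"r{i}" for i in range(8)], [2000] * 8,
                [1.0, 2, 3, 4, 5, 6, 7, 8])
    sp = markov.discretize_states(df, k=4)
    assert sp.data.sort_values("region")["state"].tolist() == [1, 1, 2, 2, 3, 3, 4, 4]


def test_discretize_degenerate_values():
    df = _panel(list("abcd"), [2000] * 4, [3.0] * 4)
    with pytest.raises(DegenerateInputError):
        markov.discretize_states(df, k=4)


def test_discretize_per_year_rank_invariance():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=8)
    df = _panel(list("abcdefgh"), [2000] * 8, vals)
    sp1 = markov.discretize_states(df, k=4, mode="per-year")
    # monotone transform preserves per-year ranks, hence states
    df2 = df.assign(value=np.exp(df["value"]))
    sp2 = markov.discretize_states(df2, k=4, mode="per-year")
    pd.testing.assert_frame_equal(sp1.data, sp2.data)


def test_transition_constant_state():
    sp = markov.StatePanel(
        data=pd.DataFrame({"region": ["r"] * 3, "year": [1, 2, 3], "state": [1, 1, 1]}),
        k=4)
    tm = markov.transition_matrix(sp)
    assert tm.probs[0, 0] == 1.0
    assert np.isnan(tm.probs[1]).all()  # unobserved rows undefined, not zero


def test_transition_alternating():
    sp = markov.StatePanel(
        data=pd.DataFrame({"region": ["r"] * 4, "year": [1, 2, 3, 4],
                           "state": [1, 2, 1, 2]}), k=2)
    tm = markov.transition_matrix(sp)
    assert tm.probs[0, 1] == 1.0 and tm.probs[1, 0] == 1.0
    assert tm.counts.sum() == 3


def test_observed_rows_are_stochastic():
    rng = np.random.default_rng(1)
    df = _panel(np.repeat(list("abcde"), 6), np.tile(range(6), 5),
                rng.normal(size=30))
    sp = markov.discretize_states(df, k=4)
    tm = markov.transition_matrix(sp)
    for r in tm.observed_rows():
        assert tm.probs[r].sum() == pytest.approx(1.0, abs=1e-12)


def test_region_relabeling_invariance():
    rng = np.random.default_rng(2)
    df = _panel(np.repeat(list("abcd"), 5), np.tile(range(5), 4),
                rng.normal(size=20))
    sp = markov.discretize_states(df, k=3)
    base = markov.transition_matrix(sp)
    relabeled = sp.data.assign(region=sp.data["region"].map(
        {"a": "z", "b": "y", "c": "x", "d": "w"}))
    other = markov.transition_matrix(markov.StatePanel(relabeled, k=3))
    np.testing.assert_array_equal(base.counts, other.counts)


def test_spatial_transitions_single_lag_class_degenerates():
    sp = markov.StatePanel(
        data=pd.DataFrame({"region": ["r", "r", "s", "s"], "year": [1, 2, 1, 2],
                           "state": [1, 2, 2, 1]}), k=2)
    lag = markov.StatePanel(
        data=pd.DataFrame({"region": ["r", "r", "s", "s"], "year": [1, 2, 1, 2],
                           "state": [1, 1, 1, 1]}), k=2)
    spt = markov.spatial_transition_matrices(sp, lag)
    ordinary = markov.transition_matrix(sp)
    np.testing.assert_array_equal(spt.by_lag_state[1].counts, ordinary.counts)
    assert spt.by_lag_state[2].counts.sum() == 0


def test_spatial_transitions_hand_enumeration():
    # two regions, 3 years; transitions stratified by hand-assigned lag states
    sp = markov.StatePanel(
        data=pd.DataFrame({"region": ["a", "a", "a", "b", "b", "b"],
                           "year": [1, 2, 3, 1, 2, 3],
                           "state": [1, 2, 2, 2, 1, 2]}), k=2)
    lag = markov.StatePanel(
        data=pd.DataFrame({"region": ["a", "a", "a", "b", "b", "b"],
                           "year": [1, 2, 3, 1, 2, 3],
                           "state": [2, 1, 1, 1, 2, 2]}), k=2)
    spt = markov.spatial_transition_matrices(sp, lag)
    # lag-1 origins: (a,2):2->2 and (b,1):2->1
    np.testing.assert_array_equal(spt.by_lag_state[1].counts,
                                  [[0, 0], [1, 1]])
    # lag-2 origins: (a,1):1->2 and (b,2):1->2
    np.testing.assert_array_equal(spt.by_lag_state[2].counts,
                                  [[0, 2], [0, 0]])


def test_spatial_transitions_count_conservation():
    rng = np.random.default_rng(3)
    df = _panel(np.repeat([f"r{i}" for i in range(6)], 8),
                np.tile(range(8), 6), rng.normal(size=48))
    sp = markov.discretize_states(df, k=4)
    lag_df = df.assign(value=rng.normal(size=48))
    lag = markov.discretize_states(lag_df, k=4)
    spt = markov.spatial_transition_matrices(sp, lag)
    np.testing.assert_array_equal(spt.total_counts(),
                                  markov.transition_matrix(sp).counts)


def test_spatial_transitions_key_mismatch():
    sp = markov.StatePanel(
        data=pd.DataFrame({"region": ["a", "a"], "year": [1, 2], "state": [1, 2]}),
        k=2)
    lag = markov.StatePanel(
        data=pd.DataFrame({"region": ["b", "b"], "year": [1, 2], "state": [1, 1]}),
        k=2)
    with pytest.raises(IntegrityError):
        markov.spatial_transition_matrices(sp, lag)


def test_bad_k():
    df = _panel(list("ab"), [1, 1], [1.0, 2.0])
    with pytest.raises(DomainError):
        markov.discretize_states(df, k=1)
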