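"""Efficiency-state discretization, Markov transition matrices, and
spatial-lag-conditioned (spatial Markov) transition matrices.

Region-year scores are binned into k ordered states (quartiles by default,
state 1 = lowest). The ordinary transition matrix counts one transition per
region per consecutive year pair; the spatial variant stratifies those
transitions by the state of the region's spatial lag (neighbourhood
average) in the origin year, revealing whether neighbours' performance
shifts a region's own transition odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DomainError, IntegrityError

__all__ = [
    "StatePanel",
    "TransitionMatrix",
    "discretize_states",
    "transition_matrix",
    "spatial_transition_matrices",
]


@dataclass
class StatePanel:
    """(region, year, state) assignments, state in 1..k."""

    data: pd.DataFrame  # columns: region, year, state
    k: int
    bins: np.ndarray | None = None  # interior quantile edges when pooled


@dataclass
class TransitionMatrix:
    k: int
    counts: np.ndarray
    probs: np.ndarray  # rows with no observations are NaN, not zero
    n_row: np.ndarray

    def observed_rows(self) -> np.ndarray:
        return np.nonzero(self.n_row > 0)[0]


def _bin(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Quantile binning; boundary values go to the LOWER state (side='left'
    puts v == edge at that edge's index, i.e. the lower bin)."""
    return np.searchsorted(edges, values, side="left") + 1


def discretize_states(
    values: pd.DataFrame,
    k: int = 4,
    mode: str = "pooled",
    value_col: str = "value",
    region_col: str = "region",
    year_col: str = "year",
) -> StatePanel:
    """Assign each (region, year) value to one of k quantile states.

    mode="pooled" computes one set of quantile edges from all values;
    mode="per-year" recomputes edges within each year, making states a
    function of that year's ranks only.
    """
    if k < 2:
        raise DomainError("need k >= 2 states")
    df = values[[region_col, year_col, value_col]].dropna().copy()
    v = df[value_col].to_numpy(dtype=float)
    if np.unique(v).size < k:
        raise DegenerateInputError(
            f"only {np.unique(v).size} distinct values for {k} quantile bins"
        )
    qs = np.arange(1, k) / k
    if mode == "pooled":
        edges = np.quantile(v, qs)
        df["state"] = _bin(v, edges)
    elif mode == "per-year":
        edges = None
        states = np.empty(len(df), dtype=int)
        for year, grp in df.groupby(year_col):
            gv = grp[value_col].to_numpy(dtype=float)
            if np.unique(gv).size < 2:
                raise DegenerateInputError(f"year {year} has degenerate values")
            states[df[year_col].to_numpy() == year] = _bin(gv, np.quantile(gv, qs))
        df["state"] = states
    else:
        raise DomainError(f"unknown mode {mode!r}")
    out = df.rename(columns={region_col: "region", year_col: "year"})
    return StatePanel(data=out[["region", "year", "state"]], k=k,
                      bins=edges if mode == "pooled" else None)


def _pairs(states: StatePanel) -> pd.DataFrame:
    """All consecutive (t, t+1) state pairs within regions."""
    df = states.data.sort_values(["region", "year"])
    nxt = df.groupby("region")[["year", "state"]].shift(-1)
    pairs = df.assign(year_next=nxt["year"], state_next=nxt["state"]).dropna()
    pairs = pairs[pairs["year_next"] == pairs["year"] + 1]
    return pairs.astype({"state_next": int, "year_next": int})


def transition_matrix(states: StatePanel) -> TransitionMatrix:
    k = states.k
    pairs = _pairs(states)
    if pairs.empty:
        raise DegenerateInputError("no consecutive-year transitions in panel")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (pairs["state"].to_numpy() - 1, pairs["state_next"].to_numpy() - 1), 1)
    n_row = counts.sum(axis=1)
    probs = np.full((k, k), np.nan)
    obs = n_row > 0
    probs[obs] = counts[obs] / n_row[obs, None]
    return TransitionMatrix(k=k, counts=counts, probs=probs, n_row=n_row)


@dataclass
class SpatialTransitionSet:
    k: int
    by_lag_state: dict = field(default_factory=dict)  # lag state -> TransitionMatrix

    def total_counts(self) -> np.ndarray:
        return sum(tm.counts for tm in self.by_lag_state.values())


def spatial_transition_matrices(
    states: StatePanel, lag_states: StatePanel
) -> SpatialTransitionSet:
    """Transition matrices stratified by the origin-year lag state.

    ``lag_states`` must be the spatial lag of the same underlying values,
    discretized with the same k; its keys must cover every origin
    (region, year) of a transition.
    """
    if states.k != lag_states.k:
        raise DomainError("states and lag_states use different k")
    pairs = _pairs(states)
    if pairs.empty:
        raise DegenerateInputError("no consecutive-year transitions in panel")
    lag = lag_states.data.rename(columns={"state": "lag_state"})
    merged = pairs.merge(lag, on=["region", "year"], how="left")
    if merged["lag_state"].isna().any():
        missing = merged.loc[merged["lag_state"].isna(), ["region", "year"]]
        raise IntegrityError(
            f"lag states missing for origins: {missing.to_records(index=False).tolist()}"
        )
    k = states.k
    out = SpatialTransitionSet(k=k)
    for cls in range(1, k + 1):
        sub = merged[merged["lag_state"] == cls]
        counts = np.zeros((k, k), dtype=int)
        if not sub.empty:
            np.add.at(
                counts,
                (sub["state"].to_numpy() - 1, sub["state_next"].to_numpy() - 1),
                1,
            )
        n_row = counts.sum(axis=1)
        probs = np.full((k, k), np.nan)
        obs = n_row > 0
        probs[obs] = counts[obs] / n_row[obs, None]
        out.by_lag_state[cls] = TransitionMatrix(k=k, counts=counts, probs=probs,
                                                 n_row=n_row)
    return out
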