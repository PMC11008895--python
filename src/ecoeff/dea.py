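"""Slack-based measure (SBM) DEA with an undesirable output, super-efficiency
scores, and contemporaneous / sequential / global frontier comparisons.

The SBM score of a decision-making unit (DMU) with inputs x0, desirable
outputs yg0 and undesirable outputs yb0 against a variable-returns-to-scale
(VRS) technology spanned by peers is

    rho = (1 - (1/m) sum_i s_i^- / x_i0)
          / (1 + 1/(s1+s2) (sum_r s_r^+ / yg_r0 + sum_b s_b^b / yb_r0))

minimized over nonnegative slacks and convex peer weights lambda with
sum(lambda) = 1. Undesirable outputs contribute reduction slacks (they are
"too much" in the same sense inputs are). rho lies in (0, 1] and equals 1
iff every slack is zero. The fractional program is solved exactly as an LP
through the Charnes-Cooper change of variables.

Super-efficiency excludes the evaluated DMU from its own reference set and
measures the distance from the DMU to the frontier of the remaining peers;
efficient units then receive scores >= 1 that rank them strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import DomainError
from .panel import PanelDataset

__all__ = [
    "DMU",
    "DEAResult",
    "dmus_from_panel",
    "sbm_efficiency",
    "super_sbm_efficiency",
    "frontier_distances",
]

_T_FLOOR = 1e-9  # lower bound keeping the Charnes-Cooper scale variable positive


@dataclass
class DMU:
    """One decision-making unit (a region-year observation)."""

    id: str
    x: np.ndarray
    y_good: np.ndarray
    y_bad: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y_good = np.atleast_1d(np.asarray(self.y_good, dtype=float))
        self.y_bad = np.atleast_1d(np.asarray(self.y_bad, dtype=float))
        for name, v in (("input", self.x), ("desirable output", self.y_good),
                        ("undesirable output", self.y_bad)):
            if v.size and (v <= 0).any():
                raise DomainError(f"nonpositive {name} in DMU {self.id!r}: {v}")


@dataclass
class DEAResult:
    id: str
    score: float | None
    input_slacks: np.ndarray | None = None
    good_output_slacks: np.ndarray | None = None
    bad_output_slacks: np.ndarray | None = None
    lambdas: dict = field(default_factory=dict)
    status: str = "optimal"


def dmus_from_panel(panel: PanelDataset, bad_output: bool = True) -> list:
    """One DMU per panel row; id is ``region:year``."""
    sch = panel.schema
    out = []
    for _, row in panel.data.iterrows():
        out.append(
            DMU(
                id=f"{row[sch.region]}:{row[sch.year]}",
                x=row[sch.inputs].to_numpy(dtype=float),
                y_good=np.array([float(row[sch.output])]),
                y_bad=np.array([float(row[sch.bad_output])])
                if bad_output and sch.bad_output
                else np.empty(0),
            )
        )
    return out


def _stack(dmus, bad_output_mode):
    """Matrices (m x K inputs, s1 x K good, s2 x K bad); in 'as-input' mode
    bad outputs are folded into the input block."""
    X = np.column_stack([d.x for d in dmus])
    Yg = np.column_stack([d.y_good for d in dmus])
    nb = dmus[0].y_bad.size
    Yb = (
        np.column_stack([d.y_bad for d in dmus]) if nb else np.empty((0, len(dmus)))
    )
    if bad_output_mode == "as-input" and nb:
        X = np.vstack([X, Yb])
        Yb = np.empty((0, len(dmus)))
    elif bad_output_mode not in ("as-output", "as-input"):
        raise DomainError(f"unknown bad_output_mode {bad_output_mode!r}")
    return X, Yg, Yb


def _check_dims(dmus):
    m, s1, s2 = dmus[0].x.size, dmus[0].y_good.size, dmus[0].y_bad.size
    for d in dmus:
        if (d.x.size, d.y_good.size, d.y_bad.size) != (m, s1, s2):
            raise DomainError(f"inconsistent dimensions at DMU {d.id!r}")


def _sbm_score_lp(x0, yg0, yb0, X, Yg, Yb, ref_ids, max_slack_stage=True):
    """Charnes-Cooper linearized SBM against an explicit reference technology
    (which must be able to reproduce the evaluated point, i.e. contain it).

    Variables: [t, Lambda_k (K), S^-_i (m), Sg_r (s1), Sb_r (s2)].
    Returns (score, slacks..., lambdas, status).
    """
    m, s1, s2 = x0.size, yg0.size, yb0.size
    K = X.shape[1]
    nvar = 1 + K + m + s1 + s2
    iT = 0
    iL = slice(1, 1 + K)
    iSm = slice(1 + K, 1 + K + m)
    iSg = slice(1 + K + m, 1 + K + m + s1)
    iSb = slice(1 + K + m + s1, nvar)

    c = np.zeros(nvar)
    c[iT] = 1.0
    c[iSm] = -1.0 / (m * x0)

    A_eq = []
    b_eq = []
    # normalization: t + (1/(s1+s2)) (sum Sg/yg0 + sum Sb/yb0) = 1
    row = np.zeros(nvar)
    row[iT] = 1.0
    denom = s1 + s2
    row[iSg] = 1.0 / (denom * yg0)
    if s2:
        row[iSb] = 1.0 / (denom * yb0)
    A_eq.append(row)
    b_eq.append(1.0)
    # x0 t - X Lambda - S^- = 0
    for i in range(m):
        row = np.zeros(nvar)
        row[iT] = x0[i]
        row[iL] = -X[i]
        row[1 + K + i] = -1.0
        A_eq.append(row)
        b_eq.append(0.0)
    # yg0 t - Yg Lambda + Sg = 0
    for r in range(s1):
        row = np.zeros(nvar)
        row[iT] = yg0[r]
        row[iL] = -Yg[r]
        row[1 + K + m + r] = 1.0
        A_eq.append(row)
        b_eq.append(0.0)
    # yb0 t - Yb Lambda - Sb = 0
    for r in range(s2):
        row = np.zeros(nvar)
        row[iT] = yb0[r]
        row[iL] = -Yb[r]
        row[1 + K + m + s1 + r] = -1.0
        A_eq.append(row)
        b_eq.append(0.0)
    # VRS: sum Lambda = t
    row = np.zeros(nvar)
    row[iT] = -1.0
    row[iL] = 1.0
    A_eq.append(row)
    b_eq.append(0.0)

    bounds = [(_T_FLOOR, None)] + [(0, None)] * (nvar - 1)
    res = linprog(c, A_eq=np.array(A_eq), b_eq=np.array(b_eq), bounds=bounds,
                  method="highs")
    if not res.success:
        return None, None, None, None, {}, f"infeasible ({res.status})"
    score = float(res.fun)

    sol = res.x
    if max_slack_stage:
        # lexicographic second stage: among optima, maximize total slack
        c2 = np.zeros(nvar)
        c2[iSm] = -1.0
        c2[iSg] = -1.0
        c2[iSb] = -1.0
        A2 = np.vstack([np.array(A_eq), c[None, :]])
        b2 = np.append(np.array(b_eq), score)
        res2 = linprog(c2, A_eq=A2, b_eq=b2, bounds=bounds, method="highs")
        if res2.success:
            sol = res2.x

    t = sol[iT]
    lam = sol[iL] / t
    lambdas = {ref_ids[k]: float(lam[k]) for k in range(K) if lam[k] > 1e-9}
    return (
        score,
        sol[iSm] / t,
        sol[iSg] / t,
        sol[iSb] / t,
        lambdas,
        "optimal",
    )


def sbm_efficiency(dmus, returns: str = "VRS", bad_output_mode: str = "as-output",
                   reference=None) -> list:
    """Plain SBM scores for every DMU.

    ``reference`` optionally restricts the technology to a sub-list of DMUs
    (used by the frontier comparisons); it must contain each evaluated DMU.
    Only VRS is exposed because the convexity constraint is part of the
    model under study; requesting CRS raises.
    """
    if returns.upper() != "VRS":
        raise DomainError("only VRS (sum lambda = 1) technologies are supported")
    ref = list(reference) if reference is not None else list(dmus)
    if len(ref) < 2:
        raise DomainError("need at least 2 DMUs in the reference technology")
    _check_dims(dmus + ref)
    X, Yg, Yb = _stack(ref, bad_output_mode)
    ref_ids = [d.id for d in ref]
    results = []
    for d in dmus:
        x0, yg0, yb0 = _point(d, bad_output_mode)
        score, sm, sg, sb, lambdas, status = _sbm_score_lp(
            x0, yg0, yb0, X, Yg, Yb, ref_ids
        )
        results.append(
            DEAResult(id=d.id, score=score, input_slacks=sm, good_output_slacks=sg,
                      bad_output_slacks=sb, lambdas=lambdas, status=status)
        )
    return results


def _point(d, bad_output_mode):
    if bad_output_mode == "as-input" and d.y_bad.size:
        return np.concatenate([d.x, d.y_bad]), d.y_good, np.empty(0)
    return d.x, d.y_good, d.y_bad


def _super_score_lp(x0, yg0, yb0, X, Yg, Yb, ref_ids):
    """Super-SBM distance from (x0, yg0, yb0) to the frontier of the peers.

    min  (1/(m+s2)) (sum Xbar_i/x_i0 + sum Ybbar_r/yb_r0)
    s.t. (1/s1) sum Ygbar_r/yg_r0 = 1
         Xbar >= X Lambda,  Ygbar <= Yg Lambda,  Ybbar >= Yb Lambda
         Xbar >= t x0,      Ygbar <= t yg0,      Ybbar >= t yb0
         sum Lambda = t,    all variables >= 0, t > 0

    (after Charnes-Cooper scaling; undesirable outputs are expanded like
    inputs because a frontier point may emit more carbon than the evaluated
    efficient unit). The optimum is >= 1.
    """
    m, s1, s2 = x0.size, yg0.size, yb0.size
    K = X.shape[1]
    if K == 0:
        raise DomainError("reference set empty after excluding the evaluated DMU")
    nvar = 1 + K + m + s1 + s2
    iT = 0
    iL = slice(1, 1 + K)
    iX = slice(1 + K, 1 + K + m)
    iYg = slice(1 + K + m, 1 + K + m + s1)
    iYb = slice(1 + K + m + s1, nvar)

    c = np.zeros(nvar)
    c[iX] = 1.0 / ((m + s2) * x0)
    if s2:
        c[iYb] = 1.0 / ((m + s2) * yb0)

    A_eq, b_eq = [], []
    row = np.zeros(nvar)
    row[iYg] = 1.0 / (s1 * yg0)
    A_eq.append(row)
    b_eq.append(1.0)
    row = np.zeros(nvar)
    row[iT] = -1.0
    row[iL] = 1.0
    A_eq.append(row)
    b_eq.append(0.0)

    A_ub, b_ub = [], []  # rows as <= 0
    for i in range(m):  # X Lambda - Xbar <= 0
        row = np.zeros(nvar)
        row[iL] = X[i]
        row[1 + K + i] = -1.0
        A_ub.append(row)
        b_ub.append(0.0)
    for i in range(m):  # t x0 - Xbar <= 0
        row = np.zeros(nvar)
        row[iT] = x0[i]
        row[1 + K + i] = -1.0
        A_ub.append(row)
        b_ub.append(0.0)
    for r in range(s1):  # Ygbar - Yg Lambda <= 0
        row = np.zeros(nvar)
        row[1 + K + m + r] = 1.0
        row[iL] = -Yg[r]
        A_ub.append(row)
        b_ub.append(0.0)
    for r in range(s1):  # Ygbar - t yg0 <= 0
        row = np.zeros(nvar)
        row[1 + K + m + r] = 1.0
        row[iT] = -yg0[r]
        A_ub.append(row)
        b_ub.append(0.0)
    for r in range(s2):  # Yb Lambda - Ybbar <= 0
        row = np.zeros(nvar)
        row[iL] = Yb[r]
        row[1 + K + m + s1 + r] = -1.0
        A_ub.append(row)
        b_ub.append(0.0)
    for r in range(s2):  # t yb0 - Ybbar <= 0
        row = np.zeros(nvar)
        row[iT] = yb0[r]
        row[1 + K + m + s1 + r] = -1.0
        A_ub.append(row)
        b_ub.append(0.0)

    bounds = [(_T_FLOOR, None)] + [(0, None)] * (nvar - 1)
    res = linprog(c, A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds,
                  method="highs")
    if not res.success:
        return None, {}, f"infeasible ({res.status})"
    t = res.x[iT]
    lam = res.x[iL] / t
    lambdas = {ref_ids[k]: float(lam[k]) for k in range(K) if lam[k] > 1e-9}
    return float(res.fun), lambdas, "optimal"


def super_sbm_efficiency(dmus, returns: str = "VRS",
                         bad_output_mode: str = "as-output") -> list:
    """Super-efficiency SBM: SBM-inefficient units keep their plain score in
    (0, 1); SBM-efficient units are re-scored against the frontier of the
    remaining peers and receive scores >= 1."""
    plain = sbm_efficiency(dmus, returns=returns, bad_output_mode=bad_output_mode)
    results = []
    for j, (d, base) in enumerate(zip(dmus, plain)):
        if base.score is None or base.score < 1.0 - 1e-7:
            results.append(base)
            continue
        others = [e for k, e in enumerate(dmus) if k != j]
        if not others:
            raise DomainError("reference set empty after excluding the evaluated DMU")
        X, Yg, Yb = _stack(others, bad_output_mode)
        x0, yg0, yb0 = _point(d, bad_output_mode)
        score, lambdas, status = _super_score_lp(
            x0, yg0, yb0, X, Yg, Yb, [e.id for e in others]
        )
        results.append(DEAResult(id=d.id, score=score, lambdas=lambdas, status=status))
    return results


def frontier_distances(dmus, years) -> pd.DataFrame:
    """Mean SBM scores per year against three nested frontiers.

    Dt: contemporaneous (peers of the same year); Do: sequential
    (peers of all years <= t); Dg: global (all peers, pooled). Because the
    reference technologies nest, Dg <= Do <= Dt holds for every DMU before
    averaging. Years with fewer than 2 DMUs are flagged and skipped.
    """
    years = np.asarray(years)
    if len(years) != len(dmus):
        raise DomainError("years must align with dmus")
    uniq = sorted(set(years.tolist()))
    if len(uniq) < 2:
        raise DomainError("need at least 2 distinct years")
    rows = []
    for t in uniq:
        mask = years == t
        group = [d for d, m in zip(dmus, mask) if m]
        if len(group) < 2:
            rows.append({"year": t, "Dt": np.nan, "Do": np.nan, "Dg": np.nan,
                         "flag": "skipped: <2 DMUs"})
            continue
        seq = [d for d, y in zip(dmus, years) if y <= t]
        scores = {}
        for label, ref in (("Dt", group), ("Do", seq), ("Dg", list(dmus))):
            res = sbm_efficiency(group, reference=ref)
            scores[label] = float(np.mean([r.score for r in res]))
        rows.append({"year": t, **scores, "flag": ""})
    return pd.DataFrame(rows)
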