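"""Independent brute-force oracles used only by the test suite.

The SBM and super-SBM oracles solve the fractional programs by
Dinkelbach's parametric method (iterating linear programs in the ORIGINAL
slack/lambda variables) instead of the Charnes-Cooper change of variables
the implementation uses, so agreement is a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _dinkelbach(num_c, num_const, den_c, den_const, A_eq, b_eq, A_ub, b_ub,
                tol=1e-11, max_iter=60):
    """min (num_const + num_c'v) / (den_const + den_c'v) over the LP-feasible
    set, via Dinkelbach iterations. Returns (q, v) or (None, None)."""
    q = 1.0
    v = None
    for _ in range(max_iter):
        c = num_c - q * den_c
        res = linprog(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                      bounds=[(0, None)] * len(num_c), method="highs")
        if not res.success:
            return None, None
        v = res.x
        num = num_const + num_c @ v
        den = den_const + den_c @ v
        f = num - q * den
        q_new = num / den
        if abs(f) < tol * max(1.0, abs(den)):
            return q_new, v
        q = q_new
    return q, v


def sbm_oracle(x0, yg0, yb0, X, Yg, Yb):
    """Plain SBM score (VRS, bad outputs as reduction slacks).

    Variables v = [lambda (K), s^- (m), s^g (s1), s^b (s2)]:
    X lam + s^- = x0, Yg lam - s^g = yg0, Yb lam + s^b = yb0, sum lam = 1.
    Objective (1 - mean(s^-/x0)) / (1 + mean over good+bad slack ratios).
    """
    x0, yg0, yb0 = map(np.atleast_1d, (x0, yg0, yb0))
    m, s1, s2 = len(x0), len(yg0), len(yb0)
    K = X.shape[1]
    nv = K + m + s1 + s2
    A_eq, b_eq = [], []
    for i in range(m):
        row = np.zeros(nv)
        row[:K] = X[i]
        row[K + i] = 1.0
        A_eq.append(row); b_eq.append(x0[i])
    for r in range(s1):
        row = np.zeros(nv)
        row[:K] = Yg[r]
        row[K + m + r] = -1.0
        A_eq.append(row); b_eq.append(yg0[r])
    for r in range(s2):
        row = np.zeros(nv)
        row[:K] = Yb[r]
        row[K + m + s1 + r] = 1.0
        A_eq.append(row); b_eq.append(yb0[r])
    row = np.zeros(nv)
    row[:K] = 1.0
    A_eq.append(row); b_eq.append(1.0)

    num_c = np.zeros(nv)
    num_c[K:K + m] = -1.0 / (m * x0)
    den_c = np.zeros(nv)
    den_c[K + m:K + m + s1] = 1.0 / ((s1 + s2) * yg0)
    if s2:
        den_c[K + m + s1:] = 1.0 / ((s1 + s2) * yb0)
    q, _ = _dinkelbach(num_c, 1.0, den_c, 1.0,
                       np.array(A_eq), np.array(b_eq), None, None)
    return q


def super_sbm_oracle(x0, yg0, yb0, X, Yg, Yb):
    """Super-SBM score against peers (the evaluated DMU must already be
    excluded from X/Yg/Yb). Variables v = [lambda (K), xbar (m),
    ygbar (s1), ybbar (s2)] with xbar >= max(X lam, x0) etc."""
    x0, yg0, yb0 = map(np.atleast_1d, (x0, yg0, yb0))
    m, s1, s2 = len(x0), len(yg0), len(yb0)
    K = X.shape[1]
    nv = K + m + s1 + s2
    A_eq = [np.concatenate([np.ones(K), np.zeros(m + s1 + s2)])]
    b_eq = [1.0]
    A_ub, b_ub = [], []
    for i in range(m):  # X lam - xbar <= 0 and x0 - xbar <= 0
        row = np.zeros(nv); row[:K] = X[i]; row[K + i] = -1.0
        A_ub.append(row); b_ub.append(0.0)
        row = np.zeros(nv); row[K + i] = -1.0
        A_ub.append(row); b_ub.append(-x0[i])
    for r in range(s1):  # ygbar - Yg lam <= 0 and ygbar <= yg0
        row = np.zeros(nv); row[:K] = -Yg[r]; row[K + m + r] = 1.0
        A_ub.append(row); b_ub.append(0.0)
        row = np.zeros(nv); row[K + m + r] = 1.0
        A_ub.append(row); b_ub.append(yg0[r])
    for r in range(s2):  # Yb lam - ybbar <= 0 and yb0 - ybbar <= 0
        row = np.zeros(nv); row[:K] = Yb[r]; row[K + m + s1 + r] = -1.0
        A_ub.append(row); b_ub.append(0.0)
        row = np.zeros(nv); row[K + m + s1 + r] = -1.0
        A_ub.append(row); b_ub.append(-yb0[r])

    num_c = np.zeros(nv)
    num_c[K:K + m] = 1.0 / ((m + s2) * x0)
    if s2:
        num_c[K + m + s1:] = 1.0 / ((m + s2) * yb0)
    den_c = np.zeros(nv)
    den_c[K + m:K + m + s1] = 1.0 / (s1 * yg0)
    q, _ = _dinkelbach(num_c, 0.0, den_c, 0.0,
                       np.array(A_eq), np.array(b_eq),
                       np.array(A_ub), np.array(b_ub))
    return q


def random_dmus(rng, n_dmu, m=2, s1=1, s2=1):
    """Random strictly positive DMU data for oracle-equivalence checks."""
    from ecoeff.dea import DMU

    return [
        DMU(id=f"D{j}",
            x=rng.uniform(1.0, 10.0, m),
            y_good=rng.uniform(1.0, 10.0, s1),
            y_bad=rng.uniform(1.0, 10.0, s2))
        for j in range(n_dmu)
    ]


def oracle_scores(dmus, mode="plain"):
    """Score every DMU with the oracle (plain SBM, or super-SBM composition
    where SBM-efficient units are re-scored without themselves)."""
    X = np.column_stack([d.x for d in dmus])
    Yg = np.column_stack([d.y_good for d in dmus])
    s2 = dmus[0].y_bad.size
    Yb = (np.column_stack([d.y_bad for d in dmus]) if s2
          else np.empty((0, len(dmus))))
    out = []
    for j, d in enumerate(dmus):
        q = sbm_oracle(d.x, d.y_good, d.y_bad, X, Yg, Yb)
        if mode == "super" and q is not None and q > 1.0 - 1e-7:
            keep = [i for i in range(len(dmus)) if i != j]
            q = super_sbm_oracle(d.x, d.y_good, d.y_bad,
                                 X[:, keep], Yg[:, keep],
                                 Yb[:, keep] if s2 else Yb)
        out.append(q)
    return out
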