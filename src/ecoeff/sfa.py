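"""Time-varying translog stochastic frontier (Battese-Coelli decay model)
and likelihood-ratio hypothesis tests.

The frontier is ln y_it = x_it' beta + v_it - u_it with white noise
v_it ~ N(0, sigma_v^2) and one-sided inefficiency

    u_it = exp(-eta (t - T_i)) * u_i,      u_i ~ N+(mu, sigma_u^2),

where N+ is the normal truncated at zero and T_i is region i's final
period: eta > 0 means inefficiency decays toward the final year, i.e.
technical efficiency TE_it = E[exp(-u_it) | eps_i] trends upward. The
likelihood uses the (sigma^2, gamma) parameterization with
sigma^2 = sigma_u^2 + sigma_v^2 and gamma = sigma_u^2/sigma^2 in [0, 1],
so gamma is directly the inefficiency share of the composite error
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr

from .errors import ConvergenceError, DomainError

logger = logging.getLogger("ecoeff.sfa")

__all__ = ["SFAFit", "LRTestResult", "translog_design", "fit_frontier", "lr_test",
           "hypothesis_tests"]

#: column order of the translog design matrix
TRANSLOG_COLUMNS = [
    "t", "lnx1", "lnx2", "lnx3", "t2",
    "lnx1_sq", "lnx2_sq", "lnx3_sq",
    "t_lnx1", "t_lnx2", "t_lnx3",
    "lnx1_lnx2", "lnx1_lnx3", "lnx2_lnx3",
    "const",
]


def translog_design(x, t) -> pd.DataFrame:
    """Translog design matrix from three positive input columns and a time
    index: first-order terms, squares, time interactions, pairwise input
    cross terms, and an intercept (15 columns)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != 3:
        raise DomainError(f"expected 3 input columns, got {x.shape[1]}")
    if (x <= 0).any():
        raise DomainError("translog requires strictly positive inputs")
    t = np.asarray(t, dtype=float)
    ln = np.log(x)
    cols = {
        "t": t,
        "lnx1": ln[:, 0], "lnx2": ln[:, 1], "lnx3": ln[:, 2],
        "t2": t**2,
        "lnx1_sq": ln[:, 0] ** 2, "lnx2_sq": ln[:, 1] ** 2, "lnx3_sq": ln[:, 2] ** 2,
        "t_lnx1": t * ln[:, 0], "t_lnx2": t * ln[:, 1], "t_lnx3": t * ln[:, 2],
        "lnx1_lnx2": ln[:, 0] * ln[:, 1],
        "lnx1_lnx3": ln[:, 0] * ln[:, 2],
        "lnx2_lnx3": ln[:, 1] * ln[:, 2],
        "const": np.ones(len(t)),
    }
    return pd.DataFrame(cols, columns=TRANSLOG_COLUMNS)


@dataclass
class SFAFit:
    beta: pd.Series
    mu: float
    eta: float
    sigma2: float
    gamma: float
    loglik: float
    te: pd.DataFrame          # region, year, te in (0, 1]
    model: str
    fixed: dict = field(default_factory=dict)
    gamma_boundary: bool = False
    converged: bool = True
    n_obs: int = 0

    @property
    def sigma_u2(self) -> float:
        return self.gamma * self.sigma2

    @property
    def sigma_v2(self) -> float:
        return (1.0 - self.gamma) * self.sigma2


def _prepare(y, Xd, regions, years):
    y = np.asarray(y, dtype=float)
    X = np.asarray(Xd, dtype=float)
    regions = np.asarray(regions)
    years = np.asarray(years, dtype=int)
    order = np.lexsort((years, regions))
    y, X, regions, years = y[order], X[order], regions[order], years[order]
    groups = []
    for r in pd.unique(regions):
        idx = np.nonzero(regions == r)[0]
        t = years[idx]
        groups.append((r, idx, t - t.max()))  # decay exponent uses t - T_i
    # balanced panels admit a fully vectorized likelihood
    balanced = len({len(g[1]) for g in groups}) == 1 and all(
        np.array_equal(g[2], groups[0][2]) for g in groups
    )
    layout = None
    if balanced:
        layout = (np.stack([g[1] for g in groups]),          # (N, T) gather index
                  groups[0][2].astype(float))                # common t - T_i
    return y, X, regions, years, groups, layout


def _bc92_loglik(eps, groups, layout, sigma2, gamma, mu, eta):
    """Battese-Coelli decay-model log-likelihood for composite residuals
    eps = y - X beta, region-grouped."""
    su2 = gamma * sigma2
    sv2 = (1.0 - gamma) * sigma2
    if su2 <= 0 or sv2 <= 0:
        return -np.inf
    su = np.sqrt(su2)
    log_phi_mu = log_ndtr(mu / su)
    if layout is not None:
        idx, trel = layout
        E = eps[idx]                       # (N, T)
        N, Ti = E.shape
        h = np.exp(-eta * trel)
        hh = h @ h
        he = E @ h
        ee = np.einsum("ij,ij->i", E, E)
        denom = sv2 + hh * su2
        mu_star = (mu * sv2 - he * su2) / denom
        s_star2 = su2 * sv2 / denom
        return float(
            N * (-0.5 * Ti * np.log(2 * np.pi) - 0.5 * (Ti - 1) * np.log(sv2)
                 - 0.5 * np.log(denom) - log_phi_mu)
            - 0.5 * (ee.sum() / sv2 + N * mu**2 / su2
                     - (mu_star**2).sum() / s_star2)
            + log_ndtr(mu_star / np.sqrt(s_star2)).sum()
        )
    ll = 0.0
    for _, idx, trel in groups:
        e = eps[idx]
        h = np.exp(-eta * trel)
        denom = sv2 + (h @ h) * su2
        mu_star = (mu * sv2 - (h @ e) * su2) / denom
        s_star2 = su2 * sv2 / denom
        Ti = len(e)
        ll += (
            -0.5 * Ti * np.log(2 * np.pi)
            - 0.5 * (Ti - 1) * np.log(sv2)
            - 0.5 * np.log(denom)
            - 0.5 * (e @ e / sv2 + mu**2 / su2 - mu_star**2 / s_star2)
            + log_ndtr(mu_star / np.sqrt(s_star2))
            - log_phi_mu
        )
    return ll


def _ols(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid / n)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return beta, sigma2, ll


_FREE = ("sigma2", "gamma", "mu", "eta")


def fit_frontier(
    y,
    Xd,
    regions,
    years,
    model: str = "bc92",
    fix: dict | None = None,
    n_starts: int = 3,
    tol: float = 1e-8,
) -> SFAFit:
    """Maximum-likelihood fit of the stochastic frontier.

    model="bc92" frees (mu, eta); model="half-normal-pooled" pins mu=0 and
    eta=0 (time-invariant half-normal). ``fix`` pins further parameters for
    nested-hypothesis fits, e.g. {"eta": 0.0} or {"gamma": 0.0}; fixing
    gamma at 0 collapses the model to OLS. Multi-start over gamma guards
    against the likelihood's local optima.
    """
    cols = list(Xd.columns) if isinstance(Xd, pd.DataFrame) else None
    y, X, regions, years, groups, layout = _prepare(y, Xd, regions, years)
    # standardize non-constant design columns for the optimizer; the raw
    # translog design is badly conditioned (squares/interactions of logs)
    Xraw = X
    scales = X.std(axis=0)
    const_like = scales < 1e-12
    scales[const_like] = 1.0
    has_const = const_like.any()
    # centering is only meaning-preserving when an intercept can absorb it
    centers = X.mean(axis=0) if has_const else np.zeros(X.shape[1])
    centers[const_like] = 0.0
    X = (X - centers) / scales
    if has_const:
        X[:, const_like] = Xraw[:, const_like]

    def _unscale(beta_s):
        beta = beta_s / scales
        if has_const:
            j = int(np.nonzero(const_like)[0][0])
            shift = np.sum(beta_s * centers / scales)
            beta[j] = beta_s[j] / Xraw[0, j] - shift / Xraw[0, j]
        return beta
    fix = dict(fix or {})
    if model == "half-normal-pooled":
        fix.setdefault("mu", 0.0)
        fix.setdefault("eta", 0.0)
    elif model != "bc92":
        raise DomainError(f"unknown model {model!r}")
    if cols is None:
        cols = [f"b{j}" for j in range(X.shape[1])]
    k = X.shape[1]

    beta_ols, s2_ols, ll_ols = _ols(y, X)

    if fix.get("gamma", None) == 0.0:
        te = pd.DataFrame({"region": regions, "year": years, "te": np.ones(len(y))})
        return SFAFit(beta=pd.Series(_unscale(beta_ols), index=cols),
                      mu=fix.get("mu", 0.0),
                      eta=fix.get("eta", 0.0), sigma2=s2_ols, gamma=0.0, loglik=ll_ols,
                      te=te, model=model, fixed=fix, gamma_boundary=True,
                      n_obs=len(y))

    free = [p for p in _FREE if p not in fix]

    def unpack(theta):
        beta = theta[:k]
        vals = dict(fix)
        for j, p in enumerate(free):
            z = theta[k + j]
            if p == "sigma2":
                vals[p] = np.exp(z)
            elif p == "gamma":
                vals[p] = 1.0 / (1.0 + np.exp(-z))
            else:
                vals[p] = z
        return beta, vals

    def nll(theta):
        beta, vals = unpack(theta)
        ll = _bc92_loglik(y - X @ beta, groups, layout,
                          vals["sigma2"], vals["gamma"], vals["mu"], vals["eta"])
        return -ll if np.isfinite(ll) else 1e12

    gamma_starts = [0.2, 0.6, 0.9][: max(1, n_starts)]
    best = None
    for g0 in gamma_starts:
        start = list(beta_ols)
        for p in free:
            if p == "sigma2":
                start.append(np.log(max(s2_ols, 1e-8)))
            elif p == "gamma":
                start.append(np.log(g0 / (1 - g0)))
            elif p == "mu":
                start.append(0.1)
            else:  # eta
                start.append(0.0)
        res = optimize.minimize(nll, np.array(start), method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": tol})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("stochastic frontier optimization failed", trace=best)

    beta, vals = unpack(best.x)
    ll = -best.fun
    # boundary handling: compare against the OLS (gamma -> 0) limit
    gamma_boundary = False
    if "gamma" in free and ll < ll_ols + 1e-10:
        if ll_ols >= ll:
            beta, sigma2, ll = beta_ols, s2_ols, ll_ols
            vals = {**vals, "sigma2": sigma2, "gamma": 0.0}
            gamma_boundary = True
    if vals["gamma"] < 1e-4 or vals["gamma"] > 1 - 1e-4:
        gamma_boundary = True

    eps = y - X @ beta  # scaled design with scaled beta: same fitted values
    te = _technical_efficiency(eps, groups, regions, years, vals)
    return SFAFit(beta=pd.Series(_unscale(beta), index=cols), mu=float(vals["mu"]),
                  eta=float(vals["eta"]), sigma2=float(vals["sigma2"]),
                  gamma=float(vals["gamma"]), loglik=float(ll), te=te, model=model,
                  fixed=fix, gamma_boundary=gamma_boundary,
                  converged=bool(best.success or np.isfinite(ll)), n_obs=len(y))


def _technical_efficiency(eps, groups, regions, years, vals):
    """Conditional-expectation predictor E[exp(-u_it) | eps_i]."""
    sigma2, gamma, mu, eta = (vals["sigma2"], vals["gamma"], vals["mu"], vals["eta"])
    su2, sv2 = gamma * sigma2, (1 - gamma) * sigma2
    te = np.ones(len(eps))
    if su2 > 0:
        for _, idx, trel in groups:
            e = eps[idx]
            h = np.exp(-eta * trel)
            denom = sv2 + (h @ h) * su2
            mu_star = (mu * sv2 - (h @ e) * su2) / denom
            s_star = np.sqrt(su2 * sv2 / denom)
            z = mu_star / s_star
            te[idx] = np.exp(-h * mu_star + 0.5 * h**2 * s_star**2) * (
                stats.norm.cdf(z - h * s_star) / max(stats.norm.cdf(z), 1e-300)
            )
    te = np.clip(te, 1e-12, 1.0)
    return pd.DataFrame({"region": regions, "year": years, "te": te})


#: columns dropped under the functional-form hypotheses
_SECOND_ORDER = ["t2", "lnx1_sq", "lnx2_sq", "lnx3_sq",
                 "t_lnx1", "t_lnx2", "t_lnx3",
                 "lnx1_lnx2", "lnx1_lnx3", "lnx2_lnx3"]
_TIME_TERMS = ["t", "t2", "t_lnx1", "t_lnx2", "t_lnx3"]


def hypothesis_tests(y, Xd, regions, years, tests=("H1", "H2", "H3", "H4", "H5"),
                     full: "SFAFit | None" = None, n_starts: int = 3) -> list:
    """The five standard LR specification tests of the translog decay
    frontier, each against the full bc92 fit:

    H1: no second-order terms (Cobb-Douglas frontier);
    H2: no technological change (all terms involving t vanish);
    H3: mu = 0 (half-normal rather than truncated-normal inefficiency);
    H4: eta = 0 (time-invariant inefficiency);
    H5: mu = eta = gamma = 0 (no inefficiency at all; boundary null).
    """
    if full is None:
        full = fit_frontier(y, Xd, regions, years, n_starts=n_starts)
    Xd = Xd if isinstance(Xd, pd.DataFrame) else pd.DataFrame(np.asarray(Xd))
    out = []
    for h in tests:
        if h == "H1":
            keep = [c for c in Xd.columns if c not in _SECOND_ORDER]
            restr = fit_frontier(y, Xd[keep], regions, years, n_starts=n_starts)
            df, boundary = len(Xd.columns) - len(keep), False
        elif h == "H2":
            keep = [c for c in Xd.columns if c not in _TIME_TERMS]
            restr = fit_frontier(y, Xd[keep], regions, years, n_starts=n_starts)
            df, boundary = len(Xd.columns) - len(keep), False
        elif h == "H3":
            restr = fit_frontier(y, Xd, regions, years, fix={"mu": 0.0},
                                 n_starts=n_starts)
            df, boundary = 1, False
        elif h == "H4":
            restr = fit_frontier(y, Xd, regions, years, fix={"eta": 0.0},
                                 n_starts=n_starts)
            df, boundary = 1, False
        elif h == "H5":
            restr = fit_frontier(y, Xd, regions, years,
                                 fix={"mu": 0.0, "eta": 0.0, "gamma": 0.0})
            df, boundary = 3, True
        else:
            raise DomainError(f"unknown hypothesis {h!r}")
        out.append(lr_test(full, restr, df=df, hypothesis=h, boundary=boundary))
    return out


@dataclass
class LRTestResult:
    hypothesis: str
    statistic: float
    df: int
    p: float
    decision: str
    boundary: bool = False


def lr_test(full: SFAFit, restricted: SFAFit, df: int, hypothesis: str = "",
            boundary: bool = False, alpha: float = 0.05) -> LRTestResult:
    """Likelihood-ratio test of a restricted frontier nested in the full one.

    statistic = 2 (loglik_full - loglik_restricted). With ``boundary`` the
    null pins a variance parameter at the edge of its space, so the
    reference distribution is the half-half mixture of chi-squared(df) and
    chi-squared(df-1) instead of plain chi-squared(df).
    """
    stat = 2.0 * (full.loglik - restricted.loglik)
    if stat < -1e-4 * max(1.0, abs(full.loglik)):
        raise DomainError(
            f"nesting violation: restricted loglik {restricted.loglik:.6f} exceeds "
            f"full {full.loglik:.6f}"
        )
    stat = max(stat, 0.0)
    if boundary:
        p_hi = stats.chi2.sf(stat, df)
        p_lo = stats.chi2.sf(stat, df - 1) if df > 1 else (1.0 if stat == 0 else 0.0)
        p = 0.5 * (p_hi + p_lo)
    else:
        p = stats.chi2.sf(stat, df)
    return LRTestResult(hypothesis=hypothesis, statistic=float(stat), df=df,
                        p=float(p), decision="reject" if p < alpha else "fail",
                        boundary=boundary)
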