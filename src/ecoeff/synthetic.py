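"""Synthetic provincial-panel generator.

Every downstream stage of the pipeline (DEA, spatial statistics, Markov
chains, SDM, stochastic frontier, grey forecasting) is exercised against
panels produced here, so the generators implement exactly the statistical
structure those stages assume:

* a translog production frontier with time-decaying truncated-normal
  inefficiency (the frontier module's data-generating process),
* spatially autocorrelated outcomes through a spatial-Durbin reduced form
  with region and year effects,
* strictly positive inputs drawn log-uniformly over ranges matching the
  order of magnitude of Chinese provincial input-output statistics
  (capital in 1e8 yuan, labour in 1e4 persons, energy in 1e4 tce), with
  carbon emissions a positive monotone function of energy,
* smooth positive aggregate series following the GM(1,1) time-response
  family, so the noiseless series is exactly recoverable by the grey
  fitter.

Each generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .panel import PanelDataset, PanelSchema
from .sfa import TRANSLOG_COLUMNS, translog_design
from .weights import SpatialWeights, row_standardize

__all__ = [
    "FrontierParams",
    "SimulationConfig",
    "make_lattice_weights",
    "simulate_panel",
    "simulate_sdm_panel",
    "simulate_grey_series",
]

#: log-uniform input ranges (capital 1e8 yuan, labour 1e4 persons, energy 1e4 tce)
DEFAULT_INPUT_RANGES = {
    "capital": (360.0, 165425.0),
    "labour": (245.0, 6826.0),
    "energy": (310.0, 44026.0),
}


@dataclass
class FrontierParams:
    """Translog frontier coefficients keyed by design column.

    The default is the Cobb-Douglas special case (all second-order terms
    zero) with moderate input elasticities and a small positive time
    trend; any coefficient can be overridden to generate a full translog.
    """

    coef: dict = field(default_factory=lambda: {
        "const": 3.76, "t": 0.02,
        "lnx1": 0.40, "lnx2": 0.30, "lnx3": 0.15,
    })

    def vector(self) -> np.ndarray:
        unknown = set(self.coef) - set(TRANSLOG_COLUMNS)
        if unknown:
            raise DomainError(f"unknown frontier coefficients {sorted(unknown)}")
        return np.array([self.coef.get(c, 0.0) for c in TRANSLOG_COLUMNS])


@dataclass
class SimulationConfig:
    """Bundle of generator settings (used by the CLI's YAML config)."""

    n_regions: int = 30
    n_years: int = 10
    seed: int = 0
    frontier: FrontierParams = field(default_factory=FrontierParams)
    mu: float = 0.5
    eta: float = 0.4
    sigma_u2: float = 0.12
    sigma_v2: float = 0.08
    rho: float = 0.3
    beta: tuple = (1.0,)
    phi: tuple = (0.2,)
    weights_scheme: str = "ring"
    grey_a: float = 0.006
    grey_noise_sd: float = 0.0

    @classmethod
    def from_mapping(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "frontier" in d:
            d["frontier"] = FrontierParams(coef=dict(d["frontier"]))
        return cls(**d)


def _region_ids(n: int) -> list:
    return [f"R{i + 1:02d}" for i in range(n)]


def make_lattice_weights(n: int, scheme: str = "ring", k: int = 3,
                         seed: int | None = None) -> SpatialWeights:
    """Symmetric binary contiguity on n regions.

    ring: cycle graph. rook-lattice: rook adjacency on the most-square
    r x c grid with r*c = n (degenerates to a path when n is prime).
    random-k: connected random k-regular graph (requires n*k even).
    """
    if n < 2:
        raise DomainError("need at least 2 regions")
    w = np.zeros((n, n))
    if scheme == "ring":
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
    elif scheme == "rook-lattice":
        r = max(d for d in range(1, int(np.sqrt(n)) + 1) if n % d == 0)
        c = n // r
        for i in range(n):
            ri, ci = divmod(i, c)
            for rj, cj in ((ri + 1, ci), (ri, ci + 1)):
                if rj < r and cj < c:
                    j = rj * c + cj
                    w[i, j] = w[j, i] = 1.0
    elif scheme == "random-k":
        if k < 1 or k >= n:
            raise DomainError(f"invalid degree k={k} for n={n}")
        if (n * k) % 2:
            raise DomainError("random-k requires n*k even")
        base = np.random.default_rng(seed).integers(0, 2**31 - 1)
        for attempt in range(50):
            g = nx.random_regular_graph(k, n, seed=int(base) + attempt)
            if nx.is_connected(g):
                break
        else:
            raise DomainError("could not generate a connected k-regular graph")
        for i, j in g.edges:
            w[i, j] = w[j, i] = 1.0
    else:
        raise DomainError(f"unknown weights scheme {scheme!r}")
    return SpatialWeights(ids=_region_ids(n), w=w)


def simulate_panel(
    n_regions: int = 30,
    n_years: int = 10,
    seed: int = 0,
    frontier: FrontierParams | None = None,
    mu: float = 0.5,
    eta: float = 0.4,
    sigma_u2: float = 0.12,
    sigma_v2: float = 0.08,
    input_ranges: dict | None = None,
    carbon_scale: float = 2.0,
    carbon_exponent: float = 1.0,
    carbon_noise_sd: float = 0.1,
    start_year: int = 2012,
):
    """Production panel with a known frontier and known inefficiency.

    ln(gdp)_it = translog(ln x_it, t; beta) + v_it - u_it with
    u_it = exp(-eta (t - T)) u_i, u_i ~ N+(mu, sigma_u2) (normal truncated
    at zero), v_it ~ N(0, sigma_v2). Inputs are iid log-uniform over
    ``input_ranges``; carbon = carbon_scale * energy^carbon_exponent *
    lognormal(0, carbon_noise_sd) is positive and increasing in energy.

    Returns (PanelDataset, truth) where truth records the latent u_it and
    TE_it = exp(-u_it) per region-year.
    """
    if sigma_u2 < 0 or sigma_v2 < 0 or sigma_u2 + sigma_v2 <= 0:
        raise DomainError("need sigma_u2, sigma_v2 >= 0 with positive sum")
    frontier = frontier or FrontierParams()
    ranges = input_ranges or DEFAULT_INPUT_RANGES
    input_names = list(ranges)
    rng = np.random.default_rng(seed)

    regions = _region_ids(n_regions)
    t_idx = np.arange(1, n_years + 1)
    rows = []
    X = np.empty((n_regions * n_years, len(input_names)))
    for j, name in enumerate(input_names):
        lo, hi = ranges[name]
        X[:, j] = np.exp(rng.uniform(np.log(lo), np.log(hi), n_regions * n_years))

    if sigma_u2 > 0:
        su = np.sqrt(sigma_u2)
        u_i = stats.truncnorm.rvs(-mu / su, np.inf, loc=mu, scale=su,
                                  size=n_regions, random_state=rng)
    else:
        u_i = np.zeros(n_regions)
    v = rng.normal(0.0, np.sqrt(sigma_v2), (n_regions, n_years))
    decay = np.exp(-eta * (t_idx - n_years))          # t - T, T = last year
    u_it = u_i[:, None] * decay[None, :]

    tcol = np.tile(t_idx, n_regions)
    design = translog_design(X, tcol)
    ln_frontier = design.to_numpy() @ frontier.vector()
    ln_y = ln_frontier + v.reshape(-1) - u_it.reshape(-1)
    carbon = (
        carbon_scale
        * X[:, input_names.index("energy")] ** carbon_exponent
        * np.exp(rng.normal(0.0, carbon_noise_sd, n_regions * n_years))
    )

    rows = pd.DataFrame({
        "region": np.repeat(regions, n_years),
        "year": np.tile(start_year + t_idx - 1, n_regions),
        **{name: X[:, j] for j, name in enumerate(input_names)},
        "gdp": np.exp(ln_y),
        "carbon": carbon,
    })
    truth = pd.DataFrame({
        "region": rows["region"],
        "year": rows["year"],
        "u": u_it.reshape(-1),
        "te": np.exp(-u_it.reshape(-1)),
        "v": v.reshape(-1),
    })
    schema = PanelSchema(inputs=input_names, output="gdp", bad_output="carbon")
    return PanelDataset(data=rows, schema=schema), truth


def simulate_sdm_panel(
    W: SpatialWeights,
    n_years: int = 20,
    rho: float = 0.3,
    beta=(1.0,),
    phi=(0.2,),
    sigma_eps: float = 1.0,
    sigma_mu2: float = 0.1,
    sigma_nu2: float = 0.1,
    seed: int = 0,
    start_year: int = 2002,
    return_components: bool = False,
):
    """Balanced panel drawn from the SDM reduced form

        y_t = (I - rho W)^{-1} (X_t beta + W X_t phi + mu + nu_t + eps_t)

    with iid standard-normal regressors and N(0, sigma_mu2)/N(0, sigma_nu2)
    region/year effects. Requires row-standardized W and rho inside the
    stability interval.
    """
    if not W.standardized:
        W = row_standardize(W)
    lo, hi = W.rho_interval()
    if not (lo < rho < hi):
        raise DomainError(f"rho={rho} outside stability interval ({lo:.4f}, {hi:.4f})")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if phi.shape != beta.shape:
        raise DomainError("beta and phi must have the same length")
    k, n = len(beta), W.n
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, np.sqrt(sigma_mu2), n)
    nu = rng.normal(0.0, np.sqrt(sigma_nu2), n_years)
    A = np.eye(n) - rho * W.w
    recs = []
    components = []
    for ti in range(n_years):
        X = rng.standard_normal((n, k))
        eps = rng.normal(0.0, sigma_eps, n)
        rhs = X @ beta + (W.w @ X) @ phi + mu + nu[ti] + eps
        yv = np.linalg.solve(A, rhs)
        components.append({"X": X, "eps": eps, "rhs": rhs, "y": yv})
        for i, rid in enumerate(W.ids):
            recs.append({"region": rid, "year": start_year + ti, "y": yv[i],
                         **{f"x{j + 1}": X[i, j] for j in range(k)}})
    df = pd.DataFrame(recs)
    if return_components:
        return df, {"mu": mu, "nu": nu, "periods": components}
    return df


def simulate_grey_series(
    length: int = 10,
    a: float = 0.006,
    u: float | None = None,
    x1: float = 15783.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Positive series from the GM(1,1) time-response family:

        x(1) = x1,  x(t) = (x1 - u/a) e^{-a(t-1)} (1 - e^{a})  for t >= 2,

    plus optional additive Gaussian noise on t >= 2. With the default
    u = a*x1/(1 - e^{-a}) the noiseless series is the geometric
    continuation of x1 with ratio e^{-a}; any noiseless draw is exactly
    recoverable by ``fit_gm11``.
    """
    if length < 4:
        raise DomainError("grey series needs length >= 4")
    if a == 0:
        raise DomainError("a = 0 gives a constant accumulated slope; pick a != 0")
    if u is None:
        u = a * x1 / (1.0 - np.exp(-a))
    t = np.arange(2, length + 1, dtype=float)
    x = np.concatenate([[x1], (x1 - u / a) * np.exp(-a * (t - 1)) * (1.0 - np.exp(a))])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x[1:] = x[1:] + rng.normal(0.0, noise_sd, length - 1)
    if (x <= 0).any():
        raise DomainError("grey series went nonpositive; reduce noise_sd or adjust (a, u)")
    return x
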