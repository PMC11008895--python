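"""Global spatial autocorrelation: Moran's I with normal-approximation
(z, p) under the randomization assumption, or a seeded permutation test.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

Under the null of no spatial structure E[I] = -1/(n-1); the randomization
variance uses the classic moment formula involving S0, S1, S2 and the
sample kurtosis b2, so no distributional assumption on x is needed beyond
exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError
from .weights import SpatialWeights, row_standardize, spatial_lag  # noqa: F401

__all__ = ["MoranResult", "global_morans_i", "spatial_lag", "row_standardize"]


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float
    method: str
    permutations: int = 0


def global_morans_i(
    x,
    weights: SpatialWeights,
    method: str = "normal",
    permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I of region values ``x`` over ``weights``.

    method="normal": z and two-sided p from the randomization-assumption
    moments. method="permutation": p from >= 999 seeded random relabelings,
    two-sided as (#{|I*| >= |I|} + 1) / (permutations + 1); z is still
    reported from the analytic moments.
    """
    x = np.asarray(x, dtype=float)
    n = weights.n
    if x.shape[0] != n:
        raise DomainError(f"x has length {x.shape[0]}, weights have {n} regions")
    if n < 3:
        raise DomainError("Moran's I needs at least 3 regions")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x is constant; Moran's I undefined")

    w = weights.w
    s0 = w.sum()
    if s0 <= 0:
        raise DegenerateInputError("weight matrix has zero total weight")

    def _moran(v):
        z = v - v.mean()
        return (n / s0) * (z @ w @ z) / (z @ z)

    I = float(_moran(x))
    e_i = -1.0 / (n - 1)

    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    zc = x - x.mean()
    b2 = n * (zc**4).sum() / ((zc**2).sum() ** 2)
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    if var <= 0:
        raise DegenerateInputError("nonpositive randomization variance")
    z_stat = (I - e_i) / np.sqrt(var)

    if method == "normal":
        p = 2.0 * stats.norm.sf(abs(z_stat))
        return MoranResult(I=I, expected=e_i, variance=float(var), z=float(z_stat),
                           p=float(p), method="normal")
    if method == "permutation":
        if permutations < 999:
            permutations = 999
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            if abs(_moran(rng.permutation(x))) >= abs(I) - 1e-14:
                count += 1
        p = (count + 1) / (permutations + 1)
        return MoranResult(I=I, expected=e_i, variance=float(var), z=float(z_stat),
                           p=float(p), method="permutation", permutations=permutations)
    raise DomainError(f"unknown method {method!r}")
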