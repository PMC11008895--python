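"""Yield and cost comparison arithmetic for organic vs conventional rice.

Yields are in kg/mu and costs in RMB/mu (one mu = 1/15 hectare). Some cost
items (the farmer's own labour and land rent) are owner-imputed: they are
real opportunity costs but not cash outlays, so cost sheets flag them and
totals can be computed with or without them on the conventional side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError

__all__ = ["CostSheet", "yield_comparison", "cost_totals"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def yield_comparison(records: pd.DataFrame) -> pd.DataFrame:
    """Per-year gap (organic - conventional, kg/mu) and the organic yield
    as a percent of conventional, rounded half-up to an integer.

    ``records`` needs columns year, organic_yield, conventional_yield.
    """
    req = {"year", "organic_yield", "conventional_yield"}
    missing = req - set(records.columns)
    if missing:
        raise DomainError(f"yield records missing columns {sorted(missing)}")
    if (records["conventional_yield"] <= 0).any() or (records["organic_yield"] <= 0).any():
        raise DomainError("yields must be strictly positive")
    out = records[["year"]].copy()
    out["gap"] = records["organic_yield"] - records["conventional_yield"]
    out["ratio_pct"] = [
        _round_half_up(o / c * 100.0)
        for o, c in zip(records["organic_yield"], records["conventional_yield"])
    ]
    return out


@dataclass
class CostSheet:
    """Itemized per-mu costs; ``imputed`` lists owner-imputed item names."""

    items: dict  # name -> (organic, conventional)
    imputed: list = field(default_factory=list)

    def __post_init__(self):
        if not self.items:
            raise DomainError("empty cost sheet")
        for name, (o, c) in self.items.items():
            if o < 0 or c < 0:
                raise DomainError(f"negative cost for item {name!r}")
        unknown = [i for i in self.imputed if i not in self.items]
        if unknown:
            raise DomainError(f"imputed flags for unknown items {unknown}")


def cost_totals(sheet: CostSheet, exclude_imputed: bool = False) -> dict:
    """Column totals and their difference (organic - conventional).

    With ``exclude_imputed`` the flagged items are dropped from the
    conventional column only, matching the parenthetical convention of the
    source cost table. The returned dict also carries a ``consistency``
    list for callers that want to compare against externally printed totals
    (the checker reports, never overwrites).
    """
    organic = sum(o for o, _ in sheet.items.values())
    conventional = sum(
        c for name, (_, c) in sheet.items.items()
        if not (exclude_imputed and name in sheet.imputed)
    )
    return {
        "organic_total": float(organic),
        "conventional_total": float(conventional),
        "difference": float(organic - conventional),
    }


def check_printed_totals(sheet: CostSheet, printed: dict) -> list:
    """Compare recomputed totals against printed ones; returns a list of
    mismatch descriptions (empty if consistent)."""
    totals = cost_totals(sheet)
    issues = []
    for key in ("organic_total", "conventional_total", "difference"):
        if key in printed and abs(printed[key] - totals[key]) > 1e-9:
            issues.append(
                f"{key}: printed {printed[key]} vs recomputed {totals[key]}"
            )
    return issues
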