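"""Tidy region x year panel container and CSV round-trip.

The canonical layout is long ("tidy") CSV: one row per (region, year) with
input columns (capital stock, labour, energy), a desirable output (GDP), an
undesirable output (carbon emissions) and free-form covariate columns. All
downstream stages consume this container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, IntegrityError, SchemaError

logger = logging.getLogger("ecoeff.panel")

__all__ = ["PanelSchema", "PanelDataset", "read_panel", "write_panel", "summarize_panel"]

#: default column roles, matching the synthetic generator's output
DEFAULT_SCHEMA = {
    "region": "region",
    "year": "year",
    "inputs": ["capital", "labour", "energy"],
    "output": "gdp",
    "bad_output": "carbon",
}


@dataclass
class PanelSchema:
    """Mapping from roles to column names in a long-format CSV."""

    region: str = "region"
    year: str = "year"
    inputs: list = field(default_factory=lambda: ["capital", "labour", "energy"])
    output: str = "gdp"
    bad_output: str | None = "carbon"
    covariates: list = field(default_factory=list)

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "PanelSchema":
        if mapping is None:
            return cls()
        merged = {**DEFAULT_SCHEMA, **mapping}
        return cls(
            region=merged["region"],
            year=merged["year"],
            inputs=list(merged["inputs"]),
            output=merged["output"],
            bad_output=merged.get("bad_output"),
            covariates=list(merged.get("covariates", [])),
        )

    def required_columns(self) -> list:
        cols = [self.region, self.year, *self.inputs, self.output]
        if self.bad_output:
            cols.append(self.bad_output)
        return cols


@dataclass
class PanelDataset:
    """Long-format panel with unique (region, year) keys.

    ``data`` holds one row per region-year; numeric roles are float64,
    covariate cells may be missing (NaN) and each stage decides whether it
    drops or rejects them.
    """

    data: pd.DataFrame
    schema: PanelSchema = field(default_factory=PanelSchema)

    def __post_init__(self):
        keys = self.data[[self.schema.region, self.schema.year]]
        dup = keys.duplicated()
        if dup.any():
            offenders = keys[dup].to_records(index=False).tolist()
            raise IntegrityError(f"duplicate (region, year) keys: {offenders}")

    @property
    def regions(self) -> list:
        return sorted(self.data[self.schema.region].unique().tolist())

    @property
    def years(self) -> list:
        return sorted(self.data[self.schema.year].unique().tolist())

    def __len__(self) -> int:
        return len(self.data)

    def pivot(self, column: str) -> pd.DataFrame:
        """region x year wide table of one variable."""
        return self.data.pivot(
            index=self.schema.region, columns=self.schema.year, values=column
        )

    def is_balanced(self) -> bool:
        return not self.pivot(self.schema.output).isna().any().any()


def read_panel(path, schema: dict | PanelSchema | None = None) -> PanelDataset:
    """Read a long-format CSV panel.

    Raises :class:`SchemaError` naming the missing role, and
    :class:`IntegrityError` listing duplicated (region, year) keys. Rows
    whose required numeric fields fail to parse are rejected with
    row-indexed diagnostics in the exception message.
    """
    sch = schema if isinstance(schema, PanelSchema) else PanelSchema.from_mapping(schema)
    df = pd.read_csv(path)
    missing = [c for c in sch.required_columns() if c not in df.columns]
    if missing:
        raise SchemaError(f"panel file {path} is missing required columns {missing}")
    numeric_roles = [*sch.inputs, sch.output]
    if sch.bad_output:
        numeric_roles.append(sch.bad_output)
    bad_rows = []
    for col in numeric_roles + [c for c in sch.covariates if c in df.columns]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if col in numeric_roles and newly_bad.any():
            bad_rows.extend((int(i), col, df.loc[i, col]) for i in df.index[newly_bad])
        df[col] = coerced
    if bad_rows:
        raise SchemaError(f"non-numeric required fields at (row, column, value): {bad_rows}")
    df[sch.year] = df[sch.year].astype(int)
    df[sch.region] = df[sch.region].astype(str)
    # pick up any covariates present but not declared
    known = set(sch.required_columns()) | set(sch.covariates)
    extra = [c for c in df.columns if c not in known]
    for col in extra:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    sch.covariates = list(dict.fromkeys([*sch.covariates, *extra]))
    logger.info("read panel: %d rows, %d regions", len(df), df[sch.region].nunique())
    return PanelDataset(data=df, schema=sch)


def write_panel(panel: PanelDataset, path) -> None:
    """Write the panel back to CSV (RFC-4180, UTF-8, header row).

    Uses full float precision so that read_panel(write_panel(p)) reproduces
    finite decimal values bit-exactly.
    """
    panel.data.to_csv(path, index=False)


def summarize_panel(panel: PanelDataset, variables: list) -> pd.DataFrame:
    """Descriptive statistics per variable: mean, sample sd, min, max and
    the annual average growth in percent.

    Annual growth is the geometric mean growth rate of the cross-region
    yearly total: with totals T_y over years y_first..y_last it is
    (T_last/T_first)^(1/(y_last - y_first)) - 1, times 100.
    """
    rows = []
    for var in variables:
        if var not in panel.data.columns:
            raise KeyError(f"variable {var!r} not in panel")
        s = panel.data[var].dropna()
        yearly = panel.data.groupby(panel.schema.year)[var].sum()
        yearly = yearly[yearly.notna()]
        if len(yearly) < 2:
            raise DegenerateInputError(f"variable {var!r} present for fewer than 2 years")
        span = yearly.index.max() - yearly.index.min()
        t0, t1 = yearly.iloc[0], yearly.iloc[-1]
        if t0 <= 0 or t1 <= 0:
            growth = np.nan
        else:
            growth = ((t1 / t0) ** (1.0 / span) - 1.0) * 100.0
        rows.append(
            {
                "variable": var,
                "mean": float(s.mean()),
                "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
                "min": float(s.min()),
                "max": float(s.max()),
                "annual_growth_pct": float(growth),
            }
        )
    return pd.DataFrame(rows)
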