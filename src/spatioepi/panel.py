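"""Long-format areal panels and their temporal aggregation.

The central container is :class:`PanelDataset`: one record per (unit, year)
with an incidence outcome (age-standardized, per 10,000), a named vector of
continuous covariates, and optional planar unit coordinates.  Cross-sectional
slices — yearly values, multi-year window means, cumulative burdens — are
carried as :class:`CrossSection` objects that downstream spatial statistics
consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CrossSection",
    "PanelDataset",
    "read_panel",
    "write_panel",
    "bin_years",
    "cumulative",
]


@dataclass
class CrossSection:
    """A single surface over units: one finite value per unit, plus a label."""

    unit_ids: list
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.unit_ids) != self.values.shape[0]:
            raise ValueError("unit_ids and values must be aligned")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in cross-section {self.label!r}")

    def reindex(self, unit_ids: list) -> "CrossSection":
        """Reorder values to match ``unit_ids`` (e.g., a weights object's order)."""
        pos = {u: i for i, u in enumerate(self.unit_ids)}
        try:
            idx = [pos[u] for u in unit_ids]
        except KeyError as e:
            raise ValueError(f"unit {e.args[0]!r} missing from cross-section") from e
        return CrossSection(list(unit_ids), self.values[idx], self.label)


@dataclass
class PanelDataset:
    """Unit x year panel with outcome, covariates, and optional coordinates.

    Invariants enforced at construction: (unit, year) pairs are unique, every
    record carries the same covariate names, outcomes are finite, and each
    unit's year range is contiguous.
    """

    df: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)
    has_coords: bool = False

    REQUIRED = ("unit_id", "year", "outcome")

    def __post_init__(self) -> None:
        df = self.df
        for c in self.REQUIRED:
            if c not in df.columns:
                raise ValueError(f"panel missing required column {c!r}")
        for c in self.covariate_names:
            if c not in df.columns:
                raise ValueError(f"declared covariate {c!r} not in data")
            if not np.issubdtype(df[c].dtype, np.number):
                raise ValueError(f"covariate {c!r} is not numeric")
            if df[c].isna().any():
                bad = df.index[df[c].isna()][0]
                raise ValueError(f"missing covariate {c!r} at row {bad}")
        dup = df.duplicated(subset=["unit_id", "year"])
        if dup.any():
            u, y = df.loc[dup.idxmax(), ["unit_id", "year"]]
            raise ValueError(f"duplicate (unit, year) pair: ({u!r}, {y})")
        if df["outcome"].isna().any():
            raise ValueError("missing outcome in analyzed rows")
        for u, g in df.groupby("unit_id"):
            ys = np.sort(g["year"].to_numpy())
            if len(ys) > 1 and not np.array_equal(ys, np.arange(ys[0], ys[-1] + 1)):
                raise ValueError(f"unit {u!r}: year range not contiguous")
        self.has_coords = {"x", "y"}.issubset(df.columns)
        self.df = df.sort_values(["unit_id", "year"], kind="stable").reset_index(drop=True)

    @property
    def unit_ids(self) -> list:
        return sorted(self.df["unit_id"].unique().tolist())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.df["year"].unique())

    @property
    def n_records(self) -> int:
        return len(self.df)

    def time_coord(self) -> np.ndarray:
        """Year offset from the panel minimum — the GTNNWR temporal coordinate."""
        return (self.df["year"] - int(self.df["year"].min())).to_numpy(float)

    def coords(self) -> np.ndarray:
        if not self.has_coords:
            raise ValueError("panel has no coordinates")
        return self.df[["x", "y"]].to_numpy(float)

    def outcome_section(self, year: int) -> CrossSection:
        sub = self.df[self.df["year"] == year].sort_values("unit_id")
        if sub.empty:
            raise ValueError(f"no records for year {year}")
        return CrossSection(sub["unit_id"].tolist(), sub["outcome"].to_numpy(float), str(year))

    def covariate_section(self, name: str, years=None, stat: str = "mean") -> CrossSection:
        """Per-unit mean of one covariate over ``years`` (default: all years)."""
        if name not in self.covariate_names:
            raise KeyError(name)
        sub = self.df if years is None else self.df[self.df["year"].isin(list(years))]
        agg = sub.groupby("unit_id")[name].agg(stat).sort_index()
        label = name if years is None else f"{name} {min(years)}-{max(years)}"
        return CrossSection(agg.index.tolist(), agg.to_numpy(float), label)

    def exclude_units(self, units: list) -> "PanelDataset":
        """Drop listed units (the analog of removing non-contiguous states)."""
        keep = ~self.df["unit_id"].isin(list(units))
        return PanelDataset(self.df[keep].copy(), list(self.covariate_names))

    def equals(self, other: "PanelDataset") -> bool:
        if self.covariate_names != other.covariate_names:
            return False
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        num = a.select_dtypes(np.number).columns
        return (
            a[["unit_id"]].equals(b[["unit_id"]])
            and bool(np.allclose(a[num].to_numpy(float), b[num].to_numpy(float), atol=0, rtol=0))
        )


def read_panel(path, config: dict | None = None) -> PanelDataset:
    """Read a long-format delimited panel file.

    ``config`` maps column names to roles::

        {"unit": "state", "year": "yr", "outcome": "incidence",
         "covariates": ["pm25", "sodium"], "x": "cx", "y": "cy",
         "exclude_units": ["AK", "HI"]}

    Unlisted numeric columns (beyond roles) are treated as covariates when
    ``covariates`` is omitted.  Rows with a missing outcome are dropped with a
    logged count; a missing covariate cell is a hard error naming the row.
    """
    config = dict(config or {})
    df = pd.read_csv(path, float_precision="round_trip")
    ren = {}
    for role, default in (("unit", "unit_id"), ("year", "year"), ("outcome", "outcome")):
        col = config.get(role, default if default in df.columns else None)
        if col is None or col not in df.columns:
            raise ValueError(f"cannot locate {role!r} column (config: {config.get(role)!r})")
        ren[col] = {"unit": "unit_id"}.get(role, role)
    for axis in ("x", "y"):
        col = config.get(axis, axis if axis in df.columns else None)
        if col is not None:
            ren[col] = axis
    df = df.rename(columns=ren)
    covs = config.get("covariates")
    if covs is None:
        reserved = {"unit_id", "year", "outcome", "x", "y"}
        covs = [c for c in df.columns if c not in reserved]
    for c in covs:
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else "?"
            raise ValueError(f"non-numeric covariate cell in column {c!r}, row {row}")
    n_missing = int(df["outcome"].isna().sum())
    if n_missing:
        logger.info("dropping %d rows with missing outcome", n_missing)
        df = df[df["outcome"].notna()]
    panel = PanelDataset(df.reset_index(drop=True), list(covs))
    excl = config.get("exclude_units")
    if excl:
        panel = panel.exclude_units(excl)
    return panel


def write_panel(panel: PanelDataset, path) -> None:
    cols = ["unit_id", "year", "outcome"]
    if panel.has_coords:
        cols += ["x", "y"]
    cols += panel.covariate_names
    # %.17g guarantees float64 round-trip through text
    panel.df[cols].to_csv(path, index=False, float_format="%.17g")


def bin_years(panel: PanelDataset, width: int = 5, stat: str = "mean") -> list[CrossSection]:
    """Aggregate the outcome into consecutive ``width``-year windows.

    The window mean per unit is the value analyzed by the five-year-interval
    spatial statistics (a 30-year panel yields six windows).  ``width`` must
    divide the panel's span exactly.
    """
    if stat != "mean":
        raise ValueError("only stat='mean' is supported")
    years = panel.years
    span = int(years[-1] - years[0] + 1)
    if len(years) != span:
        raise ValueError("panel years are not contiguous")
    if span % width != 0:
        raise ValueError(f"span {span} not divisible by bin width {width}")
    sections = []
    for start in range(int(years[0]), int(years[-1]) + 1, width):
        stop = start + width - 1
        sub = panel.df[(panel.df["year"] >= start) & (panel.df["year"] <= stop)]
        agg = sub.groupby("unit_id")["outcome"].mean().sort_index()
        sections.append(
            CrossSection(agg.index.tolist(), agg.to_numpy(float), f"{start}-{stop}")
        )
    return sections


def cumulative(panel: PanelDataset, op: str = "sum") -> CrossSection:
    """Whole-period burden per unit: summed (default) or averaged yearly values."""
    if op not in ("sum", "mean"):
        raise ValueError("op must be 'sum' or 'mean'")
    agg = panel.df.groupby("unit_id")["outcome"].agg(op).sort_index()
    years = panel.years
    return CrossSection(
        agg.index.tolist(), agg.to_numpy(float), f"{op} {years[0]}-{years[-1]}"
    )
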