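"""Core record types and CSV input/output.

Month-of-birth data are handled as per-stratum tables: the 12 monthly birth
counts for one (region-or-country label, calendar year, sex) stratum.  Counts
are stored as floats so that the leap-year February adjustment and scaling to
an equivalent study size can produce fractional counts without rounding loss.

Months are indexed 1-12 with January = 1 throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthOfBirthTable",
    "RegionStat",
    "CaseMixture",
    "read_month_tables",
    "write_month_tables",
    "read_region_stats",
    "write_region_stats",
    "load_uk_regions",
]

_SEXES = ("all", "male", "female")
_POOLED_YEAR = -1  # internal sentinel for year=None during CSV grouping


@dataclass(frozen=True)
class MonthOfBirthTable:
    """Monthly birth counts for one (label, year, sex) stratum.

    Parameters
    ----------
    label : str
        Region or country identifier.
    year : int or None
        Gregorian calendar year.  ``None`` marks a pooled table (e.g. a case
        collection spanning several birth years); month-length arithmetic
        then uses a generic 365-day year.
    counts : array-like of 12 floats
        Births in January..December.  Real-valued so that adjusted or scaled
        tables keep fractional counts.
    latitude : float, optional
        Degrees north of the population's location.
    sex : {"all", "male", "female"}
    """

    label: str
    year: Optional[int]
    counts: np.ndarray
    latitude: Optional[float] = None
    sex: str = "all"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (12,):
            raise ValueError(f"expected 12 monthly counts, got shape {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("monthly counts must be non-negative")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Monthly proportions counts / total (requires total > 0)."""
        total = self.total
        if total <= 0:
            raise ValueError(f"table {self.label!r}/{self.year} has zero total")
        return self.counts / total

    def replace(self, **changes) -> "MonthOfBirthTable":
        return replace(self, **changes)


@dataclass(frozen=True)
class RegionStat:
    """One population stratum: size, disease prevalence and exposure frequency.

    ``prevalence`` is cases per 100,000 persons; ``exposure_freq`` is an
    allele or exposure frequency in percent.
    """

    name: str
    population: float
    prevalence: float
    exposure_freq: float
    latitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(f"region {self.name!r}: population must be > 0")
        if self.prevalence < 0:
            raise ValueError(f"region {self.name!r}: prevalence must be >= 0")
        if not 0 <= self.exposure_freq <= 100:
            raise ValueError(
                f"region {self.name!r}: exposure_freq must be in [0, 100]"
            )


@dataclass(frozen=True)
class CaseMixture:
    """Normalized weights over (label, year) strata defining the case draw.

    Weights describe how a structured case collection samples the population
    strata (typically proportional to population x prevalence x year-of-birth
    frequency).  They are normalized to sum to one on construction.
    """

    weights: Mapping[tuple, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if not w:
            raise ValueError("mixture needs at least one stratum")
        if any(v < 0 for v in w.values()):
            raise ValueError("mixture weights must be non-negative")
        total = sum(w.values())
        if total <= 0:
            raise ValueError("mixture weights must not all be zero")
        object.__setattr__(
            self, "weights", {k: v / total for k, v in w.items()}
        )


def read_month_tables(path) -> list[MonthOfBirthTable]:
    """Read a births CSV into a list of :class:`MonthOfBirthTable`.

    Expected columns: ``label, year, month, count`` plus optional
    ``latitude`` and ``sex``.  Each (label, year, sex) stratum must supply
    all 12 months exactly once; missing months are an error, never
    zero-filled.  Grouping is deterministic (sorted by label, year, sex)
    regardless of row order in the file.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"label", "year", "month", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"births CSV missing columns: {sorted(missing)}")
    if "sex" not in df.columns:
        df["sex"] = "all"
    df["sex"] = df["sex"].fillna("all")
    if "latitude" not in df.columns:
        df["latitude"] = np.nan
    # pooled tables carry no single birth year; empty year round-trips as None
    df["year"] = df["year"].fillna(_POOLED_YEAR)

    months = df["month"].to_numpy()
    if np.any((months < 1) | (months > 12)):
        raise ValueError("month values must lie in 1..12")
    if np.any(df["count"].to_numpy(dtype=float) < 0):
        raise ValueError("counts must be non-negative")
    dup = df.duplicated(subset=["label", "year", "sex", "month"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate row for ({row['label']}, {row['year']}, "
            f"{row['sex']}, month {row['month']})"
        )

    tables = []
    for (label, year, sex), grp in sorted(
        df.groupby(["label", "year", "sex"], sort=False),
        key=lambda kv: (str(kv[0][0]), int(kv[0][1]), str(kv[0][2])),
    ):
        if len(grp) != 12:
            raise ValueError(
                f"incomplete year for ({label}, {year}, {sex}): "
                f"{len(grp)} of 12 months present"
            )
        grp = grp.sort_values("month")
        lat = grp["latitude"].iloc[0]
        tables.append(
            MonthOfBirthTable(
                label=str(label),
                year=None if int(year) == _POOLED_YEAR else int(year),
                counts=grp["count"].to_numpy(dtype=float),
                latitude=None if pd.isna(lat) else float(lat),
                sex=str(sex),
            )
        )
    return tables


def write_month_tables(tables: Sequence[MonthOfBirthTable], path) -> None:
    """Write tables to the births CSV schema read by :func:`read_month_tables`.

    Floats are written at full precision so a write/read round trip
    reproduces counts bit-exactly.
    """
    rows = []
    for t in tables:
        for m in range(12):
            rows.append(
                {
                    "label": t.label,
                    "year": t.year,
                    "month": m + 1,
                    "count": t.counts[m],
                    "latitude": t.latitude,
                    "sex": t.sex,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=None)


def read_region_stats(path) -> list[RegionStat]:
    """Read a regions CSV (``name, population, prevalence, exposure_freq``
    plus optional ``latitude``) into a list of :class:`RegionStat`,
    preserving row order."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"name", "population", "prevalence", "exposure_freq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"regions CSV missing columns: {sorted(missing)}")
    if "latitude" not in df.columns:
        df["latitude"] = np.nan
    regions = []
    for _, row in df.iterrows():
        try:
            population = float(row["population"])
            prevalence = float(row["prevalence"])
            freq = float(row["exposure_freq"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric field in region row {row['name']!r}") from exc
        lat = row["latitude"]
        regions.append(
            RegionStat(
                name=str(row["name"]),
                population=population,
                prevalence=prevalence,
                exposure_freq=freq,
                latitude=None if pd.isna(lat) else float(lat),
            )
        )
    return regions


def write_region_stats(regions: Sequence[RegionStat], path) -> None:
    pd.DataFrame(
        [
            {
                "name": r.name,
                "population": r.population,
                "prevalence": r.prevalence,
                "exposure_freq": r.exposure_freq,
                "latitude": r.latitude,
            }
            for r in regions
        ]
    ).to_csv(path, index=False)


def load_uk_regions() -> list[RegionStat]:
    """The packaged UK Government Office Region table.

    Mid-2010 populations of the 11 UK Government Office Regions with
    multiple sclerosis prevalence per 100,000 and the regional frequency (%)
    of the C allele of rs1042712 (lactase gene).  The population-weighted
    summary of this table is prevalence 147.88 and allele frequency 11.58%.
    """
    ref = resources.files("natalstrat").joinpath("data/uk_gor_regions.csv")
    with resources.as_file(ref) as p:
        return read_region_stats(p)
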