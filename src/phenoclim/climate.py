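"""Climate covariates: winter precipitation and spring maximum temperature.

The pheno-climatic models use two site-specific covariates derived from a
monthly climate table (`id,year,month,ppt_mm,tmax_c`, one row per month;
`id` keys the specimen or its site):

* **winter precipitation** — cumulative precipitation over December of the
  year before collection plus January and February of the collection year
  (the "previous winter"; mm);
* **spring T_max** — the mean of the March, April and May monthly maximum
  temperatures of the collection year (°C).

Climate acquisition (PRISM download, raster extraction) is out of scope:
any gridded product can be pre-extracted to the monthly CSV contract.
Missing months are never imputed — specimens without full coverage are
rejected explicitly so the model data stay auditable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import PhenoclimError, SpecimenRecord, StageScheme, DEFAULT_SCHEME, ValidationError

WINTER_MONTHS = (12, 1, 2)  # Dec belongs to the previous calendar year
SPRING_MONTHS = (3, 4, 5)

#: Column contract of the analysis table consumed by the models.
ANALYSIS_COLUMNS = ("sheet_id", "doy", "pi", "winter_ppt_mm", "spring_tmax_c")


class MissingClimateError(PhenoclimError):
    """A month required for a covariate window is absent from the table."""

    def __init__(self, site_id: str, year: int, month: int):
        self.site_id, self.year, self.month = site_id, year, month
        super().__init__(f"no climate row for id={site_id!r}, year={year}, month={month}")


@dataclass(frozen=True)
class ClimateCovariates:
    """Winter precipitation (mm) and spring mean maximum temperature (°C)."""

    sheet_id: str
    winter_ppt: float
    spring_tmax: float


def read_climate_table(path: str | os.PathLike) -> pd.DataFrame:
    """Load and validate a monthly climate CSV."""
    df = pd.read_csv(path, dtype={"id": str})
    return validate_climate_table(df)


def validate_climate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("id", "year", "month", "ppt_mm", "tmax_c") if c not in df.columns]
    if missing:
        raise ValidationError(f"climate table is missing columns {missing}")
    if (df["ppt_mm"] < 0).any():
        raise ValidationError("climate table has negative precipitation")
    if df.duplicated(subset=["id", "year", "month"]).any():
        dup = df[df.duplicated(subset=["id", "year", "month"])].iloc[0]
        raise ValidationError(
            f"duplicate climate row for id={dup['id']!r}, year={dup['year']}, month={dup['month']}"
        )
    if not df["month"].between(1, 12).all():
        raise ValidationError("climate table has months outside 1..12")
    return df


def _lookup(clim: pd.DataFrame, site_id: str, year: int, month: int, column: str) -> float:
    rows = clim[
        (clim["id"] == str(site_id)) & (clim["year"] == year) & (clim["month"] == month)
    ]
    if rows.empty:
        raise MissingClimateError(site_id, year, month)
    return float(rows.iloc[0][column])


def winter_precip(clim: pd.DataFrame, sheet_id: str, collection_year: int) -> float:
    """Cumulative Dec(y-1) + Jan(y) + Feb(y) precipitation in mm."""
    total = 0.0
    for month in WINTER_MONTHS:
        year = collection_year - 1 if month == 12 else collection_year
        total += _lookup(clim, sheet_id, year, month, "ppt_mm")
    return total


def spring_tmax(clim: pd.DataFrame, sheet_id: str, collection_year: int) -> float:
    """Mean of the March–May monthly maximum temperatures (°C)."""
    values = [_lookup(clim, sheet_id, collection_year, m, "tmax_c") for m in SPRING_MONTHS]
    return sum(values) / len(values)


def covariates_for(clim: pd.DataFrame, sheet_id: str, collection_year: int) -> ClimateCovariates:
    return ClimateCovariates(
        sheet_id=str(sheet_id),
        winter_ppt=winter_precip(clim, sheet_id, collection_year),
        spring_tmax=spring_tmax(clim, sheet_id, collection_year),
    )


def attach_covariates(
    records: Sequence[SpecimenRecord], clim: pd.DataFrame
) -> tuple[pd.DataFrame, list[dict]]:
    """Build the analysis table: one row per specimen with DOY, PI, climate.

    Specimens lacking any required climate month go to the rejects list,
    never silently; row count + reject count always equals the input count.
    """
    validate_climate_table(clim)
    # one hashed index instead of a frame scan per specimen-month
    index: dict[tuple[str, int, int], tuple[float, float]] = {
        (str(i), int(y), int(m)): (float(p), float(t))
        for i, y, m, p, t in zip(
            clim["id"], clim["year"], clim["month"], clim["ppt_mm"], clim["tmax_c"]
        )
    }

    def window(site: str, year: int) -> ClimateCovariates:
        total = 0.0
        for month in WINTER_MONTHS:
            y = year - 1 if month == 12 else year
            try:
                total += index[(site, y, month)][0]
            except KeyError:
                raise MissingClimateError(site, y, month) from None
        temps = []
        for month in SPRING_MONTHS:
            try:
                temps.append(index[(site, year, month)][1])
            except KeyError:
                raise MissingClimateError(site, year, month) from None
        return ClimateCovariates(site, total, sum(temps) / len(temps))

    rows: list[dict] = []
    rejects: list[dict] = []
    for rec in records:
        try:
            cov = window(str(rec.sheet_id), rec.collection_date.year)
        except MissingClimateError as exc:
            rejects.append(
                {"sheet_id": rec.sheet_id, "reason": str(exc), "year": exc.year,
                 "month": exc.month}
            )
            continue
        rows.append(
            {
                "sheet_id": rec.sheet_id,
                "doy": rec.doy,
                "pi": rec.sheet_pi.value,
                "winter_ppt_mm": cov.winter_ppt,
                "spring_tmax_c": cov.spring_tmax,
            }
        )
    return pd.DataFrame(rows, columns=list(ANALYSIS_COLUMNS)), rejects


def build_analysis_table(
    counts,
    metadata: pd.DataFrame,
    clim: pd.DataFrame,
    scheme: StageScheme = DEFAULT_SCHEME,
) -> tuple[pd.DataFrame, list[dict]]:
    """Counts + metadata + monthly climate -> analysis table (+ all rejects)."""
    from .core import build_specimen_records

    records, rejects = build_specimen_records(counts, metadata, scheme)
    table, climate_rejects = attach_covariates(records, clim)
    return table, rejects + climate_rejects
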