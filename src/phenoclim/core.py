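"""Phenological index and specimen-record construction.

The phenological index (PI) of a plant is the weighted mean of the stage
weights of its reproductive units:

    PI = sum_x p_x * i_x

where ``p_x`` is the proportion of reproductive units in phenophase ``x``
and ``i_x`` the integer weight of that phenophase (bud = 1, open flower = 2,
immature fruit = 3, mature fruit = 4 under the default scheme).  PI = 1
means every unit is a bud; PI = 4 means every unit is a mature fruit.  A
herbarium sheet bearing several plants receives the unweighted mean of its
plants' PI values.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("phenoclim")


class PhenoclimError(Exception):
    """Base class for package errors."""


class NoReproductiveUnitsError(PhenoclimError):
    """Raised when a PI is requested for a plant/sheet without any units."""


class ValidationError(PhenoclimError):
    """Raised for invalid counts, dates or schemes."""


class JoinError(PhenoclimError):
    """Raised when counts cannot be joined to specimen metadata."""


# ---------------------------------------------------------------------------
# Stage scheme


@dataclass(frozen=True)
class StageScheme:
    """Ordered phenophase classes and their stage weights.

    Weights must be strictly increasing; they carry the "degree of
    phenological advancement" of each class and are the values averaged by
    the PI.  The scheme generalises to any number of classes.
    """

    classes: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValidationError("a StageScheme needs at least one class")
        ws = [w for _, w in self.classes]
        if any(b <= a for a, b in zip(ws, ws[1:])):
            raise ValidationError(f"stage weights must be strictly increasing, got {ws}")
        names = [n for n, _ in self.classes]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate class names in scheme: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.classes)

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(w for _, w in self.classes)

    @property
    def min_weight(self) -> float:
        return self.classes[0][1]

    @property
    def max_weight(self) -> float:
        return self.classes[-1][1]

    @property
    def n_transitions(self) -> int:
        """Number of stage-to-stage transitions (k - 1 for k classes)."""
        return len(self.classes) - 1

    def weight_of(self, name: str) -> float:
        for n, w in self.classes:
            if n == name:
                return w
        raise KeyError(name)


#: Default four-class scheme: buds = 1, open flowers = 2, immature fruits = 3,
#: mature fruits = 4.
DEFAULT_SCHEME = StageScheme(
    (("bud", 1.0), ("flower", 2.0), ("immature_fruit", 3.0), ("mature_fruit", 4.0))
)


# ---------------------------------------------------------------------------
# Counts and indices


@dataclass(frozen=True)
class PlantCounts:
    """Counts of reproductive units per phenophase class for one plant."""

    sheet_id: str
    plant_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValidationError(
                    f"count for class {name!r} of plant {self.plant_id!r} "
                    f"(sheet {self.sheet_id!r}) must be a non-negative integer, got {c!r}"
                )

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def validate_against(self, scheme: StageScheme) -> None:
        if set(self.counts) != set(scheme.names):
            raise ValidationError(
                f"plant {self.plant_id!r}: count classes {sorted(self.counts)} do not "
                f"match scheme classes {sorted(scheme.names)}"
            )


@dataclass(frozen=True)
class PhenologicalIndex:
    """A PI value with the number of units and plants behind it."""

    value: float
    n_units: int
    n_plants: int = 1

    def __format__(self, spec: str) -> str:
        return format(self.value, spec or ".2f")


def compute_pi(counts: PlantCounts, scheme: StageScheme = DEFAULT_SCHEME) -> PhenologicalIndex:
    """PI of a single plant: weighted mean of stage weights by unit counts.

    Raises :class:`NoReproductiveUnitsError` if the plant bears no
    reproductive units (PI is undefined for such plants).
    """
    counts.validate_against(scheme)
    total = counts.total
    if total == 0:
        raise NoReproductiveUnitsError(
            f"plant {counts.plant_id!r} on sheet {counts.sheet_id!r} has no reproductive units"
        )
    value = sum(counts.counts[name] * w for name, w in scheme.classes) / total
    return PhenologicalIndex(value=value, n_units=total, n_plants=1)


def sheet_pi(
    plants: Sequence[PlantCounts], scheme: StageScheme = DEFAULT_SCHEME, *, pooled: bool = False
) -> PhenologicalIndex:
    """Sheet-level PI: unweighted mean of the per-plant PI values.

    Plants without reproductive units are excluded (their PI is undefined);
    at least one plant must contribute.  With ``pooled=True`` the counts of
    all plants are pooled first and a single PI computed — an alternative
    that weights plants by their unit numbers.
    """
    contributing = [p for p in plants if p.total > 0]
    if not contributing:
        raise NoReproductiveUnitsError("no plant on this sheet has reproductive units")
    if pooled:
        merged = {
            name: sum(p.counts[name] for p in contributing) for name in scheme.names
        }
        pooled_counts = PlantCounts(
            sheet_id=contributing[0].sheet_id, plant_id="<pooled>", counts=merged
        )
        pi = compute_pi(pooled_counts, scheme)
        return PhenologicalIndex(pi.value, pi.n_units, n_plants=len(contributing))
    pis = [compute_pi(p, scheme) for p in contributing]
    value = sum(p.value for p in pis) / len(pis)
    return PhenologicalIndex(
        value=value, n_units=sum(p.n_units for p in pis), n_plants=len(pis)
    )


def date_to_doy(d: _dt.date) -> int:
    """Ordinal day of year of a calendar date (January 1 = 1).

    July 4 is day 185 in a common year and 186 in a leap year.
    """
    if not isinstance(d, _dt.date):
        raise ValidationError(f"expected a datetime.date, got {type(d).__name__}")
    return d.timetuple().tm_yday


# ---------------------------------------------------------------------------
# Specimen records


@dataclass
class SpecimenRecord:
    """One herbarium sheet joined to its metadata, with the sheet PI."""

    sheet_id: str
    collection_date: _dt.date
    doy: int
    latitude: float
    longitude: float
    plants: list[PlantCounts] = field(default_factory=list)
    sheet_pi: PhenologicalIndex | None = None


def _parse_date(value, sheet_id: str) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValidationError(
            f"sheet {sheet_id!r}: cannot parse collection date {value!r} (ISO-8601 expected)"
        ) from exc


def build_specimen_records(
    counts: Iterable[PlantCounts],
    metadata: pd.DataFrame,
    scheme: StageScheme = DEFAULT_SCHEME,
) -> tuple[list[SpecimenRecord], list[dict]]:
    """Join per-plant counts to the specimen metadata table.

    ``metadata`` needs columns ``sheet_id, collection_date, latitude,
    longitude`` with one row per sheet.  Sheets whose plants bear no
    reproductive units cannot receive a PI; they are dropped to the returned
    rejects list (and logged), never silently.

    Returns ``(records, rejects)``.
    """
    required = {"sheet_id", "collection_date", "latitude", "longitude"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValidationError(f"metadata table is missing columns: {sorted(missing)}")
    if metadata["sheet_id"].duplicated().any():
        dups = metadata.loc[metadata["sheet_id"].duplicated(), "sheet_id"].tolist()
        raise JoinError(f"duplicate sheet_id in metadata: {dups}")
    meta = metadata.set_index(metadata["sheet_id"].astype(str))

    by_sheet: dict[str, list[PlantCounts]] = {}
    for pc in counts:
        pc.validate_against(scheme)
        by_sheet.setdefault(str(pc.sheet_id), []).append(pc)

    records: list[SpecimenRecord] = []
    rejects: list[dict] = []
    for sid, plants in by_sheet.items():
        if sid not in meta.index:
            raise JoinError(f"sheet {sid!r} has counts but no metadata row")
        row = meta.loc[sid]
        date = _parse_date(row["collection_date"], sid)
        try:
            spi = sheet_pi(plants, scheme)
        except NoReproductiveUnitsError:
            logger.warning("sheet %s dropped: no plant has reproductive units", sid)
            rejects.append({"sheet_id": sid, "reason": "no reproductive units"})
            continue
        records.append(
            SpecimenRecord(
                sheet_id=sid,
                collection_date=date,
                doy=date_to_doy(date),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                plants=plants,
                sheet_pi=spi,
            )
        )
    return records, rejects


def records_to_frame(records: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Tabulate records as the output-records CSV contract."""
    return pd.DataFrame(
        {
            "sheet_id": [r.sheet_id for r in records],
            "collection_date": [r.collection_date.isoformat() for r in records],
            "latitude": [r.latitude for r in records],
            "longitude": [r.longitude for r in records],
            "doy": [r.doy for r in records],
            "sheet_pi": [r.sheet_pi.value for r in records],
            "n_plants": [r.sheet_pi.n_plants for r in records],
        }
    )


def filter_by_pi(
    records: Sequence[SpecimenRecord], lo: float | None = None, hi: float | None = None
) -> list[SpecimenRecord]:
    """Subset records whose sheet PI lies in the closed interval [lo, hi]."""
    out = []
    for r in records:
        v = r.sheet_pi.value
        if (lo is None or v >= lo) and (hi is None or v <= hi):
            out.append(r)
    return out
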