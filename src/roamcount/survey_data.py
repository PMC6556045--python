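"""Domain types, validation and CSV I/O for road-based dog sighting surveys.

A *sighting* is one free-roaming dog seen from the survey vehicle, with its
paint-mark status and the surveyor's estimate of its perpendicular distance
from the transect line.  Sightings are grouped into :class:`ZoneSurvey`
objects, one per (working zone, survey day, route type) combination, carrying
the zone-level metadata both estimators need: the number of dogs initially
marked during the vaccination round (``n1``), the length of road driven, and
the area of the 100 m road buffer the zone covers.

The interchange format is a single flat CSV: one row per sighted dog, with the
zone metadata repeated on every row.  A zone surveyed without any sightings is
represented by a single metadata-only row whose sighting columns are empty.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "RouteType",
    "TimeOfDay",
    "SightingRecord",
    "ZoneSurvey",
    "StudyDataset",
    "SchemaError",
    "RowValidationError",
    "read_sightings",
    "write_sightings",
    "zone_counts",
    "SIGHTING_COLUMNS",
]


class SchemaError(ValueError):
    """The CSV is missing a required column or is otherwise malformed."""


class RowValidationError(ValueError):
    """A row holds an invalid value; carries the offending row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class RouteType(str, enum.Enum):
    """Whether the survey drove every road in the zone or only a subset."""

    ALL_ROADS = "all_roads"
    SUBSET = "subset"


class TimeOfDay(str, enum.Enum):
    MORNING = "morning"
    AFTERNOON = "afternoon"


@dataclass(frozen=True)
class SightingRecord:
    """One sighted dog.

    Parameters
    ----------
    zone_id:
        Working-zone identifier.
    survey_day:
        1 for the first survey, 2 for the repeat on the following day.
    route_type:
        Route driven when the dog was seen.
    marked:
        Whether a paint mark (applied at vaccination) was visible.
    perp_distance_m:
        Estimated perpendicular distance from the transect line, metres.
    surveyor_id:
        Identifier of the surveyor.
    time_of_day:
        Morning or afternoon survey.
    """

    zone_id: str
    survey_day: int
    route_type: RouteType
    marked: bool
    perp_distance_m: float
    surveyor_id: str = "A"
    time_of_day: TimeOfDay = TimeOfDay.MORNING

    def __post_init__(self):
        if self.survey_day not in (1, 2):
            raise ValueError(f"survey_day must be 1 or 2, got {self.survey_day}")
        if not math.isfinite(self.perp_distance_m) or self.perp_distance_m < 0:
            raise ValueError(
                f"perp_distance_m must be finite and >= 0, got {self.perp_distance_m}"
            )


@dataclass
class ZoneSurvey:
    """All sightings of one zone on one survey (day, route) plus metadata.

    ``n_marked_initial`` is the number of dogs vaccinated and paint-marked in
    the zone (the mark-resight ``n1``); ``road_length_m`` is the length of
    road actually driven on this route; ``buffer_area_m2`` the area within
    100 m of the zone's road network.
    """

    zone_id: str
    survey_day: int
    route_type: RouteType
    n_marked_initial: int
    road_length_m: float
    buffer_area_m2: float
    sightings: list[SightingRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.n_marked_initial < 0:
            raise ValueError("n_marked_initial must be >= 0")
        if self.road_length_m <= 0:
            raise ValueError("road_length_m must be > 0")
        if self.buffer_area_m2 <= 0:
            raise ValueError("buffer_area_m2 must be > 0")
        for s in self.sightings:
            if (s.zone_id, s.survey_day, s.route_type) != (
                self.zone_id,
                self.survey_day,
                self.route_type,
            ):
                raise ValueError(
                    f"sighting key {(s.zone_id, s.survey_day, s.route_type)} "
                    f"does not match zone key "
                    f"{(self.zone_id, self.survey_day, self.route_type)}"
                )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.zone_id, self.survey_day, self.route_type.value)

    def distances(self) -> list[float]:
        return [s.perp_distance_m for s in self.sightings]


@dataclass
class StudyDataset:
    """A full study: zone surveys keyed by (zone_id, survey_day, route_type)."""

    zones: list[ZoneSurvey] = field(default_factory=list)

    def __post_init__(self):
        keys = [z.key for z in self.zones]
        if len(keys) != len(set(keys)):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (zone, day, route) groups: {dup}")

    def __len__(self) -> int:
        return len(self.zones)

    def __iter__(self):
        return iter(self.zones)

    def get(self, zone_id: str, survey_day: int, route_type: RouteType) -> ZoneSurvey:
        key = (zone_id, survey_day, RouteType(route_type).value)
        for z in self.zones:
            if z.key == key:
                return z
        raise KeyError(key)

    def select(
        self,
        survey_day: int | None = None,
        route_type: RouteType | None = None,
    ) -> "StudyDataset":
        """Subset of surveys matching the given day and/or route type."""
        out = [
            z
            for z in self.zones
            if (survey_day is None or z.survey_day == survey_day)
            and (route_type is None or z.route_type == RouteType(route_type))
        ]
        return StudyDataset(out)


# CSV schema ------------------------------------------------------------------

#: Per-sighting columns; empty on metadata-only rows for zero-sighting zones.
SIGHTING_COLUMNS = ["marked", "perp_distance_m", "surveyor_id", "time_of_day"]

#: Grouping key + zone metadata; required and constant within each group.
_KEY_COLUMNS = ["zone_id", "survey_day", "route_type"]
_META_COLUMNS = ["n_marked_initial", "road_length_m", "buffer_area_m2"]
_ALL_COLUMNS = _KEY_COLUMNS + SIGHTING_COLUMNS + _META_COLUMNS

_BOOL_MAP = {"true": True, "false": False}


def _parse_bool(raw, idx: int) -> bool:
    if isinstance(raw, bool):
        return raw
    key = str(raw).strip().lower()
    if key not in _BOOL_MAP:
        raise RowValidationError(idx, f"marked must be 'true' or 'false', got {raw!r}")
    return _BOOL_MAP[key]


def read_sightings(path: Union[str, Path]) -> StudyDataset:
    """Read a sightings CSV into a validated :class:`StudyDataset`.

    The CSV must carry the full schema (key, sighting and metadata columns);
    rows are grouped by (zone_id, survey_day, route_type), and zone metadata
    must be identical on every row of a group.  Rows with all sighting columns
    empty declare a zone surveyed with zero sightings.

    Raises
    ------
    SchemaError
        If a required column is missing.
    RowValidationError
        If a row holds a negative distance, an unknown enum value, or
        metadata inconsistent with its group.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _ALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return StudyDataset([])

    zones: dict[tuple, ZoneSurvey] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            zone_id = str(getattr(row, "zone_id"))
            survey_day = int(getattr(row, "survey_day"))
            route_type = RouteType(getattr(row, "route_type"))
            n1 = int(getattr(row, "n_marked_initial"))
            road_length = float(getattr(row, "road_length_m"))
            area = float(getattr(row, "buffer_area_m2"))
        except (ValueError, KeyError) as exc:
            raise RowValidationError(idx, str(exc)) from exc

        key = (zone_id, survey_day, route_type.value)
        meta = (n1, road_length, area)
        if key in zones:
            zone = zones[key]
            if (zone.n_marked_initial, zone.road_length_m, zone.buffer_area_m2) != meta:
                raise RowValidationError(
                    idx, f"zone metadata conflicts with earlier rows of group {key}"
                )
        else:
            zone = ZoneSurvey(
                zone_id=zone_id,
                survey_day=survey_day,
                route_type=route_type,
                n_marked_initial=n1,
                road_length_m=road_length,
                buffer_area_m2=area,
            )
            zones[key] = zone

        sighting_raw = {c: str(getattr(row, c)).strip() for c in SIGHTING_COLUMNS}
        if all(v == "" for v in sighting_raw.values()):
            continue  # metadata-only row
        try:
            rec = SightingRecord(
                zone_id=zone_id,
                survey_day=survey_day,
                route_type=route_type,
                marked=_parse_bool(sighting_raw["marked"], idx),
                perp_distance_m=float(sighting_raw["perp_distance_m"]),
                surveyor_id=sighting_raw["surveyor_id"] or "A",
                time_of_day=TimeOfDay(sighting_raw["time_of_day"] or "morning"),
            )
        except RowValidationError:
            raise
        except ValueError as exc:
            raise RowValidationError(idx, str(exc)) from exc
        zone.sightings.append(rec)

    return StudyDataset(list(zones.values()))


def write_sightings(dataset: StudyDataset, path: Union[str, Path]) -> None:
    """Write a dataset to CSV such that :func:`read_sightings` round-trips it.

    Booleans are written as ``true``/``false``; a zone with no sightings gets
    one metadata-only row so its metadata survives the round trip.
    """
    rows = []
    for zone in dataset:
        meta = {
            "zone_id": zone.zone_id,
            "survey_day": zone.survey_day,
            "route_type": zone.route_type.value,
            "n_marked_initial": zone.n_marked_initial,
            "road_length_m": zone.road_length_m,
            "buffer_area_m2": zone.buffer_area_m2,
        }
        if not zone.sightings:
            rows.append(
                {**meta, "marked": "", "perp_distance_m": "", "surveyor_id": "",
                 "time_of_day": ""}
            )
            continue
        for s in zone.sightings:
            rows.append(
                {
                    **meta,
                    "marked": "true" if s.marked else "false",
                    "perp_distance_m": s.perp_distance_m,
                    "surveyor_id": s.surveyor_id,
                    "time_of_day": s.time_of_day.value,
                }
            )
    pd.DataFrame(rows, columns=_ALL_COLUMNS).to_csv(path, index=False)


def zone_counts(zone: ZoneSurvey) -> tuple[int, int, int]:
    """Mark-resight counts ``(n1, n2, m)`` for one zone survey.

    ``n1`` is the number of dogs initially marked, ``n2`` the number of dogs
    sighted on this survey, and ``m`` the number of those that were marked.
    ``m <= n2`` holds by construction; ``m`` versus ``n1`` is not constrained
    (double counting of moving dogs can in principle push ``m`` past ``n1``).
    """
    n2 = len(zone.sightings)
    m = sum(1 for s in zone.sightings if s.marked)
    return (zone.n_marked_initial, n2, m)
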