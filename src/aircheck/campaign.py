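"""Measurement-campaign records: reading, validation, writing and grouping.

A campaign is a long-format table of single concentration observations taken
on a fixed crossover schedule: four weeks, three sampling days per week
(Mon/Wed/Fri), two sessions per day (morning/afternoon), at two points inside
the intensive-care unit plus one unoccupied isolated room. The air-cleaning
devices are off in weeks 1 and 4 and on in weeks 2 and 3, which makes the
experimental phase derivable from the week alone:

    week 1 → off_pre     (baseline, before the devices ran)
    weeks 2–3 → on
    week 4 → off_post    (devices switched off again)

Records whose stored ACD state disagrees with their week raise a
:class:`~aircheck.errors.ConsistencyWarning` by default (real campaigns can
deviate from plan); ``strict=True`` upgrades the warning to an error.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import CampaignValidationError, ConsistencyWarning, DomainError
from .reference import normalize_compound_id


class Phase(str, enum.Enum):
    """Crossover phase of the air-cleaning intervention."""

    OFF_PRE = "off_pre"
    ON = "on"
    OFF_POST = "off_post"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


DAYS = ("Mon", "Wed", "Fri")
SESSIONS = ("morning", "afternoon")
ICU_LOCATIONS = ("icu_point_1", "icu_point_2")
LOCATIONS = ICU_LOCATIONS + ("isolated_room",)
ACD_STATES = ("off", "on")

#: ACD state implied by the crossover design, per week.
_WEEK_TO_STATE = {1: "off", 2: "on", 3: "on", 4: "off"}


def derive_phase(week: int) -> Phase:
    """Experimental phase implied by the sampling week (1–4)."""
    if week == 1:
        return Phase.OFF_PRE
    if week in (2, 3):
        return Phase.ON
    if week == 4:
        return Phase.OFF_POST
    raise DomainError(f"week must be in 1..4, got {week!r}")


@dataclass(frozen=True)
class MeasurementRecord:
    """One concentration observation with its campaign context."""

    sample_id: str
    week: int
    day: str
    session: str
    location: str
    acd_state: str
    compound_id: str
    concentration_ugm3: float
    occupancy: int | None = None
    temperature_c: float | None = None
    rh_percent: float | None = None

    @property
    def phase(self) -> Phase:
        return derive_phase(self.week)


CAMPAIGN_CSV_FIELDS = [f.name for f in fields(MeasurementRecord)]


def _parse_row(row: dict[str, str], rownum: int, strict: bool) -> MeasurementRecord:
    def bad(msg: str) -> CampaignValidationError:
        return CampaignValidationError(rownum, msg)

    try:
        week = int(row["week"])
    except ValueError:
        raise bad(f"week {row['week']!r} is not an integer") from None
    if week not in (1, 2, 3, 4):
        raise bad(f"week {week} outside the 4-week design")
    if row["day"] not in DAYS:
        raise bad(f"day {row['day']!r} not one of {DAYS}")
    if row["session"] not in SESSIONS:
        raise bad(f"session {row['session']!r} not one of {SESSIONS}")
    if row["location"] not in LOCATIONS:
        raise bad(f"location {row['location']!r} not one of {LOCATIONS}")
    if row["acd_state"] not in ACD_STATES:
        raise bad(f"acd_state {row['acd_state']!r} not one of {ACD_STATES}")
    try:
        conc = float(row["concentration_ugm3"])
    except ValueError:
        raise bad(f"concentration {row['concentration_ugm3']!r} is not a number") from None
    if conc < 0:
        raise bad(f"negative concentration {conc}")
    expected = _WEEK_TO_STATE[week]
    if row["acd_state"] != expected:
        msg = (
            f"row {rownum}: acd_state {row['acd_state']!r} inconsistent with week {week} "
            f"(crossover design implies {expected!r})"
        )
        if strict:
            raise CampaignValidationError(rownum, msg)
        warnings.warn(msg, ConsistencyWarning, stacklevel=3)

    def opt(key: str, conv: Callable[[str], object]):
        raw = (row.get(key) or "").strip()
        if not raw:
            return None
        try:
            return conv(raw)
        except ValueError:
            raise bad(f"{key} {raw!r} is not valid") from None

    compound = normalize_compound_id(row["compound_id"])
    if not compound:
        raise bad("empty compound_id")
    return MeasurementRecord(
        sample_id=row["sample_id"],
        week=week,
        day=row["day"],
        session=row["session"],
        location=row["location"],
        acd_state=row["acd_state"],
        compound_id=compound,
        concentration_ugm3=conc,
        occupancy=opt("occupancy", int),
        temperature_c=opt("temperature_c", float),
        rh_percent=opt("rh_percent", float),
    )


def read_campaign(path: str | Path, strict: bool = False) -> list[MeasurementRecord]:
    """Read and validate a campaign CSV.

    Every row is validated (schema, ranges, non-negative concentration) and
    errors carry the 1-based data row number. With ``strict=True``, an ACD
    state inconsistent with the crossover week is an error instead of a
    :class:`ConsistencyWarning`.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CampaignValidationError(None, f"{path}: empty file")
        missing = [c for c in CAMPAIGN_CSV_FIELDS if c not in reader.fieldnames]
        if missing:
            raise CampaignValidationError(None, f"{path}: header missing columns {missing}")
        records = []
        for rownum, row in enumerate(reader, start=1):
            if any(v is None for v in row.values()):
                raise CampaignValidationError(rownum, "short row (fewer cells than header)")
            records.append(_parse_row(row, rownum, strict))
    return records


def write_campaign(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    """Write records to CSV; floats use ``repr`` so a read-back is lossless."""

    def cell(v: object) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CAMPAIGN_CSV_FIELDS)
        for r in records:
            w.writerow([cell(getattr(r, name)) for name in CAMPAIGN_CSV_FIELDS])


#: Grouping keys accepted by :func:`split_by`; ``phase`` is derived from week.
_KEY_GETTERS: dict[str, Callable[[MeasurementRecord], object]] = {
    "phase": lambda r: r.phase,
    "location": lambda r: r.location,
    "compound": lambda r: r.compound_id,
    "session": lambda r: r.session,
    "acd_state": lambda r: r.acd_state,
}


def split_by(
    records: Sequence[MeasurementRecord], keys: Sequence[str]
) -> dict[tuple, list[MeasurementRecord]]:
    """Partition records by one or more design keys.

    Group keys are tuples in ``keys`` order; the groups are disjoint and their
    union is the input (a true partition). Unknown keys raise ``ValueError``.
    """
    getters = []
    for key in keys:
        if key not in _KEY_GETTERS:
            raise ValueError(f"unknown grouping key {key!r}; valid: {sorted(_KEY_GETTERS)}")
        getters.append(_KEY_GETTERS[key])
    groups: dict[tuple, list[MeasurementRecord]] = {}
    for r in records:
        groups.setdefault(tuple(g(r) for g in getters), []).append(r)
    return groups


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a campaign, with the derived ``phase`` column."""
    df = pd.DataFrame([vars(r) for r in records], columns=CAMPAIGN_CSV_FIELDS)
    if len(df):
        df["phase"] = [r.phase.value for r in records]
    else:
        df["phase"] = pd.Series(dtype=object)
    return df
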