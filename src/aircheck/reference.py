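"""Compound panel, toxicology references, guideline limits and exposure scenarios.

This module holds the shared reference data for the 14-compound aromatic VOC
panel monitored in the intensive-care-unit campaign:

* the measurement panel itself (benzene through naphthalene; TVOC is a derived
  sum, never a panel member);
* per-compound toxicology — IARC carcinogenicity group, inhalation unit risk
  (IUR, per µg/m³) and non-cancer reference concentration (RfC, µg/m³), with
  free-text sources (WHO, OEHHA, ATSDR);
* indoor-air guideline limits for benzene and TVOC from EPA/WHO/ASHRAE and the
  Turkish safe-green buildings standard (TSGBS);
* the healthcare-worker exposure scenario (ET, EF, ED, AT) used by the risk
  engine, and the A–D lifetime cancer-risk class scheme.

Two exposure-frequency values are carried side by side: the nominally stated
260 working days/year, and a calibrated 257 days/year under which the published
cancer-risk table is reproduced to well under 1% (see ``EF_CALIBRATED``).
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

from .errors import ScenarioError, UnknownCompoundError

IarcGroup = Literal["1", "2A", "2B", "3"]
Mode = Literal["paper", "strict_epa"]

#: Exposure frequency as stated for the occupational scenario, days/year.
EF_STATED = 260.0
#: Exposure frequency under which the published risk table reproduces (≤0.5%).
EF_CALIBRATED = 257.0


@dataclass(frozen=True)
class Compound:
    """One analyte of the measurement panel."""

    id: str
    display_name: str
    in_panel: bool = True


@dataclass(frozen=True)
class ToxReference:
    """Per-compound toxicology reference values.

    ``iur`` is the inhalation unit risk in (µg/m³)⁻¹; ``rfc`` the chronic
    inhalation reference concentration in µg/m³. Either may be absent
    (``None``) — absent means "no authoritative value", never zero.
    """

    compound_id: str
    iarc_group: IarcGroup | None = None
    iur: float | None = None
    iur_source: str = ""
    rfc: float | None = None
    rfc_source: str = ""

    def __post_init__(self) -> None:
        if self.iur is not None and not self.iur > 0:
            raise ValueError(f"{self.compound_id}: IUR must be > 0 when present")
        if self.rfc is not None and not self.rfc > 0:
            raise ValueError(f"{self.compound_id}: RfC must be > 0 when present")


@dataclass(frozen=True)
class ExposureScenario:
    """Occupational inhalation-exposure scenario.

    Parameters
    ----------
    et_hours_per_day : exposure time, h/day (0 < ET ≤ 24)
    ef_days_per_year : exposure frequency, days/year (0 < EF ≤ 365)
    ed_years : exposure duration, years
    at_years : averaging time, years (ED ≤ AT; 70 y ≈ lifetime)
    mode : intake convention — ``"paper"`` keeps AT in years (reproduces the
        published tables); ``"strict_epa"`` converts AT to days, the usual
        EPA convention. Paper-mode intake is exactly 365× the strict value.
    """

    et_hours_per_day: float = 8.0
    ef_days_per_year: float = EF_CALIBRATED
    ed_years: float = 30.0
    at_years: float = 70.0
    mode: Mode = "strict_epa"

    def fingerprint(self) -> str:
        """Short stable tag for report provenance columns."""
        def fmt(x: float) -> str:
            return f"{x:g}"

        return (
            f"ET{fmt(self.et_hours_per_day)}_EF{fmt(self.ef_days_per_year)}"
            f"_ED{fmt(self.ed_years)}_AT{fmt(self.at_years)}_{self.mode}"
        )

    def with_mode(self, mode: Mode) -> "ExposureScenario":
        return replace(self, mode=mode)


def validate_scenario(scenario: ExposureScenario) -> ExposureScenario:
    """Return ``scenario`` unchanged iff all physical constraints hold.

    Raises :class:`ScenarioError` naming the offending field otherwise.
    """
    s = scenario
    for name, value in (
        ("et_hours_per_day", s.et_hours_per_day),
        ("ef_days_per_year", s.ef_days_per_year),
        ("ed_years", s.ed_years),
        ("at_years", s.at_years),
    ):
        if not math.isfinite(value) or value <= 0:
            raise ScenarioError(name, f"must be positive and finite, got {value!r}")
    if s.et_hours_per_day > 24:
        raise ScenarioError("et_hours_per_day", f"{s.et_hours_per_day} exceeds 24 h/day")
    if s.ef_days_per_year > 365:
        raise ScenarioError("ef_days_per_year", f"{s.ef_days_per_year} exceeds 365 days/year")
    if s.ed_years > s.at_years:
        raise ScenarioError(
            "ed_years", f"exposure duration {s.ed_years} exceeds averaging time {s.at_years}"
        )
    if s.mode not in ("paper", "strict_epa"):
        raise ScenarioError("mode", f"unknown mode {s.mode!r}")
    return scenario


def worker_scenario(mode: Mode = "paper", calibrated: bool = True) -> ExposureScenario:
    """The healthcare-worker scenario: 8 h/day, 30 y exposure over a 70 y lifetime.

    ``calibrated=True`` uses EF = 257 days/year (reproduces the published risk
    table); ``calibrated=False`` uses the stated 260 days/year.
    """
    return ExposureScenario(
        et_hours_per_day=8.0,
        ef_days_per_year=EF_CALIBRATED if calibrated else EF_STATED,
        ed_years=30.0,
        at_years=70.0,
        mode=mode,
    )


# --------------------------------------------------------------------------
# Panel
# --------------------------------------------------------------------------

PANEL: tuple[Compound, ...] = (
    Compound("benzene", "Benzene"),
    Compound("toluene", "Toluene"),
    Compound("ethylbenzene", "Ethylbenzene"),
    Compound("m_p_xylene", "m,p-Xylene"),
    Compound("o_xylene", "o-Xylene"),
    Compound("styrene", "Styrene"),
    Compound("isopropylbenzene", "Isopropylbenzene"),
    Compound("n_propylbenzene", "n-Propylbenzene"),
    Compound("trimethylbenzene_124", "1,2,4-Trimethylbenzene"),
    Compound("trimethylbenzene_135", "1,3,5-Trimethylbenzene"),
    Compound("sec_butylbenzene", "sec-Butylbenzene"),
    Compound("isopropyltoluene_4", "4-Isopropyltoluene"),
    Compound("n_butylbenzene", "n-Butylbenzene"),
    Compound("naphthalene", "Naphthalene"),
)

PANEL_IDS: tuple[str, ...] = tuple(c.id for c in PANEL)

#: Token used for the derived total-VOC sum in tables; never a Compound.
TVOC = "TVOC"

_SYNONYMS: dict[str, str] = {
    "m_p_xylene": "m_p_xylene",
    "mp_xylene": "m_p_xylene",
    "1_2_4_trimethylbenzene": "trimethylbenzene_124",
    "1_3_5_trimethylbenzene": "trimethylbenzene_135",
    "124_trimethylbenzene": "trimethylbenzene_124",
    "135_trimethylbenzene": "trimethylbenzene_135",
    "4_isopropyltoluene": "isopropyltoluene_4",
    "p_isopropyltoluene": "isopropyltoluene_4",
    "p_cymene": "isopropyltoluene_4",
    "cumene": "isopropylbenzene",
}


def normalize_compound_id(name: str) -> str:
    """Map a compound spelling to its canonical underscore id.

    Accepts common literature spellings (``"m,p-xylene"``,
    ``"1,2,4-Trimethylbenzene"``); unknown tokens are returned normalized but
    unmapped, so non-panel compounds can still travel through campaign files.
    """
    token = re.sub(r"[\s,.\-]+", "_", name.strip().lower()).strip("_")
    return _SYNONYMS.get(token, token)


def default_panel() -> list[Compound]:
    """The 14-compound panel in table order (benzene first, naphthalene last)."""
    return list(PANEL)


# --------------------------------------------------------------------------
# Toxicology table
# --------------------------------------------------------------------------

DEFAULT_TOX_TABLE: dict[str, ToxReference] = {
    t.compound_id: t
    for t in (
        ToxReference("benzene", "1", 6.0e-6, "WHO", 9.6, "ATSDR"),
        ToxReference("toluene", None),
        ToxReference("ethylbenzene", "2B", 2.5e-6, "OEHHA", 1300.0, "ATSDR"),
        ToxReference("m_p_xylene", "3"),
        ToxReference("o_xylene", "3"),
        ToxReference("styrene", "2A"),
        ToxReference("isopropylbenzene", None),
        ToxReference("n_propylbenzene", None),
        ToxReference("trimethylbenzene_124", None),
        ToxReference("trimethylbenzene_135", None),
        ToxReference("sec_butylbenzene", None),
        ToxReference("isopropyltoluene_4", None),
        ToxReference("n_butylbenzene", None),
        ToxReference("naphthalene", "2B", 8.7e-5, "WHO", 3.7, "ATSDR"),
    )
}


def lookup_tox(
    compound_id: str, table: Mapping[str, ToxReference] | None = None
) -> ToxReference:
    """Look up the toxicology record for a compound.

    Absent IUR/RfC come back as ``None`` — explicitly missing, not zero.
    Raises :class:`UnknownCompoundError` for ids outside the table.
    """
    table = DEFAULT_TOX_TABLE if table is None else table
    cid = normalize_compound_id(compound_id)
    try:
        return table[cid]
    except KeyError:
        raise UnknownCompoundError(compound_id) from None


# --------------------------------------------------------------------------
# Guideline limits
# --------------------------------------------------------------------------

Authority = Literal["EPA", "WHO", "ASHRAE", "TSGBS"]


@dataclass(frozen=True)
class GuidelineLimit:
    """An indoor-air limit for one analyte from one authority, µg/m³."""

    analyte: str  # "benzene" or "TVOC"
    authority: Authority
    limit_ugm3: float


DEFAULT_GUIDELINES: tuple[GuidelineLimit, ...] = (
    GuidelineLimit(TVOC, "EPA", 500.0),
    GuidelineLimit(TVOC, "WHO", 500.0),
    GuidelineLimit(TVOC, "ASHRAE", 500.0),
    GuidelineLimit(TVOC, "TSGBS", 200.0),
    GuidelineLimit("benzene", "EPA", 5.0),
    GuidelineLimit("benzene", "WHO", 5.0),
    GuidelineLimit("benzene", "ASHRAE", 5.0),
    GuidelineLimit("benzene", "TSGBS", 5.0),
)


# --------------------------------------------------------------------------
# Risk class scheme
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskClassScheme:
    """Lifetime excess cancer-risk classes.

    Boundaries are inclusive upward: CR ≥ 10⁻⁴ → A (definite risk),
    10⁻⁵ ≤ CR < 10⁻⁴ → B (probable), 10⁻⁶ ≤ CR < 10⁻⁵ → C (possible),
    CR < 10⁻⁶ → D (uncertain). Exhaustive over [0, ∞).
    """

    boundaries: tuple[tuple[float, str], ...] = (
        (1e-4, "A"),
        (1e-5, "B"),
        (1e-6, "C"),
    )
    fallback: str = "D"
    descriptions: Mapping[str, str] = field(
        default_factory=lambda: {
            "A": "definite risk",
            "B": "probable risk",
            "C": "possible risk",
            "D": "uncertain risk",
        }
    )

    def __post_init__(self) -> None:
        cuts = [b for b, _ in self.boundaries]
        if any(a <= b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("class boundaries must be strictly decreasing")

    def classify(self, cr: float) -> str:
        from .errors import DomainError

        if not cr >= 0:
            raise DomainError(f"cancer risk must be >= 0, got {cr!r}")
        for cut, label in self.boundaries:
            if cr >= cut:
                return label
        return self.fallback


DEFAULT_RISK_CLASSES = RiskClassScheme()


# --------------------------------------------------------------------------
# Reference-table CSV I/O
# --------------------------------------------------------------------------

TOX_CSV_FIELDS = [
    "compound_id",
    "iarc_group",
    "iur_per_ugm3",
    "iur_source",
    "rfc_ugm3",
    "rfc_source",
]
GUIDELINE_CSV_FIELDS = ["analyte", "authority", "limit_ugm3"]


def write_tox_table(table: Mapping[str, ToxReference], path: str | Path) -> None:
    """Write a toxicology table; absent IUR/RfC become empty cells."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=TOX_CSV_FIELDS)
        w.writeheader()
        for t in table.values():
            w.writerow(
                {
                    "compound_id": t.compound_id,
                    "iarc_group": t.iarc_group or "",
                    "iur_per_ugm3": "" if t.iur is None else repr(t.iur),
                    "iur_source": t.iur_source,
                    "rfc_ugm3": "" if t.rfc is None else repr(t.rfc),
                    "rfc_source": t.rfc_source,
                }
            )


def read_tox_table(path: str | Path) -> dict[str, ToxReference]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != TOX_CSV_FIELDS:
            raise ValueError(
                f"unexpected tox table header {reader.fieldnames}, want {TOX_CSV_FIELDS}"
            )
        out: dict[str, ToxReference] = {}
        for row in reader:
            out[row["compound_id"]] = ToxReference(
                compound_id=row["compound_id"],
                iarc_group=row["iarc_group"] or None,  # type: ignore[arg-type]
                iur=float(row["iur_per_ugm3"]) if row["iur_per_ugm3"] else None,
                iur_source=row["iur_source"],
                rfc=float(row["rfc_ugm3"]) if row["rfc_ugm3"] else None,
                rfc_source=row["rfc_source"],
            )
    return out


def write_guidelines(limits: Iterable[GuidelineLimit], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=GUIDELINE_CSV_FIELDS)
        w.writeheader()
        for g in limits:
            w.writerow(
                {"analyte": g.analyte, "authority": g.authority, "limit_ugm3": repr(g.limit_ugm3)}
            )


def read_guidelines(path: str | Path) -> list[GuidelineLimit]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != GUIDELINE_CSV_FIELDS:
            raise ValueError(
                f"unexpected guidelines header {reader.fieldnames}, want {GUIDELINE_CSV_FIELDS}"
            )
        return [
            GuidelineLimit(row["analyte"], row["authority"], float(row["limit_ugm3"]))  # type: ignore[arg-type]
            for row in reader
        ]
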