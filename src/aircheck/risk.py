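"""Inhalation cancer-risk and non-cancer hazard assessment.

Lifetime excess cancer risk is the product of a chronic daily intake term and
the compound's inhalation unit risk:

    CR  = CDI × IUR
    CDI = C · (ET/24) · EF · ED / AT

with C the air concentration (µg/m³), ET the daily exposure time (h/day),
EF the exposure frequency (days/year), ED the exposure duration (years) and
AT the averaging time. Two conventions for AT are supported:

* ``mode="paper"`` keeps AT in years. This is the convention under which the
  published risk table for this campaign reproduces; it is dimensionally loose
  (EF carries days/year) but retained for faithful reproduction.
* ``mode="strict_epa"`` converts AT to days (AT·365), the standard EPA intake
  convention. Paper-mode CDI is exactly 365× the strict value, always.

Because IUR is expressed per µg/m³, the concentration is multiplied by IUR
directly — no body-weight or breathing-rate conversion is introduced.

Risk classes: CR ≥ 10⁻⁴ → A (definite), ≥ 10⁻⁵ → B (probable), ≥ 10⁻⁶ → C
(possible), below → D (uncertain). The non-cancer hazard index is HI = C/RfC,
flagged harmful when HI exceeds 1 strictly (HI = 1 is reported as
"at threshold").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .campaign import Phase
from .errors import DomainError
from .reference import (
    DEFAULT_RISK_CLASSES,
    DEFAULT_TOX_TABLE,
    ExposureScenario,
    RiskClassScheme,
    ToxReference,
    validate_scenario,
)
from .summaries import ConditionSummary


@dataclass(frozen=True)
class RiskResult:
    """Cancer-risk assessment of one compound under one phase.

    ``cdi`` and ``cr`` are ``None`` (with ``note="no-IUR"``) when the compound
    has no inhalation unit risk — a marker, not an error, so batch tables
    can proceed.
    """

    compound_id: str
    phase: Phase | None
    c_ugm3: float
    cdi: float | None
    cr: float | None
    risk_class: str | None
    scenario: ExposureScenario
    note: str = ""


@dataclass(frozen=True)
class HazardResult:
    """Non-cancer hazard index of one compound under one phase."""

    compound_id: str
    phase: Phase | None
    c_ugm3: float
    hi: float | None
    harmful: bool | None
    note: str = ""


def chronic_daily_intake(c_ugm3: float, scenario: ExposureScenario) -> float:
    """Exposure-weighted intake term CDI for concentration ``c_ugm3``.

    Paper mode: ``C·(ET/24)·EF·ED/AT`` with AT in years.
    Strict-EPA mode: the same with AT in days (divide by a further 365).
    """
    validate_scenario(scenario)
    if c_ugm3 < 0:
        raise DomainError(f"concentration must be >= 0, got {c_ugm3!r}")
    cdi = (
        c_ugm3
        * (scenario.et_hours_per_day / 24.0)
        * scenario.ef_days_per_year
        * scenario.ed_years
        / scenario.at_years
    )
    if scenario.mode == "strict_epa":
        cdi /= 365.0
    return cdi


def classify_cancer_risk(cr: float, scheme: RiskClassScheme = DEFAULT_RISK_CLASSES) -> str:
    """Map a lifetime excess cancer risk to its A–D class (boundaries inclusive up)."""
    return scheme.classify(cr)


def cancer_risk(
    c_ugm3: float,
    scenario: ExposureScenario,
    tox: ToxReference,
    phase: Phase | None = None,
    scheme: RiskClassScheme = DEFAULT_RISK_CLASSES,
) -> RiskResult:
    """CR = CDI × IUR for one compound, with its risk class attached."""
    if tox.iur is None:
        return RiskResult(
            tox.compound_id, phase, c_ugm3, None, None, None, scenario, note="no-IUR"
        )
    cdi = chronic_daily_intake(c_ugm3, scenario)
    cr = cdi * tox.iur
    return RiskResult(
        tox.compound_id, phase, c_ugm3, cdi, cr, scheme.classify(cr), scenario
    )


def hazard_index(
    c_ugm3: float, tox: ToxReference, phase: Phase | None = None
) -> HazardResult:
    """HI = C/RfC; harmful iff HI > 1 strictly (HI = 1 is "at threshold")."""
    if c_ugm3 < 0:
        raise DomainError(f"concentration must be >= 0, got {c_ugm3!r}")
    if tox.rfc is None:
        return HazardResult(tox.compound_id, phase, c_ugm3, None, None, note="no-RfC")
    hi = c_ugm3 / tox.rfc
    note = "at threshold" if hi == 1.0 else ""
    return HazardResult(tox.compound_id, phase, c_ugm3, hi, hi > 1.0, note=note)


RISK_TABLE_COLUMNS = [
    "compound_id",
    "phase",
    "mean_ugm3",
    "cdi",
    "cancer_risk",
    "risk_class",
    "hazard_index",
    "harmful",
    "mode",
    "scenario_fingerprint",
]


def risk_table(
    summaries: Iterable[ConditionSummary],
    scenario: ExposureScenario,
    tox_table: Mapping[str, ToxReference] | None = None,
    scheme: RiskClassScheme = DEFAULT_RISK_CLASSES,
) -> pd.DataFrame:
    """Cancer-risk and hazard-index table over compound × phase summaries.

    One row per input summary whose compound carries an IUR or an RfC; the
    phase mean is the exposure concentration. Compounds with neither value
    are omitted (they have nothing to report on either side).
    """
    tox_table = DEFAULT_TOX_TABLE if tox_table is None else tox_table
    rows = []
    for s in summaries:
        tox = tox_table.get(s.compound_id)
        if tox is None or (tox.iur is None and tox.rfc is None):
            continue
        rk = cancer_risk(s.mean, scenario, tox, phase=s.phase, scheme=scheme)
        hz = hazard_index(s.mean, tox, phase=s.phase)
        rows.append(
            {
                "compound_id": s.compound_id,
                "phase": s.phase.value if s.phase else "",
                "mean_ugm3": s.mean,
                "cdi": rk.cdi,
                "cancer_risk": rk.cr,
                "risk_class": rk.risk_class,
                "hazard_index": hz.hi,
                "harmful": hz.harmful,
                "mode": scenario.mode,
                "scenario_fingerprint": scenario.fingerprint(),
            }
        )
    return pd.DataFrame(rows, columns=RISK_TABLE_COLUMNS)


def summaries_from_phase_means(
    means: Mapping[str, Mapping[str, float]],
    n_by_phase: Mapping[str, int] | None = None,
) -> list[ConditionSummary]:
    """Build mean-only summaries from a {compound: {phase: mean}} mapping.

    Convenience for running the risk engine directly off published phase-mean
    tables, where SD/min/max are not needed (they are set equal to the mean).
    """
    out = []
    for cid, by_phase in means.items():
        for phase_name, mean in by_phase.items():
            n = (n_by_phase or {}).get(phase_name, 1)
            out.append(
                ConditionSummary(
                    compound_id=cid,
                    phase=Phase(phase_name),
                    n=n,
                    mean=float(mean),
                    sd=None,
                    min=float(mean),
                    max=float(mean),
                )
            )
    return out
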