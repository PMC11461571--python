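"""Seeded synthetic measurement campaigns with the structure the analysis assumes.

The raw measurements behind the reference ICU campaign were never released,
so this generator produces campaigns with the same design and the published
statistical structure, for testing every analysis stage end to end:

* concentrations are lognormal — positive and right-skewed, with per-compound
  arithmetic mean and geometric SD read off the published off-phase summaries
  (the mean/GSD pair is converted internally to the lognormal (µ, σ), so the
  *arithmetic* mean of generated off-phase data matches the configured value);
* the air cleaner acts multiplicatively: on-phase draws are scaled by
  ``(1 − r)`` with a per-compound reduction fraction ``r`` defaulting to the
  published off→on mean ratios (≈0.69 for benzene; BTX mean ≈ 0.70);
* a morning/afternoon session multiplier and an occupancy effect
  ``exp(slope·(persons − baseline))`` modulate ICU levels; the occupancy
  factor is normalized by its analytic expectation per session so it shifts
  variance, not the configured mean;
* the unoccupied isolated room gets attenuated baselines and occupancy 0.

One master seed drives everything; each compound uses a substream keyed by a
hash of its id, so adding or removing a compound never perturbs the draws of
the others. The realized true parameters are returned as a
:class:`CampaignTruth` for parameter-recovery tests.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .campaign import (
    DAYS,
    ICU_LOCATIONS,
    LOCATIONS,
    SESSIONS,
    MeasurementRecord,
    Phase,
    derive_phase,
)
from .campaign_stats import ICU_PHASE_STATS
from .errors import DomainError
from .reference import PANEL_IDS
from .summaries import ReductionEntry, reduction_table


def lognormal_params(mean: float, gsd: float) -> tuple[float, float]:
    """Lognormal (µ, σ) whose *arithmetic* mean is ``mean`` and geometric SD ``gsd``."""
    if mean <= 0:
        raise DomainError(f"mean must be > 0, got {mean}")
    if gsd < 1:
        raise DomainError(f"geometric SD must be >= 1, got {gsd}")
    sigma = math.log(gsd)
    mu = math.log(mean) - sigma**2 / 2.0
    return mu, sigma


def gsd_from_cv(cv: float) -> float:
    """Geometric SD of a lognormal with coefficient of variation ``cv``."""
    return math.exp(math.sqrt(math.log(1.0 + cv**2)))


@dataclass(frozen=True)
class CompoundProfile:
    """Generator parameters for one compound: off-phase mean, spread, reduction."""

    mean_off_ugm3: float
    gsd: float
    reduction: float  # multiplicative ACD reduction fraction r ∈ [0, 1)

    def __post_init__(self) -> None:
        if self.mean_off_ugm3 <= 0:
            raise DomainError("mean_off_ugm3 must be > 0")
        if self.gsd < 1:
            raise DomainError("gsd must be >= 1")
        if not (0 <= self.reduction < 1):
            raise DomainError("reduction must be in [0, 1)")


@dataclass(frozen=True)
class OccupancyModel:
    """Head-count model for ICU sampling events.

    With probability ``p_high[session]`` the event is a high-occupancy one
    (ward rounds: doctors, interns, nurses), drawing persons uniformly from
    ``high_range``; otherwise from ``low_range``. The concentration effect is
    ``exp(log_slope·(persons − baseline_persons))``, normalized per session to
    unit expectation.
    """

    baseline_persons: int = 4
    log_slope: float = 0.08
    p_high: Mapping[str, float] = field(
        default_factory=lambda: {"morning": 0.7, "afternoon": 0.15}
    )
    low_range: tuple[int, int] = (2, 6)
    high_range: tuple[int, int] = (7, 10)

    def factor(self, persons: int) -> float:
        return math.exp(self.log_slope * (persons - self.baseline_persons))

    def expected_factor(self, session: str) -> float:
        """Exact E[exp(slope·(persons − baseline))] for one session's mixture."""
        p = self.p_high[session]

        def mean_over(rng: tuple[int, int]) -> float:
            vals = range(rng[0], rng[1] + 1)
            return sum(self.factor(v) for v in vals) / len(vals)

        return p * mean_over(self.high_range) + (1 - p) * mean_over(self.low_range)


@dataclass(frozen=True)
class Schedule:
    """Sampling design: weeks × days × sessions × locations."""

    weeks: tuple[int, ...] = (1, 2, 3, 4)
    days: tuple[str, ...] = DAYS
    sessions: tuple[str, ...] = SESSIONS
    locations: tuple[str, ...] = LOCATIONS

    def events_per_location(self) -> int:
        return len(self.weeks) * len(self.days) * len(self.sessions)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic campaign generator."""

    profiles: Mapping[str, CompoundProfile]
    session_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"morning": 1.1, "afternoon": 0.9}
    )
    occupancy: OccupancyModel = field(default_factory=OccupancyModel)
    isolated_attenuation: float = 0.34
    schedule: Schedule = field(default_factory=Schedule)

    def validate(self) -> "GeneratorConfig":
        if not self.profiles:
            raise DomainError("config has no compound profiles")
        if self.isolated_attenuation <= 0:
            raise DomainError("isolated_attenuation must be > 0")
        for s in self.schedule.sessions:
            if s not in self.session_multiplier:
                raise DomainError(f"no session multiplier for {s!r}")
            if s not in self.occupancy.p_high:
                raise DomainError(f"no high-occupancy probability for {s!r}")
        if not self.schedule.weeks:
            raise DomainError("schedule has no weeks")
        for w in self.schedule.weeks:
            derive_phase(w)  # raises if outside the crossover design
        return self


@dataclass(frozen=True)
class CampaignTruth:
    """Realized true parameters stored alongside a generated campaign."""

    seed: int
    reductions: Mapping[str, float]
    occupancy_log_slope: float
    session_multiplier: Mapping[str, float]
    isolated_attenuation: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def design_factor_cv(
    session_multiplier: Mapping[str, float],
    occupancy: OccupancyModel,
    sessions: Sequence[str] = SESSIONS,
) -> float:
    """CV of the deterministic-design factor (session × normalized occupancy).

    Sessions are equally frequent under the balanced schedule; the occupancy
    factor is mean-one per session by construction, so only its second moment
    contributes. Used to deflate the baseline lognormal spread so the
    *marginal* off-phase CV matches a calibration target.
    """
    first = second = 0.0
    for s in sessions:
        m = session_multiplier[s]
        p = occupancy.p_high[s]

        def moments(rng: tuple[int, int]) -> tuple[float, float]:
            vals = [occupancy.factor(v) for v in range(rng[0], rng[1] + 1)]
            return sum(vals) / len(vals), sum(v * v for v in vals) / len(vals)

        lo1, lo2 = moments(occupancy.low_range)
        hi1, hi2 = moments(occupancy.high_range)
        e_g = p * hi1 + (1 - p) * lo1
        e_g2 = p * hi2 + (1 - p) * lo2
        first += m
        second += m * m * e_g2 / (e_g * e_g)
    first /= len(sessions)
    second /= len(sessions)
    return math.sqrt(max(second / (first * first) - 1.0, 0.0))


def default_config() -> GeneratorConfig:
    """Defaults calibrated to the published reference campaign.

    Per-compound off-phase arithmetic means and CVs come from the published
    pre-installation summaries; reduction fractions are the published off→on
    mean ratios (benzene ≈ 0.690, toluene ≈ 0.754, o-xylene ≈ 0.645). The
    published SDs are marginal over sessions and occupancy states, so the
    baseline lognormal CV is deflated by the analytic CV of the design factor
    — the marginal CV of generated off-phase ICU data then matches the
    published one.
    """
    session_multiplier = {"morning": 1.1, "afternoon": 0.9}
    occupancy = OccupancyModel()
    cv_factor2 = design_factor_cv(session_multiplier, occupancy) ** 2
    profiles = {}
    for cid in PANEL_IDS:
        stats = ICU_PHASE_STATS[cid]
        off, on = stats["off_pre"], stats["on"]
        cv_target2 = (off.sd / off.mean) ** 2
        cv_base2 = max((1.0 + cv_target2) / (1.0 + cv_factor2) - 1.0, 0.0)
        profiles[cid] = CompoundProfile(
            mean_off_ugm3=off.mean,
            gsd=gsd_from_cv(math.sqrt(cv_base2)),
            reduction=1.0 - on.mean / off.mean,
        )
    return GeneratorConfig(
        profiles=profiles,
        session_multiplier=session_multiplier,
        occupancy=occupancy,
    )


def _compound_rng(seed: int, compound_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(compound_id.encode())])
    )


def _sample_id(week: int, day: str, session: str, location: str) -> str:
    tag = "am" if session == "morning" else "pm"
    return f"w{week}-{day.lower()}-{tag}-{location}"


def generate_campaign(
    config: GeneratorConfig, seed: int
) -> tuple[list[MeasurementRecord], CampaignTruth]:
    """Generate a full campaign; the same seed reproduces it byte for byte."""
    config.validate()
    sched = config.schedule
    occ_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(b"occupancy")])
    )

    # Events in deterministic design order; occupancy drawn once per event.
    events = []
    for week in sched.weeks:
        state = "on" if derive_phase(week) is Phase.ON else "off"
        for day in sched.days:
            for session in sched.sessions:
                for location in sched.locations:
                    if location in ICU_LOCATIONS:
                        model = config.occupancy
                        high = occ_rng.random() < model.p_high[session]
                        lo, hi = model.high_range if high else model.low_range
                        persons = int(occ_rng.integers(lo, hi + 1))
                        occ_factor = model.factor(persons) / model.expected_factor(session)
                    else:
                        persons, occ_factor = 0, 1.0
                    events.append(
                        {
                            "sample_id": _sample_id(week, day, session, location),
                            "week": week,
                            "day": day,
                            "session": session,
                            "location": location,
                            "acd_state": state,
                            "occupancy": persons,
                            "factor": (
                                config.session_multiplier[session]
                                * occ_factor
                                * (
                                    config.isolated_attenuation
                                    if location not in ICU_LOCATIONS
                                    else 1.0
                                )
                            ),
                            "on": state == "on",
                        }
                    )

    records: list[MeasurementRecord] = []
    per_event_factor = np.array([e["factor"] for e in events])
    on_mask = np.array([e["on"] for e in events])
    for cid, prof in config.profiles.items():
        rng = _compound_rng(seed, cid)
        mu, sigma = lognormal_params(prof.mean_off_ugm3, prof.gsd)
        draws = rng.lognormal(mu, sigma, len(events))
        conc = draws * per_event_factor * np.where(on_mask, 1.0 - prof.reduction, 1.0)
        conc = np.round(conc, 6)
        for e, c in zip(events, conc):
            records.append(
                MeasurementRecord(
                    sample_id=e["sample_id"],
                    week=e["week"],
                    day=e["day"],
                    session=e["session"],
                    location=e["location"],
                    acd_state=e["acd_state"],
                    compound_id=cid,
                    concentration_ugm3=float(c),
                    occupancy=e["occupancy"],
                )
            )
    truth = CampaignTruth(
        seed=int(seed),
        reductions={cid: p.reduction for cid, p in config.profiles.items()},
        occupancy_log_slope=config.occupancy.log_slope,
        session_multiplier=dict(config.session_multiplier),
        isolated_attenuation=config.isolated_attenuation,
    )
    return records, truth


def reduction_from_samples(
    off: Sequence[float], on: Sequence[float]
) -> float:
    """Estimated reduction fraction r̂ = 1 − mean(on)/mean(off)."""
    mean_off = float(np.mean(off))
    if mean_off <= 0:
        raise DomainError(f"off-phase mean must be > 0, got {mean_off}")
    return 1.0 - float(np.mean(on)) / mean_off


def recover_reduction(
    records: Sequence[MeasurementRecord],
    baseline: Phase | str = Phase.OFF_PRE,
    locations: Sequence[str] | None = ICU_LOCATIONS,
) -> dict[str, float]:
    """Per-compound estimated reduction fraction from a campaign's phase means."""
    entries: list[ReductionEntry] = reduction_table(
        records, baseline=baseline, locations=locations
    )
    return {
        e.compound_id: e.reduction_pct / 100.0
        for e in entries
        if e.complete and e.compound_id in PANEL_IDS
    }


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    """Load a generator configuration from YAML; omitted sections keep defaults."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = default_config()
    profiles = dict(base.profiles)
    for cid, spec in (raw.get("profiles") or {}).items():
        profiles[cid] = CompoundProfile(
            mean_off_ugm3=float(spec["mean_off_ugm3"]),
            gsd=float(spec.get("gsd", 1.6)),
            reduction=float(spec.get("reduction", 0.0)),
        )
    occ_raw = raw.get("occupancy") or {}
    occupancy = OccupancyModel(
        baseline_persons=int(occ_raw.get("baseline_persons", 4)),
        log_slope=float(occ_raw.get("log_slope", 0.08)),
        p_high=occ_raw.get("p_high", {"morning": 0.7, "afternoon": 0.15}),
        low_range=tuple(occ_raw.get("low_range", (2, 6))),
        high_range=tuple(occ_raw.get("high_range", (7, 10))),
    )
    sched_raw = raw.get("schedule") or {}
    schedule = Schedule(
        weeks=tuple(sched_raw.get("weeks", (1, 2, 3, 4))),
        days=tuple(sched_raw.get("days", DAYS)),
        sessions=tuple(sched_raw.get("sessions", SESSIONS)),
        locations=tuple(sched_raw.get("locations", LOCATIONS)),
    )
    return GeneratorConfig(
        profiles=profiles,
        session_multiplier=raw.get(
            "session_multiplier", {"morning": 1.1, "afternoon": 0.9}
        ),
        occupancy=occupancy,
        isolated_attenuation=float(raw.get("isolated_attenuation", 0.34)),
        schedule=schedule,
    ).validate()
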