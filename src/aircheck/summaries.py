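"""Condition summaries, total-VOC (TVOC) sums, and intervention reduction.

Summaries mirror the reporting convention of indoor-air monitoring tables:
per compound and crossover phase, the sample count N with mean, sample SD
(n−1 divisor), minimum and maximum in µg/m³. TVOC is the derived sum of the
14-compound panel — computed per sampling event, never stored as a compound.

The air-cleaning-device effect is summarized as the percent reduction of the
phase mean, ``100·(mean_off − mean_on)/mean_off``, with the pre-installation
week (``off_pre``) as the default baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .campaign import ICU_LOCATIONS, MeasurementRecord, Phase
from .errors import DomainError, EmptyGroupError
from .reference import PANEL_IDS, TVOC


@dataclass(frozen=True)
class ConditionSummary:
    """N/mean/SD/min/max for one compound (or TVOC) under one phase."""

    compound_id: str
    phase: Phase | None
    n: int
    mean: float
    sd: float | None  # sample SD (n−1); None when n == 1
    min: float
    max: float


@dataclass(frozen=True)
class ReductionEntry:
    """Percent reduction of the phase mean for one compound (or TVOC)."""

    compound_id: str
    mean_off: float | None
    mean_on: float | None
    reduction_pct: float | None
    complete: bool = True
    note: str = ""


def _summary_from_values(
    compound_id: str, phase: Phase | None, values: Sequence[float]
) -> ConditionSummary:
    if len(values) == 0:
        raise EmptyGroupError(f"no records for {compound_id!r} in phase {phase}")
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return ConditionSummary(
        compound_id=compound_id,
        phase=phase,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
    )


def condition_summary(
    records: Iterable[MeasurementRecord],
    compound_id: str,
    phase: Phase | str,
    locations: Sequence[str] | None = None,
) -> ConditionSummary:
    """Summarize one compound under one phase.

    ``locations`` restricts the records considered (e.g. ``ICU_LOCATIONS`` to
    pool the two ICU points and exclude the isolated room); ``None`` keeps all.
    Raises :class:`EmptyGroupError` when nothing matches.
    """
    phase = Phase(phase)
    values = [
        r.concentration_ugm3
        for r in records
        if r.compound_id == compound_id
        and r.phase == phase
        and (locations is None or r.location in locations)
    ]
    return _summary_from_values(compound_id, phase, values)


@dataclass(frozen=True)
class TvocResult:
    """Per-sample TVOC: the panel sum plus which panel compounds were absent."""

    value: float
    missing: tuple[str, ...]


def tvoc_per_sample(records: Sequence[MeasurementRecord]) -> TvocResult:
    """Sum the panel concentrations of one sampling event.

    The records must all belong to one sample; a panel compound appearing
    twice within the sample is an error, panel compounds absent from the
    sample are reported in ``missing``. Non-panel compounds are ignored.
    """
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise ValueError(f"records span multiple samples: {sorted(sample_ids)}")
    seen: dict[str, float] = {}
    for r in records:
        if r.compound_id not in PANEL_IDS:
            continue
        if r.compound_id in seen:
            raise ValueError(
                f"duplicate compound {r.compound_id!r} within sample {r.sample_id!r}"
            )
        seen[r.compound_id] = r.concentration_ugm3
    missing = tuple(cid for cid in PANEL_IDS if cid not in seen)
    return TvocResult(value=float(sum(seen.values())), missing=missing)


def tvoc_by_sample(
    records: Sequence[MeasurementRecord],
) -> dict[str, tuple[Phase, TvocResult]]:
    """Per-sample TVOC for every sampling event in a campaign, keyed by sample id."""
    by_sample: dict[str, list[MeasurementRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    return {sid: (recs[0].phase, tvoc_per_sample(recs)) for sid, recs in by_sample.items()}


def tvoc_summary(
    records: Sequence[MeasurementRecord],
    phase: Phase | str,
    locations: Sequence[str] | None = ICU_LOCATIONS,
) -> ConditionSummary:
    """Phase summary of per-sample TVOC values (compound_id ``"TVOC"``)."""
    phase = Phase(phase)
    subset = [
        r for r in records if (locations is None or r.location in locations)
    ]
    values = [
        res.value for ph, res in tvoc_by_sample(subset).values() if ph == phase
    ]
    return _summary_from_values(TVOC, phase, values)


def sum_of_column_means(summaries: Sequence[ConditionSummary]) -> float:
    """Sum the 14 per-compound phase means (the "TVOC of the column").

    Requires exactly one summary per panel compound, all from the same phase;
    missing compounds raise an error naming the absentees. This is the
    statistic printed as TVOC in mean-only columns, and differs in general
    from the mean of per-sample TVOCs.
    """
    phases = {s.phase for s in summaries}
    if len(phases) > 1:
        raise ValueError(f"summaries span multiple phases: {sorted(p.value for p in phases if p)}")
    by_id = {s.compound_id: s for s in summaries}
    absent = [cid for cid in PANEL_IDS if cid not in by_id]
    if absent:
        raise ValueError(f"missing panel compounds: {absent}")
    return float(sum(by_id[cid].mean for cid in PANEL_IDS))


def percent_reduction(mean_off: float, mean_on: float) -> float:
    """Percent reduction of the on-phase mean relative to the off baseline."""
    if not (math.isfinite(mean_off) and mean_off > 0):
        raise DomainError(f"baseline mean must be > 0, got {mean_off!r}")
    return 100.0 * (mean_off - mean_on) / mean_off


def reduction_table(
    records: Sequence[MeasurementRecord],
    baseline: Phase | str = Phase.OFF_PRE,
    pool_off: bool = False,
    locations: Sequence[str] | None = ICU_LOCATIONS,
) -> list[ReductionEntry]:
    """Per-compound (plus TVOC) percent reduction of phase means, off vs on.

    The baseline is the pre-installation off week by default; ``pool_off=True``
    pools both off weeks instead. Compounds absent in either phase yield an
    incomplete entry rather than an error.
    """
    baseline = Phase(baseline)
    subset = [r for r in records if locations is None or r.location in locations]

    def phase_values(cid: str, target: str) -> list[float]:
        if target == "off" and pool_off:
            want = {Phase.OFF_PRE, Phase.OFF_POST}
        elif target == "off":
            want = {baseline}
        else:
            want = {Phase.ON}
        return [
            r.concentration_ugm3
            for r in subset
            if r.compound_id == cid and r.phase in want
        ]

    entries: list[ReductionEntry] = []
    for cid in PANEL_IDS:
        off = phase_values(cid, "off")
        on = phase_values(cid, "on")
        if not off or not on:
            side = "off" if not off else "on"
            entries.append(
                ReductionEntry(cid, None, None, None, complete=False,
                               note=f"no {side}-phase records")
            )
            continue
        mean_off = float(np.mean(off))
        mean_on = float(np.mean(on))
        entries.append(
            ReductionEntry(cid, mean_off, mean_on, percent_reduction(mean_off, mean_on))
        )

    # TVOC row: reduction of per-sample TVOC phase means
    tvoc = tvoc_by_sample(subset)
    if pool_off:
        off_vals = [t.value for ph, t in tvoc.values() if ph in (Phase.OFF_PRE, Phase.OFF_POST)]
    else:
        off_vals = [t.value for ph, t in tvoc.values() if ph == baseline]
    on_vals = [t.value for ph, t in tvoc.values() if ph == Phase.ON]
    if off_vals and on_vals:
        m_off, m_on = float(np.mean(off_vals)), float(np.mean(on_vals))
        entries.append(ReductionEntry(TVOC, m_off, m_on, percent_reduction(m_off, m_on)))
    else:
        entries.append(
            ReductionEntry(TVOC, None, None, None, complete=False, note="phase absent")
        )
    return entries
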