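"""End-to-end pipeline: campaign file in, result tables and exceedance report out.

``run_pipeline`` chains the stages — condition summaries for the ICU and the
isolated room, the reduction table, cancer-risk/hazard tables, the ANOVA and
occupancy contrasts, and the guideline-exceedance check — into one
:class:`PipelineReport` whose every number is recomputable from the input file
and configuration alone. ``write_report`` serializes it as one CSV per table
plus a human-readable markdown summary; output is deterministic for fixed
input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .anova import AnovaResult, acd_effect_tests, occupancy_association
from .campaign import ICU_LOCATIONS, MeasurementRecord, Phase, read_campaign
from .errors import AircheckError, EmptyGroupError
from .reference import (
    DEFAULT_GUIDELINES,
    DEFAULT_TOX_TABLE,
    PANEL_IDS,
    TVOC,
    ExposureScenario,
    GuidelineLimit,
    ToxReference,
    worker_scenario,
)
from .risk import risk_table
from .summaries import (
    ConditionSummary,
    condition_summary,
    reduction_table,
    tvoc_summary,
)


@dataclass(frozen=True)
class Exceedance:
    """One guideline comparison: observed statistics vs. one authority's limit."""

    analyte: str
    authority: str
    phase: str
    observed_max: float
    observed_mean: float
    limit_ugm3: float
    exceeded: bool
    trigger: str  # "max", "mean+max", or "" when not exceeded
    note: str = ""


def guideline_exceedance(
    summaries: Sequence[ConditionSummary],
    limits: Sequence[GuidelineLimit] = DEFAULT_GUIDELINES,
) -> list[Exceedance]:
    """Compare summary maxima (and means) against guideline limits.

    ``summaries`` may mix compound summaries and TVOC summaries (compound_id
    ``"TVOC"``, built from per-sample TVOCs). The exceeded flag is driven by
    the maximum — guideline comparisons in monitoring reports look at
    worst-case whisker values — and ``trigger`` records whether the mean
    exceeded too. Analytes with no matching summary are skipped with a note.
    """
    out: list[Exceedance] = []
    for lim in limits:
        matching = [s for s in summaries if s.compound_id == lim.analyte]
        if not matching:
            out.append(
                Exceedance(
                    lim.analyte, lim.authority, "", float("nan"), float("nan"),
                    lim.limit_ugm3, False, "", note="analyte not in summaries; skipped",
                )
            )
            continue
        for s in matching:
            exceeded = s.max > lim.limit_ugm3
            if exceeded:
                trigger = "mean+max" if s.mean > lim.limit_ugm3 else "max"
            else:
                trigger = ""
            out.append(
                Exceedance(
                    lim.analyte,
                    lim.authority,
                    s.phase.value if s.phase else "",
                    s.max,
                    s.mean,
                    lim.limit_ugm3,
                    exceeded,
                    trigger,
                )
            )
    return out


@dataclass
class PipelineReport:
    """All pipeline outputs for one campaign, plus run metadata."""

    icu_summaries: list[ConditionSummary]
    isolated_summaries: list[ConditionSummary]
    reductions: list
    risk: pd.DataFrame
    anova: list[AnovaResult]
    occupancy: list[AnovaResult]
    occupancy_dropped: int
    exceedances: list[Exceedance]
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _phase_summaries(
    records: Sequence[MeasurementRecord], locations: Sequence[str] | None
) -> list[ConditionSummary]:
    out = []
    for phase in Phase:
        for cid in PANEL_IDS:
            try:
                out.append(condition_summary(records, cid, phase, locations=locations))
            except EmptyGroupError:
                continue
        try:
            out.append(tvoc_summary(records, phase, locations=locations))
        except EmptyGroupError:
            continue
    return out


def run_pipeline(
    campaign: str | Path | Sequence[MeasurementRecord],
    scenario: ExposureScenario | None = None,
    tox_table: Mapping[str, ToxReference] | None = None,
    guidelines: Sequence[GuidelineLimit] = DEFAULT_GUIDELINES,
    baseline_phase: Phase | str = Phase.OFF_PRE,
    alpha: float = 0.05,
    strict: bool = False,
) -> PipelineReport:
    """Run every analysis stage on a campaign file or record list.

    The default exposure scenario is the calibrated healthcare-worker one in
    paper mode (reproducing the published table convention); pass an explicit
    :class:`ExposureScenario` to change parameters or switch to strict-EPA
    intake. Stage warnings are aggregated on the report.
    """
    scenario = scenario or worker_scenario(mode="paper")
    tox_table = DEFAULT_TOX_TABLE if tox_table is None else tox_table

    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if isinstance(campaign, (str, Path)):
            records = read_campaign(campaign, strict=strict)
        else:
            records = list(campaign)
        try:
            icu = _phase_summaries(records, ICU_LOCATIONS)
            isolated = _phase_summaries(records, ("isolated_room",))
            reductions = reduction_table(records, baseline=baseline_phase)
            risk = risk_table(
                [s for s in icu if s.compound_id != TVOC], scenario, tox_table
            )
            anova = acd_effect_tests(records, baseline_phase=baseline_phase, alpha=alpha)
            occupancy, dropped = occupancy_association(records, alpha=alpha)
            exceed = guideline_exceedance(icu, guidelines)
        except AircheckError as err:
            raise AircheckError(f"pipeline stage failed: {err}") from err
        collected = [str(w.message) for w in caught]

    metadata = {
        "aircheck_version": __version__,
        "n_records": len(records),
        "scenario": scenario.fingerprint(),
        "mode": scenario.mode,
        "baseline_phase": str(Phase(baseline_phase).value),
        "alpha": alpha,
    }
    return PipelineReport(
        icu_summaries=icu,
        isolated_summaries=isolated,
        reductions=reductions,
        risk=risk,
        anova=anova,
        occupancy=occupancy,
        occupancy_dropped=dropped,
        exceedances=exceed,
        metadata=metadata,
        warnings=collected,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _summaries_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": s.compound_id,
                "phase": s.phase.value if s.phase else "",
                "n": s.n,
                "mean_ugm3": s.mean,
                "sd_ugm3": s.sd,
                "min_ugm3": s.min,
                "max_ugm3": s.max,
            }
            for s in summaries
        ]
    )


def _reductions_frame(entries: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": e.compound_id,
                "mean_off_ugm3": e.mean_off,
                "mean_on_ugm3": e.mean_on,
                "reduction_pct": e.reduction_pct,
                "complete": e.complete,
                "note": e.note,
            }
            for e in entries
        ]
    )


def _anova_frame(results: Sequence[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "grouping": r.grouping,
                "k": r.k,
                "f_stat": r.f_stat,
                "df1": r.df_between,
                "df2": r.df_within,
                "p_value": r.p_value,
                "significant": r.significant,
                "p_bh": r.p_bh,
                "degenerate": r.degenerate,
                "note": r.note,
            }
            for r in results
        ]
    )


def _exceedance_frame(rows: Sequence[Exceedance]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in rows])


def _round_frame(df: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(ndigits)
    return out


def write_report(
    report: PipelineReport, out_dir: str | Path, round_display: bool = False
) -> list[Path]:
    """Write one CSV per table plus ``report.md``; returns the paths written.

    ``round_display=True`` rounds concentration tables to 2 decimals (risk
    values keep full precision in the CSVs; the markdown always shows 3
    significant figures for risks).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "icu_summary.csv": _summaries_frame(report.icu_summaries),
        "isolated_summary.csv": _summaries_frame(report.isolated_summaries),
        "reductions.csv": _reductions_frame(report.reductions),
        "risk_table.csv": report.risk,
        "anova.csv": _anova_frame(report.anova),
        "occupancy_anova.csv": _anova_frame(report.occupancy),
        "exceedances.csv": _exceedance_frame(report.exceedances),
    }
    written = []
    for name, df in tables.items():
        if round_display and name not in ("risk_table.csv",):
            df = _round_frame(df)
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)

    md = out_dir / "report.md"
    with open(md, "w", encoding="utf-8") as fh:
        fh.write("# Campaign analysis report\n\n")
        for key, val in sorted(report.metadata.items()):
            fh.write(f"- {key}: {val}\n")
        fh.write(f"- occupancy records dropped (no head count): {report.occupancy_dropped}\n")
        fh.write("\n## Cancer risk and hazard index (phase means)\n\n")
        for _, row in report.risk.iterrows():
            cr = "n/a" if pd.isna(row.cancer_risk) else f"{row.cancer_risk:.3g}"
            hi = "n/a" if pd.isna(row.hazard_index) else f"{row.hazard_index:.3g}"
            cls = row.risk_class if isinstance(row.risk_class, str) else "-"
            if isinstance(row.hazard_index, float) and row.hazard_index == 1.0:
                hi += " (at threshold)"
            fh.write(
                f"- {row.compound_id} [{row.phase}]: CR {cr} (class {cls}), HI {hi}\n"
            )
        fh.write("\n## Guideline exceedances\n\n")
        flagged = [e for e in report.exceedances if e.exceeded]
        if not flagged:
            fh.write("None.\n")
        for e in flagged:
            fh.write(
                f"- {e.analyte} [{e.phase}] max {e.observed_max:.2f} µg/m³ exceeds "
                f"{e.authority} limit {e.limit_ugm3:g} µg/m³ (trigger: {e.trigger})\n"
            )
        if report.warnings:
            fh.write("\n## Warnings\n\n")
            for w in report.warnings:
                fh.write(f"- {w}\n")
    written.append(md)
    return written
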