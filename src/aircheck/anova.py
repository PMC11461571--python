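"""One-way ANOVA for intervention and occupancy contrasts.

The F statistic is computed from the literal between/within sums of squares,

    F = (SSB/(k−1)) / (SSW/(n−k)),

and the p-value from the upper tail of the F(k−1, n−k) distribution (the
regularized incomplete beta function, via ``scipy.stats.f``). For two groups
this is exactly the squared pooled-variance t test.

Degenerate inputs do not raise: zero within-group variance with distinct
means reports p = 0, and zero total variance an undefined result, both with
a ``degenerate`` flag, so batch runs over many compounds always complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .campaign import ICU_LOCATIONS, MeasurementRecord, Phase
from .reference import PANEL_IDS, TVOC
from .summaries import tvoc_by_sample

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA outcome for one compound under one grouping."""

    compound_id: str
    grouping: str
    k: int
    f_stat: float | None
    df_between: int
    df_within: int
    p_value: float | None
    significant: bool | None
    alpha: float = DEFAULT_ALPHA
    degenerate: bool = False
    note: str = ""
    p_bh: float | None = None  # Benjamini–Hochberg adjusted, when requested


def p_from_f(f: float, df1: int, df2: int) -> float:
    """Upper-tail p of the F distribution (regularized incomplete beta)."""
    return float(stats.f.sf(f, df1, df2))


def one_way_anova(
    groups: Sequence[Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
    compound_id: str = "",
    grouping: str = "",
) -> AnovaResult:
    """One-way fixed-effects ANOVA over ``k ≥ 2`` groups of observations.

    Each group needs at least 2 observations. SSB/SSW are accumulated
    term by term; no shortcut formulas.
    """
    k = len(groups)
    if k < 2:
        raise ValueError(f"need at least 2 groups, got {k}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    n = int(sum(a.size for a in arrays))
    grand = float(np.concatenate(arrays).mean())
    ssb = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df1, df2 = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(
                compound_id, grouping, k, None, df1, df2, None, None, alpha,
                degenerate=True, note="zero total variance; F undefined",
            )
        return AnovaResult(
            compound_id, grouping, k, math.inf, df1, df2, 0.0, True, alpha,
            degenerate=True, note="zero within-group variance",
        )
    f = (ssb / df1) / (ssw / df2)
    p = p_from_f(f, df1, df2)
    return AnovaResult(compound_id, grouping, k, f, df1, df2, p, p < alpha, alpha)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj.tolist()


def _attach_bh(results: list[AnovaResult]) -> list[AnovaResult]:
    import dataclasses

    testable = [i for i, r in enumerate(results) if r.p_value is not None]
    if not testable:
        return results
    adj = benjamini_hochberg([results[i].p_value for i in testable])
    out = list(results)
    for i, q in zip(testable, adj):
        out[i] = dataclasses.replace(out[i], p_bh=q)
    return out


def acd_effect_tests(
    records: Sequence[MeasurementRecord],
    baseline_phase: Phase | str = Phase.OFF_PRE,
    alpha: float = DEFAULT_ALPHA,
    three_level: bool = False,
    locations: Sequence[str] | None = ICU_LOCATIONS,
    include_tvoc: bool = True,
    adjust: bool = False,
) -> list[AnovaResult]:
    """Per-compound ANOVA of concentrations across air-cleaner conditions.

    Default contrast: baseline off week vs. the on weeks (two groups).
    ``three_level=True`` compares off_pre / on / off_post instead. Raw
    per-compound p-values are reported; ``adjust=True`` adds a
    Benjamini–Hochberg column. Compounds missing a phase are skipped with a
    note.
    """
    baseline = Phase(baseline_phase)
    phases = (
        [Phase.OFF_PRE, Phase.ON, Phase.OFF_POST] if three_level else [baseline, Phase.ON]
    )
    grouping = " vs ".join(p.value for p in phases)
    subset = [r for r in records if locations is None or r.location in locations]

    def run(cid: str, values_by_phase: list[list[float]]) -> AnovaResult:
        if any(len(v) < 2 for v in values_by_phase):
            return AnovaResult(
                cid, grouping, len(phases), None, len(phases) - 1, 0, None, None,
                alpha, degenerate=True, note="phase with <2 observations; skipped",
            )
        return one_way_anova(values_by_phase, alpha, cid, grouping)

    results = []
    for cid in PANEL_IDS:
        per_phase = [
            [r.concentration_ugm3 for r in subset if r.compound_id == cid and r.phase == ph]
            for ph in phases
        ]
        results.append(run(cid, per_phase))
    if include_tvoc:
        tvoc = tvoc_by_sample(subset)
        per_phase = [[t.value for ph_, t in tvoc.values() if ph_ == ph] for ph in phases]
        results.append(run(TVOC, per_phase))
    return _attach_bh(results) if adjust else results


def occupancy_association(
    records: Sequence[MeasurementRecord],
    threshold_persons: int = 6,
    alpha: float = DEFAULT_ALPHA,
    locations: Sequence[str] | None = ICU_LOCATIONS,
    adjust: bool = False,
) -> tuple[list[AnovaResult], int]:
    """Compare concentrations between low- and high-occupancy sampling events.

    Events with more than ``threshold_persons`` present form the high group.
    Records without an occupancy count are dropped; the count dropped is
    returned alongside the results. Compounds with all observations on one
    side of the threshold are skipped with a note.
    """
    subset = [r for r in records if locations is None or r.location in locations]
    usable = [r for r in subset if r.occupancy is not None]
    dropped = len(subset) - len(usable)
    grouping = f"occupancy <= {threshold_persons} vs > {threshold_persons}"
    results = []
    for cid in PANEL_IDS:
        low = [
            r.concentration_ugm3
            for r in usable
            if r.compound_id == cid and r.occupancy <= threshold_persons
        ]
        high = [
            r.concentration_ugm3
            for r in usable
            if r.compound_id == cid and r.occupancy > threshold_persons
        ]
        if len(low) < 2 or len(high) < 2:
            results.append(
                AnovaResult(
                    cid, grouping, 2, None, 1, 0, None, None, alpha,
                    degenerate=True,
                    note="all observations on one side of the threshold; skipped",
                )
            )
            continue
        results.append(one_way_anova([low, high], alpha, cid, grouping))
    return (_attach_bh(results) if adjust else results), dropped
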