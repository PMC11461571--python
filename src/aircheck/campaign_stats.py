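"""Published summary statistics of the reference ICU monitoring campaign.

The raw measurements of the campaign this package models were never deposited;
what is public are per-compound condition summaries (N, mean, SD, min, max in
µg/m³) for the intensive-care unit under three crossover phases — week 1 with
the air-cleaning devices off (``off_pre``), weeks 2–3 with them on (``on``),
week 4 off again (``off_post``) — plus mean columns for an unoccupied isolated
room. These printed statistics serve two roles here:

* calibration targets and defaults for the synthetic campaign generator, and
* direct inputs for reproducing the published risk/hazard tables, where the
  published calculation itself starts from phase means.

Note: the ICU TVOC summary row is reported as measured per sample, so its
printed off_pre mean (136.78) is below the sum of the 14 printed compound
means (142.40); the per-sample TVOC and the sum-of-means are different
statistics and both are exposed by :mod:`aircheck.summaries`.
"""

from __future__ import annotations

from typing import NamedTuple


class PhaseStats(NamedTuple):
    """One summary cell: sample count, mean, SD, min, max (µg/m³)."""

    n: int
    mean: float
    sd: float
    min: float
    max: float


#: ICU (two sampling points pooled) per-compound summaries by crossover phase.
ICU_PHASE_STATS: dict[str, dict[str, PhaseStats]] = {
    "benzene": {
        "off_pre": PhaseStats(9, 2.58, 1.57, 0.76, 5.37),
        "on": PhaseStats(18, 0.80, 0.65, 0.01, 2.00),
        "off_post": PhaseStats(9, 0.99, 0.79, 0.02, 1.87),
    },
    "toluene": {
        "off_pre": PhaseStats(9, 25.30, 11.08, 8.27, 35.60),
        "on": PhaseStats(18, 6.22, 4.61, 0.02, 13.39),
        "off_post": PhaseStats(9, 17.27, 15.73, 0.01, 36.81),
    },
    "ethylbenzene": {
        "off_pre": PhaseStats(9, 6.15, 2.33, 1.71, 8.62),
        "on": PhaseStats(18, 1.75, 1.17, 0.01, 3.54),
        "off_post": PhaseStats(9, 1.76, 1.25, 0.09, 2.94),
    },
    "m_p_xylene": {
        "off_pre": PhaseStats(9, 5.66, 3.52, 2.36, 11.60),
        "on": PhaseStats(18, 2.72, 1.93, 0.004, 5.85),
        "off_post": PhaseStats(9, 0.52, 0.44, 0.01, 1.08),
    },
    "o_xylene": {
        "off_pre": PhaseStats(9, 5.10, 4.10, 1.06, 13.59),
        "on": PhaseStats(18, 1.81, 1.64, 0.07, 4.56),
        "off_post": PhaseStats(9, 1.11, 0.92, 0.02, 2.30),
    },
    "styrene": {
        "off_pre": PhaseStats(9, 22.52, 19.62, 0.38, 49.95),
        "on": PhaseStats(18, 3.49, 2.24, 0.30, 6.85),
        "off_post": PhaseStats(9, 4.83, 7.08, 0.87, 18.91),
    },
    "isopropylbenzene": {
        "off_pre": PhaseStats(9, 2.91, 1.71, 0.55, 5.13),
        "on": PhaseStats(18, 1.20, 0.92, 0.22, 2.88),
        "off_post": PhaseStats(9, 1.06, 0.80, 0.02, 2.15),
    },
    "n_propylbenzene": {
        "off_pre": PhaseStats(9, 16.59, 17.00, 4.19, 45.79),
        "on": PhaseStats(18, 2.80, 1.35, 1.23, 4.96),
        "off_post": PhaseStats(9, 1.02, 1.45, 0.05, 3.00),
    },
    "trimethylbenzene_124": {
        "off_pre": PhaseStats(9, 6.02, 4.76, 0.99, 12.97),
        "on": PhaseStats(18, 1.37, 1.06, 0.37, 3.13),
        "off_post": PhaseStats(9, 0.76, 0.25, 0.51, 1.21),
    },
    "trimethylbenzene_135": {
        "off_pre": PhaseStats(9, 8.71, 3.52, 4.94, 14.73),
        "on": PhaseStats(18, 3.05, 2.61, 0.44, 9.47),
        "off_post": PhaseStats(9, 0.62, 0.42, 0.12, 1.17),
    },
    "sec_butylbenzene": {
        "off_pre": PhaseStats(9, 26.41, 18.48, 3.91, 48.18),
        "on": PhaseStats(18, 4.39, 2.08, 1.82, 7.56),
        "off_post": PhaseStats(9, 0.50, 0.13, 0.29, 0.67),
    },
    "isopropyltoluene_4": {
        "off_pre": PhaseStats(9, 7.40, 4.07, 3.90, 12.88),
        "on": PhaseStats(18, 2.11, 1.54, 0.76, 5.73),
        "off_post": PhaseStats(9, 3.80, 1.83, 2.06, 6.04),
    },
    "n_butylbenzene": {
        "off_pre": PhaseStats(9, 2.13, 1.73, 0.61, 5.06),
        "on": PhaseStats(18, 1.39, 1.44, 0.15, 3.96),
        "off_post": PhaseStats(9, 1.66, 1.07, 0.33, 3.13),
    },
    "naphthalene": {
        "off_pre": PhaseStats(9, 4.92, 3.36, 1.27, 8.76),
        "on": PhaseStats(18, 0.54, 0.12, 0.44, 0.75),
        "off_post": PhaseStats(9, 4.28, 2.57, 0.44, 7.81),
    },
}

#: ICU per-sample TVOC summaries by phase (measured, not a sum of means).
ICU_TVOC_STATS: dict[str, PhaseStats] = {
    "off_pre": PhaseStats(9, 136.78, 61.82, 53.34, 215.74),
    "on": PhaseStats(18, 38.40, 16.20, 9.50, 68.20),
    "off_post": PhaseStats(9, 36.44, 15.81, 14.66, 57.85),
}

#: Isolated (unoccupied) room mean concentrations by phase, µg/m³.
ISOLATED_PHASE_MEANS: dict[str, dict[str, float]] = {
    "benzene": {"off_pre": 0.89, "on": 0.02, "off_post": 0.56},
    "toluene": {"off_pre": 8.47, "on": 0.08, "off_post": 5.20},
    "ethylbenzene": {"off_pre": 2.26, "on": 0.05, "off_post": 1.29},
    "m_p_xylene": {"off_pre": 3.69, "on": 0.01, "off_post": 0.22},
    "o_xylene": {"off_pre": 2.12, "on": 0.56, "off_post": 0.94},
    "styrene": {"off_pre": 3.72, "on": 0.30, "off_post": 1.62},
    "isopropylbenzene": {"off_pre": 1.80, "on": 0.87, "off_post": 0.25},
    "n_propylbenzene": {"off_pre": 3.19, "on": 0.73, "off_post": 0.95},
    "trimethylbenzene_124": {"off_pre": 1.23, "on": 0.88, "off_post": 0.57},
    "trimethylbenzene_135": {"off_pre": 4.55, "on": 1.73, "off_post": 1.33},
    "sec_butylbenzene": {"off_pre": 8.65, "on": 2.02, "off_post": 3.81},
    "isopropyltoluene_4": {"off_pre": 3.73, "on": 0.93, "off_post": 1.71},
    "n_butylbenzene": {"off_pre": 1.20, "on": 0.26, "off_post": 0.61},
    "naphthalene": {"off_pre": 2.70, "on": 0.25, "off_post": 1.97},
}

#: Sample counts behind the isolated-room mean columns.
ISOLATED_PHASE_N: dict[str, int] = {"off_pre": 9, "on": 18, "off_post": 9}
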