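"""Small builders for hand-made campaign records used across test modules."""

import aircheck as ac

_PHASE_WEEK = {"off_pre": 1, "on": 2, "off_post": 4}


def make_record(**overrides) -> ac.MeasurementRecord:
    base = dict(
        sample_id="s", week=1, day="Mon", session="morning",
        location="icu_point_1", acd_state="off", compound_id="benzene",
        concentration_ugm3=1.0, occupancy=None,
    )
    base.update(overrides)
    if "acd_state" not in overrides:
        base["acd_state"] = "on" if base["week"] in (2, 3) else "off"
    return ac.MeasurementRecord(**base)


def records_for_values(values, compound_id="benzene", phase="off_pre", **overrides):
    """One record per value, distinct sample ids, all in the given phase."""
    week = _PHASE_WEEK[str(ac.Phase(phase).value)]
    return [
        make_record(
            sample_id=f"{phase}-{i}", week=week, compound_id=compound_id,
            concentration_ugm3=float(v), **overrides,
        )
        for i, v in enumerate(values)
    ]


def one_sample(concs_by_compound, sample_id="s0", phase="off_pre", **overrides):
    """All compounds of a single sampling event."""
    week = _PHASE_WEEK[str(ac.Phase(phase).value)]
    return [
        make_record(
            sample_id=sample_id, week=week, compound_id=cid,
            concentration_ugm3=float(v), **overrides,
        )
        for cid, v in concs_by_compound.items()
    ]
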