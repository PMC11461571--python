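"""Inhalation cancer risk (CDI × IUR) and hazard index from phase means.

Run directly off the published reference-campaign phase means: the risk table
reproduces the published cells — naphthalene off_pre CR ≈ 1.57e-2 (class A,
definite risk) and HI ≈ 1.33 (harmful, above the RfC of 3.7 µg/m³).
"""

import aircheck as ac
from aircheck.campaign_stats import ICU_PHASE_STATS

scenario = ac.worker_scenario(mode="paper")  # 8 h/day, EF 257 d/y, 30 y over 70 y
summaries = ac.summaries_from_phase_means(
    {
        cid: {ph: ICU_PHASE_STATS[cid][ph].mean for ph in ("off_pre", "on", "off_post")}
        for cid in ac.PANEL_IDS
    }
)
table = ac.risk_table(summaries, scenario)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))

print("\nsame assessment under the strict EPA intake convention (AT in days):")
strict = ac.risk_table(summaries, ac.worker_scenario(mode="strict_epa"))
row = strict[(strict.compound_id == "naphthalene") & (strict.phase == "off_pre")]
print(f"naphthalene off_pre CR = {float(row.cancer_risk.iloc[0]):.3g} "
      "(paper-mode value / 365; hazard index unchanged)")
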