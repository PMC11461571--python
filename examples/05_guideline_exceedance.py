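"""Guideline exceedance check: benzene and TVOC maxima vs. authority limits.

Using the published reference-campaign summaries: the pre-installation TVOC
maximum (215.74 µg/m³) exceeds the Turkish safe-green-buildings limit of
200 µg/m³ but stays under the 500 µg/m³ EPA/WHO/ASHRAE value, and the benzene
maximum (5.37 µg/m³) exceeds the 5 µg/m³ limits.
"""

import aircheck as ac
from aircheck.campaign_stats import ICU_PHASE_STATS, ICU_TVOC_STATS
from aircheck.summaries import ConditionSummary

summaries = []
for phase, st in ICU_TVOC_STATS.items():
    summaries.append(ConditionSummary(ac.TVOC, ac.Phase(phase), st.n, st.mean,
                                      st.sd, st.min, st.max))
for phase, st in ICU_PHASE_STATS["benzene"].items():
    summaries.append(ConditionSummary("benzene", ac.Phase(phase), st.n, st.mean,
                                      st.sd, st.min, st.max))

for e in ac.guideline_exceedance(summaries):
    if e.note:
        continue
    status = "EXCEEDED" if e.exceeded else "ok"
    print(f"{e.analyte:8s} [{e.phase:8s}] max {e.observed_max:6.2f} µg/m³ vs "
          f"{e.authority:6s} {e.limit_ugm3:5.0f} µg/m³  {status}")
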