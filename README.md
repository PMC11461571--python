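# aircheck

Analysis toolkit for indoor-air volatile-organic-compound (VOC) monitoring
campaigns with an on/off air-cleaning intervention, built around a
hospital intensive-care-unit (ICU) study design: a 14-compound aromatic panel
(benzene … naphthalene) sampled over a four-week off/on/on/off crossover at
two ICU points and an unoccupied isolated room.

It is written for exposure scientists and industrial hygienists who need to
turn a long-format campaign table into:

* **Condition summaries** — per compound × phase N, mean, SD, min, max
  (µg/m³), and TVOC as the per-sample panel sum;
* **Intervention efficiency** — percent reduction of phase means,
  `100·(mean_off − mean_on)/mean_off`;
* **Inhalation cancer risk** — `CR = CDI × IUR` with
  `CDI = C·(ET/24)·EF·ED/AT`, classified A (CR ≥ 10⁻⁴, definite risk) /
  B (≥ 10⁻⁵) / C (≥ 10⁻⁶) / D (< 10⁻⁶);
* **Non-cancer hazard** — `HI = C/RfC`, flagged harmful when HI > 1;
* **Inference** — per-compound one-way ANOVA of the air-cleaner contrast and
  of the >6-person occupancy contrast;
* **Guideline checks** — benzene and TVOC maxima against EPA/WHO/ASHRAE
  (500 and 5 µg/m³) and Turkish safe-green-buildings (200 and 5 µg/m³) limits.

Because the underlying raw measurements are available only on request, the
package ships a seeded lognormal campaign **generator** calibrated to the
published summary statistics, so every stage is testable end to end
(see `docs/methods.md` for the model and its limits).

## Worked example

```python
import aircheck as ac

records, truth = ac.generate_campaign(ac.default_config(), seed=42)

# intervention efficiency (off_pre vs on phase means, ICU points pooled)
for e in ac.reduction_table(records)[:3]:
    print(f"{e.compound_id}: {e.mean_off:.2f} -> {e.mean_on:.2f} µg/m³ "
          f"({e.reduction_pct:.1f}% reduction)")

# cancer risk for a naphthalene phase mean of 4.92 µg/m³
scenario = ac.worker_scenario(mode="paper")   # 8 h/day, 257 d/y, 30 y / 70 y
res = ac.cancer_risk(4.92, scenario, ac.lookup_tox("naphthalene"))
print(f"CR = {res.cr:.3g} (class {res.risk_class})")
print(f"HI = {ac.hazard_index(4.92, ac.lookup_tox('naphthalene')).hi:.2f}")
```

prints (seed 42):

```
benzene: 2.73 -> 0.85 µg/m³ (68.8% reduction)
toluene: 27.04 -> 6.33 µg/m³ (76.6% reduction)
ethylbenzene: 7.21 -> 1.84 µg/m³ (74.5% reduction)
CR = 0.0157 (class A)
HI = 1.33
```

The ~70% benzene reduction is the generator's calibrated truth showing
through a finite campaign; CR 1.57×10⁻² puts naphthalene in class A
(definite risk) for a healthcare worker, and HI 1.33 > 1 flags its off-phase
level as above the 3.7 µg/m³ reference concentration.

The `examples/` directory has one short script per capability
(simulation, summaries, risk, ANOVA/occupancy, guideline exceedance), and the
same functionality is scriptable via the thin `aircheck` CLI
(`simulate`, `validate`, `summarize`, `risk`, `anova`, `guidelines`, `run`).

Two intake conventions are provided: `mode="paper"` keeps the averaging time
in years (the convention under which the published risk tables of the
reference campaign reproduce) and `mode="strict_epa"` uses AT in days; the
two differ by exactly 365 and every output row is stamped with its mode.

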