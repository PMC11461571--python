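# Methods

## Scope and data model

The package analyses long-format VOC campaigns from a four-week crossover
design: air-cleaning devices off in week 1 (`off_pre`), on in weeks 2–3
(`on`), off again in week 4 (`off_post`). The experimental phase is derived
from the week alone; a stored ACD state that disagrees with its week warns
(or errors under `strict=True`), since real campaigns can deviate from plan.
Concentrations are µg/m³ throughout; no other unit system is supported.

The measurement panel is fixed at 14 aromatic compounds (benzene through
naphthalene). TVOC is always a derived per-sample sum over the panel, never a
stored analyte: summing the panel's *phase means* ("sum of column means") and
averaging *per-sample TVOC* are different statistics, and the package exposes
both because published summary tables mix them — the reference campaign's
printed ICU TVOC mean (136.78 µg/m³) is below the sum of its 14 printed
compound means (142.40 µg/m³), consistent with per-sample computation over
events with occasional missing analytes. The printed per-sample value is
therefore not used as a numerical target anywhere.

## Exposure and risk model

Cancer risk is `CR = CDI × IUR` with the intake term

    CDI = C · (ET/24) · EF · ED / AT

- `ET` exposure time, h/day (default 8 — an ICU shift),
- `EF` exposure frequency, days/year (see calibration below),
- `ED` exposure duration, years (default 30 — a working career),
- `AT` averaging time (default 70 years ≈ lifetime).

Two AT conventions are implemented and stamped on every output row:

- **paper mode** keeps AT in years. This is dimensionally loose (EF carries
  days/year) but is the convention under which the reference campaign's
  printed risk table reproduces; it is the default for reproduction work.
- **strict_epa mode** converts AT to days (`AT·365`), the standard EPA
  intake convention, recommended for new analyses. Paper-mode CDI is exactly
  365× the strict value for any inputs — an identity the tests enforce.

Since IUR is expressed per µg/m³, the concentration multiplies IUR directly;
no body-weight/breathing-rate conversion is introduced (the printed tables
are only reproducible without one, even though intake is nominally labelled
in mg/kg/day in the source convention).

**EF calibration.** The occupational scenario is stated as 260 working
days/year, but the printed risk cells are reproduced to ≤0.5% relative error
only with an effective exposure factor `(ET/24)·EF·ED/AT ≈ 36.71`, i.e.
EF ≈ 257 days/year; with EF = 260 the benzene cell is ~1% off. Both values
are stored (`EF_STATED = 260`, `EF_CALIBRATED = 257`); the default worker
scenario and all reproduction paths use 257, and the scenario fingerprint in
every output row records which was used.

**Risk classes.** CR ≥ 10⁻⁴ → A (definite), ≥ 10⁻⁵ → B (probable),
≥ 10⁻⁶ → C (possible), below → D (uncertain); boundaries inclusive upward
("10⁻⁴ and above" is A), tested at ±1 ulp. Note that under these thresholds
benzene and ethylbenzene off-phase risks (~5.7×10⁻⁴) are class A even though
the source narrative groups them as B; the package follows the stated
thresholds and leaves the narrative label to the reader.

**Hazard.** `HI = C/RfC`, harmful iff HI > 1 strictly; HI = 1 is reported
"at threshold". Compounds lacking an IUR or RfC yield explicit `no-IUR` /
`no-RfC` markers rather than exceptions so batch tables always complete.
Toxicology defaults: benzene IARC 1, IUR 6.0×10⁻⁶ (µg/m³)⁻¹, RfC 9.6 µg/m³;
ethylbenzene 2B, 2.5×10⁻⁶, 1300; naphthalene 2B, 8.7×10⁻⁵, 3.7; styrene 2A
and the xylenes group 3 without numeric values; the remaining panel members
carry no classification. Sources are free text (WHO, OEHHA, ATSDR).

## Inference

Per-compound one-way ANOVA compares off_pre vs on by default (the contrast
behind the headline ~70% reduction); a three-level off_pre/on/off_post
variant is available. F is accumulated from literal between/within sums of
squares and the p-value is the upper F tail (regularized incomplete beta).
For two groups this equals the squared pooled-variance t test, enforced to
10⁻⁹ in tests. Raw per-compound p-values are reported by default, matching
the single-compound reporting convention of monitoring studies; an optional
Benjamini–Hochberg column is available. Zero-variance groups produce flagged
degenerate results (p = 0 when means differ, undefined when they do not)
rather than exceptions. The occupancy contrast splits ICU events at
>6 persons present; records without a head count are dropped and counted.

## Synthetic campaign generator

Concentrations are lognormal: positive, right-skewed, with SDs comparable to
means as in the published summaries. Each compound is parameterized by its
*arithmetic* off-phase mean and geometric SD, converted internally to
lognormal (µ, σ), so defaults are read straight off the published
pre-installation summaries. One draw per event is multiplied by

- `(1 − r)` in on-phase weeks, with per-compound reduction fractions `r`
  defaulting to the published off→on mean ratios (benzene 0.690, toluene
  0.754, o-xylene 0.645 — mean 69.6%, the "about 70%" headline);
- a session multiplier (morning 1.1 / afternoon 0.9 — ward rounds and
  cleaning happen in the morning);
- an occupancy factor `exp(slope·(persons − 4))` with slope 0.08/person.
  Head counts are a two-component mixture per session (high-occupancy
  probability 0.7 mornings / 0.15 afternoons; 7–10 vs 2–6 persons), chosen so
  the >6-person contrast is detectable at campaign size. The factor is
  divided by its exact per-session expectation, so it adds variance without
  shifting the configured mean;
- an isolated-room attenuation of 0.34 (the unoccupied room's published
  off-phase TVOC is about a third of the ICU's), with occupancy fixed at 0.

Because the published SDs are *marginal* over sessions and occupancy states,
the baseline GSD is deflated by the analytic CV of the session×occupancy
factor (≈0.21) so that the marginal CV of generated off-phase data matches
the published SD/mean. Both off weeks share the off_pre baselines — the
published off_post means differ (the two off weeks were not exchangeable in
reality), and modelling that drift is out of scope; recovery tests therefore
use the off_pre baseline.

Seeding: one master seed; each compound's stream is keyed by
`(seed, crc32(compound_id))` and occupancy by its own key, so the same seed
reproduces a campaign byte for byte and adding a compound never perturbs the
others. Events are independent: no within-day or within-week autocorrelation
is modelled, and no ventilation physics — passing tests on synthetic data
demonstrate the statistical machinery, not atmospheric realism.

## Numerical and reporting choices

- Sample SD uses the n−1 divisor; SD is absent (not 0) for n = 1.
- Generated concentrations are rounded to 10⁻⁶ µg/m³ so CSV round-trips are
  field-exact; analysis carries full double precision, and display rounding
  (2 decimals for µg/m³, 3 significant figures for risks) is opt-in at the
  reporting layer only.
- Guideline exceedance is flagged on the phase **maximum** (worst case, the
  whisker value used in such comparisons), with the mean reported alongside
  and the trigger annotated.
- Reduction percentages require a positive off-phase mean; increases are
  negative and values are capped at 100 by construction.

## Problem sizes used in the automated checks

Monte Carlo checks run at sizes chosen to make their bands sharp at desk
scale: 1000 replicates for the null rejection rate of the off/on ANOVA at
campaign group sizes (12 vs 24), 200 calibrated synthetic campaigns for the
power of the five compounds reported significant, and 200 seeds × 500
samples/arm for reduction recovery (where the ±0.05 band is ≈5 standard
errors wide, so coverage near 100% is expected).

## Known limitations

- Lognormality and event independence are assumptions of convenience;
  real campaigns show temporal structure the generator does not emulate.
- The intake model is a single deterministic scenario — no probabilistic
  (Monte Carlo) exposure assessment, no dermal/oral routes, no mixture
  interactions.
- The crossover is analysed as independent groups, not with repeated-measures
  or mixed-effects structure; with 9–18 samples per cell this is the same
  resolution as the published analysis, but it ignores day/session pairing.
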