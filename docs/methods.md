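# Methods

This note documents the models implemented in `ohra`, the defaults chosen
where the source frameworks leave gaps, what the synthetic survey generator
does and does not emulate, and the package's known limitations. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Unit of assessment

All models operate on a **similar exposure group (SEG)**: workers sharing a
process and therefore an exposure profile. A SEG record carries the work
schedule (hours/day `D`, days/week, from which the weekly frequency `F` and
the EPA exposure frequency `EF` derive), solvent usage, the measured 8-h
time-weighted average concentration `C-TWA` (the magnitude `M`), the
short-term concentration `C-STEL`, and categorical control measures
(automation, ventilation, PPE, first aid, emergency readiness, health
management). Compliance is judged against the permissible limits PC-TWA and
PC-STEL of the chemical profile; the shipped n-hexane profile uses
PC-TWA = 100 mg/m³ and PC-STEL = 180 mg/m³ (configuration taken from the
applicable exposure-limit standard, not survey data).

## The models

### EPA hazard quotient

`EC = CA·ET·EF·ED/AT` with `AT = ED·365·24` hours; `ED` cancels and the code
therefore never multiplies it in (EC is tested to be invariant to ED and
linear in CA, ET and EF; with ET = 24 and EF = 365, EC = CA). `HQ = EC/RfC`,
with `HQ ≥ 1` unacceptable (the boundary itself is unacceptable).

**RfC default.** The chronic inhalation reference concentration shipped for
n-hexane is **0.7 mg/m³** (the EPA IRIS value). Parts of the applied
literature quote 2 × 10⁻³ mg/m³ for n-hexane; with that value virtually every
measurable workplace exposure is flagged, and it is not consistent with
hazard-quotient magnitudes typically reported alongside workshop TWA levels.
Both behaviours are reachable: `epa.rfc_override` takes precedence over the
profile value, so users who prefer the stricter figure set it in one line.

**HQ → ordinal level.** The EPA framework itself yields a binary verdict.
For cross-model harmonization the package bands HQ at
`{0.1, 0.5, 1, 10}` onto levels 1–5 ([lower, upper) intervals), so every
unacceptable quotient lands at level 4 or 5, i.e. RR ≥ 0.8 on the 5-level
scale. The thresholds are configuration (`epa.level_thresholds`).

`EF` derives from the schedule as `days_per_week × 52` (capped at 365); the
weeks-per-year factor is configurable.

### MOM and GBZ/T 298-2017 semi-quantitative methods

All five methods share the risk matrix

    risk_raw = sqrt(HR × ER),  level = round_half_away(risk_raw) ∈ {1..5}.

The square root is a deliberate reading of the source guideline's
"Risk = HR × ER" shorthand: with HR and ER both on 1–5 scales a literal
product ranges to 25 and cannot be an ordinal 1–5, while the square-root
risk matrix is the published MOM rule and reproduces the observed ceiling —
a hazard-rating-2 substance like n-hexane can reach at most
round(√10) = 3 ("medium"), whatever its exposure rating. Rounding is
half-away-from-zero (2.5 → 3); the guideline says only that non-integers are
rounded, and half-away is the convention of the originating frameworks.

**Hazard rating (HR).** Banded from acute toxicity with conservative-maximum
over all available bases (oral LD50, inhalation LC50, carcinogenicity class —
either IARC or ACGIH codes are accepted; no precedence, the worst wins). The
default oral-LD50 bands (mg/kg, intervals (lower, upper] so an edge value
keeps the more severe rating) are

    (0, 25] → 5, (25, 200] → 4, (200, 2000] → 3, (2000, 50000] → 2, else 1,

placing n-hexane (LD50 = 25 g/kg) at HR 2 — the one hard calibration point
the banding must satisfy, enforced by unit test. LC50 bands (mg/L, 4-h rat)
and the carcinogen-class map are likewise editable defaults.

**Exposure ratio methods (MOM-ER, GBZ-ER).** `E = F·D·M/W` with the 40-h
reference week; `E/OEL` is banded at `{0.1, 0.5, 1, 2}` onto ER 1–5
([lower, upper) intervals). The two methods are the same computation reading
separate config blocks (`semiquant.mom`, `semiquant.gbz`), so they agree
exactly under identical tables but remain independently editable.

**Exposure index methods.** `ER = (∏ EIᵢ)^(1/n)` (geometric mean, bounded by
the smallest and largest factor). MOM-EI uses four factors: vapour-pressure
band (kPa edges 0.1/1/10/50 — n-hexane's 17.6 kPa bands to 4), engineering
controls (ventilation × automation table: local exhaust 1/2/3 and general
ventilation 3/4/5 for full/semi/manual), weekly usage (kg-or-L edges
1/10/100/1000) and weekly hours (edges 10/20/40/50). GBZ-EI adds emergency
readiness (complete 1 / incomplete 4), PPE (worn 1 / provided-but-unworn 3 /
absent 5) and health management (good 1 / poor 3 / none 5). GBZ-SI is GBZ-EI
with the banded `E/OEL` appended as one more sub-index. None of these band
edges are printed in the applied literature; they are best-effort defaults
from the underlying guidelines and are all configuration.

**Usage units.** Surveys report solvent usage as "kg/L" without resolving
mass vs volume; the package stores a single magnitude with that unit tag and
never converts between the two.

### COSHH control banding

Hazard group A–E from the configured risk-phrase map (R48 → D drives
n-hexane); volatility from the boiling point on the room-temperature chart
(high < 50 °C ≤ medium < 150 °C ≤ low; n-hexane at 69 °C is medium);
quantity from weekly usage (< 1 kg small, < 1000 kg medium, else large).
The base exposure potential (1–4) comes from the quantity × volatility
matrix; **open handling** — general ventilation only, or fully manual
operation — raises it one step (capped at 4). This per-record resolution of
the "2–3" exposure-potential spread reported for such surveys is a design
choice: the published per-group descriptors are not available, so openness of
handling is the observable that splits a category. The risk matrix defaults
satisfy (D, 3) → 4 and (D, 2) → 3.

### ICMM matrix

Consequence 1–5 banded from toxicity like HR (n-hexane → 2); likelihood from
`E/OEL` with edges 0.5 and 1.0 ([lower, upper) bands: below half the limit is
"low"); the consequence × likelihood matrix outputs a 4-level risk. Defaults
satisfy (2, low) → 1 and (2, high) → 3.

### Harmonization

`RR = level / scale_size`. Scale sizes are metadata attached to every result:
ICMM 4, COSHH 4, EPA 5, all semi-quantitative methods 5. The 4-level scales
are an inference from how the matrix models' medians are reported (a modal
lowest ICMM verdict corresponds to RR 0.25 = 1/4; a modal top COSHH verdict
to RR 1 = 4/4). RR bands are `[0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8),
[0.8, 1]` — half-open with the top closed, the only convention under which a
level-1 verdict on a 5-level scale (RR = 0.2) falls in band 2 and a maximal
verdict (RR = 1) in band 5. Four-level label vocabulary reuses the five-level
wording with "low" skipped (potential / medium / high / very high).

### Consistency statistics

Kruskal–Wallis is scipy's tie-corrected H (ties are pervasive in RR data);
the degenerate all-identical case returns (H = 0, p = 1) by convention rather
than the undefined tie correction. The pairwise stage is Dunn-type z-tests on
mean ranks with the standard tie correction, Bonferroni-adjusted by default
(the adjustment method is an argument; any statsmodels `multipletests`
method works). Dunn's procedure is implemented in the package because no
installed dependency provides it.

Cohen's kappa is unweighted, computed on the five RR bands (not raw levels)
from the contingency table over the full band space, with statsmodels'
large-sample two-sided p-value against kappa = 0. Two identical vectors are
perfect agreement by construction (kappa = 1, p undefined) — this also covers
the constant-marginal case where the sample estimator is 0/0. Interpretation
bands partition [−1, 1] at 0.2/0.4/0.6/0.8 (poor / general / medium /
strong / very strong).

## Synthetic survey generator

The generator emulates the published per-category summary statistics of an
84-group printing-industry n-hexane survey (32 printing, 17 oil-blending,
14 cleaning, 21 pasting): log-normal concentrations and usage with
`exp(μ)` = the printed median and σ chosen so the central ~99% interval spans
the printed range (samples clipped to the range, which leaves the median
untouched); `C-STEL = C-TWA ×` a log-normal excursion factor floored at 1
(median = the ratio of printed medians, σ = 0.5, capped at the printed
maximum); schedules as discrete distributions with 70% mass on the printed
median; control measures as independent Bernoulli/categorical draws at the
printed proportions, with PPE use conditioned on PPE provision. One
`numpy` sub-stream per category (keyed by seed and category position) keeps
categories reproducible independently of each other.

What it does **not** emulate: per-group joint structure. Correlations among
controls (PPE vs management quality), between usage and concentration, and
between schedule and concentration were never published and are modelled as
independence. Passing tests on synthetic data therefore demonstrate the
pipeline's correctness and the models' structural behaviour under realistic
marginals — not agreement with any real enterprise's joint exposure profile.
In particular the pairwise kappa values on synthetic data are emergent, not
calibrated.

**A known internal inconsistency of the calibration source.** The published
summary's E/OEL column (e.g. printing median 0.22) cannot be reproduced from
its own concentration medians and the weekly-exposure formula
(F = 6, D = 8, M = 8.10, W = 40 gives E/OEL ≈ 0.097); no schedule within the
printed ranges closes the 2× gap. The package follows the formula. On
formula-consistent synthetic data the exposure-ratio method's median verdict
is level 1 (RR 0.2) rather than level 2 (RR 0.4), so the qualitative
median-RR ordering reproduced by the pipeline is
`COSHH ≥ EPA ≥ index methods ≥ MOM-ER` with `ICMM ≤ index methods`; the
published `MOM-ER ≥ ICMM` link depends on the inconsistent E/OEL column and
is not asserted. Generator parameters were set from the published summaries
once and are not tuned to force that link.

## Numerical and interface choices

* Band lookups are `bisect`-based half-open intervals; ascending bands are
  [lower, upper), toxicity (dose) bands (lower, upper] so edge doses keep the
  severer rating. Every table is validated (ordered, exhaustive) and every
  matrix is validated (complete, monotone along both axes) at construction
  and again on config load.
* Medians of even-length samples are the midpoint of the two central order
  statistics.
* Missing `weekly_usage` derives as `daily_usage × days_per_week`.
* SEG tables are plain CSV with columns equal to the record field names, read
  with round-trip float precision so write→read is the identity on validated
  records; configs are JSON or YAML; reports are JSON with CSV side-tables.
* The pipeline is deterministic given (records, profile, config); the report
  carries a provenance block (config hash, method list, package version), and
  config blocks running on shipped defaults are logged for auditability.
* Problem sizes used in the checks: the acceptance-style suites run the
  84-group layout for pipeline-level assertions, n = 10,000 single-category
  draws for generator-recovery checks, and 200 replicates for the
  permutation-null uniformity check of the rank test — sizes chosen to make
  sampling error negligible relative to the asserted tolerances.

## Limitations

* Group-level only; no worker-level modelling, no dermal-route
  quantification, no carcinogenic (slope-factor) EPA pathway.
* COSHH control-guidance-sheet selection (the "what to do" output) is out of
  scope; only the risk band is produced.
* The GBZ sub-index band edges live in the national standard, not in the
  applied literature this package accompanies; the shipped defaults are
  reasonable but explicitly editable, and conclusions sensitive to them
  should be re-run under the user's own tables.
* Published pairwise kappa values for real surveys cannot be recomputed from
  summary tables (the per-group joint labels are unpublished); the package
  treats them only as interpretation-band examples.
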