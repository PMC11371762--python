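# ohra — occupational health risk assessment of airborne chemical exposure

`ohra` implements, as one tested pipeline, the five occupational-health-risk-assessment
model families commonly applied to volatile solvents such as n-hexane in small
workplaces, plus the machinery needed to compare their verdicts:

* **EPA hazard quotient** — non-carcinogenic inhalation risk,
  `EC = CA·ET·EF·ED / AT` with `AT = ED·365·24` (so ED cancels) and
  `HQ = EC / RfC`; `HQ ≥ 1` is an unacceptable risk.
* **Singapore MOM semi-quantitative model** — exposure-ratio and
  exposure-index methods sharing the risk matrix `risk = √(HR·ER)`, rounded
  half away from zero to an ordinal 1–5 (potential / low / medium / high /
  very high). The exposure ratio bands `E/OEL` with `E = F·D·M/W`
  (W = 40-h reference week); the exposure index is the geometric mean
  `ER = (EI₁·EI₂·…·EIₙ)^(1/n)` of ordinal sub-indices (vapour pressure,
  engineering controls, weekly usage, weekly hours).
* **GBZ/T 298-2017 (China)** — exposure-ratio, exposure-index and
  synthesis-index methods; the index variants extend the MOM factor set with
  emergency readiness, PPE and health management, and the synthesis index
  folds the banded `E/OEL` back into the geometric mean.
* **COSHH control banding** — hazard group A–E from risk phrases (R48 → D)
  crossed with an exposure potential 1–4 from quantity, volatility and
  openness of handling.
* **ICMM risk matrix** — health consequence 1–5 crossed with exposure
  likelihood (`E/OEL < 0.5` low, `< 1` medium, `≥ 1` high).

Because the models grade on different ordinal scales (4 levels for the matrix
models, 5 for the rest), verdicts are harmonized by the **risk ratio**
`RR = level / scale_size ∈ (0, 1]`, banded onto five standard intervals
(`[0, 0.2)` potential … `[0.8, 1]` very high), and compared with
tie-corrected Kruskal–Wallis (plus Dunn-type pairwise rank tests) and
unweighted Cohen's kappa on the RR bands.

Every threshold the models read — toxicity bands, E/OEL band edges, both risk
matrices, the HQ-to-level mapping — is editable, validated configuration
(`BandingConfig`), never a buried constant. A seeded generator produces
synthetic similar-exposure-group (SEG) survey tables with the statistical
structure of a printing-industry n-hexane survey (log-normal concentrations,
realistic schedules and control-measure proportions), so the whole pipeline is
testable without confidential enterprise data.

Intended users: occupational hygienists and public-health researchers
comparing risk-assessment frameworks, and developers who need a reproducible
reference implementation of these banding schemes.

## Worked example

```python
import statistics
from ohra import (BandingConfig, default_hexane_profile,
                  default_generator_spec, generate_segs, run_pipeline)

cfg = BandingConfig.default()
chem = default_hexane_profile()          # PC-TWA 100, PC-STEL 180, RfC 0.7 mg/m^3
segs = generate_segs(default_generator_spec(), seed=1)   # 84 synthetic SEGs
report = run_pipeline(segs, chem, cfg)

med = {}
for h in report.harmonized:
    med.setdefault(h.method.value, []).append(h.rr)
for m in ["coshh", "epa", "mom_ei", "gbz_ei", "gbz_si", "mom_er", "icmm"]:
    print(f"{m:8s} median RR = {statistics.median(med[m]):.2f}")
print(f"Kruskal-Wallis H = {report.kw.h_statistic:.1f}, p = {report.kw.p_value:.3g}")
print(f"kappa(gbz_ei, gbz_si) = {report.kappa.loc['gbz_ei','gbz_si']:.3f}")
```

prints

```
coshh    median RR = 1.00
epa      median RR = 0.80
mom_ei   median RR = 0.60
gbz_ei   median RR = 0.60
gbz_si   median RR = 0.40
mom_er   median RR = 0.20
icmm     median RR = 0.25
Kruskal-Wallis H = 414.3, p = 2.36e-86
kappa(gbz_ei, gbz_si) = 0.590
```

Reading the output: control banding (COSHH) grades this survey hardest — a
hazard-group-D solvent handled openly in kilogram quantities is "very high
risk" regardless of measured air levels — while the hazard quotient flags most
groups because the chronic reference concentration sits far below typical
workshop air levels. The index methods cluster in the middle, the
exposure-ratio and ICMM methods grade lowest because most measured exposures
sit well under the occupational limit. The methods differ significantly
(Kruskal–Wallis p ≪ 0.05), and the two Chinese index methods agree moderately
(kappa ≈ 0.59) because they share most of their factor set.

The same pipeline is available from the shell:

```bash
ohra simulate --seed 1 --out segs.csv
ohra assess --input segs.csv --out report.json
ohra compare --report report.json --out-dir tables/
```

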