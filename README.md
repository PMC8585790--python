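# riskport

Polygenic and clinical genomic risk, computed and communicated: a Python
package for teams returning disease-risk estimates to individuals — study
pipelines, biobank risk-disclosure projects, and preventive-care tooling.

`riskport` covers the full computational chain for a type 2 diabetes (T2D)
risk-disclosure study:

- **Polygenic risk scores** (`riskport.prs`): strand-ambiguity filtering,
  effect-allele harmonization against ALT-oriented VCF dosages, weighted
  summation with Hardy–Weinberg mean substitution for missing variants
  (`2·f` per missing dosage), and standardization against an independent
  reference population: `z = (PRS − μ_ref)/σ_ref`.
- **10-year absolute risk** (`riskport.riskmodel`): a Cox proportional-
  hazards model (Breslow partial likelihood, Newton–Raphson) over age, sex,
  BMI, total and HDL cholesterol, systolic blood pressure, medication and
  family-history flags, smoking, and the standardized PRS. The exported
  summary (β̂, covariate means x̄, Breslow baseline cumulative hazard H0)
  yields `risk = 1 − exp(−H0(10)·exp(β̂ᵀ(x − x̄)))`, plus an age-60
  projection and a counterfactual lifestyle calculator (BMI, blood
  pressure, smoking).
- **Single clinical variants** (`riskport.scv`): carrier calling for six
  shipped actionable variants (F5 Leiden, F2, three LDLR familial-
  hypercholesterolemia founder variants, SLCO1B1 rs4149056), an automated
  genotype-cluster QC score in contrast/strength intensity space, and the
  per-variant escalation rules (physician mention → personal contact).
- **Report rules** (`riskport.reporting`): thermometer risk categories
  (0–5 / 5–10 / 10–20 / >20%), the (risk × age group) doctor's-note
  recommendation matrix, PRS population percentiles, seeded two-arm RCT
  allocation, uptake percentage summaries, and schema-validated portal
  payloads.
- **Synthetic cohorts** (`riskport.simdata`): Hardy–Weinberg genotypes,
  scoring tables, realistic covariates and proportional-hazards event
  times (default PRS hazard ratio 1.5 per SD), so the whole pipeline runs
  and is tested entirely offline.

## Worked example

Simulate a cohort, fit the risk model, and score one high-risk individual:

```python
import math
from riskport import simdata, riskmodel, reporting
from riskport.riskmodel import CovariateVector
from riskport.simdata import SimConfig

sim = simdata.simulate_cohort(SimConfig(seed=42, n_samples=6000, n_prs_variants=60))
model = riskmodel.fit_cox(sim.cohort, "full")
print("HR per SD of PRS:", round(math.exp(model.beta["prs_z"]), 3))

x = CovariateVector(age=45, sex=1, bmi=31.0, total_chol=5.8, hdl=1.1,
                    sbp=142.0, bp_med=0, lipid_med=0, family_history=1,
                    smoking=1, prs_z=1.2)
est = riskmodel.absolute_risk(model, x)
cat = reporting.categorize_risk(est)
note = reporting.select_doctors_note(cat, reporting.age_group(x.age))
print("10-year risk:", round(100 * est.probability, 1), "%")
print("category:", cat.value, "| note:", note.recommendation.value)
print("risk at 60:", round(100 * riskmodel.project_risk_at_age(model, x, 60.0).probability, 1), "%")
before, after = riskmodel.risk_calculator(model, x, {"bmi": 25.0, "smoking": 0})
print("after losing weight and quitting smoking:", round(100 * after.probability, 1), "%")
```

Output:

```
HR per SD of PRS: 1.534
10-year risk: 21.8 %
category: very_high | note: recommended_to_see_physician
risk at 60: 41.4 %
after losing weight and quitting smoking: 11.9 %
```

The fitted hazard ratio recovers the simulator's generating value of 1.5
per SD of PRS. This 45-year-old smoker with BMI 31 and a PRS 1.2 SD above
the population mean has a 21.8% 10-year risk — in the "very high" band, so
the doctor's note recommends seeing a physician. Were their lifestyle
factors to stay unchanged, their 10-year risk at age 60 would be 41.4%;
the calculator shows that normal weight and quitting smoking would roughly
halve today's risk.

The same chain runs from the shell:

```sh
riskport simulate --seed 3 --out sim/
riskport score --vcf sim/genotypes.vcf --weights sim/weights.tsv \
               --ref-stats sim/ref_stats.json --out scores.tsv
riskport fit --cohort sim/cohort.tsv --covariates full --out model.json
riskport scv --vcf sim/genotypes.vcf --out scv_results.tsv
riskport report --model model.json --scores scores.tsv \
                --people sim/cohort.tsv --scv scv_results.tsv \
                --rct-seed 11 --out payloads/
```

## Layout

```
src/riskport/
  variantio.py   VCF/TSV/JSON I/O and the variant/genotype data model
  prs.py         ambiguity filter, harmonization, scoring, standardization
  riskmodel.py   Cox fit, baseline hazard, absolute risk, projections
  scv.py         carrier calling, cluster QC, note routing (+ data/*.json)
  reporting.py   categories, note matrix, RCT allocation, portal payloads
  simdata.py     synthetic genotypes, weights, covariates, event times
  cli.py         `riskport` command-line front end
docs/methods.md  model descriptions, assumptions, and design choices
```
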