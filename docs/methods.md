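# Methods

This note documents the models and procedures implemented in `riskport`, the
assumptions behind them, and the choices made where the design was open.

## Scope

`riskport` implements the computational core of a genomic-risk-disclosure
pipeline for type 2 diabetes (T2D): a polygenic risk score (PRS) computed
from genotype dosages; a Cox proportional-hazards model whose exported
summary statistics drive 10-year absolute risk predictions, an age-60
projection and a counterfactual lifestyle calculator; carrier calling for
six individually actionable single clinical variants (SCVs) with an
automated genotyping-cluster QC; a rule engine producing risk categories,
doctor's-note recommendation levels and randomized disclosure-arm
allocations; and a synthetic-cohort simulator so that the entire chain is
testable without access to any cohort data. Web-portal infrastructure,
questionnaires, register linkage, imputation, and the derivation of the
scoring weights themselves are out of scope — weights and dosages are
consumed as given.

## Polygenic risk score

The score for sample *s* is the weighted allele-dosage sum

    PRS_s = Σ_i w_i · d_si ,

where `w_i` is the per-effect-allele weight and `d_si` the effect-allele
dosage in [0, 2]. Processing order:

1. **Ambiguity filter.** A/T and C/G polymorphisms carry the same allele
   pair on both DNA strands, so their orientation cannot be resolved from
   alleles alone; they are removed outright. There is deliberately no
   frequency-based strand rescue.
2. **Harmonization.** Genotype dosages are ALT-oriented at the I/O layer.
   Weight variants are matched by (chromosome, position); if the effect
   allele is ALT the dosage is used as-is, if it is REF the dosage becomes
   `2 − d`. Allele sets that match in neither orientation are dropped and
   counted (`dropped_mismatch`); large published scores always contain some
   discordances, so mismatches are logged, never fatal.
3. **Missingness substitution.** A missing dosage (per-sample missing, or
   the whole variant absent from the genotype data) is replaced by its
   expected value under Hardy–Weinberg, `2·f_i`, with `f_i` the
   effect-allele frequency. Frequencies come from the scoring file (the
   score-derivation population) by default, so scores are deterministic and
   independent of cohort composition; cohort-frequency substitution and a
   strict failure mode are available behind a flag.
4. **Standardization.** `z = (PRS − μ_ref)/σ_ref` against the mean/SD of an
   independent reference population, carried as a small JSON artifact.
   Self-standardization is possible but must be requested explicitly.

Coverage (the fraction of weight variants found in the genotypes) is
reported with two denominators — the full table and the post-ambiguity-filter
table — because either convention is defensible.

## Survival model and absolute risk

A Cox proportional-hazards model is fitted by Newton–Raphson on the
Breslow-ties partial likelihood, with step-halving on likelihood decrease.
Convergence requires the score's maximum absolute component below 1e-8 or a
relative log-likelihood change below 1e-10, within 50 iterations. Standard
errors come from the inverse observed information.

Covariates (units): age (years), sex (0/1), BMI (kg/m²), total cholesterol
and HDL (mmol/L), systolic blood pressure (mmHg), blood-pressure and
lipid-lowering medication (0/1), family history of T2D (0/1), smoking (0/1),
and the standardized PRS (SD units). Smoking and family history are binary
codings. The "traditional" model is the same fit without the PRS term.

The baseline cumulative hazard is the Breslow estimator evaluated with
covariates centered at the training means,

    H0(t) = Σ_{t_k ≤ t} d_k / Σ_{j ∈ R(t_k)} exp(β̂ᵀ(x_j − x̄)) ,

a right-continuous step function on the event-time grid, extrapolated as
constant beyond the last event time (with a logged warning). At β = 0 it
reduces exactly to the Nelson–Aalen estimator, which the tests assert.

The absolute risk over a horizon (10 years by default) is

    risk = 1 − exp(−H0(t) · exp(β̂ᵀ(x − x̄))) .

Centering at the training means mirrors standard survival-package prediction
semantics and makes the exported summary (β̂, x̄, H0 grid, all in one JSON
document) a self-contained transfer artifact: predictions after an
export/import round-trip are bit-identical.

**Age projection.** The projected "risk at 60" replaces the age covariate
only; the time scale remains follow-up time. Because the training design
covers ages 24–75, evaluation ages are clamped to that interval, and
individuals already older than 75 are evaluated at 75 regardless of target.
Delayed entry / left truncation and an age time-scale are not modeled; this
is an explicit simplifying assumption.

**Lifestyle calculator.** Only BMI, systolic blood pressure and smoking may
be changed counterfactually; the "after" risk re-evaluates the same formula.
The complementary-log-log difference between after and before equals the
summed coefficient change exactly, which the tests use as an algebraic
oracle.

Ties use the Breslow approximation throughout — consistent with the
Breslow baseline and adequate for continuous simulated times. Competing
risks, time-varying covariates and model selection are non-goals.

## Single clinical variants

Six definitions ship as an editable JSON table: F5 "Leiden"
(1:169549811 C>T, Finnish MAF 0.02) and F2 (11:46739505 G>A, MAF 0.0046)
for venous thromboembolism; the LDLR founder variants FH_Turku
(19:11129654 G>A), FH_Pori (19:11113293 T>A) and FH_Pogosta
(19:11116937 G>A, MAF 0.0002) for familial hypercholesterolemia; and
SLCO1B1 rs4149056 (12:21178615 T>C, MAF 0.21), a pharmacogenetic variant
relevant to statin therapy. Population frequencies for FH_Turku and FH_Pori
are left empty because no established Finnish figure is carried here.

Carrier status derives only from the risk-allele count: 0/1/2 →
non-carrier / heterozygote / homozygote. Fractional dosages are hard-called
only within ±0.1 of an integer; anything else is a no-call — a deliberate
confidence policy, since these results are individually actionable.

Note routing: F5/F2 heterozygotes are advised to mention the result to
their physician (VTE information); SLCO1B1 carriers (het or hom) to mention
it if cholesterol-lowering medication is planned — the note text also says
not to stop existing statins; F5/F2 homozygotes and all FH carriers take
the personal-contact path (a doctor phones). Extending personal contact
from the demonstrated cases (F5 homozygote, FH_Pogosta heterozygotes) to
all FH variants and to F2 homozygotes is a documented generalization: these
genotypes are at least as consequential as the demonstrated ones.

**Cluster QC.** Visual inspection of genotyping clusters is operationalized
as a centroid-separation score in (contrast = log2(a/b),
strength = log2(a·b)/2) space — the standard Axiom-style transformation,
invariant (up to a shift) under uniform scaling of both channels. The score
is the minimum over genotype-class pairs of centroid distance divided by
the sum of within-class RMS radii; QC passes at ≥ 2.0 (configurable, with
the boundary value passing). Fewer than two classes with at least two
samples each yields an indeterminate failure with a reason, not an
exception.

## Reporting rules

Risk categories partition [0, 100]% as left-closed/right-open intervals:
[0,5) low, [5,10) increased, [10,20) high, [20,100] very high. The
published wording leaves the 20% boundary ambiguous (">20%" vs "10–20%");
one convention — 20% is very high — is pinned and table-tested. Age groups
are <50, 50–75 (inclusive), >75; the over-75 note matrix reuses the 50–75
rules, with risk evaluated at age 75.

The doctor's-note matrix: under 50, low/increased → lifestyle guidance
only, high → *encouraged* to see a physician, very high → *recommended*;
from 50 upward, any risk of 10% or more → recommended. The engine returns
only the recommendation code plus a template id; note text is external and
localizable. A prevalent-disease flag adds a disclaimer (the risk is shown
as "if you did not already have the disease") without suppressing the
estimate.

Displayed percentages round to the nearest integer, half away from zero;
internal probabilities are never rounded. The PRS percentile shown on the
population curve is 100·Φ(z).

RCT allocation is a seeded uniformly random permutation split into two arms
differing in size by at most one (group 1: full risk information at first
release; group 2: traditional-only first). The historical cohort's printed
arm sizes differ by three, implying some other scheme; the balanced split
is retained as the cleaner default rather than guessing. The
"average risk of matched age population" shown beside a participant's own
risk is the cohort mean within their 5-year age band (width configurable).
The projected risk at 60 is included exactly for participants aged ≤ 50.

## Synthetic data

The simulator emulates the statistical structure the pipeline assumes, with
defaults fixed once as the study conditions:

- **Genotypes:** independent Hardy–Weinberg dosages, Binomial(2, MAF) per
  variant; ALT is the minor allele. No linkage disequilibrium and no
  population stratification — so passing tests say nothing about
  LD-sensitive behaviour of real scores.
- **Weight tables:** 200 variants by default, MAFs uniform on (0.05, 0.5),
  zero-mean normal weights rescaled so the Hardy–Weinberg raw-score SD is
  exactly 1; an optional fraction of strand-ambiguous variants exercises
  the filter.
- **PRS:** computed from the simulated genotypes through the package's own
  scoring path and standardized against an independently simulated
  reference panel of 10,000, so the per-SD hazard ratio in the event model
  is directly the generating parameter.
- **Covariates:** age uniform on 24–75 (the training design's range); BMI,
  cholesterol, HDL, SBP log-normal with means near 27 kg/m², 5.4 mmol/L,
  1.5 mmol/L and 130 mmHg (≈16% above 140 mmHg); binary flags Bernoulli.
  These anchors are illustrative of a middle-aged Nordic cohort, not a
  calibration claim.
- **Event times:** exponential with hazard λ0·exp(βᵀ(x − x̄)), λ0 =
  0.005/yr, independent Exp(0.02/yr) censoring and a 15-year
  administrative cap, giving ≈10% events at default effect sizes. The
  generating per-SD PRS hazard ratio defaults to 1.5. The exponential
  choice gives the closed form 1 − exp(−λ0·t·e^lp) as an exact oracle for
  the absolute-risk machinery; a Weibull option exists for shape ≠ 1. A
  configuration whose event rate leaves (0.5%, 50%) triggers a warning.
- **Intensities:** per-genotype-class Gaussian clouds in contrast/strength
  space with centroid spacing proportional to a separation parameter;
  separation 0 collapses the clouds.

Every generator is a pure function of (configuration, seed); seeds are
mandatory. The true generating parameters are always emitted beside the
data.

## Numerical choices and problem sizes

- Scoring: exact arithmetic over double precision; the brute-force
  per-cell oracle agrees to 1e-12 on small problems.
- Cox fit: gradient tolerance 1e-8, relative log-likelihood tolerance
  1e-10, max 50 iterations, step-halving; linear predictors are shifted by
  their maximum before exponentiation (the partial likelihood is invariant
  to the shift).
- Default validation scales: parameter recovery uses 20 replicate cohorts
  of n = 50,000 (≈5,000 events each), where the fitted 95% CI covers the
  generating hazard ratio in ≥18/20 replicates; the carrier-count checks
  average ≥50 Hardy–Weinberg cohorts of n = 3,177; the end-to-end report
  run uses n = 5,000. These sizes make the whole suite run comfortably on
  one CPU while keeping Monte-Carlo error well inside the assertion
  tolerances.
- Hard-call tolerance ±0.1 and cluster-QC threshold 2.0 are policy
  constants, exposed as parameters.

## Known limitations

- No LD, imputation uncertainty, or strand inference from frequencies; the
  ambiguity filter is the only strand defence.
- Follow-up time scale with age as a covariate; no delayed entry. Risks
  for ages near the support boundary rely on the proportional-hazards
  extrapolation of the age coefficient.
- No competing-risks adjustment: the "10-year risk" is interpreted under
  the fitted censoring-independent hazard.
- The carrier-count consistency checks compare against Hardy–Weinberg
  expectations; a real cohort's counts can deviate from HWE (the homozygote
  count of the statin-transporter variant in the reference cohort sits
  about 9% above the HWE expectation at its published frequency).
- Multi-allelic VCF records are rejected by default ("split" is opt-in)
  because silent mis-orientation is the dominant scoring bug class.
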