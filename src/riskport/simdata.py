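"""Synthetic-data generators with the statistical structure the pipeline assumes.

Everything the pipeline consumes can be simulated offline: Hardy–Weinberg
genotypes at given minor-allele frequencies, scoring weight tables (with an
optional injected fraction of strand-ambiguous variants), risk-factor
covariates, proportional-hazards event times with a stated per-SD PRS hazard
ratio, and two-channel intensity clouds for cluster QC.

Every generator is a pure function of its configuration and an explicit seed;
there is no implicit entropy. The defaults encode the study conditions the
pipeline is built for: ages uniform on 24–75 (the training cohort's range),
mean BMI near 27 kg/m², a PRS hazard ratio of 1.5 per SD, and a constant
(exponential) baseline hazard chosen so that roughly 10% of a default cohort
has an event during follow-up. Event times are exponential by default because
the closed-form risk 1 − exp(−λ0·t·e^lp) then provides an exact oracle for
the absolute-risk machinery; a Weibull option exists for shape ≠ 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .prs import compute_raw_prs, harmonize, standardize
from .riskmodel import COVARIATE_ORDER, SurvivalCohort
from .scv import IntensityData
from .variantio import (
    GenotypeMatrix,
    ReferenceStats,
    VariantKey,
    WeightTable,
    WeightedVariant,
)

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_weights",
    "simulate_covariates",
    "simulate_cohort",
    "simulate_intensities",
    "DEFAULT_LOG_HRS",
]

_BASES = ("A", "C", "G", "T")
#: Unambiguous ref/alt pairs used for simulated PRS variants.
_SAFE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_AMBIG_PAIRS = (("A", "T"), ("C", "G"))

#: Generating log hazard ratios for the traditional risk factors (per unit).
DEFAULT_LOG_HRS: Mapping[str, float] = {
    "age": 0.055,          # per year
    "sex": 0.18,           # male vs female
    "bmi": 0.09,           # per kg/m^2
    "total_chol": 0.05,    # per mmol/L
    "hdl": -0.35,          # per mmol/L (protective)
    "sbp": 0.012,          # per mmHg
    "bp_med": 0.25,
    "lipid_med": 0.10,
    "family_history": 0.60,
    "smoking": 0.18,
}


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    ``prs_hr_per_sd`` is the hazard ratio per 1 SD of standardized PRS (the
    generating truth the fitting routine should recover). Rates are per year.
    A seed is mandatory; generators never draw implicit entropy.
    """

    seed: int
    n_samples: int = 5000
    n_prs_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    mafs: Sequence[float] | None = None
    ambiguous_fraction: float = 0.0
    prs_hr_per_sd: float = 1.5
    log_hrs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_HRS))
    baseline_hazard_rate: float = 0.005
    censoring_rate: float = 0.02
    follow_up_cap: float = 15.0
    reference_n: int = 10_000
    event_time_model: str = "exponential"
    weibull_shape: float = 1.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory for simulation")
        for name in ("baseline_hazard_rate", "censoring_rate", "follow_up_cap"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.prs_hr_per_sd > 0:
            raise ValidationError("prs_hr_per_sd must be > 0")
        if self.event_time_model not in ("exponential", "weibull"):
            raise ValidationError(
                f"event_time_model must be 'exponential' or 'weibull', "
                f"got {self.event_time_model!r}"
            )


@dataclass
class TrueParameters:
    """Generating values emitted beside every simulated cohort."""

    log_hrs: dict[str, float]
    prs_hr_per_sd: float
    baseline_hazard_rate: float
    censoring_rate: float
    follow_up_cap: float
    event_time_model: str
    covariate_means: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    weights: WeightTable
    reference_stats: ReferenceStats
    cohort: SurvivalCohort
    true_parameters: TrueParameters


def simulate_genotypes(
    n: int,
    mafs: Sequence[float],
    seed: int,
    chrom: str = "1",
    start_pos: int = 10_000,
    sample_prefix: str = "S",
    pairs: Sequence[tuple[str, str]] | None = None,
) -> GenotypeMatrix:
    """Hardy–Weinberg genotypes: dosage ~ Binomial(2, maf) per variant.

    ALT is the minor (frequency-``maf``) allele; positions are consecutive
    on one chromosome unless ``pairs``/coordinates are customized.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs >= 1)):
        raise ValidationError("every MAF must lie strictly in (0,1)")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)
    if pairs is None:
        pairs = [_SAFE_PAIRS[j % len(_SAFE_PAIRS)] for j in range(len(mafs))]
    keys = [
        VariantKey(chrom=chrom, pos=start_pos + j, ref=p[0], alt=p[1])
        for j, p in enumerate(pairs)
    ]
    sample_ids = [f"{sample_prefix}{i:06d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, variant_keys=keys, dosage=dosage)


def simulate_weights(
    m: int,
    seed: int,
    ambiguous_fraction: float = 0.0,
    mafs: Sequence[float] | None = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
    chrom: str = "1",
    start_pos: int = 10_000,
    score_id: str = "sim_score",
) -> WeightTable:
    """A scoring table of ``m`` variants with O(1) raw-score SD.

    Weights are zero-mean normal, rescaled so the Hardy–Weinberg raw-score SD
    is exactly 1; ``effect_freq`` equals the generating MAF. A fraction of
    variants is made strand-ambiguous (A/T or C/G allele pair) to exercise
    the ambiguity filter.
    """
    if m < 1:
        raise ValidationError("need at least one variant")
    if not 0.0 <= ambiguous_fraction <= 1.0:
        raise ValidationError("ambiguous_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    if mafs is None:
        mafs = rng.uniform(*maf_range, size=m)
    mafs = np.asarray(mafs, dtype=float)
    w = rng.normal(size=m)
    scale = np.sqrt(np.sum(w**2 * 2.0 * mafs * (1.0 - mafs)))
    w = w / scale if scale > 0 else w

    n_ambig = int(round(ambiguous_fraction * m))
    ambig_idx = set(rng.choice(m, size=n_ambig, replace=False).tolist())
    variants = []
    for j in range(m):
        if j in ambig_idx:
            ref, alt = _AMBIG_PAIRS[j % len(_AMBIG_PAIRS)]
        else:
            ref, alt = _SAFE_PAIRS[j % len(_SAFE_PAIRS)]
        key = VariantKey(chrom=chrom, pos=start_pos + j, ref=ref, alt=alt)
        variants.append(
            WeightedVariant(
                key=key,
                effect_allele=alt,
                other_allele=ref,
                weight=float(w[j]),
                effect_freq=float(mafs[j]),
            )
        )
    return WeightTable(variants=variants, score_id=score_id)


def simulate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Traditional risk-factor draws, loosely anchored to a Finnish adult cohort.

    Ages uniform on 24–75; BMI, cholesterol, HDL and systolic blood pressure
    log-normal with means near 27 kg/m², 5.4 mmol/L, 1.5 mmol/L and 130 mmHg
    (about 16% above 140 mmHg); medication, family-history and smoking flags
    Bernoulli. Illustrative distributions, not a calibration claim.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.uniform(24.0, 75.0, size=n),
            "sex": rng.binomial(1, 0.44, size=n),
            "bmi": rng.lognormal(np.log(27.0), 0.15, size=n),
            "total_chol": rng.lognormal(np.log(5.3), 0.17, size=n),
            "hdl": rng.lognormal(np.log(1.45), 0.22, size=n),
            "sbp": rng.lognormal(np.log(129.0), 0.10, size=n),
            "bp_med": rng.binomial(1, 0.15, size=n),
            "lipid_med": rng.binomial(1, 0.12, size=n),
            "family_history": rng.binomial(1, 0.30, size=n),
            "smoking": rng.binomial(1, 0.18, size=n),
        }
    )


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Full synthetic cohort: genotypes → PRS → covariates → event times.

    The PRS is computed from the simulated genotypes with the pipeline's own
    scoring path and standardized against an independently simulated
    reference panel, so ``prs_z`` is in reference-SD units and
    ``cfg.prs_hr_per_sd`` is directly the generating hazard ratio per SD.
    Event times follow hazard λ0·exp(βᵀ(x − x̄)) with independent exponential
    censoring and an administrative follow-up cap.
    """
    seeds = np.random.SeedSequence(cfg.seed).generate_state(6) % (2**31)
    weights = simulate_weights(
        cfg.n_prs_variants,
        seed=int(seeds[0]),
        ambiguous_fraction=cfg.ambiguous_fraction,
        mafs=cfg.mafs,
        maf_range=cfg.maf_range,
    )
    usable = [v for v in weights.variants]  # ambiguous ones drop in scoring
    mafs = [v.effect_freq for v in usable]
    pairs = [(v.key.ref, v.key.alt) for v in usable]
    geno = simulate_genotypes(
        cfg.n_samples, mafs, seed=int(seeds[1]), pairs=pairs
    )
    ref_geno = simulate_genotypes(
        cfg.reference_n, mafs, seed=int(seeds[2]), pairs=pairs,
        sample_prefix="R",
    )

    raw_ref = compute_raw_prs(harmonize(weights, ref_geno))
    ref_stats = ReferenceStats(
        mean=float(np.mean(raw_ref.values)),
        sd=float(np.std(raw_ref.values, ddof=1)),
        source_label=f"simulated reference panel (n={cfg.reference_n})",
    )
    raw = compute_raw_prs(harmonize(weights, geno))
    prs_z = standardize(raw, ref_stats).values

    cov = simulate_covariates(cfg.n_samples, seed=int(seeds[3]))
    cov["prs_z"] = prs_z

    betas = {**dict(cfg.log_hrs), "prs_z": float(np.log(cfg.prs_hr_per_sd))}
    means = {c: float(cov[c].mean()) for c in COVARIATE_ORDER}
    lp = np.zeros(cfg.n_samples)
    for name in COVARIATE_ORDER:
        lp += betas[name] * (cov[name].to_numpy(dtype=float) - means[name])

    rng = np.random.default_rng(int(seeds[4]))
    hazard = cfg.baseline_hazard_rate * np.exp(lp)
    if cfg.event_time_model == "exponential":
        event_t = rng.exponential(1.0 / hazard)
    else:
        # Weibull PH: H(t) = λ0·t^k·e^lp ⇒ t = (E/(λ0·e^lp))^(1/k), E~Exp(1)
        k = cfg.weibull_shape
        event_t = (rng.exponential(1.0, size=cfg.n_samples) / hazard) ** (1.0 / k)
    censor_t = np.minimum(
        rng.exponential(1.0 / cfg.censoring_rate, size=cfg.n_samples),
        cfg.follow_up_cap,
    )
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    event_rate = event.mean()
    if not 0.005 < event_rate < 0.5:
        warnings.warn(
            f"simulated event rate {event_rate:.3f} outside (0.5%, 50%); "
            "check the hazard configuration",
            stacklevel=2,
        )

    data = cov.copy()
    data.insert(0, "sample_id", geno.sample_ids)
    data["time"] = time
    data["event"] = event
    cohort = SurvivalCohort(data=data)
    truth = TrueParameters(
        log_hrs=betas,
        prs_hr_per_sd=cfg.prs_hr_per_sd,
        baseline_hazard_rate=cfg.baseline_hazard_rate,
        censoring_rate=cfg.censoring_rate,
        follow_up_cap=cfg.follow_up_cap,
        event_time_model=cfg.event_time_model,
        covariate_means=means,
    )
    return SimulatedCohort(
        genotypes=geno,
        weights=weights,
        reference_stats=ref_stats,
        cohort=cohort,
        true_parameters=truth,
    )


def simulate_intensities(
    dosages: Sequence[float],
    separation: float,
    seed: int,
    noise_sd: float = 0.35,
    strength_center: float = 10.0,
    scv_id: str = "",
    sample_prefix: str = "S",
) -> IntensityData:
    """Two-channel intensity clouds for the genotype classes of one variant.

    Class centroids sit at contrast (g − 1)·``separation`` (g the rounded
    risk-allele count) with isotropic Gaussian noise of ``noise_sd`` in
    contrast/strength space; ``separation = 0`` collapses all clouds. The
    returned signals are back-transformed to raw (a, b) channel space.
    """
    if separation < 0:
        raise ValidationError("separation must be >= 0")
    g = np.clip(np.round(np.asarray(dosages, dtype=float)), 0, 2).astype(int)
    rng = np.random.default_rng(seed)
    contrast = (g - 1) * separation + rng.normal(0.0, noise_sd, size=len(g))
    strength = strength_center + rng.normal(0.0, noise_sd, size=len(g))
    a = np.exp2(strength + contrast / 2.0)
    b = np.exp2(strength - contrast / 2.0)
    return IntensityData(
        sample_ids=[f"{sample_prefix}{i:06d}" for i in range(len(g))],
        a_signal=a,
        b_signal=b,
        calls=g,
        scv_id=scv_id,
    )
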