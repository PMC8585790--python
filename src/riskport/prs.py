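"""Polygenic risk score engine.

Pipeline: remove strand-ambiguous variants, harmonize the weight table to the
ALT-oriented genotype dosages, accumulate the weighted sum with mean-dosage
substitution for missing genotypes, and standardize against an independent
reference population.

Strand-ambiguous (A/T or C/G) polymorphisms carry the same allele pair on
both strands, so their orientation cannot be resolved from alleles alone;
they are removed outright, with no frequency-based rescue. A variant missing
from the genotypes (or a per-sample missing dosage) contributes its expected
dosage 2·f, where f is the effect-allele frequency from the score-derivation
population — the mean of a Binomial(2, f) allele count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .variantio import (
    GenotypeMatrix,
    ReferenceStats,
    VariantKey,
    WeightTable,
    WeightedVariant,
)

__all__ = [
    "FLAG_MATCHED",
    "FLAG_FLIPPED",
    "FLAG_AMBIGUOUS",
    "FLAG_MISMATCH",
    "FLAG_ABSENT",
    "HarmonizedScoreInput",
    "RawScore",
    "StandardizedScore",
    "CoverageReport",
    "filter_ambiguous",
    "harmonize",
    "compute_raw_prs",
    "standardize",
    "coverage_report",
    "score_cohort",
]

logger = logging.getLogger(__name__)

FLAG_MATCHED = "matched"
FLAG_FLIPPED = "flipped_orientation"
FLAG_AMBIGUOUS = "dropped_ambiguous"
FLAG_MISMATCH = "dropped_mismatch"
FLAG_ABSENT = "absent_from_genotypes"

_AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


def _is_ambiguous(v: WeightedVariant) -> bool:
    pair = frozenset((v.effect_allele, v.other_allele))
    return pair in _AMBIGUOUS_PAIRS


def filter_ambiguous(weights: WeightTable) -> WeightTable:
    """Drop strand-ambiguous (A/T, C/G) variants, preserving order.

    The removal count is logged; it also equals ``len(in) - len(out)``.
    """
    survivors = [v for v in weights.variants if not _is_ambiguous(v)]
    n_removed = len(weights) - len(survivors)
    if n_removed:
        logger.info(
            "removed %d strand-ambiguous variant(s) from %s",
            n_removed,
            weights.score_id,
        )
    return WeightTable(variants=survivors, score_id=weights.score_id)


@dataclass
class HarmonizedScoreInput:
    """Effect-allele-oriented dosages aligned to weight-table variants.

    ``provenance`` carries exactly one flag per *input* weight-table variant.
    Contributing variants (matched, flipped, or absent-from-genotypes) appear
    as columns of ``dosage`` in weight-table order; absent variants are
    all-NaN columns so that substitution handles them uniformly.
    """

    variant_keys: list[VariantKey]
    dosage: np.ndarray          # (n_samples, n_contributing), effect-oriented
    weights: np.ndarray         # (n_contributing,)
    effect_freqs: np.ndarray    # (n_contributing,), NaN where absent
    sample_ids: list[str]
    provenance: list[str]       # one flag per input weight-table variant
    input_keys: list[VariantKey]

    @property
    def flag_counts(self) -> dict[str, int]:
        counts = {
            FLAG_MATCHED: 0,
            FLAG_FLIPPED: 0,
            FLAG_AMBIGUOUS: 0,
            FLAG_MISMATCH: 0,
            FLAG_ABSENT: 0,
        }
        for f in self.provenance:
            counts[f] += 1
        return counts


@dataclass
class RawScore:
    """Per-sample weighted dosage sums plus substitution bookkeeping."""

    values: np.ndarray           # (n_samples,)
    sample_ids: list[str]
    n_variants_used: int
    n_substituted: np.ndarray    # (n_samples,) substitutions per sample

    def __post_init__(self) -> None:
        if np.any(self.n_substituted > self.n_variants_used):
            raise ValidationError("n_substituted cannot exceed n_variants_used")


@dataclass
class StandardizedScore:
    """Z-scores of a raw PRS against a reference population."""

    values: np.ndarray
    sample_ids: list[str]
    reference: ReferenceStats

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("standardized scores must be finite")


def harmonize(weights: WeightTable, geno: GenotypeMatrix) -> HarmonizedScoreInput:
    """Align weight-table variants to ALT-oriented genotype columns.

    The ambiguity filter is re-applied internally, so callers may pass an
    unfiltered table. Matching is by (chrom, pos); orientation is resolved
    from the allele sets: effect==ALT keeps the dosage, effect==REF flips it
    to ``2 - d``, anything else is dropped as a mismatch. Weight variants
    with no genotype record at their position are flagged absent and enter
    as all-missing columns (resolved later by frequency substitution).
    """
    by_pos: dict[tuple[str, int], list[int]] = {}
    for j, k in enumerate(geno.variant_keys):
        by_pos.setdefault((k.chrom, k.pos), []).append(j)

    n = geno.n_samples
    provenance: list[str] = []
    keys: list[VariantKey] = []
    cols: list[np.ndarray] = []
    w: list[float] = []
    freqs: list[float] = []

    for v in weights.variants:
        if _is_ambiguous(v):
            provenance.append(FLAG_AMBIGUOUS)
            continue
        candidates = by_pos.get((v.key.chrom, v.key.pos), [])
        col = None
        flag = FLAG_ABSENT if not candidates else FLAG_MISMATCH
        for j in candidates:
            gk = geno.variant_keys[j]
            if v.effect_allele == gk.alt and v.other_allele == gk.ref:
                col = geno.dosage[:, j]
                flag = FLAG_MATCHED
                break
            if v.effect_allele == gk.ref and v.other_allele == gk.alt:
                col = 2.0 - geno.dosage[:, j]  # NaN propagates
                flag = FLAG_FLIPPED
                break
        provenance.append(flag)
        if flag == FLAG_MISMATCH:
            continue
        if col is None:  # absent from genotypes
            col = np.full(n, np.nan)
        keys.append(v.key)
        cols.append(np.asarray(col, dtype=float))
        w.append(v.weight)
        freqs.append(np.nan if v.effect_freq is None else v.effect_freq)

    counts = {f: provenance.count(f) for f in set(provenance)}
    if counts.get(FLAG_MISMATCH) or counts.get(FLAG_ABSENT):
        logger.info("harmonization flags for %s: %s", weights.score_id, counts)
    dosage = np.column_stack(cols) if cols else np.empty((n, 0))
    return HarmonizedScoreInput(
        variant_keys=keys,
        dosage=dosage,
        weights=np.array(w, dtype=float),
        effect_freqs=np.array(freqs, dtype=float),
        sample_ids=list(geno.sample_ids),
        provenance=provenance,
        input_keys=[v.key for v in weights.variants],
    )


def compute_raw_prs(h: HarmonizedScoreInput, substitute: str = "weights") -> RawScore:
    """Weighted dosage sum with expected-dosage substitution for missing cells.

    score_s = Σ_i w_i · d_si, where a missing d_si is replaced by 2·f_i
    (effect-allele frequency). ``substitute`` selects the frequency source:
    "weights" (default, the scoring file's derivation-population frequency),
    "cohort" (effect-allele frequency recomputed from the observed dosages),
    or "fail" (any missing cell is an error).
    """
    if substitute not in ("weights", "cohort", "fail"):
        raise ValidationError(
            f"substitute must be 'weights', 'cohort' or 'fail', got {substitute!r}"
        )
    d = np.array(h.dosage, dtype=float)
    missing = np.isnan(d)
    n_substituted = missing.sum(axis=1).astype(int)

    if missing.any():
        if substitute == "fail":
            j = int(np.where(missing.any(axis=0))[0][0])
            raise ValidationError(
                f"missing dosage at variant {h.variant_keys[j]} with substitution disabled"
            )
        if substitute == "weights":
            freqs = h.effect_freqs
        else:
            with np.errstate(invalid="ignore"):
                freqs = np.nanmean(d, axis=0) / 2.0
        needs = missing.any(axis=0)
        bad = needs & ~np.isfinite(freqs)
        if bad.any():
            j = int(np.where(bad)[0][0])
            raise ValidationError(
                f"variant {h.variant_keys[j]} needs frequency substitution but "
                "carries no effect-allele frequency"
            )
        fill = np.broadcast_to(2.0 * freqs, d.shape)
        d[missing] = fill[missing]

    values = d @ h.weights
    return RawScore(
        values=values,
        sample_ids=list(h.sample_ids),
        n_variants_used=d.shape[1],
        n_substituted=n_substituted,
    )


def standardize(raw: RawScore, ref: ReferenceStats) -> StandardizedScore:
    """z = (raw − ref.mean) / ref.sd, per sample."""
    if not ref.sd > 0:
        raise ValidationError(f"reference sd must be > 0, got {ref.sd}")
    return StandardizedScore(
        values=(raw.values - ref.mean) / ref.sd,
        sample_ids=list(raw.sample_ids),
        reference=ref,
    )


@dataclass(frozen=True)
class CoverageReport:
    """How much of the weight table the genotype data covers.

    ``coverage`` uses the full weight table as denominator; since whether
    coverage should be assessed before or after ambiguity filtering is a
    judgement call, ``coverage_post_filter`` reports the same numerator over
    the post-filter table.
    """

    n_weight_variants: int
    flag_counts: dict[str, int]
    coverage: float
    coverage_post_filter: float


def coverage_report(weights: WeightTable, geno: GenotypeMatrix) -> CoverageReport:
    """Fraction of weight variants usable (matched or flipped) in ``geno``."""
    if len(weights) == 0:
        raise ValidationError("cannot compute coverage of an empty weight table")
    h = harmonize(weights, geno)
    counts = h.flag_counts
    found = counts[FLAG_MATCHED] + counts[FLAG_FLIPPED]
    n_post = len(weights) - counts[FLAG_AMBIGUOUS]
    return CoverageReport(
        n_weight_variants=len(weights),
        flag_counts=counts,
        coverage=found / len(weights),
        coverage_post_filter=found / n_post if n_post else 0.0,
    )


def score_cohort(
    weights: WeightTable,
    geno: GenotypeMatrix,
    ref: ReferenceStats,
    substitute: str = "weights",
) -> pd.DataFrame:
    """Full scoring pipeline; returns sample_id, raw, z, n_used, n_substituted."""
    h = harmonize(filter_ambiguous(weights), geno)
    raw = compute_raw_prs(h, substitute=substitute)
    z = standardize(raw, ref)
    return pd.DataFrame(
        {
            "sample_id": raw.sample_ids,
            "raw": raw.values,
            "z": z.values,
            "n_used": raw.n_variants_used,
            "n_substituted": raw.n_substituted,
        }
    )
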