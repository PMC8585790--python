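"""I/O layer and variant/genotype data model.

Coordinates are 1-based throughout (HGVS ``g.`` convention). Dosages at this
layer are always oriented as ALT-allele counts; harmonization to effect-allele
orientation happens in :mod:`riskport.prs`, never here. A missing dosage is
represented by NaN, a sentinel distinct from every valid dosage in [0, 2];
no code path ever treats it as zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "MISSING",
    "is_missing",
    "VariantKey",
    "WeightedVariant",
    "WeightTable",
    "GenotypeMatrix",
    "ReferenceStats",
    "read_weight_table",
    "write_weight_table",
    "read_vcf_dosages",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_reference_stats",
    "write_reference_stats",
]

#: Missing-dosage sentinel. NaN is outside [0, 2] and compares unequal to
#: every valid dosage; use :func:`is_missing` to test for it.
MISSING: float = float("nan")

_ALLELE_CHARS = frozenset("ACGT")


def is_missing(dosage: float) -> bool:
    """True if ``dosage`` is the missing-dosage sentinel."""
    return isinstance(dosage, float) and math.isnan(dosage)


def _check_allele(allele: str, what: str) -> None:
    if not allele or not set(allele) <= _ALLELE_CHARS:
        raise ValidationError(
            f"{what} must be a non-empty string over A/C/G/T, got {allele!r}"
        )


@dataclass(frozen=True)
class VariantKey:
    """A bi-allelic variant identified by 1-based position and its alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        _check_allele(self.ref, "ref")
        _check_allele(self.alt, "alt")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt must differ, got {self.ref!r} twice")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class WeightedVariant:
    """One scoring-file row: a variant, its effect allele and per-allele weight.

    ``effect_freq`` is the effect-allele frequency in the score-derivation
    population; ``None`` marks an absent frequency (substitution for missing
    genotypes is then impossible for this variant).
    """

    key: VariantKey
    effect_allele: str
    other_allele: str
    weight: float
    effect_freq: float | None = None

    def __post_init__(self) -> None:
        alleles = {self.key.ref, self.key.alt}
        if self.effect_allele not in alleles:
            raise ValidationError(
                f"effect allele {self.effect_allele!r} is neither ref nor alt of {self.key}"
            )
        if self.other_allele != (alleles - {self.effect_allele}).pop():
            raise ValidationError(
                f"other allele {self.other_allele!r} does not complement "
                f"effect allele {self.effect_allele!r} for {self.key}"
            )
        if self.effect_freq is not None and not 0.0 < self.effect_freq < 1.0:
            raise ValidationError(
                f"effect_freq must lie strictly in (0,1), got {self.effect_freq} for {self.key}"
            )


@dataclass
class WeightTable:
    """An ordered polygenic-score variant set with unique variant keys."""

    variants: list[WeightedVariant]
    score_id: str = "score"

    def __post_init__(self) -> None:
        seen: set[VariantKey] = set()
        for v in self.variants:
            if v.key in seen:
                raise ValidationError(f"duplicate variant key in weight table: {v.key}")
            seen.add(v.key)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[WeightedVariant]:
        return iter(self.variants)

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants], dtype=float)

    @property
    def effect_freqs(self) -> np.ndarray:
        """Effect-allele frequencies with NaN where absent."""
        return np.array(
            [np.nan if v.effect_freq is None else v.effect_freq for v in self.variants],
            dtype=float,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chr_name": [v.key.chrom for v in self.variants],
                "chr_position": [v.key.pos for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "effect_weight": [v.weight for v in self.variants],
                "allelefrequency_effect": [
                    np.nan if v.effect_freq is None else v.effect_freq
                    for v in self.variants
                ],
            }
        )


@dataclass
class GenotypeMatrix:
    """Per-sample ALT-allele dosages for an ordered variant list.

    ``dosage`` has shape (n_samples, n_variants); entries are real numbers in
    [0, 2] or NaN for missing.
    """

    sample_ids: list[str]
    variant_keys: list[VariantKey]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = len(self.sample_ids), len(self.variant_keys)
        if self.dosage.shape != (n, m):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{n} samples x {m} variants"
            )
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValidationError("non-missing dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)


@dataclass(frozen=True)
class ReferenceStats:
    """Mean/SD of a score in an independent reference population."""

    mean: float
    sd: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValidationError(f"reference sd must be > 0, got {self.sd}")


# ---------------------------------------------------------------------------
# Weight tables (PGS-Catalog scoring-file dialect by default)

#: Logical field -> default column header (PGS-Catalog scoring-file names).
DEFAULT_WEIGHT_DIALECT: Mapping[str, str] = {
    "chrom": "chr_name",
    "pos": "chr_position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "weight": "effect_weight",
    "effect_freq": "allelefrequency_effect",
}

_MANDATORY_WEIGHT_FIELDS = ("chrom", "pos", "effect_allele", "other_allele", "weight")


def read_weight_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    score_id: str | None = None,
) -> WeightTable:
    """Read a TSV scoring file (optionally gzipped) into a :class:`WeightTable`.

    ``dialect`` maps the logical field names (chrom, pos, effect_allele,
    other_allele, weight, effect_freq) to the file's column headers; the
    default follows the PGS-Catalog scoring-file convention. The frequency
    column is optional; rows without it carry ``effect_freq=None``.
    """
    cols = dict(DEFAULT_WEIGHT_DIALECT)
    if dialect:
        cols.update(dialect)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={cols["chrom"]: str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse weight table {path}: {exc}") from exc
    for logical in _MANDATORY_WEIGHT_FIELDS:
        if cols[logical] not in df.columns:
            raise FormatError(
                f"weight table {path} is missing mandatory column "
                f"{cols[logical]!r} (field {logical!r})"
            )
    has_freq = cols["effect_freq"] in df.columns
    variants: list[WeightedVariant] = []
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        effect = str(rec[cols["effect_allele"]])
        other = str(rec[cols["other_allele"]])
        freq = None
        if has_freq and not pd.isna(rec[cols["effect_freq"]]):
            freq = float(rec[cols["effect_freq"]])
        # Scoring files carry no ref/alt; key convention is alt=effect allele.
        key = VariantKey(
            chrom=str(rec[cols["chrom"]]),
            pos=int(rec[cols["pos"]]),
            ref=other,
            alt=effect,
        )
        variants.append(
            WeightedVariant(
                key=key,
                effect_allele=effect,
                other_allele=other,
                weight=float(rec[cols["weight"]]),
                effect_freq=freq,
            )
        )
    return WeightTable(
        variants=variants, score_id=score_id or Path(str(path)).stem
    )


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    """Write ``table`` as a TSV scoring file (default dialect); lossless."""
    df = table.to_dataframe()
    if df["allelefrequency_effect"].isna().all():
        df = df.drop(columns=["allelefrequency_effect"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF dosages


def read_vcf_dosages(
    path: str | Path,
    mode: str = "DS",
    on_multiallelic: str = "reject",
) -> GenotypeMatrix:
    """Read a VCF into an ALT-dosage :class:`GenotypeMatrix`.

    mode="DS" takes the imputed-dosage FORMAT field as-is; mode="GT" converts
    hard calls to dosages 0/1/2. Records where the field is absent, or where a
    GT allele is missing, yield NaN. Multi-allelic records are rejected with
    their coordinates under the default policy, or expanded to one column per
    ALT allele under ``on_multiallelic="split"``.
    """
    from cyvcf2 import VCF

    if mode not in ("DS", "GT"):
        raise ValidationError(f"mode must be 'DS' or 'GT', got {mode!r}")
    if on_multiallelic not in ("reject", "split"):
        raise ValidationError(
            f"on_multiallelic must be 'reject' or 'split', got {on_multiallelic!r}"
        )
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    keys: list[VariantKey] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        alts = [a for a in rec.ALT if a != "<NON_REF>"]
        if len(alts) > 1 and on_multiallelic == "reject":
            raise ValidationError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                "(re-run with the 'split' policy to expand it)"
            )
        if mode == "DS":
            ds = rec.format("DS")
            if ds is None:
                cols = [np.full(n, np.nan) for _ in alts]
            else:
                ds = np.asarray(ds, dtype=float).reshape(n, -1)
                cols = []
                for k in range(len(alts)):
                    col = ds[:, k].copy() if k < ds.shape[1] else np.full(n, np.nan)
                    # cyvcf2 encodes missing FORMAT floats as extreme values
                    col[(col < 0) | (col > 2)] = np.nan
                    cols.append(col)
        else:
            gts = rec.genotype.array() if rec.genotype is not None else None
            cols = []
            for k in range(len(alts)):
                col = np.full(n, np.nan)
                if gts is not None:
                    alleles = np.asarray(gts)[:, :2]
                    valid = (alleles >= 0).all(axis=1)
                    counts = (alleles == k + 1).sum(axis=1).astype(float)
                    col[valid] = counts[valid]
                cols.append(col)
        for alt, col in zip(alts, cols):
            keys.append(VariantKey(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt))
            columns.append(col)
    dosage = (
        np.column_stack(columns) if columns else np.empty((n, 0), dtype=float)
    )
    return GenotypeMatrix(sample_ids=sample_ids, variant_keys=keys, dosage=dosage)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with GT (rounded hard call) and DS fields.

    GT is emitted only where the dosage is an integer 0/1/2; otherwise ./.
    with the fractional DS preserved, so GT-mode and DS-mode reads agree
    whenever dosages are hard calls.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=A,Type=Float,Description="ALT allele dosage">\n'
        )
        chroms = sorted({k.chrom for k in geno.variant_keys})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        for j, key in enumerate(geno.variant_keys):
            cells = []
            for d in geno.dosage[:, j]:
                if math.isnan(d):
                    cells.append("./.:.")
                elif float(d).is_integer():
                    cells.append(f"{gt_map[int(d)]}:{d:g}")
                else:
                    cells.append(f"./.:{d:g}")
            fh.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\t.\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Plain dosage matrix (TSV), for pipelines that bypass VCF


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        geno.dosage,
        index=pd.Index(geno.sample_ids, name="sample_id"),
        columns=[str(k) for k in geno.variant_keys],
    )
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse dosage matrix {path}: {exc}") from exc
    keys = []
    for col in df.columns:
        try:
            chrom, pos, ref, alt = col.split(":")
            keys.append(VariantKey(chrom=chrom, pos=int(pos), ref=ref, alt=alt))
        except (ValueError, ValidationError) as exc:
            raise FormatError(
                f"dosage matrix column {col!r} is not a chrom:pos:ref:alt key"
            ) from exc
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        variant_keys=keys,
        dosage=df.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Reference statistics


def write_reference_stats(stats: ReferenceStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"mean": stats.mean, "sd": stats.sd, "source_label": stats.source_label},
            fh,
            indent=2,
        )
        fh.write("\n")


def read_reference_stats(path: str | Path) -> ReferenceStats:
    """Read reference mean/SD from JSON; unknown fields are ignored."""
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse reference stats {path}: {exc}") from exc
    for field_name in ("mean", "sd"):
        if field_name not in obj:
            raise FormatError(f"reference stats {path} is missing {field_name!r}")
    return ReferenceStats(
        mean=float(obj["mean"]),
        sd=float(obj["sd"]),
        source_label=str(obj.get("source_label", "")),
    )
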