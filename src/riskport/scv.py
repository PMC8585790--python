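"""Single clinical variant (SCV) carrier calling, cluster QC, and note routing.

Unlike the polygenic score, these variants are individually actionable and
reported by carrier status. Six definitions ship with the package: the F5
"Leiden" and F2 thrombophilia variants, three Finnish founder LDLR variants
causing familial hypercholesterolemia (FH), and the SLCO1B1 rs4149056
statin-transporter variant.

Genotyping quality of each SCV is checked with an automated cluster-separation
score computed from the chip's two-channel signal intensities in
contrast/strength space — an operationalized surrogate for visual inspection
of genotype clusters.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .variantio import GenotypeMatrix, VariantKey

__all__ = [
    "CarrierStatus",
    "NoteAction",
    "SCVDefinition",
    "SCVResult",
    "IntensityData",
    "ClusterQC",
    "load_scv_definitions",
    "call_carriers",
    "cluster_separation",
    "select_scv_note",
    "read_intensity_tsv",
    "write_intensity_tsv",
]

logger = logging.getLogger(__name__)

#: Fractional dosages are hard-called only within this distance of 0/1/2.
HARD_CALL_TOLERANCE = 0.1

#: Minimum centroid-separation ratio for a passing cluster QC.
SEPARATION_THRESHOLD = 2.0


class CarrierStatus(str, enum.Enum):
    NON_CARRIER = "non_carrier"
    HETEROZYGOTE = "heterozygote"
    HOMOZYGOTE = "homozygote"
    NO_CALL = "no_call"


class NoteAction(str, enum.Enum):
    NONE = "none"
    MENTION_TO_PHYSICIAN_VTE = "mention_to_physician_VTE"
    MENTION_IF_STATIN_PLANNED = "mention_if_statin_planned"
    PERSONAL_CONTACT = "personal_contact"


@dataclass(frozen=True)
class SCVDefinition:
    """One actionable variant: coordinates, risk allele, population frequency."""

    id: str
    key: VariantKey
    risk_allele: str
    maf: float | None
    category: str  # VTE | FH | pharmacogenetic

    def __post_init__(self) -> None:
        if self.risk_allele not in (self.key.ref, self.key.alt):
            raise ValidationError(
                f"risk allele {self.risk_allele!r} is neither ref nor alt of {self.key}"
            )
        if self.maf is not None and not 0.0 < self.maf < 1.0:
            raise ValidationError(f"maf must lie in (0,1), got {self.maf}")
        if self.category not in ("VTE", "FH", "pharmacogenetic"):
            raise ValidationError(f"unknown SCV category {self.category!r}")


@dataclass(frozen=True)
class SCVResult:
    sample_id: str
    scv_id: str
    status: CarrierStatus


@dataclass
class IntensityData:
    """Two-channel chip signal intensities at one variant, with called class."""

    sample_ids: list[str]
    a_signal: np.ndarray
    b_signal: np.ndarray
    calls: np.ndarray  # genotype class labels (e.g. 0/1/2 risk-allele count)
    scv_id: str = ""

    def __post_init__(self) -> None:
        self.a_signal = np.asarray(self.a_signal, dtype=float)
        self.b_signal = np.asarray(self.b_signal, dtype=float)
        self.calls = np.asarray(self.calls)
        n = len(self.sample_ids)
        if not (len(self.a_signal) == len(self.b_signal) == len(self.calls) == n):
            raise ValidationError("intensity arrays must match the sample list")
        for arr, name in ((self.a_signal, "a_signal"), (self.b_signal, "b_signal")):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class ClusterQC:
    scv_id: str
    separation_score: float
    passed: bool
    reason: str = ""


def load_scv_definitions(path: str | Path | None = None) -> list[SCVDefinition]:
    """Load SCV definitions (the built-in table unless ``path`` overrides it)."""
    if path is None:
        text = (
            resources.files("riskport").joinpath("data/scv_definitions.json")
        ).read_text()
    else:
        text = Path(path).read_text()
    try:
        obj = json.loads(text)
        defs = [
            SCVDefinition(
                id=rec["id"],
                key=VariantKey(
                    chrom=str(rec["chrom"]),
                    pos=int(rec["pos"]),
                    ref=rec["ref"],
                    alt=rec["alt"],
                ),
                risk_allele=rec["risk_allele"],
                maf=rec["maf"],
                category=rec["category"],
            )
            for rec in obj["variants"]
        ]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed SCV definition table: {exc}") from exc
    return defs


def _status_from_count(count: float) -> CarrierStatus:
    """Risk-allele count → status; fractional counts hard-called within ±0.1."""
    if np.isnan(count):
        return CarrierStatus.NO_CALL
    nearest = round(count)
    if nearest not in (0, 1, 2) or abs(count - nearest) > HARD_CALL_TOLERANCE:
        return CarrierStatus.NO_CALL
    return (
        CarrierStatus.NON_CARRIER,
        CarrierStatus.HETEROZYGOTE,
        CarrierStatus.HOMOZYGOTE,
    )[nearest]


def call_carriers(
    geno: GenotypeMatrix, defs: list[SCVDefinition] | None = None
) -> list[SCVResult]:
    """Call carrier status for every (sample, SCV definition) pair.

    A definition whose variant is not present in ``geno`` yields ``no_call``
    for all samples (logged). Dosages are ALT-oriented; when the risk allele
    is REF the count is ``2 - dosage``.
    """
    if defs is None:
        defs = load_scv_definitions()
    results: list[SCVResult] = []
    index = {k: j for j, k in enumerate(geno.variant_keys)}
    for d in defs:
        j = index.get(d.key)
        if j is None:
            logger.warning("SCV %s absent from genotype data; all samples no_call", d.id)
            counts = np.full(geno.n_samples, np.nan)
        else:
            counts = geno.dosage[:, j]
            if d.risk_allele == d.key.ref:
                counts = 2.0 - counts
        n_nocall = 0
        for sid, c in zip(geno.sample_ids, counts):
            status = _status_from_count(float(c))
            if status is CarrierStatus.NO_CALL:
                n_nocall += 1
            results.append(SCVResult(sample_id=sid, scv_id=d.id, status=status))
        if n_nocall:
            logger.info("SCV %s: %d no-call sample(s)", d.id, n_nocall)
    return results


def cluster_separation(
    intens: IntensityData, threshold: float = SEPARATION_THRESHOLD
) -> ClusterQC:
    """Centroid-separation score of genotype clusters in contrast/strength space.

    Intensities (a, b) are transformed to contrast = log2(a/b) and strength =
    log2(a·b)/2 (the standard chip-cluster coordinates; invariant up to a
    shift under uniform scaling of both channels). The score is the minimum
    over genotype-class pairs of centroid distance divided by the sum of the
    two within-class RMS radii; QC passes at score ≥ threshold. With fewer
    than two classes of ≥ 2 samples each the QC is indeterminate (fail with
    reason), never an exception.
    """
    eps = 1e-12
    a = np.maximum(intens.a_signal, eps)
    b = np.maximum(intens.b_signal, eps)
    contrast = np.log2(a / b)
    strength = np.log2(a * b) / 2.0
    pts = np.column_stack([contrast, strength])

    classes = [c for c in pd.unique(intens.calls) if np.sum(intens.calls == c) >= 2]
    if len(classes) < 2:
        return ClusterQC(
            scv_id=intens.scv_id,
            separation_score=float("nan"),
            passed=False,
            reason="indeterminate: fewer than 2 genotype classes with >=2 samples",
        )
    centroids, radii = [], []
    for c in classes:
        sub = pts[intens.calls == c]
        mu = sub.mean(axis=0)
        centroids.append(mu)
        radii.append(np.sqrt(np.mean(np.sum((sub - mu) ** 2, axis=1))))
    score = np.inf
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            dist = float(np.linalg.norm(centroids[i] - centroids[j]))
            denom = radii[i] + radii[j]
            ratio = np.inf if denom == 0 else dist / denom
            score = min(score, ratio)
    return ClusterQC(
        scv_id=intens.scv_id,
        separation_score=float(score),
        passed=bool(score >= threshold),
    )


#: (category-specific) note routing. F5/F2 heterozygotes are told to mention
#: the result to their physician (VTE risk-factor information); SLCO1B1
#: carriers to mention it if statin therapy is planned (the note's text also
#: says not to stop existing statins); F5/F2 homozygotes and every FH carrier
#: get a personal phone contact from a doctor.
def select_scv_note(
    result: SCVResult, defs: list[SCVDefinition] | None = None
) -> NoteAction:
    if defs is None:
        defs = load_scv_definitions()
    by_id = {d.id: d for d in defs}
    if result.scv_id not in by_id:
        raise ValidationError(f"unknown SCV id {result.scv_id!r}")
    d = by_id[result.scv_id]
    status = result.status
    if status in (CarrierStatus.NON_CARRIER, CarrierStatus.NO_CALL):
        return NoteAction.NONE
    if d.category == "pharmacogenetic":
        return NoteAction.MENTION_IF_STATIN_PLANNED
    if d.category == "FH":
        return NoteAction.PERSONAL_CONTACT
    # VTE: heterozygote mentions to physician; homozygote escalates
    if status is CarrierStatus.HETEROZYGOTE:
        return NoteAction.MENTION_TO_PHYSICIAN_VTE
    return NoteAction.PERSONAL_CONTACT


# ---------------------------------------------------------------------------
# Intensity TSV I/O


def write_intensity_tsv(intens: IntensityData, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": intens.sample_ids,
            "a_signal": intens.a_signal,
            "b_signal": intens.b_signal,
            "call": intens.calls,
        }
    ).to_csv(path, sep="\t", index=False)


def read_intensity_tsv(path: str | Path, scv_id: str = "") -> IntensityData:
    try:
        df = pd.read_csv(path, sep="\t")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse intensity table {path}: {exc}") from exc
    for col in ("sample_id", "a_signal", "b_signal", "call"):
        if col not in df.columns:
            raise FormatError(f"intensity table {path} is missing column {col!r}")
    return IntensityData(
        sample_ids=[str(s) for s in df["sample_id"]],
        a_signal=df["a_signal"].to_numpy(dtype=float),
        b_signal=df["b_signal"].to_numpy(dtype=float),
        calls=df["call"].to_numpy(),
        scv_id=scv_id,
    )
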