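import numpy as np
import pandas as pd
import pytest

from riskport.riskmodel import SurvivalCohort
from riskport.variantio import (
    GenotypeMatrix,
    VariantKey,
    WeightTable,
    WeightedVariant,
)


def make_variant(pos, ref="A", alt="G", chrom="1"):
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


def make_weighted(pos, ref="A", alt="G", weight=0.1, freq=0.3, effect="alt", chrom="1"):
    key = make_variant(pos, ref, alt, chrom)
    eff, other = (alt, ref) if effect == "alt" else (ref, alt)
    return WeightedVariant(
        key=key, effect_allele=eff, other_allele=other, weight=weight, effect_freq=freq
    )


@pytest.fixture
def small_weights():
    """Four-variant table: two clean, one A/T ambiguous, one C/G ambiguous."""
    return WeightTable(
        variants=[
            make_weighted(100, "A", "G", weight=0.4, freq=0.25),
            make_weighted(200, "A", "T", weight=0.2, freq=0.10),
            make_weighted(300, "C", "T", weight=-0.3, freq=0.40),
            make_weighted(400, "C", "G", weight=0.1, freq=0.50),
        ],
        score_id="toy",
    )


@pytest.fixture
def small_geno():
    """Three samples over the two unambiguous variants of ``small_weights``."""
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3"],
        variant_keys=[make_variant(100, "A", "G"), make_variant(300, "C", "T")],
        dosage=np.array([[2.0, 1.0], [0.0, np.nan], [1.4, 0.0]]),
    )


@pytest.fixture
def toy_cohort():
    """Eight subjects, one binary covariate, no censoring, distinct times."""
    return SurvivalCohort(
        data=pd.DataFrame(
            {
                "x": [1, 1, 1, 1, 0, 0, 0, 0],
                "time": [1.0, 2.5, 3.0, 4.5, 2.0, 3.5, 5.0, 6.0],
                "event": [1, 1, 1, 1, 1, 1, 1, 1],
            }
        )
    )
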