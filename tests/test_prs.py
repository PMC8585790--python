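import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskport.errors import ValidationError
from riskport.prs import (
    FLAG_ABSENT,
    FLAG_AMBIGUOUS,
    FLAG_FLIPPED,
    FLAG_MATCHED,
    FLAG_MISMATCH,
    compute_raw_prs,
    coverage_report,
    filter_ambiguous,
    harmonize,
    score_cohort,
    standardize,
)
from riskport.variantio import (
    GenotypeMatrix,
    ReferenceStats,
    VariantKey,
    WeightTable,
    WeightedVariant,
)
from riskport.simdata import simulate_genotypes, simulate_weights

from conftest import make_variant, make_weighted


def brute_force_scores(weights, geno):
    """Independent per-cell accumulation oracle for the PRS.

    Literal restatement of the scoring rules: skip A/T–C/G pairs, orient by
    allele comparison, substitute 2·freq for any missing cell.
    """
    ambiguous = ({"A", "T"}, {"C", "G"})
    scores = []
    for i, _ in enumerate(geno.sample_ids):
        total = 0.0
        for wv in weights.variants:
            if {wv.effect_allele, wv.other_allele} in ambiguous:
                continue
            dosage = None
            found_mismatch = False
            for j, gk in enumerate(geno.variant_keys):
                if (gk.chrom, gk.pos) != (wv.key.chrom, wv.key.pos):
                    continue
                if wv.effect_allele == gk.alt and wv.other_allele == gk.ref:
                    dosage = geno.dosage[i, j]
                elif wv.effect_allele == gk.ref and wv.other_allele == gk.alt:
                    dosage = 2.0 - geno.dosage[i, j]
                else:
                    found_mismatch = True
                    continue
                break
            if dosage is None and found_mismatch:
                continue  # dropped mismatch
            if dosage is None or math.isnan(dosage):
                dosage = 2.0 * wv.effect_freq
            total += wv.weight * dosage
        scores.append(total)
    return np.array(scores)


class TestFilterAmbiguous:
    def test_removes_at_and_cg_pairs_only(self):
        table = WeightTable(
            variants=[
                make_weighted(1, "A", "G"),
                make_weighted(2, "A", "T"),
                make_weighted(3, "C", "G"),
                make_weighted(4, "C", "T"),
            ]
        )
        out = filter_ambiguous(table)
        assert [(v.key.ref, v.key.alt) for v in out] == [("A", "G"), ("C", "T")]

    def test_identity_on_clean_table(self):
        table = WeightTable(variants=[make_weighted(1, "A", "G")])
        assert filter_ambiguous(table).variants == table.variants

    def test_all_ambiguous_gives_empty_table(self):
        table = WeightTable(
            variants=[make_weighted(p, "A", "T", freq=0.2) for p in (1, 2, 3)]
        )
        out = filter_ambiguous(table)
        assert len(out) == 0 and len(table) - len(out) == 3

    def test_flip_orientation_does_not_rescue_ambiguous(self):
        # effect allele on the other strand still forms an ambiguous pair
        table = WeightTable(variants=[make_weighted(1, "T", "A", effect="ref")])
        assert len(filter_ambiguous(table)) == 0


class TestHarmonize:
    def test_effect_alt_used_as_is_and_effect_ref_flipped(self):
        weights = WeightTable(
            variants=[
                make_weighted(100, "A", "G", effect="alt"),
                make_weighted(200, "C", "T", effect="ref"),
            ]
        )
        geno = GenotypeMatrix(
            sample_ids=["s"],
            variant_keys=[make_variant(100, "A", "G"), make_variant(200, "C", "T")],
            dosage=np.array([[1.4, 1.4]]),
        )
        h = harmonize(weights, geno)
        np.testing.assert_allclose(h.dosage, [[1.4, 0.6]])
        assert h.provenance == [FLAG_MATCHED, FLAG_FLIPPED]

    def test_discordant_alleles_dropped_as_mismatch(self):
        weights = WeightTable(variants=[make_weighted(100, "A", "G")])
        geno = GenotypeMatrix(
            sample_ids=["s"],
            variant_keys=[make_variant(100, "T", "C")],
            dosage=np.array([[1.0]]),
        )
        h = harmonize(weights, geno)
        assert h.provenance == [FLAG_MISMATCH]
        assert h.dosage.shape == (1, 0)

    def test_every_input_variant_gets_exactly_one_flag(self, small_weights, small_geno):
        h = harmonize(small_weights, small_geno)
        assert len(h.provenance) == len(small_weights)
        assert h.flag_counts[FLAG_AMBIGUOUS] == 2
        assert h.flag_counts[FLAG_MATCHED] == 2


class TestComputeRawPrs:
    def test_dot_product(self):
        weights = WeightTable(
            variants=[
                make_weighted(1, weight=0.1),
                make_weighted(2, weight=-0.2),
                make_weighted(3, weight=0.05),
            ]
        )
        geno = GenotypeMatrix(
            sample_ids=["s"],
            variant_keys=[v.key for v in weights.variants],
            dosage=np.array([[2.0, 1.0, 0.0]]),
        )
        raw = compute_raw_prs(harmonize(weights, geno))
        assert raw.values[0] == pytest.approx(0.0, abs=1e-15)

    def test_missing_dosage_substitutes_expected_dosage(self):
        weights = WeightTable(variants=[make_weighted(1, weight=0.4, freq=0.25)])
        geno = GenotypeMatrix(
            sample_ids=["s"],
            variant_keys=[weights.variants[0].key],
            dosage=np.array([[np.nan]]),
        )
        raw = compute_raw_prs(harmonize(weights, geno))
        assert raw.values[0] == pytest.approx(0.4 * 2 * 0.25)
        assert raw.n_substituted[0] == 1

    def test_all_missing_equals_population_mean_score(self):
        rng = np.random.default_rng(0)
        weights = WeightTable(
            variants=[
                make_weighted(p, weight=float(rng.normal()), freq=float(f))
                for p, f in zip(range(1, 8), rng.uniform(0.05, 0.95, 7))
            ]
        )
        geno = GenotypeMatrix(
            sample_ids=["s"],
            variant_keys=[v.key for v in weights.variants],
            dosage=np.full((1, 7), np.nan),
        )
        raw = compute_raw_prs(harmonize(weights, geno))
        expected = sum(2 * v.effect_freq * v.weight for v in weights.variants)
        assert raw.values[0] == pytest.approx(expected, abs=1e-12)

    def test_substitution_without_frequency_names_variant(self):
        weights = WeightTable(variants=[make_weighted(7, weight=0.4, freq=None)])
        geno = GenotypeMatrix(
            sample_ids=["s"],
            variant_keys=[weights.variants[0].key],
            dosage=np.array([[np.nan]]),
        )
        with pytest.raises(ValidationError, match="1:7"):
            compute_raw_prs(harmonize(weights, geno))

    def test_fail_mode_rejects_missingness(self):
        weights = WeightTable(variants=[make_weighted(1, freq=0.5)])
        geno = GenotypeMatrix(
            sample_ids=["s"],
            variant_keys=[weights.variants[0].key],
            dosage=np.array([[np.nan]]),
        )
        with pytest.raises(ValidationError):
            compute_raw_prs(harmonize(weights, geno), substitute="fail")


class TestStandardize:
    def test_z_score(self):
        from riskport.prs import RawScore

        raw = RawScore(
            values=np.array([1.8, 1.2]),
            sample_ids=["a", "b"],
            n_variants_used=1,
            n_substituted=np.array([0, 0]),
        )
        z = standardize(raw, ReferenceStats(mean=1.2, sd=0.3))
        np.testing.assert_allclose(z.values, [2.0, 0.0])

    def test_self_standardization_gives_mean0_sd1(self):
        weights = simulate_weights(30, seed=5)
        geno = simulate_genotypes(
            500,
            [v.effect_freq for v in weights.variants],
            seed=6,
            pairs=[(v.key.ref, v.key.alt) for v in weights.variants],
        )
        raw = compute_raw_prs(harmonize(weights, geno))
        ref = ReferenceStats(
            mean=float(np.mean(raw.values)), sd=float(np.std(raw.values, ddof=1))
        )
        z = standardize(raw, ref)
        assert np.mean(z.values) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z.values, ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestCoverage:
    def test_coverage_fraction(self):
        weights = WeightTable(
            variants=[make_weighted(p, "A", "G") for p in range(1, 101)]
        )
        present = weights.variants[:94]
        geno = GenotypeMatrix(
            sample_ids=["s"],
            variant_keys=[v.key for v in present],
            dosage=np.ones((1, 94)),
        )
        rep = coverage_report(weights, geno)
        assert rep.coverage == pytest.approx(0.94)
        assert rep.flag_counts[FLAG_ABSENT] == 6

    @pytest.mark.parametrize("n_present,expected", [(2, 1.0), (0, 0.0)])
    def test_boundary_coverages(self, n_present, expected):
        weights = WeightTable(variants=[make_weighted(p) for p in (1, 2)])
        keys = [v.key for v in weights.variants[:n_present]]
        geno = GenotypeMatrix(
            sample_ids=["s"],
            variant_keys=keys,
            dosage=np.ones((1, n_present)),
        )
        assert coverage_report(weights, geno).coverage == expected

    def test_empty_weight_table_rejected(self, small_geno):
        with pytest.raises(ValidationError):
            coverage_report(WeightTable(variants=[]), small_geno)

    def test_both_denominators_reported(self, small_weights, small_geno):
        rep = coverage_report(small_weights, small_geno)
        assert rep.coverage == pytest.approx(2 / 4)
        assert rep.coverage_post_filter == pytest.approx(2 / 2)


class TestScoreProperties:
    """Algebraic invariants of the scoring pipeline."""

    @pytest.fixture
    def random_case(self):
        weights = simulate_weights(8, seed=21)
        geno = simulate_genotypes(
            6,
            [v.effect_freq for v in weights.variants],
            seed=22,
            pairs=[(v.key.ref, v.key.alt) for v in weights.variants],
        )
        geno.dosage[0, 0] = np.nan
        geno.dosage[3, 4] = np.nan
        return weights, geno

    def test_oracle_equivalence(self, random_case):
        weights, geno = random_case
        raw = compute_raw_prs(harmonize(weights, geno))
        np.testing.assert_allclose(
            raw.values, brute_force_scores(weights, geno), atol=1e-12
        )

    @given(c=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linearity_in_weights(self, c):
        weights = simulate_weights(5, seed=31)
        geno = simulate_genotypes(
            4,
            [v.effect_freq for v in weights.variants],
            seed=32,
            pairs=[(v.key.ref, v.key.alt) for v in weights.variants],
        )
        base = compute_raw_prs(harmonize(weights, geno)).values
        scaled_table = WeightTable(
            variants=[
                WeightedVariant(
                    key=v.key,
                    effect_allele=v.effect_allele,
                    other_allele=v.other_allele,
                    weight=c * v.weight,
                    effect_freq=v.effect_freq,
                )
                for v in weights.variants
            ]
        )
        scaled = compute_raw_prs(harmonize(scaled_table, geno)).values
        np.testing.assert_allclose(scaled, c * base, atol=1e-9)

    def test_invariant_under_sample_and_variant_reordering(self, random_case):
        weights, geno = random_case
        base = compute_raw_prs(harmonize(weights, geno)).values
        perm_s = np.array([3, 0, 5, 1, 4, 2])
        perm_v = np.array([4, 1, 7, 0, 3, 6, 2, 5])
        shuffled = GenotypeMatrix(
            sample_ids=[geno.sample_ids[i] for i in perm_s],
            variant_keys=[geno.variant_keys[j] for j in perm_v],
            dosage=geno.dosage[np.ix_(perm_s, perm_v)],
        )
        out = compute_raw_prs(harmonize(weights, shuffled)).values
        np.testing.assert_allclose(out, base[perm_s], atol=1e-12)

    def test_substitution_matches_observed_expected_dosage(self):
        """A missing cell scores exactly like an observed dosage of 2·freq."""
        weights = WeightTable(
            variants=[make_weighted(1, weight=0.7, freq=0.3)]
        )
        key = weights.variants[0].key
        g_missing = GenotypeMatrix(
            sample_ids=["s"], variant_keys=[key], dosage=np.array([[np.nan]])
        )
        g_observed = GenotypeMatrix(
            sample_ids=["s"], variant_keys=[key], dosage=np.array([[0.6]])
        )
        a = compute_raw_prs(harmonize(weights, g_missing)).values
        b = compute_raw_prs(harmonize(weights, g_observed)).values
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_harmonization_involution(self, random_case):
        """Swapping ref/alt with d → 2−d in the genotypes changes nothing."""
        weights, geno = random_case
        base = compute_raw_prs(harmonize(weights, geno)).values
        flipped = GenotypeMatrix(
            sample_ids=geno.sample_ids,
            variant_keys=[
                VariantKey(chrom=k.chrom, pos=k.pos, ref=k.alt, alt=k.ref)
                for k in geno.variant_keys
            ],
            dosage=2.0 - geno.dosage,
        )
        out = compute_raw_prs(harmonize(weights, flipped)).values
        np.testing.assert_allclose(out, base, atol=1e-12)


def test_score_cohort_end_to_end_columns(small_weights, small_geno):
    ref = ReferenceStats(mean=0.0, sd=1.0)
    df = score_cohort(small_weights, small_geno, ref)
    assert list(df.columns) == ["sample_id", "raw", "z", "n_used", "n_substituted"]
    assert len(df) == 3
    np.testing.assert_allclose(df["raw"], df["z"])  # identity reference
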