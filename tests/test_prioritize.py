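"""Region expansion, array-design filtering rules, LD r2, HWE chi-square
and candidate ranking."""

import numpy as np
import pytest

from hapdeficit import (CandidateVariant, candidate_filter, design_rate,
                        expand_region, hwe_chisq, ld_r2, rank_candidates,
                        PROTEIN_CHANGING)
from hapdeficit.simulate import simulate_candidate_variants
from hapdeficit.windows import WindowSpec, HaplotypeAllele, assign_diplotypes

from conftest import small_config
from hapdeficit.simulate import simulate_population


class TestExpandRegion:
    def test_two_mb_flanks(self):
        assert expand_region(("7", 7_872_000, 10_433_000)) == \
            ("7", 5_872_000, 12_433_000)

    def test_clip_to_chromosome_start(self):
        assert expand_region(("1", 500_000, 900_000)) == ("1", 1, 2_900_000)

    def test_zero_flank_identity(self):
        assert expand_region(("3", 10, 20), flank_bp=0) == ("3", 10, 20)

    def test_clip_to_chromosome_length(self):
        assert expand_region(("3", 10, 20), flank_bp=100, chrom_length=50) == \
            ("3", 1, 50)


def _variant(pos=100, consequence="missense", hard=True, dosages=None,
             breeds=None, n=8):
    if dosages is None:
        dosages = np.array([1.0, 0, 0, 0, 0, 0, 0, 0][:n])
    breeds = breeds if breeds is not None else np.array(["Holstein"] * n)
    return CandidateVariant(chrom="1", pos=pos, ref="A", alt="G",
                            consequence=consequence, hard_filter_pass=hard,
                            dosages=np.asarray(dosages, dtype=float),
                            breeds=breeds)


class TestCandidateFilter:
    REGION = ("1", 50, 200)

    def fixture_variants(self):
        """Six variants violating exactly one rule each plus one passer."""
        other_breed = np.array(["Braunvieh"] * 8)
        return [
            _variant(pos=100),                                   # passes all
            _variant(pos=300),                                   # outside region
            _variant(pos=110, hard=False),                       # hard filter
            _variant(pos=120, consequence="other"),              # consequence
            _variant(pos=130, dosages=[2, 2, 1, 0, 0, 0, 0, 0]),  # >1 hom alt
            _variant(pos=140, dosages=[1] * 7 + [2]),            # carrier frac 1
            CandidateVariant(chrom="1", pos=150, ref="A", alt="G",
                             consequence="missense", hard_filter_pass=True,
                             dosages=np.array([1.0] + [0.0] * 7),
                             breeds=other_breed),                # no Holstein carrier
        ]

    def test_hand_enumerated_fixture_keeps_exactly_one(self):
        variants = self.fixture_variants()
        # breed-label check needs Holstein to exist somewhere
        kept = candidate_filter(variants, self.REGION,
                                require_consequence=PROTEIN_CHANGING)
        assert len(kept) == 1
        assert kept[0].pos == 100

    def test_two_homozygotes_excluded(self):
        v = _variant(dosages=[2, 2, 0, 0, 0, 0, 0, 0])
        assert candidate_filter([v], self.REGION) == []

    def test_exact_boundary_carrier_fraction_retained(self):
        v = _variant(dosages=[1, 1, 1, 1, 1, 1, 0, 0])  # 6/8 = 0.75
        assert v.carrier_fraction == 0.75
        assert candidate_filter([v], self.REGION) == [v]

    def test_just_above_boundary_excluded(self):
        v = _variant(dosages=[1, 1, 1, 1, 1, 1, 1, 0])  # 7/8
        assert candidate_filter([v], self.REGION) == []

    def test_missing_excluded_from_denominator(self):
        # 3 carriers / 4 non-missing = 0.75 -> retained
        v = _variant(dosages=[1, 1, 1, 0, np.nan, np.nan, np.nan, np.nan])
        assert candidate_filter([v], self.REGION) == [v]

    def test_unknown_breed_label_lists_labels(self):
        with pytest.raises(ValueError, match="Braunvieh"):
            candidate_filter([_variant(breeds=np.array(["Braunvieh"] * 8))],
                             self.REGION, breed_label="Angus")

    def test_idempotent_and_order_invariant(self):
        variants = self.fixture_variants()
        kept = candidate_filter(variants, self.REGION,
                                require_consequence=PROTEIN_CHANGING)
        again = candidate_filter(kept, self.REGION,
                                 require_consequence=PROTEIN_CHANGING)
        assert again == kept
        rev = candidate_filter(variants[::-1], self.REGION,
                               require_consequence=PROTEIN_CHANGING)
        assert {v.pos for v in rev} == {v.pos for v in kept}


class TestLdR2:
    def test_identical_vectors_perfect_ld(self):
        d = np.array([0, 1, 2, 1, 0, 2.0])
        assert ld_r2(d, d) == pytest.approx(1.0)

    def test_hand_computed_six_animals(self):
        a = np.array([0, 1, 2, 1, 0, 1.0])
        b = np.array([0, 1, 1, 1, 0, 2.0])
        # independent brute-force Pearson correlation
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert ld_r2(a, b) == pytest.approx((num / den) ** 2)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, 30).astype(float)
        b = rng.integers(0, 3, 30).astype(float)
        assert ld_r2(a, b) == pytest.approx(ld_r2(b, a))
        assert ld_r2(2 * a + 1, b) == pytest.approx(ld_r2(a, b))

    def test_pairwise_complete_handling(self):
        a = np.array([0, 1, 2, np.nan, 1.0])
        b = np.array([0, 1, 2, 0, np.nan])
        assert ld_r2(a, b) == pytest.approx(1.0)

    def test_constant_vector_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(ld_r2(np.ones(5), np.arange(5.0)))

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(11)
        low = 0
        for _ in range(5):
            a = rng.binomial(2, 0.3, 1000).astype(float)
            b = rng.binomial(2, 0.3, 1000).astype(float)
            low += ld_r2(a, b) < 0.01
        assert low >= 4


class TestHweChisq:
    def test_exact_hwe_counts(self):
        chi2, p = hwe_chisq(25, 50, 25)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_complete_het_deficit_gives_chi2_n(self):
        chi2, _ = hwe_chisq(50, 0, 50)
        assert chi2 == pytest.approx(100.0)

    def test_monomorphic(self):
        chi2, p = hwe_chisq(100, 0, 0)
        assert chi2 == 0.0 and p == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hwe_chisq(0, 0, 0)


class TestRankCandidates:
    def test_single_candidate_rank_one(self):
        v = _variant()
        hd = v.dosages.copy()
        [rc] = rank_candidates([v], hd)
        assert rc.rank == 1 and rc.r2_to_haplotype == pytest.approx(1.0)

    def test_equal_r2_tie_broken_by_carrier_fraction(self):
        # two animals: any non-constant dosage pair is perfectly correlated,
        # so both variants have r2 = 1 and the carrier fraction decides
        hd = np.array([0.0, 2.0])
        two = np.array(["Holstein"] * 2)
        lean = CandidateVariant(chrom="1", pos=10, ref="A", alt="G",
                                consequence="missense", hard_filter_pass=True,
                                dosages=np.array([0.0, 1.0]), breeds=two)
        heavy = CandidateVariant(chrom="1", pos=5, ref="A", alt="G",
                                 consequence="missense", hard_filter_pass=True,
                                 dosages=np.array([1.0, 2.0]), breeds=two)
        ranked = rank_candidates([heavy, lean], hd)
        assert [c.variant.pos for c in ranked] == [10, 5]
        assert [c.rank for c in ranked] == [1, 2]

    def test_equal_r2_and_carriers_tie_broken_by_position(self):
        hd = np.array([0.0, 2.0])
        two = np.array(["Holstein"] * 2)
        right = CandidateVariant(chrom="1", pos=10, ref="A", alt="G",
                                 consequence="missense", hard_filter_pass=True,
                                 dosages=np.array([0.0, 1.0]), breeds=two)
        left = CandidateVariant(chrom="1", pos=5, ref="A", alt="G",
                                consequence="missense", hard_filter_pass=True,
                                dosages=np.array([0.0, 1.0]), breeds=two)
        ranked = rank_candidates([right, left], hd)
        assert ranked[0].variant.pos == 5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates([], np.zeros(3))

    def test_seeded_causal_variant_ranks_first(self, small_pop):
        ped, geno, _, truth = small_pop
        variants = simulate_candidate_variants(geno, truth, seed=3)
        region = (truth.chrom, truth.bp_start, truth.bp_end)
        kept = candidate_filter(variants, region, flank_bp=2_000_000,
                                require_consequence=PROTEIN_CHANGING)
        w = WindowSpec(chrom=truth.chrom,
                       snp_start_index=truth.snp_start_index,
                       snp_end_index=truth.snp_end_index,
                       window_size=truth.snp_end_index - truth.snp_start_index,
                       bp_start=truth.bp_start, bp_end=truth.bp_end)
        allele = HaplotypeAllele(window=w,
                                 allele_string="".join(map(str, truth.pattern)),
                                 frequency=0.1, count=0)
        hd = assign_diplotypes(geno, allele).copies.astype(float)
        ranked = rank_candidates(kept, hd)
        assert ranked[0].variant.gene == "CAUSAL1"
        assert ranked[0].r2_to_haplotype == pytest.approx(1.0)


def test_design_rate_rounding():
    assert design_rate(205_362, 465_768) == 44
    assert design_rate(1, 2) == 50
    with pytest.raises(ValueError):
        design_rate(1, 0)
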