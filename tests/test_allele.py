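"""Allele partitioning, chi-square dosage tests, bias classes and CAPS."""

import numpy as np
import pytest

from endomir import reciprocal_design
from endomir.allele import (AlleleCountTable, call_bias_class,
                            caps_distinguishable, chi_square_bias_test,
                            insilico_caps, null_fraction_a,
                            partition_by_allele)
from endomir.preprocess import SmallRNATag
from endomir.simulate import SNPSpec

SNP = SNPSpec(11, "A", "G")
MATURE_A = "TCTTTTTATTAGTCGTTGGAT"          # A at the 11th base
MATURE_B = MATURE_A[:10] + "G" + MATURE_A[11:]


class TestPartition:
    ref = {"pre": "CCCCC" + MATURE_A + "GGGGG"}

    def run(self, tags):
        return partition_by_allele(tags, "pre", 5, 26, SNP,
                                   references=self.ref, mirna_id="miR-x")

    def test_allele_assignment_at_offset_eleven(self):
        table = self.run([SmallRNATag(MATURE_A, {"L": 7}),
                          SmallRNATag(MATURE_B, {"L": 3})])
        assert table.counts["L"] == (7, 3, 0)

    def test_tag_not_covering_snp_is_ambiguous(self):
        short = MATURE_A[11:] + "GGGGG"      # starts 3' of the SNP
        table = self.run([SmallRNATag(short, {"L": 2})])
        assert table.counts["L"] == (0, 0, 2)

    def test_third_base_is_ambiguous(self):
        third = MATURE_A[:10] + "C" + MATURE_A[11:]
        table = self.run([SmallRNATag(third, {"L": 4})])
        assert table.counts["L"] == (0, 0, 4)

    def test_counts_conserved(self):
        tags = [SmallRNATag(MATURE_A, {"L": 5}), SmallRNATag(MATURE_B, {"L": 2}),
                SmallRNATag(MATURE_A[11:] + "GGGGG", {"L": 1})]
        table = self.run(tags)
        assert sum(table.counts["L"]) == 8

    def test_offset_outside_locus_rejected(self):
        with pytest.raises(ValueError):
            partition_by_allele([], "pre", 5, 10, SNP, references=self.ref)


class TestChiSquare:
    @pytest.mark.parametrize("na,nb,null,chi2,p", [
        (30, 10, 0.5, 10.0, 1.5654e-3),
        (40, 20, 2 / 3, 0.0, 1.0),
        (75, 25, 2 / 3, 3.125, 0.0771),
    ])
    def test_closed_form_cases(self, na, nb, null, chi2, p):
        stat, pval = chi_square_bias_test(na, nb, null)
        assert stat == pytest.approx(chi2, abs=1e-9)
        assert pval == pytest.approx(p, rel=1e-3)

    def test_zero_counts_undefined(self):
        with pytest.raises(ValueError):
            chi_square_bias_test(0, 0, 0.5)

    def test_null_ratio_bounds(self):
        with pytest.raises(ValueError):
            chi_square_bias_test(5, 5, 1.0)

    def test_type_one_error_calibrated_at_dosage_null(self):
        # binomial draws at the 2:1 null; empirical p<=0.01 rate ~ 1%
        rng = np.random.default_rng(2024)
        n, reps = 200, 10_000
        k = rng.binomial(n, 2 / 3, size=reps)
        exp_a, exp_b = n * 2 / 3, n / 3
        stat = (k - exp_a) ** 2 / exp_a + ((n - k) - exp_b) ** 2 / exp_b
        from scipy.stats import chi2 as chi2_dist
        rate = (chi2_dist.sf(stat, 1) <= 0.01).mean()
        assert 0.007 <= rate <= 0.013
        # spot-check the vectorized closed form against the implementation
        s, _ = chi_square_bias_test(int(k[0]), n - int(k[0]), 2 / 3)
        assert s == pytest.approx(stat[0])


class TestNullFraction:
    def test_dosage_null_tracks_maternal_parent(self):
        assert null_fraction_a("BxM", "endosperm") == pytest.approx(2 / 3)
        assert null_fraction_a("MxB", "endosperm") == pytest.approx(1 / 3)

    def test_kernel_and_equal_model_are_half(self):
        assert null_fraction_a("BxM", "kernel") == 0.5
        assert null_fraction_a("BxM", "endosperm", dosage_null=False) == 0.5


class TestBiasClass:
    design = reciprocal_design()

    def table(self, frac_a, n=300):
        counts = {}
        for lib in self.design.libraries_for(tissue="endosperm"):
            na = int(round(n * frac_a))
            counts[lib.library_id] = (na, n - na, 0)
        return AlleleCountTable("miR-x", SNP, counts)

    def test_strong_a_excess_is_genotype_bias(self):
        call = call_bias_class(self.table(0.9), self.design)
        assert call.bias_class == "genotype-biased toward A"

    def test_dosage_ratio_is_unbiased_under_dosage_null(self):
        counts = {}
        for lib in self.design.libraries_for(tissue="endosperm"):
            frac = 2 / 3 if lib.cross == "BxM" else 1 / 3
            counts[lib.library_id] = (int(300 * frac), 300 - int(300 * frac), 0)
        call = call_bias_class(AlleleCountTable("m", SNP, counts), self.design)
        assert call.bias_class == "unbiased"

    def test_maternal_tracking_is_parent_of_origin(self):
        counts = {}
        for lib in self.design.libraries_for(tissue="endosperm"):
            frac_a = 0.95 if lib.cross == "BxM" else 0.05  # maternal allele
            counts[lib.library_id] = (int(300 * frac_a), 300 - int(300 * frac_a), 0)
        call = call_bias_class(AlleleCountTable("m", SNP, counts), self.design)
        assert call.bias_class == "parent-of-origin maternal"

    def test_no_informative_reads_unbiased(self):
        call = call_bias_class(AlleleCountTable("m", SNP, {}), self.design)
        assert call.bias_class == "unbiased"

    def test_planted_b73_bias_recovered_in_replicates(self):
        # genotype-effect simulation: allele A at 85% in both crosses
        rng = np.random.default_rng(99)
        hits = 0
        reps = 100
        for _ in range(reps):
            counts = {}
            for lib in self.design.libraries_for(tissue="endosperm"):
                na = rng.binomial(200, 0.85)
                counts[lib.library_id] = (int(na), 200 - int(na), 0)
            call = call_bias_class(AlleleCountTable("m", SNP, counts),
                                   self.design)
            hits += call.bias_class == "genotype-biased toward A"
        assert hits / reps >= 0.99


class TestCaps:
    def test_no_site_single_fragment(self):
        assert insilico_caps("A" * 300, "GAATTC") == [300]

    def test_cut_position_arithmetic(self):
        amplicon = "A" * 100 + "GAATTC" + "A" * 194  # site at 1-based 101
        assert insilico_caps(amplicon, "GAATTC", cut_offset=1) == [101, 199]

    def test_fragments_sum_to_amplicon_length(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            amp = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
            frags = insilico_caps(amp, "GATC")
            assert sum(frags) == 400

    def test_snp_destroying_site_distinguishes_alleles(self):
        a = "C" * 50 + "ACGCGT" + "C" * 50
        b = "C" * 50 + "ACACGT" + "C" * 50  # SNP kills the site
        assert caps_distinguishable(a, b, "ACGCGT")
        assert not caps_distinguishable(a, a, "ACGCGT")

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            insilico_caps("ACGT", "")
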