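"""Ground-truth generator: hairpin design, background sampling, experiments."""

import math

import numpy as np
import pytest

from endomir import (SimConfig, SNPSpec, design_hairpin, endosperm_truth_set,
                     sample_background, simulate_experiment)
from endomir._seq import can_pair, revcomp
from endomir.known import NOVEL_MIRNAS
from endomir.simulate import ConfigError, PlacementError

MIR2001 = NOVEL_MIRNAS["Zma-miR2001"]


class TestDesignHairpin:
    def test_mature_planted_once_on_5p_arm(self):
        t = design_hairpin(MIR2001, loop_len=8, seed=0)
        assert t.precursor_seq.count(MIR2001) == 1
        assert t.arm == "5p"
        assert t.precursor_seq[t.mature_start:t.mature_start + 21] == MIR2001

    def test_star_pairs_mature_with_two_nt_overhang(self):
        t = design_hairpin(MIR2001, loop_len=8, seed=1)
        # the mature's last two bases (its 3' overhang) are unpaired;
        # positions 0..18 pair antiparallel with the star, whose own
        # first two bases from its 3' end are the star overhang
        star_rev = t.star_seq[::-1]
        for i in range(0, 19):
            assert can_pair(t.mature_seq[i], star_rev[i + 2])

    def test_poly_t_mature_accepted_star_is_poly_a(self):
        t = design_hairpin("T" * 21, loop_len=8, seed=2)
        assert "A" * 19 in t.star_seq

    def test_same_seed_same_precursor(self):
        a = design_hairpin(MIR2001, loop_len=8, seed=9)
        b = design_hairpin(MIR2001, loop_len=8, seed=9)
        assert a.precursor_seq == b.precursor_seq

    def test_tandem_sits_loop_proximal_and_disjoint(self):
        tandem = "T" + MIR2001[1:][::-1]
        t = design_hairpin(MIR2001, loop_len=8, tandem=tandem, seed=3)
        assert t.tandem_start > t.mature_start + 21  # nearer the loop
        assert t.precursor_seq[t.tandem_start:t.tandem_start + 21] == tandem

    def test_loop_too_short_rejected(self):
        with pytest.raises(ValueError, match="loop"):
            design_hairpin(MIR2001, loop_len=2)

    @pytest.mark.parametrize("bad", ["T" * 19, "T" * 25])
    def test_mature_length_bounds(self, bad):
        with pytest.raises(PlacementError):
            design_hairpin(bad, loop_len=8)

    def test_snp_offset_validated(self):
        with pytest.raises(PlacementError):
            design_hairpin(MIR2001, loop_len=8, snp=SNPSpec(22, "A", "G"))


class TestSampleBackground:
    def test_five_prime_a_bias_within_three_sd(self):
        reads = sample_background(10_000, {24: 1.0}, fivep_A_bias=0.46, seed=1)
        frac = sum(r[0] == "A" for r in reads) / len(reads)
        sd = math.sqrt(0.46 * 0.54 / 10_000)
        assert abs(frac - 0.46) <= 3 * sd

    def test_length_distribution_honoured(self):
        reads = sample_background(500, {21: 1.0}, fivep_A_bias=0.9, seed=2)
        assert all(len(r) == 21 for r in reads)

    def test_zero_reads_empty(self):
        assert sample_background(0, {24: 1.0}, 0.5, seed=0) == []

    def test_bad_distribution_rejected(self):
        with pytest.raises(ConfigError):
            sample_background(10, {24: 0.5, 21: 0.2}, 0.5, seed=0)


class TestSimulateExperiment:
    def test_twelve_libraries_written(self, clean_experiment):
        assert len(clean_experiment["res"].fastq_paths) == 12

    def test_zero_noise_reads_all_planted(self, tmp_path):
        truths = [design_hairpin(MIR2001, loop_len=8, seed=0,
                                 abundance_profile={(c, d): 100.0
                                                    for c in ("BxM", "MxB")
                                                    for d in (0, 3, 5, 7, 10, 15)})]
        cfg = SimConfig(total_reads=1000, background_fraction=0.0,
                        star_fraction=0.0, seed=1)
        res = simulate_experiment(truths, cfg, tmp_path)
        lines = (tmp_path / "BxM_7DAP.fastq").read_text().splitlines()
        seqs = lines[1::4]
        assert len(seqs) == 1000
        assert all(MIR2001 in s for s in seqs)

    def test_read_conservation(self, noisy_experiment):
        cfg = noisy_experiment["cfg"]
        for path in noisy_experiment["res"].fastq_paths.values():
            n = sum(1 for _ in open(path)) // 4
            assert n == cfg.total_reads

    def test_maternal_dosage_recovered(self, tmp_path):
        profile = {(c, d): 50_000.0 for c in ("BxM", "MxB")
                   for d in (0, 3, 5, 7, 10, 15)}
        truth = design_hairpin(MIR2001, loop_len=8, seed=0,
                               snp=SNPSpec(11, "A", "G"),
                               abundance_profile=profile)
        cfg = SimConfig(total_reads=40_000, star_fraction=0.0, seed=5)
        res = simulate_experiment([truth], cfg, tmp_path)
        allele_b = truth.mature_allele("B")
        lines = (tmp_path / "BxM_10DAP.fastq").read_text().splitlines()
        seqs = lines[1::4]
        n_a = sum(s.startswith(MIR2001) for s in seqs)
        n_b = sum(s.startswith(allele_b) for s in seqs)
        n = n_a + n_b
        sd = math.sqrt(n * (2 / 3) * (1 / 3))
        assert abs(n_a - n * 2 / 3) <= 3 * sd

    def test_seed_determinism_byte_identical(self, tmp_path):
        truths = endosperm_truth_set(n_hairpins=3, seed=4)
        cfg = SimConfig(total_reads=2000, seed=4)
        r1 = simulate_experiment(truths, cfg, tmp_path / "a")
        r2 = simulate_experiment(truths, cfg, tmp_path / "b")
        for lib in r1.fastq_paths:
            assert (r1.fastq_paths[lib].read_bytes()
                    == r2.fastq_paths[lib].read_bytes())
        assert r1.truth_tsv.read_bytes() == r2.truth_tsv.read_bytes()

    def test_missing_stage_in_profile_rejected(self, tmp_path):
        truth = design_hairpin(MIR2001, loop_len=8, seed=0,
                               abundance_profile={("BxM", 7): 100.0})
        with pytest.raises(ConfigError, match="missing stage"):
            simulate_experiment([truth], SimConfig(total_reads=100, seed=0),
                                tmp_path)

    def test_truth_coordinates_exact(self, clean_experiment):
        for t in clean_experiment["truths"]:
            p = t.precursor_seq
            assert p[t.mature_start:t.mature_start + len(t.mature_seq)] == t.mature_seq
            assert p[t.star_start:t.star_start + len(t.star_seq)] == t.star_seq
            if t.tandem_seq:
                assert p[t.tandem_start:t.tandem_start + 21] == t.tandem_seq


def test_truth_set_matures_are_unique():
    truths = endosperm_truth_set(n_hairpins=24, n_tandem=5, seed=0)
    seqs = [t.mature_seq for t in truths]
    seqs += [t.tandem_seq for t in truths if t.tandem_seq]
    assert len(seqs) == len(set(seqs))
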