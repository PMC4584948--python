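"""Duplex evaluation, the high-confidence filter and tandem detection."""

import pytest

from endomir import (design_hairpin, detect_tandem, evaluate_duplex,
                     high_confidence_filter)
from endomir.fold import fold_sequence
from endomir.hairpin import annotate_precursors
from endomir.known import NOVEL_MIRNAS

MIR2001 = NOVEL_MIRNAS["Zma-miR2001"]


def folded_truth(seed=0, tandem=None):
    t = design_hairpin(MIR2001, loop_len=8, tandem=tandem, seed=seed)
    return t, fold_sequence(t.precursor_seq)


class TestEvaluateDuplex:
    def test_designed_duplex_accepted_with_exact_star(self):
        t, f = folded_truth(seed=1)
        v = evaluate_duplex(f, t.mature_start, t.mature_start + 21)
        assert v.accepted
        assert v.duplex.star_start == t.star_start
        assert v.duplex.star_end == t.star_start + 21
        assert v.duplex.arm == "5p"

    def test_too_many_unpaired_rejected(self):
        # a window hanging 6 nt into an unpaired tail exceeds the 4-nt
        # unpaired tolerance
        from endomir._seq import revcomp
        import numpy as np
        rng = np.random.default_rng(2)
        # G/C-only stem with A-only loop and tail: the tail cannot pair
        stem = "".join(np.array(list("GC"))[rng.integers(0, 2, 25)])
        seq = stem + "AAAAAA" + revcomp(stem) + "A" * 6
        f = fold_sequence(seq)
        n = len(seq)
        v = evaluate_duplex(f, n - 21, n)  # 15 stem + 6 tail positions
        assert not v.accepted
        assert v.reason == "too many unpaired mature positions"

    def test_loop_spanning_rejected(self):
        t, f = folded_truth(seed=3)
        loop_mid = len(t.precursor_seq) // 2
        v = evaluate_duplex(f, loop_mid - 10, loop_mid + 11)
        assert not v.accepted
        assert v.reason == "loop-spanning"

    def test_star_outside_window_rejected(self):
        # mature flush at the precursor start leaves no room for the
        # star's 2-nt 3' overhang
        from endomir._seq import revcomp
        stem = MIR2001 + "ACGT"
        seq = stem + "AACAAC" + revcomp(stem)
        f = fold_sequence(seq)
        v = evaluate_duplex(f, 0, 21)
        assert not v.accepted

    def test_placement_bounds_checked(self):
        _, f = folded_truth(seed=4)
        with pytest.raises(ValueError):
            evaluate_duplex(f, -1, 20)


class TestHighConfidenceFilter:
    rpm_hot = {"L1": 150.0, "L2": 3.0}
    rpm_cold = {"L1": 99.0}

    def test_all_published_novel_sequences_pass(self):
        for seq in NOVEL_MIRNAS.values():
            assert high_confidence_filter(seq, self.rpm_hot)

    def test_wrong_length_fails(self):
        assert not high_confidence_filter("T" * 22, self.rpm_hot)

    def test_wrong_five_prime_base_fails(self):
        assert not high_confidence_filter("A" + MIR2001[1:], self.rpm_hot)

    def test_insufficient_abundance_fails(self):
        assert not high_confidence_filter(MIR2001, self.rpm_cold)

    def test_each_criterion_individually_necessary(self):
        # mutating exactly one criterion flips the verdict
        assert high_confidence_filter(MIR2001, self.rpm_hot)
        assert not high_confidence_filter(MIR2001 + "T", self.rpm_hot)
        assert not high_confidence_filter("G" + MIR2001[1:], self.rpm_hot)
        assert not high_confidence_filter(MIR2001, {"L1": 100.0})  # strict >

    def test_k_of_n_configuration(self):
        assert not high_confidence_filter(MIR2001, self.rpm_hot,
                                          min_libraries=2)


class TestDetectTandem:
    def test_single_duplex_no_tandem(self):
        t, f = folded_truth(seed=5)
        v = evaluate_duplex(f, t.mature_start, t.mature_start + 21)
        assert detect_tandem(f, [v.duplex]) == []
        assert v.duplex.tandem_rank == 0

    def test_loop_proximal_duplex_ranked_one(self):
        tandem = "T" + MIR2001[1:][::-1]
        t, f = folded_truth(seed=6, tandem=tandem)
        vm = evaluate_duplex(f, t.mature_start, t.mature_start + 21)
        vt = evaluate_duplex(f, t.tandem_start, t.tandem_start + 21)
        pairs = detect_tandem(f, [vm.duplex, vt.duplex])
        assert len(pairs) == 1
        assert vm.duplex.tandem_rank == 0      # loop-distal keeps base name
        assert vt.duplex.tandem_rank == 1      # loop-proximal gets ".1"
        assert pairs[0].primary is vm.duplex

    def test_rank_independent_of_input_order(self):
        tandem = "T" + MIR2001[1:][::-1]
        t, f = folded_truth(seed=6, tandem=tandem)
        vm = evaluate_duplex(f, t.mature_start, t.mature_start + 21)
        vt = evaluate_duplex(f, t.tandem_start, t.tandem_start + 21)
        detect_tandem(f, [vt.duplex, vm.duplex])
        assert vm.duplex.tandem_rank == 0 and vt.duplex.tandem_rank == 1


class TestAnnotatePrecursors:
    def test_zero_noise_full_recall_and_exact_stars(self, clean_experiment):
        tags = clean_experiment["tags"]
        totals = clean_experiment["totals"]
        cfg = clean_experiment["cfg"]
        res = clean_experiment["res"]
        calls, tandems = annotate_precursors(
            tags, totals, str(res.precursor_fasta), cfg.design)
        truth = res.truth_table
        planted = truth[truth.role.isin(["mature", "tandem"])]
        called = {(c.precursor_id, c.duplex.mature_start + 1) for c in calls}
        assert all((r.precursor_id, r.start) in called
                   for r in planted.itertuples())
        stars = {(r.precursor_id, r.start)
                 for r in truth[truth.role.isin(["star", "tandem_star"])].itertuples()}
        assert all((c.precursor_id, c.duplex.star_start + 1) in stars
                   for c in calls)
        assert len(tandems) == int(truth.role.eq("tandem").sum())

    def test_tandem_calls_named_dot_one(self, clean_experiment):
        calls, _ = annotate_precursors(
            clean_experiment["tags"], clean_experiment["totals"],
            str(clean_experiment["res"].precursor_fasta),
            clean_experiment["cfg"].design)
        proximal = [c for c in calls if c.duplex.tandem_rank == 1]
        assert proximal and all(c.mirna_id.endswith(".1") for c in proximal)

    def test_precision_with_background(self, noisy_experiment):
        calls, _ = annotate_precursors(
            noisy_experiment["tags"], noisy_experiment["totals"],
            str(noisy_experiment["res"].precursor_fasta),
            noisy_experiment["cfg"].design)
        truth = noisy_experiment["res"].truth_table
        truth_seqs = set(truth[truth.role.isin(["mature", "tandem"])].seq)
        flagged = [c for c in calls if c.passes_filter]
        tp = sum(c.mature_seq in truth_seqs for c in flagged)
        assert tp / len(flagged) >= 0.95
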