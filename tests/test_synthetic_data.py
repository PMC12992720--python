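"""Generator structure, determinism, clock statistics, and truth closure."""

import numpy as np
import pytest

from ervscape.orf_integrity import OrfStatus, classify_integrity, scan_orfs
from ervscape.seqcore_io import Feature, revcomp
from ervscape.silencing_potential import build_kmer_index, coverage
from ervscape.synthetic_data import (
    FragmentPlan,
    SimParams,
    assemble_cluster,
    evolve_insertion,
    inject_inactivation,
    make_consensus,
    make_recombinant,
    make_variant,
)


class TestMakeConsensus:
    def test_ltr_copies_identical(self, default_consensus):
        ltr5 = default_consensus.region(Feature.LTR5)
        ltr3 = default_consensus.region(Feature.LTR3)
        assert ltr5 == ltr3

    def test_orfs_at_annotated_coordinates(self, default_consensus):
        hits = scan_orfs(default_consensus.sequence, min_aa=80)
        spans = {(h.start, h.end) for h in hits}
        for feat in (Feature.GAG, Feature.POL, Feature.ENVF):
            ann = default_consensus.feature(feat)
            assert (ann.start, ann.end) in spans

    def test_deterministic(self):
        p = SimParams(seed=99)
        a = make_consensus(p, "x")
        b = make_consensus(p, "x")
        assert a.sequence.seq == b.sequence.seq
        assert a.features == b.features

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(ltr_len=0)
        with pytest.raises(ValueError):
            SimParams(base_comp=(0.5, 0.5, 0.5, 0.5))


class TestEvolveInsertion:
    def test_age_zero_is_exact_copy(self, default_consensus):
        rec, truth = evolve_insertion(default_consensus, 0.0, seed=1)
        assert rec.sequence.seq == default_consensus.sequence.seq
        assert truth["n_sub_ltr5"] == truth["n_sub_ltr3"] == 0

    def test_poisson_substitution_load_per_ltr(self, default_consensus):
        # expected pairwise LTR differences = 2 * r * T * L
        r, age, L = 0.0346, 0.5, 400
        lam_pair = 2 * r * age * L
        n = 300
        totals = []
        for s in range(n):
            _, truth = evolve_insertion(default_consensus, age, r=r, seed=s)
            totals.append(truth["n_sub_ltr5"] + truth["n_sub_ltr3"])
        totals = np.array(totals)
        se = totals.std(ddof=1) / np.sqrt(n)
        assert abs(totals.mean() - lam_pair) <= 3 * se

    def test_deterministic_per_seed(self, default_consensus):
        a, _ = evolve_insertion(default_consensus, 0.3, seed=5)
        b, _ = evolve_insertion(default_consensus, 0.3, seed=5)
        c, _ = evolve_insertion(default_consensus, 0.3, seed=6)
        assert a.sequence.seq == b.sequence.seq
        assert a.sequence.seq != c.sequence.seq

    def test_negative_age_rejected(self, default_consensus):
        with pytest.raises(ValueError):
            evolve_insertion(default_consensus, -0.1)


class TestAssembleCluster:
    def test_full_antisense_fragment_gives_full_silencing(self, default_consensus):
        cons = default_consensus
        plan = [FragmentPlan(cons.id, 0, len(cons.sequence), "antisense")]
        cluster, truth = assemble_cluster(plan, {cons.id: cons}, seed=3)
        idx = build_kmer_index(cluster, 25)
        assert coverage(cons.sequence, idx, "antisense").fraction == 1.0
        assert truth[0]["orientation"] == "antisense"

    def test_sense_fragment_gives_no_antisense_signal(self, default_consensus):
        cons = default_consensus
        plan = [FragmentPlan(cons.id, 0, len(cons.sequence), "sense")]
        cluster, _ = assemble_cluster(plan, {cons.id: cons}, seed=4)
        idx = build_kmer_index(cluster, 25)
        assert coverage(cons.sequence, idx, "antisense").fraction <= 1e-3

    def test_planned_coverage_recovered_within_junction_slack(self, default_consensus):
        cons = default_consensus
        L = len(cons.sequence)
        plan = [
            FragmentPlan(cons.id, 0, int(0.25 * L), "antisense"),
            FragmentPlan(cons.id, int(0.40 * L), int(0.60 * L), "antisense"),
            FragmentPlan(cons.id, int(0.85 * L), L, "antisense"),
        ]
        planned = sum(f.end - f.start for f in plan) / L
        cluster, _ = assemble_cluster(plan, {cons.id: cons}, seed=5)
        idx = build_kmer_index(cluster, 25)
        frac = coverage(cons.sequence, idx, "antisense").fraction
        slack = len(plan) * 2 * 24 / L  # < (k-1) per fragment junction
        assert abs(frac - planned) <= slack

    def test_truth_predicts_covered_intervals(self, default_consensus):
        """Closure: the truth table alone predicts the analysis output."""
        cons = default_consensus
        plan = [FragmentPlan(cons.id, 500, 1500, "antisense")]
        cluster, truth = assemble_cluster(plan, {cons.id: cons}, seed=6)
        idx = build_kmer_index(cluster, 25)
        covered = coverage(cons.sequence, idx, "antisense").covered
        t = truth[0]
        # interior of the fragment is covered; outside (minus slack) is not
        assert covered[t["start"] : t["end"]].all()
        assert not covered[: t["start"] - 24].any()
        assert not covered[t["end"] + 24 :].any()

    def test_fragment_exceeding_consensus_rejected(self, default_consensus):
        plan = [FragmentPlan(default_consensus.id, 0, 10**6, "antisense")]
        with pytest.raises(ValueError):
            assemble_cluster(plan, {default_consensus.id: default_consensus})


class TestMakeRecombinant:
    def test_no_breakpoints_copies_parent1(self, default_consensus):
        var_a, _ = make_variant(default_consensus, 20, 7, "a")
        var_b, _ = make_variant(default_consensus, 20, 8, "b")
        rec, truth = make_recombinant(var_a.sequence, var_b.sequence, [])
        assert rec.seq == var_a.sequence.seq
        assert truth["breakpoints_parent1"] == []

    def test_single_switch_sequence_content(self, default_consensus):
        var_a, _ = make_variant(default_consensus, 20, 7, "a")
        var_b, _ = make_variant(default_consensus, 20, 8, "b")
        bp = 2000
        rec, _ = make_recombinant(var_a.sequence, var_b.sequence, [bp])
        assert rec.seq[:bp] == var_a.sequence.seq[:bp]
        assert rec.seq[bp:] == var_b.sequence.seq[bp:]

    def test_double_switch_carries_middle_from_parent2(self, default_consensus):
        var_a, _ = make_variant(default_consensus, 20, 7, "a")
        var_b, _ = make_variant(default_consensus, 20, 8, "b")
        rec, _ = make_recombinant(var_a.sequence, var_b.sequence, [1000, 3000])
        assert rec.seq[:1000] == var_a.sequence.seq[:1000]
        assert rec.seq[1000:3000] == var_b.sequence.seq[1000:3000]
        assert rec.seq[3000:] == var_a.sequence.seq[3000:]

    def test_unequal_length_parents_mapped_through_alignment(self, default_consensus):
        var_a, _ = make_variant(default_consensus, 10, 7, "a")
        # parent2 with a 30-nt deletion upstream of the breakpoint
        seq_b = var_a.sequence.seq
        from ervscape.seqcore_io import NucSequence

        parent2 = NucSequence("b", seq_b[:600] + seq_b[630:])
        bp = 2000
        rec, _ = make_recombinant(var_a.sequence, parent2, [bp])
        assert rec.seq[:bp] == var_a.sequence.seq[:bp]
        assert rec.seq[bp:] == parent2.seq[bp - 30 :]

    def test_breakpoint_bounds_checked(self, default_consensus):
        var_a, _ = make_variant(default_consensus, 10, 7, "a")
        with pytest.raises(ValueError):
            make_recombinant(var_a.sequence, var_a.sequence, [0])
        with pytest.raises(ValueError):
            make_recombinant(var_a.sequence, var_a.sequence, [100, 100])


class TestInjectInactivation:
    def test_insertion_produces_envf_frameshift(self, default_consensus):
        mut, truth = inject_inactivation(
            default_consensus, Feature.ENVF, "insertion", 400, seed=2
        )
        rep = classify_integrity(mut.sequence, default_consensus)
        assert rep.statuses[Feature.ENVF] is OrfStatus.FRAMESHIFT
        assert len(mut.sequence) == len(default_consensus.sequence) + 1

    def test_stop_substitution_at_exact_codon(self, default_consensus):
        mut, truth = inject_inactivation(
            default_consensus, Feature.POL, "substitution_stop", 600
        )
        pol = default_consensus.feature(Feature.POL)
        pos = truth["orf_position"]
        codon_idx = pos // 3
        mutated_codon = mut.sequence.seq[
            pol.start + 3 * codon_idx : pol.start + 3 * codon_idx + 3
        ]
        assert mutated_codon in ("TAA", "TAG", "TGA")
        # one-substitution event
        diffs = sum(
            a != b
            for a, b in zip(mut.sequence.seq, default_consensus.sequence.seq)
        )
        assert diffs == 1

    def test_indel_avoids_homopolymers(self, default_consensus):
        seq = default_consensus.sequence.seq
        gag = default_consensus.feature(Feature.GAG)
        # find a homopolymer position inside gag and request it
        pos = next(
            p for p in range(gag.start + 10, gag.end - 10)
            if seq[p] == seq[p + 1]
        ) - gag.start
        mut, truth = inject_inactivation(
            default_consensus, Feature.GAG, "deletion", pos, seed=3
        )
        actual = gag.start + truth["orf_position"]
        assert seq[actual] != seq[actual - 1]
        assert seq[actual] != seq[actual + 1]

    def test_downstream_features_shifted(self, default_consensus):
        mut, _ = inject_inactivation(
            default_consensus, Feature.GAG, "insertion", 100, seed=4
        )
        old_ltr3 = default_consensus.feature(Feature.LTR3)
        new_ltr3 = mut.feature(Feature.LTR3)
        assert new_ltr3.start == old_ltr3.start + 1
        assert mut.region(Feature.LTR3) == default_consensus.region(Feature.LTR3)

    def test_position_outside_orf_rejected(self, default_consensus):
        with pytest.raises(ValueError):
            inject_inactivation(default_consensus, Feature.GAG, "insertion", 10**6)
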