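"""LTR variant typing, diagnostic-site painting, breakpoints, site profiles."""

import numpy as np
import pytest

from ervscape.seqcore_io import InsertionRecord, Msa, NucSequence
from ervscape.synthetic_data import (
    SimParams,
    make_consensus,
    make_recombinant,
    make_variant,
)
from ervscape.variants_recombination import (
    UNTYPED,
    UnrelatedQueryError,
    VariantDef,
    VariantLibrary,
    call_recombinant,
    detect_ltr_mismatch,
    diagnostic_sites,
    site_frequency_profile,
    type_ltr,
)


def random_nuc(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def library():
    rng = np.random.default_rng(17)
    ltr408 = random_nuc(rng, 408)
    ltr376 = random_nuc(rng, 376)
    return VariantLibrary(
        [
            VariantDef("LTR-408", NucSequence("LTR-408", ltr408), 408),
            VariantDef("LTR-376", NucSequence("LTR-376", ltr376), 376),
        ]
    )


class TestTypeLtr:
    def test_exact_reference_is_perfect_match(self, library):
        ref = library.variants[0].ltr.seq
        assert type_ltr(ref, library) == ("LTR-408", 1.0)

    def test_five_substitutions_still_typed(self, library):
        rng = np.random.default_rng(18)
        ref = list(library.variants[0].ltr.seq)
        for p in rng.choice(408, 5, replace=False):
            ref[p] = rng.choice([b for b in "ACGT" if b != ref[p]])
        name, ident = type_ltr("".join(ref), library)
        assert name == "LTR-408"
        assert ident == pytest.approx(403 / 408, abs=1e-3)

    def test_random_sequence_untyped(self, library):
        rng = np.random.default_rng(19)
        name, ident = type_ltr(random_nuc(rng, 400), library)
        assert name == UNTYPED
        assert ident < 0.8

    def test_length_mismatch_declared(self):
        with pytest.raises(ValueError):
            VariantDef("LTR-408", NucSequence("LTR-408", "ACGT"), 408)


@pytest.fixture(scope="module")
def panel():
    cons = make_consensus(SimParams(seed=23), "rv")
    var_a, _ = make_variant(cons, 40, 101, "varA")
    var_b, _ = make_variant(cons, 40, 102, "varB")
    lib = VariantLibrary(
        [
            VariantDef("typeA", NucSequence("typeA", var_a.sequence.seq[:400])),
            VariantDef("typeB", NucSequence("typeB", var_b.sequence.seq[:400])),
        ]
    )
    return cons, var_a, var_b, lib


class TestLtrMismatch:
    def test_cross_variant_recombinant_flagged(self, panel):
        cons, var_a, var_b, lib = panel
        rec, _ = make_recombinant(
            var_a.sequence, var_b.sequence, [len(cons.sequence) // 2], "rec"
        )
        mismatch, t5, t3 = detect_ltr_mismatch(
            InsertionRecord(sequence=rec), lib, reference=var_a
        )
        assert mismatch is True
        assert (t5, t3) == ("typeA", "typeB")

    def test_non_recombinant_not_flagged(self, panel):
        cons, var_a, var_b, lib = panel
        mismatch, t5, t3 = detect_ltr_mismatch(
            InsertionRecord(sequence=NucSequence("plain", var_b.sequence.seq)),
            lib, reference=var_b,
        )
        assert mismatch is False
        assert t5 == t3 == "typeB"

    def test_untyped_ltr_is_indeterminate(self, panel):
        cons, var_a, var_b, lib = panel
        rng = np.random.default_rng(24)
        chimera = random_nuc(rng, 400) + var_a.sequence.seq[400:]
        mismatch, t5, t3 = detect_ltr_mismatch(
            InsertionRecord(sequence=NucSequence("odd", chimera), ltr5=chimera[:400],
                            ltr3=chimera[-400:]),
            lib,
        )
        assert mismatch is None
        assert t5 == UNTYPED


def build_msa_with_sites(seed=0, n=600, n_sites=30):
    """Equal-length parent pair panels with planted diagnostic positions."""
    rng = np.random.default_rng(seed)
    base = random_nuc(rng, n)
    positions = np.sort(rng.choice(np.arange(5, n - 5), n_sites, replace=False))
    b = list(base)
    for p in positions:
        b[p] = rng.choice([x for x in "ACGT" if x != b[p]])
    a_seq, b_seq = base, "".join(b)
    rows = [("A1", a_seq), ("A2", a_seq), ("B1", b_seq), ("B2", b_seq)]
    return rows, a_seq, b_seq, positions.tolist()


class TestDiagnosticSites:
    def test_planted_positions_recovered_exactly(self):
        rows, _, _, positions = build_msa_with_sites(seed=30)
        msa = Msa(rows)
        sites = diagnostic_sites(msa, "A1", "A2", "B1", "B2")
        assert [s.column for s in sites.sites] == positions

    def test_discordant_parent_column_excluded(self):
        rows = [("A1", "CAT"), ("A2", "TAT"), ("B1", "GAT"), ("B2", "GAT")]
        sites = diagnostic_sites(Msa(rows), "A1", "A2", "B1", "B2")
        assert sites.sites == []

    def test_shared_gap_is_diagnostic_and_indel_collapsed(self):
        rows = [
            ("A1", "AC--GTA"), ("A2", "AC--GTA"),
            ("B1", "ACTTGTA"), ("B2", "ACTTGTA"),
        ]
        sites = diagnostic_sites(Msa(rows), "A1", "A2", "B1", "B2")
        assert len(sites.sites) == 1
        assert sites.sites[0].column == 2
        assert sites.sites[0].allele_a == "-"

    def test_symmetric_under_parent_swap(self):
        rows, _, _, _ = build_msa_with_sites(seed=31)
        msa = Msa(rows)
        ab = diagnostic_sites(msa, "A1", "A2", "B1", "B2")
        ba = diagnostic_sites(msa, "B1", "B2", "A1", "A2")
        assert [(s.column, s.allele_a, s.allele_b) for s in ab.sites] == [
            (s.column, s.allele_b, s.allele_a) for s in ba.sites
        ]

    def test_degenerate_parent_pair_flagged(self):
        rows, _, _, _ = build_msa_with_sites(seed=32)
        msa = Msa(rows)
        sites = diagnostic_sites(msa, "A1", "A1", "B1", "B2")
        assert sites.degenerate_a and not sites.degenerate_b

    def test_absent_row_raises(self):
        rows, _, _, _ = build_msa_with_sites(seed=33)
        with pytest.raises(KeyError):
            diagnostic_sites(Msa(rows), "A1", "A2", "B1", "nope")


class TestCallRecombinant:
    def test_pure_parent_single_segment(self):
        rows, a_seq, _, _ = build_msa_with_sites(seed=40)
        msa = Msa(rows + [("Q", a_seq)])
        sites = diagnostic_sites(msa, "A1", "A2", "B1", "B2")
        call = call_recombinant(msa, "Q", sites)
        assert call.n_switches == 0
        assert [s.call for s in call.segments] == ["A"]

    def test_single_switch_breakpoint_interval(self):
        rows, a_seq, b_seq, positions = build_msa_with_sites(seed=41)
        cut = 300
        q = a_seq[:cut] + b_seq[cut:]
        msa = Msa(rows + [("Q", q)])
        sites = diagnostic_sites(msa, "A1", "A2", "B1", "B2")
        call = call_recombinant(msa, "Q", sites)
        assert call.n_switches == 1
        (lo, hi) = call.breakpoints[0]
        assert lo < cut <= hi
        left = max(p for p in positions if p < cut)
        right = min(p for p in positions if p >= cut)
        assert (lo, hi) == (left, right)

    def test_double_recombinant_aba(self):
        rows, a_seq, b_seq, positions = build_msa_with_sites(seed=42, n_sites=40)
        c1, c2 = 200, 420
        q = a_seq[:c1] + b_seq[c1:c2] + a_seq[c2:]
        msa = Msa(rows + [("Q", q)])
        sites = diagnostic_sites(msa, "A1", "A2", "B1", "B2")
        call = call_recombinant(msa, "Q", sites)
        assert call.n_switches == 2
        assert [s.call for s in call.segments] == ["A", "B", "A"]
        for (lo, hi), cut in zip(call.breakpoints, (c1, c2)):
            assert lo < cut <= hi

    def test_isolated_convergent_site_does_not_split_segment(self):
        rows, a_seq, b_seq, positions = build_msa_with_sites(seed=43, n_sites=30)
        # query is parent A except at one diagnostic site where it carries B's allele
        q = list(a_seq)
        q[positions[10]] = b_seq[positions[10]]
        msa = Msa(rows + [("Q", "".join(q))])
        sites = diagnostic_sites(msa, "A1", "A2", "B1", "B2")
        call = call_recombinant(msa, "Q", sites, min_sites_per_segment=2)
        assert call.n_switches == 0
        assert [s.call for s in call.segments] == ["A"]

    def test_all_nonref_query_rejected(self):
        rows, _, _, positions = build_msa_with_sites(seed=44)
        rng = np.random.default_rng(45)
        q = random_nuc(rng, len(rows[0][1]))
        msa = Msa(rows + [("Q", q)])
        sites = diagnostic_sites(msa, "A1", "A2", "B1", "B2")
        # make every site nonref explicitly
        qlist = list(q)
        for s in sites.sites:
            allowed = [b for b in "ACGT" if b not in (s.allele_a, s.allele_b)]
            qlist[s.column] = allowed[0]
        msa = Msa(rows + [("Q2", "".join(qlist))])
        with pytest.raises(UnrelatedQueryError):
            call_recombinant(msa, "Q2", sites)

    def test_needs_two_sites(self):
        rows = [("A1", "CA"), ("A2", "CA"), ("B1", "TA"), ("B2", "TA"), ("Q", "CA")]
        msa = Msa(rows)
        sites = diagnostic_sites(msa, "A1", "A2", "B1", "B2")
        with pytest.raises(ValueError):
            call_recombinant(msa, "Q", sites)


class TestSiteFrequencyProfile:
    def test_counted_example(self):
        rows = [(f"r{i}", s) for i, s in enumerate("AAACG-")]
        df = site_frequency_profile(Msa(rows))
        row = df.iloc[0]
        assert row.occupancy == pytest.approx(5 / 6)
        assert (row.base1, row.f1) == ("A", pytest.approx(3 / 5))
        assert (row.base2, row.f2) == ("C", pytest.approx(1 / 5))
        assert (row.base3, row.f3) == ("G", pytest.approx(1 / 5))

    def test_all_gap_column(self):
        rows = [("a", "-A"), ("b", "-C")]
        df = site_frequency_profile(Msa(rows))
        assert df.iloc[0].occupancy == 0
        assert df.iloc[0][["f1", "f2", "f3"]].tolist() == [0, 0, 0]

    def test_invariant_column(self):
        rows = [("a", "G"), ("b", "G"), ("c", "G")]
        df = site_frequency_profile(Msa(rows))
        assert df.iloc[0].f1 == 1.0 and df.iloc[0].f2 == 0.0

    def test_rank_order_and_row_permutation_invariance(self):
        rng = np.random.default_rng(50)
        n, ncol = 8, 120
        rows = [(f"r{i}", random_nuc(rng, ncol)) for i in range(n)]
        df1 = site_frequency_profile(Msa(rows))
        assert (df1.f1 >= df1.f2).all() and (df1.f2 >= df1.f3).all()
        df2 = site_frequency_profile(Msa(rows[::-1]))
        assert df1.equals(df2)
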