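import itertools

import numpy as np
import pytest

from pcevol.compensatory import (
    printed_expected,
    CompSubModel,
    compensatory_test,
    compsub_report,
    count_substitutions,
    expected_counts,
)
from pcevol.core_io import as_alignment
from pcevol.rna import SecondaryStructure, can_pair
from pcevol.synthetic import SynthConfig, simulate_polycistron_alignment

# a 14-nt reference hairpin used throughout: pairs (0,13),(1,12),(2,11),(3,10)
REF = "GGCAGAAAAUUGCC"
DB = "((((......))))"
STRUCT = SecondaryStructure.from_dot_bracket(DB)


def _aln(*variants, ids=None):
    return as_alignment([REF, *variants], ids=ids)


class TestCounting:
    def test_identical_alignment_has_no_events(self):
        assert count_substitutions(_aln(REF), "seq0", STRUCT) == []

    def test_cg_to_ug_is_single_pairing_to_pairing(self):
        # pair (2,11) is C-G in the reference; change C to U -> U-G wobble
        var = REF[:2] + "U" + REF[3:]
        (ev,) = count_substitutions(_aln(var), "seq0", STRUCT)
        assert ev.kind == "single"
        assert ev.pairing
        assert ev.site_pair == (2, 11)

    def test_cg_to_cc_is_single_pairing_to_non_pairing(self):
        var = REF[:11] + "C" + REF[12:]  # G at 11 -> C: pair C-C
        (ev,) = count_substitutions(_aln(var), "seq0", STRUCT)
        assert ev.kind == "single"
        assert not ev.pairing

    def test_double_substitution_classified_on_both_positions(self):
        var = REF[:2] + "U" + REF[3:11] + "A" + REF[12:]  # C-G -> U-A
        (ev,) = count_substitutions(_aln(var), "seq0", STRUCT)
        assert ev.kind == "double"
        assert ev.pairing

    def test_identical_changes_in_many_taxa_count_once(self):
        var = REF[:2] + "U" + REF[3:]
        events = count_substitutions(_aln(var, var, var), "seq0", STRUCT)
        assert len(events) == 1
        assert len(events[0].taxa) == 3
        undeduped = count_substitutions(
            _aln(var, var, var), "seq0", STRUCT, deduplicate=False
        )
        assert len(undeduped) == 3

    def test_counting_invariant_under_taxon_order(self):
        v1 = REF[:2] + "U" + REF[3:]
        v2 = REF[:1] + "A" + REF[2:]
        a = count_substitutions(_aln(v1, v2), "seq0", STRUCT)
        b = count_substitutions(
            as_alignment([v2, REF, v1], ids=["seq2", "seq0", "seq1"]), "seq0", STRUCT
        )
        assert {(e.site_pair, e.kind, e.derived) for e in a} == {
            (e.site_pair, e.kind, e.derived) for e in b
        }

    def test_gap_columns_in_reference_are_projected_through(self):
        # same stems, but the alignment carries a gap column in the reference
        gapped_ref = REF[:7] + "-" + REF[7:]
        gapped_var = (REF[:2] + "U" + REF[3:])[:7] + "A" + (REF[:2] + "U" + REF[3:])[7:]
        aln = as_alignment([gapped_ref, gapped_var], ids=["seq0", "seq1"])
        (ev,) = count_substitutions(aln, "seq0", STRUCT)
        assert ev.site_pair == (2, 11)

    def test_structure_length_mismatch_errors(self):
        with pytest.raises(Exception, match="length"):
            count_substitutions(
                _aln(REF), "seq0", SecondaryStructure.from_dot_bracket("(...)")
            )

    def test_brute_force_oracle_small_alignments(self):
        """Event lists match an independent exhaustive pairwise comparison."""
        rng = np.random.default_rng(4)
        bases = "ACGU"
        for trial in range(10):
            n_taxa = int(rng.integers(2, 6))
            variants = []
            for _ in range(n_taxa - 1):
                v = list(REF)
                for _ in range(int(rng.integers(0, 5))):
                    k = int(rng.integers(0, len(REF)))
                    v[k] = bases[int(rng.integers(0, 4))]
                variants.append("".join(v))
            aln = _aln(*variants)
            events = count_substitutions(aln, "seq0", STRUCT)
            # oracle: direct nested loops over pairs, taxa and derived states
            expected = set()
            for (i, j) in STRUCT.pairs:
                for v in variants:
                    x, y = v[i], v[j]
                    if x == REF[i] and y == REF[j]:
                        continue
                    kind = (
                        "double" if (x != REF[i] and y != REF[j]) else "single"
                    )
                    expected.add(((i, j), kind, (x, y), can_pair(x, y)))
            got = {(e.site_pair, e.kind, e.derived, e.pairing) for e in events}
            assert got == expected


class TestExpectation:
    def test_dixon_hillis_expectations_for_fifty_singles(self):
        exp = expected_counts(50, 0)
        assert exp["single_pp"] == pytest.approx(6.25)
        assert exp["single_pn"] == pytest.approx(43.75)
        # table-style display: half-up on the pairing cell, complement on
        # the other so the row still sums to the observed total
        pp, pn = printed_expected(50, 4, 32)
        assert (pp, pn) == (6.3, 43.7)

    def test_zero_doubles_give_zero_expectations(self):
        exp = expected_counts(50, 0)
        assert exp["double_pp"] == 0
        assert exp["double_pn"] == 0

    def test_expected_cells_sum_to_observed_totals(self):
        exp = expected_counts(37, 11)
        assert exp["single_pp"] + exp["single_pn"] == pytest.approx(37, abs=1e-9)
        assert exp["double_pp"] + exp["double_pn"] == pytest.approx(11, abs=1e-9)

    def test_weights_sum_to_denominators(self):
        m = CompSubModel()
        assert m.single_pp + m.single_pn == 32
        assert m.double_pp + m.double_pn == 43


class TestSignificance:
    def test_strong_excess_is_highly_significant(self):
        p = compensatory_test(27, 23, 6.25, 43.75)
        assert p["fisher_p"] < 1e-4
        assert p["binomial_p"] < 1e-4

    def test_observed_equal_to_expected_not_significant(self):
        p = compensatory_test(6, 44, 6.25, 43.75)
        assert p["fisher_p"] == pytest.approx(1.0)
        assert p["binomial_p"] > 0.5

    def test_all_zero_table_gives_p_one(self):
        p = compensatory_test(0, 0, 0.0, 0.0)
        assert p == {"fisher_p": 1.0, "binomial_p": 1.0}


class TestReport:
    def test_reference_alone_gives_empty_table(self):
        aln = as_alignment([REF, REF], ids=["P01", "copy"])
        rep = compsub_report(aln, "P01", STRUCT)
        assert rep.total_singles == 0
        assert rep.total_doubles == 0
        assert rep.p_single["fisher_p"] == 1.0

    def test_observed_cells_conserve_event_totals(self, default_sim):
        sim = default_sim
        sub = sim.alignment.columns(sim.regions["pre482"])
        rep = compsub_report(sub, sub.records[0].id, sim.structures["pre482"])
        singles = [e for e in rep.events if e.kind == "single"]
        doubles = [e for e in rep.events if e.kind == "double"]
        assert rep.total_singles == len(singles)
        assert rep.total_doubles == len(doubles)

    def test_coupled_simulation_shows_pairing_excess(self):
        """One closed-loop check: generator coupling c=1 at elevated stem
        rate produces a detectable pairing->pairing excess."""
        cfg = SynthConfig(
            tree="star:30",
            region_lengths=(0, 107, 0, 85, 0),
            region_rates=(0, 0.08, 0, 0.08, 0),
            coupling=1.0,
            seed=99,
        )
        sim = simulate_polycistron_alignment(cfg)
        sub = sim.alignment.columns(sim.regions["pre482"])
        rep = compsub_report(sub, sub.records[0].id, sim.structures["pre482"])
        assert rep.p_single["binomial_p"] < 0.05
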