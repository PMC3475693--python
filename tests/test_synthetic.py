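import numpy as np
import pytest

from pcevol.core_io import revcomp
from pcevol.evodistance import pairwise_distance
from pcevol.rna import can_pair
from pcevol.synthetic import (
    MIR1448,
    MIR482_2,
    SimulationError,
    SynthConfig,
    build_hairpin_precursor,
    mutate_sequence,
    simulate_cds_targets,
    simulate_est_library,
    simulate_polycistron_alignment,
)


class TestHairpinDesign:
    def test_layout_and_lengths(self):
        rng = np.random.default_rng(0)
        d = build_hairpin_precursor(MIR482_2, 107, rng)
        assert len(d.sequence) == 107
        s, e = d.mature_interval
        assert d.sequence[s:e] == MIR482_2

    def test_all_designed_pairs_are_canonical(self):
        rng = np.random.default_rng(1)
        d = build_hairpin_precursor(MIR1448, 85, rng)
        for i, j in d.stem_pairs:
            assert can_pair(d.sequence[i], d.sequence[j])

    def test_too_short_precursor_rejected(self):
        with pytest.raises(SimulationError):
            build_hairpin_precursor(MIR482_2, 45, np.random.default_rng(0))


class TestPolycistronSimulation:
    def test_zero_rates_give_identical_sequences(self):
        cfg = SynthConfig(tree="star:5", region_rates=(0, 0, 0, 0, 0), seed=1)
        sim = simulate_polycistron_alignment(cfg)
        assert len({r.residues for r in sim.alignment.records}) == 1

    def test_same_seed_is_bit_reproducible(self):
        cfg = SynthConfig(tree="star:5", seed=42)
        a = simulate_polycistron_alignment(cfg)
        b = simulate_polycistron_alignment(cfg)
        assert [r.residues for r in a.alignment.records] == [
            r.residues for r in b.alignment.records
        ]

    def test_region_intervals_tile_the_sequence(self, default_sim):
        lengths = SynthConfig().region_lengths
        pos = 0
        for name, n in zip(
            ("flank5", "pre482", "internal", "pre1448", "flank3"), lengths
        ):
            assert default_sim.regions[name] == (pos, pos + n)
            pos += n
        assert pos == len(default_sim.root)

    def test_realized_distances_track_region_rates(self, default_sim):
        """Regions simulated at higher rates show higher mean pairwise
        p-distance, preserving flank > precursor > internal ordering."""
        aln = default_sim.alignment
        means = {}
        for name, iv in default_sim.regions.items():
            sub = aln.columns(iv)
            vals = [
                pairwise_distance(a.residues, b.residues).p_dist
                for k, a in enumerate(sub.records)
                for b in sub.records[k + 1:]
            ]
            means[name] = np.mean(vals)
        assert means["flank5"] > means["pre482"] > means["internal"]
        assert means["flank3"] > means["pre1448"] > means["internal"]

    def test_coupling_rewires_partner_sites(self):
        """At c=1 a stem mutation is always accompanied by a re-pairing
        partner state, so derived stem pairs stay canonical far more often
        than at c=0."""
        def pairing_fraction(coupling, seed):
            cfg = SynthConfig(
                tree="star:10",
                region_lengths=(0, 107, 0, 0, 0),
                region_rates=(0, 0.15, 0, 0, 0),
                coupling=coupling,
                seed=seed,
            )
            sim = simulate_polycistron_alignment(cfg)
            ok = tot = 0
            for rec in sim.alignment.records:
                for i, j in sim.stem_pairs:
                    if (rec.residues[i], rec.residues[j]) != (sim.root[i], sim.root[j]):
                        tot += 1
                        ok += can_pair(rec.residues[i], rec.residues[j])
            return ok / tot
        assert pairing_fraction(1.0, 5) > pairing_fraction(0.0, 5) + 0.3

    def test_newick_tree_input_accepted(self):
        cfg = SynthConfig(
            tree="((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);",
            region_lengths=(10, 107, 0, 0, 0),
            seed=2,
        )
        sim = simulate_polycistron_alignment(cfg)
        assert sorted(sim.alignment.ids) == ["a", "b", "c", "d"]

    def test_invalid_coupling_rejected(self):
        with pytest.raises(SimulationError):
            SynthConfig(coupling=1.5)


class TestESTLibrary:
    def test_truth_table_matches_planted_intervals(self):
        from pcevol.annotate import default_references

        ref = default_references()[0].residues
        lib = simulate_est_library(ref, n=6, planted_fraction=0.5, seed=3)
        planted = lib.truth[lib.truth.planted]
        assert len(planted) == 3
        for _, row in planted.iterrows():
            rec = next(r for r in lib.records if r.id == row.est_id)
            assert rec.residues[row.a_start : row.a_end] == ref
            homolog = rec.residues[row.b_start : row.b_end]
            d = pairwise_distance(ref, homolog)
            assert d.p_dist == pytest.approx(row.divergence, abs=0.01)

    def test_same_seed_identical_library(self):
        from pcevol.annotate import default_references

        ref = default_references()[0].residues
        a = simulate_est_library(ref, n=4, seed=9)
        b = simulate_est_library(ref, n=4, seed=9)
        assert [r.residues for r in a.records] == [r.residues for r in b.records]

    def test_too_short_ests_rejected(self):
        with pytest.raises(SimulationError):
            simulate_est_library("A" * 500, n=2, length_range=(600, 700))


class TestCDSTargets:
    def test_planted_site_is_reverse_complement_at_requested_frame(self):
        mirnas = {"A": MIR482_2}
        sim = simulate_cds_targets(mirnas, [(0, "A", 1, 0)], n_transcripts=2, seed=4)
        row = sim.truth.iloc[0]
        rec = sim.records[0]
        assert rec.residues[row.start : row.end] == revcomp(MIR482_2)
        assert row.start % 3 == 1

    def test_conflicting_plants_error(self):
        mirnas = {"A": MIR482_2}
        plants = [(0, "A", 0, 0)] * 40  # more sites than fit in one CDS
        with pytest.raises(SimulationError, match="room"):
            simulate_cds_targets(mirnas, plants, n_transcripts=1, cds_codons=40, seed=5)

    def test_mutated_site_carries_requested_mismatches(self):
        mirnas = {"A": MIR482_2}
        sim = simulate_cds_targets(mirnas, [(0, "A", 0, 3)], n_transcripts=1, seed=6)
        row = sim.truth.iloc[0]
        site = sim.records[0].residues[row.start : row.end]
        diffs = sum(1 for x, y in zip(site, revcomp(MIR482_2)) if x != y)
        assert diffs == 3


def test_mutate_sequence_exact_divergence():
    rng = np.random.default_rng(7)
    seq = "ACGU" * 25
    mutated = mutate_sequence(seq, 0.2, rng)
    assert sum(1 for a, b in zip(seq, mutated) if a != b) == 20
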