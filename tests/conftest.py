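"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pcevol.rna import SecondaryStructure, can_pair, default_model, energy_of_structure
from pcevol.synthetic import SynthConfig, simulate_polycistron_alignment


# ---------------------------------------------------------------------------
# brute-force folding oracle: enumerate every pseudoknot-free structure


def enumerate_pair_sets(seq: str, min_hairpin: int = 3):
    """Yield every nested set of canonical pairs for a short sequence."""

    def rec(positions):
        if not positions:
            yield []
            return
        i = positions[0]
        yield from rec(positions[1:])  # i unpaired
        for idx in range(1, len(positions)):
            j = positions[idx]
            if j - i - 1 < min_hairpin or not can_pair(seq[i], seq[j]):
                continue
            for inner in rec(positions[1:idx]):
                for outer in rec(positions[idx + 1:]):
                    yield [(i, j)] + inner + outer

    yield from rec(list(range(len(seq))))


def brute_force_mfe(seq: str, model=None):
    """Minimum energy over all structures; ties broken toward more pairs."""
    model = model or default_model()
    best_e, best_pairs = 0.0, []
    for pairs in enumerate_pair_sets(seq):
        s = SecondaryStructure.from_pairs(len(seq), pairs)
        e = energy_of_structure(seq, s, model)
        if e < best_e - 1e-9 or (abs(e - best_e) < 1e-9 and len(pairs) > len(best_pairs)):
            best_e, best_pairs = e, pairs
    return best_e, best_pairs


# ---------------------------------------------------------------------------
# jackknife standard error for region-rate recovery


def jackknife_se_of_mean(aln, interval, kind="k2p"):
    """Delete-one-taxon jackknife SE of the mean pairwise distance."""
    from pcevol.core_io import Alignment
    from pcevol.evodistance import region_substitution_table

    n = len(aln)
    estimates = []
    for drop in range(n):
        sub = Alignment([r for k, r in enumerate(aln.records) if k != drop])
        tab = region_substitution_table(sub, {"r": interval}, kind=kind)
        estimates.append(tab.rows[0].mean)
    estimates = np.asarray(estimates)
    return np.sqrt((n - 1) / n * np.sum((estimates - estimates.mean()) ** 2))


# ---------------------------------------------------------------------------
# shared simulated datasets (session-scoped: simulation is deterministic)


@pytest.fixture(scope="session")
def default_sim():
    """A 20-taxon polycistron alignment at the default study conditions."""
    return simulate_polycistron_alignment(SynthConfig(tree="star:20", seed=20))


@pytest.fixture(scope="session")
def small_sim():
    """A fast 6-taxon simulation for structural/annotation tests."""
    return simulate_polycistron_alignment(SynthConfig(tree="star:6", seed=3))
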