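"""Compensatory substitutions in simulated precursor stems.

Evolves 30 precursor sequences with strong compensatory coupling (when a
stem site mutates, its partner usually re-pairs), then counts substitutions
against the first sequence's stem structure and tests the excess of
pairing-preserving changes over the Dixon-Hillis expectations.
"""

from pcevol import compsub_report
from pcevol.synthetic import SynthConfig, simulate_polycistron_alignment

cfg = SynthConfig(
    tree="star:30",
    region_lengths=(0, 107, 0, 85, 0),
    region_rates=(0, 0.05, 0, 0.05, 0),
    coupling=0.9,
    seed=1,
)
sim = simulate_polycistron_alignment(cfg)
sub = sim.alignment.columns(sim.regions["pre482"])
rep = compsub_report(sub, sub.records[0].id, sim.structures["pre482"])
print(rep.to_frame().to_string(index=False))
print(f"single substitutions: Fisher p = {rep.p_single['fisher_p']:.2e}, "
      f"binomial p = {rep.p_single['binomial_p']:.2e}")
print("(pairing->pairing changes far exceed the 4/32 random expectation:")
print(" the stem is under selection for secondary structure)")
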