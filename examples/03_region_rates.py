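"""Region-wise substitution ratios on a simulated polycistron alignment.

Simulates 20 sequences of the five-region polycistron at the study's
region-specific rates, then estimates per-region K2P means the way the
published region table is built, and runs the Welch t-test between the
functional (precursor) and flanking regions.
"""

from pcevol import region_ratio_test, region_substitution_table
from pcevol.synthetic import SynthConfig, simulate_polycistron_alignment

cfg = SynthConfig(tree="star:20", seed=20)
sim = simulate_polycistron_alignment(cfg)
tab = region_substitution_table(sim.alignment, sim.regions)
print("region    length  K2P mean +- SD    (generating rate)")
for row, rate in zip(tab.rows, cfg.region_rates):
    print(f"{row.region:9s} {row.length:5d}  {row.mean:.4f} +- {row.sd:.4f}  ({rate})")

t, p = region_ratio_test(
    list(tab.distances["flank5"]) + list(tab.distances["flank3"]),
    list(tab.distances["pre482"]) + list(tab.distances["pre1448"]),
)
print(f"flanks vs precursors, Welch t-test: t = {t:.1f}, two-tailed p = {p:.2e}")
print("(flanking DNA evolves several-fold faster than the precursor hairpins)")
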