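"""Target gain/loss between miR482.2 and miR1448, with frameshift targeting.

Builds a synthetic transcript set mirroring the published pattern — ten
transcripts carry perfect miR482.2 sites, one of them also a miR1448 site,
and one carries a miR1448 site in a shifted codon frame — then classifies
each transcript as shared, lost or gained, labelling gains whose sites sit
in a different codon frame than the parent miRNA's targets.
"""

from pcevol import classify_gain_loss
from pcevol.synthetic import MIR1448, MIR482_2, simulate_cds_targets

mirnas = {"miR482.2": MIR482_2, "miR1448": MIR1448}
plants = (
    [(i, "miR482.2", 1, 0) for i in range(10)]
    + [(9, "miR1448", 1, 0)]          # one NBS-LRR-like target kept by both
    + [(10, "miR1448", 2, 0)]         # an ABC-transporter-like frameshift gain
)
sim = simulate_cds_targets(mirnas, plants, n_transcripts=12, seed=7)
cds = {r["transcript_id"]: (r["cds_start"], r["cds_end"]) for _, r in sim.cds.iterrows()}
rep = classify_gain_loss(MIR482_2, MIR1448, sim.records, cds)

print(f"shared targets : {sorted({h.transcript_id for h in rep.shared})}")
print(f"lost by miR1448: {sorted({h.transcript_id for h in rep.a_only})}")
for h in rep.b_only:
    print(f"gained by miR1448: {h.transcript_id} frame={h.frame} "
          f"({h.classification}; parent modal frame {rep.modal_frame_a})")
    print(f"  encoded peptide across the site: {h.peptide}")
print("(a gained site in a different codon frame is 'frameshift targeting')")
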