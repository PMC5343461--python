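"""Scan a 3' UTR for miRNA complementary sites and call the silencing mode.

Plants a site with end mismatches (positions 1 and 20) plus a seed wobble
(position 9), scores every window with the expectation penalty, and
renders the best duplex.
"""

from utreg import mirna
from utreg.simulate import SimulationSpec, simulate_utrs

MIRNA = "TGAGGTAGTAGGTTGTATAG"  # 20-nt mature miRNA, DNA alphabet

spec = SimulationSpec(n_genes=5, group_counts={}, seed=3,
                      utr_len_min=120, utr_len_max=200)
recs, truth = simulate_utrs(
    spec, "utr3", mirna=MIRNA,
    mirna_mismatch_positions=(1, 20), mirna_wobble_positions=(9,),
)

rec = recs[0]
planted = truth.mirna_sites[rec.id][0]
sites = mirna.scan_targets(MIRNA, rec, mirna_id="ath-miRx")
best = sites[0]
print(f"Best site in {rec.id}: [{best.site_start}-{best.site_end}], "
      f"expectation {best.expectation:.1f} (cap 3.0), action {best.action}")
print(f"Planted at [{planted['start']}-{planted['end']}], "
      f"expectation {planted['expectation']:.1f}, action {planted['action']}")
print()
print(mirna.render_duplex(best, MIRNA))
print()
print("Mismatch 1.0, G:U wobble 0.5, penalties doubled in the seed "
      "(positions 2-13); any non-match at positions 9-11 predicts "
      "translational inhibition instead of cleavage.")
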