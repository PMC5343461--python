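"""Detect upstream ORFs in 5' leaders and classify their Kozak context.

Plants one 30-codon uORF (strong Kozak, 30-nt leader) per synthetic 5'
UTR, scans them back, and runs the prevalence z-test on the published
foreground/background gene counts.
"""

from utreg import uorf
from utreg.simulate import SimulationSpec, simulate_utrs

spec = SimulationSpec(n_genes=100, group_counts={}, seed=2,
                      utr_len_min=150, utr_len_max=300)
recs, truth = simulate_utrs(spec, "utr5", uorf_codons=30,
                            uorf_kozak="strong", uorf_leader=30)

recovered = 0
for rec in recs:
    planted = truth.uorfs[rec.id][0]
    hits = {(u.start, u.end): u for u in uorf.scan_uorfs(rec, min_len_nt=60)}
    recovered += (planted["start"], planted["end"]) in hits

print(f"Planted uORFs recovered at exact coordinates: {recovered}/{len(recs)}")

first = truth.uorfs[recs[0].id][0]
u = next(
    u for u in uorf.scan_uorfs(recs[0], 60)
    if (u.start, u.end) == (first["start"], first["end"])
)
feats = uorf.positional_features(u, len(recs[0]))
print(f"Planted uORF in {recs[0].id}: [{u.start}-{u.end}], {u.codons} codons, "
      f"Kozak {u.kozak}, {feats['dist_from_cap']} nt of leader, "
      f"{feats['dist_to_main_orf']} nt to the main start codon")

z, p, direction = uorf.prevalence_ztest(89, 455, 6089, 19128)
print(f"\nuORF prevalence in regulated genes vs the gene universe: "
      f"z = {z:.2f}, p = {p:.2e}, direction '{direction}'")
print("The negative z means regulated genes carry uORFs *less* often than "
      "the genome-wide background — the naive enrichment hypothesis fails.")
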