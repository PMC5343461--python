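"""Compare and cluster PWMs, then match them against literature motifs.

Builds PWMs around the Pumilio (UGUA[ACU]AUA) and Bruno-like
(U[GA]U[AG]U[GA]U) elements, clusters similar matrices into averages, and
scans example heptamers with the degenerate patterns.
"""

import numpy as np

from utreg import pwm as pw

pumilio = pw.KnownMotif("pumilio", "UGUAHAUA", "Pumilio-binding element")
bruno = pw.KnownMotif("bruno", "URURURU", "Bruno-like binding element")

base = pw.pattern_to_pwm(pumilio).matrix
rng = np.random.default_rng(7)
noisy = []
for i in range(3):
    m = base + rng.uniform(0, 0.03, size=base.shape)
    m /= m.sum(axis=1, keepdims=True)
    noisy.append(pw.PWM(f"discovered_{i}", m, n_sites=10))

clusters = pw.cluster_average(noisy, min_overlap=7, rng=8)
print(f"{len(noisy)} discovered matrices -> {len(clusters)} cluster(s)")
avg = clusters[0][1]
res = pw.compare_pwms(avg, pw.pattern_to_pwm(pumilio), min_overlap=7, rng=9)
print(f"Cluster average vs Pumilio element: score {res.score:.3f}, "
      f"E = {res.evalue:.3g}, match = {res.match}")
print(f"Average information content: {pw.info_content(avg).sum():.2f} bits "
      f"over {avg.width} positions")

print("\nDegenerate-pattern scan (U rendered; internally DNA):")
for word in ("UGUGUAU", "UAUGUAU", "UGUACAUA", "UGUAGAUA"):
    hits_b = pw.iupac_scan(bruno, word)
    hits_p = pw.iupac_scan(pumilio, word)
    print(f"  {word}: bruno={'yes' if hits_b else 'no '} "
          f"pumilio={'yes' if hits_p else 'no'}")
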