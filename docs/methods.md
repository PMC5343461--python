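# Methods

This note documents the models, the defaults and why they were chosen,
the numerical choices, and what the synthetic benchmarks do and do not
show. Parameter names refer to `utreg.pipeline.RunConfig` and
`utreg.simulate.SimulationSpec`.

## Translational-efficiency classification

TE is the ratio of translatome to transcriptome FPKM, computed per
replicate pair (replicate *i* of one fraction against replicate *i* of the
other) with a pseudocount of 0.5 FPKM on both sides. The pseudocount keeps
the ratio finite at zero transcriptome FPKM while preserving ordering; at
FPKM ≫ 0.5 its effect is negligible, but for genes below ~2 FPKM it
shrinks |log₂ TE| noticeably — very low expressed genes are therefore
biased toward N labels, which is the conservative direction.

Significance uses a **moderated one-sample t-test** on replicate log₂ TE.
Gene-wise variances are squeezed toward a scaled inverse-chi-square prior
fitted by matching the moments of log s² (the limma recipe: the prior
degrees of freedom d₀ solve a trigamma equation; d₀ = ∞ when gene-wise
variances are statistically exchangeable, in which case the test is a
z-test at the pooled variance). The moderated df is d₀ + (n−1). The design
rationale: with 2–3 replicates an unpooled t-test (df ≤ 2) cannot produce
p-values small enough to clear BH correction over thousands of genes, no
matter how large the effect — group recovery saturates around 70–75%. The
moderated test restores power (≥ 99% planted-group recovery at the default
conditions) while staying calibrated under the null (fraction of null
genes at p ≤ 0.05 measured at 0.042–0.051 on 2,000 genes).

Flags require both BH q ≤ α (default 0.05, per condition across genes) and
|mean log₂ TE| ≥ `effect_floor` (default 0.5, i.e. a 1.4-fold deviation) —
the floor guards against statistically significant but biologically
trivial deviations when replication is strong.

Group assignment: Y/N label per condition; YN*/NY* take their direction
from the sign of log₂ TE in the significant condition; YY genes with
agreeing signs become YYup/YYdown; both-significant genes with opposite
signs are reported `discordant` rather than forced into a YY group; both-N
genes are `none`. The up/down rule (sign of log₂ TE in the labelled
condition) is one reading of an ambiguous verbal definition; it is the
only rule consistent with "TE significantly different from 1" determining
the labels, and it makes the condition-swap symmetry (YN ↔ NY) exact.

## uORF scanning

All ATGs are extended codon-wise to their first in-frame stop; ORFs whose
stop falls beyond the UTR are discarded (a uORF must terminate in the
leader). When several in-frame ATGs share a stop, only the 5′-most
(maximal) ORF is reported; the internal ones are counted in
`nested_starts`. Default minimum length 60 nt (20 codons including the
stop), configurable — chosen below the shortest uORF the upstream
literature reports (66 nt) so that nothing at the reported scale is
missed. Codons containing N never match ATG or a stop, so N-containing
windows cannot found or terminate an ORF.

Kozak classes partition contexts exactly: strong = purine at −3 and G at
+4 (A of ATG = +1), sub-optimal = exactly one criterion, weak = neither.
Positions outside the sequence fail their criterion. "Sub-optimal" lacks a
standard quantitative definition; exactly-one-of-two is the simplest rule
that makes the three classes a partition.

Positional features report the raw distances plus two flags: ≥ 20 nt of
leader upstream (room for cap-proximal scanning) and ≤ 20 nt from the
main start (reinitiation-coupling distance).

The prevalence test is a pooled two-proportion z-test (two-sided); its
squared statistic equals the 1-df chi-square on the 2×2 table without
continuity correction, which the tests verify to 1e-9. A degenerate pooled
proportion (0 or 1) returns p = 1 with a warning rather than NaN.

## miRNA target scoring

Ungapped windows only: every described duplex defect in the motivating
data is a mismatch or wobble, not an indel, and ungapped scoring keeps the
site the exact length of the miRNA. (A gap-tolerant mode would be an
extension; it is not implemented.) The penalty scheme — mismatch 1.0, G:U
wobble 0.5, penalties ×2 at miRNA positions 2–13 — is the plant
target-prediction convention; the cap (3.0), duplex length (20) and
central window (9–11) are exposed in `ScoringConfig`. Note the scoring
seed (2–13) is deliberately distinct from the recognition seed sometimes
quoted as 2–11; both are configuration.

Wobble detection is orientation-aware (miRNA G : target U, or miRNA U :
target G). Windows containing N are skipped. The accessibility (UPE)
threshold of 25.0 used by energy-based servers is recorded in the config
for provenance but never evaluated — computing it needs an RNA folding
engine and all sites here pass unconditionally; predicted site lists are
therefore a superset of what an accessibility-filtered server would
return.

## Seed enrichment

The statistic for seed *s* in a subgroup of *m* sequences is
S = Σᵢ dᵢ(s), the sum of per-sequence minimum Hamming distances. The
background model stores, for each seed, the empirical pmf of d on a large
background sequence set; the null of S is the exact m-fold convolution of
that pmf (computed by exponentiation-by-squaring of `np.convolve`, so even
m in the hundreds is cheap), and p = P(S_null ≤ S) exactly — no sampling.
Empirical pmfs can put zero mass below an observed score; p-values are
floored at 1e-300 to stay strictly positive.

BH correction is applied within a subgroup, across all seeds scored there
(4^6 = 4,096 for 6-mers; for 8-mers the seed universe is restricted to
seeds observed exactly in the foreground plus their 1-mismatch
neighborhood, keeping 4^8 tractable — a full-enumeration mode exists and
is exercised in tests). Aggregation across subgroups keeps each seed's
minimum q and counts the subgroups where it passed; the multiple-testing
universe (per subgroup) is recorded in output metadata via the run
manifest. Sequences shorter than k are excluded from both foreground and
background. Subgroups are drawn without replacement within a subgroup and
independently across subgroups (500 × 10 by default); sets smaller than
the subgroup size fall back to the whole set with a warning.

Enriched seeds are extended to k-wide PWMs from each subgroup sequence's
best-match window (leftmost tie-break), pseudocount 0.25 per cell.

## PWM comparison and clustering

Similarity is the mean per-column Pearson correlation over the best
offset/orientation with ≥ `min_overlap` (default 7) aligned columns,
orientations forward and reverse complement. Zero-variance columns
(exactly uniform) compare as 1 when equal, else 0. The p-value is a
permutation tail: column sets of the matched overlap are drawn from a
background column pool (Dirichlet(1,1,1,1) by default, or caller-supplied)
and E = p × (number of candidate offset/orientation pairs); match iff
E ≤ 0.05. Mean column correlation with a permutation E-value is a simple,
transparent comparison statistic in the family of motif-comparison tools
(Tomtom and kin); the downstream clustering only consumes the binary match
relation, which is made symmetric by seeding the null identically for both
argument orders and sharing one column pool.

Clustering is single linkage on the match relation; each cluster is
averaged by aligning members to the widest member at their best
offset/orientation, averaging probabilities position-wise over covering
members, and renormalizing. Singletons pass through unchanged. Known-motif
matching renders a degenerate IUPAC pattern as an indicator-style PWM
(allowed bases share the mass; pseudocount 0.01) and reuses the same
comparison.

`scan_pwm` scores log₂-odds against a uniform background with a 1e-6
probability floor (indicator matrices would otherwise produce −∞); the
threshold is a fraction of the maximum achievable score.

## Synthetic data

The generators emit exactly the formats the pipeline reads, with a
ground-truth manifest. Defaults encode the emulated study design: six
planted groups of (65, 58, 90, 265, 12, 24) genes — 514 regulated genes —
inside a 2,000-gene universe, 3 replicates, |log₂ TE| effect 2.0,
dispersion 0.05.

FPKM is simulated directly rather than via read counts: transcriptome
means are log-uniform on [10, 1000] FPKM, translatome means multiply in
the planted effect, and replicates are gamma-scaled negative-binomial
counts at an internal depth factor of 100 counts/FPKM, rescaled back. The
**dispersion parameter is defined as the replicate-level dispersion of the
TE ratio**; each fraction carries half the variance budget, so dispersion
0.05 gives replicate log₂ TE with σ ≈ 0.32. The depth factor and
expression range are set so shot noise stays small against the
overdispersion across the whole expression range; they are not meant to
model a specific sequencing depth.

UTR sequences are i.i.d. nucleotides at GC 0.35 (plant-UTR-like AT
richness). Planted elements (IUPAC motif concretizations, uORFs with
constructed Kozak contexts, miRNA complementary sites with chosen
mismatch/wobble positions) are substituted at recorded, non-overlapping
positions. After planting a uORF, chance upstream in-frame ATGs that would
reach the planted stop are rewritten (they would make the planted ORF
non-maximal), and the Kozak bases are re-asserted afterwards — planting an
A at −3 can itself spell an upstream ATG, in which case the −2 base is
set to C, which cannot complete any ATG. Wobble positions must fall on a
G or U of the miRNA; requesting one elsewhere is an error rather than a
silent mismatch.

What the synthetic data does **not** emulate: real UTR composition (codon
structure, repeats, Markov dependence), expression-dependent dispersion
trends, correlated replicates, multiple regulatory elements interacting in
one UTR, or miRNA families. Passing benchmarks therefore demonstrate
algorithmic correctness and statistical calibration under the stated
model, not performance on real Arabidopsis data.

## Problem sizes and determinism

The shipped benchmarks and the acceptance script run at desk scale chosen
to keep the whole suite in a couple of minutes on one core: background
sets of 1,000 × 150-nt sequences, 100 subgroups of 10, 2,000-gene
expression tables, 200-sequence scanner-oracle sweeps, Monte-Carlo checks
at 200,000 draws. The production defaults (500 subgroups, genome-scale
backgrounds) are the configured values in `RunConfig` and scale linearly.
Every stochastic component takes an explicit seed (`numpy.random.
default_rng`); full runs are byte-reproducible, and the run manifest
records every threshold and seed used.

## Known limitations

- The TE test assumes log₂ TE is approximately normal across replicates;
  heavy-tailed FPKM noise at very low expression violates this and is only
  partly absorbed by the pseudocount.
- uORF detection is strictly ATG-initiated; near-cognate starts (CUG/GUG)
  are not scanned.
- The enrichment null treats background sequences as exchangeable with
  foreground sequences in everything but motif content; strong
  length or composition mismatch between foreground and background will
  miscalibrate p-values (match their length distributions when building
  backgrounds).
- PWM comparison against a Dirichlet column pool is a generic null; a
  pool built from actually-discovered motif columns is supported and
  preferable when many motifs are available.
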