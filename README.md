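# utreg

Classification of translationally regulated genes and discovery of the
regulatory elements in their untranslated regions — upstream ORFs, plant
miRNA target sites, and de novo sequence motifs.

## Who this is for

Groups with paired transcriptome/translatome RNA-seq (e.g. ribosome-tagged
affinity purification in *Arabidopsis*) who want to ask, end to end: which
genes are regulated at the level of translation rather than transcription,
and what sequence features in their 5′ and 3′ UTRs might be responsible?

## The model

**Translational efficiency.** For gene *g* in condition *c*,

    TE_gc = (translatome FPKM + ε) / (transcriptome FPKM + ε),   ε = 0.5

Under purely transcriptional control TE ≈ 1. Replicate log₂ TE is tested
against 0 with a moderated one-sample t-test (empirical-Bayes variance
squeeze across genes), BH-corrected per condition, with an effect floor
|log₂ TE| ≥ 0.5. A gene is labelled Y (significant deviation) or N per
condition, and the label pair plus the deviation's sign yields six groups:
YNup/YNdown (treated only), NYup/NYdown (control only), YYup/YYdown (both,
concordant); opposite-sign YY genes are reported as `discordant`.

**uORFs.** Every ATG in a 5′ UTR is extended to its first in-frame stop;
maximal ORFs ≥ 60 nt that terminate inside the leader are reported with
their Kozak context (strong: purine at −3 *and* G at +4; sub-optimal:
exactly one; weak: neither) and positional features. A two-proportion
pooled z-test compares uORF prevalence against a background gene universe.

**miRNA target sites.** Each UTR window the length of the miRNA is paired
antiparallel against it; the expectation score sums penalties (mismatch
1.0, G:U wobble 0.5, doubled at miRNA positions 2–13) and sites with
expectation ≤ 3.0 are reported. Perfect pairing at positions 9–11 predicts
cleavage; any central defect predicts translational inhibition.

**Seed enrichment.** A 6/8-mer's score against a sequence is its minimum
Hamming distance to any window. On a genome-scale background set each seed
gets an empirical distance distribution; for a resampled subgroup of *m*
foreground sequences the null of the summed score is the exact *m*-fold
convolution of that distribution, giving exact left-tail p-values,
BH-corrected within each subgroup (reported at Q ≤ 0.05). Enriched seeds
are extended to PWMs, clustered by mean-column-correlation matching
(E ≤ 0.05, overlap ≥ 7, permutation null) into averaged matrices, and
matched against known motifs given as degenerate IUPAC patterns.

## Worked example

```bash
python examples/discover_motifs.py
```

```
Enriched seeds (q <= 0.05): 28
  TGTGTA: best q = 3.27e-10, significant in 100/100 subgroups
  GTGTAC: best q = 4.71e-07, significant in 57/100 subgroups
  ...
Planted seed TGTGTA detected in 100/100 subgroups.
```

The planted 6-mer is recovered in every subgroup with a q-value far below
the 0.05 threshold; the trailing hits are its shifted overlaps, which
share most of their windows with the planted word and are collapsed by the
downstream PWM clustering step. The other scripts in `examples/` each
demonstrate one capability (TE classification, uORF scanning, miRNA target
calls, known-motif matching) the same way: build a small synthetic input
with known ground truth, run the method, print what comes back.

A full pipeline run over files is available both from Python
(`utreg.pipeline.run_pipeline`) and from the shell:

```bash
utreg simulate --outdir demo           # synthetic input bundle
utreg run-all --outdir demo_out ...    # classify → scan → discover → report
```

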