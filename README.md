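# gcscore

Probe-level differential expression for Affymetrix/Thermo-Fisher
oligonucleotide microarrays.

Summarization pipelines (RMA and relatives) collapse the many probes of a
probeset into one expression value before testing. This package instead
compares two arrays **probe by probe** and turns each probeset's summed,
error-weighted intensity differences into a z-score-like statistic — the
GCS-score — recovering the statistical power of having 4–10 oligonucleotides
per transcript. It supports the whole-transcriptome array generations
(ClariomS, ClariomD/XTA: HTA/MTA/RTA), where non-specific binding is
estimated from GC-content-matched antigenomic background probes, and the
older 3′ IVT generation, where paired mismatch (MM) probes play that role.
Probes can be grouped at gene level (transcript clusters, TC) or exon level
(probe selection regions, PSR, and exon–exon junctions, JUC) for splicing
analysis. It is aimed at anyone analysing Clariom-style CEL data with small
replicate numbers, where probe-level testing is most valuable.

## The statistic

For arrays A and B, each is scaled so the median intensity of the
grouping-level probes reaches a target (SF; default target 500), the noise
floor `rawQ` is the standard deviation of the bottom 2% of probe
intensities, and the significant difference threshold is

```
SDT = 4 · rawQ · SF
```

Per PM probe *i*, the background-corrected intensity is
`l_i = SF·PM_i − median(background at the probe's GC count)` (GC method) or
`l_i = SF·(PM_i − MM_i)` (PM−MM method). For a probeset *k* of *N* probes:

```
GCSs_k = Σ_i (l_iB − l_iA) / (ε_i · √N),
ε_i    = sqrt(γ²·(l_iA² + l_iB²) + SDT_A² + SDT_B²),   γ = 0.1
```

The γ term caps the influence of strongly expressed probes, so the score
measures relative change rather than absolute intensity. Raw scores are
centred and scaled on the middle 98% of their distribution; with no extreme
differential expression the output is approximately standard normal, so
|score| ≳ 1.8–2 flags likely change.

For replicated designs (T treatments vs C controls) all T·C pairs are
scored, scores are averaged per treatment replicate, the grand mean AvgSs
serves as an effect-size filter (|AvgSs| > 1.8), and a one-class SAM
permutation test (sign-flip null, s0 fudge factor, q-values) controls the
FDR of "mean score ≠ 0".

## Worked example

`examples/01_score_a_pair.py` simulates a 2,000-probeset chip with 2% of
probesets changed two-fold and scores one treatment against one control:

```
chip: 20575 probes, 2000 probesets
ctrl1: SF=1.2883 rawQ=13.039 SDT=67.20
treat1: SF=1.2919 rawQ=12.896 SDT=66.64
null probesets:  mean=+0.011 SD=0.941  (should be ~0 / ~1)
DE probesets:    mean |score| = 10.97 (two-fold changes push |score| well past the ~1.8 threshold)
```

Unchanged probesets score like standard-normal draws; the two-fold changes
stand out by an order of magnitude. `examples/02_replicated_workflow.py`
runs the full 3v3 workflow (replicate averaging, SAM, selection) and
`examples/03_command_line.sh` does the same from the shell via the
`gcscore` CLI (`simulate`, `makechip`, `score`, `batch`, `sam`
subcommands).

Input formats are deliberately open: a three-table TSV chip bundle
(probes / probesets / probe-to-probeset mapping), per-array intensities as
two-column TSV or plain-text version-3 CEL files, and a CSV comparison
design (`sample_id, path, group`). Binary Calvin CEL files are detected and
rejected with advice to convert externally.

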