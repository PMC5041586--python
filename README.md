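# qkat

Integer copy-number typing for multi-copy immune gene families (KIR, LILR)
from multiplex real-time qPCR Cq data, with resolution of unphased per-locus
copy numbers into gene-content haplotype pairs.

The KIR cluster (chromosome 19q13.4) is highly copy-number variable:
non-allelic homologous recombination generates haplotypes with deleted,
duplicated and fused genes, so presence/absence typing misses real structural
diversity. This package implements the analysis side of quantitative KIR
typing for people running (or modelling) such assays: it turns raw
quantification-cycle (Cq) exports into QC-flagged integer copy-number calls,
checks them against gene-content consistency rules, and imputes haplotype
pairs from a frequency-annotated haplotype library. A synthetic-data module
generates realistic quadruplicate 384-well Cq plates from haplotype-sampled
genotypes, so the full stack runs and is testable with no instrument.

## The model

In real-time PCR the quantification cycle is log-linear in starting template.
Within one multiplex well, the target and an endogenous two-copy reference
gene (STAT6) amplify together, so

```
ΔCq = Cq_target − Cq_reference
```

cancels the DNA-input term. Comparing a test sample with a calibrator of
known copy number `n_cal` gives, at perfect efficiency,

```
ΔΔCq = mean ΔCq_sample − mean ΔCq_calibrator
CN    = n_cal · 2^(−ΔΔCq)
```

which is rounded to the nearest integer (the *predicted* copy number). The
separation between adjacent clusters on the ΔΔCq scale is `log2((n+1)/n)` —
exactly 1 cycle between 1 and 2 copies (a 2× ratio), `log2 1.5 ≈ 0.585`
between 2 and 3 (1.5×) — so cluster standard deviations must stay below
`log2((n+1)/n)/6` (≈ 0.167 for 1 vs 2) to separate adjacent copy numbers in
more than 99.6 % of samples, or below `/4` (0.25) for the 95 % tier.

Replicate QC before calling: replicates with reference Cq > 32 are dropped,
a replicate more than 4 SD from its peers (leave-one-out) is dropped as an
outlier, and zero copies are assigned when the target exceeds Cq 35 while
the reference is sound. Each call carries a confidence (posterior mass of
the assigned integer under a Gaussian mixture on integer copy numbers) and
an absolute z-score against its cluster. Genes typed by two assays
(KIR3DL1, KIR3DL2) are cross-checked: discordance flags a rare-allele
dropout (`PAIR_DISCORDANT`); 2DS4 totals must equal full-length + deletion
variants; framework genes (3DL3, 3DP1, 2DL4, 3DL2) are expected at two
copies unless a known co-duplication/deletion group moved together.

Haplotype-pair resolution renders a genotype as a concatenated *markersig*
string (e.g. `211`) and a per-locus regular expression (`(2|1|0)(1|0)(1|0)`),
matches it against library signatures, subtracts each match from the
genotype, and keeps pairs whose residual is itself a library haplotype —
ranked by combined frequency (f₁ × f₂).

## Worked example

```
$ python examples/03_haplotype_pairs.py
genotype (2, 1, 1): markersig '211', regex '(2|1|0)(1|0)(1|0)'
  pair ('h1', 'h2'): combined frequency 0.12000
  pair ('h3', 'null'): combined frequency 0.00005

KIR genotype 21112222111100112: RESOLVED, 8 candidate pairs
best pair: ('cA01', 'cB01') (combined frequency 0.0927)
```

The toy genotype (2, 1, 1) admits two decompositions; the pair of common
haplotypes h1 + h2 (0.4 × 0.3 = 0.12) outranks the rare h3 + null pair. The
real 17-locus genotype below it, built from one group-A and one group-B KIR
haplotype, resolves to 8 candidate pairs, with the true pair ranked first by
combined frequency.

```
$ qkat end-to-end --out run --samples 6 --seed 5
...
genotype recovery: 6/6 samples exact
```

simulates six samples on the bundled 20-marker panel (40 wells each, three
controls per plate), calls copy numbers against the control calibrators,
resolves haplotype pairs, and confirms every genotype round-tripped exactly.
Other examples: `01_panel_and_plates.py` (plate planning), `02_copy_number_
calling.py` (calling + cluster dispersion tiers), `04_allele_dropout.py`
(paired-assay dropout detection), `05_end_to_end.py` (library-level
pipeline).

## Files and formats

* **Cq export CSV** `plate,well,sample,reaction,replicate,channel,cq` — one
  row per well and channel; blank/`-`/`>40` cells mean no amplification.
* **Panel YAML** — markers (id, gene, channel, reference flag), reactions
  (targets + reference), paired assays and sum rules; see
  `src/qkat/data/kir_panel.yaml`.
* **Haplotype library CSV** — `haplotype_id,signature,count,frequency,
  cen_motif,tel_motif` with hyphen-delimited signatures and a
  `# marker_order:` header. The bundled library is a synthetic
  European-origin-style fixture; supply your own when analysing a different
  population.
* **Outputs** — a copy-number table (calculated/predicted CN, confidence,
  z-score, QC flags), a cluster-dispersion report with discrimination tiers,
  and three haplotype files: all candidate pairs, best pairs only, and a log
  of unresolved samples with their single-haplotype matches.
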