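# Full KIR copy-number panel: 20 target markers over the KIR genes and
# their important variants, typed in ten triplex reactions against the
# endogenous reference gene STAT6 (fixed at two copies per diploid genome),
# in quadruplicate.  21 marker assays = 21 primer pairs.
#
# KIR3DL1 and KIR3DL2 are each interrogated by two assays targeting
# different regions of the gene (fusion-gene / allele-dropout detection);
# 2DS4 has separate assays for the gene total, the full-length variant (FL)
# and the deletion variant (del), linked by a sum rule.
#
# The pairing of targets into reactions below is a fixed, documented
# convention of this package, not the published bench pairing.
name: qkat-kir
reference_copy_number: 2
replicates: 4
markers:
  - {id: 3DL3,    gene: 3DL3,    region: exon 4,  channel: FAM}
  - {id: 2DS2,    gene: 2DS2,    region: exon 4,  channel: Orange}
  - {id: 2DL2,    gene: 2DL2,    region: exon 5,  channel: FAM}
  - {id: 2DL3,    gene: 2DL3,    region: exon 5,  channel: Orange}
  - {id: 2DP1,    gene: 2DP1,    region: exon 4,  channel: FAM}
  - {id: 2DL1,    gene: 2DL1,    region: exon 5,  channel: Orange}
  - {id: 3DP1,    gene: 3DP1,    region: exon 2,  channel: FAM}
  - {id: 2DL4,    gene: 2DL4,    region: exon 7,  channel: Orange}
  - {id: 3DL1e4,  gene: 3DL1,    region: exon 4,  channel: FAM}
  - {id: 3DS1,    gene: 3DS1,    region: exon 4,  channel: Orange}
  - {id: 3DL1e9,  gene: 3DL1,    region: exon 9,  channel: FAM}
  - {id: 2DL5,    gene: 2DL5,    region: exon 4,  channel: Orange}
  - {id: 2DS3,    gene: 2DS3,    region: exon 4,  channel: FAM}
  - {id: 2DS5,    gene: 2DS5,    region: exon 4,  channel: Orange}
  - {id: 2DS4FL,  gene: 2DS4FL,  region: exon 5 (full length), channel: FAM}
  - {id: 2DS4del, gene: 2DS4del, region: exon 5 (22 bp deletion), channel: Orange}
  - {id: 2DS4,    gene: 2DS4,    region: exon 4 (gene total), channel: FAM}
  - {id: 2DS1,    gene: 2DS1,    region: exon 4,  channel: Orange}
  - {id: 3DL2e4,  gene: 3DL2,    region: exon 4,  channel: FAM}
  - {id: 3DL2e9,  gene: 3DL2,    region: exon 9,  channel: Orange}
  - {id: STAT6,   gene: STAT6,   region: exon 1,  channel: Cy5, reference: true}
reactions:
  - {id: R01, targets: [3DL3, 2DS2],      reference: STAT6}
  - {id: R02, targets: [2DL2, 2DL3],      reference: STAT6}
  - {id: R03, targets: [2DP1, 2DL1],      reference: STAT6}
  - {id: R04, targets: [3DP1, 2DL4],      reference: STAT6}
  - {id: R05, targets: [3DL1e4, 3DS1],    reference: STAT6}
  - {id: R06, targets: [3DL1e9, 2DL5],    reference: STAT6}
  - {id: R07, targets: [2DS3, 2DS5],      reference: STAT6}
  - {id: R08, targets: [2DS4FL, 2DS4del], reference: STAT6}
  - {id: R09, targets: [2DS4, 2DS1],      reference: STAT6}
  - {id: R10, targets: [3DL2e4, 3DL2e9],  reference: STAT6}
paired_assays:
  - [3DL1e4, 3DL1e9]
  - [3DL2e4, 3DL2e9]
sum_rules:
  - {total: 2DS4, components: [2DS4FL, 2DS4del]}
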