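# Default gene-content consistency rules for KIR genotypes.
#
# Framework genes sit on essentially every haplotype and are expected at
# two copies per diploid genome.  Co-variation groups are loci known to be
# duplicated or deleted together on structural-variant haplotypes: when all
# members of a group moved together, a framework gene inside the group is
# not flagged.  The 3DL1/S1 locus total is the sum of the 3DL1 and 3DS1
# gene copy numbers (allelic at one locus).
# All entries are user-overridable.
framework_genes:
  3DL3: 2
  3DP1: 2
  2DL4: 2
  3DL2: 2
covariation_groups:
  - [3DP1, 2DL4, 3DL1/S1]
locus_totals:
  3DL1/S1: [3DL1, 3DS1]
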