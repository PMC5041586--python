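# Methods

## Relative-quantification model

The caller implements the comparative-Cq (ΔΔCq) method for genomic copy
number. Within a multiplex well, ΔCq = Cq(target) − Cq(reference) removes
the DNA-input term because both assays share the tube; between wells, the
per-sample concentration offset therefore cancels by construction, which is
why the simulator's concentration noise does not propagate into calls.
Against a calibrator with known copy number `n_cal`,

    CN = n_cal · 2^(−ΔΔCq),   ΔΔCq = mean ΔCq(sample) − mean ΔCq(calibrator)

assuming perfect doubling per cycle. Efficiency-corrected mode replaces the
base 2 with per-assay bases (1 + E): when target and reference efficiencies
coincide the ratio is computed as `(1+E)^(−ΔΔCq)` on the same ΔΔCq value
(so E = 1 is bit-identical to the uncorrected path); when they differ, the
two-base form `(1+E_t)^{ΔCq_t,cal→s} / (1+E_r)^{ΔCq_r,cal→s}` is used,
which requires per-assay Cq means and therefore a physical calibrator.
Uncorrected mode is the default: with well-quantified DNA input and
near-unit efficiencies the correction changes calls negligibly, and
efficiencies are user-supplied inputs, not estimated here.

## Replicate QC

Per sample × marker, over (by default) four replicate wells:

1. **Reference failure** — replicates whose reference assay does not amplify
   (`REF_FAIL`) or crosses threshold after 32 cycles (`REF_CQ_HIGH`) are
   removed: the well contains too little or degraded DNA to interpret.
2. **Zero call** — a target later than Cq 35 (or non-amplifying) while the
   reference is sound marks the replicate as a zero candidate. If every
   surviving replicate is a zero candidate the marker is called 0 copies
   (`ZERO_CALL`), bypassing the exponential arithmetic entirely; isolated
   zero candidates in an otherwise amplifying set are dropped from the mean
   (`ZERO_CANDIDATE`).
3. **Outlier removal** — a surviving replicate whose ΔCq lies more than 4 SD
   from the rest is removed (`OUTLIER_REMOVED`). The rule is evaluated
   leave-one-out: with the extreme point included in the statistics, the
   largest attainable deviation in a quadruplicate is about 1.5 SD, so an
   inclusive 4-SD rule could never fire. An inclusive mode is available as a
   switch (`leave_one_out=False`) for comparison. With fewer than three
   finite replicates the outlier step is skipped. Whether the original
   procedure used inclusive or leave-one-out statistics is not documented;
   leave-one-out is the choice that makes the rule operative.

All replicates removed yields `TOO_FEW_REPLICATES` and no call.

## Rounding, confidence and z-score

Calculated copy numbers are rounded to the **nearest** integer, ties away
from zero. The phrase "rounded up" in assay descriptions is read as
round-to-nearest: ceiling would systematically call 2.1 as 3 and could not
reproduce concordant validation against integer truth. A ceiling mode is
deliberately not offered.

Cluster statistics (mean, SD with n−1 denominator, n) are computed per
marker over samples sharing an assigned copy number, on the calculated
copy-number scale — the scale on which calls cluster around integers (the
monotone transform `n_cal·2^(−ΔΔCq)` of the ΔΔCq scale). The absolute
z-score of a call is its distance from its own cluster's mean in cluster
SDs; SD = 0 with a nonzero deviation reports infinite z and a flag, and
singleton clusters report the z as undefined (`SD_UNDEFINED`).

The confidence metric is defined here (the original software's formula is
proprietary) as the posterior mass of the assigned integer under an
equal-prior Gaussian mixture whose components sit at the integer copy
numbers with the marker's pooled within-cluster SD. A call halfway between
two well-separated clusters scores ≈ 0.5 by symmetry. This is a
reimplementation choice, not a claim of identity with any vendor metric.

## Discrimination tiers

Adjacent copy numbers n and n+1 are separated by `log2((n+1)/n)` cycles on
the ΔΔCq scale. Fitting k standard deviations inside one separation bounds
the usable cluster SD at `log2((n+1)/n)/k`: k = 6 gives the >99.6 % tier
(0.167 between 1 and 2 copies), k = 4 the >95 % tier (0.25). The bound
shrinks with copy number, which is why discrimination beyond 4–5 copies
becomes qualitative. Separation from 0 copies is excluded: absence is
detected by non-amplification, not by a ΔΔCq distance.

## Calibration modes

* **Known sample** — a sample of known per-marker copy number anchors ΔΔCq.
* **Controls** — several known controls are merged, preferring the control
  whose copy number at a marker is closest to 2 (markers at 0 copies in a
  control carry no anchor). The bundled trio (group-A homozygote, group-B
  compound, A/B heterozygote) jointly covers every panel marker at ≥ 1 copy.
* **Cohort mode** — with no calibrator, each marker is anchored on the
  densest 1-D cluster of per-sample mean ΔCq values (densest window of
  0.5 cycles — half the widest cluster separation), assigned the
  user-supplied expected modal copy number. Ties between equally dense,
  well-separated clusters are broken toward the lower-ΔCq (higher-copy)
  cluster and flagged `AMBIGUOUS_MODE`; fewer than 10 samples flags `LOW_N`.

## Consistency rules

Paired assays (two assays on the same gene: KIR3DL1 exon 4/9, KIR3DL2) must
agree; disagreement flags `PAIR_DISCORDANT` on both rows and blocks haplotype
inference for the sample, since the genotype vector is then ambiguous — this
is the designed detection path for rare-allele dropout. Sum rules (2DS4
total = FL + del) flag `RULE_VIOLATION` on all involved rows. Gene-content
rules (configurable YAML; defaults bundled): framework genes 3DL3, 3DP1,
2DL4 and 3DL2 at two copies, with the co-variation group {3DP1, 2DL4,
3DL1/S1 locus total} exempting coherent co-duplications/deletions. These are
screens for follow-up, not hard errors.

## Haplotype-pair resolution

A genotype over the library's marker order is rendered as the markersig
string and a per-locus regex enumerating every value one haplotype could
carry (observed total down to 0). Regex matching against signature strings
is exactly the element-wise ≤ test (property-tested); matched candidates are
subtracted from the genotype and a pair is emitted when the residual is
itself a library signature. Both members of a pair must exist in the
library; the combined frequency f₁ × f₂ is a ranking score, not a genotype
probability (no Hardy–Weinberg 2pq factor — the original ranking is the
plain product, and self-pairs score f²). Ties for best pair are all kept.
Unordered pairs are emitted once. Copy numbers above 9 use a hyphen-
delimited canonical form internally; the undelimited digit form is only
rendered when all values ≤ 9. Unresolvable samples are logged with their
single-haplotype matches. The trio filter keeps a child pair only if one
haplotype occurs in some paternal and the other in some maternal candidate
pair — a Mendelian consistency screen, not full segregation analysis.

## Synthetic-data generator

The generator emulates the study conditions of a validated quadruplicate
384-well run:

* genotypes: two haplotypes drawn i.i.d. ∝ frequency from the library
  (random mating); ground truth retained per sample;
* Cq model: `Cq = base − (log2(cn/2) + conc)/log2(1+E) + ε` with per-marker
  base Cq (defaults 24 target / 22 reference — plausible values for 5 ng
  genomic input; real per-assay baselines are instrument- and lot-specific
  and are configurable), per-sample log2-concentration offset `conc ~
  N(0, 0.5)` and per-channel noise `ε ~ N(0, σ_ΔCq/√2)` so replicate ΔCq has
  SD σ_ΔCq = 0.15 cycles by default, inside the 0.167 tier of a validated
  assay. Noise is Gaussian on the Cq scale, the standard qPCR assumption.
* zeros: cn = 0 does not amplify; a `leaky_zero` option emits late finite
  Cq (37–40) to exercise the Cq > 35 zero rule;
* allele dropout: a (sample, marker) event hides one chromosome's copy from
  that single assay (cn → cn − 1 there), reproducing the one-copy-lower
  discordance of a SNP under a probe; at cn = 1 the assay goes dark
  entirely;
* seeding: one master seed spawns per-plate child streams; identical seeds
  give byte-identical exports.

What the generator does **not** model: fluorescence curves and Cq-calling
artefacts, PCR inhibitors, pipetting failures beyond Gaussian noise,
cross-channel bleed, or linkage between library frequencies and real
population structure. Passing tests therefore demonstrate the correctness
of the calling and resolution logic under the stated noise model, not the
wet-lab performance of any assay.

## Bundled fixtures

The 20-marker/10-reaction panel mirrors the published KIR design counts;
the pairing of targets into reactions is a fixed convention of this package
(the bench pairing is not public). The haplotype library is synthetic: its
ped1416_* entries emulate eight pedigree-deduced haplotypes including the
3DP1/2DL4/3DL1-S1 duplication carrier, plus common group-A/B signatures and
a 3DL1→3DL2 deletion haplotype; counts and frequencies are documented
placeholders. Analyses of real cohorts should supply population-matched
libraries.

## Problem sizes in the test suite

The suite simulates cohorts of 24–40 samples on the full panel and up to
2000 samples on a minimal duplex panel for the miscall-rate check, 10 000
replicate draws for noise-convergence, and 1000 random instances for the
pair-enumeration oracle — sizes chosen to make the statistical assertions
stable at fixed seeds while keeping the suite fast on a laptop.
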