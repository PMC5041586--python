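"""Integer copy-number calling from replicate Cq data (comparative ΔΔCq).

The comparative-Cq model: within one multiplex well, ΔCq = Cq(target) −
Cq(reference) cancels the DNA-input term; between a test sample and a
calibrator of known copy number, ΔΔCq = mean ΔCq(sample) − mean
ΔCq(calibrator), and at perfect amplification efficiency the copy number is

    CN = CN(calibrator) x 2^(−ΔΔCq).

Quality control before calling, per replicate set:

* replicates whose reference assay fails to amplify, or crosses threshold
  later than 32 cycles, are removed (too little/degraded DNA);
* zero copies are assigned when the target assay's Cq exceeds 35 cycles (or
  does not amplify) while the reference is sound — the target is absent, not
  merely dilute;
* a surviving replicate whose ΔCq lies more than 4 standard deviations from
  the other replicates is removed as an outlier.  The 4-SD rule is evaluated
  leave-one-out by default: an extreme replicate inflates an SD that
  includes it and could otherwise never reach 4 SD in a quadruplicate.

Calculated copy numbers are rounded to the nearest integer (ties away from
zero) to give the predicted copy number, and annotated with a confidence
(posterior mass of the assigned integer under an equal-prior Gaussian
mixture centred on the integer copy numbers) and an absolute z-score
against the cluster of samples assigned the same copy number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .io import NO_AMPLIFICATION, CqValue, WellRecord
from .panel import Panel

logger = logging.getLogger(__name__)

REF_CQ_MAX = 32.0
ZERO_TARGET_CQ = 35.0
OUTLIER_K = 4.0


class CallingError(ValueError):
    pass


class ReferenceFailure(CallingError):
    """The reference assay of a well did not amplify; the well is uninterpretable."""


# ---------------------------------------------------------------------------
# theoretical separations


def ddcq_separation(cn_low: int) -> float:
    """ΔΔCq distance between adjacent copy-number clusters cn_low and cn_low+1.

    log2((n+1)/n): 1 cycle between 1 and 2 copies, log2(1.5) ≈ 0.585 between
    2 and 3 — separations narrow as copy number grows.
    """
    if cn_low < 1:
        raise ValueError("separation from 0 copies is qualitative, not a ΔΔCq distance")
    return math.log2((cn_low + 1) / cn_low)


def copy_ratio(cn_from: int, cn_to: int) -> float:
    """Fold change between two copy-number states (2x for 1→2, 1.5x for 2→3)."""
    if cn_from < 1 or cn_to < 1:
        raise ValueError("fold change needs positive copy numbers")
    return cn_to / cn_from


def discrimination_threshold(cn_low: int, k: int) -> float:
    """Maximal cluster SD leaving k standard deviations within one separation.

    k=6 is the >99.6 % discrimination tier (0.167 between 1 and 2 copies),
    k=4 the >95 % tier (0.25): adjacent clusters are distinguishable when
    each sits within k/2 SD of its centre.
    """
    if k < 1:
        raise ValueError("k must be a positive number of standard deviations")
    return ddcq_separation(cn_low) / k


# ---------------------------------------------------------------------------
# per-well / per-replicate operations


def delta_cq(well: WellRecord, marker_id: str, reference_marker: str) -> float:
    """Cq(target) − Cq(reference) for one well.

    A non-amplifying target returns +inf (a zero-copy candidate); a
    non-amplifying reference raises :class:`ReferenceFailure`.
    """
    cq_t = well.cq_by_marker[marker_id]
    cq_r = well.cq_by_marker[reference_marker]
    if cq_r is NO_AMPLIFICATION:
        raise ReferenceFailure(f"reference {reference_marker} failed in well {well.well}")
    if cq_t is NO_AMPLIFICATION:
        return math.inf
    return float(cq_t) - float(cq_r)


@dataclass
class DeltaCqSet:
    """QC-filtered replicate ΔCq values for one sample x marker."""

    sample_id: str
    marker_id: str
    replicate_delta_cq: list[float]
    replicate_ref_cq: list[float]
    mean_delta_cq: float | None
    mean_ref_cq: float | None
    mean_target_cq: float | None
    n_used: int
    zero_call: bool
    flags: set[str] = field(default_factory=set)


def qc_filter(
    replicates: Sequence[tuple[CqValue, CqValue]],
    sample_id: str = "",
    marker_id: str = "",
    *,
    ref_cq_max: float = REF_CQ_MAX,
    zero_target_cq: float = ZERO_TARGET_CQ,
    outlier_k: float = OUTLIER_K,
    leave_one_out: bool = True,
) -> DeltaCqSet:
    """Apply the replicate QC rules and return the surviving ΔCq set.

    ``replicates`` is a list of (Cq_target, Cq_reference) per replicate well;
    either value may be NO_AMPLIFICATION.
    """
    if not replicates:
        raise CallingError("qc_filter needs at least one replicate")
    flags: set[str] = set()

    survivors: list[tuple[CqValue, float]] = []
    for cq_t, cq_r in replicates:
        if cq_r is NO_AMPLIFICATION:
            flags.add("REF_FAIL")
            continue
        if float(cq_r) > ref_cq_max:
            flags.add("REF_CQ_HIGH")
            continue
        survivors.append((cq_t, float(cq_r)))

    if not survivors:
        flags.add("TOO_FEW_REPLICATES")
        return DeltaCqSet(sample_id, marker_id, [], [], None, None, None, 0, False, flags)

    finite = [
        (float(t), r) for t, r in survivors
        if t is not NO_AMPLIFICATION and float(t) <= zero_target_cq
    ]
    if not finite:
        flags.add("ZERO_CALL")
        refs = [r for _, r in survivors]
        return DeltaCqSet(
            sample_id, marker_id, [], refs, None,
            float(np.mean(refs)), None, len(survivors), True, flags,
        )
    if len(finite) < len(survivors):
        flags.add("ZERO_CANDIDATE")

    deltas = [t - r for t, r in finite]
    keep = _outlier_mask(deltas, outlier_k, leave_one_out)
    if not all(keep):
        flags.add("OUTLIER_REMOVED")
    kept = [(d, finite[i]) for i, (d, k) in enumerate(zip(deltas, keep)) if k]
    if not kept:
        flags.add("TOO_FEW_REPLICATES")
        return DeltaCqSet(sample_id, marker_id, [], [], None, None, None, 0, False, flags)
    kept_d = [d for d, _ in kept]
    kept_t = [t for _, (t, _) in kept]
    kept_r = [r for _, (_, r) in kept]
    return DeltaCqSet(
        sample_id, marker_id, kept_d, kept_r,
        float(np.mean(kept_d)), float(np.mean(kept_r)), float(np.mean(kept_t)),
        len(kept), False, flags,
    )


def _outlier_mask(deltas: Sequence[float], k: float, leave_one_out: bool) -> list[bool]:
    n = len(deltas)
    if n < 3:
        return [True] * n
    arr = np.asarray(deltas, dtype=float)
    keep = []
    if leave_one_out:
        for i in range(n):
            others = np.delete(arr, i)
            sd = others.std(ddof=1)
            dev = abs(arr[i] - others.mean())
            if sd == 0.0:
                keep.append(dev < 1e-9)
            else:
                keep.append(dev <= k * sd)
    else:
        sd = arr.std(ddof=1)
        mean = arr.mean()
        keep = [True] * n if sd == 0.0 else [abs(x - mean) <= k * sd for x in arr]
    if not any(keep):  # mutual exclusion pathology: keep everything
        return [True] * n
    return keep


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibratorEntry:
    marker_id: str
    cn: int
    mean_delta_cq: float
    mean_target_cq: float = math.nan
    mean_ref_cq: float = math.nan
    flags: set[str] = field(default_factory=set)


@dataclass
class Calibrator:
    """Per-marker anchor ΔCq values with their known copy numbers."""

    source: str
    entries: dict[str, CalibratorEntry]

    @classmethod
    def from_sample(
        cls,
        delta_sets: Mapping[tuple[str, str], DeltaCqSet],
        sample_id: str,
        known_cn: Mapping[str, int],
    ) -> "Calibrator":
        entries = {}
        for (sid, marker), ds in delta_sets.items():
            if sid != sample_id or marker not in known_cn:
                continue
            cn = int(known_cn[marker])
            if cn < 1 or ds.mean_delta_cq is None:
                continue
            entries[marker] = CalibratorEntry(
                marker, cn, ds.mean_delta_cq,
                ds.mean_target_cq if ds.mean_target_cq is not None else math.nan,
                ds.mean_ref_cq if ds.mean_ref_cq is not None else math.nan,
            )
        if not entries:
            raise CallingError(f"calibrator sample {sample_id!r} has no usable markers")
        return cls(sample_id, entries)

    @classmethod
    def from_controls(
        cls,
        delta_sets: Mapping[tuple[str, str], DeltaCqSet],
        controls: Sequence[tuple[str, Mapping[str, int]]],
    ) -> "Calibrator":
        """Merge several known-copy-number controls, preferring 2-copy anchors."""
        entries: dict[str, CalibratorEntry] = {}
        preference: dict[str, tuple] = {}
        for sid, known_cn in controls:
            for marker, cn in known_cn.items():
                cn = int(cn)
                ds = delta_sets.get((sid, marker))
                if cn < 1 or ds is None or ds.mean_delta_cq is None:
                    continue
                rank = (abs(cn - 2), -ds.n_used)
                if marker not in entries or rank < preference[marker]:
                    preference[marker] = rank
                    entries[marker] = CalibratorEntry(
                        marker, cn, ds.mean_delta_cq,
                        ds.mean_target_cq if ds.mean_target_cq is not None else math.nan,
                        ds.mean_ref_cq if ds.mean_ref_cq is not None else math.nan,
                    )
        if not entries:
            raise CallingError("no usable calibrator marker among the controls")
        return cls("CONTROLS", entries)

    @classmethod
    def from_cohort(
        cls,
        delta_sets: Mapping[tuple[str, str], DeltaCqSet],
        expected_modes: Mapping[str, int],
    ) -> "Calibrator":
        """Anchor each marker on the modal ΔCq cluster of the whole cohort."""
        per_marker: dict[str, list[float]] = {}
        for (_, marker), ds in delta_sets.items():
            if marker in expected_modes and ds.mean_delta_cq is not None:
                per_marker.setdefault(marker, []).append(ds.mean_delta_cq)
        entries = {}
        for marker, values in per_marker.items():
            anchor, flags = cohort_calibrate(values, expected_modes[marker])
            entries[marker] = CalibratorEntry(
                marker, int(expected_modes[marker]), anchor, flags=flags
            )
        if not entries:
            raise CallingError("no markers with callable ΔCq for cohort calibration")
        return cls("COHORT_MODE", entries)


def cohort_calibrate(
    values: Sequence[float],
    expected_modal_cn: int,
    *,
    window: float = 0.5,
    min_n: int = 10,
) -> tuple[float, set[str]]:
    """Anchor ΔCq on the densest 1-D cluster, assigned the expected modal CN.

    The modal cluster is the densest window of width ``window`` cycles
    (half the 1-vs-2-copy separation).  Ties between well-separated equally
    dense clusters are broken toward the lower ΔCq (higher copy number)
    cluster and flagged AMBIGUOUS_MODE.
    """
    if expected_modal_cn < 1:
        raise CallingError("expected modal copy number must be >= 1")
    vals = np.sort(np.asarray(list(values), dtype=float))
    if vals.size == 0:
        raise CallingError("cohort_calibrate needs at least one value")
    flags: set[str] = set()
    if vals.size < min_n:
        flags.add("LOW_N")
        logger.warning(
            "cohort calibration from %d samples (< %d); modal cluster may be unreliable",
            vals.size, min_n,
        )
    if vals.size == 1:
        return float(vals[0]), flags

    counts = np.searchsorted(vals, vals + window, side="right") - np.arange(vals.size)
    best = counts.max()
    starts = np.flatnonzero(counts == best)
    means = np.array([vals[i:i + best].mean() for i in starts])
    if means.max() - means.min() > window:
        flags.add("AMBIGUOUS_MODE")
    chosen = int(starts[int(np.argmin(means))])
    return float(vals[chosen:chosen + best].mean()), flags


# ---------------------------------------------------------------------------
# calling


@dataclass
class Efficiency:
    """Per-assay amplification efficiencies (1.0 = perfect doubling)."""

    per_marker: dict[str, float] = field(default_factory=dict)
    reference: float = 1.0
    default: float = 1.0

    def __post_init__(self) -> None:
        for marker, e in {**self.per_marker, "<reference>": self.reference,
                          "<default>": self.default}.items():
            if not 0 < e <= 1.2:
                raise CallingError(f"efficiency {e} for {marker} outside (0, 1.2]")

    def of(self, marker_id: str) -> float:
        return self.per_marker.get(marker_id, self.default)


def call_copy_number(
    sample: DeltaCqSet,
    calibrator_entry: CalibratorEntry,
    efficiency: Efficiency | None = None,
) -> float:
    """Calculated (real-valued) copy number for one sample x marker.

    Default is the uncorrected comparative-Cq form CN_cal x 2^(−ΔΔCq).
    With efficiencies, the efficiency-corrected ratio uses per-assay bases
    (1+E); when target and reference efficiencies coincide this reduces to
    (1+E)^(−ΔΔCq) on the same ΔΔCq (bit-identical to uncorrected at E=1).
    A zero call bypasses the exponential arithmetic entirely.
    """
    if sample.zero_call:
        return 0.0
    if sample.mean_delta_cq is None:
        raise CallingError(f"{sample.sample_id}/{sample.marker_id}: no surviving replicates")
    ddcq = sample.mean_delta_cq - calibrator_entry.mean_delta_cq
    if efficiency is None:
        return calibrator_entry.cn * 2.0 ** (-ddcq)
    e_t = efficiency.of(sample.marker_id)
    e_r = efficiency.reference
    if e_t == e_r:
        return calibrator_entry.cn * (1.0 + e_t) ** (-ddcq)
    if (
        sample.mean_target_cq is None
        or math.isnan(calibrator_entry.mean_target_cq)
        or math.isnan(calibrator_entry.mean_ref_cq)
    ):
        raise CallingError(
            "efficiency correction with distinct target/reference efficiencies "
            "needs per-assay Cq means for sample and calibrator"
        )
    a = calibrator_entry.mean_target_cq - sample.mean_target_cq
    b = calibrator_entry.mean_ref_cq - sample.mean_ref_cq
    return calibrator_entry.cn * (1.0 + e_t) ** a / (1.0 + e_r) ** b


def round_copy_number(calculated: float) -> int:
    """Nearest integer, ties away from zero; the predicted copy number."""
    if calculated < 0 or not math.isfinite(calculated):
        raise CallingError(f"calculated copy number {calculated} is not a nonnegative real")
    return int(math.floor(calculated + 0.5))


# ---------------------------------------------------------------------------
# cluster statistics, confidence and z-score


@dataclass
class ClusterStats:
    """Per-marker dispersion of calculated copy numbers within each assigned CN."""

    marker_id: str
    clusters: dict[int, tuple[float, float, int]]  # cn -> (mean, sd, n)

    def pooled_sd(self) -> float:
        """Within-cluster SD pooled over clusters with n >= 2 (nan if none)."""
        num = den = 0.0
        for _, (mean, sd, n) in self.clusters.items():
            if n >= 2 and not math.isnan(sd):
                num += (n - 1) * sd * sd
                den += n - 1
        return math.sqrt(num / den) if den > 0 else math.nan


def cluster_stats(
    calls: Iterable[tuple[float, int]], marker_id: str = ""
) -> ClusterStats:
    """Mean, SD (n−1 denominator) and n of calculated CN per assigned integer CN."""
    groups: dict[int, list[float]] = {}
    for calculated, predicted in calls:
        if calculated is None or (isinstance(calculated, float) and math.isnan(calculated)):
            continue
        groups.setdefault(int(predicted), []).append(float(calculated))
    clusters = {}
    for cn, values in sorted(groups.items()):
        arr = np.asarray(values)
        sd = float(arr.std(ddof=1)) if arr.size >= 2 else math.nan
        clusters[cn] = (float(arr.mean()), sd, int(arr.size))
    return ClusterStats(marker_id, clusters)


def confidence_metrics(
    calculated: float, predicted: int, stats: ClusterStats
) -> tuple[float, float, set[str]]:
    """(confidence, absolute z-score, flags) for one call.

    z is measured against the cluster of samples assigned the same copy
    number; the confidence is the posterior mass of the assigned integer
    under an equal-prior Gaussian mixture with means at the integer copy
    numbers and the marker's pooled within-cluster SD.
    """
    flags: set[str] = set()
    mean, sd, n = stats.clusters.get(predicted, (float(predicted), math.nan, 0))
    dev = abs(calculated - mean)
    if n < 2 or math.isnan(sd):
        z = math.nan
        flags.add("SD_UNDEFINED")
    elif sd == 0.0:
        z = 0.0 if dev < 1e-12 else math.inf
        if math.isinf(z):
            flags.add("SD_UNDEFINED")
    else:
        z = dev / sd

    pooled = stats.pooled_sd()
    max_cn = max([*stats.clusters.keys(), predicted, 2])
    lattice = range(0, max_cn + 2)
    if math.isnan(pooled) or pooled == 0.0:
        confidence = 1.0 if dev < 1e-12 else 0.0
        if math.isnan(pooled):
            flags.add("SD_UNDEFINED")
    else:
        dens = np.array([norm.pdf(calculated, loc=k, scale=pooled) for k in lattice])
        total = dens.sum()
        confidence = float(dens[list(lattice).index(predicted)] / total) if total > 0 else 0.0
    return confidence, z, flags


# ---------------------------------------------------------------------------
# consistency checks


def paired_assay_check(
    table: pd.DataFrame, panel: Panel
) -> dict[tuple[str, str], set[str]]:
    """Flag discordant paired assays and violated sum rules.

    Two assays of the same gene disagreeing (the allele-dropout signature)
    flag PAIR_DISCORDANT on both assays' rows; a sum-rule total differing
    from the sum of its components flags RULE_VIOLATION on all involved rows.
    """
    flags: dict[tuple[str, str], set[str]] = {}
    calls = {
        (r.sample_id, r.marker_id): r.predicted_cn
        for r in table.itertuples()
        if pd.notna(r.predicted_cn)
    }
    samples = sorted({s for s, _ in calls})
    for sid in samples:
        for a, b in panel.paired_assays:
            va, vb = calls.get((sid, a)), calls.get((sid, b))
            if va is not None and vb is not None and va != vb:
                flags.setdefault((sid, a), set()).add("PAIR_DISCORDANT")
                flags.setdefault((sid, b), set()).add("PAIR_DISCORDANT")
        for total, components in panel.sum_rules:
            vt = calls.get((sid, total))
            vc = [calls.get((sid, c)) for c in components]
            if vt is None or any(v is None for v in vc):
                continue
            if vt != sum(vc):
                for m in [total, *components]:
                    flags.setdefault((sid, m), set()).add("RULE_VIOLATION")
    return flags


def load_rules(path: str | Path | None = None) -> dict:
    """Load a haplotype-rules config (bundled defaults if no path given)."""
    if path is None:
        text = resources.files("qkat.data").joinpath("default_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def haplotype_rules_check(
    genotype: Mapping[str, int], rules: Mapping | None = None
) -> list[str]:
    """Check a gene-level genotype against standard haplotype-content rules.

    Framework genes are expected at two copies; a framework gene inside a
    co-variation group (loci duplicated/deleted together on known structural
    haplotypes) is exempt when the whole group moved together.
    Returns human-readable violation strings (empty = consistent).
    """
    if rules is None:
        rules = load_rules()
    totals = {
        name: sum(int(genotype.get(g, 0)) for g in genes)
        for name, genes in (rules.get("locus_totals") or {}).items()
    }

    def value(locus: str) -> int | None:
        if locus in totals:
            return totals[locus]
        if locus in genotype:
            return int(genotype[locus])
        return None

    consistent_groups: list[list[str]] = []
    for group in rules.get("covariation_groups") or []:
        vals = [value(l) for l in group]
        if None not in vals and len(set(vals)) == 1:
            consistent_groups.append(list(group))

    violations = []
    for gene, expected in (rules.get("framework_genes") or {}).items():
        observed = value(gene)
        if observed is None or observed == int(expected):
            continue
        if any(gene in group for group in consistent_groups):
            continue  # coherent co-duplication/deletion, not an error
        violations.append(
            f"framework gene {gene}: {observed} copies (expected {expected})"
        )
    return violations


# ---------------------------------------------------------------------------
# cohort pipeline


def build_delta_sets(
    wells: Iterable[WellRecord], panel: Panel, **qc_options
) -> dict[tuple[str, str], DeltaCqSet]:
    """Group wells into replicate sets and QC-filter each sample x marker."""
    groups: dict[tuple[str, str], list[tuple[int, CqValue, CqValue]]] = {}
    for well in wells:
        reaction = panel.reaction(well.reaction_id)
        ref = reaction.reference_marker
        for marker in reaction.target_markers:
            groups.setdefault((well.sample_id, marker), []).append(
                (well.replicate_index, well.cq_by_marker[marker], well.cq_by_marker[ref])
            )
    out = {}
    for (sid, marker), reps in groups.items():
        reps.sort(key=lambda t: t[0])
        out[(sid, marker)] = qc_filter(
            [(t, r) for _, t, r in reps], sid, marker, **qc_options
        )
    return out


@dataclass
class CohortCalls:
    """Result of a cohort calling run: the table plus its cluster statistics."""

    table: pd.DataFrame
    cluster_stats: dict[str, ClusterStats]
    calibrator: Calibrator


def call_cohort(
    wells: Iterable[WellRecord],
    panel: Panel,
    *,
    calibrator: Calibrator | None = None,
    calibrator_sample: str | None = None,
    calibrator_cn: Mapping[str, int] | None = None,
    controls: Sequence[tuple[str, Mapping[str, int]]] | None = None,
    cohort_modes: Mapping[str, int] | None = None,
    efficiency: Efficiency | None = None,
    rules: Mapping | None = None,
    **qc_options,
) -> CohortCalls:
    """QC, calibrate, call, round and annotate every sample x marker.

    Exactly one calibration mode must be given: a prebuilt ``calibrator``, a
    ``calibrator_sample`` (with its known ``calibrator_cn`` per marker),
    ``controls`` (several known-copy-number samples, merged), or
    ``cohort_modes`` (expected modal copy number per marker, anchored on the
    cohort's densest ΔCq cluster).
    """
    delta_sets = build_delta_sets(wells, panel, **qc_options)

    modes = [calibrator is not None, calibrator_sample is not None,
             controls is not None, cohort_modes is not None]
    if sum(modes) != 1:
        raise CallingError("specify exactly one calibration mode")
    if calibrator_sample is not None:
        if calibrator_cn is None:
            raise CallingError("calibrator_sample needs calibrator_cn")
        calibrator = Calibrator.from_sample(delta_sets, calibrator_sample, calibrator_cn)
    elif controls is not None:
        calibrator = Calibrator.from_controls(delta_sets, controls)
    elif cohort_modes is not None:
        calibrator = Calibrator.from_cohort(delta_sets, cohort_modes)
    assert calibrator is not None

    rows = []
    for (sid, marker), ds in sorted(delta_sets.items()):
        flags = set(ds.flags)
        entry = calibrator.entries.get(marker)
        if entry is not None:
            flags |= entry.flags
        if ds.zero_call:
            calculated: float = 0.0
        elif ds.mean_delta_cq is None:
            calculated = math.nan
        elif entry is None:
            calculated = math.nan
            flags.add("NO_CALIBRATOR")
        else:
            calculated = call_copy_number(ds, entry, efficiency)
        predicted = round_copy_number(calculated) if not math.isnan(calculated) else None
        rows.append(
            {
                "sample_id": sid, "marker_id": marker, "calculated_cn": calculated,
                "predicted_cn": predicted, "confidence": math.nan, "z_score": math.nan,
                "qc_flags": flags, "n_replicates_used": ds.n_used,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise CallingError("no wells to call")
    table["predicted_cn"] = table["predicted_cn"].astype("Int64")

    stats = {
        marker: cluster_stats(
            [
                (r.calculated_cn, int(r.predicted_cn))
                for r in sub.itertuples()
                if pd.notna(r.predicted_cn)
            ],
            marker,
        )
        for marker, sub in table.groupby("marker_id")
    }
    for i, row in table.iterrows():
        if pd.isna(row.predicted_cn):
            continue
        conf, z, extra = confidence_metrics(
            row.calculated_cn, int(row.predicted_cn), stats[row.marker_id]
        )
        table.at[i, "confidence"] = conf
        table.at[i, "z_score"] = z
        row.qc_flags.update(extra)

    pair_flags = paired_assay_check(table, panel)
    for i, row in table.iterrows():
        extra = pair_flags.get((row.sample_id, row.marker_id))
        if extra:
            row.qc_flags.update(extra)

    if rules is not None:
        from .haplotypes import project_genotype

        gene_of = {m.marker_id: m.gene for m in panel.target_markers}
        lt = rules.get("locus_totals") or {}
        for sid, sub in table.groupby("sample_id"):
            marker_cn = {
                r.marker_id: int(r.predicted_cn)
                for r in sub.itertuples()
                if pd.notna(r.predicted_cn)
            }
            genes = {}
            for m, cn in marker_cn.items():
                if m in panel.sum_rule_totals:
                    continue
                genes.setdefault(gene_of[m], set()).add(cn)
            genotype = {g: v.pop() for g, v in genes.items() if len(v) == 1}
            violations = haplotype_rules_check(genotype, rules)
            if not violations:
                continue
            bad_genes = {v.split()[2].rstrip(":") for v in violations}
            for name, members in lt.items():
                if any(f"{name}:" in v or f" {name} " in v for v in violations):
                    bad_genes.update(members)
            idx = table.index[
                (table.sample_id == sid)
                & table.marker_id.map(lambda m: gene_of.get(m) in bad_genes)
            ]
            for i in idx:
                table.at[i, "qc_flags"].add("RULE_VIOLATION")

    table["qc_flags"] = table["qc_flags"].map(lambda s: ";".join(sorted(s)))
    return CohortCalls(table=table, cluster_stats=stats, calibrator=calibrator)
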