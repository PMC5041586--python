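"""ΔΔCq caller: QC rules, calibration, rounding, metrics, consistency checks."""

import math

import numpy as np
import pandas as pd
import pytest

from qkat import (
    CalibratorEntry,
    ClusterStats,
    Efficiency,
    WellRecord,
    call_copy_number,
    cluster_stats,
    cohort_calibrate,
    confidence_metrics,
    copy_ratio,
    ddcq_separation,
    delta_cq,
    discrimination_threshold,
    haplotype_rules_check,
    paired_assay_check,
    qc_filter,
    round_copy_number,
)
from qkat.calling import CallingError, DeltaCqSet, ReferenceFailure
from qkat.io import NO_AMPLIFICATION


def _well(cq_target, cq_ref):
    return WellRecord("p1", "A1", "S1", "R1", 1,
                      {"M1": cq_target, "REF": cq_ref})


def _dset(mean_dcq, marker="M1", zero=False, target_cq=None, ref_cq=None):
    return DeltaCqSet(
        "S1", marker, [mean_dcq] if not zero else [], [],
        None if zero else mean_dcq, ref_cq, target_cq, 4 if not zero else 0, zero,
    )


class TestDeltaCq:
    def test_basic_difference(self):
        assert delta_cq(_well(24.0, 23.0), "M1", "REF") == 1.0

    def test_identity(self):
        assert delta_cq(_well(23.0, 23.0), "M1", "REF") == 0.0

    def test_one_copy_vs_two_copies_differ_by_one_cycle(self):
        # same DNA input: one copy crosses threshold one cycle later
        two_copy = delta_cq(_well(23.0, 22.0), "M1", "REF")
        one_copy = delta_cq(_well(24.0, 22.0), "M1", "REF")
        assert one_copy - two_copy == 1.0

    def test_no_amplification_target_is_zero_candidate(self):
        assert math.isinf(delta_cq(_well(NO_AMPLIFICATION, 23.0), "M1", "REF"))

    def test_reference_failure_raises(self):
        with pytest.raises(ReferenceFailure):
            delta_cq(_well(24.0, NO_AMPLIFICATION), "M1", "REF")


class TestQcFilter:
    def test_late_reference_replicate_removed(self):
        reps = [(25.0, 24.0), (25.1, 24.1), (24.9, 23.9), (25.0, 32.5)]
        out = qc_filter(reps)
        assert "REF_CQ_HIGH" in out.flags
        assert out.n_used == 3
        assert out.mean_delta_cq == pytest.approx(1.0)

    def test_zero_call_when_target_late_and_reference_sound(self):
        reps = [(36.0, 30.0)] * 4
        out = qc_filter(reps)
        assert out.zero_call
        assert "ZERO_CALL" in out.flags
        assert out.mean_delta_cq is None

    def test_leave_one_out_outlier_removed(self):
        # ΔCq values {1.00, 1.02, 0.98, 1.50}: the other three have mean 1.00
        # and SD 0.02, so 1.50 sits 25 SD away and is removed.
        reps = [(25.00, 24.0), (25.02, 24.0), (24.98, 24.0), (25.50, 24.0)]
        out = qc_filter(reps)
        assert "OUTLIER_REMOVED" in out.flags
        assert out.n_used == 3
        assert out.mean_delta_cq == pytest.approx(1.0)

    def test_inclusive_mode_keeps_the_same_point(self):
        # inclusive SD of all four is inflated by the extreme value itself
        # (max possible deviation in a quadruplicate is ~1.5 SD), so the
        # 4-SD rule can never fire.
        reps = [(25.00, 24.0), (25.02, 24.0), (24.98, 24.0), (25.50, 24.0)]
        out = qc_filter(reps, leave_one_out=False)
        assert out.n_used == 4

    def test_all_replicates_removed(self):
        out = qc_filter([(25.0, 33.0), (25.0, NO_AMPLIFICATION)])
        assert "TOO_FEW_REPLICATES" in out.flags
        assert out.mean_delta_cq is None
        assert out.n_used == 0

    def test_requires_at_least_one_replicate(self):
        with pytest.raises(CallingError):
            qc_filter([])

    def test_mixed_zero_candidate_dropped_from_mean(self):
        reps = [(25.0, 24.0), (25.0, 24.0), (25.0, 24.0), (NO_AMPLIFICATION, 24.0)]
        out = qc_filter(reps)
        assert "ZERO_CANDIDATE" in out.flags
        assert not out.zero_call
        assert out.n_used == 3


class TestCallCopyNumber:
    CAL = CalibratorEntry("M1", cn=2, mean_delta_cq=1.0,
                          mean_target_cq=23.0, mean_ref_cq=22.0)

    def test_identity_at_zero_ddcq(self):
        assert call_copy_number(_dset(1.0), self.CAL) == pytest.approx(2.0)

    def test_one_cycle_is_one_halving(self):
        assert call_copy_number(_dset(2.0), self.CAL) == pytest.approx(1.0)

    def test_three_copies_is_1p5_fold(self):
        assert call_copy_number(_dset(1.0 - math.log2(1.5)), self.CAL) == pytest.approx(3.0)

    def test_zero_call_short_circuits(self):
        assert call_copy_number(_dset(None, zero=True), self.CAL) == 0.0

    @pytest.mark.parametrize("ddcq", np.linspace(-2, 2, 9).tolist())
    def test_strictly_decreasing_and_halving(self, ddcq):
        lo = call_copy_number(_dset(1.0 + ddcq), self.CAL)
        hi = call_copy_number(_dset(1.0 + ddcq + 1.0), self.CAL)
        assert hi < lo
        assert hi == pytest.approx(lo / 2.0, rel=1e-12)

    def test_perfect_efficiency_bit_identical_to_uncorrected(self):
        eff = Efficiency(per_marker={"M1": 1.0}, reference=1.0)
        for ddcq in (-1.3, 0.0, 0.7, 2.25):
            s = _dset(1.0 + ddcq)
            assert call_copy_number(s, self.CAL, eff) == call_copy_number(s, self.CAL)

    def test_distinct_efficiencies_use_per_assay_bases(self):
        # one-copy sample at E_target = 0.9: target Cq is later than the
        # calibrator's by log(2)/log(1.9) cycles; reference unchanged.
        e_t = 0.9
        shift = math.log(2) / math.log(1 + e_t)
        sample = _dset(1.0 + shift, target_cq=23.0 + shift, ref_cq=22.0)
        eff = Efficiency(per_marker={"M1": e_t}, reference=1.0)
        assert call_copy_number(sample, self.CAL, eff) == pytest.approx(1.0)

    def test_missing_mean_raises(self):
        broken = DeltaCqSet("S1", "M1", [], [], None, None, None, 0, False)
        with pytest.raises(CallingError):
            call_copy_number(broken, self.CAL)


class TestRounding:
    @pytest.mark.parametrize(
        "calculated,expected",
        [(1.94, 2), (0.12, 0), (2.5, 3), (1.5, 2), (0.49, 0), (0.5, 1), (3.0, 3)],
    )
    def test_nearest_integer_ties_away_from_zero(self, calculated, expected):
        assert round_copy_number(calculated) == expected

    def test_negative_rejected(self):
        with pytest.raises(CallingError):
            round_copy_number(-0.1)


class TestCohortCalibrate:
    def test_modal_cluster_found(self):
        rng = np.random.default_rng(42)
        values = np.concatenate([
            rng.normal(0.0, 0.05, 70),   # two copies (mode)
            rng.normal(1.0, 0.05, 25),   # one copy
            rng.normal(-0.58, 0.05, 5),  # three copies
        ])
        anchor, flags = cohort_calibrate(values, expected_modal_cn=2)
        assert abs(anchor) < 0.1
        assert "AMBIGUOUS_MODE" not in flags

    def test_single_sample_is_its_own_calibrator(self):
        anchor, flags = cohort_calibrate([0.37], expected_modal_cn=2)
        assert anchor == 0.37
        assert "LOW_N" in flags

    def test_bimodal_tie_prefers_higher_copy_cluster(self):
        values = [0.0] * 50 + [1.0] * 50
        anchor, flags = cohort_calibrate(values, expected_modal_cn=2)
        assert anchor == 0.0  # lower ΔCq = higher copy number
        assert "AMBIGUOUS_MODE" in flags

    def test_empty_rejected(self):
        with pytest.raises(CallingError):
            cohort_calibrate([], expected_modal_cn=2)


class TestClusterStatsAndConfidence:
    def test_identical_samples_have_zero_sd(self):
        stats = cluster_stats([(2.0, 2)] * 5, "M1")
        mean, sd, n = stats.clusters[2]
        assert (mean, sd, n) == (2.0, 0.0, 5)

    def test_two_clusters_match_direct_computation(self):
        rng = np.random.default_rng(0)
        ones = rng.normal(1.0, 0.1, 40)
        twos = rng.normal(2.0, 0.1, 60)
        calls = [(v, 1) for v in ones] + [(v, 2) for v in twos]
        stats = cluster_stats(calls, "M1")
        assert set(stats.clusters) == {1, 2}
        assert stats.clusters[1][0] == pytest.approx(ones.mean())
        assert stats.clusters[1][1] == pytest.approx(ones.std(ddof=1))
        assert stats.clusters[2][2] == 60

    def test_z_score_at_mean_and_two_sd(self):
        stats = ClusterStats("M1", {1: (1.0, 0.1, 50), 2: (2.0, 0.1, 50)})
        _, z0, _ = confidence_metrics(1.0, 1, stats)
        _, z2, _ = confidence_metrics(1.2, 1, stats)
        assert z0 == 0.0
        assert z2 == pytest.approx(2.0)

    def test_halfway_point_has_half_confidence(self):
        stats = ClusterStats("M1", {1: (1.0, 0.1, 50), 2: (2.0, 0.1, 50)})
        conf, _, _ = confidence_metrics(1.5, 2, stats)
        assert conf == pytest.approx(0.5, abs=1e-6)

    def test_zero_sd_with_deviation_flags_infinite_z(self):
        stats = ClusterStats("M1", {2: (2.0, 0.0, 5)})
        _, z, flags = confidence_metrics(2.3, 2, stats)
        assert math.isinf(z)
        assert "SD_UNDEFINED" in flags


class TestDiscriminationThreshold:
    def test_published_tiers(self):
        assert round(discrimination_threshold(1, 6), 3) == 0.167
        assert discrimination_threshold(1, 4) == 0.25

    def test_thresholds_shrink_with_copy_number(self):
        assert discrimination_threshold(2, 6) == pytest.approx(math.log2(1.5) / 6)
        values = [discrimination_threshold(n, 6) for n in range(1, 8)]
        assert values == sorted(values, reverse=True)

    @pytest.mark.parametrize("n", range(1, 11))
    @pytest.mark.parametrize("k", [4, 6])
    def test_closed_form_identity(self, n, k):
        # exact up to one rounding of the divide-multiply round trip
        assert discrimination_threshold(n, k) * k == pytest.approx(
            math.log2((n + 1) / n), rel=1e-15
        )

    def test_zero_copies_rejected(self):
        with pytest.raises(ValueError):
            discrimination_threshold(0, 6)

    def test_theoretical_separations(self):
        assert ddcq_separation(1) == 1.0
        assert copy_ratio(1, 2) == 2.0
        assert copy_ratio(2, 3) == 1.5


def _calls_frame(rows):
    return pd.DataFrame(
        [{"sample_id": s, "marker_id": m, "predicted_cn": cn} for s, m, cn in rows]
    )


class TestConsistencyChecks:
    def test_discordant_pair_flagged(self, kir_panel):
        table = _calls_frame([("S1", "3DL1e4", 1), ("S1", "3DL1e9", 2)])
        flags = paired_assay_check(table, kir_panel)
        assert "PAIR_DISCORDANT" in flags[("S1", "3DL1e4")]
        assert "PAIR_DISCORDANT" in flags[("S1", "3DL1e9")]

    def test_sum_rule_holds(self, kir_panel):
        table = _calls_frame(
            [("S1", "2DS4", 2), ("S1", "2DS4FL", 1), ("S1", "2DS4del", 1)]
        )
        assert paired_assay_check(table, kir_panel) == {}

    def test_sum_rule_violation_flagged(self, kir_panel):
        table = _calls_frame(
            [("S1", "2DS4", 2), ("S1", "2DS4FL", 2), ("S1", "2DS4del", 1)]
        )
        flags = paired_assay_check(table, kir_panel)
        for marker in ("2DS4", "2DS4FL", "2DS4del"):
            assert "RULE_VIOLATION" in flags[("S1", marker)]

    def test_framework_genes_at_two_copies_pass(self):
        genotype = {"3DL3": 2, "3DP1": 2, "2DL4": 2, "3DL2": 2, "3DL1": 1, "3DS1": 1}
        assert haplotype_rules_check(genotype) == []

    def test_framework_deletion_flagged(self):
        genotype = {"3DL3": 1, "3DP1": 2, "2DL4": 2, "3DL2": 2}
        violations = haplotype_rules_check(genotype)
        assert len(violations) == 1
        assert "3DL3" in violations[0]

    def test_consistent_coduplication_not_flagged(self):
        genotype = {"3DL3": 2, "3DL2": 2, "3DP1": 3, "2DL4": 3, "3DL1": 2, "3DS1": 1}
        assert haplotype_rules_check(genotype) == []

    def test_isolated_duplication_flagged(self):
        genotype = {"3DL3": 2, "3DL2": 2, "3DP1": 3, "2DL4": 2, "3DL1": 1, "3DS1": 1}
        violations = haplotype_rules_check(genotype)
        assert any("3DP1" in v for v in violations)


class TestCohortModeCalling:
    def test_cohort_mode_recovers_copy_numbers(self):
        from conftest import make_mini_panel
        from qkat import NoiseModel, TruthSet, call_cohort, simulate_plate

        panel = make_mini_panel()
        cns = [2] * 30 + [1] * 8 + [3] * 4
        truth = TruthSet.from_genotypes(
            {f"S{i:02d}": {"G1": cn} for i, cn in enumerate(cns)}
        )
        noise = NoiseModel(sigma_delta_cq=0.05)
        wells, _ = simulate_plate(truth, panel, noise, controls=(), seed=19)
        result = call_cohort(wells, panel, cohort_modes={"M1": 2})
        assert result.calibrator.source == "COHORT_MODE"
        table = result.table.set_index("sample_id")
        for s in truth.samples:
            assert table.loc[s.sample_id].predicted_cn == s.locus_cn["G1"]

    def test_exactly_one_calibration_mode_required(self, kir_panel):
        from qkat import call_cohort

        with pytest.raises(CallingError, match="exactly one"):
            call_cohort([], kir_panel)
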