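import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cordmotion.cohort_stats import (CohortTable, apply_exclusions,
                                     build_cohort_table,
                                     cluster_bootstrap_pooled_p,
                                     derive_biometrics, friedman_intersegment,
                                     icc_two_way, mean_arterial_pressure,
                                     reliability_report, segment_summary,
                                     spearman_correlations)
from cordmotion.errors import InsufficientDataError, StructuralError
from cordmotion.synthetic_cohort import CohortConfig, synthesize_cohort
from cordmotion.velocity_pipeline import READOUT_NAMES, quantify_series_set

SEGMENTS6 = ["C2", "C3", "C4", "C5", "C6", "C7"]


def readouts_frame(values_by_subject_segment, scan_id="scan1", rater_id="R1",
                   corrected=True):
    """Build a readouts table where every readout equals the given value."""
    rows = []
    for subject, per_segment in values_by_subject_segment.items():
        for segment, value in per_segment.items():
            rows.append({
                "subject_id": subject, "scan_id": scan_id, "rater_id": rater_id,
                "segment": segment, "corrected": corrected,
                "amplitude": value, "max_cranial": value, "max_caudal": value,
                "displacement": value, "drift_estimate": 0.25,
                "rr_interval": 1000.0,
            })
    return pd.DataFrame(rows)


def simple_cohort(values_by_subject_segment, subjects=None, **kwargs):
    readouts = readouts_frame(values_by_subject_segment, **kwargs)
    if subjects is None:
        subjects = pd.DataFrame({
            "subject_id": sorted(values_by_subject_segment),
            "excluded": False, "exclusion_reason": ""})
    return build_cohort_table(readouts, subjects)


class TestCohortTable:
    def test_duplicate_keys_rejected(self):
        df = readouts_frame({"S01": {"C5": 1.0}})
        df = pd.concat([df, df])
        with pytest.raises(StructuralError):
            build_cohort_table(df, pd.DataFrame({"subject_id": ["S01"]}))

    def test_excluded_without_reason_rejected(self):
        readouts = readouts_frame({"S01": {"C5": 1.0}})
        subjects = pd.DataFrame({"subject_id": ["S01"], "excluded": [True],
                                 "exclusion_reason": [""]})
        with pytest.raises(StructuralError):
            CohortTable(readouts=readouts, subjects=subjects)

    def test_long_format(self):
        cohort = simple_cohort({"S01": {"C5": 0.4}})
        long = cohort.long()
        assert len(long) == 4
        assert set(long["readout"]) == set(READOUT_NAMES)


class TestApplyExclusions:
    def _cohort(self, n, n_flagged):
        ids = [f"S{i:02d}" for i in range(1, n + 1)]
        values = {s: {"C5": 0.4} for s in ids}
        subjects = pd.DataFrame({
            "subject_id": ids,
            "excluded": [i >= n - n_flagged for i in range(n)],
            "exclusion_reason": ["incidental stenosis" if i >= n - n_flagged
                                 else "" for i in range(n)],
        })
        return simple_cohort(values, subjects)

    def test_22_recruited_4_stenosis_leaves_18(self):
        filtered, n_before, n_after = apply_exclusions(self._cohort(22, 4))
        assert (n_before, n_after) == (22, 18)
        assert filtered.subjects["subject_id"].nunique() == 18
        assert filtered.readouts["subject_id"].nunique() == 18

    def test_no_flags_is_identity(self):
        cohort = self._cohort(5, 0)
        filtered, n_before, n_after = apply_exclusions(cohort)
        assert (n_before, n_after) == (5, 5)
        pd.testing.assert_frame_equal(filtered.readouts, cohort.readouts)

    def test_all_flagged_warns_and_empties(self):
        ids = ["S01", "S02"]
        subjects = pd.DataFrame({"subject_id": ids, "excluded": [True, True],
                                 "exclusion_reason": ["stenosis"] * 2})
        cohort = simple_cohort({s: {"C5": 1.0} for s in ids}, subjects)
        with pytest.warns(UserWarning, match="all subjects excluded"):
            filtered, _, n_after = apply_exclusions(cohort)
        assert n_after == 0
        assert filtered.readouts.empty

    def test_subject_order_permutation_invariant(self):
        cohort = self._cohort(8, 2)
        shuffled = CohortTable(
            readouts=cohort.readouts.sample(frac=1, random_state=3)
            .reset_index(drop=True),
            subjects=cohort.subjects.sample(frac=1, random_state=4)
            .reset_index(drop=True))
        a = apply_exclusions(cohort)[0]
        b = apply_exclusions(shuffled)[0]
        assert set(a.subjects.subject_id) == set(b.subjects.subject_id)


class TestDeriveBiometrics:
    def test_printed_cohort_means(self):
        df = pd.DataFrame({"subject_id": ["S01"],
                           "sys_before": [129.7], "sys_after": [122.7],
                           "dia_before": [80.0], "dia_after": [77.0]})
        out = derive_biometrics(df)
        assert out.mean_systolic[0] == pytest.approx(126.2)
        assert out.mean_diastolic[0] == pytest.approx(78.5)
        assert round(out.mean_arterial_pressure[0], 1) == 94.4

    def test_equal_pressures_map_is_identity(self):
        df = pd.DataFrame({"subject_id": ["S01"], "sys_before": [100.0],
                           "sys_after": [100.0], "dia_before": [100.0],
                           "dia_after": [100.0]})
        assert derive_biometrics(df).mean_arterial_pressure[0] == pytest.approx(100.0)

    def test_map_algebraic_identity(self, rng):
        # dia + (sys - dia)/3 == (2*dia + sys)/3
        for _ in range(20):
            sys_v, dia_v = rng.uniform(90, 180), rng.uniform(50, 110)
            assert mean_arterial_pressure(sys_v, dia_v) == pytest.approx(
                (2 * dia_v + sys_v) / 3.0, abs=1e-12)

    def test_missing_propagates(self):
        df = pd.DataFrame({"subject_id": ["S01", "S02"],
                           "sys_before": [120.0, np.nan],
                           "sys_after": [110.0, 115.0],
                           "dia_before": [80.0, 75.0],
                           "dia_after": [70.0, 72.0]})
        out = derive_biometrics(df)
        assert np.isnan(out.mean_systolic[1])
        assert np.isnan(out.mean_arterial_pressure[1])
        assert not np.isnan(out.mean_diastolic[1])


class TestSegmentSummary:
    def test_constant_cohort(self):
        values = {f"S{i:02d}": {"C5": 0.445} for i in range(1, 19)}
        out = segment_summary(simple_cohort(values), "amplitude")
        row = out[out.segment == "C5"].iloc[0]
        assert row["mean"] == pytest.approx(0.445)
        assert row["sd"] == pytest.approx(0.0)
        assert row["n"] == 18

    def test_two_subject_hand_computation(self):
        values = {"S01": {"C5": 0.0}, "S02": {"C5": 1.0}}
        row = segment_summary(simple_cohort(values), "displacement").iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["sd"] == pytest.approx(np.sqrt(0.5))   # sample SD, n-1

    def test_single_subject_insufficient(self):
        with pytest.raises(InsufficientDataError):
            segment_summary(simple_cohort({"S01": {"C5": 1.0}}), "amplitude")


def brute_force_friedman(matrix):
    """Rank-sum formula chi2 = 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1)."""
    n, k = matrix.shape
    ranks = np.array([sps.rankdata(row) for row in matrix])
    rank_sums = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(rank_sums ** 2) - 3.0 * n * (k + 1)


class TestFriedman:
    def _cohort_from_matrix(self, matrix, segments):
        values = {f"S{i:02d}": dict(zip(segments, row))
                  for i, row in enumerate(matrix, start=1)}
        return simple_cohort(values)

    def test_identical_segments_gives_zero_statistic(self):
        matrix = np.tile([[0.3], [0.5], [0.4]], (1, 6))
        res = friedman_intersegment(self._cohort_from_matrix(matrix, SEGMENTS6),
                                    "amplitude")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value > 0.99

    def test_constructed_separation_significant(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.3, size=6)
        rows = []
        for b in base:
            # C5 = C2 + 0.15, others strictly intermediate
            rows.append([b, b + 0.03, b + 0.06, b + 0.15, b + 0.09, b + 0.12])
        res = friedman_intersegment(self._cohort_from_matrix(np.array(rows),
                                                             SEGMENTS6),
                                    "amplitude")
        pair = res.pairwise.query("seg_a == 'C2' and seg_b == 'C5'").iloc[0]
        # hand rank arithmetic for n=6, k=6: identical per-subject rank
        # vectors give mean-rank gap 5, se = sqrt(6*7/36), z = 4.6291
        assert pair.z == pytest.approx(-5.0 / np.sqrt(42.0 / 36.0), abs=1e-12)
        assert pair.p_adj < 0.05

    def test_matches_rank_sum_formula_oracle(self, rng):
        matrix = rng.uniform(size=(5, 6))        # continuous: no ties
        res = friedman_intersegment(self._cohort_from_matrix(matrix, SEGMENTS6),
                                    "max_cranial")
        assert res.statistic == pytest.approx(brute_force_friedman(matrix),
                                              abs=1e-10)

    def test_per_subject_constant_shift_invariance(self, rng):
        matrix = rng.uniform(size=(7, 6))
        shifted = matrix + rng.uniform(-5, 5, size=(7, 1))
        r1 = friedman_intersegment(self._cohort_from_matrix(matrix, SEGMENTS6),
                                   "amplitude")
        r2 = friedman_intersegment(self._cohort_from_matrix(shifted, SEGMENTS6),
                                   "amplitude")
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_incomplete_subject_dropped_with_warning(self, rng):
        matrix = rng.uniform(size=(5, 6))
        cohort = self._cohort_from_matrix(matrix, SEGMENTS6)
        readouts = cohort.readouts[~((cohort.readouts.subject_id == "S01")
                                     & (cohort.readouts.segment == "C7"))]
        cohort2 = CohortTable(readouts=readouts.reset_index(drop=True),
                              subjects=cohort.subjects)
        with pytest.warns(UserWarning, match="missing segments"):
            res = friedman_intersegment(cohort2, "amplitude")
        assert res.n_subjects == 4

    def test_too_few_segments(self):
        values = {"S01": {"C2": 1.0, "C3": 2.0}, "S02": {"C2": 2.0, "C3": 1.0}}
        with pytest.raises(InsufficientDataError):
            friedman_intersegment(simple_cohort(values), "amplitude")


def brute_force_icc_absolute_average(x):
    """ICC(A,k) from explicitly accumulated two-way ANOVA sums of squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (x[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (x[:, j].mean() - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (x[i, j] - grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestICC:
    def test_identical_columns_gives_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        res = icc_two_way(x)
        assert res.icc == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_absolute_agreement_penalizes_bias(self, rng):
        subjects = rng.normal(0, 5, size=20)
        x = np.column_stack([subjects, subjects + 3.0])   # constant rater bias
        absolute = icc_two_way(x, "absolute_agreement", "average").icc
        consistency = icc_two_way(x, "consistency", "average").icc
        assert consistency == pytest.approx(1.0)
        assert absolute < consistency

    def test_matches_anova_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 21))
            k = int(rng.integers(2, 4))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            res = icc_two_way(x)
            assert res.icc == pytest.approx(brute_force_icc_absolute_average(x),
                                            abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "score": x.ravel(),
        })
        table = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                         ratings="score")
        ref = table[table.Type.isin(["ICC2k", "ICC(A,k)"])].iloc[0]
        res = icc_two_way(x)
        assert res.icc == pytest.approx(ref.ICC, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pval, abs=1e-9)

    def test_zero_between_subject_variance_warns(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        with pytest.warns(UserWarning):
            res = icc_two_way(x)
        assert res.icc <= 0.0

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(ValueError):
            icc_two_way(x)


def _two_scan_cohort(**overrides):
    params = dict(seed=31, n_subjects=12, segments=("C5",), n_scans=2,
                  pixel_noise_sd=0.0, drift=(0.25, 0.04), retest_scale_sd=0.05)
    params.update(overrides)
    cfg = CohortConfig(**params)
    data = synthesize_cohort(cfg)
    readouts = quantify_series_set(data.series, cfg.roi)
    return build_cohort_table(readouts, data.subjects, data.anatomy)


class TestReliabilityReport:
    def test_duplicate_scan_gives_icc_one(self, rng):
        values = rng.uniform(0.2, 0.6, size=8)
        rows = []
        for scan in ("scan1", "scan2"):
            df = readouts_frame({f"S{i:02d}": {"C5": v}
                                 for i, v in enumerate(values, 1)},
                                scan_id=scan)
            rows.append(df)
        cohort = build_cohort_table(
            pd.concat(rows, ignore_index=True),
            pd.DataFrame({"subject_id": [f"S{i:02d}" for i in range(1, 9)]}))
        rel = reliability_report(cohort, "test_retest")
        np.testing.assert_allclose(rel.icc, 1.0, atol=1e-12)

    def test_corrected_beats_raw_for_displacement(self):
        cohort = _two_scan_cohort()
        corrected = reliability_report(cohort, "test_retest", use_correction=True)
        raw = reliability_report(cohort, "test_retest", use_correction=False)
        key = ["segment", "readout"]
        merged = corrected.merge(raw, on=key, suffixes=("_corr", "_raw"))
        disp = merged[merged.readout == "displacement"].iloc[0]
        assert disp.icc_corr > disp.icc_raw

    def test_amplitude_icc_independent_of_correction(self):
        cohort = _two_scan_cohort(seed=32)
        corrected = reliability_report(cohort, "test_retest", use_correction=True)
        raw = reliability_report(cohort, "test_retest", use_correction=False)
        a_corr = corrected[corrected.readout == "amplitude"].iloc[0].icc
        a_raw = raw[raw.readout == "amplitude"].iloc[0].icc
        assert a_corr == pytest.approx(a_raw, abs=1e-9)

    def test_inter_rater_close_rois_agree(self):
        cfg = CohortConfig(seed=33, n_subjects=8, segments=("C5",),
                           pixel_noise_sd=25.0)
        data = synthesize_cohort(cfg)
        rois = {"R1": cfg.roi, "R2": cfg.roi.shifted(0.2, -0.2)}
        readouts = quantify_series_set(data.series, rois)
        cohort = build_cohort_table(readouts, data.subjects)
        rel = reliability_report(cohort, "inter_rater")
        assert (rel.icc > 0.95).all()

    def test_unpaired_subject_dropped_with_warning(self, rng):
        values = rng.uniform(0.2, 0.6, size=5)
        scan1 = readouts_frame({f"S{i:02d}": {"C5": v}
                                for i, v in enumerate(values, 1)}, scan_id="scan1")
        scan2 = readouts_frame({f"S{i:02d}": {"C5": v + 0.01}
                                for i, v in enumerate(values[:-1], 1)},
                               scan_id="scan2")
        cohort = build_cohort_table(
            pd.concat([scan1, scan2], ignore_index=True),
            pd.DataFrame({"subject_id": [f"S{i:02d}" for i in range(1, 6)]}))
        with pytest.warns(UserWarning, match="unpaired"):
            rel = reliability_report(cohort, "test_retest")
        assert (rel.n == 4).all()


class TestSpearman:
    def _cohort_with_covariate(self, values, covariate):
        ids = [f"S{i:02d}" for i in range(1, len(values) + 1)]
        cohort_values = {s: {"C5": v} for s, v in zip(ids, values)}
        subjects = pd.DataFrame({"subject_id": ids, "excluded": False,
                                 "exclusion_reason": "", "body_size": covariate})
        return simple_cohort(cohort_values, subjects)

    def test_self_correlation_is_one(self):
        cohort = self._cohort_with_covariate([0.1, 0.4, 0.2, 0.3, 0.5],
                                             [1, 2, 3, 4, 5])
        out = spearman_correlations(cohort, "displacement", "displacement")
        assert out.iloc[0].rho == pytest.approx(1.0)

    def test_negated_covariate_gives_minus_one(self):
        values = [0.1, 0.4, 0.2, 0.3, 0.5]
        cohort = self._cohort_with_covariate(values, [-v for v in values])
        out = spearman_correlations(cohort, "displacement", "body_size")
        assert out.iloc[0].rho == pytest.approx(-1.0)

    def test_six_pair_hand_rank_computation(self):
        values = [0.30, 0.10, 0.50, 0.20, 0.60, 0.40]
        covariate = [170.0, 180.0, 160.0, 178.0, 150.0, 166.0]
        cohort = self._cohort_with_covariate(values, covariate)
        out = spearman_correlations(cohort, "displacement", "body_size")
        # ranks(values) = [3,1,5,2,6,4]; ranks(cov) = [4,6,2,5,1,3]
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)), d = [-1,-5,3,-3,5,1]
        d2 = sum(d * d for d in (-1, -5, 3, -3, 5, 1))
        expected = 1 - 6 * d2 / (6 * 35)
        assert out.iloc[0].rho == pytest.approx(expected, abs=1e-12)

    def test_constant_covariate_reported_missing(self):
        cohort = self._cohort_with_covariate([0.1, 0.2, 0.3, 0.4, 0.5],
                                             [170.0] * 5)
        out = spearman_correlations(cohort, "displacement", "body_size")
        assert np.isnan(out.iloc[0].rho)
        assert "constant" in out.iloc[0].note

    def test_too_few_pairs_noted(self):
        cohort = self._cohort_with_covariate([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
        out = spearman_correlations(cohort, "displacement", "body_size")
        assert np.isnan(out.iloc[0].rho)

    def test_pooled_scope_stacks_segments(self, rng):
        ids = [f"S{i:02d}" for i in range(1, 7)]
        values = {s: {seg: rng.uniform(0.2, 0.6) for seg in SEGMENTS6}
                  for s in ids}
        subjects = pd.DataFrame({"subject_id": ids, "excluded": False,
                                 "exclusion_reason": "",
                                 "body_size": rng.uniform(150, 190, size=6)})
        cohort = simple_cohort(values, subjects)
        out = spearman_correlations(cohort, "displacement", "body_size",
                                    scope="pooled_all_segments")
        assert out.iloc[0].n == 36

    def test_null_p_values_roughly_uniform(self):
        # pooled rho on independent noise: small |rho|, p ~ U(0,1)
        master = np.random.default_rng(7)
        pvals, rhos = [], []
        for _ in range(200):
            values = master.normal(size=24)
            cov = master.normal(size=24)
            rho, p = sps.spearmanr(values, cov)
            pvals.append(p)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.05
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_cluster_bootstrap_null_not_significant(self, rng):
        ids = [f"S{i:02d}" for i in range(1, 9)]
        values = {s: {seg: rng.uniform(0.2, 0.6) for seg in SEGMENTS6}
                  for s in ids}
        subjects = pd.DataFrame({"subject_id": ids, "excluded": False,
                                 "exclusion_reason": "",
                                 "body_size": rng.uniform(150, 190, size=8)})
        cohort = simple_cohort(values, subjects)
        p = cluster_bootstrap_pooled_p(cohort, "displacement", "body_size",
                                       n_boot=200, seed=5)
        assert p > 0.01
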