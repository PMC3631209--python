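import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mqfpcr import catalog
from mqfpcr.dosage_stats import (
    NormalizedRatio,
    SampleRatio,
    Score,
    assign_peaks,
    call_dosage,
    cohort_stats,
    dagostino_pearson,
    diagnostic_cis,
    normalize,
    parse_peak_table,
    pseudo_z,
    roc,
    score_cohort,
    wilson_cc,
    z_scores,
)

from _oracles import concordant_pair_auc


PEAK_TSV = (
    "Sample\tDye\tSize\tHeight\tArea\n"
    "s1\tNED\t214.1\t500\t5000\n"
    "s1\tNED\t218.0\t480\t4800\n"
    "s2\tNED\t214.3\t400\t4100\n"
)


class TestParsePeakTable:
    def test_well_formed_rows(self):
        records = parse_peak_table(PEAK_TSV)
        assert len(records) == 3
        assert records[0].sample_id == "s1" and records[0].area == 5000

    def test_fractional_sizes(self):
        records = parse_peak_table(PEAK_TSV)
        assert records[2].size == pytest.approx(214.3)

    def test_missing_area_column(self):
        bad = "Sample\tSize\tHeight\ns1\t214\t500\n"
        with pytest.raises(ValueError, match="Area"):
            parse_peak_table(bad)

    def test_unparseable_row_rejected_with_number(self):
        bad = PEAK_TSV + "s3\tNED\tnotasize\t1\t2\n"
        with pytest.warns(UserWarning, match=r"\[5\]"):
            records = parse_peak_table(bad)
        assert len(records) == 3


class TestAssignPeaks:
    def test_window_arithmetic_on_published_sizes(self):
        """Peaks at 214.1/218.0 against the 218(test)/214(control) assay."""
        records = parse_peak_table(PEAK_TSV)
        ratios, uncallable = assign_peaks(records, catalog.WBS, tol=1.0)
        (r,) = [x for x in ratios if x.sample_id == "s1"]
        assert r.test_area == 4800 and r.control_area == 5000
        assert r.ratio == pytest.approx(0.96)

    def test_sample_missing_a_peak_reported(self):
        records = parse_peak_table(PEAK_TSV)
        _, uncallable = assign_peaks(records, catalog.WBS, tol=1.0)
        assert [s for s, _ in uncallable] == ["s2"]

    def test_stutter_outside_window_ignored(self):
        tsv = (
            "Sample\tSize\tHeight\tArea\n"
            "s1\t213.0\t900\t9000\n"   # stutter, > 1 bp from 214
            "s1\t214.2\t500\t5000\n"
            "s1\t218.1\t480\t4800\n"
        )
        ratios, _ = assign_peaks(parse_peak_table(tsv), catalog.WBS, tol=1.0)
        assert ratios[0].control_area == 5000

    def test_ambiguous_equidistant_peaks_error(self):
        tsv = (
            "Sample\tSize\tHeight\tArea\n"
            "s1\t213.5\t500\t5000\n"
            "s1\t214.5\t500\t5000\n"
            "s1\t218.0\t480\t4800\n"
        )
        with pytest.raises(ValueError, match="equidistant"):
            assign_peaks(parse_peak_table(tsv), catalog.WBS, tol=1.0)


class TestNormalize:
    @pytest.mark.parametrize(
        "r,ref,expected", [(0.96, 0.96, 1.0), (0.48, 0.96, 0.5), (1.92, 0.96, 2.0)]
    )
    def test_reference_division(self, r, ref, expected):
        sr = SampleRatio("s", test_area=r * 1000, control_area=1000)
        assert normalize(sr, ref).nr == pytest.approx(expected)

    def test_reference_against_itself_is_one(self):
        sr = SampleRatio("ref", 777.0, 810.0)
        assert normalize(sr, sr.ratio).nr == pytest.approx(1.0)


class TestNormalityGate:
    def test_gaussian_cohort_not_rejected(self):
        rng = np.random.default_rng(1)
        k2, p = dagostino_pearson(rng.normal(1.0, 0.05, size=500))
        assert p > 0.05

    def test_lognormal_cohort_rejected(self):
        rng = np.random.default_rng(2)
        k2, p = dagostino_pearson(rng.lognormal(0.0, 1.0, size=500))
        assert p < 0.01

    def test_small_cohort_refused(self):
        with pytest.raises(ValueError, match="n >= 20"):
            dagostino_pearson(np.arange(10))

    def test_constant_vector_refused(self):
        with pytest.raises(ValueError, match="constant"):
            dagostino_pearson(np.ones(50))


class TestScores:
    @pytest.mark.parametrize(
        "x,expected", [(0.5, -5.0), (1.0, 0.0), (1.2, 2.0)]
    )
    def test_z_arithmetic(self, x, expected):
        # cohort engineered to mean 1.0, sample sd 0.1
        cohort = [0.9, 0.95, 1.0, 1.05, 1.1]
        sd = np.std(cohort, ddof=1)
        scaled = 1.0 + (np.array(cohort) - 1.0) * (0.1 / sd)
        assert z_scores(scaled, x) == pytest.approx(expected)

    def test_pseudo_z_median_centering(self):
        assert pseudo_z([1, 2, 3, 4, 5], 3) == 0.0

    def test_pseudo_z_quartile_arithmetic(self):
        # Q1=2, Q3=4 by linear interpolation; pseudo-sd = 2/1.349
        assert pseudo_z([1, 2, 3, 4, 5], 5) == pytest.approx(1.349)

    @given(
        st.lists(st.integers(-500, 500), min_size=5, max_size=30, unique=True),
        st.integers(-500, 500),
        st.floats(0.01, 10),
        st.floats(-100, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_equivariance(self, cohort, x, a, b):
        cohort = [v / 10 for v in cohort]  # well-conditioned distinct values
        x = x / 10
        transformed = [a * v + b for v in cohort]
        try:
            expected_z = z_scores(cohort, x)
            expected_pz = pseudo_z(cohort, x)
        except ValueError:
            return
        assert z_scores(transformed, a * x + b) == pytest.approx(expected_z, abs=1e-6)
        assert pseudo_z(transformed, a * x + b) == pytest.approx(expected_pz, abs=1e-6)

    def test_zero_sd_error(self):
        with pytest.raises(ValueError):
            z_scores([1.0, 1.0, 1.0], 2.0)
        with pytest.raises(ValueError):
            pseudo_z([1.0, 1.0, 1.0, 1.0], 2.0)


def _nrs(prefix, values):
    return [NormalizedRatio(f"{prefix}{i}", v) for i, v in enumerate(values)]


class TestScoreCohort:
    def test_gaussian_controls_use_z(self):
        rng = np.random.default_rng(3)
        controls = _nrs("c", rng.normal(1.0, 0.05, size=100))
        samples = _nrs("s", [0.5, 1.0])
        scores, stats = score_cohort(controls, samples)
        assert all(s.method == "Z" for s in scores)
        assert stats.p_normal >= 0.05

    def test_skewed_controls_use_pz(self):
        rng = np.random.default_rng(4)
        controls = _nrs("c", rng.lognormal(0.0, 0.8, size=100))
        samples = _nrs("s", [0.5])
        scores, stats = score_cohort(controls, samples)
        assert all(s.method == "PZ" for s in scores)
        assert stats.p_normal < 0.05

    def test_small_cohort_routes_to_pz(self):
        controls = _nrs("c", [0.9, 0.95, 1.0, 1.05, 1.1, 0.97, 1.02, 0.99, 1.01, 1.03])
        scores, stats = score_cohort(controls, _nrs("s", [0.5]))
        assert scores[0].method == "PZ"
        assert stats.p_normal is None

    def test_duplicate_id_rejected(self):
        controls = _nrs("x", [1.0, 1.1, 0.9, 1.05])
        with pytest.raises(ValueError, match="duplicate"):
            score_cohort(controls, [NormalizedRatio("x0", 0.5)])


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([-5.1, -4.2, -3.8, 0.1, -0.5, 0.4, 1.0])
        labels = np.array([1, 1, 1, 0, 0, 0, 0], bool)
        result = roc(scores, labels, direction="deletion")
        assert result.auc == 1.0
        assert result.sensitivity == 100.0 and result.specificity == 100.0
        assert -3.8 < result.threshold < -0.5

    def test_no_information(self):
        result = roc(np.ones(6), np.array([1, 0, 1, 0, 1, 0], bool), "duplication")
        assert result.auc == pytest.approx(0.5)

    def test_two_vs_two_pair_counting(self):
        scores = np.array([3.0, 1.0, 2.0, 0.0])
        labels = np.array([1, 1, 0, 0], bool)
        result = roc(scores, labels, "duplication")
        assert result.auc == pytest.approx(concordant_pair_auc([3.0, 1.0], [2.0, 0.0]))

    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=25),
        st.lists(st.integers(-5, 5), min_size=2, max_size=25),
    )
    @settings(max_examples=150, deadline=None)
    def test_auc_equals_mann_whitney_identity(self, pos, neg):
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([True] * len(pos) + [False] * len(neg))
        result = roc(scores, labels, "duplication")
        assert result.auc == pytest.approx(concordant_pair_auc(pos, neg), abs=1e-12)

    def test_threshold_consistent_with_calls(self):
        scores = np.array([-5.0, -4.0, 0.2, -0.1])
        labels = np.array([1, 1, 0, 0], bool)
        result = roc(scores, labels, "deletion")
        calls = call_dosage(
            [Score(f"s{i}", v, "Z") for i, v in enumerate(scores)],
            result.threshold,
            "deletion",
        )
        assert [c.call == "deletion" for c in calls] == list(labels)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc(np.array([1.0, 2.0]), np.array([True, True]), "duplication")


class TestDiagnosticCIs:
    def test_ppv_lower_bound_at_14_of_14(self):
        cis = diagnostic_cis(tp=14, fp=0, tn=100, fn=0)
        assert cis.ppv.percent == 100.0
        assert cis.ppv.lo == pytest.approx(73.24, abs=0.05)
        assert cis.ppv.hi == 100.0
        assert cis.fpr.percent == 0.0
        assert cis.fpr.hi == pytest.approx(100 - cis.ppv.lo, abs=1e-9)

    def test_zero_denominator_absent(self):
        cis = diagnostic_cis(tp=0, fp=0, tn=5, fn=0)
        assert cis.ppv is None and cis.fpr is None
        assert cis.npv.percent == 100.0

    def test_lower_bound_clipped_at_zero(self):
        lo, hi = wilson_cc(0, 10)
        assert lo == 0.0 and 0 < hi < 1

    @given(st.integers(1, 60), st.integers(0, 60))
    @settings(max_examples=200, deadline=None)
    def test_interval_contains_point_estimate(self, n, x):
        x = min(x, n)
        lo, hi = wilson_cc(x, n)
        assert 0.0 <= lo <= x / n <= hi <= 1.0

    @pytest.mark.parametrize("frac", [1.0, 0.5])
    def test_interval_narrows_with_n(self, frac):
        widths = []
        for n in (10, 20, 40, 80, 160):
            x = int(round(frac * n))
            lo, hi = wilson_cc(x, n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)


class TestCallDosage:
    def test_deletion_threshold(self):
        scores = [Score("a", -5.1, "Z"), Score("b", -0.3, "Z")]
        calls = call_dosage(scores, -2.5, "deletion")
        assert [c.call for c in calls] == ["deletion", "normal"]

    def test_duplication_threshold(self):
        (call,) = call_dosage([Score("p", 6.56, "Z")], 3.0, "duplication")
        assert call.call == "duplication"

    def test_exact_threshold_is_normal(self):
        (call,) = call_dosage([Score("a", -2.5, "Z")], -2.5, "deletion")
        assert call.call == "normal"
        (call,) = call_dosage([Score("a", 3.0, "Z")], 3.0, "duplication")
        assert call.call == "normal"
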