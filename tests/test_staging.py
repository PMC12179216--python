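"""z-transformation, pattern scoring, categorization, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pspdti.errors import DegenerateDesignError, SampleSizeError, ScoringError
from pspdti.staging import (
    CATEGORIES,
    PatternScores,
    categorization_summary,
    categorize,
    diagnostic_performance,
    fit_control_reference,
    longitudinal_summary,
    nominal_specificity,
    pattern_scores,
    psprs_group_summary,
)

from conftest import make_mini_atlas


def table_from(rows, columns):
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["subject_id", "timepoint"])
    return pd.DataFrame(list(rows.values()), index=idx, columns=columns)


@pytest.fixture
def mini_atlas():
    return make_mini_atlas()


@pytest.fixture
def mini_reference(mini_atlas):
    rows = {
        ("C0", "baseline"): [0.40, 0.40, 0.40],
        ("C1", "baseline"): [0.50, 0.50, 0.50],
        ("C2", "baseline"): [0.60, 0.60, 0.60],
    }
    table = table_from(rows, mini_atlas.names)
    return fit_control_reference(table, ["C0", "C1", "C2"])


class TestControlReference:
    def test_hand_computed_mean_and_sd(self, mini_reference):
        assert np.allclose(mini_reference.mu, 0.5)
        assert np.allclose(mini_reference.sigma, 0.1)
        assert mini_reference.n_controls == 3

    def test_single_control_rejected(self, mini_atlas):
        table = table_from({("C0", "baseline"): [0.4, 0.4, 0.4]}, mini_atlas.names)
        with pytest.raises(SampleSizeError):
            fit_control_reference(table, ["C0"])

    def test_zero_variance_named(self, mini_atlas):
        rows = {
            ("C0", "baseline"): [0.4, 0.4, 0.4],
            ("C1", "baseline"): [0.4, 0.5, 0.5],
        }
        table = table_from(rows, mini_atlas.names)
        with pytest.raises(DegenerateDesignError, match="roi_p1"):
            fit_control_reference(table, ["C0", "C1"])


class TestPatternScores:
    def _score(self, mini_atlas, mini_reference, values):
        table = table_from({("S", "baseline"): values}, mini_atlas.names)
        return pattern_scores(table, mini_reference, mini_atlas)[0]

    def test_subject_at_control_mean_scores_half(self, mini_atlas, mini_reference):
        s = self._score(mini_atlas, mini_reference, [0.5, 0.5, 0.5])
        assert s.scores == pytest.approx((0.5, 0.5, 0.5))
        assert s.affected == (False, False, False)

    def test_one_sigma_below_everywhere_all_affected(self, mini_atlas, mini_reference):
        s = self._score(mini_atlas, mini_reference, [0.4, 0.4, 0.4])
        assert s.scores == pytest.approx((-0.5, -0.5, -0.5))
        assert s.affected == (True, True, True)

    def test_boundary_at_threshold_not_affected(self, mini_atlas, mini_reference):
        # exactly mu - 0.47 sigma: score 0.03 on the shifted scale, strict <
        values = [0.5 - 0.47 * 0.1] * 3
        s = self._score(mini_atlas, mini_reference, values)
        assert s.scores == pytest.approx((0.03, 0.03, 0.03), abs=1e-9)
        assert s.affected == (False, False, False)

    def test_raw_z_scale_toggle(self, mini_atlas, mini_reference):
        table = table_from({("S", "baseline"): [0.4, 0.5, 0.5]}, mini_atlas.names)
        s = pattern_scores(table, mini_reference, mini_atlas, scale="raw_z")[0]
        assert s.scores[0] == pytest.approx(-1.0)
        assert s.affected == (True, False, False)

    def test_fully_missing_pattern_is_scoring_error(self, mini_atlas, mini_reference):
        table = table_from({("S", "baseline"): [np.nan, 0.5, 0.5]}, mini_atlas.names)
        with pytest.raises(ScoringError):
            pattern_scores(table, mini_reference, mini_atlas)

    def test_mismatched_columns_rejected(self, mini_atlas, mini_reference):
        table = table_from({("S", "baseline"): [0.5, 0.5, 0.5]}, ["a", "b", "c"])
        with pytest.raises(ScoringError):
            pattern_scores(table, mini_reference, mini_atlas)


class TestCategorize:
    @pytest.mark.parametrize(
        "affected,expected",
        [
            ((True, False, False), "CSalpha"),
            ((True, False, True), "CSalpha"),  # pattern 3 ignored for CS-alpha
            ((True, True, False), "CSbeta"),
            ((True, True, True), "CSchi"),
            ((False, False, False), "uncategorized"),
            ((False, True, True), "uncategorized"),
            ((False, True, False), "uncategorized"),
            ((False, False, True), "uncategorized"),
        ],
    )
    def test_rule_table_exhaustive(self, affected, expected):
        s = PatternScores("S", "baseline", (0.0, 0.0, 0.0), affected)
        assert categorize(s).category == expected

    def test_rule_table_mutually_exclusive_and_total(self):
        seen = set()
        import itertools

        for bits in itertools.product([False, True], repeat=3):
            cat = categorize(PatternScores("S", "baseline", (0, 0, 0), bits)).category
            assert cat in CATEGORIES
            seen.add((bits, cat))
        assert len(seen) == 8  # one category per combination

    @given(
        st.floats(-3, 0.029),
        st.tuples(st.floats(-3, 3), st.floats(-3, 3)),
        st.tuples(st.floats(0, 3), st.floats(0, 3)),
    )
    @settings(deadline=None)
    def test_lowering_scores_never_moves_category_backward(self, s1, others, drops):
        """With pattern 1 affected, decreasing scores 2 and 3 only advances
        the step along CS-alpha -> CS-beta -> CS-chi."""
        threshold = 0.03
        order = {"CSalpha": 0, "CSbeta": 1, "CSchi": 2}

        def cat(s2, s3):
            affected = (True, s2 < threshold, s3 < threshold)
            return categorize(PatternScores("S", "b", (s1, s2, s3), affected)).category

        before = cat(*others)
        after = cat(others[0] - drops[0], others[1] - drops[1])
        if before != "CSalpha" or after != "CSalpha":
            assert order[after] >= order[before]


class TestNominalSpecificity:
    def test_default_offset_rounds_to_68_percent(self):
        assert round(nominal_specificity(0.47), 2) == 0.68

    def test_zero_offset_is_half(self):
        assert nominal_specificity(0.0) == pytest.approx(0.5)

    def test_large_offset_tends_to_one(self):
        assert nominal_specificity(50.0) == pytest.approx(1.0)

    def test_monte_carlo_fraction_matches_normal_cdf(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=100_000)
        fraction = (z > -0.47).mean()
        assert abs(fraction - stats.norm.cdf(0.47)) < 0.005


class TestDiagnosticPerformance:
    def _scores(self, n, affected):
        return [
            PatternScores(f"S{i}", "baseline", (0, 0, 0), (a, a, a))
            for i, a in zip(range(n), affected)
        ]

    def test_specificity_49_of_63(self):
        controls = self._scores(63, [False] * 49 + [True] * 14)
        patients = self._scores(1, [True])
        patients = [PatternScores("P0", "baseline", (0, 0, 0), (True, True, True))]
        groups = {s.subject_id: "control" for s in controls}
        groups["P0"] = "psp"
        perf = diagnostic_performance(controls + patients, groups)
        assert perf.loc[1, "specificity_pct"] == pytest.approx(77.8, abs=0.05)

    def test_sensitivity_65_of_66(self):
        controls = [PatternScores(f"C{i}", "baseline", (0, 0, 0), (False,) * 3) for i in range(5)]
        patients = [
            PatternScores(f"P{i}", "baseline", (0, 0, 0), (i < 65,) * 3) for i in range(66)
        ]
        groups = {s.subject_id: "control" for s in controls}
        groups.update({s.subject_id: "psp" for s in patients})
        perf = diagnostic_performance(controls + patients, groups)
        assert perf.loc[1, "sensitivity_pct"] == pytest.approx(98.5, abs=0.05)

    def test_all_controls_unaffected_full_specificity(self):
        controls = [PatternScores(f"C{i}", "baseline", (0, 0, 0), (False,) * 3) for i in range(4)]
        patients = [PatternScores("P0", "baseline", (0, 0, 0), (True,) * 3)]
        groups = {**{s.subject_id: "control" for s in controls}, "P0": "psp"}
        perf = diagnostic_performance(controls + patients, groups)
        assert (perf.specificity_pct == 100.0).all()

    def test_counts_match_brute_force_on_random_labels(self):
        rng = np.random.default_rng(5)
        scores = [
            PatternScores(
                f"S{i}", "baseline", (0, 0, 0), tuple(rng.random(3) < 0.5)
            )
            for i in range(50)
        ]
        groups = {s.subject_id: ("psp" if rng.random() < 0.5 else "control") for s in scores}
        if not any(g == "psp" for g in groups.values()):
            groups["S0"] = "psp"
        if not any(g == "control" for g in groups.values()):
            groups["S1"] = "control"
        perf = diagnostic_performance(scores, groups)
        for k in range(3):
            controls = [s for s in scores if groups[s.subject_id] == "control"]
            patients = [s for s in scores if groups[s.subject_id] == "psp"]
            spec = 100 * len([s for s in controls if not s.affected[k]]) / len(controls)
            sens = 100 * len([s for s in patients if s.affected[k]]) / len(patients)
            assert perf.loc[k + 1, "specificity_pct"] == pytest.approx(spec)
            assert perf.loc[k + 1, "sensitivity_pct"] == pytest.approx(sens)


class TestCategorizationSummary:
    def _results(self, counts):
        out = []
        i = 0
        for cat, n in zip(CATEGORIES, counts):
            from pspdti.staging import CategoryResult

            for _ in range(n):
                out.append(CategoryResult(f"S{i}", "baseline", cat))
                i += 1
        return out

    def test_cohort_counts_give_89_7_percent(self):
        summary = categorization_summary(self._results((14, 14, 42, 8)))
        assert summary["total"] == 78
        assert summary["categorized_pct"] == pytest.approx(100 * 70 / 78, abs=1e-9)
        assert round(summary["categorized_pct"], 1) == 89.7

    def test_pooled_counts_give_93_8_percent(self):
        summary = categorization_summary(self._results((26, 17, 92, 9)))
        assert summary["total"] == 144
        assert round(summary["categorized_pct"], 1) == 93.8

    def test_empty_input(self):
        summary = categorization_summary([])
        assert summary["total"] == 0 and summary["categorized_pct"] == 0.0


class TestPSPRSSummary:
    def _scores(self, values):
        return [
            PatternScores(f"P{i}", "baseline", tuple(v), (True, True, True))
            for i, v in enumerate(values)
        ]

    def test_single_patient_per_group(self):
        scores = self._scores([(-0.5, -0.3, -0.1), (-0.8, -0.5, -0.3), (-1.2, -1.0, -0.6)])
        stages = {"P0": 1, "P1": 2, "P2": 3}
        out = psprs_group_summary(scores, stages)
        assert out.loc["1", "pattern1"] == pytest.approx(-0.5)
        assert out.loc["3+4", "pattern3"] == pytest.approx(-0.6)

    def test_stage_4_pooled_with_3(self):
        scores = self._scores([(-1.0, -1.0, -1.0), (-2.0, -2.0, -2.0)])
        out = psprs_group_summary(scores, {"P0": 3, "P1": 4})
        assert out.loc["3+4", "n"] == 2
        assert out.loc["3+4", "pattern1"] == pytest.approx(-1.5)

    def test_identical_patients_equal_means(self):
        scores = self._scores([(-1.0, -0.5, -0.2)] * 4)
        out = psprs_group_summary(scores, {"P0": 1, "P1": 1, "P2": 2, "P3": 3})
        assert np.allclose(out.pattern1, -1.0)

    def test_severity_monotone_in_generated_cohort(self):
        """Group means fall from severity group 1 to 3+4 in every pattern
        when the generator ties lesion depth to stage."""
        from pspdti.staging import fit_control_reference, pattern_scores
        from pspdti.synthetic import simulate_cohort
        from pspdti.tract import build_structure_table

        from conftest import age_corrected_maps
        from pspdti.synthetic import LesionModel

        atlas = make_mini_atlas()
        # a clearly graded severity profile so the group ordering is the
        # signal, not the noise (patterns have a single structure here)
        lesions = LesionModel(
            stage_offsets={1: (-0.02, -0.03, -0.04), 2: (0.0, -0.02, -0.03), 3: (0.0, 0.0, -0.02)}
        )
        cohort = simulate_cohort(50, {1: 50, 2: 50, 3: 50}, lesions=lesions, atlas=atlas, seed=9)
        table = build_structure_table(atlas, {}, age_corrected_maps(cohort))
        ref = fit_control_reference(table, cohort.control_ids)
        scores = pattern_scores(table, ref, atlas)
        stages = {
            r.subject_id: r.psprs_stage for r in cohort.records if r.group == "psp"
        }
        out = psprs_group_summary([s for s in scores if s.subject_id in stages], stages)
        for pattern in ("pattern1", "pattern2", "pattern3"):
            vals = out[pattern].to_numpy()
            # the most severe group always sits lowest
            assert vals[2] < vals[0] and vals[2] < vals[1]
        # patterns 2 and 3 are untouched at stage 1, so the mild group sits
        # near the control level while later groups have moved well below
        assert out.loc["1", "pattern2"] > out.loc["2", "pattern2"]
        assert out.loc["2", "pattern3"] > out.loc["3+4", "pattern3"]


class TestLongitudinal:
    def _scores(self, sid, baseline, followup):
        return [
            PatternScores(sid, "baseline", baseline, (True, True, True)),
            PatternScores(sid, "followup", followup, (True, True, True)),
        ]

    def test_identical_timepoints_give_zero_delta_and_floor(self, mini_atlas):
        scores = self._scores("P0", (-0.5, -0.3, -0.1), (-0.5, -0.3, -0.1))
        rows = {
            ("C0", "baseline"): [0.5, 0.5, 0.5],
            ("C0", "followup"): [0.5, 0.5, 0.5],
        }
        table = table_from(rows, mini_atlas.names)
        out = longitudinal_summary(scores, table, ["C0"], ["P0"])
        assert out.delta_scores == pytest.approx((0.0, 0.0, 0.0))
        assert out.retest_floor_mean == pytest.approx(0.0)

    def test_progression_lowers_newly_affected_patterns(self):
        scores = self._scores("P0", (-1.0, 0.4, 0.5), (-1.3, -0.8, 0.4))
        table = table_from({("C0", "baseline"): [0.5] * 3}, make_mini_atlas().names)
        out = longitudinal_summary(scores, table, [], ["P0"])
        assert out.delta_scores[0] < 0 and out.delta_scores[1] < 0
        assert np.isnan(out.retest_floor_mean)

    def test_retest_floor_matches_half_normal_expectation(self, mini_atlas):
        """Pure retest noise of SD 0.007 per structure: the mean absolute
        difference lands near 0.007*sqrt(2/pi), inside (0.002, 0.012)."""
        rng = np.random.default_rng(0)
        n_controls, n_structures = 17, 36
        columns = [f"s{i}" for i in range(n_structures)]
        rows = {}
        for i in range(n_controls):
            base = 0.4 + rng.normal(0, 0.01, n_structures)
            rows[(f"C{i}", "baseline")] = base
            rows[(f"C{i}", "followup")] = base + rng.normal(0, 0.007, n_structures)
        table = table_from(rows, columns)
        scores = self._scores("P0", (0, 0, 0), (0, 0, 0))
        out = longitudinal_summary(scores, table, [f"C{i}" for i in range(n_controls)], ["P0"])
        assert 0.002 < out.retest_floor_mean < 0.012
        assert out.n_control_pairs == n_controls

    def test_no_paired_patients_rejected(self, mini_atlas):
        table = table_from({("C0", "baseline"): [0.5] * 3}, mini_atlas.names)
        with pytest.raises(SampleSizeError):
            longitudinal_summary([], table, ["C0"], ["P0"])
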