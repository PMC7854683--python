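"""Position/transition matrices, group differences, J–S profiles,
deviation heatmaps — hand examples, invariants, and brute-force oracle
equivalence."""

import numpy as np
import pytest

from conftest import (
    brute_deviation,
    brute_position_counts,
    brute_transition_counts,
    js_distance_by_hand,
    random_cohort,
)
from coursetrace import (
    Cohort,
    LearnerRecord,
    TaskCatalog,
    delta_transition,
    deviation_matrix,
    js_profile,
    position_probability_matrix,
    transition_summary,
)


def nominal_cohort(T: int, n_learners: int = 3) -> Cohort:
    catalog = TaskCatalog(session_of=(1,) * T, type_of=("quiz",) * T)
    seq = tuple(range(1, T + 1))
    return Cohort(
        catalog,
        tuple(LearnerRecord(f"L{k}", seq) for k in range(n_learners)),
    )


class TestPositionMatrix:
    def test_all_nominal_cohort_gives_identity(self):
        pm = position_probability_matrix(nominal_cohort(5))
        assert np.allclose(pm.P, np.eye(5))
        assert not pm.never_completed.any()

    def test_hand_counted_rows(self, tiny_cohort):
        pm = position_probability_matrix(tiny_cohort)
        assert np.allclose(pm.P[0], [2 / 3, 1 / 3, 0])
        assert np.allclose(pm.P[2], [0, 1 / 3, 2 / 3])

    def test_never_completed_task_flagged_zero_row(self, tiny_catalog):
        cohort = Cohort(tiny_catalog, (LearnerRecord("A", (1, 3)),))
        pm = position_probability_matrix(cohort)
        assert pm.never_completed[1]
        assert np.all(pm.P[1] == 0)

    def test_defined_rows_sum_to_one(self):
        for seed in range(5):
            pm = position_probability_matrix(random_cohort(seed))
            sums = pm.P.sum(axis=1)
            assert np.allclose(sums[~pm.never_completed], 1.0, atol=1e-12)


class TestTransitionSummary:
    def test_hand_counted_task_level(self, tiny_cohort):
        ts = transition_summary(tiny_cohort, "task", include_start=False)
        assert ts.counts[0, 1] == 1 and ts.counts[1, 2] == 1
        assert ts.counts[1, 0] == 1 and ts.counts[0, 2] == 2
        assert ts.counts.sum() == 5
        assert ts.joint[0, 2] == pytest.approx(0.4)
        assert np.allclose(ts.conditional[0], [0, 1 / 3, 2 / 3])

    def test_session_coarse_graining_by_substitution(self):
        catalog = TaskCatalog(session_of=(1, 1, 2, 2), type_of=("quiz",) * 4)
        cohort = Cohort(catalog, (LearnerRecord("A", (1, 2, 3, 4)),))
        ss = transition_summary(cohort, "session")
        assert ss.include_start and ss.states == (0, 1, 2)
        # session sequence (1,1,2,2): from session 1 -> {1: 1/2, 2: 1/2}
        assert np.allclose(ss.conditional[1], [0, 0.5, 0.5])

    def test_single_completion_degenerate(self, tiny_catalog):
        cohort = Cohort(tiny_catalog, (LearnerRecord("A", (2,)),))
        ts = transition_summary(cohort, "task", include_start=False)
        assert ts.counts.sum() == 0
        assert np.all(np.isnan(ts.conditional))

    def test_joint_conserved_and_rows_normalised(self):
        for seed in range(8):
            cohort = random_cohort(seed)
            for res in ("task", "session"):
                ts = transition_summary(cohort, res)
                if ts.counts.sum():
                    assert ts.joint.sum() == pytest.approx(1.0, abs=1e-12)
                rows = ts.conditional[ts.row_defined]
                assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-12)

    def test_task_diagonal_is_zero(self):
        for seed in range(5):
            ts = transition_summary(random_cohort(seed), "task")
            assert np.all(np.diag(ts.counts) == 0)

    def test_nominal_cohort_superdiagonal(self):
        ts = transition_summary(nominal_cohort(5), "task", include_start=False)
        expected = np.zeros((5, 5))
        expected[np.arange(4), np.arange(1, 5)] = 1.0
        cond = np.where(np.isnan(ts.conditional), 0.0, ts.conditional)
        assert np.allclose(cond, expected)

    def test_matches_brute_force_recount(self):
        for seed in range(10):
            cohort = random_cohort(seed)
            for res in ("task", "session"):
                for start in (False, True):
                    ts = transition_summary(cohort, res, include_start=start)
                    brute = brute_transition_counts(cohort, res, start)
                    offset = 1 if start else 0
                    for (a, b), c in brute.items():
                        assert ts.counts[a - 1 + offset, b - 1 + offset] == c
                    assert ts.counts.sum() == sum(brute.values())

    def test_position_matches_brute_force_recount(self):
        for seed in range(10):
            cohort = random_cohort(seed)
            pm = position_probability_matrix(cohort)
            brute = brute_position_counts(cohort)
            for (task, pos), c in brute.items():
                assert pm.counts[task - 1, pos - 1] == c
            assert pm.counts.sum() == sum(brute.values())

    def test_learner_order_invariance(self, tiny_cohort):
        flipped = Cohort(tiny_cohort.catalog, tiny_cohort.learners[::-1])
        a = transition_summary(tiny_cohort, "task")
        b = transition_summary(flipped, "task")
        assert np.array_equal(a.counts, b.counts)
        pa = position_probability_matrix(tiny_cohort)
        pb = position_probability_matrix(flipped)
        assert np.array_equal(pa.counts, pb.counts)


class TestDeltaTransition:
    def test_identical_matrices_zero_parts(self, tiny_cohort):
        ts = transition_summary(tiny_cohort, "session")
        delta, pos, neg = delta_transition(ts, ts)
        assert np.nansum(pos) == 0 and np.nansum(neg) == 0

    def test_disjoint_rows_split_cleanly(self, tiny_catalog):
        a = Cohort(tiny_catalog, (LearnerRecord("A", (1, 2)),))
        b = Cohort(tiny_catalog, (LearnerRecord("B", (1, 3)),))
        ta = transition_summary(a, "task", include_start=False)
        tb = transition_summary(b, "task", include_start=False)
        delta, pos, neg = delta_transition(ta, tb)
        assert pos[0, 1] == 1.0 and neg[0, 2] == 1.0
        # rows with no outgoing transitions in either matrix are missing
        assert np.isnan(pos[2]).all() and np.isnan(neg[2]).all()

    def test_mismatched_states_rejected(self, tiny_cohort):
        ts = transition_summary(tiny_cohort, "task")
        ss = transition_summary(tiny_cohort, "session")
        with pytest.raises(ValueError):
            delta_transition(ts, ss)


class TestJSProfile:
    def test_identical_matrices_all_zero(self, tiny_cohort):
        ts = transition_summary(tiny_cohort, "session")
        prof = js_profile(ts, ts)
        defined = ~np.isnan(prof.row_distances)
        assert defined.any()
        assert np.all(prof.row_distances[defined] == 0)
        assert prof.mean_outgoing == 0.0

    def test_disjoint_support_gives_one(self, tiny_catalog):
        a = Cohort(tiny_catalog, (LearnerRecord("A", (1, 2)),))
        b = Cohort(tiny_catalog, (LearnerRecord("B", (1, 3)),))
        ta = transition_summary(a, "task", include_start=False)
        tb = transition_summary(b, "task", include_start=False)
        prof = js_profile(ta, tb)
        assert prof.row_distances[0] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_value(self):
        # row (1,0) vs (0.5,0.5): divergence H(.75,.25) - 0.5 bits
        assert js_distance_by_hand([1, 0], [0.5, 0.5]) == pytest.approx(
            0.5579230452841438, abs=1e-12
        )
        cat = TaskCatalog(session_of=(1, 1, 1), type_of=("quiz",) * 3)
        a = Cohort(cat, (LearnerRecord("A", (1, 2)), LearnerRecord("B", (1, 2))))
        b = Cohort(cat, (LearnerRecord("C", (1, 2)), LearnerRecord("D", (1, 3))))
        ta = transition_summary(a, "task", include_start=False)
        tb = transition_summary(b, "task", include_start=False)
        prof = js_profile(ta, tb)
        assert prof.row_distances[0] == pytest.approx(0.558, abs=1e-3)

    def test_symmetry_bounds_and_oracle_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            cat = TaskCatalog(session_of=(1,) * 4, type_of=("quiz",) * 4)
            from coursetrace.ensemble_stats import _js_distance

            d = _js_distance(p, q)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(_js_distance(q, p), abs=1e-14)
            assert d == pytest.approx(js_distance_by_hand(p, q), abs=1e-10)

    def test_triangle_inequality_spot_check(self):
        from coursetrace.ensemble_stats import _js_distance

        rng = np.random.default_rng(11)
        for _ in range(30):
            p, q, r = (rng.dirichlet(np.ones(5)) for _ in range(3))
            assert _js_distance(p, r) <= _js_distance(p, q) + _js_distance(
                q, r
            ) + 1e-12


class TestDeviationMatrix:
    def test_all_nominal_full_completion_is_zero_row(self):
        dev = deviation_matrix(nominal_cohort(6, n_learners=1), order_by="id")
        assert np.allclose(dev.D[0], 0.0)

    def test_hand_example(self, tiny_catalog):
        cohort = Cohort(tiny_catalog, (LearnerRecord("A", (1, 3)),))
        dev = deviation_matrix(cohort, order_by="id")
        assert dev.D[0, 0] == pytest.approx(1 / 2 - 1 / 3)
        assert dev.D[0, 1] == pytest.approx(0.0)
        assert np.isnan(dev.D[0, 2])

    def test_empty_sequence_fully_absent(self, tiny_catalog):
        cohort = Cohort(
            tiny_catalog,
            (LearnerRecord("A", ()), LearnerRecord("B", (1,))),
        )
        dev = deviation_matrix(cohort, order_by="id")
        assert np.isnan(dev.D[0]).all()
        assert dev.completed_length[0] == 0

    def test_entries_bounded_and_match_oracle(self):
        for seed in range(10):
            cohort = random_cohort(seed)
            dev = deviation_matrix(cohort, order_by="id")
            finite = dev.D[np.isfinite(dev.D)]
            assert np.all(finite > -1) and np.all(finite < 1)
            brute = brute_deviation(cohort)
            for k, lid in enumerate(dev.learner_ids):
                vals = brute[lid]
                assert np.allclose(dev.D[k, : len(vals)], vals)

    def test_grade_ordering_descending(self, tiny_cohort):
        dev = deviation_matrix(tiny_cohort, order_by="grade")
        assert dev.learner_ids == ("A", "B", "C")
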