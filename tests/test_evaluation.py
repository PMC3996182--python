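"""Success metrics, fold planning and the cross-validation harness."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventdss.evaluation import (
    classification_success,
    cross_validate,
    kfold_indices,
    overall_accuracy,
    regression_success,
)
from ventdss.training import TrainConfig


class TestFoldPlans:
    def test_singleton_folds(self):
        plan = kfold_indices(10, 10, seed=0)
        assert sorted(len(f) for f in plan.folds) == [1] * 10

    def test_158_over_10(self):
        plan = kfold_indices(158, 10, seed=1)
        assert sorted(len(f) for f in plan.folds) == [15, 15] + [16] * 8

    def test_deterministic(self):
        assert kfold_indices(50, 5, seed=3) == kfold_indices(50, 5, seed=3)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 6, seed=0)

    @given(st.integers(4, 200), st.integers(2, 10), st.integers(0, 1000))
    @settings(max_examples=100, deadline=None)
    def test_plan_invariants(self, n, k, seed):
        if k > n:
            return
        plan = kfold_indices(n, k, seed)
        flat = [i for fold in plan.folds for i in fold]
        assert sorted(flat) == list(range(n))  # disjoint and complete
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1


class TestSuccessMetrics:
    def test_perfect_prediction(self):
        out = regression_success(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]),
                                 np.array([10.0, 10.0]))
        np.testing.assert_array_equal(out, [100.0, 100.0])

    def test_error_equal_to_range_scores_zero(self):
        out = regression_success(np.array([[5.0]]), np.array([[0.0]]), 5.0)
        assert out[0] == 0.0

    def test_half_range_average(self):
        pred = np.array([[0.0], [5.0]])
        true = np.array([[0.0], [0.0]])
        assert regression_success(pred, true, 10.0)[0] == pytest.approx(75.0)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            regression_success(np.array([[1.0]]), np.array([[1.0]]), 0.0)

    def test_tolerance_mode(self):
        pred = np.array([[0.4], [3.0]])
        true = np.array([[0.0], [0.0]])
        out = regression_success(pred, true, 10.0, mode="tolerance",
                                 tolerance_fraction=0.05)
        assert out[0] == pytest.approx(50.0)

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=20),
        st.floats(0.5, 10.0),
        st.floats(-50, 50),
    )
    @settings(max_examples=100)
    def test_affine_invariance(self, truths, scale, shift):
        y = np.asarray(truths)[:, None]
        rng = np.random.default_rng(0)
        pred = y + rng.normal(size=y.shape)
        base = regression_success(pred, y, 200.0)
        rescaled = regression_success(pred * scale + shift, y * scale + shift,
                                      200.0 * scale)
        np.testing.assert_allclose(base, rescaled, atol=1e-9)

    def test_classification_success(self):
        assert classification_success([1, 1, 0], [1, 1, 0]) == 100.0
        assert classification_success([1, 0, 0, 0], [0, 0, 0, 0]) == 75.0
        with pytest.raises(ValueError):
            classification_success([], [])

    def test_classification_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        pred = rng.integers(0, 2, size=50)
        true = rng.permutation(pred)
        expected = 100.0 * sum(int(p == t) for p, t in zip(pred, true)) / 50
        assert classification_success(pred, true) == pytest.approx(expected)


class TestOverallAccuracy:
    def test_extremes(self):
        assert overall_accuracy([100, 100, 100, 100]) == 100.0
        assert overall_accuracy([0, 0, 0, 0]) == 0.0

    def test_best_published_rates_aggregate(self):
        # best per-output rates across the published configuration table:
        # frequency 99.81, tidal volume 99.54, FiO2 100 (sequential-order
        # row), mode classification 94.40 (Bayesian regularization)
        assert overall_accuracy([99.81, 99.54, 100.0, 94.40]) == 98.44

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            overall_accuracy([101, 0, 0, 0])


@pytest.fixture(scope="module")
def small_cohort():
    from ventdss.synthetic import CohortSpec, generate_cohort

    sizes = {"COPD": 12, "ARDS": 14, "CVD": 14}
    tables = _shrunk_tables(sizes)
    return generate_cohort(CohortSpec(seed=2, sizes=sizes, tables=tables))


def _shrunk_tables(sizes):
    """Reference tables scaled down proportionally to small group sizes."""
    from ventdss.bayes import FINDING_NAMES, FindingTable, load_reference_tables

    out = []
    for t in load_reference_tables():
        n = sizes[t.disease]
        counts = [int(round(p * n)) for p in t.probabilities]
        ps = FINDING_NAMES.index("pressure_support")
        vs = FINDING_NAMES.index("volume_support")
        counts[vs] = n - counts[ps]
        out.append(FindingTable(t.disease, n, tuple(counts)))
    return out


class TestCrossValidation:
    CONFIG = TrainConfig(algorithm="lm", hidden_units=4, max_epochs=10, seed=0)

    def test_reported_stats_recomputable(self, small_cohort):
        report = cross_validate(small_cohort, self.CONFIG, k=5, seed=0)
        for stats in report.per_output.values():
            assert stats.mean == pytest.approx(np.mean(stats.fold_scores), abs=1e-9)
            assert stats.std == pytest.approx(
                np.std(stats.fold_scores, ddof=1), abs=1e-9
            )
            assert len(stats.fold_scores) == 5
            assert all(0.0 <= v <= 100.0 for v in stats.fold_scores)

    def test_deterministic(self, small_cohort):
        a = cross_validate(small_cohort, self.CONFIG, k=5, seed=0)
        b = cross_validate(small_cohort, self.CONFIG, k=5, seed=0)
        for name in a.per_output:
            assert a.per_output[name].fold_scores == b.per_output[name].fold_scores

    def test_heldout_fold_never_leaks_into_training(self, small_cohort):
        """Flipping every mode label in one held-out fold must complement that
        fold's classification score exactly: if the trained model had seen the
        corrupted labels, its predictions (and hence the complement identity)
        would break."""
        plan = kfold_indices(len(small_cohort), 5, seed=0)
        victim_fold = 0
        victim = set(plan.folds[victim_fold])
        corrupted = [
            dataclasses.replace(
                rec, support_mode="VS" if rec.support_mode == "PS" else "PS"
            )
            if i in victim
            else rec
            for i, rec in enumerate(small_cohort)
        ]
        base = cross_validate(small_cohort, self.CONFIG, k=5, seed=0)
        poisoned = cross_validate(corrupted, self.CONFIG, k=5, seed=0)
        base_score = base.per_output["ps_vs"].fold_scores[victim_fold]
        poisoned_score = poisoned.per_output["ps_vs"].fold_scores[victim_fold]
        assert poisoned_score == pytest.approx(100.0 - base_score, abs=1e-9)
        # regression targets in the held-out fold equally cannot influence
        # the model: the fitted parameters are identical either way
        from ventdss.estimators import SupportModeClassifier
        from ventdss.network import flatten
        from ventdss.records import cohort_to_matrix, cohort_to_targets

        train_idx = [i for i in range(len(small_cohort)) if i not in victim]
        models = []
        for cohort in (small_cohort, corrupted):
            rows = [cohort[i] for i in train_idx]
            X = cohort_to_matrix(rows)
            _, modes = cohort_to_targets(rows)
            clf = SupportModeClassifier(
                hidden_units=4, algorithm="lm", max_epochs=10, random_state=0
            ).fit(X, modes)
            models.append(flatten(clf.model_))
        np.testing.assert_array_equal(models[0], models[1])

    def test_incomplete_outputs_rejected(self, small_cohort):
        broken = [dataclasses.replace(small_cohort[0], frequency=None)] + list(
            small_cohort[1:]
        )
        with pytest.raises(ValueError):
            cross_validate(broken, self.CONFIG, k=5, seed=0)


class TestSweep:
    def test_single_entry_matches_direct_call(self, small_cohort):
        from ventdss.training import sweep_hidden_units

        frame = sweep_hidden_units(small_cohort, "lm", [4], folds=5, seed=0,
                                   max_epochs=10)
        direct = cross_validate(
            small_cohort,
            TrainConfig(algorithm="lm", hidden_units=4, max_epochs=10, seed=0),
            k=5,
            seed=0,
        )
        assert len(frame) == 1
        for name, stats in direct.per_output.items():
            assert frame.iloc[0][name] == pytest.approx(stats.mean)

    def test_empty_unit_list_rejected(self, small_cohort):
        from ventdss.training import sweep_hidden_units

        with pytest.raises(ValueError):
            sweep_hidden_units(small_cohort, "lm", [], folds=5, seed=0)
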