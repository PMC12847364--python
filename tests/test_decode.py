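"""Scenario enumeration, discretization, mRMR (vs brute force), CV decoding."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import cross_val_score

from sibci.config import AnalysisConfig
from sibci.decode import (
    ScenarioSpec,
    crossvalidate_scenario,
    discretize_features,
    enumerate_scenarios,
    mrmr_select,
    mutual_information,
    train_classifier,
)
from sibci.fbcsp import (
    FilterBankSpec,
    apply_filterbank,
    design_filterbank,
    extract_logvar_features,
    fit_csp,
)
from sibci.stats import chance_band


class TestScenarios:
    def test_counts_match_table_layouts(self):
        assert len(enumerate_scenarios(2)) == 21
        assert len(enumerate_scenarios(4)) == 25
        assert len(enumerate_scenarios(5)) == 11
        assert len(enumerate_scenarios(6)) == 2

    def test_si_pair_allowed_only_in_binary(self):
        pairs = {s.tasks for s in enumerate_scenarios(2)}
        assert ("SIkin", "SInoKin") in pairs
        for k in (4, 5, 6):
            for s in enumerate_scenarios(k):
                assert not {"SIkin", "SInoKin"} <= set(s.tasks)

    def test_six_class_scenarios_are_the_two_si_variants(self):
        six = enumerate_scenarios(6)
        assert {frozenset(s.tasks) for s in six} == {
            frozenset({"L", "R", "F", "T", "SIkin", "REST"}),
            frozenset({"L", "R", "F", "T", "SInoKin", "REST"}),
        }

    def test_invalid_sizes_and_specs_rejected(self):
        with pytest.raises(ValueError):
            enumerate_scenarios(3)
        with pytest.raises(ValueError):
            ScenarioSpec(("L",))
        with pytest.raises(ValueError):
            ScenarioSpec(("L", "R", "SIkin", "SInoKin"))
        with pytest.raises(ValueError):
            ScenarioSpec(("L", "XX"))

    def test_enumeration_is_deterministic(self):
        assert [s.name for s in enumerate_scenarios(4)] == [
            s.name for s in enumerate_scenarios(4)
        ]


class TestDiscretize:
    def test_equal_frequency_bins(self, rng):
        x = rng.standard_normal((100, 3))
        codes, edges = discretize_features(x, 5)
        for j in range(3):
            counts = np.bincount(codes[:, j], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_training_edges_reused_on_test_data(self, rng):
        train = rng.standard_normal((50, 2))
        codes_tr, edges = discretize_features(train, 4)
        codes_again, _ = discretize_features(train, 4, edges=edges)
        np.testing.assert_array_equal(codes_tr, codes_again)
        test = rng.standard_normal((20, 2)) * 10
        codes_te, _ = discretize_features(test, 4, edges=edges)
        assert codes_te.min() >= 0 and codes_te.max() <= 3

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal((60, 1))
        c1, _ = discretize_features(x, 5)
        c2, _ = discretize_features(np.exp(3 * x), 5)
        np.testing.assert_array_equal(c1, c2)

    def test_constant_column_single_bin(self):
        codes, edges = discretize_features(np.ones((30, 1)), 5)
        assert len(np.unique(codes)) == 1


def _mi_oracle(a, b):
    """Independent plug-in MI from an explicit contingency table."""
    import itertools

    n = len(a)
    mi = 0.0
    for va, vb in itertools.product(np.unique(a), np.unique(b)):
        pab = np.mean((a == va) & (b == vb))
        if pab > 0:
            mi += pab * np.log(pab / (np.mean(a == va) * np.mean(b == vb)))
    return mi


def _mrmr_oracle(Xd, y, k):
    """Brute-force greedy MID: recompute every score sum from scratch."""
    n = Xd.shape[1]
    selected = []
    while len(selected) < k:
        best, best_score = None, -np.inf
        for j in range(n):
            if j in selected:
                continue
            rel = _mi_oracle(Xd[:, j], y)
            red = (
                np.mean([_mi_oracle(Xd[:, j], Xd[:, s]) for s in selected])
                if selected
                else 0.0
            )
            score = rel - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
    return selected


class TestMRMR:
    def test_mutual_information_matches_oracle(self, rng):
        a = rng.integers(0, 4, 200)
        b = (a + rng.integers(0, 2, 200)) % 4
        assert mutual_information(a, b) == pytest.approx(_mi_oracle(a, b), abs=1e-12)

    def test_single_feature_selected_regardless_of_mi(self, rng):
        Xd = rng.integers(0, 5, (30, 1))
        y = rng.integers(0, 2, 30)
        assert mrmr_select(Xd, y, 1) == [0]

    def test_redundancy_penalty_orders_copy_after_noisy_feature(self, rng):
        """A≈label, B=copy of A, C=independently noisy label, D=noise.

        After picking A, the MID score of B is I(A;y) - H(A) (strongly
        negative) while C retains I(C;y) - I(C;A) > score(B), so the
        redundant copy is demoted below the noisy-but-fresh feature.
        A must carry *some* noise: were A identical to y, every remaining
        score would tie at zero and the ordering would be the index
        tie-break, not a redundancy effect.
        """
        n = 400
        y = rng.integers(0, 2, n)
        a = np.where(rng.random(n) < 0.05, 1 - y, y)
        b = a.copy()
        c = np.where(rng.random(n) < 0.3, rng.integers(0, 2, n), y)
        d = rng.integers(0, 2, n)
        Xd = np.column_stack([a, b, c, d])
        order = mrmr_select(Xd, y, 4)
        assert order[0] == 0
        assert order.index(2) < order.index(1)
        assert order == _mrmr_oracle(Xd, y, 4)

    @pytest.mark.parametrize("n_feat", [6, 12])
    def test_matches_bruteforce_on_random_tables(self, rng, n_feat):
        Xd = rng.integers(0, 4, (80, n_feat))
        y = rng.integers(0, 3, 80)
        assert mrmr_select(Xd, y, n_feat) == _mrmr_oracle(Xd, y, n_feat)

    def test_k_25_of_90_unique_indices(self, rng):
        Xd = rng.integers(0, 5, (60, 90))
        y = rng.integers(0, 6, 60)
        sel = mrmr_select(Xd, y, 25)
        assert len(sel) == 25 and len(set(sel)) == 25

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mrmr_select(np.empty((0, 0)), np.array([]), 1)


class TestClassifier:
    def test_separable_toy_data_fits_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        clf = train_classifier(X, y, AnalysisConfig(), seed=0)
        assert (clf.predict(X) == y).mean() == 1.0
        assert clf.n_estimators == 100

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_classifier(rng.standard_normal((10, 2)), np.zeros(10), AnalysisConfig(), 0)


class TestCrossValidation:
    def test_five_by_ten_folds_and_confusion_bookkeeping(self, tiny_epochs):
        cfg = AnalysisConfig(n_repeats=5)
        res = crossvalidate_scenario(tiny_epochs, ScenarioSpec(("L", "R")), cfg, seed=1)
        assert res.fold_accuracies.shape == (5, 10)
        # each trial is tested once per repeat; averaging over repeats makes
        # confusion rows sum to per-class trial counts
        np.testing.assert_allclose(res.confusion.sum(axis=1), [10.0, 10.0])
        assert res.confusion.sum() == 20.0
        assert 0 <= res.mean_accuracy <= 100

    def test_identical_seed_reproduces_everything(self, tiny_epochs, fast_analysis):
        sc = ScenarioSpec(("F", "REST"))
        r1 = crossvalidate_scenario(tiny_epochs, sc, fast_analysis, seed=7)
        r2 = crossvalidate_scenario(tiny_epochs, sc, fast_analysis, seed=7)
        np.testing.assert_array_equal(r1.fold_accuracies, r2.fold_accuracies)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        assert r1.selected_counts.equals(r2.selected_counts)

    def test_missing_task_rejected(self, tiny_epochs, fast_analysis):
        only_lr = tiny_epochs.select_tasks(["L", "R"])
        with pytest.raises(ValueError, match="REST"):
            crossvalidate_scenario(only_lr, ScenarioSpec(("L", "REST")), fast_analysis, 0)

    def test_leakage_guard_null_data(self, null_epochs, fast_analysis):
        """Fold-fitted pipeline stays at chance on g=0 data, while fitting
        CSP + selection on the full dataset before splitting inflates it.

        A single 10+10-trial session's CV mean is too noisy for a sharp
        band check (that lives in the multi-session acceptance test); here
        the contrast with the leaky variant on the *same* data is the
        point: the leaky estimate must exceed the upper chance bound while
        the fold-fitted one stays far below it.
        """
        sc = ScenarioSpec(("L", "R"))
        safe = crossvalidate_scenario(null_epochs, sc, fast_analysis, seed=11)
        lo, hi = chance_band(20, 2)

        # deliberately leaky variant, assembled from the same primitives
        sub = null_epochs.select_tasks(sc.tasks)
        coeffs = design_filterbank(FilterBankSpec(), sub.fs)
        band = apply_filterbank(sub, coeffs, fast_analysis.bands)
        model = fit_csp(band, fast_analysis.n_csp_pairs)
        feats = extract_logvar_features(band, model)
        codes, _ = discretize_features(feats.X, 5)
        sel = mrmr_select(codes, sub.labels, 25)
        leaky = cross_val_score(
            RandomForestClassifier(n_estimators=100, random_state=0),
            feats.X[:, sel],
            sub.labels,
            cv=10,
        ).mean() * 100
        assert leaky > hi
        assert leaky - safe.mean_accuracy > 15
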