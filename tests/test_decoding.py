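"""Decoding: balancing, AUC oracle, leakage protection, calibration."""

import warnings

import numpy as np
import pytest

from deactdyn.containers import TrialBetaMatrix
from deactdyn.decoding import (
    auc_score,
    cross_modal_decode,
    cv_decode,
    feature_decode_4class,
    fit_reducer_classifier,
    reduce_train_project_test,
    undersample,
)
from deactdyn.synthgen import PatternSpec, gen_beta_patterns


def pairwise_auc_oracle(scores, labels):
    """Brute-force Mann-Whitney pair count with ties counted 1/2."""
    pos = scores[np.asarray(labels, bool)]
    neg = scores[~np.asarray(labels, bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestUndersample:
    def test_balanced_input_unchanged(self, separable_trials):
        out = undersample(separable_trials, seed=0, per_run=True)
        np.testing.assert_array_equal(out.patterns, separable_trials.patterns)

    def test_majority_class_reduced_reproducibly(self, rng):
        pats = rng.normal(size=(50, 5))
        cond = np.array(["A"] * 30 + ["B"] * 20)
        runs = np.zeros(50, int)
        t = TrialBetaMatrix(pats, cond, runs)
        a = undersample(t, seed=3)
        b = undersample(t, seed=3)
        assert np.sum(a.condition == "A") == np.sum(a.condition == "B") == 20
        np.testing.assert_array_equal(a.patterns, b.patterns)

    def test_exact_balance_for_many_seeds(self, rng):
        pats = rng.normal(size=(37, 4))
        cond = np.array(["A"] * 25 + ["B"] * 12)
        t = TrialBetaMatrix(pats, cond, np.zeros(37, int))
        for seed in range(100):
            out = undersample(t, seed=seed)
            assert np.sum(out.condition == "A") == np.sum(out.condition == "B") == 12

    def test_run_missing_class_rejected(self, rng):
        pats = rng.normal(size=(6, 3))
        cond = np.array(["A", "A", "A", "B", "B", "B"])
        runs = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="run 0"):
            undersample(TrialBetaMatrix(pats, cond, runs), per_run=True)


class TestAucScore:
    def test_perfect_separation(self):
        assert auc_score(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties_half(self):
        assert auc_score(np.ones(6), np.array([1, 1, 1, 0, 0, 0])) == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 20))
            scores = rng.choice([0.1, 0.25, 0.5, 0.9], size=n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc_score(scores, labels) == pytest.approx(
                pairwise_auc_oracle(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_score(np.array([0.1, 0.9]), np.array([1, 1]))


class TestReduction:
    def test_test_equals_train_gives_identical_projection(self, rng):
        x = rng.normal(size=(20, 10))
        tr, te = reduce_train_project_test(x, x, n_components=4)
        np.testing.assert_allclose(tr, te)

    def test_rank_deficient_training_clamped_with_warning(self, rng):
        base = rng.normal(size=10)
        x = np.outer(rng.normal(size=20), base)  # rank 1 after centering... rank<=2
        with pytest.warns(RuntimeWarning, match="clamp"):
            tr, _ = reduce_train_project_test(x, x, n_components=5)
        assert tr.shape[1] <= 2

    def test_feature_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            reduce_train_project_test(rng.normal(size=(5, 4)), rng.normal(size=(5, 3)))

    def test_reconstruction_error_matches_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(20, 10))
        k = 3
        tr, _ = reduce_train_project_test(x, x, n_components=k)
        # Oracle: top-k eigenvectors of the covariance matrix.
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        v = evecs[:, ::-1][:, :k]
        recon_oracle = xc @ v @ v.T
        err_oracle = np.linalg.norm(xc - recon_oracle)
        # Package reconstruction error through the fitted subspace.
        from sklearn.decomposition import PCA
        pca = PCA(n_components=k, svd_solver="full").fit(x)
        recon = (tr @ pca.components_)
        err = np.linalg.norm(xc - recon)
        assert err == pytest.approx(err_oracle, rel=1e-8)

    def test_no_leakage_fitted_parameters_depend_on_train_only(self, rng):
        # Corrupting the held-out data must leave every fitted parameter
        # (loadings, classifier weights) bit-identical.
        train = rng.normal(size=(30, 12))
        labels = np.array(["A", "B"] * 15)
        test_a = rng.normal(size=(10, 12))
        test_b = rng.normal(size=(10, 12)) * 100
        pca1, clf1 = fit_reducer_classifier(train, labels, 5)
        pca2, clf2 = fit_reducer_classifier(train, labels, 5)
        np.testing.assert_array_equal(pca1.components_, pca2.components_)
        np.testing.assert_array_equal(clf1.coef_, clf2.coef_)
        tr1, _ = reduce_train_project_test(train, test_a, 5)
        tr2, _ = reduce_train_project_test(train, test_b, 5)
        np.testing.assert_array_equal(tr1, tr2)


class TestCvDecode:
    def test_high_separation_near_perfect_auc(self, separable_trials):
        res = cv_decode(separable_trials, scheme="leave_one_run_out", n_boot=10, seed=0)
        assert res.mean >= 0.99

    def test_zero_separation_auc_near_chance(self):
        # Average over many independent null datasets (single-dataset CV AUC
        # has substantial sampling spread).
        means = []
        for s in range(30):
            t = gen_beta_patterns(
                PatternSpec(n_trials_per_condition=25, n_runs=5, n_features=40,
                            condition_separation=0.0, feature_coupling=0.0,
                            noise_sd=1.0, seed=2000 + s)
            )
            means.append(cv_decode(t, n_boot=5, seed=s).mean)
        assert np.mean(means) == pytest.approx(0.5, abs=0.03)

    def test_label_permutation_mean_auc_at_chance(self, separable_trials, rng):
        scores = []
        for i in range(100):
            perm = TrialBetaMatrix(
                separable_trials.patterns,
                rng.permutation(separable_trials.condition),
                separable_trials.run,
            )
            try:
                res = cv_decode(perm, scheme="kfold", k=5, n_boot=1, n_repeats=1, seed=i)
            except ValueError:
                continue  # permutation left a run unbalanced for undersampling
            scores.append(res.mean)
        assert np.mean(scores) == pytest.approx(0.5, abs=0.03)

    def test_seed_determinism(self, separable_trials):
        a = cv_decode(separable_trials, n_boot=5, seed=9)
        b = cv_decode(separable_trials, n_boot=5, seed=9)
        np.testing.assert_array_equal(a.per_iteration, b.per_iteration)

    def test_per_iteration_length_contract(self, separable_trials):
        res = cv_decode(separable_trials, n_boot=7, seed=0)
        assert len(res.per_iteration) == 7
        res1 = cv_decode(separable_trials, scheme="kfold", k=5, n_repeats=2, n_boot=1, seed=0)
        assert len(res1.per_iteration) == 10

    def test_loro_needs_two_runs(self, rng):
        t = TrialBetaMatrix(rng.normal(size=(10, 4)),
                            np.array(["A", "B"] * 5), np.zeros(10, int))
        with pytest.raises(ValueError, match="2 runs"):
            cv_decode(t, scheme="leave_one_run_out")


class TestCrossModal:
    def _pair(self, separation=8.0, shuffle_test=False, seed=0):
        base = dict(n_trials_per_condition=25, n_runs=5, n_features=40,
                    condition_separation=separation, feature_coupling=0.0, noise_sd=1.0)
        train = gen_beta_patterns(PatternSpec(**base, seed=seed), structure_seed=77)
        test = gen_beta_patterns(PatternSpec(**base, seed=seed + 1), structure_seed=77)
        if shuffle_test:
            rng = np.random.default_rng(seed + 2)
            test = TrialBetaMatrix(test.patterns, rng.permutation(test.condition), test.run)
        return train, test

    def test_shared_structure_transfers(self):
        train, test = self._pair()
        res = cross_modal_decode(train, test, n_boot=20, seed=0)
        assert res.mean >= 0.95

    def test_shuffled_test_labels_at_chance(self):
        means = []
        for s in range(10):
            train, test = self._pair(shuffle_test=True, seed=100 + 3 * s)
            means.append(cross_modal_decode(train, test, n_boot=20, seed=s).mean)
        assert np.mean(means) == pytest.approx(0.5, abs=0.03)

    def test_train_as_test_flagged_as_leakage_diagnostic(self):
        train, _ = self._pair()
        with pytest.warns(RuntimeWarning, match="leakage"):
            res = cross_modal_decode(train, train, n_boot=5, seed=0)
        assert res.mean >= 0.95

    def test_dimension_mismatch_reports_both(self, rng):
        a = TrialBetaMatrix(rng.normal(size=(8, 4)), np.array(["A", "B"] * 4),
                            np.zeros(8, int))
        b = TrialBetaMatrix(rng.normal(size=(8, 5)), np.array(["A", "B"] * 4),
                            np.zeros(8, int))
        with pytest.raises(ValueError, match="4.*5"):
            cross_modal_decode(a, b)


class TestFeatureDecode4Class:
    def _coupled(self, coupling=0.9, separation=8.0, seed=0, n_per=40):
        return gen_beta_patterns(
            PatternSpec(n_trials_per_condition=n_per, n_runs=5, n_features=40,
                        condition_separation=separation, feature_coupling=coupling,
                        noise_sd=1.0, seed=seed)
        )

    def test_distinct_ratings_split_evenly(self):
        t = self._coupled()
        med = np.median(t.ratings["rating"])
        high = np.sum(t.ratings["rating"] > med)
        assert high == t.n_trials // 2

    def test_null_structure_accuracy_near_quarter_chance(self):
        means = []
        for s in range(20):
            t = self._coupled(coupling=0.0, separation=0.0, seed=3000 + s, n_per=20)
            means.append(feature_decode_4class(t, "rating", n_boot=5, seed=s).mean)
        assert np.mean(means) == pytest.approx(0.25, abs=0.03)

    def test_strong_structure_high_accuracy(self):
        # Bimodal ratings: trials near the median are otherwise inherently
        # ambiguous for a median-split label no matter how strong the
        # coupling, since the latent loading varies continuously.
        rng = np.random.default_rng(4)
        n = 80
        ratings = np.concatenate([rng.uniform(1, 3, n // 2), rng.uniform(7, 9, n // 2)])
        rng.shuffle(ratings)
        t = gen_beta_patterns(
            PatternSpec(n_trials_per_condition=40, n_runs=5, n_features=40,
                        condition_separation=10.0, feature_coupling=0.9,
                        noise_sd=1.0, seed=4),
            feature_ratings=ratings,
        )
        res = feature_decode_4class(t, "rating", n_boot=10, seed=0)
        assert res.mean >= 0.9

    def test_unknown_feature_rejected_with_available_names(self):
        t = self._coupled()
        with pytest.raises(KeyError, match="rating"):
            feature_decode_4class(t, "valence")
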