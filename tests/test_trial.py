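"""Tests for the trial-statistics engine (AUC, fits, holdout, search)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from renaltwin import trial as tr


def brute_force_auc(scores, labels):
    """Exhaustive pair-counting oracle: P(score1 > score0) + 0.5 ties."""
    s1 = [s for s, l in zip(scores, labels) if l == 1]
    s0 = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a, b in itertools.product(s1, s0))
    return wins / (len(s1) * len(s0))


def binormal_dataset(n_per_class, delta, seed=0, n_features=1):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n_per_class)
    X = rng.normal(0.0, 1.0, size=(2 * n_per_class, n_features))
    X[y == 1, 0] += delta
    cols = [f"f{i}" for i in range(n_features)]
    return tr.TrialDataset(X=pd.DataFrame(X, columns=cols), y=y)


class TestAuc:
    def test_perfect_separation_and_all_ties(self):
        assert tr.auc_roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
        assert tr.auc_roc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_exhaustive_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.7, 0.2, 0.9, 0.5, 0.4]
        labels = [0, 0, 1, 1, 0, 1, 0, 1, 1, 0]
        assert tr.auc_roc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_matches_library_reference(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[0], labels[1] = 0, 1
        assert tr.auc_roc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_antisymmetry_with_ties(self):
        rng = np.random.default_rng(2)
        scores = np.round(rng.normal(size=40), 1)  # force ties
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        assert tr.auc_roc(scores, labels) + tr.auc_roc(-scores, labels) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)
        labels = np.r_[np.ones(25, int), np.zeros(25, int)]
        base = tr.auc_roc(scores, labels)
        assert tr.auc_roc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
        assert tr.auc_roc(scores**3, labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tr.auc_roc([1, 2, 3], [1, 1, 1])


class TestFit:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            tr.fit_linear_logodds(np.zeros((4, 1)), np.ones(4, int))

    def test_separated_data_ranks_perfectly(self):
        X = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        coef, b0 = tr.fit_linear_logodds(X, y)
        assert tr.auc_roc(X @ coef + b0, y) == 1.0

    def test_coefficient_sign_tracks_class_mean(self):
        """A feature with the higher mean in class 1 gets a positive weight
        (checked over many simulated draws)."""
        rng = np.random.default_rng(4)
        signs = []
        for _ in range(200):
            y = np.repeat([1, 0], 20)
            X = rng.normal(0, 1, size=(40, 1))
            X[y == 1] += 1.0
            coef, _ = tr.fit_linear_logodds(X, y)
            signs.append(coef[0] > 0)
        assert np.mean(signs) > 0.95


class TestRepeatedHoldout:
    def test_seed_determinism(self):
        ds = binormal_dataset(50, 1.0, seed=5)
        a = tr.repeated_holdout(ds, ["f0"], n_iter=10, seed=3)
        b = tr.repeated_holdout(ds, ["f0"], n_iter=10, seed=3)
        assert np.array_equal(a.aucs, b.aucs)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_binormal_closed_form_recovery(self):
        """Mean validation AUC approaches Phi(delta/sqrt(2)) for a single
        Gaussian feature with standardised shift delta."""
        ds = binormal_dataset(200, 2.0, seed=6)
        ev = tr.repeated_holdout(ds, ["f0"], n_iter=50, seed=1)
        assert ev.mean_auc == pytest.approx(norm.cdf(2 / np.sqrt(2)), abs=0.03)

    def test_null_case(self):
        ds = binormal_dataset(100, 0.0, seed=7)
        ev = tr.repeated_holdout(ds, ["f0"], n_iter=50, seed=1)
        assert ev.mean_auc == pytest.approx(0.5, abs=0.05)

    def test_auc_converges_with_sample_size(self):
        """Estimation error of the binormal AUC shrinks as n grows."""
        target = norm.cdf(1 / np.sqrt(2))
        errs = []
        for n in (100, 400, 1600):
            ds = binormal_dataset(n, 1.0, seed=8)
            ev = tr.repeated_holdout(ds, ["f0"], n_iter=20, seed=2)
            errs.append(abs(ev.mean_auc - target))
        assert errs[2] < errs[0]
        assert errs[2] < 0.02


class TestCorrelation:
    def test_three_point_hand_computation(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 7.0],
                          "z": [3.0, 1.0, 0.5]})
        ds = tr.TrialDataset(X=X, y=np.array([0, 1, 0]))
        corr, order = tr.correlation_matrix(ds)
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "y"] == pytest.approx(0.9934, abs=1e-4)
        assert set(order) == set(X.columns)

    def test_perfect_anticorrelation_and_psd(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=30)})
        ds = tr.TrialDataset(X=X, y=np.r_[np.ones(15, int), np.zeros(15, int)])
        corr, _ = tr.correlation_matrix(ds)
        assert corr.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)
        eig = np.linalg.eigvalsh(corr.to_numpy())
        assert eig.min() > -1e-8

    def test_zero_variance_column_flagged(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        ds = tr.TrialDataset(X=X, y=np.array([0, 1, 0, 1]))
        corr, _ = tr.correlation_matrix(ds)
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0


@pytest.fixture(scope="module")
def ds5():
    return binormal_dataset(40, 1.0, seed=10, n_features=5)


class TestCombinationSearch:

    def test_enumerates_all_when_under_cap(self, ds5):
        res, = tr.combination_search(ds5, dims=[2], cap_per_dim=100, n_iter=5)
        assert res.n_evaluated == 10  # C(5, 2)
        assert set(res.table["biomarkers"]) == set(
            itertools.combinations(ds5.X.columns, 2)
        )

    def test_dimension_one_matches_univariate_ranking(self, ds5):
        res, = tr.combination_search(ds5, dims=[1], cap_per_dim=100, n_iter=10, seed=4)
        uni = {
            c: tr.repeated_holdout(ds5, [c], n_iter=10, seed=4).mean_auc
            for c in ds5.X.columns
        }
        for combo, auc in zip(res.table["biomarkers"], res.table["auc"]):
            assert auc == pytest.approx(uni[combo[0]], abs=1e-12)

    def test_sampled_mode_is_seeded(self):
        ds = binormal_dataset(30, 0.5, seed=11, n_features=8)
        a, = tr.combination_search(ds, dims=[3], cap_per_dim=10, n_iter=3, seed=5)
        b, = tr.combination_search(ds, dims=[3], cap_per_dim=10, n_iter=3, seed=5)
        assert list(a.table["biomarkers"]) == list(b.table["biomarkers"])
        assert a.n_evaluated == 10

    def test_frequencies_bounded_by_top_size(self, ds5):
        res, = tr.combination_search(
            ds5, dims=[2], cap_per_dim=100, n_iter=10, auc_threshold=0.0
        )
        assert res.frequencies.sum() <= len(res.top) * 2
        assert len(res.top10) <= 10

    def test_dimension_exceeding_vocabulary(self, ds5):
        with pytest.raises(ValueError, match="exceeds"):
            tr.combination_search(ds5, dims=[6], cap_per_dim=10, n_iter=2)


class TestUnivariateScreen:
    def test_location_prefixed_columns(self):
        rng = np.random.default_rng(12)
        n = 60
        y = np.repeat([1, 0], n // 2)
        X = pd.DataFrame({
            "main.PI": rng.normal(size=n) + 2.0 * y,
            "arcuate.PI": rng.normal(size=n) + 0.3 * y,
            "main.RI": rng.normal(size=n),
        })
        ds = tr.TrialDataset(X=X, y=y)
        table = tr.univariate_screen(ds, locations=("main", "arcuate"), n_iter=20)
        assert table.loc["main", "PI"] > table.loc["arcuate", "PI"]
        assert abs(table.loc["main", "RI"] - 0.5) < 0.12

    def test_permuted_labels_centre_on_half(self):
        rng = np.random.default_rng(13)
        n = 200
        X = pd.DataFrame({"main.PI": rng.normal(size=n)})
        y = rng.permutation(np.repeat([1, 0], n // 2))
        ds = tr.TrialDataset(X=X, y=y)
        table = tr.univariate_screen(ds, locations=("main",), n_iter=30)
        assert table.loc["main", "PI"] == pytest.approx(0.5, abs=0.07)
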