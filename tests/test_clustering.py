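"""PAM/cosine clustering, diagnostics and cross-cohort k-NN projection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.pairwise import cosine_distances

from chemonet.clustering import (
    ClusterModel,
    choose_k,
    cosine_distance,
    crossvalidate,
    explained_variance,
    fit_cluster_model,
    knn_project,
    pam_fit,
)
from chemonet.core_data import ExpressionCohort


def exhaustive_kmedoids_cost(X, k):
    """Oracle: optimal k-medoids total cost by enumerating all medoid subsets."""
    D = cosine_distances(X)
    best = np.inf
    for med in itertools.combinations(range(X.shape[0]), k):
        cost = D[:, list(med)].min(axis=1).sum()
        best = min(best, cost)
    return best


def as_panel(X, prefix="s"):
    """samples × features array -> genes × samples frame."""
    return pd.DataFrame(np.asarray(X, dtype=float).T,
                        index=[f"g{j}" for j in range(np.shape(X)[1])],
                        columns=[f"{prefix}{i}" for i in range(np.shape(X)[0])])


class TestCosine:
    def test_collinear(self):
        assert cosine_distance([1, 1], [2, 2]) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_antipodal(self):
        assert cosine_distance([1, 0], [-1, 0]) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0, 0], [1, 0])


class TestPam:
    def test_recovers_two_planted_directions(self):
        X = np.array([[1, 0], [0.9, 0.1], [0, 1], [0.1, 0.9]])
        model = pam_fit(as_panel(X), k=2)
        labels = model.assignments.to_numpy()
        assert labels[0] == labels[1] and labels[2] == labels[3] and labels[0] != labels[2]

    def test_matches_exhaustive_oracle_cost(self, rng):
        """BUILD+SWAP reaches the optimal cost on every small instance."""
        for n, k in [(6, 2), (7, 2), (8, 3), (5, 3)]:
            for _ in range(10):
                X = rng.normal(size=(n, 3))
                model = pam_fit(as_panel(X), k=k)
                assert model.total_cost == pytest.approx(exhaustive_kmedoids_cost(X, k), abs=1e-9)

    def test_k_equals_n_zero_cost(self, rng):
        X = rng.normal(size=(5, 2))
        model = pam_fit(as_panel(X), k=5)
        assert model.total_cost == pytest.approx(0.0, abs=1e-12)
        assert len(set(model.medoid_ids)) == 5

    def test_duplicated_dataset_same_partition(self, rng):
        X = rng.normal(size=(6, 3))
        base = pam_fit(as_panel(X), k=2).assignments.to_numpy()
        doubled = pam_fit(as_panel(np.vstack([X, X]), prefix="d"), k=2).assignments.to_numpy()
        assert adjusted_rand_score(base, doubled[:6]) == pytest.approx(1.0)
        assert (doubled[:6] == doubled[6:]).all()

    def test_too_few_distinct_points_rejected(self):
        X = np.ones((4, 2)) * [[1, 2]]
        with pytest.raises(ValueError, match="distinct"):
            pam_fit(as_panel(X), k=2)

    def test_high_cluster_naming_invariant_to_sample_order(self, rng):
        X = np.vstack([rng.normal(2, 0.3, size=(10, 4)), rng.normal(-2, 0.3, size=(10, 4))])
        panel = as_panel(X)
        model = pam_fit(panel, k=2)
        perm = rng.permutation(20)
        shuffled = pam_fit(panel.iloc[:, perm], k=2)
        joint = pd.concat([model.assignments.rename("a"), shuffled.assignments.rename("b")], axis=1)
        assert (joint["a"] == joint["b"]).all()
        high_mean = panel.loc[:, model.assignments == "high"].to_numpy().mean()
        low_mean = panel.loc[:, model.assignments == "low"].to_numpy().mean()
        assert high_mean > low_mean


class TestDiagnostics:
    def test_choose_k_prefers_two_on_separated_data(self, rng):
        X = np.vstack([rng.normal([3, 0, 0], 0.4, size=(20, 3)), rng.normal([0, 3, 0], 0.4, size=(20, 3))])
        diag = choose_k(as_panel(X), range(2, 6))
        assert diag.recommended_k == 2
        assert all(-1 <= s <= 1 for s in diag.silhouette.values())

    def test_silhouette_low_without_planted_separation(self):
        """A null-design chemokine panel shows no usable cluster structure."""
        from chemonet import synthetic
        from chemonet.core_data import zscore_genes

        d = synthetic.SimulationDesign(seed=1, panel_shift=0.0, n_samples=200,
                                       n_genes=120, n_cohorts=1)
        bundle = synthetic.simulate_cohort(d, 0)
        scaled, _ = zscore_genes(bundle.cohort, list(d.chemokine_panel))
        diag = choose_k(scaled, range(2, 7))
        assert max(diag.silhouette.values()) < 0.25

    def test_singleton_clusters_use_zero_convention(self, rng):
        X = rng.normal(size=(6, 2))
        diag = choose_k(as_panel(X), [5])  # k = n - 1 forces singletons
        assert np.isfinite(diag.silhouette[5])

    def test_explained_variance_extremes(self, rng):
        X = rng.normal(size=(6, 2))
        panel = as_panel(X)
        singletons = pd.Series([f"c{i}" for i in range(6)], index=panel.columns)
        assert explained_variance(panel, singletons) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            explained_variance(panel, pd.Series(["c"] * 6, index=panel.columns))

    def test_crossvalidate_planted_structure_is_stable(self, rng):
        X = np.vstack([rng.normal(2, 0.5, size=(25, 4)), rng.normal(-2, 0.5, size=(25, 4))])
        assert crossvalidate(as_panel(X), k=2, folds=5, seed=0) > 0.9

    def test_single_fold_rejected(self, rng):
        with pytest.raises(ValueError):
            crossvalidate(as_panel(rng.normal(size=(10, 2))), k=2, folds=1)


def make_cohort(values, prefix="t"):
    df = pd.DataFrame(np.asarray(values, dtype=float).T,
                      index=[f"g{j}" for j in range(np.shape(values)[1])],
                      columns=[f"{prefix}{i}" for i in range(np.shape(values)[0])])
    return ExpressionCohort(cohort_id=prefix, values=df)


class TestProjection:
    def _fit(self, rng, n=40):
        X = np.vstack([rng.normal(2, 0.5, size=(n // 2, 4)), rng.normal(-2, 0.5, size=(n // 2, 4))])
        cohort = make_cohort(X)
        return cohort, fit_cluster_model(cohort, [f"g{j}" for j in range(4)], k=2)

    def test_identical_sample_copies_label(self, rng):
        cohort, model = self._fit(rng)
        test = make_cohort(cohort.values.to_numpy().T, prefix="x")
        labels = knn_project(model, test, k_neighbors=5)
        assert (labels.to_numpy() == model.assignments.to_numpy()).all()

    def test_missing_panel_gene_listed(self, rng):
        cohort, model = self._fit(rng)
        test = make_cohort(rng.normal(size=(10, 3)), prefix="x")  # lacks g3
        with pytest.raises(ValueError, match="g3"):
            knn_project(model, test)

    def test_k_neighbors_capped_by_training_size(self, rng):
        cohort, model = self._fit(rng)
        test = make_cohort(rng.normal(size=(5, 4)), prefix="x")
        with pytest.raises(ValueError, match="k_neighbors"):
            knn_project(model, test, k_neighbors=100)

    def test_sibling_cohort_agreement(self, rng):
        cohort, model = self._fit(rng, n=60)
        truth = np.array(["high"] * 15 + ["low"] * 15)
        Y = np.vstack([rng.normal(2, 0.5, size=(15, 4)), rng.normal(-2, 0.5, size=(15, 4))])
        labels = knn_project(model, make_cohort(Y, prefix="y"), k_neighbors=15)
        assert (labels.to_numpy() == truth).mean() > 0.9

    def test_model_json_roundtrip(self, rng, tmp_path):
        cohort, model = self._fit(rng)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ClusterModel.from_json(path)
        test = make_cohort(rng.normal(size=(8, 4)), prefix="z")
        pd.testing.assert_series_equal(
            knn_project(model, test, 5), knn_project(back, test, 5)
        )
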