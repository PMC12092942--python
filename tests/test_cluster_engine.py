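import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from edss_patterns.binarize import binarize_table
from edss_patterns.cluster_engine import (ClusterParams, EmbedParams, NOISE,
                                          _cluster, _fit_umap, apply_model,
                                          dbcv_check, default_grid,
                                          fit_embed_cluster, relative_validity,
                                          small_grid, tune)
from edss_patterns.synthetic_data import generate_cohort, planted_config


def test_param_validation():
    with pytest.raises(ValueError):
        EmbedParams(n_neighbors=1)
    with pytest.raises(ValueError):
        EmbedParams(n_components=4)
    with pytest.raises(ValueError):
        ClusterParams(min_cluster_size=1)


def test_two_separated_archetypes_recovered_exactly(catalog):
    """Two planted archetypes, n=600: exactly 2 clusters, near-perfect ARI."""
    table = generate_cohort(planted_config(600, weights=(0.5, 0.5, 0, 0), seed=0),
                            catalog)
    model = fit_embed_cluster(binarize_table(table),
                              EmbedParams(n_neighbors=30, seed=0),
                              ClusterParams(min_cluster_size=30))
    assert model.n_clusters == 2
    nz = model.labels != NOISE
    ari = adjusted_rand_score(table["truth_archetype"][nz], model.labels[nz])
    assert ari >= 0.95


def test_four_archetypes_recovered(planted, planted_model):
    table, _ = planted
    nz = planted_model.labels != NOISE
    ari = adjusted_rand_score(table["truth_archetype"][nz],
                              planted_model.labels[nz])
    assert planted_model.n_clusters >= 4
    assert ari >= 0.8
    assert np.isfinite(planted_model.relative_validity)


def test_identical_rows_degenerate_but_stable():
    X = np.zeros((60, 15))
    X[:, 3] = 1
    a = fit_embed_cluster(X, EmbedParams(n_neighbors=10, seed=1),
                          ClusterParams(min_cluster_size=5))
    b = fit_embed_cluster(X, EmbedParams(n_neighbors=10, seed=1),
                          ClusterParams(min_cluster_size=5))
    assert set(a.labels) <= {NOISE, 0}  # one cluster or all noise
    assert (a.labels == b.labels).all()


def test_too_few_rows_raises():
    X = np.zeros((10, 15))
    with pytest.raises(ValueError, match="n_neighbors"):
        fit_embed_cluster(X, EmbedParams(n_neighbors=15),
                          ClusterParams(min_cluster_size=5))
    with pytest.raises(ValueError, match="min_cluster_size"):
        fit_embed_cluster(X, EmbedParams(n_neighbors=5),
                          ClusterParams(min_cluster_size=50))


class TestApply:
    def test_self_consistency_on_training_rows(self, planted, planted_model):
        _, features = planted
        relabeled = apply_model(planted_model, features)
        both = (planted_model.labels != NOISE) & (relabeled != NOISE)
        agreement = (relabeled[both] == planted_model.labels[both]).mean()
        assert agreement >= 0.9

    def test_empty_validation_set(self, planted, planted_model):
        _, features = planted
        out = apply_model(planted_model, features.head(0))
        assert out.shape == (0,)

    def test_dimension_mismatch_rejected(self, planted_model):
        with pytest.raises(ValueError, match="dimension"):
            apply_model(planted_model, np.zeros((4, 7)))

    def test_held_out_fold_distribution_close_to_training(self, catalog):
        from edss_patterns.patterns import pattern_distribution
        table = generate_cohort(planted_config(750, seed=4), catalog)
        features = binarize_table(table)
        train, val = features.iloc[:500], features.iloc[500:]
        model = fit_embed_cluster(train, EmbedParams(n_neighbors=30, seed=4),
                                  ClusterParams(min_cluster_size=25))
        val_labels = apply_model(model, val)
        t = pattern_distribution(train, model.labels, by_stratum=False)
        v = pattern_distribution(val, val_labels, by_stratum=False)
        gap = max(abs(t.loc["all", p] - v.loc["all", p]) for p in "ABCD")
        assert gap <= 10.0


class TestTune:
    def test_grid_of_one_returns_that_combination(self, planted):
        _, features = planted
        grid = [(EmbedParams(n_neighbors=30, seed=0),
                 ClusterParams(min_cluster_size=30))]
        model = tune(features, grid)
        assert (model.embed_params, model.cluster_params) == grid[0]
        assert len(model.score_table) == 1

    def test_score_table_has_one_row_per_grid_point(self, planted):
        _, features = planted
        grid = small_grid(len(features), seed=0)
        model = tune(features, grid)
        assert len(model.score_table) == len(grid)
        assert model.relative_validity == model.score_table["relative_validity"].max()

    def test_empty_grid_rejected(self, planted):
        _, features = planted
        with pytest.raises(ValueError, match="empty"):
            tune(features, [])

    def test_all_single_cluster_grid_raises(self):
        X = np.zeros((80, 15))  # identical rows can never split in two
        grid = [(EmbedParams(n_neighbors=10, seed=0),
                 ClusterParams(min_cluster_size=40))]
        with pytest.raises(ValueError, match="revise"):
            tune(X, grid)

    def test_default_grid_covers_documented_ranges(self):
        grid = default_grid(1000)
        nns = {ep.n_neighbors for ep, _ in grid}
        ncs = {ep.n_components for ep, _ in grid}
        assert nns == {15, 30, 50} and ncs == {2, 3}
        assert {cp.min_cluster_size for _, cp in grid} == {10, 25, 50}


class TestValidity:
    def _blobs(self, seed=0, n=50, spread=0.1, gap=5.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, spread, (n, 2))
        b = rng.normal(gap, spread, (n, 2))
        return np.vstack([a, b])

    def test_separated_blobs_beat_random_split(self):
        emb = self._blobs()
        good = np.array([0] * 50 + [1] * 50)
        bad = np.random.default_rng(1).integers(0, 2, 100)
        assert dbcv_check(emb, good) > dbcv_check(emb, bad)
        assert relative_validity(emb, good) > relative_validity(emb, bad)

    def test_determinism(self):
        emb = self._blobs(seed=2)
        labels = np.array([0] * 50 + [1] * 50)
        assert dbcv_check(emb, labels) == dbcv_check(emb, labels)

    def test_single_cluster_undefined(self):
        emb = self._blobs()
        with pytest.raises(ValueError, match="two clusters"):
            dbcv_check(emb, np.zeros(100, dtype=int))
        assert relative_validity(emb, np.zeros(100, dtype=int)) == -1.0

    def test_oracle_scale_guard(self):
        emb = np.zeros((2500, 2))
        with pytest.raises(ValueError, match="2000"):
            dbcv_check(emb, np.zeros(2500, dtype=int))

    def test_ranking_agreement_with_full_dbcv(self, catalog):
        """Over a 6-point grid on planted data the relative-validity argmax
        matches the full-DBCV argmax in most seeds."""
        agree = 0
        for seed in range(6):
            table = generate_cohort(planted_config(240, seed=seed), catalog)
            X = binarize_table(table).filter(like="f_").to_numpy(float)
            rvs, dbs = [], []
            for nn in (15, 30):
                emb = np.asarray(
                    _fit_umap(X, EmbedParams(n_neighbors=nn, seed=seed)).embedding_,
                    dtype=float)
                for mcs in (8, 15, 30):
                    labels = _cluster(emb, ClusterParams(min_cluster_size=mcs))
                    rvs.append(relative_validity(emb, labels))
                    try:
                        dbs.append(dbcv_check(emb, labels))
                    except ValueError:
                        dbs.append(-np.inf)
            agree += int(np.argmax(rvs) == np.argmax(dbs))
        assert agree >= 4
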