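"""Two-stage Random Forest model: split rule, fitting, importance
ranking, panel-size optimization, prediction."""

import numpy as np
import pytest

import decompscore as d
from conftest import make_records, make_table


class TestTestSetSize:
    @pytest.mark.parametrize(
        "n,expected", [(56, 19), (83, 28), (73, 24), (70, 23), (72, 24),
                       (71, 24), (6, 2), (9, 3)]
    )
    def test_nearest_rounding_default(self, n, expected):
        assert d.test_set_size(n) == expected

    @pytest.mark.parametrize("n,expected", [(73, 25), (70, 24), (9, 3)])
    def test_ceiling_option(self, n, expected):
        spec = d.SplitSpec(rounding="ceiling")
        assert d.test_set_size(n, spec) == expected

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            d.test_set_size(2)


class TestSplit:
    def test_default_split_of_73(self):
        ids = [f"s{i:03d}" for i in range(73)]
        train, test = d.split_train_test(ids, d.SplitSpec(seed=1))
        assert len(test) == 24 and len(train) == 49
        assert sorted(train + test) == sorted(ids)
        assert not set(train) & set(test)

    def test_same_seed_same_partition(self):
        ids = [f"s{i}" for i in range(30)]
        assert d.split_train_test(ids, d.SplitSpec(seed=9)) == d.split_train_test(
            ids, d.SplitSpec(seed=9)
        )

    def test_different_seeds_differ(self):
        ids = [f"s{i}" for i in range(30)]
        partitions = {
            tuple(d.split_train_test(ids, d.SplitSpec(seed=s))[1])
            for s in range(10)
        }
        assert len(partitions) > 5

    def test_input_order_irrelevant(self):
        ids = [f"s{i}" for i in range(20)]
        assert d.split_train_test(ids, d.SplitSpec(seed=2)) == d.split_train_test(
            ids[::-1], d.SplitSpec(seed=2)
        )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            d.split_train_test(["a", "a", "b"], d.SplitSpec(seed=0))


class TestFitForest:
    def test_constant_response_predicts_constant(self):
        X = np.random.default_rng(0).uniform(size=(10, 3))
        with pytest.warns(UserWarning, match="constant"):
            forest = d.fit_forest(X, [42.0] * 10,
                                  d.ForestConfig(n_trees=50, rng_seed=0))
        assert np.allclose(forest.predict(X), 42.0)

    def test_predictions_bounded_by_training_scores(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(30, 4))
        y = rng.uniform(20, 80, 30)
        forest = d.fit_forest(X, y, d.ForestConfig(n_trees=100, rng_seed=1))
        preds = forest.predict(rng.uniform(-5, 5, size=(50, 4)))
        assert preds.min() >= y.min() and preds.max() <= y.max()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="2 training samples"):
            d.fit_forest(np.ones((1, 2)), [5.0])

    def test_oob_tracks_sensory_on_synthetic_panel(self, default_dataset):
        """On the full-scale default product, the 100-compound forest's
        OOB predictions correlate strongly with sensory scores."""
        cfg, recs, table, truth = default_dataset
        labels = d.segregate(recs)
        selected = [
            r.compound_id for r in d.volcano_select(table, labels) if r.selected
        ]
        sub = table.subset_compounds(selected)
        y = [r.sensory_score for r in recs]
        forest = d.fit_forest(sub.areas.T, y,
                              d.ForestConfig(n_trees=300, rng_seed=3))
        r = d.pearson_r(y, forest.oob_predictions)
        assert r >= 0.9


class TestRankImportance:
    def test_single_compound_first(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(20, 1))
        forest = d.fit_forest(X, X[:, 0] * 60 + 20,
                              d.ForestConfig(n_trees=50, rng_seed=0),
                              compound_ids=["only"])
        assert d.rank_importance(forest)[0] == "only"

    def test_dominant_signal_ranked_first(self):
        """One informative compound among pure-noise columns is ranked
        first (5 seeds)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = rng.uniform(20, 80, 40)
            X = rng.uniform(0, 1e4, size=(40, 8))
            X[:, 3] = 100.0 * 2 ** (3 * (y - 50) / 50)
            ids = [f"c{i}" for i in range(8)]
            forest = d.fit_forest(
                X, y, d.ForestConfig(n_trees=150, rng_seed=seed),
                compound_ids=ids,
            )
            assert d.rank_importance(forest, seed=seed)[0] == "c3"

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(20, 80, 30)
        X = rng.uniform(0, 1e3, size=(30, 5))
        X[:, 1] = y * 10
        ids = ["a", "b", "c", "d", "e"]
        f1 = d.fit_forest(X, y, d.ForestConfig(n_trees=100, rng_seed=0),
                          compound_ids=ids)
        perm = [4, 1, 3, 0, 2]
        f2 = d.fit_forest(X[:, perm], y,
                          d.ForestConfig(n_trees=100, rng_seed=0),
                          compound_ids=[ids[i] for i in perm])
        assert d.rank_importance(f1, seed=7)[0] == d.rank_importance(
            f2, seed=7
        )[0] == "b"


class TestOptimizeCompoundCount:
    def test_trace_covers_grid_and_forced_panel(self, small_dataset):
        cfg, recs, table, truth = small_dataset
        train = table.subset_compounds(truth.marker_ids[:10])
        y = [r.sensory_score for r in recs]
        panel, trace = d.optimize_compound_count(
            truth.marker_ids[:10], train, y,
            d.ForestConfig(n_trees=100, rng_seed=0), k_grid=[10],
        )
        assert panel == truth.marker_ids[:10]
        assert len(trace) == 1 and trace[0][0] == 10

    def test_single_marker_among_noise_yields_small_panel(self):
        """With one strong planted marker and pure-noise companions, the
        optimized panel stays small (<= 10 of 60 compounds; 5 seeds)."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 48
            y = rng.uniform(15, 85, n)
            ids = [f"c{i:02d}" for i in range(60)]
            X = rng.uniform(0, 1e4, size=(n, 60))
            X[:, 0] = 1e4 * 2 ** (3 * (y - 50) / 50) * rng.lognormal(0, 0.1, n)
            compounds = [
                d.CompoundMeta(ids[i], 100.0 + i, 1.0) for i in range(60)
            ]
            table = d.FeatureTable(
                compounds, [f"s{i}" for i in range(n)], X.T
            )
            forest = d.fit_forest(X, y, d.ForestConfig(n_trees=150,
                                                       rng_seed=seed),
                                  compound_ids=ids)
            ranked = d.rank_importance(forest, seed=seed)
            panel, trace = d.optimize_compound_count(
                ranked, table, y,
                d.ForestConfig(n_trees=150, rng_seed=seed),
                k_grid=[1, 2, 3, 5, 10, 20, 40, 60],
            )
            assert len(panel) <= 10
            assert len(trace) == 8

    def test_empty_grid_rejected(self, small_dataset):
        _, recs, table, truth = small_dataset
        with pytest.raises(ValueError, match="k_grid"):
            d.optimize_compound_count(
                truth.marker_ids[:5],
                table.subset_compounds(truth.marker_ids[:5]),
                [r.sensory_score for r in recs],
                d.ForestConfig(n_trees=50), k_grid=[],
            )

    def test_panel_is_ranking_prefix(self, small_bundle, small_dataset):
        _, recs, table, _ = small_dataset
        k_star = len(small_bundle.panel)
        best = max(small_bundle.trace, key=lambda kr: kr[1])
        ks_at_best = [k for k, r in small_bundle.trace if r == best[1]]
        assert k_star == min(ks_at_best)


class TestPredictScores:
    def test_predictions_within_training_range(self, small_bundle,
                                               small_dataset):
        _, recs, table, _ = small_dataset
        y = small_bundle.forest.y_train
        scores = d.predict_scores(small_bundle, table, small_bundle.test_ids)
        assert all(y.min() <= v <= y.max() for v in scores.values())

    def test_duplicate_queries_identical(self, small_bundle, small_dataset):
        _, recs, table, _ = small_dataset
        s = small_bundle.test_ids[0]
        out = d.predict_scores(small_bundle, table, [s, s])
        a = d.predict_scores(small_bundle, table, [s])
        assert out[s] == a[s]

    def test_missing_panel_compound_named(self, small_bundle, small_dataset):
        _, recs, table, _ = small_dataset
        keep = [c for c in table.compound_ids if c != small_bundle.panel[0]]
        stripped = table.subset_compounds(keep)
        with pytest.raises(KeyError, match=small_bundle.panel[0]):
            d.predict_scores(small_bundle, stripped, small_bundle.test_ids)


class TestProductModel:
    def test_end_to_end_determinism(self, small_dataset):
        cfg, recs, table, _ = small_dataset
        kwargs = dict(
            split_spec=d.SplitSpec(seed=3),
            forest_config=d.ForestConfig(n_trees=100, rng_seed=4),
            n_top=20,
            k_grid=[2, 5, 20],
        )
        b1 = d.fit_product_model(table, recs, **kwargs)
        b2 = d.fit_product_model(table, recs, **kwargs)
        assert b1.panel == b2.panel
        assert b1.trace == b2.trace
        assert d.predict_scores(b1, table, b1.test_ids) == d.predict_scores(
            b2, table, b2.test_ids
        )

    def test_no_test_leakage(self, small_dataset):
        """Perturbing test-sample areas never changes the selection or
        the panel (train-scope selection and OOB-based optimization)."""
        cfg, recs, table, _ = small_dataset
        kwargs = dict(
            split_spec=d.SplitSpec(seed=3),
            forest_config=d.ForestConfig(n_trees=100, rng_seed=4),
            n_top=20,
            k_grid=[2, 5, 20],
        )
        b1 = d.fit_product_model(table, recs, **kwargs)
        rng = np.random.default_rng(0)
        areas = table.areas.copy()
        test_cols = [table.samples.index(s) for s in b1.test_ids]
        areas[:, test_cols] *= rng.uniform(0.2, 5.0,
                                           size=(table.n_compounds,
                                                 len(test_cols)))
        perturbed = d.FeatureTable(table.compounds, table.samples, areas)
        b2 = d.fit_product_model(perturbed, recs, **kwargs)
        assert b2.panel == b1.panel
        assert b2.trace == b1.trace

    def test_bundle_roundtrip_reproduces_predictions(self, tmp_path,
                                                     small_bundle,
                                                     small_dataset):
        _, recs, table, _ = small_dataset
        path = tmp_path / "bundle.json"
        d.save_bundle(small_bundle, path, table)
        back = d.load_bundle(path)
        assert back.panel == small_bundle.panel
        assert back.trace == small_bundle.trace
        orig = d.predict_scores(small_bundle, table, small_bundle.test_ids)
        again = d.predict_scores(back, table, small_bundle.test_ids)
        assert orig == again
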