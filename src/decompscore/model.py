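"""Two-stage Random Forest sensory-score modeling.

Stage one fits a regression forest (default 2000 trees) to the training
samples over the 100 volcano-selected compounds and ranks compounds by
permutation importance. Stage two iterates the panel size k: for each k
a forest is fit on the top-k compounds and the Pearson correlation r_k
between training sensory scores and out-of-bag (OOB) predictions is
recorded; the panel maximizing r_k (smallest k on ties) defines the
final model used to predict sensory-like scores for held-out samples.

The train/test split takes one third of the samples (nearest-integer
rounding by default) at random under an explicit seed. All random draws
flow from named integer seeds recorded in the ModelBundle, so a fit is
exactly reproducible from its bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil, floor
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .differential import DifferentialRecord, segregate, volcano_select
from .types import FeatureTable, SensoryRecord

__all__ = [
    "SplitSpec",
    "ForestConfig",
    "FittedForest",
    "ModelBundle",
    "test_set_size",
    "split_train_test",
    "fit_forest",
    "rank_importance",
    "optimize_compound_count",
    "predict_scores",
    "fit_product_model",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class SplitSpec:
    """Test-set sizing and randomization for the train/test split.

    ``rounding="nearest"`` (default) rounds n/3 half-up; ``"ceiling"``
    takes the ceiling.
    """

    test_fraction: float = 1 / 3
    rounding: str = "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie strictly in (0, 1)")
        if self.rounding not in ("nearest", "ceiling"):
            raise ValueError("rounding must be 'nearest' or 'ceiling'")


@dataclass(frozen=True)
class ForestConfig:
    """Random Forest hyperparameters (regression mode, permutation
    importance). ``n_trees`` defaults to 2000."""

    n_trees: int = 2000
    rng_seed: int = 0
    importance_repeats: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def test_set_size(n_samples: int, split_spec: SplitSpec = SplitSpec()) -> int:
    """Number of test samples for an n-sample product set.

    Exact rational arithmetic so that e.g. n=9 with a one-third fraction
    never suffers float round-off.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples to split")
    frac = Fraction(split_spec.test_fraction).limit_denominator(10**6)
    x = n_samples * frac
    if split_spec.rounding == "ceiling":
        n_test = ceil(x)
    else:
        n_test = floor(x + Fraction(1, 2))
    return max(1, min(n_test, n_samples - 1))


def split_train_test(
    sample_ids: Sequence[str], split_spec: SplitSpec = SplitSpec()
) -> tuple[list[str], list[str]]:
    """Seeded random partition into (train_ids, test_ids).

    Deterministic given the spec's seed; input order does not matter
    (ids are sorted before shuffling).
    """
    ids = list(sample_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    n_test = test_set_size(len(ids), split_spec)
    rng = np.random.default_rng(split_spec.seed)
    perm = rng.permutation(sorted(ids))
    test = sorted(perm[:n_test])
    train = sorted(perm[n_test:])
    return train, test


@dataclass
class FittedForest:
    """A fitted regression ensemble plus the metadata needed to use it."""

    model: RandomForestRegressor
    compound_ids: list[str]
    train_sample_ids: list[str]
    y_train: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))

    @property
    def oob_predictions(self) -> np.ndarray:
        """OOB prediction per training sample (requires enough trees for
        every sample to be out of bag at least once)."""
        return self.model.oob_prediction_

    def importances(self, seed: int = 0, n_repeats: int = 5) -> np.ndarray:
        """Permutation importance of each compound on the training set."""
        r = permutation_importance(
            self.model, self._X_train, self.y_train,
            n_repeats=n_repeats, random_state=seed,
        )
        return r.importances_mean

    _X_train: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def fit_forest(
    feature_matrix: np.ndarray,
    scores: Sequence[float],
    forest_config: ForestConfig = ForestConfig(),
    compound_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> FittedForest:
    """Fit a regression forest of ``n_trees`` trees to sensory scores.

    ``feature_matrix`` is samples x compounds (peak areas). OOB
    predictions are enabled; with very few trees some samples may never
    be out of bag, so a warning is issued below 50 trees.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(list(scores), dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(
            f"feature matrix {X.shape} does not match {y.size} scores"
        )
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if np.ptp(y) == 0:
        warnings.warn(
            "constant sensory response; the forest will predict a constant",
            stacklevel=2,
        )
    if forest_config.n_trees < 50:
        warnings.warn(
            "fewer than 50 trees: OOB predictions may be undefined for "
            "some samples",
            stacklevel=2,
        )
    model = RandomForestRegressor(
        n_estimators=forest_config.n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=forest_config.rng_seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # constant-y and sparse-OOB warnings are handled above
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        warnings.filterwarnings("ignore", message="invalid value encountered")
        model.fit(X, y)
    n = X.shape[0]
    return FittedForest(
        model=model,
        compound_ids=list(compound_ids) if compound_ids is not None
        else [f"c{i}" for i in range(X.shape[1])],
        train_sample_ids=list(sample_ids) if sample_ids is not None
        else [f"s{i}" for i in range(n)],
        y_train=y,
        _X_train=X,
    )


def rank_importance(
    forest: FittedForest, seed: int = 0, n_repeats: int = 5
) -> list[str]:
    """Compound ids in descending permutation-importance order.

    Ties are broken by lexicographic compound id so the ranking is
    deterministic and invariant to column order.
    """
    imp = forest.importances(seed=seed, n_repeats=n_repeats)
    order = sorted(
        range(len(imp)), key=lambda i: (-imp[i], forest.compound_ids[i])
    )
    return [forest.compound_ids[i] for i in order]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(a, b)[0, 1])


def optimize_compound_count(
    ranked_ids: Sequence[str],
    train_table: FeatureTable,
    scores: Sequence[float],
    forest_config: ForestConfig = ForestConfig(),
    k_grid: Sequence[int] | None = None,
) -> tuple[list[str], list[tuple[int, float]]]:
    """Panel-size optimization over the importance ranking.

    For each k in ``k_grid`` (default 1..len(ranked_ids)) a forest is
    fit on the top-k compounds and r_k = Pearson(training scores, OOB
    predictions) recorded. Returns (panel, trace) where panel is the
    top-k* ranking prefix with k* = argmax r_k (smallest k on ties) and
    trace lists every (k, r_k) evaluated.
    """
    ranked_ids = list(ranked_ids)
    if k_grid is None:
        k_grid = range(1, len(ranked_ids) + 1)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    if k_grid[0] < 1 or k_grid[-1] > len(ranked_ids):
        raise ValueError(
            f"k_grid must lie within 1..{len(ranked_ids)}"
        )
    y = np.asarray(list(scores), dtype=float)
    frame = train_table.to_frame()
    trace = []
    best_k, best_r = None, -np.inf
    for k in k_grid:
        panel_k = ranked_ids[:k]
        X = frame.loc[panel_k].to_numpy().T
        fitted = fit_forest(X, y, forest_config, compound_ids=panel_k,
                            sample_ids=train_table.samples)
        oob = fitted.oob_predictions
        mask = np.isfinite(oob)
        r_k = _pearson(y[mask], oob[mask])
        trace.append((k, r_k))
        if r_k > best_r:  # strict: ties keep the smaller k
            best_k, best_r = k, r_k
    return ranked_ids[:best_k], trace


@dataclass
class ModelBundle:
    """Everything needed to reproduce and apply one product's model."""

    product: str
    panel: list[str]
    forest: FittedForest
    trace: list[tuple[int, float]]
    train_ids: list[str]
    test_ids: list[str]
    split_spec: SplitSpec
    forest_config: ForestConfig
    selection: list[DifferentialRecord] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)


def predict_scores(
    bundle: ModelBundle,
    feature_table: FeatureTable,
    sample_ids: Sequence[str],
) -> dict[str, float]:
    """Modeled sensory-like score per requested sample.

    Predictions are tree-mean aggregates, so they lie within the range
    of the training scores. Raises ``KeyError`` naming any panel
    compound missing from the table.
    """
    table_ids = set(feature_table.compound_ids)
    missing = [c for c in bundle.panel if c not in table_ids]
    if missing:
        raise KeyError(f"panel compounds missing from feature table: {missing}")
    sub = feature_table.subset_compounds(bundle.panel)
    col = {s: j for j, s in enumerate(sub.samples)}
    absent = [s for s in sample_ids if s not in col]
    if absent:
        raise KeyError(f"samples not in feature table: {absent}")
    X = sub.areas[:, [col[s] for s in sample_ids]].T
    preds = bundle.forest.predict(X)
    return {s: float(p) for s, p in zip(sample_ids, preds)}


def fit_product_model(
    feature_table: FeatureTable,
    sensory_records: Sequence[SensoryRecord],
    split_spec: SplitSpec = SplitSpec(),
    forest_config: ForestConfig = ForestConfig(),
    fc_threshold: float = 1.0,
    n_top: int = 100,
    pseudo_area: float = 1.0,
    k_grid: Sequence[int] | None = None,
    selection_scope: str = "train",
) -> ModelBundle:
    """End-to-end per-product fit: split, volcano-select, initial forest,
    importance ranking, panel-size optimization, final forest.

    ``selection_scope="train"`` (default) computes the differential
    selection on training samples only, preventing test leakage; the
    study-faithful alternative ``"all"`` uses every sample.
    """
    if selection_scope not in ("train", "all"):
        raise ValueError("selection_scope must be 'train' or 'all'")
    records = {r.sample_id: r for r in sensory_records}
    if len(records) != len(sensory_records):
        raise ValueError("duplicate sample ids in sensory records")
    extra = set(records) - set(feature_table.samples)
    if extra:
        raise ValueError(f"sensory records without feature columns: {sorted(extra)}")

    products = {r.product for r in sensory_records}
    product = products.pop() if len(products) == 1 else "+".join(sorted(products))

    train_ids, test_ids = split_train_test(sorted(records), split_spec)

    sel_ids = train_ids if selection_scope == "train" else sorted(records)
    sel_table = feature_table.subset_samples(sel_ids)
    labels = segregate([records[s] for s in sel_ids])
    selection = volcano_select(
        sel_table, labels, fc_threshold=fc_threshold, n_top=n_top,
        pseudo_area=pseudo_area,
    )
    selected_ids = [r.compound_id for r in selection if r.selected]
    if not selected_ids:
        raise ValueError("volcano selection returned no compounds")

    y_train = np.array([records[s].sensory_score for s in train_ids])
    train_table = feature_table.subset_compounds(selected_ids).subset_samples(
        train_ids
    )
    initial = fit_forest(
        train_table.areas.T, y_train, forest_config,
        compound_ids=selected_ids, sample_ids=train_ids,
    )
    ranked = rank_importance(
        initial, seed=forest_config.rng_seed,
        n_repeats=forest_config.importance_repeats,
    )
    panel, trace = optimize_compound_count(
        ranked, train_table, y_train, forest_config, k_grid=k_grid
    )
    final_table = train_table.subset_compounds(panel)
    final = fit_forest(
        final_table.areas.T, y_train, forest_config,
        compound_ids=panel, sample_ids=train_ids,
    )
    return ModelBundle(
        product=product,
        panel=panel,
        forest=final,
        trace=trace,
        train_ids=train_ids,
        test_ids=test_ids,
        split_spec=split_spec,
        forest_config=forest_config,
        selection=selection,
        seeds={"split": split_spec.seed, "forest": forest_config.rng_seed},
    )


def save_bundle(
    bundle: ModelBundle, path: str | Path, feature_table: FeatureTable
) -> None:
    """Serialize a bundle as portable JSON.

    The forest itself is not pickled: the JSON stores the panel, trace,
    split, seeds, forest hyperparameters and the training matrix, from
    which ``load_bundle`` refits the identical forest (a Random Forest
    is a deterministic function of its data, seed and configuration).
    """
    train_areas = (
        feature_table.subset_compounds(bundle.panel)
        .subset_samples(bundle.train_ids)
        .areas
    )
    payload = {
        "product": bundle.product,
        "panel": bundle.panel,
        "trace": [[k, r] for k, r in bundle.trace],
        "train_ids": bundle.train_ids,
        "test_ids": bundle.test_ids,
        "split_spec": {
            "test_fraction": bundle.split_spec.test_fraction,
            "rounding": bundle.split_spec.rounding,
            "seed": bundle.split_spec.seed,
        },
        "forest_config": {
            "n_trees": bundle.forest_config.n_trees,
            "rng_seed": bundle.forest_config.rng_seed,
            "importance_repeats": bundle.forest_config.importance_repeats,
        },
        "seeds": bundle.seeds,
        "y_train": [float(v) for v in bundle.forest.y_train],
        "train_areas": [[float(v) for v in row] for row in train_areas],
        "selection": [
            {
                "compound_id": r.compound_id,
                "log2fc": r.log2fc,
                "p_value": r.p_value,
                "passes_fc": r.passes_fc,
                "selected": r.selected,
            }
            for r in bundle.selection
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_bundle(path: str | Path) -> ModelBundle:
    """Reconstruct a bundle saved by :func:`save_bundle`, refitting the
    forest deterministically from the stored training data and seed."""
    payload = json.loads(Path(path).read_text())
    split_spec = SplitSpec(**payload["split_spec"])
    forest_config = ForestConfig(**payload["forest_config"])
    areas = np.asarray(payload["train_areas"], dtype=float)
    forest = fit_forest(
        areas.T,
        payload["y_train"],
        forest_config,
        compound_ids=payload["panel"],
        sample_ids=payload["train_ids"],
    )
    return ModelBundle(
        product=payload["product"],
        panel=list(payload["panel"]),
        forest=forest,
        trace=[(int(k), float(r)) for k, r in payload["trace"]],
        train_ids=list(payload["train_ids"]),
        test_ids=list(payload["test_ids"]),
        split_spec=split_spec,
        forest_config=forest_config,
        selection=[
            DifferentialRecord(**rec) for rec in payload.get("selection", [])
        ],
        seeds={k: int(v) for k, v in payload.get("seeds", {}).items()},
    )
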