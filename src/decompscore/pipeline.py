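"""End-to-end orchestration: simulate -> select -> fit -> predict ->
evaluate -> annotate, with a manifest that reproduces the run.

A run is configured by :class:`RunConfig` (YAML-loadable). Exactly one
of the two modes is active:

* simulate-mode — the synthetic generator produces each product's
  sensory and feature tables from a master seed;
* data-mode — feature and sensory CSVs are read from disk.

A single master seed fans out deterministically to per-product,
per-stage seeds (split, forest, generator), so one integer reproduces
the whole study. The manifest records every seed and parameter in
effect, including the documented decision toggles (rounding mode,
selection scope, boundary convention).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from ._version import __version__
from .annotation import PPM_TOL, RT_TOL, match_reference, write_annotation_csv
from .evaluation import (
    ProductEvaluation,
    PredictionRecord,
    TriplicateRange,
    evaluate_product,
    make_prediction_record,
    range_proportions,
    triplicate_groups,
    triplicate_ranges,
)
from .io_tables import (
    load_reference_compounds,
    read_feature_table,
    read_sensory_table,
    write_report,
)
from .model import (
    ForestConfig,
    SplitSpec,
    fit_product_model,
    predict_scores,
    save_bundle,
)
from .synthetic import GeneratorConfig, default_study_configs, derive_seed, simulate_study
from .types import FeatureTable, SensoryRecord

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; YAML-serializable."""

    mode: str = "simulate"  # "simulate" | "data"
    out_dir: str = "decompscore_run"
    master_seed: int = 0
    # simulate-mode
    products: tuple[str, ...] = ()  # empty = full default study
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # data-mode
    feature_table_path: str | None = None
    sensory_table_path: str | None = None
    reference_table_path: str | None = None  # None = packaged library
    # modeling
    split: SplitSpec = field(default_factory=SplitSpec)
    forest: ForestConfig = field(default_factory=ForestConfig)
    fc_threshold: float = 1.0
    n_top: int = 100
    pseudo_area: float = 1.0
    k_grid: tuple[int, ...] | None = None  # None = exhaustive 1..n_top
    selection_scope: str = "train"
    # annotation
    ppm_tol: float = PPM_TOL
    rt_tol: float = RT_TOL

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "data"):
            raise ValueError("mode must be 'simulate' or 'data'")
        if self.mode == "data":
            missing = [
                p
                for p in (self.feature_table_path, self.sensory_table_path)
                if p is None
            ]
            if missing:
                raise ValueError(
                    "data-mode requires feature_table_path and "
                    "sensory_table_path"
                )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        for key, klass in (
            ("generator", GeneratorConfig),
            ("split", SplitSpec),
            ("forest", ForestConfig),
        ):
            if isinstance(raw.get(key), dict):
                raw[key] = klass(**raw[key])
        if isinstance(raw.get("products"), list):
            raw["products"] = tuple(raw["products"])
        if isinstance(raw.get("k_grid"), list):
            raw["k_grid"] = tuple(raw["k_grid"])
        return cls(**raw)


def _manifest(config: RunConfig, product_seeds: dict) -> dict:
    cfg = asdict(config)
    cfg["generator"]["triplicate_increments"] = sorted(
        config.generator.triplicates
    )
    # the output location is not part of the run's identity
    cfg.pop("out_dir", None)
    return {
        "decompscore_version": __version__,
        "config": cfg,
        "product_seeds": product_seeds,
        "decisions": {
            "split_rounding": config.split.rounding,
            "selection_scope": config.selection_scope,
            "boundary_convention": "score of exactly 50 -> nondecomposed",
            "optimization_metric": "Pearson r on out-of-bag training predictions",
        },
    }


def _run_one_product(
    product: str,
    features: FeatureTable,
    sensory: Sequence[SensoryRecord],
    config: RunConfig,
    out_dir: Path,
) -> tuple[ProductEvaluation, list[PredictionRecord], list[TriplicateRange]]:
    split = replace(
        config.split, seed=derive_seed(config.master_seed, product, "split")
    )
    forest = replace(
        config.forest,
        rng_seed=derive_seed(config.master_seed, product, "forest"),
    )
    try:
        bundle = fit_product_model(
            features,
            sensory,
            split_spec=split,
            forest_config=forest,
            fc_threshold=config.fc_threshold,
            n_top=config.n_top,
            pseudo_area=config.pseudo_area,
            k_grid=config.k_grid,
            selection_scope=config.selection_scope,
        )
    except Exception as exc:
        raise PipelineError(f"fit stage failed for {product}: {exc}") from exc
    save_bundle(bundle, out_dir / f"{product}_model.json", features)

    by_id = {r.sample_id: r for r in sensory}
    try:
        test_scores = predict_scores(bundle, features, bundle.test_ids)
    except Exception as exc:
        raise PipelineError(f"predict stage failed for {product}: {exc}") from exc
    test_preds = [
        make_prediction_record(s, by_id[s].sensory_score, m)
        for s, m in test_scores.items()
    ]

    try:
        evaluation = evaluate_product(product, len(sensory), test_preds)
        trip_rows = [
            r.sample_id
            for rows in triplicate_groups(sensory).values()
            for r in rows
        ]
        trip_scores = predict_scores(bundle, features, sorted(trip_rows))
        trips = triplicate_ranges(sensory, trip_scores)
    except Exception as exc:
        raise PipelineError(f"evaluate stage failed for {product}: {exc}") from exc

    try:
        refs = load_reference_compounds(config.reference_table_path)
        panel_meta = [
            c for c in features.compounds if c.compound_id in set(bundle.panel)
        ]
        matches = match_reference(
            panel_meta, refs, ppm_tol=config.ppm_tol, rt_tol=config.rt_tol
        )
        write_annotation_csv(matches, out_dir / f"{product}_annotation.csv")
    except Exception as exc:
        raise PipelineError(f"annotate stage failed for {product}: {exc}") from exc

    return evaluation, test_preds, trips


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns a summary dict and writes artifacts
    (per-product model bundles and annotation reports, combined
    evaluation CSVs, triplicate ranges, manifest) under ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    datasets: dict[str, tuple[FeatureTable, list[SensoryRecord]]] = {}
    product_seeds: dict[str, dict[str, int]] = {}
    if config.mode == "simulate":
        gen_overrides = {
            k: v
            for k, v in asdict(config.generator).items()
            if k not in ("product", "n_increments", "seed",
                         "triplicate_increments")
        }
        configs = default_study_configs(
            products=list(config.products) or None, **gen_overrides
        )
        if config.products and len(configs) != len(config.products):
            known = {c.product for c in configs}
            raise PipelineError(
                "simulate stage: unknown products "
                f"{sorted(set(config.products) - known)}"
            )
        try:
            study = simulate_study(configs, config.master_seed)
        except Exception as exc:
            raise PipelineError(f"simulate stage failed: {exc}") from exc
        for product, ds in study.items():
            datasets[product] = (ds.features, list(ds.sensory))
    else:
        for label, path in (
            ("feature table", config.feature_table_path),
            ("sensory table", config.sensory_table_path),
        ):
            if not Path(path).exists():
                raise PipelineError(f"input stage: missing {label}: {path}")
        features = read_feature_table(config.feature_table_path)
        sensory = read_sensory_table(config.sensory_table_path)
        for product in sorted({r.product for r in sensory}):
            recs = [r for r in sensory if r.product == product]
            cols = [r.sample_id for r in recs]
            datasets[product] = (features.subset_samples(cols), recs)

    evaluations, predictions, trips = [], [], []
    for product in sorted(datasets):
        features, sensory = datasets[product]
        product_seeds[product] = {
            "split": derive_seed(config.master_seed, product, "split"),
            "forest": derive_seed(config.master_seed, product, "forest"),
        }
        ev, preds, tr = _run_one_product(
            product, features, sensory, config, out_dir
        )
        evaluations.append(ev)
        predictions.extend(preds)
        trips.extend(tr)

    write_report(evaluations, predictions, out_dir, triplicate_ranges=trips)
    manifest = _manifest(config, product_seeds)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )

    summary = {
        "products": [e.product for e in evaluations],
        "n_test_total": sum(e.n_test for e in evaluations),
        "fp_total": sum(e.fp_count for e in evaluations),
        "fn_total": sum(e.fn_count for e in evaluations),
        "correlations": {e.product: e.correlation_r for e in evaluations},
        "n_triplicates": len(trips),
    }
    if trips:
        summary["range_proportions"] = range_proportions(trips)
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    return summary
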