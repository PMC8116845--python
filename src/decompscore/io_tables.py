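"""CSV readers/writers for the pipeline's tabular interfaces.

Dialect: comma-separated UTF-8. A feature-table file starts with a
metadata block of four columns (``compound_id``, ``name``,
``neutral_mass``, ``rt``) followed by one column per sample. This
mirrors the shape of an aligned peak-area export from untargeted
LC-HRMS processing without binding to any vendor's header names.
Missing/empty area cells map to 0 (gap-filled tables treat absent
signals as below detection).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import CompoundMeta, FeatureTable, ReferenceCompound, SensoryRecord

logger = logging.getLogger(__name__)

_META_COLS = ["compound_id", "name", "neutral_mass", "rt"]
_SENSORY_COLS = ["sample_id", "product", "increment", "extraction_day", "sensory_score"]

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_sensory_table",
    "write_sensory_table",
    "load_reference_compounds",
    "write_report",
    "load_study_design",
]


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a compounds x samples peak-area CSV.

    Raises ``ValueError`` on duplicate sample ids, negative areas
    (naming the offending row/column) or non-numeric mass/RT.
    """
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    raw_samples = [c for c in header if c not in _META_COLS]
    if len(set(raw_samples)) != len(raw_samples):
        dupes = sorted({c for c in raw_samples if raw_samples.count(c) > 1})
        raise ValueError(f"{path}: duplicate sample ids in header: {dupes}")

    df = pd.read_csv(path, dtype={"compound_id": str, "name": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")

    for col in ("neutral_mass", "rt"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "compound_id"].iloc[0]
            raise ValueError(f"{path}: non-numeric {col} for compound {bad!r}")
        df[col] = vals

    areas = df[sample_cols].apply(pd.to_numeric, errors="raise")
    areas = areas.fillna(0.0).to_numpy(dtype=float)
    if np.any(areas < 0):
        r, c = np.argwhere(areas < 0)[0]
        raise ValueError(
            f"{path}: negative area for compound "
            f"{df['compound_id'].iloc[r]!r}, sample {sample_cols[c]!r}"
        )
    compounds = [
        CompoundMeta(
            compound_id=str(row.compound_id),
            neutral_mass=float(row.neutral_mass),
            rt=float(row.rt),
            name="" if pd.isna(row.name_) else str(row.name_),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    return FeatureTable(compounds, sample_cols, areas)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table in the dialect ``read_feature_table`` reads.

    Floats are written with 6 decimal places; the roundtrip is lossless
    at that precision.
    """
    meta = pd.DataFrame(
        {
            "compound_id": table.compound_ids,
            "name": [c.name for c in table.compounds],
            "neutral_mass": [c.neutral_mass for c in table.compounds],
            "rt": [c.rt for c in table.compounds],
        }
    )
    out = pd.concat([meta, table.to_frame().reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False, float_format="%.6f")


def read_sensory_table(path: str | Path) -> list[SensoryRecord]:
    """Read per-sample sensory records; order preserved.

    Unknown columns are ignored with a logged warning. Scores outside
    [1, 100] raise ``ValueError``.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "product": str})
    missing = [c for c in _SENSORY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sensory columns {missing}")
    extra = [c for c in df.columns if c not in _SENSORY_COLS]
    if extra:
        logger.warning("%s: ignoring unknown sensory columns %s", path, extra)
    return [
        SensoryRecord(
            sample_id=str(r.sample_id),
            product=str(r.product),
            increment=int(r.increment),
            extraction_day=int(r.extraction_day),
            sensory_score=float(r.sensory_score),
        )
        for r in df.itertuples(index=False)
    ]


def write_sensory_table(records: Sequence[SensoryRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "product": [r.product for r in records],
            "increment": [r.increment for r in records],
            "extraction_day": [r.extraction_day for r in records],
            "sensory_score": [r.sensory_score for r in records],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def load_reference_compounds(path: str | Path | None = None) -> list[ReferenceCompound]:
    """Load a reference-compound table (defaults to the packaged library
    of seafood decomposition markers)."""
    if path is None:
        src = resources.files("decompscore.data").joinpath("reference_compounds.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"name", "neutral_mass", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns {sorted(missing)}")
    refs = []
    for r in df.itertuples(index=False):
        products = tuple(
            str(getattr(r, "used_in_products", "")).split(";")
        ) if "used_in_products" in df.columns and pd.notna(getattr(r, "used_in_products", None)) else ()
        refs.append(
            ReferenceCompound(
                name=str(r.name),
                neutral_mass=float(r.neutral_mass),
                rt=float(r.rt),
                direction=str(getattr(r, "direction", "increasing")),
                confirmation=str(getattr(r, "confirmation", "unknown")),
                used_in_products=products,
            )
        )
    return refs


def load_study_design(path: str | Path | None = None) -> pd.DataFrame:
    """Per-product design summary (product code, printed sample count,
    number of quality increments). Defaults to the packaged 23-product
    study layout."""
    if path is None:
        src = resources.files("decompscore.data").joinpath("study_design.csv")
        with resources.as_file(src) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def write_report(
    evaluations: Iterable,
    predictions: Iterable,
    out_dir: str | Path,
    triplicate_ranges: Iterable = (),
) -> dict[str, Path]:
    """Write the per-product accuracy summary, the prediction scatter
    data, and (if provided) the triplicate-range reproducibility table.

    ``evaluations`` are ``ProductEvaluation`` and ``predictions`` are
    ``PredictionRecord`` objects (see :mod:`decompscore.evaluation`).
    Correlations are printed to 3 decimals. Returns the paths written.
    """
    evaluations = list(evaluations)
    predictions = list(predictions)
    if not evaluations:
        raise ValueError("write_report: evaluations must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    paths = {}
    summary = pd.DataFrame(
        {
            "product": [e.product for e in evaluations],
            "n_samples": [e.n_samples for e in evaluations],
            "n_test": [e.n_test for e in evaluations],
            "correlation": [f"{e.correlation_r:.3f}" for e in evaluations],
            "fp_count": [e.fp_count for e in evaluations],
            "fn_count": [e.fn_count for e in evaluations],
        }
    )
    paths["summary"] = out_dir / "product_summary.csv"
    summary.to_csv(paths["summary"], index=False)

    if predictions:
        pred = pd.DataFrame(
            {
                "sample_id": [p.sample_id for p in predictions],
                "sensory_score": [p.sensory_score for p in predictions],
                "modeled_score": [p.modeled_score for p in predictions],
                "sensory_call": [p.sensory_call for p in predictions],
                "model_call": [p.model_call for p in predictions],
                "error_type": [p.error_type for p in predictions],
            }
        )
        paths["predictions"] = out_dir / "predictions.csv"
        pred.to_csv(paths["predictions"], index=False, float_format="%.6f")

    triplicate_ranges = list(triplicate_ranges)
    if triplicate_ranges:
        trip = pd.DataFrame(
            {
                "product": [t.product for t in triplicate_ranges],
                "state": [t.state for t in triplicate_ranges],
                "score_1": [t.scores[0] for t in triplicate_ranges],
                "score_2": [t.scores[1] for t in triplicate_ranges],
                "score_3": [t.scores[2] for t in triplicate_ranges],
                "range": [t.range for t in triplicate_ranges],
            }
        )
        paths["triplicates"] = out_dir / "triplicate_ranges.csv"
        trip.to_csv(paths["triplicates"], index=False, float_format="%.6f")
    return paths
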