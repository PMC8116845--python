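"""Accuracy and reproducibility statistics for modeled sensory scores.

Classification at the regulatory boundary: a score above 50 is called
decomposed, 50 or below nondecomposed (strictly-greater-than on the
decomposed side matches the false-positive/false-negative definitions,
which both use strict inequalities; a modeled score landing exactly on
50 takes the conservative negative call). A false positive is a sensory
score below 50 with a modeled score above 50; a false negative is the
reverse.

Reproducibility is summarized by triplicate ranges: the max - min of
the three modeled scores obtained for the same portion extracted and
analyzed on three separate days, for one portion each from the low,
middle (borderline) and high decomposition states of every product.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .differential import DECOMPOSED, NONDECOMPOSED
from .types import SensoryRecord

__all__ = [
    "PredictionRecord",
    "ProductEvaluation",
    "TriplicateRange",
    "classify_score",
    "make_prediction_record",
    "confusion_counts",
    "pearson_r",
    "rate_percent",
    "triplicate_groups",
    "triplicate_ranges",
    "range_proportions",
    "evaluate_product",
]


def classify_score(score: float) -> str:
    """Decomposed/nondecomposed call for a score on the 1-100 scale.

    Modeled scores may fall slightly outside [1, 100]; they are accepted.
    Exactly 50 is called nondecomposed (documented boundary convention).
    """
    return DECOMPOSED if score > 50 else NONDECOMPOSED


@dataclass(frozen=True)
class PredictionRecord:
    """A sample's sensory vs modeled score with qualitative calls."""

    sample_id: str
    sensory_score: float
    modeled_score: float
    sensory_call: str
    model_call: str
    error_type: str  # "none" | "false_positive" | "false_negative"


def make_prediction_record(
    sample_id: str, sensory_score: float, modeled_score: float
) -> PredictionRecord:
    """Derive calls and FP/FN flag from the two scores with one rule."""
    s_call = classify_score(sensory_score)
    m_call = classify_score(modeled_score)
    if s_call == NONDECOMPOSED and m_call == DECOMPOSED:
        err = "false_positive"
    elif s_call == DECOMPOSED and m_call == NONDECOMPOSED:
        err = "false_negative"
    else:
        err = "none"
    return PredictionRecord(
        sample_id=sample_id,
        sensory_score=sensory_score,
        modeled_score=modeled_score,
        sensory_call=s_call,
        model_call=m_call,
        error_type=err,
    )


def confusion_counts(
    prediction_records: Sequence[PredictionRecord],
) -> tuple[int, int, int]:
    """(false positives, false negatives, total records)."""
    fp = sum(1 for r in prediction_records if r.error_type == "false_positive")
    fn = sum(1 for r in prediction_records if r.error_type == "false_negative")
    return fp, fn, len(prediction_records)


def pearson_r(
    sensory_scores: Sequence[float], modeled_scores: Sequence[float]
) -> float:
    """Pearson product-moment correlation between the two score vectors."""
    a = np.asarray(list(sensory_scores), dtype=float)
    b = np.asarray(list(modeled_scores), dtype=float)
    if a.size != b.size:
        raise ValueError("score vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 score pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant score vector")
    return float(np.corrcoef(a, b)[0, 1])


def rate_percent(count: int, n: int, decimals: int = 1) -> float:
    """100*count/n rounded half-up to ``decimals`` places."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= count <= n):
        raise ValueError("count must lie in [0, n]")
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(100) * Decimal(count) / Decimal(n)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(val)


@dataclass(frozen=True)
class ProductEvaluation:
    """Per-product test-set accuracy summary."""

    product: str
    n_samples: int
    n_test: int
    correlation_r: float
    fp_count: int
    fn_count: int


def evaluate_product(
    product: str,
    n_samples: int,
    test_predictions: Sequence[PredictionRecord],
) -> ProductEvaluation:
    fp, fn, n = confusion_counts(test_predictions)
    r = pearson_r(
        [p.sensory_score for p in test_predictions],
        [p.modeled_score for p in test_predictions],
    )
    return ProductEvaluation(
        product=product,
        n_samples=n_samples,
        n_test=n,
        correlation_r=r,
        fp_count=fp,
        fn_count=fn,
    )


@dataclass(frozen=True)
class TriplicateRange:
    """Spread of the three modeled scores for one third-day-replicated
    portion (low / middle / high decomposition state)."""

    product: str
    state: str  # "low" | "middle" | "high"
    scores: tuple[float, float, float]
    range: float


def _portion_key(record: SensoryRecord) -> tuple:
    """Portion identity: sample_id minus the trailing extraction-day tag
    when ids follow the '<...>-d<day>' convention, else the design
    coordinates plus the portion's (shared) sensory score."""
    head, sep, tail = record.sample_id.rpartition("-d")
    if sep and tail == str(record.extraction_day):
        return ("id", head)
    return ("design", record.product, record.increment, record.sensory_score)


def triplicate_groups(
    sensory_records: Sequence[SensoryRecord],
) -> dict[tuple, list[SensoryRecord]]:
    """Portions extracted on three days, keyed by portion identity.

    A portion qualifies when a day-3 record exists; its group contains
    all of that portion's extraction rows.
    """
    by_portion: dict[tuple, list[SensoryRecord]] = {}
    for rec in sensory_records:
        by_portion.setdefault(_portion_key(rec), []).append(rec)
    return {
        key: rows
        for key, rows in by_portion.items()
        if any(r.extraction_day == 3 for r in rows)
    }


def _state_label(increment: int, increments_present: Sequence[int]) -> str:
    lo, hi = min(increments_present), max(increments_present)
    if increment == lo:
        return "low"
    if increment == hi:
        return "high"
    return "middle"


def triplicate_ranges(
    sensory_records: Sequence[SensoryRecord],
    modeled_scores: Mapping[str, float],
) -> list[TriplicateRange]:
    """Max - min of modeled scores across each triplicate portion.

    ``modeled_scores`` maps sample_id -> modeled score and must cover
    every triplicate row. Raises ``ValueError`` if a qualifying portion
    does not have exactly 3 extraction rows.
    """
    groups = triplicate_groups(sensory_records)
    trip_increments = sorted({rows[0].increment for rows in groups.values()})
    out = []
    for key in sorted(groups, key=str):
        rows = groups[key]
        if len(rows) != 3:
            raise ValueError(
                f"triplicate portion {key} has {len(rows)} extraction rows, "
                "expected 3"
            )
        missing = [r.sample_id for r in rows if r.sample_id not in modeled_scores]
        if missing:
            raise ValueError(f"no modeled score for triplicate rows {missing}")
        scores = tuple(
            modeled_scores[r.sample_id]
            for r in sorted(rows, key=lambda r: r.extraction_day)
        )
        out.append(
            TriplicateRange(
                product=rows[0].product,
                state=_state_label(rows[0].increment, trip_increments),
                scores=scores,  # type: ignore[arg-type]
                range=max(scores) - min(scores),
            )
        )
    return out


def range_proportions(
    ranges: Sequence[float] | Sequence[TriplicateRange],
    cutoffs: Sequence[float] = (5.0, 10.0, 15.0),
) -> dict[float, float]:
    """Percentage of triplicate ranges at or below each cutoff (rounded
    half-up to whole percent)."""
    vals = [
        r.range if isinstance(r, TriplicateRange) else float(r) for r in ranges
    ]
    if not vals:
        raise ValueError("no ranges given")
    return {
        float(c): rate_percent(sum(1 for v in vals if v <= c), len(vals),
                               decimals=0)
        for c in cutoffs
    }
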