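"""Volcano-style differential compound selection.

Samples are segregated at the 50-point sensory boundary (score > 50 =
decomposed, < 50 = nondecomposed; exactly 50 is undefined and rejected).
Per compound, a log2 fold change of group mean areas and a two-sided
Welch t-test p-value on log2-transformed areas are computed; the
selection keeps the ``n_top`` lowest p-values among compounds whose
|log2FC| exceeds the threshold (default 1, i.e. a two-fold change in
either direction).

A pseudo-area (default 1 area unit) is added before ratios and logs so
that gap-filled zeros stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .types import FeatureTable, SensoryRecord

__all__ = [
    "DECOMPOSED",
    "NONDECOMPOSED",
    "DifferentialRecord",
    "segregate",
    "log2_fold_change",
    "welch_p",
    "volcano_select",
    "write_volcano_csv",
]

DECOMPOSED = "decomposed"
NONDECOMPOSED = "nondecomposed"


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-compound volcano statistics and selection flags."""

    compound_id: str
    log2fc: float
    p_value: float
    passes_fc: bool
    selected: bool


def segregate(sensory_records: Sequence[SensoryRecord]) -> dict[str, str]:
    """Label each sample decomposed (score > 50) or nondecomposed (< 50).

    A score of exactly 50 raises ``ValueError``: the boundary sample has
    no defined class and the caller must resolve it (e.g. re-score or
    drop the sample).
    """
    labels = {}
    for rec in sensory_records:
        if rec.sensory_score == 50:
            raise ValueError(
                f"sample {rec.sample_id!r} has a sensory score of exactly 50; "
                "the decomposed/nondecomposed rule is undefined at the "
                "boundary — re-score or exclude this sample"
            )
        labels[rec.sample_id] = (
            DECOMPOSED if rec.sensory_score > 50 else NONDECOMPOSED
        )
    return labels


def log2_fold_change(
    areas_decomposed: np.ndarray,
    areas_nondecomposed: np.ndarray,
    pseudo_area: float = 1.0,
) -> float:
    """log2((mean decomposed + pseudo) / (mean nondecomposed + pseudo))."""
    a_d = np.asarray(areas_decomposed, dtype=float)
    a_n = np.asarray(areas_nondecomposed, dtype=float)
    if a_d.size < 1 or a_n.size < 1:
        raise ValueError("both groups must contain at least one sample")
    if np.any(a_d < 0) or np.any(a_n < 0):
        raise ValueError("peak areas must be non-negative")
    return float(np.log2((a_d.mean() + pseudo_area) / (a_n.mean() + pseudo_area)))


def welch_p(
    areas_decomposed: np.ndarray,
    areas_nondecomposed: np.ndarray,
    pseudo_area: float = 1.0,
) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value on log2 areas.

    Areas are transformed to ``log2(area + pseudo_area)`` internally.
    With zero variance in both groups and equal means there is no
    evidence of a difference: p = 1 by convention (p = 0 if the means
    differ, the limit of an infinite t statistic).
    """
    a_d = np.asarray(areas_decomposed, dtype=float)
    a_n = np.asarray(areas_nondecomposed, dtype=float)
    if a_d.size < 2 or a_n.size < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    if np.any(a_d < 0) or np.any(a_n < 0):
        raise ValueError("peak areas must be non-negative")
    x = np.log2(a_d + pseudo_area)
    y = np.log2(a_n + pseudo_area)
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def volcano_select(
    feature_table: FeatureTable,
    labels: Mapping[str, str],
    fc_threshold: float = 1.0,
    n_top: int = 100,
    pseudo_area: float = 1.0,
) -> list[DifferentialRecord]:
    """Volcano selection: the ``n_top`` lowest p-values among compounds
    with |log2FC| > ``fc_threshold``.

    Ties in p at the selection boundary are broken by larger |log2FC|,
    then lexicographic compound id, making the selection deterministic.
    Records are returned in the table's compound order.
    """
    dec_ids = [s for s in feature_table.samples if labels.get(s) == DECOMPOSED]
    non_ids = [s for s in feature_table.samples if labels.get(s) == NONDECOMPOSED]
    if not dec_ids or not non_ids:
        raise ValueError(
            "volcano selection needs both a decomposed and a nondecomposed "
            f"group (got {len(dec_ids)} decomposed, {len(non_ids)} "
            "nondecomposed labeled samples in the table)"
        )
    pos = {s: j for j, s in enumerate(feature_table.samples)}
    a_d = feature_table.areas[:, [pos[s] for s in dec_ids]]
    a_n = feature_table.areas[:, [pos[s] for s in non_ids]]

    stats_rows = []
    for i, cid in enumerate(feature_table.compound_ids):
        lfc = log2_fold_change(a_d[i], a_n[i], pseudo_area)
        p = welch_p(a_d[i], a_n[i], pseudo_area)
        stats_rows.append((cid, lfc, p, abs(lfc) > fc_threshold))

    passers = [r for r in stats_rows if r[3]]
    passers.sort(key=lambda r: (r[2], -abs(r[1]), r[0]))
    chosen = {r[0] for r in passers[:n_top]}

    return [
        DifferentialRecord(
            compound_id=cid,
            log2fc=lfc,
            p_value=p,
            passes_fc=ok,
            selected=cid in chosen,
        )
        for cid, lfc, p, ok in stats_rows
    ]


def write_volcano_csv(records: Sequence[DifferentialRecord], path) -> None:
    """Volcano-plot data export: log2FC vs -log10 p with selection flags."""
    import pandas as pd

    with np.errstate(divide="ignore"):
        neglog = [-np.log10(r.p_value) if r.p_value > 0 else np.inf
                  for r in records]
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "neg_log10_p": neglog,
            "passes_fc": [r.passes_fc for r in records],
            "selected": [r.selected for r in records],
        }
    ).to_csv(path, index=False, float_format="%.6f")
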