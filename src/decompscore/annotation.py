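"""Tolerance-window annotation of compounds against a reference library.

A compound matches a reference when both its neutral monoisotopic mass
lies within +/-5 ppm and its retention time within +/-0.2 min of the
reference values (inclusive windows, matching the '+/-' confirmation
convention). Matching is performed in neutral-mass space; callers must
supply neutral masses (no adduct arithmetic is done). A compound may
fall inside several reference windows — all matches are reported, none
resolved, since closely related or isomeric compounds can share a
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .types import CompoundMeta, ReferenceCompound

__all__ = [
    "AnnotationMatch",
    "ppm_error",
    "match_reference",
    "write_annotation_csv",
    "PPM_TOL",
    "RT_TOL",
]

#: Default confirmation windows: +/-5 ppm mass, +/-0.2 min RT.
PPM_TOL = 5.0
RT_TOL = 0.2

_STATUS = {
    "standard": "standard-confirmed",
    "database": "database-putative",
    "unknown": "unknown",
}


@dataclass(frozen=True)
class AnnotationMatch:
    """One compound-to-reference assignment within tolerance."""

    compound_id: str
    reference_name: str
    ppm_error: float  # signed, observed vs reference
    rt_delta: float  # minutes, signed
    status: str  # "standard-confirmed" | "database-putative" | "unknown"


def ppm_error(observed_mass: float, reference_mass: float) -> float:
    """Signed mass deviation in parts per million:
    ``1e6 * (observed - reference) / reference``."""
    if observed_mass <= 0 or reference_mass <= 0:
        raise ValueError("masses must be positive")
    return 1e6 * (observed_mass - reference_mass) / reference_mass


def match_reference(
    compounds: Sequence[CompoundMeta],
    reference_table: Sequence[ReferenceCompound],
    ppm_tol: float = PPM_TOL,
    rt_tol: float = RT_TOL,
) -> list[AnnotationMatch]:
    """All compound/reference pairs within both tolerance windows.

    Compounds matching nothing are emitted once with
    ``reference_name=""`` and ``status="unknown"`` so the report covers
    every input compound.
    """
    matches: list[AnnotationMatch] = []
    for comp in compounds:
        hits = []
        for ref in reference_table:
            ppm = ppm_error(comp.neutral_mass, ref.neutral_mass)
            d_rt = comp.rt - ref.rt
            if abs(ppm) <= ppm_tol and abs(d_rt) <= rt_tol:
                hits.append(
                    AnnotationMatch(
                        compound_id=comp.compound_id,
                        reference_name=ref.name,
                        ppm_error=ppm,
                        rt_delta=d_rt,
                        status=_STATUS.get(ref.confirmation, "unknown"),
                    )
                )
        if hits:
            matches.extend(hits)
        else:
            matches.append(
                AnnotationMatch(
                    compound_id=comp.compound_id,
                    reference_name="",
                    ppm_error=float("nan"),
                    rt_delta=float("nan"),
                    status="unknown",
                )
            )
    return matches


def write_annotation_csv(matches: Sequence[AnnotationMatch], path) -> None:
    pd.DataFrame(
        {
            "compound_id": [m.compound_id for m in matches],
            "reference_name": [m.reference_name for m in matches],
            "ppm_error": [m.ppm_error for m in matches],
            "rt_delta": [m.rt_delta for m in matches],
            "status": [m.status for m in matches],
        }
    ).to_csv(path, index=False, float_format="%.4f")
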