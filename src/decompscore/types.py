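"""Core domain containers for the decomposition-scoring pipeline.

A *feature table* is the aligned output of untargeted LC-HRMS processing:
one row per compound (characterized by neutral monoisotopic mass and
retention time), one column per sample, cells holding peak areas. A
*sensory table* carries the expert-assigned 1-100 decomposition score per
sample together with the study-design coordinates (product, quality
increment, extraction day). Scores below 50 mean nondecomposed, above 50
decomposed; 50 itself is the regulatory boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundMeta",
    "FeatureTable",
    "SensoryRecord",
    "ReferenceCompound",
]


@dataclass(frozen=True)
class CompoundMeta:
    """Identity and chromatographic coordinates of one aligned feature."""

    compound_id: str
    neutral_mass: float  # Da, monoisotopic
    rt: float  # minutes
    name: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.neutral_mass) or self.neutral_mass <= 0:
            raise ValueError(
                f"compound {self.compound_id!r}: neutral_mass must be > 0, "
                f"got {self.neutral_mass}"
            )
        if not np.isfinite(self.rt) or self.rt < 0:
            raise ValueError(
                f"compound {self.compound_id!r}: rt must be >= 0, got {self.rt}"
            )


class FeatureTable:
    """Compounds x samples peak-area matrix with compound metadata.

    Parameters
    ----------
    compounds
        Ordered compound metadata; ids must be unique.
    samples
        Ordered unique sample identifiers (columns).
    areas
        Array of shape ``(len(compounds), len(samples))`` with
        non-negative peak areas (arbitrary area units).
    """

    def __init__(
        self,
        compounds: Sequence[CompoundMeta],
        samples: Sequence[str],
        areas: np.ndarray,
    ) -> None:
        compounds = list(compounds)
        samples = [str(s) for s in samples]
        areas = np.asarray(areas, dtype=float)
        ids = [c.compound_id for c in compounds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dupes}")
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if areas.shape != (len(compounds), len(samples)):
            raise ValueError(
                f"areas shape {areas.shape} does not match "
                f"({len(compounds)}, {len(samples)})"
            )
        if np.any(areas < 0):
            r, c = np.argwhere(areas < 0)[0]
            raise ValueError(
                f"negative area at compound {ids[r]!r}, sample {samples[c]!r}"
            )
        self.compounds = compounds
        self.samples = samples
        self.areas = areas

    @property
    def compound_ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        """Areas as a DataFrame indexed by compound_id, columns = samples."""
        return pd.DataFrame(
            self.areas, index=self.compound_ids, columns=self.samples
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        """Column subset (in the requested order)."""
        pos = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [pos[s] for s in sample_ids]
        return FeatureTable(self.compounds, list(sample_ids), self.areas[:, idx])

    def subset_compounds(self, compound_ids: Sequence[str]) -> "FeatureTable":
        """Row subset (in the requested order)."""
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in compound_ids if c not in pos]
        if missing:
            raise KeyError(f"compounds not in table: {missing}")
        idx = [pos[c] for c in compound_ids]
        return FeatureTable(
            [self.compounds[i] for i in idx], self.samples, self.areas[idx, :]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.compounds == other.compounds
            and self.samples == other.samples
            and np.array_equal(self.areas, other.areas)
        )

    def __repr__(self) -> str:
        return (
            f"FeatureTable({self.n_compounds} compounds x "
            f"{self.n_samples} samples)"
        )


@dataclass(frozen=True)
class SensoryRecord:
    """One sample's sensory evaluation and design coordinates.

    ``sensory_score`` is on the 1-100 expert scale (higher = more
    decomposed). ``extraction_day`` is the replicate extraction day
    (1 or 2 for the duplicate design, 3 for reproducibility replicates).
    """

    sample_id: str
    product: str
    increment: int
    extraction_day: int
    sensory_score: float

    def __post_init__(self) -> None:
        if not (1 <= self.sensory_score <= 100):
            raise ValueError(
                f"sample {self.sample_id!r}: sensory_score "
                f"{self.sensory_score} outside the 1-100 scale"
            )
        if self.increment < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: increment must be >= 1"
            )
        if self.extraction_day not in (1, 2, 3):
            raise ValueError(
                f"sample {self.sample_id!r}: extraction_day must be 1, 2 or 3"
            )


@dataclass(frozen=True)
class ReferenceCompound:
    """A library entry used for tolerance-window annotation.

    ``direction`` records whether the compound is detected at higher
    levels in decomposed ("increasing") or nondecomposed ("decreasing")
    samples. ``confirmation`` is the identification confidence level:
    "standard" (reference-standard confirmed), "database" (putative
    spectral-database match) or "unknown".
    """

    name: str
    neutral_mass: float
    rt: float
    direction: str = "increasing"
    confirmation: str = "unknown"
    used_in_products: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.name!r}: neutral_mass must be > 0")
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(
                f"{self.name!r}: direction must be 'increasing' or "
                f"'decreasing', got {self.direction!r}"
            )
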