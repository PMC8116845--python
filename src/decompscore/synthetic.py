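"""Synthetic LC-HRMS study generator.

Emulates the decomposition study design: per product, ``n_increments``
discrete quality increments (fresh -> advanced decomposition), 5 sample
portions per increment, each portion extracted in duplicate on separate
days, plus a third-day replicate of one portion from the low, borderline
and high increments. Sensory scores are assigned per *portion* (sensory
assessment happens once, before frozen storage), so replicate extraction
rows share the portion's score.

The feature table holds ``n_background`` non-responsive compounds and
``n_markers`` responsive ones. A marker's expected area follows

    area = baseline * 2**(b * d(s)) * lognormal_noise * day_factor

where ``d(s) = (score - 50) / 50`` maps the sensory score onto [-1, 1]
around the decomposition boundary, and ``b`` is the compound's log2
slope, positive for markers that accumulate with decomposition and
negative for the minority detected at higher levels in fresh samples.
Slopes are calibrated from the noiseless design trajectory so that the
mean absolute log2 fold change between decomposed (score > 50) and
nondecomposed (score < 50) groups equals ``effect_log2fc``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .types import CompoundMeta, FeatureTable, SensoryRecord

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "MarkerTruth",
    "marker_response",
    "simulate_sensory_scores",
    "simulate_feature_table",
    "simulate_study",
    "default_study_configs",
]

#: Chromatographic window (minutes) used when drawing synthetic RTs.
_RT_RANGE = (0.5, 33.0)
#: Neutral-mass window (Da) used when drawing synthetic masses.
_MASS_RANGE = (100.0, 900.0)


def _default_triplicate_increments(n: int) -> frozenset[int]:
    # low, borderline, high: 1st, middle, and highest increment
    return frozenset({1, math.ceil(n / 2), n})


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and noise parameters for one simulated product.

    Defaults reproduce the standard product layout: 7 increments x 5
    portions x 2 extraction days + 3 third-day replicate rows = 73
    samples, 1900 background + 100 marker compounds, 15% of markers
    decreasing with decomposition, a mean group contrast of 3 log2
    units, 20% multiplicative analytical noise, and a day batch effect
    of 0.1 on the natural-log scale.
    """

    product: str = "SYN"
    n_increments: int = 7
    samples_per_increment: int = 5
    extraction_days: int = 2
    triplicate_increments: frozenset[int] | None = None
    n_background: int = 1900
    n_markers: int = 100
    frac_decreasing: float = 0.15
    effect_log2fc: float = 3.0
    noise_cv: float = 0.2
    day_effect_sd: float = 0.1
    score_low: float = 15.0
    score_high: float = 85.0
    score_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_increments", "samples_per_increment", "extraction_days",
                     "n_background", "n_markers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.frac_decreasing <= 1.0):
            raise ValueError("frac_decreasing must lie in [0, 1]")
        if not (1 <= self.score_low < 50 < self.score_high <= 100):
            raise ValueError(
                "score endpoints must lie in [1, 100] and straddle the "
                "50-point decomposition boundary"
            )

    @property
    def triplicates(self) -> frozenset[int]:
        if self.triplicate_increments is not None:
            return frozenset(self.triplicate_increments)
        return _default_triplicate_increments(self.n_increments)

    @property
    def n_samples(self) -> int:
        """Number of emitted sample records."""
        return (
            self.n_increments * self.samples_per_increment * self.extraction_days
            + len(self.triplicates)
        )

    def increment_means(self) -> np.ndarray:
        """Noiseless sensory trajectory: linear from score_low to score_high."""
        if self.n_increments == 1:
            return np.array([(self.score_low + self.score_high) / 2])
        return np.linspace(self.score_low, self.score_high, self.n_increments)


@dataclass(frozen=True)
class MarkerTruth:
    compound_id: str
    direction: str  # "increasing" | "decreasing"
    log2_slope: float  # signed slope b on the d(s) scale


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure emitted alongside a synthetic feature table."""

    markers: tuple[MarkerTruth, ...]
    true_scores: tuple[float, ...]  # noiseless per-increment trajectory

    @property
    def marker_ids(self) -> list[str]:
        return [m.compound_id for m in self.markers]


def marker_response(baseline: float, log2_slope: float, score: float) -> float:
    """Noiseless expected area of a marker at a given sensory score.

    ``baseline`` is the area at the 50-point boundary; the response is
    ``baseline * 2**(log2_slope * (score - 50) / 50)``.
    """
    return baseline * 2.0 ** (log2_slope * (score - 50.0) / 50.0)


def simulate_sensory_scores(
    config: GeneratorConfig, seed: int | None = None
) -> list[SensoryRecord]:
    """Draw the per-product sensory table.

    Portion scores are Gaussian around the increment mean (sd =
    ``score_sd``), clipped to [1, 100]; a draw landing exactly on 50 is
    resampled because the decomposed/nondecomposed rule is undefined
    there. Realized increment means are guaranteed strictly increasing
    (the whole product is redrawn in the vanishingly rare case they are
    not). Duplicate/triplicate extraction rows of a portion share its
    single score.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    means = config.increment_means()
    for _ in range(100):
        portion_scores = np.clip(
            rng.normal(
                means[:, None],
                config.score_sd,
                size=(config.n_increments, config.samples_per_increment),
            ),
            1.0,
            100.0,
        )
        while np.any(portion_scores == 50.0):
            mask = portion_scores == 50.0
            portion_scores[mask] = np.clip(
                rng.normal(means[:, None] * np.ones_like(portion_scores),
                           config.score_sd)[mask], 1.0, 100.0,
            )
        if np.all(np.diff(portion_scores.mean(axis=1)) > 0):
            break
    else:  # pragma: no cover - requires pathological config
        raise RuntimeError("could not draw strictly increasing increment means")

    records = []
    for inc in range(1, config.n_increments + 1):
        for portion in range(1, config.samples_per_increment + 1):
            score = float(portion_scores[inc - 1, portion - 1])
            days = list(range(1, config.extraction_days + 1))
            # third-day reproducibility replicate: portion 1 of the
            # low / borderline / high increments
            if inc in config.triplicates and portion == 1:
                days.append(config.extraction_days + 1)
            for day in days:
                records.append(
                    SensoryRecord(
                        sample_id=f"{config.product}-i{inc}-p{portion}-d{day}",
                        product=config.product,
                        increment=inc,
                        extraction_day=day,
                        sensory_score=score,
                    )
                )
    return records


def _slopes_for_contrasts(
    config: GeneratorConfig, targets: np.ndarray
) -> np.ndarray:
    """Slopes b whose noiseless decomposed/nondecomposed group contrast
    equals each target (in log2 units).

    The contrast of a slope-b marker under the design trajectory is
    ``log2(mean(2**(b*d)) over d>0 / mean(2**(b*d)) over d<0)`` — log2 of
    the ratio of *mean areas*, matching how fold change is computed
    downstream. It is strictly increasing in b; solved by bisection.
    """
    means = config.increment_means()
    d = (np.repeat(means, config.samples_per_increment) - 50.0) / 50.0
    dec, non = d[d > 0], d[d < 0]
    if len(dec) == 0 or len(non) == 0:  # pragma: no cover - config guard
        return np.asarray(targets, dtype=float)

    def contrast(b: np.ndarray) -> np.ndarray:
        num = np.mean(2.0 ** (b[:, None] * dec[None, :]), axis=1)
        den = np.mean(2.0 ** (b[:, None] * non[None, :]), axis=1)
        return np.log2(num / den)

    targets = np.asarray(targets, dtype=float)
    lo = np.zeros_like(targets)
    hi = np.full_like(targets, 2.0)
    for _ in range(60):  # expand until bracketed
        short = contrast(hi) < targets
        if not short.any():
            break
        hi[short] *= 2.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        below = contrast(mid) < targets
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return (lo + hi) / 2.0


def simulate_feature_table(
    config: GeneratorConfig,
    sensory_records: Sequence[SensoryRecord],
    seed: int | None = None,
) -> tuple[FeatureTable, GroundTruth]:
    """Draw the compounds x samples peak-area matrix.

    Markers respond to the sample's decomposition driver
    ``d = (score - 50)/50``; background compounds do not. Both receive
    multiplicative lognormal noise (CV = ``noise_cv``) and a per-day,
    per-compound batch factor (sd = ``day_effect_sd`` on the log scale).
    """
    if seed is None:
        seed = config.seed + 1
    if not sensory_records:
        raise ValueError("sensory_records must be non-empty")
    products = {r.product for r in sensory_records}
    if products != {config.product}:
        raise ValueError(
            f"sensory records are for products {sorted(products)}, "
            f"config is for {config.product!r}"
        )
    ids = [r.sample_id for r in sensory_records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in sensory records")

    rng = np.random.default_rng(seed)
    n_total = config.n_markers + config.n_background
    scores = np.array([r.sensory_score for r in sensory_records])
    days = np.array([r.extraction_day for r in sensory_records])
    d = (scores - 50.0) / 50.0

    # compound metadata: plausible mass/RT coordinates, uniform draws
    masses = rng.uniform(*_MASS_RANGE, size=n_total)
    rts = rng.uniform(*_RT_RANGE, size=n_total)
    digits = len(str(n_total))
    compounds = [
        CompoundMeta(
            compound_id=(
                f"MK{i + 1:0{digits}d}" if i < config.n_markers
                else f"BG{i - config.n_markers + 1:0{digits}d}"
            ),
            neutral_mass=round(float(masses[i]), 5),
            rt=round(float(rts[i]), 2),
        )
        for i in range(n_total)
    ]

    # marker effect magnitudes: ~N(effect_log2fc, effect/4) truncated at
    # effect/4, mapped to slopes whose design-group contrast matches,
    # signed by direction (a minority decreases with decomposition)
    n_dec = int(round(config.frac_decreasing * config.n_markers))
    signs = np.ones(config.n_markers)
    signs[:n_dec] = -1.0
    rng.shuffle(signs)
    magnitudes = np.maximum(
        rng.normal(config.effect_log2fc, config.effect_log2fc / 4.0,
                   size=config.n_markers),
        config.effect_log2fc / 4.0,
    )
    slopes = signs * _slopes_for_contrasts(config, magnitudes)

    # log-scale noise parameters
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    baselines = 10.0 ** rng.uniform(5.0, 7.0, size=n_total)

    n_days = int(days.max())
    day_factors = np.exp(
        rng.normal(0.0, config.day_effect_sd, size=(n_total, n_days))
    )

    expected = np.tile(baselines[:, None], (1, len(ids)))
    expected[: config.n_markers, :] *= 2.0 ** (slopes[:, None] * d[None, :])
    noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=expected.shape))
    areas = expected * noise * day_factors[:, days - 1]

    truth = GroundTruth(
        markers=tuple(
            MarkerTruth(
                compound_id=compounds[i].compound_id,
                direction="increasing" if slopes[i] > 0 else "decreasing",
                log2_slope=float(slopes[i]),
            )
            for i in range(config.n_markers)
        ),
        true_scores=tuple(float(m) for m in config.increment_means()),
    )
    return FeatureTable(compounds, ids, areas), truth


@dataclass(frozen=True)
class ProductDataset:
    """One simulated product: sensory table, feature table, ground truth."""

    product: str
    config: GeneratorConfig
    sensory: tuple[SensoryRecord, ...]
    features: FeatureTable
    truth: GroundTruth


def derive_seed(master_seed: int, *keys: str | int) -> int:
    """Deterministic per-stage seed fan-out (always < 2**31)."""
    ss = np.random.SeedSequence(
        master_seed,
        spawn_key=tuple(
            k if isinstance(k, int) else int.from_bytes(k.encode(), "little")
            for k in keys
        ),
    )
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_study(
    configs: Sequence[GeneratorConfig] | Mapping[str, GeneratorConfig],
    master_seed: int,
) -> dict[str, ProductDataset]:
    """Simulate a multi-product study with deterministic per-product seeds."""
    if isinstance(configs, Mapping):
        configs = [replace(c, product=p) for p, c in configs.items()]
    configs = list(configs)
    if not configs:
        raise ValueError("at least one product config is required")
    codes = [c.product for c in configs]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate product codes: {dupes}")

    datasets = {}
    for cfg in configs:
        s_seed = derive_seed(master_seed, cfg.product, "sensory")
        f_seed = derive_seed(master_seed, cfg.product, "features")
        sensory = simulate_sensory_scores(cfg, s_seed)
        features, truth = simulate_feature_table(cfg, sensory, f_seed)
        datasets[cfg.product] = ProductDataset(
            product=cfg.product,
            config=cfg,
            sensory=tuple(sensory),
            features=features,
            truth=truth,
        )
    return datasets


def default_study_configs(
    products: Sequence[str] | None = None,
    **overrides,
) -> list[GeneratorConfig]:
    """Default 23-product study layout (8 increments for the swordfish
    product without CO treatment, 7 elsewhere)."""
    from .io_tables import load_study_design

    design = load_study_design()
    if products is not None:
        design = design[design["product"].isin(products)]
    return [
        GeneratorConfig(
            product=row.product,
            n_increments=int(row.n_increments),
            **overrides,
        )
        for row in design.itertuples(index=False)
    ]
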