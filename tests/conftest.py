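import numpy as np
import pytest

import decompscore as d
from decompscore.types import CompoundMeta, FeatureTable


@pytest.fixture(scope="session")
def default_dataset():
    """One full-scale synthetic product at generator defaults
    (7 increments x 5 portions x 2 days + 3 triplicate rows = 73 samples,
    1900 background + 100 marker compounds)."""
    cfg = d.GeneratorConfig()
    recs = d.simulate_sensory_scores(cfg, 101)
    table, truth = d.simulate_feature_table(cfg, recs, 102)
    return cfg, recs, table, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced product (180 compounds, 30 markers) for fast model tests."""
    cfg = d.GeneratorConfig(n_background=150, n_markers=30)
    recs = d.simulate_sensory_scores(cfg, 7)
    table, truth = d.simulate_feature_table(cfg, recs, 8)
    return cfg, recs, table, truth


@pytest.fixture(scope="session")
def small_bundle(small_dataset):
    """A fitted two-stage model on the reduced product."""
    cfg, recs, table, truth = small_dataset
    return d.fit_product_model(
        table,
        recs,
        split_spec=d.SplitSpec(seed=11),
        forest_config=d.ForestConfig(n_trees=150, rng_seed=12),
        n_top=30,
        k_grid=[1, 3, 6, 12, 30],
    )


def make_table(areas, sample_ids=None, masses=None, rts=None, prefix="C"):
    """Tiny feature table from a 2-D array for hand-built test cases."""
    areas = np.asarray(areas, dtype=float)
    n_c, n_s = areas.shape
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(n_s)]
    compounds = [
        CompoundMeta(
            compound_id=f"{prefix}{i + 1}",
            neutral_mass=masses[i] if masses else 100.0 + i,
            rt=rts[i] if rts else 1.0 + 0.1 * i,
        )
        for i in range(n_c)
    ]
    return FeatureTable(compounds, sample_ids, areas)


def make_records(scores, product="TST", increment=1, day=1):
    """Sensory records with explicit scores, one per sample."""
    return [
        d.SensoryRecord(
            sample_id=f"S{j + 1}",
            product=product,
            increment=increment,
            extraction_day=day,
            sensory_score=float(s),
        )
        for j, s in enumerate(scores)
    ]
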