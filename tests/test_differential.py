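"""Volcano differential selection: boundary rule, fold change, Welch
test, and agreement with brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import decompscore as d
from decompscore.differential import DECOMPOSED, NONDECOMPOSED
from conftest import make_records, make_table


class TestSegregate:
    @pytest.mark.parametrize(
        "score,label",
        [(52, DECOMPOSED), (45, NONDECOMPOSED), (50.001, DECOMPOSED),
         (49.999, NONDECOMPOSED)],
    )
    def test_boundary_rule(self, score, label):
        recs = make_records([score])
        assert d.segregate(recs)["S1"] == label

    def test_exact_fifty_rejected(self):
        with pytest.raises(ValueError, match="exactly 50"):
            d.segregate(make_records([50]))


class TestLog2FoldChange:
    def test_four_fold_change(self):
        assert d.log2_fold_change([4000.0], [1000.0], 0.0) == pytest.approx(2.0)

    def test_equal_means_zero(self):
        assert d.log2_fold_change([5.0, 7.0], [6.0, 6.0], 0.0) == 0.0

    def test_zero_group_finite_via_pseudo_area(self):
        lfc = d.log2_fold_change([0.0], [1000.0], pseudo_area=1.0)
        assert lfc == pytest.approx(np.log2(1 / 1001), abs=1e-3)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            d.log2_fold_change([-1.0], [1.0])


def welch_oracle(x, y):
    """Textbook Welch t-test: t statistic and Welch-Satterthwaite degrees
    of freedom computed from first principles, p from the t distribution."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    dof = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2 * stats.t.sf(abs(t), dof)


class TestWelchP:
    def test_identical_groups_give_p_one(self):
        assert d.welch_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_no_variance_equal_means_convention(self):
        assert d.welch_p([5.0, 5.0], [5.0, 5.0]) == 1.0

    def test_no_variance_different_means(self):
        assert d.welch_p([5.0, 5.0], [9.0, 9.0]) == 0.0

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            d.welch_p([1.0], [1.0, 2.0])

    def test_agrees_with_first_principles_welch(self):
        # areas chosen so the internal log2(area+1) transform gives the
        # log-scale groups the oracle sees
        log_x = np.array([10.0, 10.1, 9.9])
        log_y = np.array([13.0, 13.2, 12.8])
        areas_x = 2.0**log_x - 1.0
        areas_y = 2.0**log_y - 1.0
        expected = welch_oracle(log_x, log_y)
        assert d.welch_p(areas_x, areas_y) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_oracle_on_random_groups(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(10, 1e5, size=rng.integers(2, 12))
        b = rng.uniform(10, 1e5, size=rng.integers(2, 12))
        expected = welch_oracle(np.log2(a + 1), np.log2(b + 1))
        assert d.welch_p(a, b) == pytest.approx(expected, abs=1e-10)


def brute_force_volcano(table, labels, fc_threshold=1.0, n_top=100,
                        pseudo=1.0):
    """Independent selection: full per-compound statistics, explicit sort
    over the cross-product of (p, |lfc|, id)."""
    dec = [s for s in table.samples if labels[s] == DECOMPOSED]
    non = [s for s in table.samples if labels[s] == NONDECOMPOSED]
    frame = table.to_frame()
    rows = []
    for cid in table.compound_ids:
        lfc = np.log2(
            (frame.loc[cid, dec].mean() + pseudo)
            / (frame.loc[cid, non].mean() + pseudo)
        )
        x = np.log2(frame.loc[cid, dec].to_numpy() + pseudo)
        y = np.log2(frame.loc[cid, non].to_numpy() + pseudo)
        if x.var() == 0 and y.var() == 0:
            p = 1.0 if x.mean() == y.mean() else 0.0
        else:
            p = welch_oracle(x, y)
        rows.append((cid, lfc, p))
    passers = sorted(
        (r for r in rows if abs(r[1]) > fc_threshold),
        key=lambda r: (r[2], -abs(r[1]), r[0]),
    )
    return {r[0] for r in passers[:n_top]}


class TestVolcanoSelect:
    def _random_case(self, seed, n_c=18, n_s=12):
        rng = np.random.default_rng(seed)
        table = make_table(rng.uniform(0, 1e4, size=(n_c, n_s)))
        scores = rng.uniform(20, 80, n_s)
        scores[scores == 50] = 51
        recs = make_records(scores)
        return table, d.segregate(recs)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_oracle(self, seed):
        table, labels = self._random_case(seed)
        expected = brute_force_volcano(table, labels, n_top=5)
        got = {
            r.compound_id
            for r in d.volcano_select(table, labels, n_top=5)
            if r.selected
        }
        assert got == expected

    def test_selects_exactly_n_top_when_more_pass(self):
        rng = np.random.default_rng(0)
        n_c = 150
        base = rng.uniform(1e3, 1e4, n_c)
        # every compound responds: decomposed samples at 4x the mean
        areas = np.column_stack(
            [base * rng.lognormal(0, 0.05, n_c) for _ in range(5)]
            + [4 * base * rng.lognormal(0, 0.05, n_c) for _ in range(5)]
        )
        table = make_table(areas)
        labels = d.segregate(make_records([40] * 5 + [60] * 5))
        recs = d.volcano_select(table, labels, n_top=100)
        assert sum(r.selected for r in recs) == 100

    def test_fewer_passers_all_selected(self):
        table, labels = self._random_case(3, n_c=20)
        recs = d.volcano_select(table, labels, n_top=100)
        n_pass = sum(r.passes_fc for r in recs)
        assert sum(r.selected for r in recs) == min(100, n_pass)

    def test_selected_implies_passes_fc(self, default_dataset):
        _, recs, table, _ = default_dataset
        records = d.volcano_select(table, d.segregate(recs))
        assert all(r.passes_fc for r in records if r.selected)
        assert all(abs(r.log2fc) > 1.0 for r in records if r.selected)
        assert all(0 <= r.p_value <= 1 for r in records)

    def test_invariant_to_sample_permutation_and_global_rescaling(self):
        table, labels = self._random_case(11)
        baseline = {
            r.compound_id
            for r in d.volcano_select(table, labels, n_top=6, pseudo_area=0.0)
            if r.selected
        }
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(table.samples))
        permuted = table.subset_samples(perm)
        scaled = make_table(permuted.areas * 1000.0,
                            sample_ids=permuted.samples)
        got = {
            r.compound_id
            for r in d.volcano_select(scaled, labels, n_top=6, pseudo_area=0.0)
            if r.selected
        }
        assert got == baseline

    def test_one_group_empty_rejected(self):
        table = make_table(np.ones((3, 4)))
        labels = d.segregate(make_records([60, 60, 60, 60]))
        with pytest.raises(ValueError, match="group"):
            d.volcano_select(table, labels)


def test_volcano_csv_export(tmp_path):
    import pandas as pd

    table = make_table(np.random.default_rng(0).uniform(1, 100, (4, 6)))
    labels = d.segregate(make_records([40, 41, 42, 60, 61, 62]))
    records = d.volcano_select(table, labels, n_top=2)
    path = tmp_path / "volcano.csv"
    d.differential.write_volcano_csv(records, path)
    back = pd.read_csv(path)
    assert list(back.columns) == [
        "compound_id", "log2fc", "neg_log10_p", "passes_fc", "selected",
    ]
    assert len(back) == 4
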