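import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

import nestde as nd
from nestde.core import CountMatrix, NestedDesign, PseudobulkMatrix


def _pb(values, conditions, batches=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    S = values.shape[1]
    sample_ids = [f"s{i}" for i in range(S)]
    return PseudobulkMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=sample_ids,
        sample_to_condition=dict(zip(sample_ids, conditions)),
        sample_to_batch=dict(
            zip(sample_ids, batches or ["b1"] * S)
        ),
    )


class TestPseudobulk:
    def test_one_cell_per_sample_is_identity(self):
        counts = np.array([[1, 2], [3, 4]])
        cm = CountMatrix(sp.csr_matrix(counts), ["g1", "g2"], ["c1", "c2"])
        design = NestedDesign(
            {"c1": "s1", "c2": "s2"},
            {"s1": "b1", "s2": "b1"},
            {"s1": "1", "s2": "2"},
        )
        pb = nd.pseudobulk(cm, design)
        assert np.array_equal(pb.values, counts)

    def test_hand_aggregation_toy(self, toy_counts, toy_design):
        pb = nd.pseudobulk(toy_counts, toy_design)
        # s1 = c0+c1, s2 = c2+c3 of the toy matrix
        expected = np.array([[3, 7], [0, 0], [5, 7], [4, 4]], dtype=float)
        assert np.array_equal(pb.values, expected)
        mean = nd.pseudobulk(toy_counts, toy_design, agg="mean")
        assert np.array_equal(mean.values, expected / 2)

    def test_mass_conservation(self, small_dataset_sim):
        sim = small_dataset_sim
        pb = nd.pseudobulk(sim.counts, sim.design)
        assert pb.values.sum() == pytest.approx(sim.counts.counts.sum())

    def test_empty_sample_dropped_with_warning(self, toy_counts, toy_design):
        design = NestedDesign(
            dict(toy_design.cell_to_sample),
            {**toy_design.sample_to_batch, "s3": "b1"},
            {**toy_design.sample_to_condition, "s3": "1"},
        )
        pb = nd.pseudobulk(toy_counts, design)
        assert list(pb.sample_ids) == ["s1", "s2"]


class TestNormalize:
    def test_cpm_column_totals(self, toy_counts, toy_design):
        pb = nd.normalize_pseudobulk(nd.pseudobulk(toy_counts, toy_design), "cpm")
        np.testing.assert_allclose(pb.values.sum(axis=0), [1e6, 1e6])

    def test_none_is_identity(self, toy_counts, toy_design):
        pb = nd.pseudobulk(toy_counts, toy_design)
        assert nd.normalize_pseudobulk(pb, "none") is pb

    def test_log1p_cpm_hand_values(self):
        pb = _pb([[2, 1], [2, 3]], ["1", "2"])
        out = nd.normalize_pseudobulk(pb, "log1p_cpm")
        expected = np.log1p(
            np.array([[2, 1], [2, 3]]) / np.array([4, 4]) * 1e6
        )
        np.testing.assert_allclose(out.values, expected)

    def test_zero_column_rejected(self):
        pb = _pb([[1, 0], [1, 0]], ["1", "2"])
        with pytest.raises(ValueError):
            nd.normalize_pseudobulk(pb, "cpm")


class TestPermutationTest:
    def test_constant_gene_p_is_one(self):
        pb = _pb([[5, 5, 5, 5, 5, 5]], ["1", "1", "1", "2", "2", "2"])
        res = nd.permutation_test(pb, nd.PermutationConfig(normalization="none"))
        assert res.table.p_value.iloc[0] == 1.0

    def test_exhaustive_three_vs_three_toy(self):
        # {10,11,12} vs {20,21,22}: of the 20 distinct assignments only the
        # observed one and its mirror reach |delta| = 10 -> p = 2/20
        pb = _pb([[10, 11, 12, 20, 21, 22]], ["1", "1", "1", "2", "2", "2"])
        res = nd.permutation_test(pb, nd.PermutationConfig(normalization="none"))
        assert res.table.p_value.iloc[0] == pytest.approx(0.1)
        assert res.table.n_resamples_used.iloc[0] == 20
        assert res.table.effect.iloc[0] == pytest.approx(-10.0)

    def test_monte_carlo_agrees_with_exhaustive(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(50, size=(30, 6)).astype(float)
        conds = ["1", "1", "1", "2", "2", "2"]
        exact = nd.permutation_test(
            _pb(values, conds), nd.PermutationConfig(normalization="none")
        )
        mc = nd.permutation_test(
            _pb(values, conds),
            nd.PermutationConfig(
                normalization="none", exhaustive_threshold=1, n_perm=4000, seed=1
            ),
        )
        p_ex = exact.table.p_value.to_numpy()
        p_mc = mc.table.p_value.to_numpy()
        se = np.sqrt(p_ex * (1 - p_ex) / 4000)
        assert np.all(np.abs(p_mc - p_ex) <= 3 * se + 1 / 4000)

    def test_p_floor_one_over_n(self):
        pb = _pb([[0, 0, 0, 100, 100, 100]], ["1", "1", "1", "2", "2", "2"])
        cfg = nd.PermutationConfig(
            normalization="none", exhaustive_threshold=1, n_perm=500, seed=2
        )
        res = nd.permutation_test(pb, cfg)
        assert res.table.p_value.iloc[0] >= 1 / 500

    def test_null_p_values_uniform(self):
        # exchangeable pseudobulks with no DE and no batches: KS should not
        # reject uniformity on the attainable grid at alpha = 0.01
        rng = np.random.default_rng(7)
        values = rng.normal(100, 10, size=(5000, 10))
        conds = ["1"] * 5 + ["2"] * 5
        res = nd.permutation_test(
            _pb(values, conds), nd.PermutationConfig(normalization="none")
        )
        p = res.table.p_value.to_numpy()
        assert scipy.stats.kstest(p, "uniform").pvalue > 0.01

    def test_single_condition_rejected(self):
        pb = _pb([[1, 2]], ["1", "1"])
        with pytest.raises(ValueError):
            nd.permutation_test(pb, nd.PermutationConfig())


def _two_condition_cm(values1, values2, cells_per_sample=1):
    """Build a CountMatrix + design with one gene per row of values."""
    values = np.concatenate([values1, values2])
    n1 = len(values1)
    cells = [f"c{i}" for i in range(len(values))]
    cm = CountMatrix(
        sp.csr_matrix(np.atleast_2d(values)), ["g0"], cells
    )
    design = NestedDesign(
        {c: f"s{i}" for i, c in enumerate(cells)},
        {f"s{i}": "b1" for i in range(len(cells))},
        {f"s{i}": ("1" if i < n1 else "2") for i in range(len(cells))},
    )
    return cm, design


class TestHierarchicalBootstrap:
    def test_adaptive_escalation_on_floor_genes(self, small_dataset_sim):
        sim = small_dataset_sim
        cm = nd.filter_genes(sim.counts)
        cfg = nd.BootstrapConfig(
            n_boot_initial=200, n_boot_escalated=400, cells_per_draw=20, seed=0
        )
        res = nd.hierarchical_bootstrap(cm, sim.design, cfg)
        used = res.table.n_resamples_used.to_numpy()
        p = res.table.p_value.to_numpy()
        assert set(used) <= {200, 400}
        assert (used == 400).any()  # strong DE genes hit the stage-1 floor
        # non-escalated genes never sit at the stage-1 floor unless all-tied
        stage1 = used == 200
        assert np.all((p[stage1] > 1 / 200) | (p[stage1] == 1.0))

    def test_duplicated_conditions_symmetric(self):
        # both conditions hold copies of the same cells: no gene should look
        # convincingly different
        rng = np.random.default_rng(8)
        base = rng.poisson(5, size=(50, 200))
        counts = np.concatenate([base, base], axis=1)
        cells = [f"c{i}" for i in range(400)]
        cm = CountMatrix(sp.csr_matrix(counts), [f"g{i}" for i in range(50)], cells)
        design = NestedDesign(
            {c: f"s{i // 100}" for i, c in enumerate(cells)},
            {f"s{i}": "b1" for i in range(4)},
            {f"s{i}": ("1" if i < 2 else "2") for i in range(4)},
        )
        cfg = nd.BootstrapConfig(
            n_boot_initial=300, n_boot_escalated=600, cells_per_draw=50, seed=1
        )
        res = nd.hierarchical_bootstrap(cm, design, cfg)
        assert res.table.p_value.median() >= 0.2

    def test_exclusive_expression_hits_floor(self):
        # g0 expressed only in condition 1; g1 constant so every cell has
        # nonzero total for CPM
        counts = np.array([[40, 50, 60, 0, 0, 0], [10, 10, 10, 10, 10, 10]])
        cells = [f"c{i}" for i in range(6)]
        cm = CountMatrix(sp.csr_matrix(counts), ["g0", "g1"], cells)
        design = NestedDesign(
            {c: f"s{i}" for i, c in enumerate(cells)},
            {f"s{i}": "b1" for i in range(6)},
            {f"s{i}": ("1" if i < 3 else "2") for i in range(6)},
        )
        cfg = nd.BootstrapConfig(
            n_boot_initial=100, n_boot_escalated=200, cells_per_draw=5, seed=2
        )
        res = nd.hierarchical_bootstrap(cm, design, cfg)
        assert res.table.p_value.iloc[0] == pytest.approx(1 / 200)
        assert res.table.n_resamples_used.iloc[0] == 200

    def test_p_never_below_floor(self, small_dataset_sim):
        sim = small_dataset_sim
        cfg = nd.BootstrapConfig(
            n_boot_initial=100, n_boot_escalated=300, cells_per_draw=20, seed=3
        )
        res = nd.hierarchical_bootstrap(sim.counts, sim.design, cfg)
        used = res.table.n_resamples_used.to_numpy()
        assert np.all(res.table.p_value.to_numpy() >= 1 / used - 1e-12)

    def test_deterministic_under_seed(self, small_dataset_sim):
        sim = small_dataset_sim
        cfg = nd.BootstrapConfig(
            n_boot_initial=100, n_boot_escalated=200, cells_per_draw=10, seed=4
        )
        a = nd.hierarchical_bootstrap(sim.counts, sim.design, cfg)
        b = nd.hierarchical_bootstrap(sim.counts, sim.design, cfg)
        assert a.table.equals(b.table)

    def test_batch_in_single_condition_excluded(self):
        # batch b2 exists only in condition 1: excluded with a warning;
        # shared batch b1 remains
        counts = np.ones((2, 8), dtype=int)
        cells = [f"c{i}" for i in range(8)]
        cm = CountMatrix(sp.csr_matrix(counts), ["g0", "g1"], cells)
        design = NestedDesign(
            {c: f"s{i // 2}" for i, c in enumerate(cells)},
            {"s0": "b1", "s1": "b2", "s2": "b1", "s3": "b1"},
            {"s0": "1", "s1": "1", "s2": "2", "s3": "2"},
        )
        cfg = nd.BootstrapConfig(
            n_boot_initial=50, n_boot_escalated=100, cells_per_draw=2, seed=5
        )
        res = nd.hierarchical_bootstrap(cm, design, cfg)
        assert len(res.table) == 2

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            nd.BootstrapConfig(n_boot_initial=100, n_boot_escalated=100)


class TestCellTTest:
    def test_identical_groups_p_one(self):
        counts = np.tile([[3, 7]], (1, 2))  # cells (3,7) vs (3,7)
        cells = [f"c{i}" for i in range(4)]
        cm = CountMatrix(sp.csr_matrix(counts), ["g0"], cells)
        design = NestedDesign(
            {c: f"s{i // 2}" for i, c in enumerate(cells)},
            {"s0": "b1", "s1": "b1"},
            {"s0": "1", "s1": "2"},
        )
        res = nd.cell_t_test(cm, design, normalization="raw")
        assert res.table.p_value.iloc[0] == 1.0
        assert res.table.effect.iloc[0] == 0.0

    def test_welch_textbook_toy(self):
        cm, design = _two_condition_cm([1, 2, 3], [4, 5, 6])
        res = nd.cell_t_test(cm, design, normalization="raw")
        # hand Welch: means 2 vs 5, s1=s2=1, se = sqrt(1/3+1/3), t = -3/se,
        # df = 4 (equal variances/sizes)
        se = np.sqrt(2 / 3)
        t_expected = -3 / se
        p_expected = 2 * scipy.stats.t.sf(abs(t_expected), df=4)
        assert res.table.effect.iloc[0] == pytest.approx(-3.0)
        assert res.table.p_value.iloc[0] == pytest.approx(p_expected, rel=1e-6)

    def test_inflated_fpr_on_negative_control(self, small_negative_control_sim):
        # with ICC > 0, treating cells as replicates inflates significance
        sim = small_negative_control_sim
        cm = nd.filter_genes(sim.counts)
        res = nd.cell_t_test(cm, sim.design)
        fpr = (res.table.p_value <= 0.05).mean()
        assert fpr > 0.05

    def test_requires_two_cells_per_condition(self):
        cm, design = _two_condition_cm([1], [2])
        with pytest.raises(ValueError):
            nd.cell_t_test(cm, design, normalization="raw")
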