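import itertools

import numpy as np
import pytest
import scipy.stats

from scduet.diffexp import (
    DEConfig,
    NeighborDE,
    bh_adjust,
    log_fc,
    neighboring_de,
    wilcoxon_rank_sum,
)
from scduet.synthetic_data import (
    SimulationConfig,
    simulate_two_types,
    spike_interaction_signature,
)

from conftest import tiny_matrix


def exact_mwu_pvalue(x, y):
    """Oracle: two-sided p by exhaustive enumeration of rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    u_min = min(u_obs, n * m - u_obs)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        if min(u, n * m - u) <= u_min:
            count += 1
        total += 1
    return u_obs, min(1.0, count / total)


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n, m = rng.integers(3, 8, size=2)
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.normal(), size=m)
            u, p = wilcoxon_rank_sum(x, y)
            u_oracle, p_oracle = exact_mwu_pvalue(x, y)
            assert u == pytest.approx(u_oracle)
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_permutation_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 6, size=30).astype(float)
        y = (rng.integers(0, 6, size=30) + rng.integers(0, 2, size=30)).astype(float)
        _, p = wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        n, nm = len(x), len(x) * len(y)
        ranks_all = scipy.stats.rankdata(pooled)
        u_obs = ranks_all[:n].sum() - n * (n + 1) / 2
        stat_obs = abs(u_obs - nm / 2)
        b = 10_000
        hits = 0
        for _ in range(b):
            perm = rng.permutation(len(pooled))
            u = ranks_all[perm[:n]].sum() - n * (n + 1) / 2
            if abs(u - nm / 2) >= stat_obs - 1e-9:
                hits += 1
        p_mc = hits / b
        se = np.sqrt(p_mc * (1 - p_mc) / b)
        assert p == pytest.approx(p_mc, abs=max(3 * se, 0.01))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = rng.normal(loc=0.8, size=15)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1], [2, 3])


class TestBH:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.05, 0.5], [0.015, 0.075, 0.5]),
            ([0.2], [0.2]),
        ],
    )
    def test_hand_step_up_examples(self, pvals, expected):
        np.testing.assert_allclose(bh_adjust(pvals), expected, atol=1e-12)

    def test_adjusted_at_least_raw_and_order_invariant(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestLogFC:
    @pytest.mark.parametrize(
        "m1,m2,b,expected", [(3, 1, 1, 1.0), (2, 2, 1, 0.0), (0, 1, 1, -1.0)]
    )
    def test_printed_formula(self, m1, m2, b, expected):
        assert log_fc(m1, m2, b) == pytest.approx(expected)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m1, m2 = rng.uniform(0, 50, size=2)
            assert log_fc(m1, m2) == pytest.approx(-log_fc(m2, m1), abs=1e-12)


@pytest.fixture(scope="module")
def spiked_split():
    cfg = SimulationConfig(
        n_cells_a=120, n_cells_b=20, n_genes=600, signature_genes=12,
        signature_fc=4.0, seed=31,
    )
    matrix, truth = simulate_two_types(cfg)
    spiked = spike_interaction_signature(matrix, truth, cfg)
    is_a = truth.cell_type == "A"
    mat_a = spiked.subset_cells(np.where(is_a)[0])
    selected = set(spiked.cell_ids[truth.interacting])
    return mat_a, selected, truth


class TestNeighboringDE:

    def test_spiked_genes_recovered_as_up(self, spiked_split):
        mat_a, selected, truth = spiked_split
        result = neighboring_de(mat_a, selected)
        recovered = set(result.up) & set(truth.signature_gene_ids)
        assert len(recovered) >= 0.9 * len(truth.signature_gene_ids)

    def test_null_gene_not_flagged(self):
        # every cell identical -> each gene has identical values in both
        # groups at every stage of the pipeline
        counts = np.tile([4, 9, 7, 0, 2], (30, 1))
        mat = tiny_matrix(counts)
        result = neighboring_de(mat, set(mat.cell_ids[:15]))
        row = result.table.set_index("gene").loc["g2"]
        assert not row["pass"]
        assert row["pval"] == 1.0
        assert row["log_fc"] == 0.0

    def test_permuted_labels_flag_nothing(self, spiked_split):
        mat_a, selected, _ = spiked_split
        rng = np.random.default_rng(44)
        flagged = []
        for _ in range(5):
            fake = set(rng.choice(mat_a.cell_ids, size=len(selected), replace=False))
            result = neighboring_de(mat_a, fake)
            flagged.append(int(result.table["pass"].sum()))
        assert sum(f == 0 for f in flagged) >= 4

    def test_model_results_wrapper_matches_function(self, spiked_split):
        mat_a, selected, _ = spiked_split
        r1 = NeighborDE(mat_a, selected).fit()
        r2 = neighboring_de(mat_a, selected)
        np.testing.assert_allclose(
            r1.table["pval_adj"].to_numpy(), r2.table["pval_adj"].to_numpy()
        )

    def test_logfc_uses_linear_norm10k_means(self, spiked_split):
        mat_a, selected, _ = spiked_split
        result = neighboring_de(mat_a, selected)
        norm = mat_a.counts / mat_a.totals()[:, None] * 1e4
        sel_mask = np.array([c in selected for c in mat_a.cell_ids])
        g0 = result.table.iloc[0]
        expected = np.log2(
            (norm[sel_mask, 0].mean() + 1) / (norm[~sel_mask, 0].mean() + 1)
        )
        assert g0["log_fc"] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_groups_rejected(self):
        mat = tiny_matrix(np.ones((4, 3), dtype=int))
        with pytest.raises(ValueError):
            neighboring_de(mat, {"c0"})
        with pytest.raises(ValueError):
            neighboring_de(mat, {"missing"})

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DEConfig(alpha_adj=0.0)
        with pytest.raises(ValueError):
            DEConfig(pseudo_b=0.0)
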