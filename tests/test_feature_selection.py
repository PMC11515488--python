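import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from wtgan.feature_selection import (
    EmptySelectionError,
    pearson_r,
    rank_relevance,
    redundancy_filter,
    select_features,
)
from wtgan.synthetic_data import SimSpec, simulate_mgecd

from conftest import make_table


def brute_force_pearson(v, u):
    """Independent two-pass evaluation of the product-moment formula."""
    v, u = list(map(float, v)), list(map(float, u))
    mv = sum(v) / len(v)
    mu = sum(u) / len(u)
    num = sum((a - mv) * (b - mu) for a, b in zip(v, u))
    den = (sum((a - mv) ** 2 for a in v) * sum((b - mu) ** 2 for b in u)) ** 0.5
    return num / den


class TestPearsonR:
    @pytest.mark.parametrize(
        "v,u,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_known_values(self, v, u, expected):
        assert pearson_r(v, u) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        v, u = rng.normal(size=n), rng.normal(size=n)
        r = pearson_r(v, u)
        assert r == pytest.approx(brute_force_pearson(v, u), abs=1e-12)
        assert r == pytest.approx(stats.pearsonr(v, u).statistic, abs=1e-10)
        assert r == pytest.approx(pearson_r(u, v), abs=1e-15)  # symmetry

    def test_constant_vector_is_undefined(self):
        assert np.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestRankRelevance:
    def test_label_copy_ranks_first_constant_last(self):
        labels = [0, 1, 0, 1]
        t = make_table(
            np.column_stack([np.full(4, 7.0), [0.1, 0.9, 0.2, 0.8], labels]), labels
        )
        ranked = rank_relevance(t)
        assert ranked[0][0] == "g2" and ranked[0][1] == pytest.approx(1.0)
        assert ranked[-1][0] == "g0" and ranked[-1][1] == 0.0

    def test_sorted_descending_with_index_tiebreak(self):
        rng = np.random.default_rng(5)
        t = make_table(rng.normal(size=(20, 6)), rng.integers(0, 2, 20))
        ranked = rank_relevance(t)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)


class TestRedundancyFilter:
    def _three_gene_table(self):
        # g0 and g1 near-duplicates (|r| > 0.9), g2 independent
        rng = np.random.default_rng(3)
        g0 = rng.normal(size=50)
        g1 = g0 + rng.normal(scale=0.1, size=50)
        g2 = rng.normal(size=50)
        return make_table(np.column_stack([g0, g1, g2]), rng.integers(0, 2, 50))

    def test_threshold_one_keeps_everything(self):
        t = self._three_gene_table()
        res = redundancy_filter(t, ["g0", "g1", "g2"], threshold=1.0)
        assert res.kept == ["g0", "g1", "g2"] and res.dropped == []

    def test_correlated_pair_drops_lower_ranked_member(self):
        t = self._three_gene_table()
        res = redundancy_filter(t, ["g0", "g1", "g2"], threshold=0.75)
        assert res.kept == ["g0", "g2"] and res.dropped == ["g1"]

    def test_idempotent_on_kept_subset(self):
        t = self._three_gene_table()
        res = redundancy_filter(t, ["g0", "g1", "g2"], threshold=0.75)
        sub = t.subset_genes(res.kept)
        res2 = redundancy_filter(sub, res.kept, threshold=0.75)
        assert res2.kept == res.kept and res2.dropped == []

    def test_kept_pairs_below_threshold(self):
        table, _ = simulate_mgecd(SimSpec(n_samples=50, n_features=60, n_informative=12, block_size=6,
                                          block_rho=0.7, seed=8))
        ranking = [g for g, _ in rank_relevance(table)]
        res = redundancy_filter(table, ranking, threshold=0.6)
        kept = table.subset_genes(res.kept).values
        c = np.corrcoef(kept, rowvar=False)
        off = np.abs(c[np.triu_indices_from(c, k=1)])
        assert off.max() <= 0.6 + 1e-9

    def test_kept_count_monotone_in_threshold(self):
        table, _ = simulate_mgecd(SimSpec(n_samples=40, n_features=50, n_informative=10, block_size=5,
                                          block_rho=0.6, seed=2))
        ranking = [g for g, _ in rank_relevance(table)]
        sizes = [
            len(redundancy_filter(table, ranking, th).kept)
            for th in (0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert sizes == sorted(sizes)

    def test_duplicated_blocks_keep_one_representative(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(30, 4))
        dup = np.repeat(base, 3, axis=1)  # 4 blocks of 3 identical genes
        t = make_table(dup, rng.integers(0, 2, 30))
        ranking = [g for g, _ in rank_relevance(t)]
        res = redundancy_filter(t, ranking, threshold=0.99)
        assert len(res.kept) == 4

    def test_bad_threshold_raises(self):
        t = self._three_gene_table()
        with pytest.raises(ValueError):
            redundancy_filter(t, ["g0", "g1", "g2"], threshold=0.0)


class TestSelectFeatures:
    def test_noop_configuration_returns_input(self):
        rng = np.random.default_rng(7)
        t = make_table(rng.normal(size=(25, 8)), rng.integers(0, 2, 25))
        sel, res = select_features(t, threshold=1.0, relevance_cutoff=0.0)
        assert sel.n_genes == t.n_genes
        assert sorted(sel.gene_ids) == sorted(t.gene_ids)
        assert res.dropped == []

    def test_partition_into_kept_and_dropped(self):
        table, _ = simulate_mgecd(SimSpec(n_samples=40, n_features=60, n_informative=12, seed=4))
        sel, res = select_features(table, threshold=0.7)
        assert sorted(res.kept + res.dropped) == sorted(table.gene_ids)
        assert set(res.kept) & set(res.dropped) == set()
        assert sel.gene_ids == res.kept

    def test_max_features_caps_selection(self):
        table, _ = simulate_mgecd(SimSpec(n_samples=40, n_features=60, n_informative=12, seed=4))
        sel, res = select_features(table, threshold=1.0, max_features=5)
        assert sel.n_genes == 5

    def test_all_genes_eliminated_raises(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.normal(size=(20, 3)), rng.integers(0, 2, 20))
        with pytest.raises(EmptySelectionError):
            select_features(t, threshold=1.0, relevance_cutoff=1.0)
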