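import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from gliostate.de import derive_consistent_signature, match_subsample, mwu_de, normalize_counts
from gliostate.simulate import generate_de_pair
from tests.conftest import dense_matrix


def exact_mwu_by_enumeration(a: list[float], b: list[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    pooled = a + b
    n_a = len(a)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mean_u = n_a * len(b) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


class TestMatchSubsample:
    def test_identity_pair_untouched(self):
        rng = np.random.default_rng(0)
        m = dense_matrix(rng.poisson(3.0, (20, 15)))
        pair = match_subsample(m, m, seed=1)
        assert pair.cells_dropped_a == pair.cells_dropped_b == 0
        assert pair.thinning_p == 1.0 and pair.thinned == "none"
        assert (pair.a.counts != m.counts).nnz == 0

    def test_double_depth_thinned_to_parity(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(5.0, (100, 1000))
        b = dense_matrix(base, cell_prefix="b")
        a = dense_matrix(base * 2, cell_prefix="a")  # exactly 2x depth
        pair = match_subsample(a, b, seed=2)
        assert pair.thinning_p == pytest.approx(0.5)
        avg_a = pair.a.cell_totals().mean()
        avg_b = pair.b.cell_totals().mean()
        assert abs(avg_a - avg_b) / avg_b < 0.01

    def test_unequal_cells_subsampled_to_smaller(self):
        rng = np.random.default_rng(2)
        a = dense_matrix(rng.poisson(3.0, (30, 50)), cell_prefix="a")
        b = dense_matrix(rng.poisson(3.0, (30, 80)), cell_prefix="b")
        pair = match_subsample(a, b, seed=3)
        assert pair.a.n_cells == pair.b.n_cells == 50
        assert pair.cells_dropped_b == 30

    def test_thinning_preserves_gene_proportions(self):
        """Binomial thinning keeps per-gene expression shares (chi-square)."""
        rng = np.random.default_rng(3)
        base = rng.poisson(20.0, (200, 400))
        b = dense_matrix(base, cell_prefix="b")
        a = dense_matrix(base * 3, cell_prefix="a")
        pair = match_subsample(a, b, seed=4)
        pre = (base * 3).sum(axis=1).astype(float)
        post = np.asarray(pair.a.counts.sum(axis=1)).ravel().astype(float)
        expected = pre * post.sum() / pre.sum()
        stat = ((post - expected) ** 2 / expected).sum()
        pval = scipy.stats.chi2.sf(stat, df=len(pre) - 1)
        assert pval > 0.01

    def test_idempotent_on_matched_pair(self):
        rng = np.random.default_rng(4)
        m1 = dense_matrix(rng.poisson(3.0, (20, 30)), cell_prefix="a")
        m2 = dense_matrix(rng.poisson(3.0, (20, 30)), cell_prefix="b")
        pair = match_subsample(m1, m2, seed=5)
        again = match_subsample(pair.a, pair.b, seed=6)
        # cell counts already equal -> no cells dropped on the second pass
        assert again.cells_dropped_a == again.cells_dropped_b == 0

    def test_zero_cell_condition_rejected(self):
        import scipy.sparse as sp

        from gliostate.io import CountMatrix

        empty = CountMatrix(genes=["g0"], cells=[], counts=sp.csr_matrix((1, 0), dtype=int))
        full = dense_matrix(np.ones((1, 3), dtype=int))
        full.genes = ["g0"]
        with pytest.raises(ValueError, match="zero-cell"):
            match_subsample(empty, full)


class TestNormalizeCounts:
    def test_equal_totals_identity(self):
        m = dense_matrix(np.array([[1, 2], [3, 2], [2, 2]]))  # totals 6 and 6
        norm = normalize_counts(m)
        np.testing.assert_allclose(norm.to_numpy(), np.asarray(m.counts.todense(), dtype=float))

    def test_scale_removal(self):
        base = np.array([[2, 4], [4, 8]])  # cell 2 = cell 1 doubled
        norm = normalize_counts(dense_matrix(base))
        np.testing.assert_allclose(norm["c0"].to_numpy() * norm["c1"].sum() / norm["c0"].sum(),
                                   norm["c1"].to_numpy())
        # size factors are relative to the median total
        assert np.median(norm.sum(axis=0)) == pytest.approx(np.median(base.sum(axis=0)))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(dense_matrix(np.zeros((3, 3), dtype=int)))


class TestMWUDE:
    def _pair_from(self, a_vals, b_vals):
        """Two-gene matrices with equal cell totals so normalization is identity."""
        total = max(a_vals + b_vals) + 10
        a = dense_matrix(np.array([a_vals, [total - v for v in a_vals]]), cell_prefix="a")
        b = dense_matrix(np.array([b_vals, [total - v for v in b_vals]]), cell_prefix="b")
        return match_subsample(a, b, seed=0)

    def test_identical_values_null_gene(self):
        pair = self._pair_from([5, 6, 7], [5, 6, 7])
        t = mwu_de(pair)
        assert t.loc["g0", "log2fc"] == pytest.approx(0.0)
        assert t.loc["g0", "p"] == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_oracle(self):
        pair = self._pair_from([5, 6, 7], [1, 2, 3])
        t = mwu_de(pair, method="exact")
        u_oracle, p_oracle = exact_mwu_by_enumeration([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert t.loc["g0", "u_stat"] == pytest.approx(u_oracle)
        assert t.loc["g0", "p"] == pytest.approx(p_oracle)
        assert u_oracle == 9 and p_oracle == pytest.approx(0.1)

    def test_common_scale_invariance(self):
        # every cell is a shuffle of one count vector: equal totals, so
        # matching does no stochastic thinning, size factors are 1 and the
        # values stay integral -- scale invariance is then exact
        rng = np.random.default_rng(0)
        pool = rng.poisson(4.0, 30)
        base_a = np.column_stack([rng.permutation(pool) for _ in range(40)])
        base_b = base_a[rng.permutation(30)]
        p1 = mwu_de(match_subsample(dense_matrix(base_a, cell_prefix="a"),
                                    dense_matrix(base_b, cell_prefix="b"), seed=1))["p"]
        p2 = mwu_de(match_subsample(dense_matrix(base_a * 3, cell_prefix="a"),
                                    dense_matrix(base_b * 3, cell_prefix="b"), seed=1))["p"]
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy())

    def test_planted_depletion_power_and_error(self):
        a, b, planted = generate_de_pair(1000, 500, planted_genes=50, fold=4.0,
                                         direction="down", seed=7)
        t = mwu_de(match_subsample(a, b, seed=7))
        hit = t.loc[t.index.isin(planted)]
        recall = ((hit["q"] < 0.05) & (hit["log2fc"] > 1)).mean()
        null = t.loc[~t.index.isin(planted)]
        fp = ((null["q"] < 0.05) & (null["log2fc"].abs() > 1)).mean()
        assert recall >= 0.90
        assert fp <= 0.05

    def test_q_dominates_p(self):
        a, b, _ = generate_de_pair(200, 100, seed=0)
        t = mwu_de(match_subsample(a, b, seed=0))
        assert (t["q"] >= t["p"] - 1e-12).all()


class TestDerivedSignature:
    @staticmethod
    def _table(entries):
        """entries: gene -> (log2fc, q)."""
        genes = sorted(entries)
        return pd.DataFrame(
            {"log2fc": [entries[g][0] for g in genes], "q": [entries[g][1] for g in genes]},
            index=pd.Index(genes, name="gene"),
        )

    def test_support_rule_enumerated(self):
        """Exact >=3-of-4 membership over constructed support patterns."""
        hit_up, miss = (2.0, 0.01), (0.0, 0.9)
        hit_down = (-2.0, 0.01)
        patterns = {
            "up4": [hit_up] * 4,
            "up3": [hit_up] * 3 + [miss],
            "up2": [hit_up] * 2 + [miss] * 2,
            "big_fc_not_sig": [(2.0, 0.2)] * 4,
            "sig_small_fc": [(0.5, 0.01)] * 4,
            "down3": [hit_down] * 3 + [miss],
            "mixed": [hit_up] * 3 + [hit_down],
        }
        tables = [self._table({g: patterns[g][i] for g in patterns}) for i in range(4)]
        sig = derive_consistent_signature(tables)
        assert set(sig.up) == {"up4", "up3", "mixed"}
        assert set(sig.down) == {"down3"}
        assert sig.support_up["up2"] == 2
        assert sig.support_up["big_fc_not_sig"] == 0
        assert sig.support_up["sig_small_fc"] == 0

    def test_conflicting_gene_excluded(self):
        both = {"g": (2.0, 0.01)}
        neg = {"g": (-2.0, 0.01)}
        tables = [self._table(both)] * 3 + [self._table(neg)] * 3
        sig = derive_consistent_signature(tables, min_support=3)
        assert sig.up == [] and sig.down == []

    def test_universe_mismatch_intersected(self, caplog):
        t1 = self._table({"a": (2.0, 0.01), "b": (2.0, 0.01)})
        t2 = self._table({"a": (2.0, 0.01)})
        with caplog.at_level("WARNING"):
            sig = derive_consistent_signature([t1, t1, t2], min_support=3)
        assert sig.up == ["a"]

    def test_planted_design_recovered(self):
        from gliostate.simulate import generate_replicate_design

        a_reps, b_reps, up, down = generate_replicate_design(seed=17)
        tables = [
            mwu_de(match_subsample(a, b, seed=10 * i + j))
            for i, a in enumerate(a_reps)
            for j, b in enumerate(b_reps)
        ]
        sig = derive_consistent_signature(tables)
        up_s, down_s = set(up), set(down)
        assert len(set(sig.up) & up_s) / len(up_s) >= 0.90
        assert len(set(sig.up) - up_s) <= 0.05 * max(len(sig.up), 1)
        assert len(set(sig.down) & down_s) / len(down_s) >= 0.90


class TestNullCalibration:
    def test_fdr_control_under_global_null(self):
        fracs = []
        for s in range(20):
            a, b, _ = generate_de_pair(1000, 250, seed=100 + s)
            t = mwu_de(match_subsample(a, b, seed=s))
            fracs.append((t["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05
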