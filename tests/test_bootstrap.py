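import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aracne_kit import (
    BootstrapAggregate,
    accumulate,
    bootstrap_sample,
    canonical_edges,
    consolidate,
    poisson_tail,
)

from _reference import poisson_tail_cumsum


class TestBootstrapSample:
    def test_columns_are_resampled_columns(self, small_matrix):
        out = bootstrap_sample(small_matrix, seed=1)
        assert out.n_samples == small_matrix.n_samples
        original = {tuple(c) for c in small_matrix.values.T}
        for col in out.values.T:
            assert tuple(col) in original

    def test_seed_reproducibility(self, small_matrix):
        a = bootstrap_sample(small_matrix, seed=5)
        b = bootstrap_sample(small_matrix, seed=5)
        assert np.array_equal(a.values, b.values)
        assert a.sample_ids == b.sample_ids

    def test_coverage_fraction_near_632(self):
        """Expected fraction of distinct original samples is 1 - 1/e."""
        from aracne_kit import ExpressionMatrix

        m = 400
        matrix = ExpressionMatrix(
            ["g"], [f"s{j}" for j in range(m)], np.arange(m, dtype=float)[None, :]
        )
        fracs = [
            len(np.unique(bootstrap_sample(matrix, seed=s).values)) / m
            for s in range(30)
        ]
        assert np.mean(fracs) == pytest.approx(1 - math.exp(-1), abs=0.02)


class TestAccumulate:
    def agg(self):
        return BootstrapAggregate.empty(np.array([0, 1]), ["a", "b", "c"])

    def test_empty_mask_is_noop_on_counts(self):
        agg = self.agg()
        accumulate(agg, np.zeros((2, 3), bool), np.ones((2, 3)))
        assert agg.count.sum() == 0 and agg.mi_sum.sum() == 0
        assert agg.n_bootstraps == 1

    def test_edge_present_in_all_runs_counts_b(self):
        agg = self.agg()
        mask = np.zeros((2, 3), bool)
        mask[0, 2] = True
        for _ in range(7):
            accumulate(agg, mask, np.full((2, 3), 0.5))
        assert agg.count[0, 2] == 7
        assert agg.mi_sum[0, 2] == pytest.approx(3.5)

    def test_order_independent(self):
        rng = np.random.default_rng(2)
        runs = [
            (rng.random((2, 3)) < 0.5, rng.random((2, 3))) for _ in range(6)
        ]
        a, b = self.agg(), self.agg()
        for mask, mi in runs:
            accumulate(a, mask, mi)
        for mask, mi in reversed(runs):
            accumulate(b, mask, mi)
        np.testing.assert_allclose(a.mi_sum, b.mi_sum)
        np.testing.assert_array_equal(a.count, b.count)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accumulate(self.agg(), np.zeros((3, 3), bool), np.zeros((3, 3)))


class TestPoissonTail:
    def test_closed_form_k1_lambda1(self):
        assert poisson_tail(1, 1.0) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_large_k_small_lambda_is_tiny(self):
        assert poisson_tail(10, 0.1) < 1e-15

    @settings(max_examples=80, derandomize=True)
    @given(st.integers(1, 30), st.floats(0.01, 20.0))
    def test_matches_cumsum_oracle(self, k, lam):
        assert poisson_tail(k, lam) == pytest.approx(
            poisson_tail_cumsum(k, lam), abs=1e-9
        )

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(1, 20), st.floats(0.05, 5.0), st.floats(0.05, 5.0))
    def test_monotone_in_k_and_lambda(self, k, lam1, lam2):
        assert poisson_tail(k + 1, lam1) <= poisson_tail(k, lam1)
        lo, hi = sorted((lam1, lam2))
        assert poisson_tail(k, lo) <= poisson_tail(k, hi)


class TestConsolidate:
    def make_agg(self, counts, mi_per_run=0.5, b=10):
        tf_rows = np.array([0, 1])
        agg = BootstrapAggregate.empty(tf_rows, ["t1", "t2", "g1", "g2"])
        for (i, g), k in counts.items():
            agg.count[i, g] = k
            agg.mi_sum[i, g] = k * mi_per_run
        agg.n_bootstraps = b
        return agg

    def test_zero_bootstraps_rejected(self):
        agg = self.make_agg({})
        agg.n_bootstraps = 0
        with pytest.raises(ValueError):
            consolidate(agg)

    def test_unseen_edges_absent(self):
        net = consolidate(self.make_agg({(0, 2): 10}), alpha=0.5)
        pairs = set(zip(net.rows["Regulator"], net.rows["Target"]))
        assert ("t1", "g2") not in pairs and ("t2", "g1") not in pairs

    def test_consistent_edge_claimed_and_mi_is_mean(self):
        agg = self.make_agg({(0, 2): 10, (1, 3): 1}, mi_per_run=0.7)
        net = consolidate(agg, alpha=0.05)
        rows = net.rows.set_index(["Regulator", "Target"])
        assert ("t1", "g1") in rows.index
        assert rows.loc[("t1", "g1"), "MI"] == pytest.approx(0.7)
        assert rows.loc[("t1", "g1"), "Count"] == 10
        # the once-seen edge is not significant against the Poisson null
        assert ("t2", "g2") not in rows.index

    def test_lambda_and_bonferroni_against_hand_computation(self):
        agg = self.make_agg({(0, 2): 10, (1, 3): 1})
        # canonical slots: t1->t2, t1->g1, t1->g2, t2->g1, t2->g2 = 5
        lam = 11 / 5
        p_direct = poisson_tail_cumsum(10, lam)
        net = consolidate(agg, alpha=0.05)
        rows = net.rows.set_index(["Regulator", "Target"])
        assert rows.loc[("t1", "g1"), "AdjPvalue"] == pytest.approx(
            min(1.0, p_direct * 2), rel=1e-9
        )

    def test_canonical_edges_count_tf_tf_once(self):
        rows, cols = canonical_edges(np.array([0, 1]), 4)
        assert len(rows) == 5
        assert (0, 0) not in set(zip(rows.tolist(), cols.tolist()))
        # slot (t2, t1) is excluded, (t1, t2) kept
        pairs = set(zip(rows.tolist(), cols.tolist()))
        assert (0, 1) in pairs and (1, 0) not in pairs
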