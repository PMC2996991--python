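"""Endofactor arithmetic, the 2x2 G-test, q-values and the q <= 0.01 filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from camwound.endothelial_filter import (
    DEFAULT_POOL_RATIO,
    EndoRecord,
    endo_factor,
    endothelial_screen,
    filter_endothelial,
    lr_test,
    q_values,
)
from camwound.synthetic_data import generate_est_pools

# pool-size ratio used throughout: fixed by internal consistency of the
# published screen's finite rows (e.g. 34 endo / 68 non-endo -> factor 2.195507)
N_E = 1.0e6
N_N = DEFAULT_POOL_RATIO * 1.0e6


class TestEndoFactor:
    @pytest.mark.parametrize(
        "ce,cn,expected,places",
        [
            (136, 30, 19.90593, 5),
            (6, 819, 0.032169, 6),
            (1, 60, 0.073184, 6),
            (13, 10, 5.708318, 6),
            (14, 13, 4.728784, 6),
            (9, 5, 7.903825, 6),
            (34, 68, 2.195507, 6),
            (22, 37, 2.610873, 6),
        ],
    )
    def test_reproduces_published_screen_rows(self, ce, cn, expected, places):
        assert round(endo_factor(ce, cn, N_E, N_N), places) == expected

    def test_absent_from_nonendo_pool_is_infinite(self):
        assert endo_factor(4, 0, N_E, N_N) == math.inf

    def test_absent_from_endo_pool_is_zero(self):
        assert endo_factor(0, 42, N_E, N_N) == 0.0

    def test_equal_proportions_give_unity(self):
        assert endo_factor(10, 10, 1000, 1000) == pytest.approx(1.0)

    def test_absent_from_both_pools_rejected(self):
        with pytest.raises(ValueError, match="absent from both"):
            endo_factor(0, 0, N_E, N_N)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 500), st.integers(1, 500))
    def test_scaling_identity(self, ce, cn):
        # factor = (c_e/c_n) * (N_n/N_e) whenever c_n > 0
        assert endo_factor(ce, cn, N_E, N_N) == pytest.approx((ce / cn) * (N_N / N_E))

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 500), st.integers(1, 500))
    def test_reciprocal_product_is_unity(self, ce, cn):
        f = endo_factor(ce, cn, N_E, N_N)
        g = endo_factor(cn, ce, N_N, N_E)
        assert f * g == pytest.approx(1.0)


def g_statistic_oracle(table):
    """Direct log-likelihood evaluation: G = 2 * sum obs * ln(obs/exp)."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    g = 0.0
    for obs, exp in zip(table.ravel(), expected.ravel()):
        if obs > 0:
            g += obs * math.log(obs / exp)
    return 2.0 * g


class TestLRTest:
    def test_null_table_is_exactly_null(self):
        # counts proportional to the pool sizes: expectation equals observation
        stat, p = lr_test(10, 40, 1000, 4000)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_log_likelihood_oracle(self):
        stat, p = lr_test(50, 5, 1000, 4400)
        table = [[50, 950], [5, 4395]]
        g = g_statistic_oracle(table)
        assert stat == pytest.approx(g, abs=1e-9)
        assert p == pytest.approx(chi2.sf(g, df=1), abs=1e-12)

    def test_agrees_with_pearson_chi_square_asymptotically(self):
        # near the null (a shared EST rate in both pools) G and Pearson are
        # asymptotically equivalent; agreement within 10% for cells >= 20
        rng = np.random.default_rng(44)
        checked = 0
        for _ in range(100):
            ne, nn = int(rng.integers(2000, 9000)), int(rng.integers(2000, 9000))
            rate = float(rng.uniform(0.01, 0.05))
            ce = int(rng.binomial(ne, rate))
            cn = int(rng.binomial(nn, rate))
            g, _ = lr_test(ce, cn, ne, nn)
            table = np.array([[ce, ne - ce], [cn, nn - cn]], dtype=float)
            exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
            pearson = ((table - exp) ** 2 / exp).sum()
            if min(table.min(), exp.min()) >= 20 and pearson > 1e-3:
                assert abs(g - pearson) / pearson < 0.10
                checked += 1
        assert checked > 50  # the sweep actually exercised the comparison

    def test_invariant_under_pool_swap(self):
        g1, _ = lr_test(30, 7, 1000, 4391)
        g2, _ = lr_test(7, 30, 4391, 1000)
        assert g1 == pytest.approx(g2, rel=1e-12)

    def test_counts_exceeding_totals_rejected(self):
        with pytest.raises(ValueError):
            lr_test(11, 0, 10, 100)


class TestQValues:
    def test_all_unity(self):
        assert np.allclose(q_values([1.0, 1.0, 1.0]), 1.0)

    def test_hand_computed_step_up(self):
        # BH: q_(i) = min over j>=i of m*p_(j)/j -> all collapse to 0.03
        assert np.allclose(q_values([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_order_preserved(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 1000)
        q = q_values(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            q_values([0.5, 1.5])

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 200) ** 2
        assert (q_values(p, method="storey") <= q_values(p, method="bh") + 1e-15).all()


class TestFilterEndothelial:
    def _rec(self, gene, q, ef=2.0):
        return EndoRecord(gene, 10, 5, ef, 0.001, q, "up" if ef > 1 else "down")

    def test_q_boundary_is_inclusive(self):
        kept = filter_endothelial([self._rec("a", 0.010), self._rec("b", 0.011)])
        assert [r.gene_symbol for r in kept] == ["a"]

    def test_infinite_factors_sort_first_within_equal_q(self):
        recs = [self._rec("finite", 0.0, 5.0), self._rec("inf", 0.0, math.inf)]
        kept = filter_endothelial(recs)
        assert kept[0].gene_symbol == "inf"

    def test_planted_pool_enrichment_recovered_across_seeds(self):
        """All planted endothelial genes retained, >= 95% precision, 10 seeds."""
        for seed in range(10):
            table, truth = generate_est_pools(
                n_genes=500, enriched_fraction=0.04, enrichment_factor=20.0, seed=seed
            )
            screen = endothelial_screen(table, 10000, 43910)
            kept = filter_endothelial(screen, q_max=0.01)
            kept_genes = {r.gene_symbol for r in kept}
            planted = set(truth.endothelial_genes)
            assert planted <= kept_genes, f"seed {seed}: planted gene missed"
            precision = len(planted & kept_genes) / len(kept_genes)
            assert precision >= 0.95, f"seed {seed}: precision {precision:.3f}"
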