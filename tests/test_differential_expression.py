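"""Wilcoxon statistic, fold changes, permutation FDR and gene selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camwound.differential_expression import (
    CALL_DOWN,
    CALL_UP,
    DEConfig,
    DEResult,
    _relabelings,
    mean_fold_change,
    permutation_fdr,
    select_de_genes,
    signed_fold_change,
    wilcoxon_statistic,
)
from camwound.expression_matrix import ExpressionMatrix
from camwound.synthetic_data import generate_expression_experiment


def brute_force_rank_sum(a, b):
    """Independent midrank computation by pairwise comparison counting."""
    pooled = list(a) + list(b)
    total = 0.0
    for x in a:
        smaller = sum(1 for y in pooled if y < x)
        equal = sum(1 for y in pooled if y == x)
        # midrank = (# smaller) + (equal + 1) / 2
        total += smaller + (equal + 1) / 2
    return total


class TestWilcoxonStatistic:
    def test_fully_separated_groups(self):
        assert wilcoxon_statistic([1, 2, 3], [4, 5, 6]) == 6.0

    def test_tie_gets_midrank(self):
        assert wilcoxon_statistic([5], [5]) == 1.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_statistic([], [1.0])

    def test_matches_enumeration_oracle_over_all_assignments(self):
        rng = np.random.default_rng(17)
        pooled = rng.uniform(0, 10, 6)
        pooled[4] = pooled[1]  # plant a tie
        for idx in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in idx]
            b = [pooled[i] for i in range(6) if i not in idx]
            assert wilcoxon_statistic(a, b) == pytest.approx(brute_force_rank_sum(a, b))


class TestFoldChange:
    def test_mean_ratio(self, paired_design):
        data = pd.DataFrame(
            {s: [4.0] for s in ["w1", "w2", "w3"]} | {s: [2.0] for s in ["c1", "c2", "c3"]},
            index=["p"],
        )
        fc = mean_fold_change(ExpressionMatrix(data), paired_design)
        assert fc["p"] == pytest.approx(2.0)

    def test_identical_groups_give_unity(self, paired_design):
        data = pd.DataFrame({s: [7.0, 3.0] for s in ["w1", "w2", "w3", "c1", "c2", "c3"]},
                            index=["pA", "pB"])
        fc = mean_fold_change(ExpressionMatrix(data), paired_design)
        assert np.allclose(fc, 1.0)

    def test_zero_control_mean_names_probe(self, paired_design):
        data = pd.DataFrame(
            {s: [4.0] for s in ["w1", "w2", "w3"]} | {s: [0.0] for s in ["c1", "c2", "c3"]},
            index=["pZ"],
        )
        with pytest.raises(ValueError, match="pZ"):
            mean_fold_change(ExpressionMatrix(data), paired_design)

    def test_recovers_planted_79_fold_effect(self):
        # strongest observed array effect: ~79-fold up-regulation
        m, d, truth = generate_expression_experiment(
            n_genes=50, n_pairs=3, de_fraction=1.0, fc_distribution=79.23,
            noise_cv=0.05, seed=8,
        )
        fc = mean_fold_change(m, d)
        assert np.all(np.abs(fc / 79.23 - 1) < 0.15)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "ratio,expected", [(0.11, -9.09), (1.0, 1.0), (0.15, -6.67), (3.33, 3.33)]
    )
    def test_published_convention(self, ratio, expected):
        assert round(signed_fold_change(ratio), 2) == expected

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            signed_fold_change(0.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.01, max_value=100.0, allow_nan=False))
    def test_roundtrip_and_gap(self, ratio):
        s = signed_fold_change(ratio)
        assert not (-1 < s < 1)
        # invert the convention and recover the original ratio
        back = s if s >= 1 else -1.0 / s
        assert back == pytest.approx(ratio, rel=1e-12)


class TestPermutationFDR:
    def test_3v3_design_enumerates_20_assignments(self, paired_design):
        m, _, _ = generate_expression_experiment(n_genes=10, seed=0)
        masks, exhaustive = _relabelings(paired_design, ["w1", "w2", "w3", "c1", "c2", "c3"],
                                         DEConfig())
        assert exhaustive and len(masks) == 20

    def test_paired_mode_enumerates_sign_flips(self, paired_design):
        masks, exhaustive = _relabelings(paired_design, ["w1", "w2", "w3", "c1", "c2", "c3"],
                                         DEConfig(paired=True))
        assert exhaustive and len(masks) == 8  # 2^3 within-egg swaps

    def test_null_calibration_small(self):
        """On pure-null data almost nothing is called at nominal FDR 5%."""
        called = total = 0
        for seed in range(3):
            m, d, _ = generate_expression_experiment(n_genes=500, n_pairs=3,
                                                     de_fraction=0.0, seed=seed)
            res = permutation_fdr(m, d, DEConfig(seed=seed))
            up, down = select_de_genes(res)
            called += len(up) + len(down)
            total += len(res)
        assert called / total <= 0.10

    def test_planted_genes_recovered(self):
        m, d, truth = generate_expression_experiment(
            n_genes=1000, n_pairs=3, de_fraction=0.1, fc_distribution=4.0,
            noise_cv=0.1, seed=123,
        )
        res = permutation_fdr(m, d, DEConfig(seed=123))
        up, _ = select_de_genes(res)
        planted = {g for g, f in truth.de_flags.items() if f}
        recovered = planted & {r.probe_id for r in up}
        assert len(recovered) / len(planted) >= 0.8

    def test_fdr_non_increasing_in_statistic_extremity(self):
        m, d, _ = generate_expression_experiment(n_genes=400, n_pairs=3,
                                                 de_fraction=0.2, fc_distribution=5.0,
                                                 noise_cv=0.2, seed=5)
        res = permutation_fdr(m, d, DEConfig(seed=5))
        e0 = 3 * 7 / 2.0
        by_score = sorted(res, key=lambda r: abs(r.statistic - e0))
        fdrs = [r.fdr for r in by_score]
        assert all(nxt <= cur + 1e-12 for cur, nxt in zip(fdrs, fdrs[1:]))

    def test_exhaustive_and_sampled_modes_agree(self):
        m, d, _ = generate_expression_experiment(n_genes=300, n_pairs=3,
                                                 de_fraction=0.1, fc_distribution=4.0,
                                                 noise_cv=0.1, seed=9)
        exhaustive = permutation_fdr(m, d, DEConfig(n_permutations=200, seed=9))
        sampled = permutation_fdr(m, d, DEConfig(n_permutations=15, seed=9))
        diffs = [abs(a.fdr - b.fdr) for a, b in zip(exhaustive, sampled)]
        assert np.mean(diffs) < 0.15

    def test_paired_mode_runs_and_recovers(self):
        m, d, truth = generate_expression_experiment(
            n_genes=500, n_pairs=3, de_fraction=0.1, fc_distribution=6.0,
            noise_cv=0.1, seed=21,
        )
        res = permutation_fdr(m, d, DEConfig(seed=21, paired=True))
        up, _ = select_de_genes(res)
        planted = {g for g, f in truth.de_flags.items() if f}
        assert len(planted & {r.probe_id for r in up}) / len(planted) >= 0.8


class TestSelectDEGenes:
    def _result(self, probe, fc, fdr):
        return DEResult(probe, 0.0, fc, signed_fold_change(fc), fdr,
                        CALL_UP if fc > 1 else CALL_DOWN)

    def test_fc_exactly_2_excluded(self):
        up, down = select_de_genes([self._result("p", 2.0, 0.001)])
        assert up == [] and down == []

    def test_down_regulation(self):
        up, down = select_de_genes([self._result("p", 0.4, 0.01)])
        assert [r.probe_id for r in down] == ["p"]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(2)
        results = [
            self._result(f"p{i}", float(np.exp(rng.normal(0, 1.5))), float(rng.uniform(0, 0.2)))
            for i in range(200)
        ]
        cfg = DEConfig()
        up, down = select_de_genes(results, cfg)
        oracle_up = {r.probe_id for r in results if r.fdr < 0.05 and r.fold_change > 2}
        oracle_down = {r.probe_id for r in results if r.fdr < 0.05 and r.fold_change < 0.5}
        assert {r.probe_id for r in up} == oracle_up
        assert {r.probe_id for r in down} == oracle_down
        # sorted by |signed fold change| descending
        mags = [abs(r.signed_fold_change) for r in up]
        assert mags == sorted(mags, reverse=True)
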