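"""Expression table parsing, trimmed-mean global scaling and QC clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from camwound.expression_matrix import (
    ExpressionFormatError,
    ExpressionMatrix,
    SampleDesign,
    cluster_samples,
    normalize_global_scaling,
    read_expression_table,
    trimmed_mean,
)
from camwound.synthetic_data import generate_expression_experiment


def _write(tmp_path, text):
    p = tmp_path / "expr.tsv"
    p.write_text(text)
    return p


class TestReadExpressionTable:
    def test_parses_values_preserving_order(self, tmp_path):
        p = _write(tmp_path, "probe\ts1\ts2\npA\t1\t2\npB\t3\t4\n")
        m = read_expression_table(p)
        assert m.probe_ids == ["pA", "pB"]
        assert m.sample_ids == ["s1", "s2"]
        assert m.values.tolist() == [[1.0, 2.0], [3.0, 4.0]]

    def test_empty_data_section_rejected(self, tmp_path):
        p = _write(tmp_path, "probe\ts1\ts2\n")
        with pytest.raises(ExpressionFormatError, match="no probes"):
            read_expression_table(p)

    def test_duplicate_probe_named_in_error(self, tmp_path):
        p = _write(tmp_path, "probe\ts1\npA\t1\npA\t2\n")
        with pytest.raises(ExpressionFormatError, match="pA"):
            read_expression_table(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = _write(tmp_path, "probe\ts1\ts2\npA\t1\t2\npB\tx\t4\n")
        with pytest.raises(ExpressionFormatError, match=r"'pB'.*'s1'"):
            read_expression_table(p)

    def test_negative_values_rejected(self):
        with pytest.raises(ExpressionFormatError, match="non-negative"):
            ExpressionMatrix(pd.DataFrame({"s1": [-1.0]}, index=["p"]))


class TestDesign:
    def test_unbalanced_egg_rejected(self):
        with pytest.raises(ExpressionFormatError, match="e1"):
            SampleDesign(
                pd.DataFrame(
                    {
                        "sample_id": ["a", "b", "c"],
                        "group": ["wound", "wound", "control"],
                        "egg_id": ["e1", "e1", "e1"],
                    }
                )
            )

    def test_pairing_lookup(self, paired_design):
        assert paired_design.sample_for("e2", "control") == "c2"
        assert paired_design.n_pairs == 3


class TestGlobalScaling:
    def test_constant_column_hits_target(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [200.0] * 10}, index=[f"p{i}" for i in range(10)]))
        out = normalize_global_scaling(m, target=100)
        assert np.allclose(out.values, 100.0)

    def test_column_at_target_is_fixed_point(self):
        vals = np.linspace(50, 150, 11)
        vals = vals * (100 / trimmed_mean(vals, 0.02))
        m = ExpressionMatrix(pd.DataFrame({"s": vals}, index=[f"p{i}" for i in range(11)]))
        out = normalize_global_scaling(m, target=100)
        assert np.allclose(out.values[:, 0], vals, atol=1e-12)

    def test_trimmed_mean_against_sort_and_slice_oracle(self):
        rng = np.random.default_rng(5)
        col = rng.uniform(10, 200, 100)
        col[:3] = [5000.0, 9000.0, 12000.0]  # planted outliers
        col[3] = 0.01
        m = ExpressionMatrix(pd.DataFrame({"s": col}, index=[f"p{i}" for i in range(100)]))
        out = normalize_global_scaling(m, target=100, trim_fraction=0.02)
        # independent oracle: sort, drop floor(0.02*n) values at each tail, average
        scaled = np.sort(out.values[:, 0])
        k = int(np.floor(0.02 * len(scaled)))
        oracle_tm = scaled[k : len(scaled) - k].mean()
        assert abs(oracle_tm - 100.0) < 1e-9

    def test_all_zero_column_names_sample(self):
        m = ExpressionMatrix(
            pd.DataFrame({"good": [1.0, 2.0], "dead": [0.0, 0.0]}, index=["p1", "p2"])
        )
        with pytest.raises(ExpressionFormatError, match="dead"):
            normalize_global_scaling(m)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        m = ExpressionMatrix(
            pd.DataFrame(rng.uniform(1, 500, (60, 4)), index=[f"p{i}" for i in range(60)],
                         columns=list("abcd"))
        )
        once = normalize_global_scaling(m)
        twice = normalize_global_scaling(once)
        assert np.abs(twice.values - once.values).max() < 1e-12

    def test_invalid_trim_fraction(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [1.0, 2.0]}, index=["p1", "p2"]))
        with pytest.raises(ValueError, match="trim_fraction"):
            normalize_global_scaling(m, trim_fraction=0.5)


class TestClusterSamples:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(3)
        col = rng.uniform(1, 100, 20)
        m = ExpressionMatrix(
            pd.DataFrame({"a": col, "b": col, "c": col[::-1]}, index=[f"p{i}" for i in range(20)])
        )
        den = cluster_samples(m)
        assert den.merges[0][:2] == (0, 1)
        assert den.merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_average_linkage_oracle(self, small_matrix):
        den = cluster_samples(small_matrix)
        X = small_matrix.values.T
        dist = 1.0 - np.corrcoef(X)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        mine = cophenet(den.linkage_matrix())
        theirs = cophenet(Z)
        assert np.allclose(mine, theirs, atol=1e-10)

    def test_two_planted_groups_merge_within_first(self, small_matrix):
        den = cluster_samples(small_matrix)
        parts = [frozenset(den.labels[i] for i in c) for c in den.cut(2)]
        assert frozenset({"s1", "s2"}) in parts and frozenset({"s3", "s4"}) in parts

    def test_simulated_experiment_separates_design_groups(self):
        m, d, _ = generate_expression_experiment(
            n_genes=500, n_pairs=3, de_fraction=0.3, fc_distribution=10.0, noise_cv=0.1, seed=42
        )
        den = cluster_samples(m)
        parts = {frozenset(den.labels[i] for i in c) for c in den.cut(2)}
        assert parts == {frozenset(d.wound_samples), frozenset(d.control_samples)}

    def test_invariant_to_global_rescaling(self, small_matrix):
        den1 = cluster_samples(small_matrix)
        scaled = ExpressionMatrix(small_matrix.data * 37.5)
        den2 = cluster_samples(scaled)
        assert [m[:2] for m in den1.merges] == [m[:2] for m in den2.merges]
        assert np.allclose(den1.heights, den2.heights, atol=1e-10)

    def test_heights_bounded_and_monotone(self, small_matrix):
        den = cluster_samples(small_matrix)
        h = den.heights
        assert all(0 <= x <= 2 for x in h)
        assert all(b >= a - 1e-12 for a, b in zip(h, h[1:]))

    def test_zero_variance_sample_named(self):
        m = ExpressionMatrix(
            pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]},
                         index=["p1", "p2", "p3"])
        )
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(m)
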