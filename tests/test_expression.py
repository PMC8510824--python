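"""Expression I/O and the filter → impute → z-score preprocessing chain."""

import numpy as np
import pytest

from cfnforest.expression import (
    ExpressionMatrix,
    filter_missing_samples,
    knn_impute,
    preprocess,
    read_expression,
    write_expression,
    zscore_normalize,
)


def _random_matrix(rng, n=6, d=4, missing_rate=0.2):
    values = rng.normal(size=(n, d)).round(6)
    mask = rng.uniform(size=(n, d)) < missing_rate
    mask[0] = False  # keep at least one fully observed sample
    vals = values.copy()
    vals[mask] = np.nan
    return ExpressionMatrix(
        [f"s{i}" for i in range(n)], [f"g{j}" for j in range(d)], vals, mask
    )


class TestReadWrite:
    def test_na_cells_become_masked(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("sample_id,g1,g2\ns1,1.0,2.0\ns2,NA,4.0\ns3,5.0,6.0\n")
        X = read_expression(p)
        assert X.missing_mask.sum() == 1
        assert X.missing_mask[1, 0]
        assert X.values[2, 1] == 6.0
        assert X.sample_ids == ["s1", "s2", "s3"]

    def test_ragged_row_names_the_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,g1,g2,g3,g4,g5\ns1,1,2,3,4\n")
        with pytest.raises(ValueError, match="line 2"):
            read_expression(p)

    @pytest.mark.parametrize("bad", ["s1,1,2\ns1,3,4", "dup header"])
    def test_duplicate_ids_rejected(self, tmp_path, bad):
        p = tmp_path / "dup.csv"
        if bad == "dup header":
            p.write_text("sample_id,g1,g1\ns1,1,2\n")
        else:
            p.write_text("sample_id,g1,g2\n" + bad + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_expression(p)

    @pytest.mark.parametrize("seed", range(5))
    def test_write_read_round_trip_bit_exact(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        X = _random_matrix(rng)
        p = tmp_path / "rt.csv"
        write_expression(X, p)
        Y = read_expression(p)
        assert Y.sample_ids == X.sample_ids and Y.gene_ids == X.gene_ids
        assert np.array_equal(Y.missing_mask, X.missing_mask)
        obs = ~X.missing_mask
        assert np.array_equal(Y.values[obs], X.values[obs])

    def test_transpose_reads_gene_by_sample_layout(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("gene_id,s1,s2\ng1,1.0,2.0\ng2,3.0,4.0\n")
        X = read_expression(p, transpose=True)
        assert X.sample_ids == ["s1", "s2"]
        assert X.values[0, 1] == 3.0


class TestMissingFilter:
    def _five_gene(self, missing_per_sample):
        n = len(missing_per_sample)
        vals = np.ones((n, 5))
        mask = np.zeros((n, 5), dtype=bool)
        for i, m in enumerate(missing_per_sample):
            mask[i, :m] = True
        vals[mask] = np.nan
        return ExpressionMatrix(
            [f"s{i}" for i in range(n)], [f"g{j}" for j in range(5)], vals, mask
        )

    def test_forty_percent_missing_is_removed(self):
        X = self._five_gene([0, 2])  # s2 misses 2/5 = 40%
        kept, removed = filter_missing_samples(X, 0.20)
        assert removed == ["s1"]
        assert kept.sample_ids == ["s0"]

    def test_exactly_threshold_is_retained(self):
        X = self._five_gene([0, 1])  # 1/5 = exactly 20%
        kept, removed = filter_missing_samples(X, 0.20)
        assert removed == []
        assert kept.sample_ids == ["s0", "s1"]

    def test_clean_matrix_unchanged(self, tiny_matrix):
        clean = ExpressionMatrix(
            ["a", "b"], ["g1", "g2"], np.ones((2, 2)), np.zeros((2, 2), bool)
        )
        kept, removed = filter_missing_samples(clean)
        assert removed == [] and np.array_equal(kept.values, clean.values)

    def test_all_removed_raises(self):
        X = self._five_gene([3, 4])
        with pytest.raises(ValueError, match="threshold"):
            filter_missing_samples(X, 0.20)


class TestKnnImpute:
    def test_nearest_neighbour_copy_k1(self):
        vals = np.array([[1.0, np.nan, 3.0], [1.0, 7.0, 3.0], [9.0, 9.0, 9.0]])
        X = ExpressionMatrix(["a", "b", "c"], ["g1", "g2", "g3"], vals,
                             np.isnan(vals))
        out = knn_impute(X, k=1)
        assert out.values[0, 1] == 7.0  # copied from the identical sample b
        assert not out.missing_mask.any()

    def test_identity_without_missing(self):
        vals = np.arange(6.0).reshape(2, 3)
        X = ExpressionMatrix(["a", "b"], ["g1", "g2", "g3"], vals,
                             np.zeros((2, 3), bool))
        out = knn_impute(X, k=1)
        assert np.array_equal(out.values, vals)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = _random_matrix(rng, n=6, d=4, missing_rate=0.25)
        k = 3
        out = knn_impute(X, k=k)
        for i in range(6):
            for j in range(4):
                if not X.missing_mask[i, j]:
                    assert out.values[i, j] == X.values[i, j]
                    continue
                # oracle: exhaustive ranking over all other samples
                dists = []
                for r in range(6):
                    if r == i:
                        continue
                    shared = ~X.missing_mask[i] & ~X.missing_mask[r]
                    if not shared.any():
                        continue
                    d = np.sqrt(np.sum(
                        (X.values[i, shared] - X.values[r, shared]) ** 2))
                    dists.append((d, r))
                dists.sort(key=lambda t: (t[0], t[1]))
                donors = [r for _, r in dists if not X.missing_mask[r, j]][:k]
                expected = np.mean([X.values[r, j] for r in donors])
                assert out.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn_on_unambiguous_fixture(self):
        # one missing cell and otherwise complete rows: the distance-scaling
        # convention cannot change neighbor ranking, so sklearn's KNNImputer
        # is a valid independent oracle here
        from sklearn.impute import KNNImputer

        rng = np.random.default_rng(3)
        vals = rng.normal(size=(8, 5))
        vals[2, 4] = np.nan
        X = ExpressionMatrix([f"s{i}" for i in range(8)],
                             [f"g{j}" for j in range(5)], vals, np.isnan(vals))
        ours = knn_impute(X, k=3).values
        theirs = KNNImputer(n_neighbors=3).fit_transform(vals)
        assert np.allclose(ours, theirs)

    def test_unobservable_gene_raises(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        X = ExpressionMatrix(["a", "b"], ["g1", "g2"], vals, np.isnan(vals))
        with pytest.raises(ValueError, match="impute"):
            knn_impute(X, k=1)


class TestZScore:
    def test_constant_column_maps_to_zero(self):
        vals = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        X = ExpressionMatrix(["a", "b", "c"], ["g1", "g2"], vals,
                             np.zeros((3, 2), bool))
        out, stats = zscore_normalize(X)
        assert np.all(out.values[:, 0] == 0.0)
        assert out.values[:, 1] == pytest.approx(
            [-1.224744871, 0.0, 1.224744871], abs=1e-8
        )
        assert stats.spread[1] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_idempotent_on_standardized_column(self):
        col = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        X = ExpressionMatrix(["a", "b", "c"], ["g"], col[:, None],
                             np.zeros((3, 1), bool))
        out, _ = zscore_normalize(X)
        assert np.allclose(out.values[:, 0], col, atol=1e-12)

    def test_variance_divisor_variant(self):
        vals = np.array([[1.0], [2.0], [3.0]])
        X = ExpressionMatrix(["a", "b", "c"], ["g"], vals, np.zeros((3, 1), bool))
        out, stats = zscore_normalize(X, divisor="var")
        assert stats.spread[0] == pytest.approx(2.0 / 3.0)
        assert out.values[:, 0] == pytest.approx([-1.5, 0.0, 1.5])

    def test_missing_values_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="impute"):
            zscore_normalize(tiny_matrix)


class TestChainInvariants:
    @pytest.mark.parametrize("seed", range(3))
    def test_full_chain_centers_and_scales_each_gene(self, seed):
        rng = np.random.default_rng(seed)
        X = _random_matrix(rng, n=12, d=6, missing_rate=0.1)
        out, stats, _ = preprocess(X)
        means = out.values.mean(axis=0)
        sds = out.values.std(axis=0)
        assert np.all(np.abs(means) < 1e-9)
        for j in range(6):
            assert sds[j] == pytest.approx(1.0, abs=1e-9) or sds[j] == 0.0

    def test_chain_is_deterministic(self, rng):
        X = _random_matrix(rng, n=10, d=5)
        a, _, _ = preprocess(X.copy())
        b, _, _ = preprocess(X.copy())
        assert np.array_equal(a.values, b.values)

    def test_imputation_preserves_observed_entries(self, rng):
        X = _random_matrix(rng, n=10, d=5, missing_rate=0.3)
        out = knn_impute(X, k=3)
        obs = ~X.missing_mask
        assert np.array_equal(out.values[obs], X.values[obs])
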