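"""Correction-stage contracts: median scaling, presence filter, KNN."""

import numpy as np
import pandas as pd
import pytest
from sklearn.impute import KNNImputer

from nitrosig import preprocess


def _mat(values, scale="linear"):
    m = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"g{i}" for i in range(len(values))],
    )
    m.columns = [f"s{j}" for j in range(m.shape[1])]
    m.attrs["scale"] = scale
    return m


# brute-force KNN reference: enumerate all gene pairs, spec semantics
def knn_reference(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    X = matrix.to_numpy(dtype=float)
    n, m = X.shape
    filled = X.copy()
    for g in range(n):
        for j in range(m):
            if not np.isnan(X[g, j]):
                continue
            cand = []
            for h in range(n):
                if h == g or np.isnan(X[h, j]):
                    continue
                both = ~np.isnan(X[g]) & ~np.isnan(X[h])
                if not both.any():
                    continue
                d2 = ((X[g, both] - X[h, both]) ** 2).sum()
                d = np.sqrt(d2 * m / both.sum())
                cand.append((d, h))
            if not cand:
                filled[g, j] = np.nanmean(X[g])
                continue
            cand.sort(key=lambda t: t[0])
            nearest = cand[:k]
            if nearest[0][0] == 0.0:
                zero = [h for d, h in nearest if d == 0.0]
                filled[g, j] = np.mean([X[h, j] for h in zero])
            else:
                w = np.array([1.0 / d for d, _ in nearest])
                v = np.array([X[h, j] for _, h in nearest])
                filled[g, j] = float((w * v).sum() / w.sum())
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


class TestGlobalMedianNormalization:
    def test_scaling_factors_from_sample_and_grand_medians(self):
        # sample medians 2 and 8, grand median 4 -> factors 2.0 and 0.5
        mat = _mat(np.array([[1, 4], [2, 8], [4, 9]]))
        out = preprocess.normalize_global_median(mat)
        np.testing.assert_allclose(out["s0"], mat["s0"] * 2.0)
        np.testing.assert_allclose(out["s1"], mat["s1"] * 0.5)
        assert out.median(axis=0).tolist() == [4.0, 4.0]

    def test_already_equalized_matrix_is_unchanged(self):
        # per-sample medians and pooled median all equal 4
        mat = _mat(np.array([[1, 2], [4, 4], [9, 7]]))
        out = preprocess.normalize_global_median(mat)
        pd.testing.assert_frame_equal(out, mat)

    def test_equalizes_per_sample_medians(self, rng):
        mat = _mat(rng.uniform(0.5, 50, (100, 6)))
        out = preprocess.normalize_global_median(mat)
        medians = out.median(axis=0).to_numpy()
        assert np.ptp(medians) < 1e-9

    def test_preserves_within_sample_rank_order(self, rng):
        mat = _mat(rng.uniform(0.5, 50, (60, 5)))
        out = preprocess.normalize_global_median(mat)
        for col in mat.columns:
            assert (
                np.argsort(mat[col].to_numpy()).tolist()
                == np.argsort(out[col].to_numpy()).tolist()
            )

    def test_all_missing_sample_rejected(self):
        mat = _mat([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="no present values"):
            preprocess.normalize_global_median(mat)


class TestPresenceFilter:
    def test_threshold_is_inclusive_at_75_percent(self):
        vals = np.ones((2, 12))
        vals[0, :3] = np.nan  # 9/12 = 75% present -> kept
        vals[1, :4] = np.nan  # 8/12 -> dropped
        out = preprocess.filter_presence(_mat(vals), 0.75)
        assert list(out.index) == ["g0"]

    def test_no_missing_is_identity(self, rng):
        mat = _mat(rng.uniform(1, 5, (20, 8)))
        pd.testing.assert_frame_equal(preprocess.filter_presence(mat), mat)

    def test_half_missing_everywhere_drops_everything(self, rng):
        vals = rng.uniform(1, 5, (10, 8))
        vals[:, :4] = np.nan
        out = preprocess.filter_presence(_mat(vals), 0.75)
        assert out.empty


class TestLog2Transform:
    def test_floor_is_half_smallest_positive(self):
        mat = _mat([[4.0, 0.001], [8.0, 1.0]])
        out = preprocess.to_log2(mat, floor=0.5)
        assert out.loc["g0", "s1"] == np.log2(0.5)
        assert out.loc["g0", "s0"] == 2.0
        auto = preprocess.to_log2(mat)
        assert auto.loc["g0", "s1"] == np.log2(0.001)  # floor = 0.0005

    def test_missing_stays_missing(self):
        mat = _mat([[4.0, np.nan]])
        out = preprocess.to_log2(mat)
        assert np.isnan(out.loc["g0", "s1"])
        assert out.attrs["scale"] == "log2"


class TestKnnImpute:
    def test_zero_missing_is_identity(self, rng):
        mat = _mat(rng.normal(8, 1, (15, 6)), scale="log2")
        pd.testing.assert_frame_equal(preprocess.knn_impute(mat), mat)

    def test_zero_distance_duplicate_supplies_value(self, rng):
        row = rng.normal(8, 1, 8)
        vals = np.vstack([row, row, rng.normal(8, 1, (4, 8))])
        vals[0, 3] = np.nan
        out = preprocess.knn_impute(_mat(vals, scale="log2"), k=1)
        assert out.iloc[0, 3] == row[3]

    def test_matches_brute_force_reference(self, rng):
        vals = rng.normal(8, 1, (50, 8))
        mask = rng.random(vals.shape) < 0.05
        vals[mask] = np.nan
        mat = _mat(vals, scale="log2")
        out = preprocess.knn_impute(mat, k=3)
        ref = knn_reference(mat, k=3)
        np.testing.assert_allclose(out.to_numpy(), ref.to_numpy(), atol=1e-9)

    def test_present_values_pass_through_bit_identical(self, rng):
        vals = rng.normal(8, 1, (40, 10))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        mat = _mat(vals, scale="log2")
        out = preprocess.knn_impute(mat, k=4)
        present = ~np.isnan(vals)
        assert (out.to_numpy()[present] == vals[present]).all()
        assert not np.isnan(out.to_numpy()).any()

    def test_agrees_with_sklearn_knnimputer(self, rng):
        # independent cross-check on a case without fallbacks
        vals = rng.normal(8, 1, (60, 8))
        vals[rng.random(vals.shape) < 0.04] = np.nan
        mat = _mat(vals, scale="log2")
        ours = preprocess.knn_impute(mat, k=5).to_numpy()
        theirs = KNNImputer(n_neighbors=5, weights="distance").fit_transform(vals)
        np.testing.assert_allclose(ours, theirs, atol=1e-9)

    def test_row_mean_fallback_when_no_donor_exists(self):
        vals = np.array(
            [
                [1.0, 2.0, np.nan],
                [1.5, 2.5, np.nan],
                [0.5, 1.5, np.nan],
            ]
        )
        vals = np.hstack([vals, np.full((3, 1), 4.0)])
        vals[0, 2] = np.nan  # column 2 empty across all genes
        vals[1, 2] = np.nan
        vals[2, 2] = np.nan
        mat = _mat(vals, scale="log2")
        out = preprocess.knn_impute(mat, k=2)
        assert out.iloc[0, 2] == pytest.approx(np.nanmean(vals[0]))


class TestAverageReplicates:
    def test_arithmetic_mean_of_replicates(self, small_dataset):
        _, matrix, design, _ = small_dataset
        log2 = preprocess.to_log2(matrix.fillna(1.0))
        avg = preprocess.average_replicates(log2, design)
        d = design.set_index("sample_id")
        cell = d[(d["strain"] == "CEG") & (d["regime"] == "LN") & (d["time_h"] == 12)]
        np.testing.assert_allclose(
            avg["CEG_LN_12h"].to_numpy(),
            log2[cell.index].mean(axis=1).to_numpy(),
        )
        assert avg.shape[1] == 18

    def test_identical_replicates_average_to_themselves(self):
        design = pd.DataFrame(
            {
                "sample_id": ["a1", "a2"],
                "strain": ["S", "S"],
                "regime": ["LN", "LN"],
                "time_h": [12, 12],
                "replicate": [1, 2],
            }
        )
        mat = _mat([[4.0, 6.0]], scale="log2")
        mat.columns = ["a1", "a2"]
        avg = preprocess.average_replicates(mat, design)
        assert avg.iloc[0, 0] == 5.0

    def test_unbalanced_cells_rejected(self):
        design = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1"],
                "strain": ["S", "S", "T"],
                "regime": ["LN"] * 3,
                "time_h": [12] * 3,
                "replicate": [1, 2, 1],
            }
        )
        mat = _mat([[1.0, 2.0, 3.0]], scale="log2")
        mat.columns = ["a1", "a2", "b1"]
        with pytest.raises(ValueError, match="[Uu]nbalanced"):
            preprocess.average_replicates(mat, design)


def test_pipeline_runs_in_fixed_order_and_keeps_present_values(small_dataset):
    _, matrix, _, _ = small_dataset
    linear, log2 = preprocess.run(matrix)
    assert linear.attrs["scale"] == "linear"
    assert log2.attrs["scale"] == "log2"
    assert not np.isnan(log2.to_numpy()).any()
    assert set(log2.index) == set(linear.index)
    # originally-present values survive normalization+log untouched by imputation
    norm = preprocess.normalize_global_median(matrix)
    kept = preprocess.filter_presence(norm)
    relog = preprocess.to_log2(kept)
    present = ~np.isnan(relog.to_numpy())
    assert (log2.to_numpy()[present] == relog.to_numpy()[present]).all()
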