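import numpy as np
import pandas as pd
import pytest

from morphospace import (
    ParcelMatrix,
    ThresholdPolicy,
    knn_index_summary,
    loo_predictability,
    predict_map,
    predictability_index,
    project_and_predict,
    t_to_z,
)
from morphospace._stats import Z_CAP, t_cap
from morphospace.errors import ZeroVarianceError
from morphospace.predictability import covariate_correlation

from .oracles import ols_t_oracle, pearson_oracle, spearman_oracle, t_to_z_quadrature


def _random_case(rng, n_maps=7, n_parcels=6):
    data = pd.DataFrame(rng.normal(2.0, 1.5, size=(n_maps, n_parcels)),
                        index=[f"m{i}" for i in range(n_maps)],
                        columns=range(1, n_parcels + 1))
    coords = rng.normal(size=(n_maps, 3))
    return data, coords


class TestTToZ:
    def test_zero_maps_to_zero(self):
        for df in (1, 5, 100):
            assert t_to_z(0.0, df) == 0.0

    def test_sign_symmetric(self):
        rng = np.random.default_rng(0)
        t = rng.normal(scale=3, size=20)
        z_pos = t_to_z(t, 7)
        z_neg = t_to_z(-t, 7)
        assert np.allclose(z_pos, -z_neg, atol=1e-12)

    def test_strictly_monotone(self):
        t = np.linspace(-6, 6, 41)
        z = t_to_z(t, 9)
        assert np.all(np.diff(z) > 0)

    @pytest.mark.parametrize("t,df", [(2.0, 10), (-1.3, 4), (0.7, 30), (4.5, 2)])
    def test_matches_quadrature_oracle(self, t, df):
        assert t_to_z(t, df) == pytest.approx(t_to_z_quadrature(t, df), abs=1e-8)

    def test_clamped_at_cap(self):
        assert t_to_z(1e9, 5) == Z_CAP
        assert t_to_z(np.inf, 5) == Z_CAP
        assert t_to_z(-np.inf, 5) == -Z_CAP

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            t_to_z(1.0, 0.5)


class TestPredictMap:
    def test_matches_closed_form_ols_oracle(self, fake_space_factory):
        rng = np.random.default_rng(4)
        data, coords = _random_case(rng)
        matrix = ParcelMatrix(data)
        space = fake_space_factory(coords, matrix)
        model, _ = predict_map("m0", space, matrix)
        d = np.linalg.norm(coords[1:] - coords[0], axis=1)
        for k, pid in enumerate(matrix.parcel_ids):
            y = data.iloc[1:, k].tolist()
            expected = ols_t_oracle(list(-d), y)
            assert model.table.loc[pid, "t"] == pytest.approx(expected, abs=1e-10)

    def test_constant_parcel_has_zero_t(self, fake_space_factory):
        rng = np.random.default_rng(5)
        data, coords = _random_case(rng)
        data[3] = 1.7  # identical across references
        matrix = ParcelMatrix(data)
        space = fake_space_factory(coords, matrix)
        model, predicted = predict_map("m0", space, matrix)
        assert model.table.loc[3, "t"] == 0.0
        assert predicted.z_raw[3] == 0.0

    def test_perfect_fit_hits_documented_cap(self, fake_space_factory):
        rng = np.random.default_rng(6)
        _, coords = _random_case(rng)
        d_all = np.linalg.norm(coords - coords[0], axis=1)
        data = pd.DataFrame({1: -d_all, 2: rng.normal(size=7)},
                            index=[f"m{i}" for i in range(7)])
        matrix = ParcelMatrix(data)
        space = fake_space_factory(coords, matrix)
        model, predicted = predict_map("m0", space, matrix)
        assert model.table.loc[1, "t"] == pytest.approx(t_cap(model.df))
        assert predicted.z_raw[1] == Z_CAP

    def test_thresholded_values_contract(self, fake_space_factory):
        rng = np.random.default_rng(7)
        data, coords = _random_case(rng, n_maps=10, n_parcels=12)
        matrix = ParcelMatrix(data)
        space = fake_space_factory(coords, matrix)
        _, predicted = predict_map("m2", space, matrix,
                                   policy=ThresholdPolicy(2.0))
        v = predicted.values.to_numpy()
        assert np.all((v == 0) | (v >= 2.0))

    def test_too_few_references_rejected(self, fake_space_factory):
        rng = np.random.default_rng(8)
        data, coords = _random_case(rng, n_maps=4)
        matrix = ParcelMatrix(data)
        space = fake_space_factory(coords, matrix)
        with pytest.raises(ValueError, match="reference"):
            predict_map("m0", space, matrix)

    def test_degenerate_distances_rejected(self, fake_space_factory):
        rng = np.random.default_rng(9)
        data, _ = _random_case(rng)
        coords = np.zeros((7, 3))
        matrix = ParcelMatrix(data)
        space = fake_space_factory(coords, matrix)
        with pytest.raises(ZeroVarianceError):
            predict_map("m0", space, matrix)

    def test_idw_backend_interpolates(self, fake_space_factory):
        rng = np.random.default_rng(10)
        data, coords = _random_case(rng, n_maps=8)
        matrix = ParcelMatrix(data)
        space = fake_space_factory(coords, matrix)
        model, predicted = predict_map("m1", space, matrix, backend="idw")
        assert model is None
        d = np.linalg.norm(np.delete(coords, 1, axis=0) - coords[1], axis=1)
        w = 1 / d ** 2
        refs = data.drop(index="m1").to_numpy()
        expected = w @ refs / w.sum()
        assert np.allclose(predicted.z_raw.to_numpy(), expected)


class TestPredictabilityIndex:
    def _predicted(self, values, threshold=0.5):
        from morphospace.predictability import PredictedMap
        s = pd.Series(values, index=range(1, len(values) + 1), dtype=float)
        return PredictedMap(target_id="m0",
                            values=s.where(s >= threshold, 0.0),
                            z_raw=s, threshold=threshold)

    def test_self_correlation_is_one(self):
        p = self._predicted([1.0, 2.0, 3.0, 4.0])
        measured = pd.Series([1.0, 2.0, 3.0, 4.0], index=range(1, 5))
        res = predictability_index(p, measured, thresholded=False)
        assert res.index == pytest.approx(1.0)

    def test_antisymmetry(self):
        p = self._predicted([1.0, 2.0, 3.0, 4.0])
        measured = pd.Series([-1.0, -2.0, -3.0, -4.0], index=range(1, 5))
        res = predictability_index(p, measured, thresholded=False)
        assert res.index == pytest.approx(-1.0)

    @pytest.mark.parametrize("method,oracle", [("pearson", pearson_oracle),
                                               ("spearman", spearman_oracle)])
    def test_matches_textbook_formula(self, method, oracle):
        pred_vals = [0.2, 1.7, 0.9, 2.4, 0.1]
        meas_vals = [0.5, 1.1, 1.3, 2.0, 0.4]
        p = self._predicted(pred_vals)
        measured = pd.Series(meas_vals, index=range(1, 6))
        res = predictability_index(p, measured, method=method, thresholded=False)
        assert res.index == pytest.approx(oracle(pred_vals, meas_vals), abs=1e-12)

    def test_zero_variance_raises(self):
        p = self._predicted([1.0, 1.0, 1.0])
        measured = pd.Series([1.0, 2.0, 3.0], index=range(1, 4))
        with pytest.raises(ZeroVarianceError):
            predictability_index(p, measured, thresholded=False)

    def test_spearman_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=8)
        p = self._predicted(vals)
        measured = pd.Series(rng.normal(size=8), index=range(1, 9))
        r1 = predictability_index(p, measured, method="spearman", thresholded=False)
        r2 = predictability_index(p, np.exp(measured) * 3 + 1, method="spearman",
                                  thresholded=False)
        assert r1.index == pytest.approx(r2.index)


class TestLoo:
    def test_recovers_noiseless_structure(self, default_loo):
        assert default_loo["index"].median() >= 0.9

    def test_order_independent(self, fake_space_factory):
        rng = np.random.default_rng(12)
        data, coords = _random_case(rng, n_maps=9, n_parcels=8)
        matrix = ParcelMatrix(data)
        space = fake_space_factory(coords, matrix)
        res = loo_predictability(space, matrix, thresholded=False)
        order = [4, 2, 0, 8, 6, 1, 3, 7, 5]
        matrix2 = matrix.subset([matrix.map_ids[i] for i in order])
        space2 = fake_space_factory(coords[order], matrix2)
        res2 = loo_predictability(space2, matrix2, thresholded=False)
        merged = res.set_index("map_id")["index"] - res2.set_index("map_id")["index"]
        assert np.allclose(merged.to_numpy(), 0.0, atol=1e-12)

    def test_removing_one_map_perturbs_little(self, fake_space_factory):
        rng = np.random.default_rng(13)
        data, coords = _random_case(rng, n_maps=20, n_parcels=15)
        matrix = ParcelMatrix(data)
        space = fake_space_factory(coords, matrix)
        full = loo_predictability(space, matrix, thresholded=False)
        keep = matrix.map_ids[1:]
        reduced_matrix = matrix.subset(keep)
        reduced_space = fake_space_factory(coords[1:], reduced_matrix)
        reduced = loo_predictability(reduced_space, reduced_matrix, thresholded=False)
        diff = (full.set_index("map_id")["index"].loc[keep]
                - reduced.set_index("map_id")["index"])
        assert np.abs(diff.to_numpy()).max() < 0.25


class TestProjection:
    def test_self_projection_consistency(self, default_space, default_dataset,
                                         default_loo):
        _, _, ds = default_dataset
        sample = ds.parcel_matrix.subset(ds.parcel_matrix.map_ids[::6])
        results, coords = project_and_predict(default_space, ds.parcel_matrix,
                                              sample, thresholded=False)
        assert coords.shape == (sample.n_maps, 3)
        loo = default_loo.set_index("map_id")["index"]
        proj = results.set_index("map_id")["index"]
        # Spearman on all references vs LOO Pearson: same maps stay well
        # predicted when re-presented out of sample
        assert (proj.loc[sample.map_ids] > 0.8).mean() >= 0.9
        assert proj.median() == pytest.approx(loo.loc[sample.map_ids].median(),
                                              abs=0.1)

    def test_constant_new_map_rejected(self, default_space, default_dataset):
        _, _, ds = default_dataset
        data = ds.parcel_matrix.data.iloc[:1].copy()
        data.iloc[0] = 5.0
        with pytest.raises(ZeroVarianceError):
            project_and_predict(default_space, ds.parcel_matrix,
                                ParcelMatrix(data), thresholded=False)

    def test_on_branch_beats_far_placement(self, default_space, default_dataset):
        _, _, ds = default_dataset
        on_branch = ds.parcel_matrix.subset([ds.parcel_matrix.map_ids[10]])
        far = pd.DataFrame(
            np.random.default_rng(3).uniform(0, 8, size=(1, ds.parcel_matrix.n_parcels)),
            index=["far"], columns=ds.parcel_matrix.parcel_ids)
        res_on, _ = project_and_predict(default_space, ds.parcel_matrix, on_branch,
                                        thresholded=False)
        res_far, _ = project_and_predict(default_space, ds.parcel_matrix,
                                         ParcelMatrix(far), thresholded=False)
        assert res_on["index"].iloc[0] > res_far["index"].iloc[0]


class TestKnnSummary:
    def _setup(self, rng):
        data, coords = _random_case(rng, n_maps=12, n_parcels=5)
        matrix = ParcelMatrix(data)
        results = pd.DataFrame({"map_id": matrix.map_ids,
                                "index": rng.uniform(-1, 1, 12)})
        return coords, matrix, results

    def test_k1_at_training_coordinate(self, fake_space_factory):
        rng = np.random.default_rng(14)
        coords, matrix, results = self._setup(rng)
        space = fake_space_factory(coords, matrix)
        got = knn_index_summary(space, results, coords[3], k=1)
        assert got == pytest.approx(results["index"].iloc[3])

    def test_k_all_is_global_mean(self, fake_space_factory):
        rng = np.random.default_rng(15)
        coords, matrix, results = self._setup(rng)
        space = fake_space_factory(coords, matrix)
        got = knn_index_summary(space, results, rng.normal(size=3), k=12)
        assert got == pytest.approx(results["index"].mean())

    def test_matches_exhaustive_sort_oracle(self, fake_space_factory):
        rng = np.random.default_rng(16)
        coords, matrix, results = self._setup(rng)
        space = fake_space_factory(coords, matrix)
        query = rng.normal(size=3)
        d = [float(np.linalg.norm(coords[i] - query)) for i in range(12)]
        order = sorted(range(12), key=lambda i: (d[i], i))[:5]
        expected = np.mean([results["index"].iloc[i] for i in order])
        assert knn_index_summary(space, results, query, k=5) == pytest.approx(expected)

    def test_invalid_k_rejected(self, fake_space_factory):
        rng = np.random.default_rng(17)
        coords, matrix, results = self._setup(rng)
        space = fake_space_factory(coords, matrix)
        with pytest.raises(ValueError):
            knn_index_summary(space, results, coords[0], k=0)
        with pytest.raises(ValueError):
            knn_index_summary(space, results, coords[0], k=13)


class TestCovariateCorrelation:
    def test_identity_covariate(self):
        results = pd.DataFrame({"map_id": ["a", "b", "c", "d"],
                                "index": [0.1, 0.4, 0.2, 0.9]})
        cov = pd.Series([0.1, 0.4, 0.2, 0.9], index=["a", "b", "c", "d"])
        got = covariate_correlation(results, cov)
        assert got.r == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        idx = [0.2, 0.5, 0.1, 0.8, 0.3]
        cov = [12.0, 40.0, 7.0, 65.0, 20.0]
        results = pd.DataFrame({"map_id": list("abcde"), "index": idx})
        got = covariate_correlation(results, pd.Series(cov, index=list("abcde")))
        assert got.r == pytest.approx(pearson_oracle(idx, cov), abs=1e-12)

    def test_independent_covariate_small_r(self):
        rng = np.random.default_rng(18)
        idx = rng.uniform(0, 1, 40)
        results = pd.DataFrame({"map_id": [f"m{i}" for i in range(40)], "index": idx})
        rs = []
        for s in range(20):
            cov = pd.Series(np.random.default_rng(s).permutation(idx),
                            index=results["map_id"])
            rs.append(covariate_correlation(results, cov).r)
        assert abs(np.mean(rs)) < 0.15

    def test_missing_covariate_rejected(self):
        results = pd.DataFrame({"map_id": ["a", "b", "c"], "index": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="missing"):
            covariate_correlation(results, pd.Series([1.0], index=["a"]))
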