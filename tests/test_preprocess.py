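import numpy as np
import pandas as pd
import pytest

import priorcut as pc
from priorcut.data import CovariateTable, OmicsMatrix


def _mat(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(values,
                       [f"{prefix}{i}" for i in range(values.shape[0])],
                       [f"v{j}" for j in range(values.shape[1])])


class TestPQN:
    def test_hand_example(self):
        # reference (1.5, 3, 4.5); dilution factors (2/3, 4/3)
        x = pc.pqn_normalize(_mat([[1, 2, 3], [2, 4, 6]]))
        np.testing.assert_allclose(x.values, [[1.5, 3, 4.5], [1.5, 3, 4.5]], rtol=1e-12)

    def test_identical_samples_unchanged(self):
        x = _mat([[1, 2, 3]] * 4)
        np.testing.assert_allclose(pc.pqn_normalize(x).values, x.values)

    def test_scale_invariance_with_fixed_reference(self, rng):
        raw = _mat(rng.lognormal(size=(15, 8)))
        ref = np.nanmedian(raw.values, axis=0)
        scaled = OmicsMatrix(raw.values * rng.uniform(0.1, 10, size=15)[:, None],
                             raw.sample_ids, raw.variable_ids)
        np.testing.assert_allclose(pc.pqn_normalize(scaled, reference=ref).values,
                                   pc.pqn_normalize(raw, reference=ref).values,
                                   atol=1e-10)

    def test_scaled_sample_recovered_when_medians_unaffected(self, rng):
        # the dilution factor cancels a x7 factor on one sample exactly as
        # long as that sample does not set any per-variable median
        base = rng.lognormal(size=(5, 6))
        base[4] = base.max(axis=0) * 2  # row 4 is the max of every variable
        scaled = base.copy()
        scaled[4] *= 7.0
        out_base = pc.pqn_normalize(_mat(base)).values
        out_scaled = pc.pqn_normalize(_mat(scaled)).values
        np.testing.assert_allclose(out_scaled[4], out_base[4], rtol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pc.pqn_normalize(_mat([[1, -2], [3, 4]]))

    def test_missing_ignored_in_medians(self):
        v = np.array([[1.0, 2.0, 3.0], [2.0, np.nan, 6.0], [1.0, 2.0, 3.0]])
        out = pc.pqn_normalize(_mat(v))
        assert np.isnan(out.values[1, 1])
        assert not np.isnan(out.values[1, 0])


class TestLogTransform:
    def test_known_values(self):
        x = _mat([[1.0, 1000.0]])
        np.testing.assert_allclose(pc.log_transform(x, 10).values, [[0.0, 3.0]], atol=1e-12)
        np.testing.assert_allclose(pc.log_transform(x, "e").values[0, 0], 0.0)
        np.testing.assert_allclose(pc.log_transform(_mat([[8.0]]), 2).values, [[3.0]])

    def test_round_trip(self, rng):
        x = _mat(rng.lognormal(size=(5, 4)))
        back = np.exp(pc.log_transform(x, "e").values)
        np.testing.assert_allclose(back, x.values, rtol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pc.log_transform(_mat([[0.0, 1.0]]))


class TestFilterMissing:
    def test_no_missing_unchanged(self, rng):
        x = _mat(rng.normal(size=(10, 4)))
        out = pc.filter_missing(x, 0.2, 0.1)
        np.testing.assert_array_equal(out.values, x.values)

    def test_strictly_greater_rule(self):
        v = np.ones((10, 3))
        v[:3, 0] = np.nan   # 30% missing -> dropped at 0.2
        v[:2, 1] = np.nan   # exactly 20% -> kept
        out = pc.filter_missing(_mat(v), 0.2, 1.0)
        assert out.variable_ids == ["v1", "v2"]

    def test_variables_filtered_before_samples(self):
        # sample s0 is 50% missing only because of a bad variable; once that
        # variable is dropped the sample survives the 10% rule
        v = np.ones((10, 2))
        v[:, 0] = np.nan
        v[0, 0] = np.nan
        out = pc.filter_missing(_mat(v), 0.2, 0.1)
        assert out.variable_ids == ["v1"]
        assert len(out.sample_ids) == 10

    def test_empty_result_rejected(self):
        v = np.full((4, 2), np.nan)
        with pytest.raises(ValueError, match="removed all"):
            pc.filter_missing(_mat(v), 0.0, 0.0)


class TestKNNImpute:
    def test_complete_matrix_identity(self, rng):
        x = _mat(rng.normal(size=(8, 4)))
        np.testing.assert_array_equal(pc.knn_impute(x, 2).values, x.values)

    def test_perfect_neighbor_reproduced(self, rng):
        base = rng.normal(size=(12, 4))
        v = np.column_stack([base, base[:, 0]])  # v4 duplicates v0
        v[5, 0] = np.nan
        out = pc.knn_impute(_mat(v), k=1)
        assert out.values[5, 0] == pytest.approx(base[5, 0], abs=1e-10)

    def test_rmse_below_variable_sd(self, rng):
        cov = np.full((5, 5), 0.7) + 0.3 * np.eye(5)
        truth = rng.multivariate_normal(np.zeros(5), cov, size=20)
        holes = rng.random(truth.shape) < 0.05
        holes[:, truth.std(axis=0) == 0] = False
        v = np.where(holes, np.nan, truth)
        out = pc.knn_impute(_mat(v), k=3)
        err = out.values[holes] - truth[holes]
        assert np.sqrt(np.mean(err ** 2)) < truth.std(axis=0).max()

    def test_filter_then_impute_complete(self, rng):
        v = rng.normal(size=(20, 6))
        v[rng.random(v.shape) < 0.08] = np.nan
        out = pc.knn_impute(pc.filter_missing(_mat(v), 0.2, 0.5), k=3)
        assert out.n_missing == 0

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller than"):
            pc.knn_impute(_mat(rng.normal(size=(5, 3))), k=3)


class TestResidualize:
    def _cov(self, values, ids):
        return CovariateTable(pd.DataFrame(values, index=ids))

    def test_intercept_only_centers(self, rng):
        x = _mat(rng.normal(2.0, 1.0, size=(10, 3)))
        c = self._cov({"z": np.zeros(10)}, x.sample_ids)
        out = pc.residualize(x, c)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)

    def test_variable_equal_to_covariate_zeroed(self, rng):
        age = rng.normal(50, 10, size=12)
        x = OmicsMatrix(np.column_stack([age, rng.normal(size=12)]),
                        [f"s{i}" for i in range(12)], ["a", "b"])
        out = pc.residualize(x, self._cov({"age": age}, x.sample_ids))
        np.testing.assert_allclose(out.values[:, 0], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        x = _mat(rng.normal(size=(30, 4)))
        cov = self._cov({"age": rng.normal(size=30), "bmi": rng.normal(size=30)},
                        x.sample_ids)
        out = pc.residualize(x, cov)
        for name in ("age", "bmi"):
            c = cov.values[name].to_numpy()
            corr = np.corrcoef(np.column_stack([out.values, c]), rowvar=False)[-1, :-1]
            np.testing.assert_allclose(corr, 0.0, atol=1e-10)

    def test_idempotent(self, rng):
        x = _mat(rng.normal(size=(15, 3)))
        cov = self._cov({"age": rng.normal(size=15)}, x.sample_ids)
        once = pc.residualize(x, cov)
        twice = pc.residualize(once, cov)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_collinear_design_named(self, rng):
        a = rng.normal(size=10)
        x = _mat(rng.normal(size=(10, 2)))
        cov = self._cov({"a": a, "b": 2 * a}, x.sample_ids)
        with pytest.raises(ValueError, match="rank-deficient"):
            pc.residualize(x, cov)

    def test_inner_join_drops_unmatched(self, rng):
        x = _mat(rng.normal(size=(6, 2)))
        cov = self._cov({"age": rng.normal(size=4)}, x.sample_ids[:4])
        out = pc.residualize(x, cov)
        assert out.sample_ids == x.sample_ids[:4]
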