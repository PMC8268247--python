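import numpy as np
import pytest

from metabodisc.datatypes import FeatureTable
from metabodisc.preprocess import (
    autoscale,
    glog_transform,
    impute_missing,
    normality_screen,
    pqn_normalize,
)
from metabodisc.simulate import CohortSpec, generate_cohort


def _table(values, mask=None):
    n, m = np.asarray(values).shape
    return FeatureTable([f"S{i}" for i in range(n)], [f"M{j}" for j in range(m)], values, mask)


class TestImputeMissing:
    def test_exact_rank_one_completion(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(1, 2, 30), rng.uniform(1, 2, 20)
        x = np.outer(a, b)
        mask = rng.random(x.shape) < 0.10
        result = impute_missing(_table(x, mask), max_rank=3, seed=1)
        assert np.allclose(result.table.values[mask], x[mask], atol=1e-6)

    def test_observed_entries_bit_exact(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=(25, 12))
        mask = rng.random(x.shape) < 0.15
        result = impute_missing(_table(x, mask), max_rank=4, seed=1)
        assert np.array_equal(result.table.values[~mask], x[~mask])
        assert result.table.is_complete

    def test_complete_table_returned_unchanged(self):
        x = np.arange(12.0).reshape(4, 3) + 1
        result = impute_missing(_table(x), max_rank=2, seed=0)
        assert np.array_equal(result.table.values, x)
        assert result.chosen_rank == 0

    def test_noisy_low_rank_rmse_bounded(self):
        # rank-3 + N(0, sigma^2), 15% MCAR: held-out RMSE < 2 sigma
        rng = np.random.default_rng(2)
        sigma = 0.1
        u = rng.standard_normal((200, 3))
        v = rng.standard_normal((3, 100))
        x = u @ v + sigma * rng.standard_normal((200, 100))
        mask = rng.random(x.shape) < 0.15
        result = impute_missing(_table(x, mask), max_rank=6, seed=3)
        rmse = np.sqrt(np.mean((result.table.values[mask] - x[mask]) ** 2))
        assert rmse < 2 * sigma
        assert result.chosen_rank == 3

    def test_all_missing_column_rejected(self):
        x = np.ones((4, 2))
        mask = np.zeros_like(x, bool)
        mask[:, 1] = True
        with pytest.raises(ValueError, match="M1"):
            impute_missing(_table(x, mask))


class TestPqn:
    def test_double_concentration_sample(self):
        ref_rows = np.tile(np.array([1.0, 2.0, 4.0, 8.0]), (5, 1))
        x = np.vstack([ref_rows, 2.0 * ref_rows[:1]])
        table, dilution = pqn_normalize(_table(x), reference="study_median")
        assert dilution[-1] == pytest.approx(2.0)
        assert np.allclose(table.values[-1], ref_rows[0])

    def test_identical_samples_unchanged(self):
        x = np.tile(np.array([3.0, 1.0, 5.0]), (6, 1))
        table, dilution = pqn_normalize(_table(x), reference="study_median")
        assert np.allclose(dilution, 1.0)
        assert np.allclose(table.values, x)

    def test_scaling_one_sample_scales_its_dilution_exactly(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=(10, 30))
        t1, d1 = pqn_normalize(_table(x), reference="study_median")
        x2 = x.copy()
        x2[4] *= 3.7
        # use the same reference by computing it from the unmodified rows:
        # median over study rows changes, so compare against a fixed reference
        # built by excluding the scaled row from both runs
        ref = np.median(x[[i for i in range(10) if i != 4]], axis=0)
        d_before = np.median(x[4] / ref)
        d_after = np.median(x2[4] / ref)
        assert d_after == pytest.approx(3.7 * d_before)
        assert np.allclose(x2[4] / d_after, x[4] / d_before)

    def test_dilution_recovery_on_synthetic_cohort(self):
        spec = CohortSpec(seed=21)
        table, meta, truth = generate_cohort(spec)
        imputed = impute_missing(table, max_rank=4, seed=1).table
        _, dilution = pqn_normalize(imputed, meta)
        r = np.corrcoef(dilution, truth.dilution_factors)[0, 1]
        assert r >= 0.99

    def test_nonpositive_reference_rejected(self):
        x = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        with pytest.raises(ValueError, match="M1"):
            pqn_normalize(_table(x), reference="study_median")


class TestGlog:
    def test_lambda_zero_is_log2(self):
        table, lam = glog_transform(_table(np.array([[8.0]])), lam=0.0)
        assert table.values[0, 0] == pytest.approx(3.0)

    def test_lambda_one_at_zero(self):
        table, _ = glog_transform(_table(np.array([[0.0]])), lam=1.0)
        assert table.values[0, 0] == pytest.approx(-1.0)

    def test_strictly_increasing(self):
        x = np.sort(np.concatenate([[0.0], np.random.default_rng(0).lognormal(size=50)]))
        for lam in [1e-6, 1.0, 100.0]:
            table, _ = glog_transform(_table(x[None, :]), lam=lam)
            assert np.all(np.diff(table.values[0]) > 0)

    def test_auto_lambda_rule(self):
        x = np.array([[5.0, 40.0], [10.0, 80.0]])
        _, lam = glog_transform(_table(x), lam="auto")
        assert lam == pytest.approx((5.0 / 10.0) ** 2)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            glog_transform(_table(np.ones((2, 2))), lam=-1.0)


class TestAutoscale:
    def test_columns_standardized(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(size=(50, 8))
        table, scaler = autoscale(_table(x))
        assert np.allclose(table.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(table.values.std(axis=0, ddof=1), 1.0, atol=1e-12)
        assert np.allclose(scaler.apply(x), table.values)

    def test_constant_column_rejected(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="M1"):
            autoscale(_table(x))


class TestNormalityScreen:
    def test_discriminates_normal_from_exponential(self):
        rng = np.random.default_rng(5)
        normal_p, expo_p = [], []
        for _ in range(100):
            n = _table(rng.standard_normal((500, 1)))
            e = _table(rng.exponential(size=(500, 1)))
            normal_p.append(normality_screen(n)[0]["p_value"])
            expo_p.append(normality_screen(e)[0]["p_value"])
        assert np.mean(np.array(normal_p) > 0.01) >= 0.95
        assert np.mean(np.array(expo_p) < 0.01) >= 0.95

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_screen(_table(np.ones((2, 1))))


class TestPipelineProperties:
    def test_glog_pqn_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(size=(12, 20))
        t = _table(x)
        norm, _ = pqn_normalize(t, reference="study_median")
        out, _ = glog_transform(norm, lam=1.0)
        perm = rng.permutation(12)
        t_perm = FeatureTable([t.sample_ids[i] for i in perm], t.metabolite_ids, x[perm])
        norm_p, _ = pqn_normalize(t_perm, reference="study_median")
        out_p, _ = glog_transform(norm_p, lam=1.0)
        assert np.allclose(out_p.values, out.values[perm])
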