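import numpy as np
import pytest

from metabodisc.opls import (
    OPLSDA,
    fit_opls_da,
    permutation_check,
    q2_cross_validate,
    select_n_orthogonal,
)

from oracles import nipals_pls1_weights


def _toy(n=60, m=20, seed=0, effect=1.0, orth_scale=0.0):
    """Centered matrix with a y-aligned direction and optionally a strong
    y-orthogonal component."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    yc = y - y.mean()
    v = rng.standard_normal(m)
    v /= np.linalg.norm(v)
    x = effect * np.outer(yc, v) + 0.3 * rng.standard_normal((n, m))
    if orth_scale > 0:
        u = rng.standard_normal(n)
        u -= u @ yc / (yc @ yc) * yc  # orthogonalize to y
        w = rng.standard_normal(m)
        w -= (w @ v) * v
        w /= np.linalg.norm(w)
        x = x + orth_scale * np.outer(u, w)
    return x - x.mean(axis=0), y


class TestFit:
    def test_pure_predictive_structure_r2y_one(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 10 + [0] * 10)
        v = rng.standard_normal(8)
        v /= np.linalg.norm(v)
        x = np.outer(y - y.mean(), v)
        res = fit_opls_da(x, y, n_orth=0)
        assert res.r2y == pytest.approx(1.0, abs=1e-10)

    def test_zero_orthogonal_matches_nipals_pls1_oracle(self):
        x, y = _toy(seed=2)
        res = fit_opls_da(x, y, n_orth=0)
        _, t_oracle = nipals_pls1_weights(x, y)
        cos = abs(res.t @ t_oracle) / (np.linalg.norm(res.t) * np.linalg.norm(t_oracle))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_filtering_removes_strong_y_orthogonal_component(self):
        # augment X with a strong component orthogonal to y living on a fresh
        # coordinate; one orthogonal component must recover (to 1e-6) the
        # plain PLS fit on X with that component's sample direction projected
        # out -- the defining filtering property of the construction
        x0, y = _toy(seed=3)
        yc = y - y.mean()
        rng = np.random.default_rng(99)
        u = rng.standard_normal(len(y))
        u -= u @ yc / (yc @ yc) * yc
        u -= u.mean()
        x1 = np.column_stack([x0, 5e4 * u])
        res1 = fit_opls_da(x1, y, n_orth=1)
        x_clean = x0 - np.outer(u, u @ x0) / (u @ u)
        res_clean = fit_opls_da(x_clean, y, n_orth=0)
        corr1 = abs(np.corrcoef(res1.t, yc)[0, 1])
        corr_clean = abs(np.corrcoef(res_clean.t, yc)[0, 1])
        assert corr1 == pytest.approx(corr_clean, abs=1e-6)

    def test_one_class_rejected(self):
        x = np.random.default_rng(0).standard_normal((10, 4))
        with pytest.raises(ValueError):
            fit_opls_da(x, np.ones(10), n_orth=0)

    def test_unit_norm_weights_invariant(self):
        x, y = _toy(seed=4, orth_scale=2.0)
        res = fit_opls_da(x, y, n_orth=3)
        assert np.linalg.norm(res.w) == pytest.approx(1.0, abs=1e-10)
        for k in range(3):
            assert np.linalg.norm(res.W_orth[:, k]) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_scores_uncorrelated_with_y(self):
        x, y = _toy(seed=5, orth_scale=3.0)
        res = fit_opls_da(x, y, n_orth=2)
        yc = y - y.mean()
        for k in range(2):
            t_o = res.T_orth[:, k]
            rel = abs(t_o @ yc) / (np.linalg.norm(t_o) * np.linalg.norm(yc))
            assert rel < 1e-8

    def test_deflation_reduces_frobenius_norm(self):
        x, y = _toy(seed=6, orth_scale=3.0)
        norms = []
        xc = x.copy()
        yc = y - y.mean()
        for _ in range(3):
            res = OPLSDA(y, xc).fit(n_orthogonal=1)
            xc = xc - np.outer(res.T_orth[:, 0], res.P_orth[:, 0])
            norms.append(np.linalg.norm(xc))
        assert norms[0] > norms[1] > norms[2]

    def test_r2y_invariant_to_column_permutation_and_label_swap(self):
        x, y = _toy(seed=7, orth_scale=1.0)
        res = fit_opls_da(x, y, n_orth=1)
        perm = np.random.default_rng(8).permutation(x.shape[1])
        res_perm = fit_opls_da(x[:, perm], y, n_orth=1)
        res_swap = fit_opls_da(x, 1 - y, n_orth=1)
        assert res_perm.r2y == pytest.approx(res.r2y, abs=1e-10)
        assert res_swap.r2y == pytest.approx(res.r2y, abs=1e-10)
        assert np.allclose(res_swap.t, -res.t, atol=1e-10)


class TestPredict:
    def test_training_prediction_reproduces_scores(self):
        x, y = _toy(seed=9, orth_scale=2.0)
        res = fit_opls_da(x, y, n_orth=2)
        scores, y_hat, klass = res.predict(x)
        assert np.allclose(scores, res.t, atol=1e-10)

    def test_separable_cohort_validation_auc_one(self):
        x, y = _toy(n=80, seed=10, effect=6.0)
        train = np.arange(0, 80, 2)
        test = np.arange(1, 80, 2)
        res = fit_opls_da(x[train] - x[train].mean(axis=0), y[train], n_orth=0)
        scores, _, _ = res.predict(x[test] - x[train].mean(axis=0))
        cases, controls = scores[y[test] == 1], scores[y[test] == 0]
        auc = np.mean(cases[:, None] > controls[None, :])
        assert auc == 1.0

    def test_null_cohort_validation_auc_near_half(self):
        rng = np.random.default_rng(11)
        aucs = []
        for _ in range(10):
            x = rng.standard_normal((180, 30))
            y = np.array([1] * 60 + [0] * 120)
            train = rng.permutation(180)[:126]
            test = np.setdiff1d(np.arange(180), train)
            res = fit_opls_da(x[train] - x[train].mean(axis=0), y[train], n_orth=0)
            s, _, _ = res.predict(x[test] - x[train].mean(axis=0))
            c, k = s[y[test] == 1], s[y[test] == 0]
            aucs.append((np.sum(c[:, None] > k[None, :]) + 0.5 * np.sum(c[:, None] == k[None, :]))
                        / (len(c) * len(k)))
        assert 0.4 <= np.median(aucs) <= 0.6

    def test_dimension_mismatch_rejected(self):
        x, y = _toy(seed=12)
        res = fit_opls_da(x, y, n_orth=0)
        with pytest.raises(ValueError):
            res.predict(np.ones((3, 5)))


class TestQ2:
    def test_pure_structure_high_q2(self):
        x, y = _toy(n=200, seed=13, effect=3.0)
        assert q2_cross_validate(x, y, 0, folds=7, seed=0) > 0.9

    def test_null_q2_nonpositive(self):
        rng = np.random.default_rng(14)
        count = 0
        for i in range(50):
            x = rng.standard_normal((60, 25))
            y = np.array([1] * 30 + [0] * 30)
            if q2_cross_validate(x, y, 0, folds=7, seed=i) <= 0:
                count += 1
        assert count >= 45

    def test_leave_one_out_matches_hand_rolled_loop(self):
        x, y = _toy(n=12, m=5, seed=15)
        got = q2_cross_validate(x, y, 0, folds=12, seed=0)
        press = 0.0
        for i in range(12):
            train = np.setdiff1d(np.arange(12), [i])
            centers = x[train].mean(axis=0)
            scales = x[train].std(axis=0, ddof=1)
            scales[scales == 0] = 1.0
            res = fit_opls_da((x[train] - centers) / scales, y[train], n_orth=0)
            _, y_hat, _ = res.predict((x[i] - centers) / scales)
            press += (y[i] - y_hat) ** 2
        expected = 1.0 - press / np.sum((y - y.mean()) ** 2)
        assert got == pytest.approx(expected, abs=1e-12)


class TestPermutationCheck:
    def test_planted_effect_small_p(self):
        x, y = _toy(n=100, seed=16, effect=2.0)
        stats = permutation_check(x, y, 0, n_perm=99, seed=0)
        assert stats.perm_p <= 0.05
        assert stats.r2y >= stats.q2

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(17)
        ps = []
        for i in range(10):
            x = rng.standard_normal((40, 10))
            y = np.array([1] * 20 + [0] * 20)
            ps.append(permutation_check(x, y, 0, n_perm=24, seed=i).perm_p)
        assert np.mean([0.05 <= p <= 1.0 for p in ps]) >= 0.9

    def test_identical_seed_identical_stream(self):
        x, y = _toy(seed=18)
        s1 = permutation_check(x, y, 0, n_perm=20, seed=5)
        s2 = permutation_check(x, y, 0, n_perm=20, seed=5)
        assert np.array_equal(s1.q2_permuted, s2.q2_permuted)


class TestSelectNOrthogonal:
    def test_pure_predictive_returns_zero(self):
        x, y = _toy(n=150, seed=19, effect=3.0)
        assert select_n_orthogonal(x, y, max_orth=3, seed=0) == 0

    def test_planted_orthogonal_structure_selects_at_least_one(self):
        rng = np.random.default_rng(20)
        x, y = _toy(n=200, m=30, seed=20, effect=1.0)
        yc = y - y.mean()
        for _ in range(2):
            u = rng.standard_normal(200)
            u -= u @ yc / (yc @ yc) * yc
            w = rng.standard_normal(30)
            w /= np.linalg.norm(w)
            x = x + 4.0 * np.outer(u, w)
        x = x - x.mean(axis=0)
        assert select_n_orthogonal(x, y, max_orth=4, seed=0) >= 1

    def test_max_orth_zero_returns_zero(self):
        x, y = _toy(seed=21)
        assert select_n_orthogonal(x, y, max_orth=0, seed=0) == 0
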