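"""Reliability coefficients, factorability diagnostics, minres EFA, BH."""

import numpy as np
import pytest
from scipy import optimize, stats

from timbretest import psychometrics as psy
from timbretest.errors import DegenerateDataError, ValidationWarning


def data_with_exact_covariance(cov, n=200, seed=0):
    """Gaussian-ish data whose *sample* covariance equals ``cov`` exactly."""
    cov = np.asarray(cov, dtype=float)
    p = cov.shape[0]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p))
    z -= z.mean(axis=0)
    chol_emp = np.linalg.cholesky(np.cov(z, rowvar=False))
    white = z @ np.linalg.inv(chol_emp).T
    return white @ np.linalg.cholesky(cov).T


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        col = np.random.default_rng(1).normal(size=50)
        x = np.column_stack([col] * 4)
        assert psy.cronbach_alpha(x) == pytest.approx(1.0, abs=1e-12)

    def test_compound_symmetric_covariance(self):
        # diag 1, off-diag 0.5, p=3: alpha = 3*0.5 / (1 + 2*0.5) = 0.75
        cov = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        x = data_with_exact_covariance(cov)
        assert psy.cronbach_alpha(x) == pytest.approx(0.75, abs=1e-10)

    def test_brute_force_formula_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 5)) + rng.normal(size=(40, 1))
        k = x.shape[1]
        expected = k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / x.sum(1).var(ddof=1))
        assert psy.cronbach_alpha(x) == pytest.approx(expected, abs=1e-12)

    def test_cross_check_against_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 6)) + 0.8 * rng.normal(size=(60, 1))
        alpha_pg = pg.cronbach_alpha(data=pd.DataFrame(x))[0]
        assert psy.cronbach_alpha(x) == pytest.approx(alpha_pg, abs=1e-9)

    def test_independent_items_near_zero(self):
        x = np.random.default_rng(5).normal(size=(10000, 2))
        assert abs(psy.cronbach_alpha(x)) < 0.05

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            psy.cronbach_alpha(np.ones((10, 3)))


class TestOmegaTotal:
    def test_equals_alpha_under_tau_equivalence(self):
        # exact compound symmetry = equal loadings; alpha and omega coincide
        cov = np.full((4, 4), 0.4) + 0.6 * np.eye(4)
        x = data_with_exact_covariance(cov)
        assert psy.omega_total(x) == pytest.approx(psy.cronbach_alpha(x), abs=1e-6)

    def test_exceeds_alpha_with_zero_loading_item(self):
        r = np.eye(4)
        r[:3, :3] = 0.64 + 0.36 * np.eye(3)  # three items loading 0.8, one inert
        x = data_with_exact_covariance(r)
        assert psy.omega_total(x) > psy.cronbach_alpha(x)

    def test_near_one_for_noiseless_unidimensional_data(self):
        rng = np.random.default_rng(6)
        ability = rng.normal(size=300)
        x = np.column_stack([ability * w for w in (1.0, 0.7, 1.3)])
        x += 1e-6 * rng.normal(size=x.shape)
        with pytest.warns(ValidationWarning):
            omega = psy.omega_total(x)
        assert omega > 0.99


class TestICC:
    def test_identical_measurements_give_one(self):
        y = np.random.default_rng(7).normal(size=30)
        icc, df = psy.icc_absolute(y, y)
        assert icc == pytest.approx(1.0, abs=1e-12)
        assert df == 29

    def test_constant_shift_penalized(self):
        y = np.random.default_rng(8).normal(size=30)
        icc, _ = psy.icc_absolute(y, y + 1.0)
        assert icc < 1.0

    def test_matches_closed_form_variance_ratio(self):
        # sigma2_subject = 1, sigma2_error = 0.25 -> ICC = 1/1.25 = 0.8
        rng = np.random.default_rng(9)
        estimates = []
        for _ in range(200):
            subj = rng.normal(size=25)
            y1 = subj + 0.5 * rng.normal(size=25)
            y2 = subj + 0.5 * rng.normal(size=25)
            estimates.append(psy.icc_absolute(y1, y2)[0])
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.05)

    def test_cross_check_against_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(10)
        subj = rng.normal(size=20)
        y1 = subj + 0.4 * rng.normal(size=20)
        y2 = 0.2 + subj + 0.4 * rng.normal(size=20)
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(20), 2),
                "rater": np.tile(["t1", "t2"], 20),
                "score": np.column_stack([y1, y2]).ravel(),
            }
        )
        table = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
        assert psy.icc_absolute(y1, y2)[0] == pytest.approx(
            table.loc["ICC(A,1)", "ICC"], abs=1e-9
        )


class TestFactorability:
    def test_identity_matrix_is_spherical(self):
        chi2, df, p = psy.bartlett_sphericity(np.eye(6), n_obs=95)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_df_for_six_variables_is_fifteen(self):
        _, df, _ = psy.bartlett_sphericity(np.eye(6), n_obs=95)
        assert df == 15

    def test_bartlett_formula_by_hand(self):
        r = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        n = 100
        chi2, df, _ = psy.bartlett_sphericity(r, n)
        expected = -(n - 1 - (2 * 3 + 5) / 6) * np.log(np.linalg.det(r))
        assert chi2 == pytest.approx(expected, abs=1e-10)
        assert df == 3

    def test_kmo_compound_symmetric_by_hand(self):
        # p=3, rho=0.5: partials are 1/3, KMO = (6/4) / (6/4 + 6/9) = 0.6923
        r = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        assert psy.kmo(r) == pytest.approx(1.5 / (1.5 + 2.0 / 3.0), abs=1e-10)


def one_factor_data(loadings, n=5000, seed=11):
    rng = np.random.default_rng(seed)
    loadings = np.asarray(loadings)
    f = rng.normal(size=(n, 1))
    e = rng.normal(size=(n, len(loadings))) * np.sqrt(1 - loadings**2)
    return f @ loadings[None, :] + e


class TestMinresEFA:
    def test_single_factor_loading_recovery(self):
        x = one_factor_data([0.8] * 5)
        report = psy.efa_minres(data=x, n_factors=1, method="pearson")
        assert np.allclose(report.loadings["F1"], 0.8, atol=0.05)

    def test_kaiser_and_parallel_select_one_factor(self):
        x = one_factor_data([0.8] * 5)
        report = psy.efa_minres(data=x, method="pearson")
        assert report.n_factors_kaiser == 1
        assert report.n_factors_parallel == 1

    def test_two_orthogonal_factors_recovered(self):
        rng = np.random.default_rng(12)
        f = rng.normal(size=(5000, 2))
        lam = np.zeros((6, 2))
        lam[:3, 0] = 0.8
        lam[3:, 1] = 0.7
        e = rng.normal(size=(5000, 6)) * np.sqrt(1 - (lam**2).sum(1))
        x = f @ lam.T + e
        report = psy.efa_minres(data=x, method="pearson")
        assert report.n_factors_parallel == 2
        L = np.abs(report.loadings.to_numpy())
        primary = L.argmax(axis=1)
        assert list(primary) == [primary[0]] * 3 + [primary[3]] * 3
        cross = np.take_along_axis(L, (1 - primary)[:, None], axis=1)
        assert np.all(cross < 0.2)

    def test_residual_gradient_vanishes_at_solution(self):
        x = one_factor_data([0.7, 0.8, 0.6, 0.75, 0.65])
        r = np.corrcoef(x, rowvar=False)
        lam, psi = psy.minres_factor(r, 1)

        off = ~np.eye(5, dtype=bool)

        def objective(p):
            reduced = r - np.diag(p)
            vals, vecs = np.linalg.eigh(reduced)
            top = np.argsort(vals)[::-1][:1]
            ll = vecs[:, top] * np.sqrt(np.clip(vals[top], 0, None))
            resid = r - ll @ ll.T
            return np.sum(resid[off] ** 2)

        grad = optimize.approx_fprime(psi, objective, 1e-7)
        assert np.max(np.abs(grad)) < 1e-4

    def test_variance_explained_approaches_mean_communality(self):
        x = one_factor_data([0.8] * 5)
        report = psy.efa_minres(data=x, n_factors=1, method="pearson")
        assert report.variance_explained == pytest.approx(0.64, abs=0.03)


class TestBenjaminiHochberg:
    def test_hand_worked_step_up_examples(self):
        all_pass = psy._bh_reject(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        assert all_pass.all()
        partial = psy._bh_reject(np.array([0.01, 0.02, 0.04, 0.30]), 0.05)
        assert list(partial) == [True, True, False, False]

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        p = rng.uniform(size=50)
        expected = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert np.array_equal(psy._bh_reject(p, 0.05), expected)


class TestSpearmanBH:
    def test_monotone_transform_gives_unit_rho(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=100)
        report = psy.spearman_bh(np.column_stack([x, np.exp(x)]))
        assert report.rho.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero_and_nonsignificant(self):
        rng = np.random.default_rng(15)
        report = psy.spearman_bh(rng.normal(size=(10000, 2)))
        assert abs(report.rho.iloc[0, 1]) < 0.05
        assert not report.significant.iloc[0, 1]

    def test_constant_column_excluded(self):
        rng = np.random.default_rng(16)
        x = np.column_stack([rng.normal(size=50), np.full(50, 3.0), rng.normal(size=50)])
        report = psy.spearman_bh(x)
        assert report.excluded == ("1",)
        assert report.rho.shape == (2, 2)

    def test_adjusted_flags_monotone_in_raw_p(self):
        rng = np.random.default_rng(17)
        base = rng.normal(size=(200, 1))
        x = base + np.array([0.2, 0.8, 1.5, 3.0]) * rng.normal(size=(200, 4))
        report = psy.spearman_bh(x)
        p = report.p_values.to_numpy()[np.triu_indices(4, 1)]
        sig = report.significant.to_numpy()[np.triu_indices(4, 1)]
        # no significant pair may have a larger p-value than a nonsignificant one
        if sig.any() and (~sig).any():
            assert p[sig].max() <= p[~sig].min()
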