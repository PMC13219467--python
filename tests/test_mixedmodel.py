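"""Tests of the restricted likelihood and the AI-REML fit.

Oracles: closed-form balanced one-way REML, derivative-free simplex
maximization of the exposed restricted likelihood, and simulation with
known components.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import forestgs as fgs
from forestgs.mixedmodel import (
    ModelData,
    ModelFit,
    VarianceComponents,
    _default_start,
    _to_raw,
    predict_genetic_values,
    restricted_loglik,
)


class TestRestrictedLoglik:
    def test_balanced_one_way_matches_closed_form(self):
        # maximizing the restricted likelihood of y = mu + u_g + e over
        # (sigma_u^2, sigma_e^2) must land on the classical ANOVA-based
        # REML estimates: sigma_e^2 = MSE, sigma_u^2 = (MSA - MSE) / n
        rng = np.random.default_rng(1)
        a, n = 8, 6
        u = rng.normal(0, np.sqrt(2.0), a)
        y = np.repeat(u, n) + rng.normal(0, 1.0, a * n) + 5.0
        grp = np.repeat(np.arange(a), n)
        Z = np.zeros((a * n, a))
        Z[np.arange(a * n), grp] = 1.0
        X = np.ones((a * n, 1))
        ybar = np.array([y[grp == i].mean() for i in range(a)])
        MSA = n * ((ybar - y.mean()) ** 2).sum() / (a - 1)
        MSE = sum(((y[grp == i] - ybar[i]) ** 2).sum() for i in range(a)) / (
            a * (n - 1)
        )

        def neg(t):
            su, se = np.exp(t)
            return -restricted_loglik(y, X, su * (Z @ Z.T) + se * np.eye(y.size))

        res = minimize(neg, np.log([1.0, 1.0]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        su_hat, se_hat = np.exp(res.x)
        assert se_hat == pytest.approx(MSE, rel=1e-5)
        assert su_hat == pytest.approx((MSA - MSE) / n, rel=1e-5)

    def test_invariant_to_observation_order(self, tiny_trial):
        A = fgs.build_A(tiny_trial.pedigree)
        D = fgs.build_D(tiny_trial.pedigree)
        spec = fgs.ModelSpec(method="ablup")
        data = ModelData(tiny_trial.phenotypes, A, D, spec)
        comp = _default_start(data)
        base = fgs.reml_loglik(comp, data)
        perm = tiny_trial.phenotypes.sample(frac=1.0, random_state=3)
        data_p = ModelData(perm, A, D, spec)
        assert fgs.reml_loglik(comp, data_p) == pytest.approx(base, abs=1e-8)

    def test_floor_variances_reduce_to_fixed_effects_model(self, tiny_trial):
        # with every random variance at the floor the restricted likelihood
        # equals the direct dense evaluation with V = site-diagonal residual
        A = fgs.build_A(tiny_trial.pedigree)
        D = fgs.build_D(tiny_trial.pedigree)
        data = ModelData(tiny_trial.phenotypes, A, D,
                         fgs.ModelSpec(method="ablup"))
        eps = 1e-12
        comp = VarianceComponents(
            block=(eps, eps), additive=(eps, eps), r_a=0.0,
            dominance=(eps, eps), r_d=0.0, residual=(0.7, 1.3),
        )
        got = fgs.reml_loglik(comp, data)
        V = np.diag(np.where(data.site_idx == 0, 0.7, 1.3))
        expected = restricted_loglik(data.y, data.X, V)
        assert got == pytest.approx(expected, abs=1e-6)


class TestRemlFit:
    def test_optimum_matches_simplex_oracle(self, tiny_trial):
        A = fgs.build_A(tiny_trial.pedigree)
        D = fgs.build_D(tiny_trial.pedigree)
        data = ModelData(tiny_trial.phenotypes, A, D,
                         fgs.ModelSpec(method="ablup"))
        fit = fgs.reml_fit(data)
        rng = np.random.default_rng(0)

        def neg(t):
            try:
                return -restricted_loglik(
                    data.y, data.X, data.build_V(_to_raw(data, t))
                )
            except Exception:
                return 1e10

        best = -np.inf
        for _ in range(10):
            res = minimize(neg, rng.normal(0, 1, len(data.param_names)),
                           method="Nelder-Mead",
                           options={"maxiter": 6000, "xatol": 1e-8,
                                    "fatol": 1e-10})
            best = max(best, -res.fun)
        assert fit.loglik >= best - 1e-4

    def test_ablup_equals_gblup_when_g_matrices_are_pedigree(self, tiny_trial):
        A = fgs.build_A(tiny_trial.pedigree)
        D = fgs.build_D(tiny_trial.pedigree)
        fit_a, _ = fgs.fit_model(tiny_trial.phenotypes, A, D,
                                 fgs.ModelSpec(method="ablup"))
        Ga = fgs.RelationshipMatrix(A.values.copy(), list(A.ids), "Ga")
        Gd = fgs.RelationshipMatrix(D.values.copy(), list(D.ids), "Gd")
        fit_g, _ = fgs.fit_model(tiny_trial.phenotypes, Ga, Gd,
                                 fgs.ModelSpec(method="gblup"))
        assert fit_g.loglik == pytest.approx(fit_a.loglik, abs=1e-5)
        for k, v in fit_a.components.as_dict().items():
            assert fit_g.components.as_dict()[k] == pytest.approx(v, abs=1e-3)

    def test_zero_dominance_boundary_is_pinned_and_reported_zero(self):
        # on a null-dominance dataset whose restricted likelihood favors the
        # boundary, both dominance variances must be driven to the floor,
        # flagged as pinned, and reported as exactly 0.00
        arch = fgs.TraitArchitecture(
            additive_var=(0.5, 0.5), r_a=0.9, dominance_var=(0.0, 0.0),
            block_var=(0.05, 0.05), residual_var=(0.45, 0.45),
        )
        trial = fgs.simulate_trial(n_parents=8, n_families=20,
                                   offspring_per_family=24, n_snps=600,
                                   arch=arch, seed=33)
        A = fgs.build_A(trial.pedigree)
        D = fgs.build_D(trial.pedigree)
        fit, _ = fgs.fit_model(trial.phenotypes, A, D,
                               fgs.ModelSpec(method="ablup"))
        assert {"dominance_S1", "dominance_S2"} <= set(fit.pinned)
        reported = fit.reported_components()
        assert reported["dominance_S1"] == 0.0
        assert reported["dominance_S2"] == 0.0

    def test_loglik_non_decreasing_over_accepted_iterations(self, small_fit):
        fit, _ = small_fit
        trace = np.array(fit.trace)
        assert (np.diff(trace) >= -1e-9).all()

    def test_ai_matrix_symmetric(self, small_fit):
        fit, _ = small_fit
        np.testing.assert_allclose(fit.ai_matrix, fit.ai_matrix.T,
                                   atol=1e-8)

    def test_monotone_recovery_of_site_correlation(self):
        # data generated at r_a = 0.2 vs 0.8 must order correctly on average
        est = {0.2: [], 0.8: []}
        for r_a in (0.2, 0.8):
            for rep in range(4):
                arch = fgs.TraitArchitecture(
                    additive_var=(0.5, 0.5), r_a=r_a,
                    dominance_var=(0.05, 0.05), r_d=0.5,
                    block_var=(0.05, 0.05), residual_var=(0.4, 0.4),
                )
                trial = fgs.simulate_trial(
                    n_parents=10, n_families=15, offspring_per_family=16,
                    n_snps=700, arch=arch, seed=1000 + rep,
                )
                A = fgs.build_A(trial.pedigree)
                D = fgs.build_D(trial.pedigree)
                Ga, _ = fgs.blend_and_invert(
                    fgs.build_Ga(trial.genotypes), A, 0.02
                )
                Gd, _ = fgs.blend_and_invert(
                    fgs.build_Gd(trial.genotypes), D, 0.02
                )
                fit, _ = fgs.fit_model(trial.phenotypes, Ga, Gd,
                                       fgs.ModelSpec())
                est[r_a].append(fit.components.r_a)
        assert np.mean(est[0.8]) > np.mean(est[0.2])

    def test_plot_term_model_runs(self):
        arch = fgs.TraitArchitecture(plot_var=(0.1, 0.1))
        trial = fgs.simulate_trial(n_parents=8, n_families=10,
                                   offspring_per_family=12, n_snps=400,
                                   arch=arch, seed=17)
        A = fgs.build_A(trial.pedigree)
        D = fgs.build_D(trial.pedigree)
        fit, data = fgs.fit_model(trial.phenotypes, A, D,
                                  fgs.ModelSpec(method="ablup", use_plot=True))
        assert "plot_S1" in fit.components.as_dict()
        assert fit.converged


class TestSolveBlups:
    def test_classical_shrinkage_of_group_means(self):
        # balanced iid-genotype toy at known variances: the additive BLUP is
        # the group mean shrunk by m*sa2 / (m*sa2 + se2)
        rng = np.random.default_rng(5)
        n_g, m = 12, 4
        sa2, se2 = 0.6, 0.9
        rows = []
        truth = rng.normal(0, np.sqrt(sa2), n_g)
        for i in range(n_g):
            site = "S1" if i < n_g // 2 else "S2"
            for j in range(m):
                rows.append({
                    "genotype": f"g{i}", "family": "F", "site": site,
                    "block": f"B{j}",
                    "y": truth[i] + rng.normal(0, np.sqrt(se2)),
                })
        df = pd.DataFrame(rows)
        ids = [f"g{i}" for i in range(n_g)]
        K = fgs.RelationshipMatrix(np.eye(n_g), ids, "Ga")
        data = ModelData(df, K, K, fgs.ModelSpec())
        eps = 1e-9
        comp = VarianceComponents(
            block=(eps, eps), additive=(sa2, sa2), r_a=0.0,
            dominance=(eps, eps), r_d=0.0, residual=(se2, se2),
        )
        fit = ModelFit(
            components=comp, loglik=0.0, beta=np.zeros(2),
            beta_names=["mean", "site"], converged=True, n_iter=0,
            ai_matrix=np.eye(len(data.param_names)),
            param_names=list(data.param_names),
        )
        values, _ = solve = fgs.solve_blups(fit, data)
        home = values.at_home_site().set_index("genotype")
        shrink = m * sa2 / (m * sa2 + se2)
        for site in ("S1", "S2"):
            sub = df[df["site"] == site]
            site_mean = sub["y"].mean()
            for g, grp in sub.groupby("genotype"):
                expected = shrink * (grp["y"].mean() - site_mean)
                assert home.loc[g, "ebv"] == pytest.approx(expected, abs=0.02)

    def test_egv_identity_and_floor_additive(self, small_fit):
        fit, data = small_fit
        values, _ = fgs.solve_blups(fit, data, force=True)
        t = values.table
        np.testing.assert_allclose(t["egv"], t["ebv"] + t["edv"], atol=1e-12)

    def test_floor_additive_shrinks_ebv_to_zero(self, tiny_trial):
        A = fgs.build_A(tiny_trial.pedigree)
        D = fgs.build_D(tiny_trial.pedigree)
        data = ModelData(tiny_trial.phenotypes, A, D,
                         fgs.ModelSpec(method="ablup"))
        eps = 1e-10
        comp = VarianceComponents(
            block=(0.1, 0.1), additive=(eps, eps), r_a=0.0,
            dominance=(0.1, 0.1), r_d=0.5, residual=(0.5, 0.5),
        )
        fit = ModelFit(
            components=comp, loglik=0.0, beta=np.zeros(2),
            beta_names=["mean", "site"], converged=True, n_iter=0,
            ai_matrix=np.eye(len(data.param_names)),
            param_names=list(data.param_names),
        )
        values, _ = fgs.solve_blups(fit, data)
        assert np.abs(values.table["ebv"]).max() < 1e-6

    def test_predict_matches_solve_for_training_genotypes(self, small_fit):
        fit, data = small_fit
        values, _ = fgs.solve_blups(fit, data, force=True)
        some = data.genotype_ids[:5]
        pred = predict_genetic_values(fit, data, some)
        vt = values.table.set_index(["genotype", "site"])
        pt = pred.set_index(["genotype", "site"])
        for g in some:
            for s in data.sites:
                assert pt.loc[(g, s), "ebv"] == pytest.approx(
                    vt.loc[(g, s), "ebv"], abs=1e-10
                )
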