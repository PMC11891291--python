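"""EM-REML engine tests: closed-form oracles, direct-likelihood
equivalence, BLUP identities and the model-suite runner."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, optimize, stats

from germtherm.config import SimulationConfig
from germtherm.lmm import (
    GBLUPModel,
    build_design,
    extract_gblups,
    fit_model_suite,
    heritability,
    tukey_hsd,
    wald_z_test,
)
from germtherm.relatedness import compute_grm
from germtherm.simulate import simulate_cohort


def direct_reml_loglik(theta, y, X, Z, G):
    """Closed-form REML log-likelihood from the dense V matrix (oracle,
    independent of the MME route)."""
    sg2, se2 = theta
    n, p = X.shape
    V = se2 * np.eye(n) + sg2 * Z @ G @ Z.T
    Vinv = linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = linalg.solve(XtVinvX, X.T @ Vinv @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtVinvX)
    return -0.5 * (ldV + ldX + r @ Vinv @ r + (n - p) * np.log(2 * np.pi))


def small_instance(seed=0, q=6, n=30, p=2):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(q, q + 4))
    G = A @ A.T / (q + 4)
    G = G / np.diag(G).mean()
    idx = rng.integers(0, q, size=n)
    Z = np.zeros((n, q))
    Z[np.arange(n), idx] = 1.0
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    g = np.linalg.cholesky(G + 1e-8 * np.eye(q)) @ rng.normal(size=q)
    y = X @ rng.normal(size=p) + 1.5 * g[idx] + rng.normal(size=n)
    return y, X, idx, Z, G


class TestEmReml:
    def test_balanced_one_way_matches_anova_reml(self):
        """y=(1,2,3,4) in two accessions of two seeds, G=I: closed-form
        REML gives sigma2_e = MSW = 0.5, sigma2_g = (MSB-MSW)/2 = 1.75."""
        fit = GBLUPModel(
            np.array([1.0, 2.0, 3.0, 4.0]), np.ones((4, 1)),
            np.array([0, 0, 1, 1]), np.eye(2), xnames=["intercept"],
        ).fit(tol=1e-14, max_iter=20000)
        assert fit.sigma2_e == pytest.approx(0.5, abs=1e-6)
        assert fit.sigma2_g == pytest.approx(1.75, abs=1e-6)
        assert fit.converged

    def test_loglik_trace_non_decreasing(self):
        y, X, idx, Z, G = small_instance(1)
        fit = GBLUPModel(y, X, idx, G).fit()
        diffs = np.diff(fit.loglik_trace)
        assert (diffs > -1e-8).all()

    def test_exact_fixed_effect_data_pins_residual_at_floor(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = X @ np.array([2.0, -1.0])
        fit = GBLUPModel(y, X, rng.integers(0, 5, 40), np.eye(5)).fit()
        assert fit.sigma2_e <= 1e-6
        assert fit.boundary
        assert np.abs(fit.gblups.to_numpy()).max() < 1e-4

    def test_em_fixed_point_maximizes_direct_reml_criterion(self):
        """On small instances the EM fixed point matches a direct numerical
        maximization of the closed-form REML log-likelihood."""
        for seed in (3, 4):
            y, X, idx, Z, G = small_instance(seed)
            fit = GBLUPModel(y, X, idx, G).fit(tol=1e-12, max_iter=10000)
            res = optimize.minimize(
                lambda t: -direct_reml_loglik(np.exp(t), y, X, Z, G),
                x0=np.log([1.0, 1.0]), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
            )
            assert fit.llf == pytest.approx(-res.fun, abs=1e-4)
            assert direct_reml_loglik([fit.sigma2_g, fit.sigma2_e], y, X, Z, G) \
                == pytest.approx(-res.fun, abs=1e-4)

    def test_gblups_match_direct_formula(self):
        """ghat = sigma2_g G Z' V^{-1} (y - X beta_gls) at the converged
        variance components (5 accessions)."""
        y, X, idx, Z, G = small_instance(7, q=5, n=25)
        fit = GBLUPModel(y, X, idx, G).fit(tol=1e-12, max_iter=10000)
        sg2, se2 = fit.sigma2_g, fit.sigma2_e
        V = se2 * np.eye(len(y)) + sg2 * Z @ G @ Z.T
        Vinv = linalg.inv(V)
        beta = linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        ghat = sg2 * G @ Z.T @ Vinv @ (y - X @ beta)
        assert np.allclose(fit.gblups.to_numpy(), ghat, atol=1e-8)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_duplicate_accessions_get_equal_gblups(self):
        rng = np.random.default_rng(8)
        G = np.array(
            [[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]]
        )
        y = np.array([1.0, 2.0, 1.0, 2.0, 5.0, 6.0])
        idx = np.array([0, 0, 1, 1, 2, 2])
        fit = GBLUPModel(y, np.ones((6, 1)), idx, G).fit()
        g = fit.gblups.to_numpy()
        assert g[0] == pytest.approx(g[1], abs=1e-6)

    def test_unphenotyped_accession_predicted_through_g(self):
        y, X, idx, Z, G = small_instance(9, q=6, n=30)
        idx = np.where(idx == 5, 0, idx)          # accession 5 has no data
        fit = GBLUPModel(y, X, idx, G).fit()
        assert fit.gblups.size == 6
        assert np.isfinite(fit.gblups.iloc[5])
        assert fit.n_accessions == 5

    def test_gblup_shrinkage_bound(self):
        y, X, idx, Z, G = small_instance(10)
        fit = GBLUPModel(y, X, idx, G).fit()
        assert fit.gblups.var() <= fit.sigma2_g * np.diag(fit.model.G).max() + 1e-9


class TestInference:
    def test_heritability_values(self):
        y, X, idx, Z, G = small_instance(11)
        fit = GBLUPModel(y, X, idx, G).fit()
        fit.sigma2_g, fit.sigma2_e = 1.0, 3.0
        fit.h2 = fit.sigma2_g / (fit.sigma2_g + fit.sigma2_e)
        assert heritability(fit) == pytest.approx(0.25)
        assert 0.0 <= fit.h2 <= 1.0

    def test_wald_z_normal_reference(self):
        y, X, idx, Z, G = small_instance(12)
        fit = GBLUPModel(y, X, idx, G, xnames=["intercept", "slope"]).fit()
        fit.params[:] = [1.96, 0.0]
        fit.bse[:] = [1.0, 1.0]
        z, p = wald_z_test(fit, "intercept")
        assert p == pytest.approx(2 * stats.norm.sf(1.96), abs=1e-12)
        z0, p0 = wald_z_test(fit, "slope")
        assert z0 == 0.0 and p0 == 1.0
        with pytest.raises(KeyError):
            wald_z_test(fit, "absent_term")

    def test_z_sign_flips_with_reference_level(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            {
                "accession": [f"a{i}" for i in range(20)] * 4,
                "type": (["wild"] * 10 + ["landrace"] * 10) * 4,
                "y": rng.normal(size=80),
            }
        )
        df.loc[df["type"] == "wild", "y"] += 1.0
        G = np.eye(20)
        ids = [f"a{i}" for i in range(20)]

        def z_for(frame, level):
            m = GBLUPModel.from_dataframe(frame, "y", ("type",), (ids, G))
            f = m.fit()
            return f.wald_z(f"type[{level}]")[0]

        z1 = z_for(df, "wild")                     # reference = landrace
        df2 = df.replace({"type": {"landrace": "zlandrace"}})
        z2 = z_for(df2, "zlandrace")               # reference = wild
        assert z1 == pytest.approx(-z2, rel=1e-6)

    def test_tukey_q_identity_with_t_for_two_levels(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(
            {
                "accession": [f"a{i % 12}" for i in range(96)],
                "type": ["wild", "landrace"] * 48,
                "y": rng.normal(size=96),
            }
        )
        ids = sorted(df["accession"].unique())
        fit = GBLUPModel.from_dataframe(df, "y", ("type",), (ids, np.eye(12))).fit()
        tk = tukey_hsd(fit, "type")
        assert len(tk) == 1
        row = tk.iloc[0]
        # q = sqrt(2) |t| and the k=2 studentized-range p equals the
        # two-sided t p-value on the same contrast
        t = abs(row["difference"] / row["se_diff"])
        assert row["q"] == pytest.approx(np.sqrt(2) * t, rel=1e-9)
        df_resid = fit.n_obs - len(fit.params)
        p_t = 2 * stats.t.sf(t, df_resid)
        assert row["p"] == pytest.approx(p_t, rel=1e-6)

    def test_tukey_zero_difference_p_one(self):
        # level means equal by construction -> difference 0, q = 0, p = 1
        y = np.array([1.0, 1.1, 2.0, 1.9])
        df = pd.DataFrame(
            {"accession": ["a", "a", "b", "b"], "type": ["w", "l", "w", "l"], "y": y}
        )
        fit = GBLUPModel.from_dataframe(df, "y", ("type",), (["a", "b"], np.eye(2))).fit()
        tk = tukey_hsd(fit, "type")
        assert tk.iloc[0]["p"] == pytest.approx(1.0, abs=1e-9)

    def test_tukey_single_level_errors(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(
            {"accession": list("abcd") * 3, "type": ["wild"] * 12,
             "y": rng.normal(size=12)}
        )
        fit = GBLUPModel.from_dataframe(
            df, "y", (), (list("abcd"), np.eye(4))
        ).fit()
        with pytest.raises(KeyError):
            fit.tukey_hsd("type")


class TestDesign:
    def test_aliased_and_constant_columns_dropped(self):
        df = pd.DataFrame(
            {
                "temperature": ["cold"] * 6,
                "type": ["wild", "landrace"] * 3,
                "conservation_days": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            }
        )
        X, names, meta = build_design(df, ("temperature", "type", "conservation"))
        assert "temperature[cold]" not in names     # constant in subset
        assert any(n.startswith("type[") for n in names)
        dup = df.assign(copy_days=df["conservation_days"])
        X2, names2, meta2 = build_design(dup, ("conservation", "conservation"))
        assert len(meta2["dropped_aliased"]) == 1

    def test_temperature_by_country_gives_one_slope_per_country(self):
        df = pd.DataFrame(
            {
                "temperature": ["cold", "warm"] * 6,
                "country": ["France"] * 4 + ["Italy"] * 4 + ["Spain"] * 4,
            }
        )
        X, names, meta = build_design(df, ("temperature:country",))
        slopes = [n for n in names if n.startswith("temperature[warm]:country[")]
        assert len(slopes) == 3


@pytest.fixture(scope="module")
def cohort_and_grm():
    cfg = SimulationConfig(n_accessions=40, n_snps=200, seeds_per_cell=10,
                           ge_correlation=1.0, latitude_slope=0.0, rng_seed=31)
    cohort = simulate_cohort(cfg)
    return cohort, compute_grm(cohort.genotypes)


class TestSuites:
    def test_suite_1c_returns_four_fits(self, cohort_and_grm):
        cohort, rel = cohort_and_grm
        fits = fit_model_suite(cohort.phenotypes, rel, "GT", "1c")
        assert len(fits) == 4
        assert {k.split(":")[1] for k in fits} == {"cold", "warm"}

    def test_suite_3d_has_one_slope_per_country(self, cohort_and_grm):
        cohort, rel = cohort_and_grm
        phen = cohort.phenotypes.assign(
            gra=np.random.default_rng(0).normal(size=len(cohort.phenotypes))
        )
        fits = fit_model_suite(phen, rel, "GRA", "3d")
        names = fits["all"].params.index
        n_countries = phen["country"].nunique()
        slopes = [n for n in names if ":country[" in n]
        assert len(slopes) == n_countries

    def test_no_gxe_cohort_gives_consistent_rankings(self):
        """At genetic correlation 1 and high gBLUP reliability (many seeds,
        small residual noise), cold and warm gBLUPs from the split fits
        rank accessions nearly identically."""
        from germtherm.config import FixedEffects

        cfg = SimulationConfig(
            n_accessions=40, n_snps=200, seeds_per_cell=25, sigma2_e=10.0,
            ge_correlation=1.0, latitude_slope=0.0, rng_seed=37,
            fixed_effects=FixedEffects(gr_type_wild=-0.5),
        )
        cohort = simulate_cohort(cfg)
        rel = compute_grm(cohort.genotypes)
        fits = fit_model_suite(cohort.phenotypes, rel, "GT", "1c")
        for t in ("wild", "landrace"):
            cold = fits[f"{t}:cold"].gblups
            warm = fits[f"{t}:warm"].gblups
            rho = stats.spearmanr(cold, warm).statistic
            assert rho > 0.95

    def test_gra_suite_1_redirected_to_3(self, cohort_and_grm, caplog):
        cohort, rel = cohort_and_grm
        phen = cohort.phenotypes.assign(gra=0.0)
        phen["gra"] = np.random.default_rng(1).normal(size=len(phen))
        fits = fit_model_suite(phen, rel, "GRA", "1b")
        assert set(fits) == {"wild", "landrace"}

    def test_unknown_suite_rejected(self, cohort_and_grm):
        cohort, rel = cohort_and_grm
        with pytest.raises(ValueError):
            fit_model_suite(cohort.phenotypes, rel, "GT", "2x")
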