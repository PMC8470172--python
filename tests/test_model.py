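import numpy as np
import pandas as pd
import pytest

from rrgwas.basis import LegendreBasis, design_matrix
from rrgwas.model import (
    IdentifiabilityError,
    ModelSpec,
    RandomRegressionModel,
    VarianceComponents,
    build_design,
    select_orders,
    solve_mme,
)
from rrgwas.pedigree import RelationshipMatrix, build_A
from rrgwas.simulate import (
    SimConfig,
    default_variance_components,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_study,
)


def dense_gls_blup(sys, A, vc):
    """Independent oracle: GLS fixed effects and BLUPs from the explicit
    phenotypic covariance V = Z1 (A (x) D) Z1' + Z2 (I (x) P) Z2' + I s2e."""
    n_pe = len(sys.pheno_ids)
    G1 = np.kron(A, vc.D)
    G2 = np.kron(np.eye(n_pe), vc.P)
    V = sys.Z1 @ G1 @ sys.Z1.T + sys.Z2 @ G2 @ sys.Z2.T + vc.sigma2_e * np.eye(sys.n_records)
    X = sys.X
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ sys.y)
    resid = sys.y - X @ beta
    a_hat = G1 @ sys.Z1.T @ Vi @ resid
    p_hat = G2 @ sys.Z2.T @ Vi @ resid
    return beta, a_hat, p_hat


def dense_logRL(sys, A, vc):
    n_pe = len(sys.pheno_ids)
    V = (
        sys.Z1 @ np.kron(A, vc.D) @ sys.Z1.T
        + sys.Z2 @ np.kron(np.eye(n_pe), vc.P) @ sys.Z2.T
        + vc.sigma2_e * np.eye(sys.n_records)
    )
    X = sys.X
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ sys.y)
    r = sys.y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + r @ Vi @ sys.y
    )


def _random_instance(seed, n_founders=8, drop=0):
    cfg = SimConfig(seed=seed, n_founders=n_founders, n_generations=1, n_snps=2)
    sim = simulate_study(cfg)
    pheno = sim.phenotypes
    if drop:
        rng = np.random.default_rng(seed)
        pheno = pheno.drop(index=rng.choice(len(pheno), size=drop, replace=False))
        pheno = pheno.reset_index(drop=True)
    return sim, pheno


class TestBuildDesign:
    def test_z1_rows_are_basis_rows(self):
        pheno = pd.DataFrame({"id": ["a", "a"], "age_months": [0.0, 18.0], "weight": [1.0, 2.0]})
        spec = ModelSpec(order_fixed=1, order_additive=1, order_pe=1)
        sys = build_design(pheno, spec)
        b = LegendreBasis(order=1, t_min=0, t_max=18)
        np.testing.assert_allclose(sys.Z1, design_matrix(np.array([0.0, 18.0]), b))

    def test_no_factors_still_solvable(self):
        pheno = pd.DataFrame(
            {"id": ["a", "a", "b", "b"], "age_months": [0, 18, 0, 18], "weight": [1.0, 2, 3, 4]}
        )
        sys = build_design(pheno, ModelSpec(order_fixed=1, order_additive=0, order_pe=0))
        assert sys.X1.shape[1] == 0
        vc = VarianceComponents(D=[[1.0]], P=[[1.0]], sigma2_e=1.0)
        sol = solve_mme(sys, np.eye(2), vc)
        assert np.isfinite(sol.fitted).all()

    def test_confounded_factors_rejected(self):
        pheno = pd.DataFrame(
            {
                "id": ["a", "a", "b", "b"],
                "age_months": [0, 18, 0, 18],
                "weight": [1.0, 2, 3, 4],
                "farm": ["x", "x", "y", "y"],
                "herd": ["u", "u", "v", "v"],  # identical partition as farm
            }
        )
        with pytest.raises(IdentifiabilityError, match="confounded"):
            build_design(pheno, ModelSpec(order_fixed=1, order_additive=0, order_pe=0,
                                          factors=("farm", "herd")))

    def test_order_cap_enforced(self):
        pheno = pd.DataFrame(
            {"id": ["a", "a"], "age_months": [0, 18], "weight": [1.0, 2.0]}
        )
        with pytest.raises(IdentifiabilityError, match="distinct ages"):
            build_design(pheno, ModelSpec(order_fixed=3, order_additive=0, order_pe=0))


class TestSolveMme:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_gls_blup_oracle(self, seed):
        """Henderson MME solutions equal explicit-V GLS/BLUP to 1e-6."""
        sim, pheno = _random_instance(seed, drop=3 if seed % 2 else 0)
        A = build_A(sim.pedigree)
        vc = VarianceComponents(
            D=np.array([[200.0, 50.0], [50.0, 80.0]]),
            P=np.array([[100.0, 20.0], [20.0, 60.0]]),
            sigma2_e=120.0,
        )
        sys = build_design(pheno, ModelSpec(order_fixed=2, order_additive=1, order_pe=1),
                           ped_ids=A.ids)
        sol = solve_mme(sys, np.linalg.inv(A.values), vc)
        beta, a_hat, p_hat = dense_gls_blup(sys, A.values, vc)
        got = np.concatenate([sol.fixed_regression, sol.additive.ravel(), sol.permanent_env.ravel()])
        want = np.concatenate([beta, a_hat, p_hat])
        np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-6 * np.abs(want).max())

    def test_interpolation_limit_small_residual(self):
        """With sigma2_e -> 0 and saturated PE curves the fit reproduces y."""
        sim, pheno = _random_instance(3)
        A = build_A(sim.pedigree)
        sys = build_design(pheno, ModelSpec(order_fixed=1, order_additive=0, order_pe=3),
                           ped_ids=A.ids)
        vc = VarianceComponents(D=np.eye(1) * 100, P=np.eye(4) * 1e4, sigma2_e=1e-6)
        sol = solve_mme(sys, np.linalg.inv(A.values), vc)
        np.testing.assert_allclose(sol.fitted, sys.y, atol=1e-2)

    def test_vanishing_shrinkage_matches_least_squares(self):
        """Single unrelated individual, huge D: a_hat -> per-individual OLS."""
        ages = np.array([0.0, 6.0, 12.0, 18.0])
        rng = np.random.default_rng(0)
        y = 3.0 + 2.0 * ages + rng.normal(0, 0.1, 4)
        pheno = pd.DataFrame({"id": "a", "age_months": ages, "weight": y})
        sys = build_design(pheno, ModelSpec(order_fixed=0, order_additive=1, order_pe=0))
        vc = VarianceComponents(D=np.eye(2) * 1e8, P=np.eye(1) * 1e-8, sigma2_e=1.0)
        sol = solve_mme(sys, np.eye(1), vc)
        b = LegendreBasis(order=1, t_min=0, t_max=18)
        phi = design_matrix(ages, b)
        X_full = np.column_stack([np.full(4, np.sqrt(0.5)), phi])
        coef, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        fitted_ols = X_full @ coef
        np.testing.assert_allclose(sol.fitted, fitted_ols, atol=1e-3)


class TestReml:
    def test_restricted_loglike_matches_dense_oracle_balanced(self):
        sim, pheno = _random_instance(5)
        model = RandomRegressionModel(pheno, sim.pedigree, order_fixed=2,
                                      order_additive=1, order_pe=1)
        assert len(model._blocks.ys) > 1  # balanced fast path in use
        vc = default_variance_components()
        assert model.loglike_restricted(vc) == pytest.approx(
            dense_logRL(model.sys, model.A_sub, vc), abs=1e-8
        )

    def test_restricted_loglike_matches_dense_oracle_unbalanced(self):
        sim, pheno = _random_instance(5, drop=4)
        model = RandomRegressionModel(pheno, sim.pedigree, order_fixed=2,
                                      order_additive=1, order_pe=1)
        assert len(model._blocks.ys) == 1  # single dense block
        vc = default_variance_components()
        assert model.loglike_restricted(vc) == pytest.approx(
            dense_logRL(model.sys, model.A_sub, vc), abs=1e-8
        )

    def test_monotone_ascent(self, fitted_sim):
        res = fitted_sim["results"]
        traj = res.trajectory
        assert traj[-1] >= traj[0]
        assert res.loglike == pytest.approx(max(traj), abs=1e-6)

    def test_record_order_invariance(self):
        sim, pheno = _random_instance(9, n_founders=12)
        res1 = RandomRegressionModel(pheno, sim.pedigree, order_fixed=2,
                                     order_additive=1, order_pe=1).fit()
        shuffled = pheno.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = RandomRegressionModel(shuffled, sim.pedigree, order_fixed=2,
                                     order_additive=1, order_pe=1).fit()
        np.testing.assert_allclose(res1.vc.D, res2.vc.D, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(res1.vc.sigma2_e, res2.vc.sigma2_e, rtol=1e-4)

    def test_intercept_only_recovery(self):
        """Simulated intercept-only random effects: the estimates averaged
        over 20 seeds land within 15% of truth at n = 402 x 4 ages."""
        true = VarianceComponents(D=[[400.0]], P=[[250.0]], sigma2_e=150.0)
        est = {"D": [], "P": [], "e": []}
        for seed in range(20):
            cfg = SimConfig(seed=300 + seed, n_founders=134, n_generations=2,
                            n_snps=2, true_vc=true)
            sim = simulate_study(cfg)
            res = RandomRegressionModel(sim.phenotypes, sim.pedigree, order_fixed=3,
                                        order_additive=0, order_pe=0).fit()
            est["D"].append(res.vc.D[0, 0])
            est["P"].append(res.vc.P[0, 0])
            est["e"].append(res.vc.sigma2_e)
        assert abs(np.mean(est["e"]) - 150) / 150 < 0.15
        assert abs(np.mean(est["D"]) - 400) / 400 < 0.15
        assert abs(np.mean(est["P"]) - 250) / 250 < 0.15

    def test_no_false_heritability_on_noise(self):
        """Pure-noise phenotypes with A = I give near-zero genetic share."""
        rng = np.random.default_rng(11)
        h2 = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 150
            ids = np.repeat([f"i{k}" for k in range(n)], 4)
            ages = np.tile([0.0, 6.0, 12.0, 18.0], n)
            pheno = pd.DataFrame(
                {"id": ids, "age_months": ages, "weight": rng.normal(100, 10, 4 * n)}
            )
            res = RandomRegressionModel(pheno, None, order_fixed=1,
                                        order_additive=0, order_pe=0).fit()
            h2.append(res.heritability(np.array([9.0]))[0])
        assert np.median(h2) < 0.1

    def test_single_age_collapses_to_animal_model(self):
        """One record per individual at one age: total variance is recovered
        even though its split is not identified."""
        rng = np.random.default_rng(4)
        n = 300
        pheno = pd.DataFrame(
            {"id": [f"i{k}" for k in range(n)], "age_months": 12.0,
             "weight": rng.normal(50, 4, n)}
        )
        model = RandomRegressionModel(pheno, None, order_fixed=0,
                                      order_additive=0, order_pe=0)
        res = model.fit()
        total = 0.5 * res.vc.D[0, 0] + 0.5 * res.vc.P[0, 0] + res.vc.sigma2_e
        assert total == pytest.approx(np.var(pheno["weight"], ddof=1), rel=0.05)


class TestSelectOrders:
    def test_single_candidate_returned(self):
        sim, pheno = _random_instance(2, n_founders=12)
        best, table = select_orders(pheno, sim.pedigree, [(2, 1, 1)])
        assert len(table) == 1
        assert (best.spec.order_fixed, best.spec.order_additive, best.spec.order_pe) == (2, 1, 1)

    def test_nesting_never_decreases_loglike(self):
        sim, pheno = _random_instance(6, n_founders=20)
        _, table = select_orders(pheno, sim.pedigree, [(1, 1, 1), (2, 1, 1), (3, 1, 1)])
        ll = table.sort_values("order_fixed")["loglike"].to_numpy()
        assert np.all(np.diff(ll) > -1e-4)

    def test_bic_prefers_generating_order(self):
        """Data generated with linear (order-1) genetic curves: BIC picks
        order_additive = 1 over {0, 1} in most seeds."""
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = SimConfig(seed=700 + seed, n_founders=100, n_generations=2, n_snps=2)
            sim = simulate_study(cfg)
            best, _ = select_orders(sim.phenotypes, sim.pedigree,
                                    [(3, 0, 1), (3, 1, 1)])
            wins += best.spec.order_additive == 1
        assert wins >= int(0.8 * n_seeds)


def test_summary_contains_key_quantities(fitted_sim):
    text = fitted_sim["results"].summary()
    for token in ("logRL", "AIC", "BIC", "sigma2_e", "h2(t)", "mean curve"):
        assert token in text


def test_heritability_between_zero_and_one(fitted_sim):
    h2 = fitted_sim["results"].heritability(np.array([0.0, 6.0, 12.0, 18.0]))
    assert np.all((h2 >= 0) & (h2 <= 1))
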