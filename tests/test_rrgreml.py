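"""Random-regression REML: design construction, likelihood correctness
against a direct dense oracle, monotone convergence, BLUPs, projections
and heritability curves."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from bovrr import relmat, rrgreml as rr, simdata
from bovrr.basis import basis_at_age, legendre_basis


def toy_records(n_animals, ages, seed=0, trait="CW"):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_animals):
        for age in ages:
            rows.append(
                dict(cow_id=f"a{i}", trait=trait, value_kg=rng.normal(500, 30),
                     age_yr=age, opp_group=f"g{i % 2}", cum_calf_sex=0)
            )
    return pd.DataFrame(rows), np.array([f"a{i}" for i in range(n_animals)])


class TestBasis:
    def test_normalized_legendre_values(self):
        phi = legendre_basis(np.array([-1.0, 0.0, 1.0]), order=1)
        c0, c1 = np.sqrt(0.5), np.sqrt(1.5)
        np.testing.assert_allclose(
            phi, [[c0, -c1], [c0, 0.0], [c0, c1]], atol=1e-12
        )

    def test_age_standardization_boundaries(self):
        phi = basis_at_age(8.0, 2.0, 8.0, 1)[0]
        np.testing.assert_allclose(phi, legendre_basis([1.0], 1)[0])

    def test_age_outside_bounds_raises(self):
        with pytest.raises(ValueError):
            basis_at_age(9.0, 2.0, 8.0, 1)


class TestBuildDesign:
    def test_order_zero_is_scaled_incidence(self):
        recs, ids = toy_records(3, [2.0, 5.0])
        d = rr.build_design(recs, rr.ModelSpec(order=0), ids)
        Z = d.Z().toarray()
        assert Z.shape == (6, 3)
        nz = Z[Z != 0]
        np.testing.assert_allclose(nz, np.sqrt(0.5))

    def test_two_record_cow_rows_are_boundary_bases(self):
        recs, ids = toy_records(1, [2.0, 8.0])
        d = rr.build_design(recs, rr.ModelSpec(order=1), ids)
        np.testing.assert_allclose(d.Phi[0], legendre_basis([-1.0], 1)[0])
        np.testing.assert_allclose(d.Phi[1], legendre_basis([1.0], 1)[0])

    def test_full_rank_after_dropping_redundant_levels(self, small_records, small_herd):
        spec = rr.ModelSpec(trait="CW", order=1)
        ids = small_herd["genotypes"].animal_ids
        d = rr.build_design(small_records, spec, ids)
        assert np.linalg.matrix_rank(d.X) == d.X.shape[1]

    def test_missing_cow_raises(self):
        recs, ids = toy_records(3, [2.0])
        with pytest.raises(ValueError, match="missing"):
            rr.build_design(recs, rr.ModelSpec(), ids[:2])


def direct_restricted_loglik(y, X, V):
    """Closed-form REML log-likelihood, computed densely (oracle)."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    sld = np.linalg.slogdet
    return -0.5 * (
        sld(V)[1] + sld(XtViX)[1] + y @ P @ y
        + (len(y) - X.shape[1]) * np.log(2 * np.pi)
    )


class TestRemlOracle:
    def test_tiny_additive_instance_matches_numeric_maximization(self):
        """n=30 cows, intercept-only additive model: the optimizer's logL
        equals brute-force maximization of the closed-form restricted
        likelihood to 1e-4."""
        herd = simdata.simulate_herd(
            30, 120, ratio_a8=0.4, ratio_d8=0.0, seed=21,
            n_chromosomes=2, chrom_length=20_000_000, n_founders_per_breed=8,
        )
        from bovrr import records as recmod

        recs = recmod.build_records(herd["events"])
        G, _, _ = relmat.additive_grm(herd["genotypes"])
        spec = rr.ModelSpec(trait="CW", order=0, include_dominance=False, tol=1e-9)
        designs = rr.build_design(recs, spec, herd["genotypes"].animal_ids)
        fit = rr.reml_fit(designs, G, spec=spec)

        Z = designs.Z().toarray()
        c0 = 0.5  # phi_0^2: constant-basis scaling absorbed into ZGZ'
        ZGZt = Z @ G @ Z.T / c0 * c0  # explicit for clarity
        ZGZt = Z @ np.kron(np.ones((1, 1)), G) @ Z.T

        def neg_ll(theta):
            sa, se = np.exp(theta)
            V = sa * ZGZt + se * np.eye(len(designs.y))
            return -direct_restricted_loglik(designs.y, designs.X, V)

        x0 = np.log([np.var(designs.y) / 2, np.var(designs.y) / 2])
        res = scipy.optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                      options={"xatol": 1e-8, "fatol": 1e-10})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)

    def test_mme_loglik_equals_direct_formula(self):
        recs, ids = toy_records(10, [2.0, 4.0, 6.0, 8.0], seed=5)
        rng = np.random.default_rng(2)
        A = rng.standard_normal((10, 10))
        G = A @ A.T / 10 + np.eye(10) * 0.3
        spec = rr.ModelSpec(order=1, include_dominance=False)
        designs = rr.build_design(recs, spec, ids)
        fac = rr._Factor("G", G, 10, 2)
        K = np.array([[120.0, 30.0], [30.0, 60.0]])
        fac.set_K(K, 0.0)
        mme = rr._MME(designs, [fac])
        ll, _, _ = mme.loglik_and_factor(700.0)
        Z = designs.Z().toarray()
        V = Z @ np.kron(K, G) @ Z.T + 700.0 * np.eye(len(designs.y))
        assert ll == pytest.approx(
            direct_restricted_loglik(designs.y, designs.X, V), abs=1e-8
        )


@pytest.fixture(scope="module")
def herd_fit(small_herd, small_records, small_grms):
    spec = rr.ModelSpec(trait="CW", order=1, tol=1e-4, max_iter=60)
    designs = rr.build_design(
        small_records, spec, small_herd["genotypes"].animal_ids
    )
    fit = rr.reml_fit(designs, small_grms["G"], small_grms["D"], spec=spec)
    return fit, designs


class TestRemlFit:
    def test_loglik_monotone_over_iterations(self, herd_fit):
        fit, _ = herd_fit
        tr = np.array(fit.loglik_trace)
        assert np.all(np.diff(tr) >= -1e-6 * np.abs(tr[:-1]))

    def test_components_positive_and_psd(self, herd_fit):
        fit, _ = herd_fit
        assert fit.sigma2_e > 0
        for K in (fit.K_a, fit.K_d):
            assert np.min(np.linalg.eigvalsh(K)) >= -1e-8 * np.trace(K)

    def test_scaling_equivariance(self, small_herd, small_records, small_grms):
        """y -> c*y scales variance components by c^2, leaves h^2 alone."""
        spec = rr.ModelSpec(trait="CW", order=1, tol=1e-5, max_iter=60)
        ids = small_herd["genotypes"].animal_ids
        d1 = rr.build_design(small_records, spec, ids)
        fit1 = rr.reml_fit(d1, small_grms["G"], small_grms["D"], spec=spec)
        scaled = small_records.copy()
        scaled.loc[scaled["trait"] == "CW", "value_kg"] *= 3.0
        d2 = rr.build_design(scaled, spec, ids)
        fit2 = rr.reml_fit(d2, small_grms["G"], small_grms["D"], spec=spec)
        assert fit2.sigma2_e == pytest.approx(9.0 * fit1.sigma2_e, rel=0.02)
        np.testing.assert_allclose(fit2.K_a, 9.0 * fit1.K_a, rtol=0.05, atol=1e-4)
        h1 = rr.heritability_curve(fit1, [8.0]).iloc[0]
        h2 = rr.heritability_curve(fit2, [8.0]).iloc[0]
        assert h2["h2_a"] == pytest.approx(h1["h2_a"], abs=0.01)


class TestBlup:
    def test_constant_y_gives_zero_blups(self):
        recs, ids = toy_records(8, [2.0, 5.0, 8.0], seed=3)
        recs["value_kg"] = 500.0
        rng = np.random.default_rng(4)
        A = rng.standard_normal((8, 8))
        G = A @ A.T / 8 + np.eye(8) * 0.3
        spec = rr.ModelSpec(order=1, include_dominance=False)
        designs = rr.build_design(recs, spec, ids)
        fit = rr.RRFit(
            spec=spec, animal_ids=ids, K_a=np.eye(2) * 50.0, K_d=None,
            K_pe=None, sigma2_e=400.0, loglik=0.0,
        )
        out = rr.blup_effects(fit, designs, G)
        np.testing.assert_allclose(out["a"], 0.0, atol=1e-8)

    def test_blup_accuracy_increases_with_herd_size(self):
        cors = []
        for n in (100, 400):
            herd = simdata.simulate_herd(
                n, 500, ratio_a8=0.5, ratio_d8=0.0, seed=31,
                n_chromosomes=3, chrom_length=30_000_000,
            )
            from bovrr import records as recmod

            recs = recmod.build_records(herd["events"])
            G, _, _ = relmat.additive_grm(herd["genotypes"])
            spec = rr.ModelSpec(trait="CW", order=1, include_dominance=False,
                                tol=1e-3, max_iter=40)
            designs = rr.build_design(recs, spec, herd["genotypes"].animal_ids)
            fit = rr.reml_fit(designs, G, spec=spec)
            proj = rr.project_to_age(fit.coef_a, None, spec, age=8.0,
                                     animal_ids=herd["genotypes"].animal_ids)
            truth = herd["truth"].set_index("animal_id")
            merged = proj.set_index("animal_id").join(truth["a8"])
            cors.append(np.corrcoef(merged["u_a"], merged["a8"])[0, 1])
        assert cors[0] > 0
        assert cors[1] > cors[0]

    def test_additive_intercepts_sum_near_zero(self, small_herd, small_records, small_grms):
        spec = rr.ModelSpec(trait="CW", order=1, tol=1e-3, max_iter=40)
        designs = rr.build_design(
            small_records, spec, small_herd["genotypes"].animal_ids
        )
        fit = rr.reml_fit(designs, small_grms["G"], small_grms["D"], spec=spec)
        intercepts = fit.coef_a[:, 0]
        assert abs(intercepts.sum()) < 1e-4 * np.abs(intercepts).sum()


class TestProjection:
    def test_order_zero_projection_is_constant(self):
        spec = rr.ModelSpec(order=0)
        coef = np.array([[2.0], [-1.0]])
        p5 = rr.project_to_age(coef, None, spec, age=5.0)
        p8 = rr.project_to_age(coef, None, spec, age=8.0)
        np.testing.assert_allclose(p5["u_a"], p8["u_a"])
        np.testing.assert_allclose(p5["u_a"], coef[:, 0] * np.sqrt(0.5))

    def test_zero_coefficients_project_to_zero(self):
        spec = rr.ModelSpec(order=1)
        out = rr.project_to_age(np.zeros((3, 2)), np.zeros((3, 2)), spec)
        assert (out[["u_a", "u_d", "total"]] == 0).all().all()

    def test_hand_evaluated_projection(self):
        spec = rr.ModelSpec(order=1)
        coef_a = np.array([[1.0, 2.0]])
        coef_d = np.array([[0.5, -1.0]])
        out = rr.project_to_age(coef_a, coef_d, spec, age=8.0)
        phi = basis_at_age(8.0, 2.0, 8.0, 1)[0]
        assert out["u_a"][0] == pytest.approx(phi @ [1.0, 2.0])
        assert out["u_d"][0] == pytest.approx(phi @ [0.5, -1.0])
        assert out["total"][0] == pytest.approx(out["u_a"][0] + out["u_d"][0])


class TestHeritabilityCurve:
    def _fit(self, K_a, K_d, s2e, order=1):
        return rr.RRFit(
            spec=rr.ModelSpec(order=order), animal_ids=np.array(["a"]),
            K_a=np.atleast_2d(K_a), K_d=None if K_d is None else np.atleast_2d(K_d),
            K_pe=None, sigma2_e=s2e, loglik=0.0,
        )

    def test_order_zero_curve_is_flat(self):
        curve = rr.heritability_curve(self._fit([[100.0]], [[20.0]], 80.0, order=0),
                                      [2, 4, 6, 8])
        assert curve["h2_a"].nunique() == 1
        # constant basis value phi_0 = sqrt(1/2): v_a = 50, v_d = 10
        assert curve["h2_a"][0] == pytest.approx(50.0 / 140.0)

    def test_zero_dominance_curve(self):
        curve = rr.heritability_curve(
            self._fit(np.eye(2) * 50, np.zeros((2, 2)), 100.0), [2, 5, 8]
        )
        assert (curve["h2_d"] == 0).all()

    def test_fractions_bounded_by_one(self, small_grms, small_records, small_herd):
        spec = rr.ModelSpec(trait="CW", order=1, tol=1e-3, max_iter=40)
        designs = rr.build_design(
            small_records, spec, small_herd["genotypes"].animal_ids
        )
        fit = rr.reml_fit(designs, small_grms["G"], small_grms["D"], spec=spec)
        curve = rr.heritability_curve(fit, np.arange(2, 8.5, 0.5))
        assert ((curve["h2_a"] + curve["h2_d"]) <= 1.0 + 1e-12).all()
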