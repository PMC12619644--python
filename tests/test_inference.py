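import numpy as np
import pandas as pd
import pytest

from kdca import (
    DesignInputs,
    MvnSimConfig,
    empirical_pvalue,
    eigengene_test,
    fisher_combine,
    fit_mean_model,
    gamma_approx_pvalue,
    hsic_statistic,
    kdca_test,
    permutation_null,
    permute_and_reconstruct,
    simulate_mvn_pathway,
    standardize,
)
from kdca.inference import PermutationEngine, PermutationResult
from kdca.kernelize import linear_kernel
from kdca.residualize import estimate_variance_groupwise

from conftest import design_from_sim, make_design


class TestHsicStatistic:
    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 21))
            A = rng.standard_normal((n, n))
            A = A + A.T
            B = rng.standard_normal((n, n))
            B = B + B.T
            brute = sum(
                A[j, jp] * B[jp, j] for j in range(n) for jp in range(n)
            ) / n
            assert abs(hsic_statistic(A, B) - brute) < 1e-10

    def test_degenerate_cases(self, rng):
        n = 6
        assert hsic_statistic(np.zeros((n, n)), rng.standard_normal((n, n))) == 0.0
        assert hsic_statistic(np.eye(n), np.eye(n)) == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            hsic_statistic(np.eye(3), np.eye(4))


class TestEmpiricalPvalue:
    @pytest.mark.parametrize(
        "T_obs,null,expected",
        [
            (5.0, [1.0, 2.0, 3.0, 4.0], 1 / 5),
            (0.0, [1.0, 2.0, 3.0, 4.0], 1.0),
            (2.0, [2.0, 2.0, 2.0], 1.0),  # ties count as exceedances
        ],
    )
    def test_printed_formula(self, T_obs, null, expected):
        assert empirical_pvalue(T_obs, np.array(null)) == pytest.approx(expected)

    def test_floor_is_one_over_b_plus_one(self, rng):
        null = rng.standard_normal(999)
        p = empirical_pvalue(1e9, null)
        assert p == pytest.approx(1 / 1000)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, np.array([]))


class TestEmpiricalPvalueProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        null=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200),
        T_obs=st.floats(-1e6, 1e6),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_bounds_and_monotonicity(self, null, T_obs):
        B = len(null)
        p = empirical_pvalue(T_obs, np.array(null))
        assert 1 / (B + 1) <= p <= 1.0
        # a larger observed statistic can never raise the p-value
        p_hi = empirical_pvalue(T_obs + 1.0, np.array(null))
        assert p_hi <= p


class TestPermuteAndReconstruct:
    def _standardized(self, rng):
        design = make_design(rng, n=50, r=4)
        res = standardize(estimate_variance_groupwise(fit_mean_model(design)))
        return design, res

    def test_identity_permutation_recovers_y(self, rng):
        design, res = self._standardized(rng)
        Yb = permute_and_reconstruct(res, np.arange(50))
        assert np.allclose(Yb, design.Y, atol=1e-10)

    def test_gene_gene_correlations_preserved(self, rng):
        _, res = self._standardized(rng)
        perm = rng.permutation(50)
        assert np.allclose(
            np.corrcoef(res.e_std[perm], rowvar=False),
            np.corrcoef(res.e_std, rowvar=False),
            atol=1e-12,
        )

    def test_column_means_preserved(self, rng):
        design, res = self._standardized(rng)
        perm = rng.permutation(50)
        Yb = permute_and_reconstruct(res, perm)
        # row-shuffled standardized residuals keep each gene's sample mean
        # contribution under the group-wise variance model to close order
        assert np.allclose(Yb.mean(axis=0), design.Y.mean(axis=0), atol=0.5)

    def test_invalid_permutation_rejected(self, rng):
        _, res = self._standardized(rng)
        with pytest.raises(ValueError, match="not a permutation"):
            permute_and_reconstruct(res, np.zeros(50, dtype=int))


class TestPermutationEngineInternals:
    def test_fast_statistics_match_full_kernel_route(self, rng):
        """The algebraic shortcuts must agree with explicit kernel matrices."""
        from kdca.kernelize import (
            center_columns,
            cross_products,
            gaussian_kernel,
            projection_kernel,
            risk_factor_kernel,
        )

        design = make_design(rng, n=40, r=5)
        eng = PermutationEngine(design)
        cp = center_columns(cross_products(eng.obs_ez))
        KX = risk_factor_kernel(design.X, design.categorical)
        expected = [
            hsic_statistic(linear_kernel(cp), KX),
            hsic_statistic(projection_kernel(cp), KX),
            hsic_statistic(gaussian_kernel(cp), KX),
        ]
        assert np.allclose(eng.T_obs, expected, atol=1e-8)

    def test_diagnostics_report_effective_rank(self, rng):
        design = make_design(rng, n=60, r=4)  # q = 6 < n, full rank
        res = kdca_test(design, B=20, seed=1)
        assert res.diagnostics["effective_rank_Z"] == 6
        assert res.diagnostics["n_pairs"] == 6

    def test_determinism_bit_identical(self, rng):
        design = make_design(rng, n=60, r=4)
        r1 = kdca_test(design, B=60, seed=42)
        r2 = kdca_test(design, B=60, seed=42)
        assert r1.p_combined == r2.p_combined
        for a, b in zip(r1.per_kernel, r2.per_kernel):
            assert a.p_empirical == b.p_empirical
            assert np.array_equal(a.T_null, b.T_null)

    def test_early_stop_agrees_with_full_run(self, rng):
        design = make_design(rng, n=60, r=4)
        full = kdca_test(design, B=120, seed=9)
        es = kdca_test(design, B=120, seed=9, early_stop=True, early_stop_B=50)
        if es.diagnostics.get("early_stopped"):
            # stopped early: p computed from the first 50 permutations of the
            # same stream
            head = kdca_test(design, B=50, seed=9)
            assert es.p_combined == head.p_combined
        else:
            assert es.p_combined == full.p_combined

    def test_stream_extension_matches_full_run(self, rng):
        """Early stopping that continues must reproduce the one-shot run."""
        design = make_design(rng, n=60, r=4)
        eng = PermutationEngine(design)
        full = eng.null_stats(40, seed=7)
        head = eng.null_stats(25, seed=7)
        tail = eng.null_stats(40, seed=7, b_start=25)
        assert np.array_equal(np.vstack([head, tail]), full)


class TestFisherCombine:
    def _result(self, p, null, B):
        return PermutationResult(
            kernel_name="k", T_obs=0.0, T_null=np.asarray(null, float),
            p_empirical=p, B=B, seed=0,
        )

    def test_all_ones_give_zero_statistic(self):
        res = [self._result(1.0, [1.0, 2.0], 2) for _ in range(3)]
        comb = fisher_combine(res)
        assert comb.T_prime_obs == 0.0

    def test_half_pvalues_arithmetic(self):
        res = [self._result(0.5, [1.0, 2.0], 2) for _ in range(3)]
        comb = fisher_combine(res)
        assert comb.T_prime_obs == pytest.approx(-6.0 * np.log(0.5))

    def test_mismatched_b_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fisher_combine([self._result(0.5, [1.0], 1), self._result(0.5, [1.0, 2.0], 2)])

    def test_per_permutation_pvalues_self_inclusive(self, rng):
        # T'(b) is finite because each p_d(b) >= 1/B
        null = rng.standard_normal(30)
        res = [self._result(0.3, null, 30) for _ in range(2)]
        comb = fisher_combine(res)
        assert np.isfinite(comb.T_prime_null).all()
        assert comb.T_prime_null.max() <= -4.0 * np.log(1 / 30) + 1e-12

    def test_identical_kernels_match_single_kernel_pvalue(self, rng):
        # with fully dependent kernels the combination degenerates to the
        # single-kernel test
        design = make_design(rng, n=60, r=4)
        single = permutation_null(design, kernels=("linear",), B=80, seed=3)[0]
        comb = kdca_test(design, kernels=("linear", "linear", "linear"), B=80, seed=3)
        assert comb.p_combined == pytest.approx(single.p_empirical, abs=0.05)


class TestNullCalibration:
    def test_pvalues_uniform_under_null(self, rng):
        """Empirical p-values from the permutation scheme are uniform when
        the risk factor is independent of expression."""
        from scipy.stats import kstest

        ps = []
        for _ in range(220):
            data = simulate_mvn_pathway(
                MvnSimConfig(n=80, r=4, tau_range=(0.0, 0.0), delta_max=0.1), rng
            )
            design = design_from_sim(data)
            res = permutation_null(design, kernels=("linear",), B=99,
                                   seed=int(rng.integers(2**31)))
            ps.append(res[0].p_empirical)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_observed_statistic_exchangeable_with_null(self, rng):
        design = make_design(rng, n=60, r=4)
        res = permutation_null(design, kernels=("linear",), B=99, seed=1)[0]
        # under the null the observed T should not be an outlier
        rank = (res.T_null >= res.T_obs).mean()
        assert 0.0 < rank <= 1.0


class TestEigengene:
    def test_two_gene_pathway_matches_linear_kernel_exactly(self, rng):
        # with r = 2 the cross-product matrix has a single column, so the
        # top-component statistic is a monotone transform of the linear
        # kernel statistic and the permutation p-values coincide
        data = simulate_mvn_pathway(MvnSimConfig(n=80, r=2, delta_max=0.0), rng)
        design = design_from_sim(data)
        lin = permutation_null(design, kernels=("linear",), B=150, seed=9)[0]
        eig = eigengene_test(design, B=150, seed=9)
        assert eig.p_empirical == lin.p_empirical

    def test_null_uniformity(self, rng):
        from scipy.stats import kstest

        ps = []
        for _ in range(120):
            data = simulate_mvn_pathway(
                MvnSimConfig(n=80, r=4, tau_range=(0.0, 0.0)), rng
            )
            ps.append(
                eigengene_test(
                    design_from_sim(data), B=99, seed=int(rng.integers(2**31))
                ).p_empirical
            )
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_signal_in_second_component_favors_kernel_test(self, rng):
        """When differential co-expression lives below the top component the
        eigengene summary loses power relative to the linear kernel."""
        hits_lin = hits_eig = 0
        for _ in range(40):
            n = 120
            x = rng.integers(0, 2, n).astype(float)
            # dominant static component + weaker x-dependent component
            base = rng.standard_normal((n, 1)) @ np.array([[2.0, 2.0, -2.0, -2.0]])
            sig = 0.6 * (x * rng.standard_normal(n))[:, None] @ np.array(
                [[1.0, -1.0, 1.0, -1.0]]
            )
            Y = base + sig + 0.6 * rng.standard_normal((n, 4))
            design = DesignInputs(Y=Y, X=pd.DataFrame({"x": x}), categorical=("x",))
            seed = int(rng.integers(2**31))
            lin = permutation_null(design, kernels=("linear",), B=99, seed=seed)[0]
            eig = eigengene_test(design, B=99, seed=seed)
            hits_lin += lin.p_empirical <= 0.05
            hits_eig += eig.p_empirical <= 0.05
        assert hits_lin > hits_eig


class TestGammaApproximation:
    def test_rank_one_kernels_give_scaled_chi2(self, rng):
        n = 1200
        u = rng.standard_normal(n)
        u -= u.mean()
        w = rng.standard_normal(n)
        w -= w.mean()
        KZ = np.outer(u, u)
        KX = np.outer(w, w)
        lam = float(u @ u)
        eta = float(w @ w)
        from scipy.stats import chi2

        for T in (0.5, 1.0, 3.0):
            Tval = T * lam * eta / n**2
            p_gamma = gamma_approx_pvalue(Tval, KZ, KX)
            assert p_gamma == pytest.approx(chi2.sf(T, df=1), abs=1e-3)

    def test_zero_statistic_gives_unit_pvalue(self, rng):
        n = 1100
        Z = rng.standard_normal((n, 3))
        Z -= Z.mean(axis=0)
        x = rng.standard_normal((n, 1))
        x -= x.mean()
        assert gamma_approx_pvalue(0.0, Z @ Z.T, x @ x.T) == pytest.approx(1.0, abs=1e-6)

    def test_small_sample_guard(self, rng):
        Z = rng.standard_normal((50, 3))
        with pytest.raises(ValueError, match="n < 1000"):
            with pytest.warns(RuntimeWarning):
                gamma_approx_pvalue(1.0, Z @ Z.T, Z @ Z.T)

    def test_matches_spectral_monte_carlo_oracle(self, rng):
        """Independent oracle: sample the weighted chi-square null directly
        from the kernel eigenvalue spectra and compare tails."""
        n = 1100
        Z = rng.standard_normal((n, 4))
        Z -= Z.mean(axis=0)
        x = rng.standard_normal((n, 1))
        x -= x.mean(axis=0)
        A, Bm = Z @ Z.T, x @ x.T
        lam = np.linalg.eigvalsh(A)
        lam = lam[lam > 1e-8 * lam[-1]]
        eta = np.linalg.eigvalsh(Bm)
        eta = eta[eta > 1e-8 * eta[-1]]
        draws = rng.chisquare(1, size=(40000, lam.size, eta.size))
        Ts = (draws * np.outer(lam, eta)).sum(axis=(1, 2)) / n**2
        for q in (0.25, 0.5, 0.75, 0.9):
            t = np.quantile(Ts, q)
            p_mc = (Ts >= t).mean()
            p_gamma = gamma_approx_pvalue(t, A, Bm)
            assert abs(p_gamma - p_mc) < 0.03

    def test_agrees_with_fixed_kernel_permutation_null(self, rng):
        """The Gamma mode approximates the null of the statistic with the
        observed kernels held fixed; compare against the recycled-fit
        (no-refit) permutation null, which is exactly that distribution."""
        checked = 0
        for _ in range(6):
            data = simulate_mvn_pathway(
                MvnSimConfig(n=2000, r=4, tau_range=(0.0, 0.0), delta_max=0.0), rng
            )
            design = design_from_sim(data)
            perm = permutation_null(design, kernels=("linear",), B=2000,
                                    seed=int(rng.integers(2**31)), refit=False)[0]
            if not 0.05 < perm.p_empirical < 0.5:
                continue
            eng = PermutationEngine(design, kernels=("linear",))
            from kdca.kernelize import center_columns, cross_products, risk_factor_kernel

            cp = center_columns(cross_products(eng.obs_ez))
            KX = risk_factor_kernel(design.X, design.categorical)
            p_gamma = gamma_approx_pvalue(perm.T_obs, linear_kernel(cp), KX)
            assert abs(p_gamma - perm.p_empirical) < 0.05
            checked += 1
        assert checked >= 1

    def test_asymptotic_mode_smoke(self, rng):
        data = simulate_mvn_pathway(
            MvnSimConfig(n=1200, r=4, tau_range=(0.0, 0.0), delta_max=0.0), rng
        )
        res = kdca_test(
            design_from_sim(data), B=0, mode="asymptotic",
            kernels=("linear", "projection"),
        )
        assert 0.0 < res.p_combined <= 1.0
        assert res.diagnostics["mode"] == "asymptotic"

    def test_non_psd_kernel_rejected_in_asymptotic_mode(self, rng):
        # the squared-inner-product variant is not PSD, so the Gamma mode
        # must refuse it
        data = simulate_mvn_pathway(
            MvnSimConfig(n=1100, r=4, tau_range=(0.0, 0.0), delta_max=0.0), rng
        )
        with pytest.raises(ValueError, match="positive semidefinite"):
            kdca_test(
                design_from_sim(data), B=0, mode="asymptotic",
                kernels=("linear", "gaussian_inner"),
            )
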