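"""HSIC test statistic, permutation null, kernel combination and baselines.

The test statistic for one kernel is ``T = tr(K_Z K_X) / n``, the
Hilbert-Schmidt independence criterion between the cross-product similarity
matrix and the risk-factor similarity matrix.  Because mean and variance
effects of the risk factor are estimated from the data, the null distribution
is approximated by a permutation scheme that preserves them: standardized
residuals are row-shuffled, expression is reconstructed as
``Y(b) = fitted + s * e_std[perm]``, and the *entire* pipeline (mean fit,
variance fit, standardization, cross products, kernels) is re-run on each
reconstructed matrix.  Empirical p-values use the add-one formula
``p = (#{T(b) >= T} + 1) / (B + 1)``, so the smallest attainable p-value is
``1/(B+1)``.

Per-kernel p-values are combined with Fisher's method; the combined statistic
is calibrated against the same permutation stream, which makes the combination
valid under arbitrary dependence between kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve

from .kernelize import KernelMatrix, KernelSpec, encode_risk_factors
from .residualize import (
    DesignInputs,
    ResidualSet,
    _dglm_batch,
    _groupwise_sd,
    variance_design,
)

__all__ = [
    "PermutationResult",
    "CombinedResult",
    "hsic_statistic",
    "empirical_pvalue",
    "permute_and_reconstruct",
    "permutation_null",
    "fisher_combine",
    "eigengene_test",
    "gamma_approx_pvalue",
    "kdca_test",
    "DEFAULT_KERNELS",
]

DEFAULT_KERNELS = ("linear", "projection", "gaussian")
# numerical floor on relative eigenvalues of Z'Z when inverting for the
# projection statistic; keeps 1/lambda finite against float noise
_EIG_FLOOR = 1e-12


@dataclass
class PermutationResult:
    """Observed and null statistics for one kernel (or baseline statistic)."""

    kernel_name: str
    T_obs: float
    T_null: np.ndarray
    p_empirical: float
    B: int
    seed: int


@dataclass
class CombinedResult:
    """Fisher-combined result across kernels."""

    per_kernel: list[PermutationResult]
    T_prime_obs: float
    T_prime_null: np.ndarray
    p_combined: float
    eigengene: PermutationResult | None = None
    diagnostics: dict = field(default_factory=dict)


def hsic_statistic(K_Z: KernelMatrix | np.ndarray, K_X: KernelMatrix | np.ndarray) -> float:
    """``T = tr(K_Z K_X) / n`` via the elementwise (Hadamard) sum."""
    A = K_Z.K if isinstance(K_Z, KernelMatrix) else np.asarray(K_Z, float)
    B = K_X.K if isinstance(K_X, KernelMatrix) else np.asarray(K_X, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"kernel shape mismatch: {A.shape} vs {B.shape}")
    return float((A * B).sum() / A.shape[0])


def empirical_pvalue(T_obs: float, T_null: np.ndarray) -> float:
    """Add-one empirical p-value; ties count as exceedances."""
    T_null = np.asarray(T_null, dtype=float)
    if T_null.size == 0:
        raise ValueError("empty null vector")
    return float((np.count_nonzero(T_null >= T_obs) + 1) / (T_null.size + 1))


def permute_and_reconstruct(res: ResidualSet, perm: np.ndarray) -> np.ndarray:
    """Null expression matrix ``Y(b) = fitted + s * e_std[perm]``.

    The row-wise shuffle of standardized residuals keeps gene-gene
    correlations and the fitted mean/variance structure intact while breaking
    any association between the residuals and the risk factor.
    """
    perm = np.asarray(perm)
    n = res.e.shape[0]
    if perm.shape != (n,) or not np.array_equal(np.sort(perm), np.arange(n)):
        raise ValueError("perm is not a permutation of 0..n-1")
    if res.e_std is None or res.s is None:
        raise ValueError("residuals must be standardized first")
    return res.fitted + res.s * res.e_std[perm]


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


def _resolve_kernels(kernels) -> list[KernelSpec]:
    out = []
    for k in kernels:
        out.append(k if isinstance(k, KernelSpec) else KernelSpec(str(k)))
    return out


def resolve_variance_mode(design: DesignInputs, variance_mode: str) -> str:
    if variance_mode == "auto":
        return "groupwise" if design.all_risk_categorical else "dglm"
    if variance_mode not in ("groupwise", "dglm", "constant"):
        raise ValueError(f"unknown variance mode {variance_mode!r}")
    return variance_mode


class PermutationEngine:
    """Shared machinery for the observed fit and the permutation null.

    Precomputes everything that is fixed across permutations (mean-design
    orthonormal basis, variance-model design or group labels, risk-factor
    kernel) and evaluates the per-kernel statistics from a reconstructed
    expression matrix without materializing n x n kernels where algebra
    permits (``tr(Z Z' X X') = ||Z'X||_F^2``).
    """

    def __init__(
        self,
        design: DesignInputs,
        kernels=DEFAULT_KERNELS,
        variance_mode: str = "auto",
        variance_covariates=None,
        include_eigengene: bool = False,
        refit: bool = True,
        dglm_max_iter: int = 25,
        dglm_tol: float = 1e-6,
    ):
        self.design = design
        self.kernels = _resolve_kernels(kernels)
        self.include_eigengene = include_eigengene
        self.refit = refit
        self.variance_mode = resolve_variance_mode(design, variance_mode)
        self.Dm, self.mean_names = design.design_matrix()
        self.Q, _ = np.linalg.qr(self.Dm)
        if self.variance_mode == "groupwise":
            if not design.categorical:
                raise ValueError(
                    "groupwise variance requires a categorical risk factor"
                )
            self.codes = design.group_codes()
        elif self.variance_mode == "dglm":
            self.Dv, _ = variance_design(design, variance_covariates)
        self.dglm_max_iter = dglm_max_iter
        self.dglm_tol = dglm_tol
        self.Xc = encode_risk_factors(design.X, design.categorical)
        self.KX = self.Xc @ self.Xc.T if self._needs_dense_kx() else None
        if include_eigengene:
            Qx, _ = np.linalg.qr(self.Xc)  # orthonormal basis, columns centered
            self.Qx = Qx
        self.stat_names = [k.name for k in self.kernels] + (
            ["eigengene"] if include_eigengene else []
        )
        if self.KX is not None:
            n = design.n_samples
            self._triu = np.triu_indices(n, k=1)
            self._kx_triu = self.KX[self._triu]
            self._kx_diag_sum = float(np.trace(self.KX))
        self.n_refit_failures = 0
        self._fit_observed()

    def _needs_dense_kx(self) -> bool:
        return any(k.name.startswith("gaussian") for k in self.kernels)

    # -- pipeline ----------------------------------------------------------

    def _residualize(self, Y: np.ndarray):
        if self.variance_mode == "dglm":
            _, e, s, _, converged, _ = _dglm_batch(
                Y, self.Dm, self.Dv, max_iter=self.dglm_max_iter,
                tol=self.dglm_tol, Q=self.Q,
            )
            return e, s, converged
        e = Y - self.Q @ (self.Q.T @ Y)
        if self.variance_mode == "groupwise":
            s = _groupwise_sd(e, self.codes, self.design.gene_ids)
        else:  # constant
            dof = max(Y.shape[0] - self.Dm.shape[1], 1)
            v = (e**2).sum(axis=0) / dof
            s = np.broadcast_to(np.sqrt(v), e.shape)
        return e, s, True

    def _stats_from_Y(self, Y: np.ndarray) -> np.ndarray:
        e, s, _ = self._residualize(Y)
        ez = e / s
        r = ez.shape[1]
        ii, kk = np.triu_indices(r, k=1)
        Z = ez[:, ii] * ez[:, kk]
        Zc = Z - Z.mean(axis=0, keepdims=True)
        return self._stats_from_Zc(Zc)

    def _stats_from_Zc(self, Zc: np.ndarray) -> np.ndarray:
        n = Zc.shape[0]
        need_proj = any(k.name == "projection" for k in self.kernels)
        lam = V = None
        Gq = Zc.T @ Zc if (need_proj or self.include_eigengene) else None
        if self.include_eigengene:
            lam, V = np.linalg.eigh(Gq)
            if lam[-1] <= 0:
                raise ValueError("degenerate cross-product matrix")
        M = Zc.T @ self.Xc  # q x L, shared by linear/projection
        out = []
        for spec in self.kernels:
            if spec.name == "linear":
                out.append(float((M**2).sum() / n))
            elif spec.name == "projection":
                if lam is None:
                    # full column rank in the common case: Cholesky solve of
                    # Z'Z; eigendecomposition fallback applies the rank rule
                    try:
                        out.append(float((M * cho_solve(cho_factor(Gq), M)).sum() / n))
                        continue
                    except np.linalg.LinAlgError:
                        lam, V = np.linalg.eigh(Gq)
                if lam[-1] <= 0:
                    raise ValueError("degenerate cross-product matrix")
                floor = max(spec.projection_rank_tol**2, _EIG_FLOOR) * lam[-1]
                keep = lam > floor
                if not keep.any():
                    raise ValueError("degenerate cross-product matrix")
                VM = V[:, keep].T @ M
                out.append(float(((VM**2) / lam[keep, None]).sum() / n))
            elif spec.name == "gaussian":
                Gn = Zc @ Zc.T
                sq = np.einsum("ii->i", Gn)
                d2u = sq[self._triu[0]] + sq[self._triu[1]] - 2.0 * Gn[self._triu]
                ku = np.exp(-spec.nu * np.maximum(d2u, 0.0))
                out.append(
                    float((2.0 * (ku @ self._kx_triu) + self._kx_diag_sum) / n)
                )
            else:  # gaussian_inner
                Gn = Zc @ Zc.T
                gu = Gn[self._triu]
                ku = np.exp(-spec.nu * gu * gu)
                sq = np.einsum("ii->i", Gn)
                diag = float(np.exp(-spec.nu * sq * sq) @ np.diag(self.KX))
                out.append(float((2.0 * (ku @ self._kx_triu) + diag) / n))
        if self.include_eigengene:
            u1 = Zc @ V[:, -1]
            u1 = u1 - u1.mean()
            denom = float(u1 @ u1)
            if denom <= 0:
                raise ValueError("degenerate top component")
            proj = self.Qx.T @ u1
            out.append(float(n * (proj @ proj) / denom))
        return np.asarray(out)

    # -- observed ----------------------------------------------------------

    def _fit_observed(self) -> None:
        Y = self.design.Y
        e, s, converged = self._residualize(Y)
        self.obs_converged = converged
        self.obs_fitted = Y - e
        self.obs_s = np.asarray(s)
        self.obs_ez = e / s
        r = self.obs_ez.shape[1]
        ii, kk = np.triu_indices(r, k=1)
        Z = self.obs_ez[:, ii] * self.obs_ez[:, kk]
        self.obs_Zc = Z - Z.mean(axis=0, keepdims=True)
        self.T_obs = self._stats_from_Zc(self.obs_Zc)

    # -- null --------------------------------------------------------------

    def null_stats(self, B: int, seed: int, b_start: int = 0) -> np.ndarray:
        """Null statistics for permutations ``b_start .. B-1``.

        Each permutation draws its index vector from an independent
        counter-based substream ``(seed, b)``, so results do not depend on
        execution order and streams can be extended without recomputation.
        A permutation whose refit fails is redrawn once; a second failure
        aborts.

        With ``refit=False`` the observed fits are recycled: the permuted
        standardized residuals enter the cross products directly, which is
        algebraically a row shuffle of the observed cross-product matrix.
        This is faster but ignores that the mean/variance adjustment is
        estimated, so the default re-runs the full pipeline per permutation.
        """
        if B < 1:
            raise ValueError("B must be >= 1")
        n = self.design.n_samples
        out = np.empty((B - b_start, len(self.stat_names)))
        for b in range(b_start, B):
            last_err = None
            for attempt in (0, 1):
                rng = np.random.default_rng(np.random.SeedSequence([seed, b, attempt]))
                perm = rng.permutation(n)
                try:
                    if self.refit:
                        Yb = self.obs_fitted + self.obs_s * self.obs_ez[perm]
                        out[b - b_start] = self._stats_from_Y(Yb)
                    else:
                        out[b - b_start] = self._stats_from_Zc(self.obs_Zc[perm])
                    last_err = None
                    break
                except Exception as err:  # redraw once, then abort
                    last_err = err
                    self.n_refit_failures += 1
            if last_err is not None:
                raise RuntimeError(
                    f"permutation {b} failed twice during refit: {last_err}"
                ) from last_err
        return out


def permutation_null(
    design: DesignInputs,
    kernels=DEFAULT_KERNELS,
    B: int = 1000,
    seed: int = 0,
    variance_mode: str = "auto",
    variance_covariates=None,
    refit: bool = True,
) -> list[PermutationResult]:
    """Observed statistic, permutation null and empirical p-value per kernel.

    All kernels share the same permutation stream so per-permutation
    statistics are directly comparable across kernels.
    """
    eng = PermutationEngine(
        design,
        kernels=kernels,
        variance_mode=variance_mode,
        variance_covariates=variance_covariates,
        refit=refit,
    )
    null = eng.null_stats(B, seed)
    return _results_from(eng, null, B, seed)


def _results_from(
    eng: PermutationEngine, null: np.ndarray, B: int, seed: int
) -> list[PermutationResult]:
    out = []
    for d, name in enumerate(eng.stat_names):
        out.append(
            PermutationResult(
                kernel_name=name,
                T_obs=float(eng.T_obs[d]),
                T_null=null[:, d].copy(),
                p_empirical=empirical_pvalue(eng.T_obs[d], null[:, d]),
                B=B,
                seed=seed,
            )
        )
    return out


def fisher_combine(results: list[PermutationResult]) -> CombinedResult:
    """Combine per-kernel empirical p-values with Fisher's method.

    The observed combined statistic is ``T' = -2 sum_d log p_d``.  For each
    permutation ``b`` the per-kernel p-value is ranked *within that kernel's
    own null vector* (self-inclusive, so ``p_d(b) >= 1/B`` and the log is
    finite), and the combined null ``T'(b)`` is referenced by the same
    add-one empirical formula.  Calibrating against the joint permutation
    stream keeps the test valid under any dependence between kernels.
    """
    if len(results) < 2:
        raise ValueError("need at least two kernels to combine")
    B = results[0].B
    if any(res.B != B for res in results):
        raise ValueError("mismatched permutation counts across kernels")
    logs_obs = 0.0
    T_prime_null = np.zeros(B)
    for res in results:
        logs_obs += np.log(res.p_empirical)
        sorted_null = np.sort(res.T_null)
        # #{b': T(b') >= T(b)} / B, self-inclusive
        ge_counts = B - np.searchsorted(sorted_null, res.T_null, side="left")
        T_prime_null += -2.0 * np.log(ge_counts / B)
    T_prime_obs = -2.0 * logs_obs
    return CombinedResult(
        per_kernel=results,
        T_prime_obs=float(T_prime_obs),
        T_prime_null=T_prime_null,
        p_combined=empirical_pvalue(T_prime_obs, T_prime_null),
    )


def eigengene_test(
    design: DesignInputs,
    B: int = 1000,
    seed: int = 0,
    variance_mode: str = "auto",
    variance_covariates=None,
) -> PermutationResult:
    """Baseline: association of the top component of ``Z`` with the risk factor.

    The statistic is ``n R^2`` of the top left singular vector of the centered
    cross-product matrix regressed on the risk-factor column(s); the p-value
    comes from the identical mean/variance-preserving permutation scheme, so
    only the statistic differs from the kernel tests.
    """
    eng = PermutationEngine(
        design,
        kernels=(),
        variance_mode=variance_mode,
        variance_covariates=variance_covariates,
        include_eigengene=True,
    )
    null = eng.null_stats(B, seed)
    return _results_from(eng, null, B, seed)[0]


def gamma_approx_pvalue(
    T_obs: float,
    K_Z: KernelMatrix | np.ndarray,
    K_X: KernelMatrix | np.ndarray,
    allow_small_n: bool = False,
) -> float:
    """Large-sample Gamma approximation to the HSIC null.

    Under the null the statistic is asymptotically a weighted sum of chi-square
    variables with weights from the eigenvalue spectra of the doubly-centered
    kernels ``A = H K_Z H`` and ``B = H K_X H``; matching the first two moments
    (``E T = tr A tr B / n^2``, ``Var T = 2 ||A||_F^2 ||B||_F^2 / n^4``) gives
    a Gamma tail probability.  Intended for large samples only; below n = 1000
    the permutation null should be used instead.
    """
    A = K_Z.K if isinstance(K_Z, KernelMatrix) else np.asarray(K_Z, float)
    Bm = K_X.K if isinstance(K_X, KernelMatrix) else np.asarray(K_X, float)
    if A.shape != Bm.shape:
        raise ValueError("kernel shape mismatch")
    n = A.shape[0]
    if n < 1000 and not allow_small_n:
        warnings.warn(
            f"n={n} < 1000: the Gamma approximation is unreliable at this "
            "sample size; pass allow_small_n=True to force it",
            RuntimeWarning,
            stacklevel=2,
        )
        raise ValueError("refusing Gamma approximation for n < 1000")
    A = _double_center(A)
    Bm = _double_center(Bm)
    for Kc in (A, Bm):
        evals = np.linalg.eigvalsh(Kc)
        if evals[0] < -1e-8 * max(evals[-1], 1.0):
            raise ValueError("centered kernel is not positive semidefinite")
    mean = float(np.trace(A) * np.trace(Bm)) / n**2
    var = 2.0 * float((A * A).sum() * (Bm * Bm).sum()) / n**4
    if mean <= 0 or var <= 0:
        raise ValueError("degenerate kernel spectra")
    shape = mean**2 / var
    scale = var / mean
    return float(sps.gamma.sf(T_obs, a=shape, scale=scale))


def _double_center(K: np.ndarray) -> np.ndarray:
    rm = K.mean(axis=0, keepdims=True)
    cm = K.mean(axis=1, keepdims=True)
    return K - rm - cm + K.mean()


def kdca_test(
    design: DesignInputs,
    kernels=DEFAULT_KERNELS,
    B: int = 1000,
    seed: int = 0,
    variance_mode: str = "auto",
    variance_covariates=None,
    mode: str = "permutation",
    include_eigengene: bool = False,
    refit: bool = True,
    early_stop: bool = False,
    early_stop_B: int = 1000,
    early_stop_p: float = 0.1,
    allow_small_n: bool = False,
) -> CombinedResult:
    """Full kernel differential co-expression test for one pathway.

    Orchestrates residualization, cross products, kernel statistics, the
    permutation null and Fisher combination; optionally also runs the
    eigengene baseline on the same permutation stream.  ``mode="asymptotic"``
    replaces the permutation null with per-kernel Gamma tail probabilities
    (large samples only) combined with the chi-square reference, which assumes
    independent kernels.
    """
    eng = PermutationEngine(
        design,
        kernels=kernels,
        variance_mode=variance_mode,
        variance_covariates=variance_covariates,
        include_eigengene=include_eigengene,
        refit=refit,
    )
    sv = np.linalg.svd(eng.obs_Zc, compute_uv=False)
    diagnostics = {
        "variance_mode": eng.variance_mode,
        "dglm_converged": bool(eng.obs_converged),
        "n_pairs": design.n_genes * (design.n_genes - 1) // 2,
        "effective_rank_Z": int((sv > 1e-8 * sv[0]).sum()) if sv.size else 0,
    }
    if mode == "asymptotic":
        return _asymptotic_result(eng, diagnostics, allow_small_n)
    if mode != "permutation":
        raise ValueError(f"unknown mode {mode!r}")

    if early_stop and B > early_stop_B:
        null = eng.null_stats(early_stop_B, seed)
        results = _results_from(eng, null, early_stop_B, seed)
        combined = fisher_combine(results[: len(eng.kernels)])
        if combined.p_combined > early_stop_p:
            diagnostics["early_stopped"] = True
            return _finalize(eng, results, combined, diagnostics)
        null = np.vstack([null, eng.null_stats(B, seed, b_start=early_stop_B)])
    else:
        null = eng.null_stats(B, seed)
        B = null.shape[0]
    results = _results_from(eng, null, null.shape[0], seed)
    combined = fisher_combine(results[: len(eng.kernels)])
    return _finalize(eng, results, combined, diagnostics)


def _finalize(eng, results, combined, diagnostics) -> CombinedResult:
    if eng.include_eigengene:
        combined.eigengene = results[-1]
    diagnostics["n_refit_failures"] = eng.n_refit_failures
    combined.diagnostics = diagnostics
    return combined


def _asymptotic_result(eng: PermutationEngine, diagnostics: dict, allow_small_n: bool) -> CombinedResult:
    from .kernelize import (
        center_columns,
        cross_products,
        gaussian_inner_kernel,
        gaussian_kernel,
        linear_kernel,
        projection_kernel,
    )

    cp = center_columns(cross_products(eng.obs_ez))
    KX = KernelMatrix(K=eng.Xc @ eng.Xc.T, source="X", spec=KernelSpec("linear"))
    per_kernel = []
    logs = 0.0
    for spec in eng.kernels:
        if spec.name == "linear":
            KZ = linear_kernel(cp)
        elif spec.name == "projection":
            KZ = projection_kernel(cp, tol=spec.projection_rank_tol)
        elif spec.name == "gaussian":
            KZ = gaussian_kernel(cp, nu=spec.nu)
        else:
            KZ = gaussian_inner_kernel(cp, nu=spec.nu)
        T = hsic_statistic(KZ, KX)
        p = gamma_approx_pvalue(T, KZ, KX, allow_small_n=allow_small_n)
        p = min(max(p, np.finfo(float).tiny), 1.0)
        per_kernel.append(
            PermutationResult(
                kernel_name=spec.name,
                T_obs=T,
                T_null=np.empty(0),
                p_empirical=p,
                B=0,
                seed=0,
            )
        )
        logs += np.log(p)
    T_prime = -2.0 * logs
    p_comb = float(sps.chi2.sf(T_prime, df=2 * len(per_kernel)))
    diagnostics["mode"] = "asymptotic"
    return CombinedResult(
        per_kernel=per_kernel,
        T_prime_obs=T_prime,
        T_prime_null=np.empty(0),
        p_combined=p_comb,
        diagnostics=diagnostics,
    )
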