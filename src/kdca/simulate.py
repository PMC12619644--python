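"""Synthetic pathways with known differential co-expression structure.

Two generators drive the power and type-I-error experiments and double as the
repository's fixture factory.

Multivariate-normal pathway model
    For individual ``j`` and gene ``k``:
    ``E[Y_jk] = alpha_k + X_j + C_j``, ``log Var[Y_jk] = 1 + delta_k X_j``,
    and the correlation between genes ``k != k'`` is ``rho_j + tau X_j`` for
    pairs in which both genes carry differential co-expression and ``rho_j``
    otherwise.  ``rho_j`` is an individual-specific baseline correlation
    drawn per sample; ``tau`` (drawn once per pathway) is the
    correlation-specific effect of the risk factor; ``delta_k`` is a pure
    variance effect, a confounder the test must remove.  ``tau = 0`` gives
    the global null.

Negative-binomial count model
    Genes are drawn independently with
    ``log E[Y_jk] = log(alpha_k) + beta_k X_j + gamma_k C_j +
    delta_k X_j U_jk`` where the latent factor ``U_jk`` is independent across
    genes.  Because the interaction is not shared between genes, pathways
    assembled from these genes satisfy the differential co-expression null,
    yet the interaction induces a risk-factor variance effect once counts are
    log-transformed — the adversarial null for variance adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MvnSimConfig",
    "NbSimConfig",
    "MvnSimData",
    "NbSimData",
    "simulate_mvn_pathway",
    "simulate_nb_counts",
    "simulate_multifactor",
    "pathway_blocks",
]


@dataclass(frozen=True)
class MvnSimConfig:
    """Parameters of the multivariate-normal pathway generator.

    Defaults reproduce the reference simulation conditions: n = 300 samples,
    pathways of 10 genes, Bernoulli(0.5) categorical or Uniform(0, 2)
    continuous risk factor, baseline correlation rho_j ~ Uniform(0.25, 0.50),
    co-expression effect tau ~ Uniform(0.1, 0.2), variance effects
    delta_k ~ Uniform(0, delta_max).
    """

    n: int = 300
    r: int = 10
    risk: str = "categorical"  # "categorical" -> Bernoulli(0.5), else Uniform(0,2)
    null_fraction: float = 0.0
    sign_scheme: str = "positive"  # or "mixed": pair signs +/- tau
    tau_range: tuple[float, float] = (0.1, 0.2)
    rho_range: tuple[float, float] = (0.25, 0.50)
    delta_max: float = 0.0
    n_factors: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.r < 2:
            raise ValueError("pathway needs at least 2 genes")
        if not 0 <= self.null_fraction <= 1:
            raise ValueError("null_fraction must lie in [0, 1]")
        for rng_ in (self.tau_range, self.rho_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"range not ordered: {rng_}")
        if self.risk not in ("categorical", "continuous"):
            raise ValueError("risk must be 'categorical' or 'continuous'")
        if self.sign_scheme not in ("positive", "mixed"):
            raise ValueError("sign_scheme must be 'positive' or 'mixed'")
        if self.n_factors not in (1, 3):
            raise ValueError("n_factors must be 1 or 3")
        if self.delta_max < 0:
            raise ValueError("delta_max must be >= 0")

    @property
    def is_null(self) -> bool:
        return self.tau_range == (0.0, 0.0)


@dataclass(frozen=True)
class NbSimConfig:
    """Parameters of the negative-binomial count generator.

    ``beta_sd``/``gamma_sd``/``delta_sd`` are the standard deviations of the
    per-gene effects (the Normal(0, 0.01) and Normal(0, 6.25e-4) entries read
    as variances); ``alpha`` is Lognormal(meanlog, sdlog).
    """

    n: int = 300
    n_genes: int = 10000
    pathway_size: int = 10
    risk: str = "categorical"
    alpha_meanlog: float = 5.54
    alpha_sdlog: float = 0.697
    beta_sd: float = 0.1
    gamma_sd: float = 0.1
    delta_sd: float = 0.025
    dispersion: float = 0.25
    library_sizes: tuple[int, ...] = (2_000_000, 10_000_000)
    scale_library: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.pathway_size < 2 or self.pathway_size > self.n_genes:
            raise ValueError("invalid pathway size")
        if self.risk not in ("categorical", "continuous"):
            raise ValueError("risk must be 'categorical' or 'continuous'")


@dataclass
class MvnSimData:
    Y: np.ndarray                # n x r
    X: np.ndarray                # n x L
    C: np.ndarray                # n
    gene_is_dca: np.ndarray      # bool, length r
    pair_tau_signed: np.ndarray  # length q; 0 for null pairs
    tau: float
    rho: np.ndarray              # per-individual baseline correlation
    delta: np.ndarray            # per-gene variance effects
    alpha: np.ndarray
    n_psd_repairs: int


@dataclass
class NbSimData:
    counts: np.ndarray       # n x n_genes, integer
    X: np.ndarray            # n
    C: np.ndarray            # n
    library_sizes: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray


def _draw_risk(rng: np.random.Generator, risk: str, n: int, L: int) -> np.ndarray:
    if risk == "categorical":
        return rng.binomial(1, 0.5, size=(n, L)).astype(float)
    return rng.uniform(0.0, 2.0, size=(n, L))


def simulate_mvn_pathway(
    cfg: MvnSimConfig,
    rng: np.random.Generator | None = None,
    X: np.ndarray | None = None,
    C: np.ndarray | None = None,
) -> MvnSimData:
    """Draw one pathway from the multivariate-normal model.

    Each individual gets their own correlation matrix (baseline ``rho_j``
    plus ``tau``-shifts on differentially co-expressed pairs), scaled by the
    per-gene conditional SDs ``exp((1 + delta_k X_j)/2)``.  With mixed signs
    a matrix can leave the positive-semidefinite cone; such matrices are
    repaired by eigenvalue clipping at 1e-8 followed by rescaling to unit
    diagonal, and the repair count is reported.

    ``X`` / ``C`` may be supplied to share one risk factor and covariate
    across several pathways of the same study; by default fresh ones are
    drawn, giving independent replicates.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, r = cfg.n, cfg.r
    if X is None:
        X = _draw_risk(rng, cfg.risk, n, cfg.n_factors)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.size == n:
            X = X.T
        if X.shape != (n, cfg.n_factors):
            raise ValueError(f"supplied X must have shape ({n}, {cfg.n_factors})")
    xbar = (2.0 / 3.0) * X.sum(axis=1) if cfg.n_factors == 3 else X[:, 0]
    C = rng.uniform(0.0, 2.0, n) if C is None else np.asarray(C, dtype=float)
    alpha = rng.normal(0.0, 1.0, r)
    delta = rng.uniform(0.0, cfg.delta_max, r)
    rho = rng.uniform(*cfg.rho_range, n)
    tau = float(rng.uniform(*cfg.tau_range))

    n_null = int(round(cfg.null_fraction * r))
    is_dca = np.ones(r, dtype=bool)
    if n_null:
        is_dca[rng.choice(r, size=n_null, replace=False)] = False

    ii, kk = np.triu_indices(r, k=1)
    signal_pair = is_dca[ii] & is_dca[kk]
    signs = np.ones(ii.size)
    if cfg.sign_scheme == "mixed":
        signs = rng.choice([-1.0, 1.0], size=ii.size)
    pair_tau = np.where(signal_pair, signs * tau, 0.0)

    # per-individual correlation matrices (n, r, r)
    eye = np.eye(r)
    R = rho[:, None, None] * (1.0 - eye) + eye
    Delta = np.zeros((r, r))
    Delta[ii, kk] = pair_tau
    Delta += Delta.T
    R = R + xbar[:, None, None] * Delta

    off = R[:, ii, kk]
    bad = np.abs(off) >= 1.0
    if bad.any():
        j, p = np.nonzero(bad)
        j0, p0 = int(j[0]), int(p[0])
        raise ValueError(
            f"correlation {off[j0, p0]:.3f} outside (-1, 1) for individual "
            f"{j0}, gene pair {(int(ii[p0]), int(kk[p0]))}"
        )

    n_repairs = 0
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        lam, V = np.linalg.eigh(R)
        needs = lam[:, 0] < 1e-8
        n_repairs = int(needs.sum())
        lam = np.maximum(lam, 1e-8)
        Rfix = np.einsum("nij,nj,nkj->nik", V, lam, V, optimize=True)
        d = np.sqrt(np.einsum("nii->ni", Rfix))
        Rfix = Rfix / (d[:, :, None] * d[:, None, :])
        R = np.where(needs[:, None, None], Rfix, R)
        chol = np.linalg.cholesky(R)

    sd = np.exp(0.5 * (1.0 + delta[None, :] * xbar[:, None]))
    mean = alpha[None, :] + xbar[:, None] + C[:, None]
    z = rng.standard_normal((n, r))
    Y = mean + sd * np.einsum("nij,nj->ni", chol, z, optimize=True)
    return MvnSimData(
        Y=Y,
        X=X,
        C=C,
        gene_is_dca=is_dca,
        pair_tau_signed=pair_tau,
        tau=tau,
        rho=rho,
        delta=delta,
        alpha=alpha,
        n_psd_repairs=n_repairs,
    )


def simulate_multifactor(
    cfg: MvnSimConfig, rng: np.random.Generator | None = None
) -> MvnSimData:
    """Three Bernoulli(0.5) risk factors entering through their scaled mean
    ``(2/3) sum_l X_jl``; returns the full n x 3 risk matrix for multivariate
    kernel testing."""
    if cfg.n_factors != 3:
        cfg = replace(cfg, n_factors=3)
    if cfg.risk != "categorical":
        raise ValueError("the multifactor design uses Bernoulli(0.5) factors")
    return simulate_mvn_pathway(cfg, rng)


def simulate_nb_counts(
    cfg: NbSimConfig, rng: np.random.Generator | None = None
) -> NbSimData:
    """Draw a count matrix from the negative-binomial model.

    Counts have mean ``mu_jk`` and variance ``mu + dispersion * mu^2``.  When
    ``scale_library`` is on, each sample is multinomially resampled to a
    total drawn from ``library_sizes``, preserving NB-like marginals while
    imposing realistic sequencing depths.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, G = cfg.n, cfg.n_genes
    alpha = rng.lognormal(cfg.alpha_meanlog, cfg.alpha_sdlog, G)
    beta = rng.normal(0.0, cfg.beta_sd, G)
    gamma = rng.normal(0.0, cfg.gamma_sd, G)
    delta = rng.normal(0.0, cfg.delta_sd, G)
    X = _draw_risk(rng, cfg.risk, n, 1)[:, 0]
    C = rng.uniform(0.0, 2.0, n)
    U = rng.standard_normal((n, G))
    logmu = (
        np.log(alpha)[None, :]
        + beta[None, :] * X[:, None]
        + gamma[None, :] * C[:, None]
        + delta[None, :] * X[:, None] * U
    )
    mu = np.exp(logmu)
    k = 1.0 / cfg.dispersion  # NB size parameter: Var = mu + dispersion * mu^2
    counts = rng.negative_binomial(k, k / (k + mu)).astype(np.int64)
    lib = rng.choice(np.asarray(cfg.library_sizes, dtype=np.int64), size=n)
    if cfg.scale_library:
        scaled = np.empty_like(counts)
        for j in range(n):
            tot = counts[j].sum()
            if tot == 0:
                raise ValueError(f"sample {j} drew an all-zero count vector")
            scaled[j] = rng.multinomial(lib[j], counts[j] / tot)
        counts = scaled
    return NbSimData(
        counts=counts,
        X=X,
        C=C,
        library_sizes=lib,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        delta=delta,
    )


def pathway_blocks(n_genes: int, size: int) -> list[np.ndarray]:
    """Partition gene indices into consecutive pathways of ``size`` genes."""
    n_path = n_genes // size
    return [np.arange(i * size, (i + 1) * size) for i in range(n_path)]
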