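"""Mean/variance adjustment of pathway expression.

Differential co-expression inference starts from *standardized* residuals:
per gene, the expression values are adjusted for the mean effects of the risk
factor(s), covariates and batch variables, and then divided by an estimate of
the conditional standard deviation.  Removing the variance effect of the risk
factor is what prevents a purely variance-specific effect from masquerading as
differential co-expression.

Three conditional-variance estimators are provided:

``groupwise``
    per-gene sample variance within each level of a categorical risk factor;
``dglm``
    a double generalized linear model — iteratively reweighted least squares
    for the mean paired with a gamma GLM (log link) of the squared residuals
    on the variance covariates — for continuous or discrete risk factors;
``constant``
    a single pooled variance per gene (no variance effects assumed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignInputs",
    "ResidualSet",
    "fit_mean_model",
    "estimate_variance_groupwise",
    "fit_double_glm",
    "standardize",
]


@dataclass
class DesignInputs:
    """Validated inputs for one pathway test.

    Parameters
    ----------
    Y
        Expression matrix, ``n`` samples x ``r`` genes, approximately normal
        scale (e.g. logCPM or log2(count + offset)).
    X
        Risk-factor table, ``n`` x ``L``.  Columns named in ``categorical``
        are treated as factors (>= 2 levels, each with >= 2 samples); all
        other columns are treated as continuous/discrete numeric.
    C
        Optional covariate table (``n`` x ``l_C``).
    M
        Optional batch-variable table (``n`` x ``l_M``).
    """

    Y: np.ndarray
    X: pd.DataFrame
    C: pd.DataFrame | None = None
    M: pd.DataFrame | None = None
    categorical: tuple[str, ...] = ()
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be a 2-D samples x genes matrix")
        n, r = self.Y.shape
        if r < 2:
            raise ValueError(f"need at least 2 genes to form a gene pair, got r={r}")
        if not isinstance(self.X, pd.DataFrame):
            self.X = pd.DataFrame(np.asarray(self.X), columns=None)
            self.X.columns = [f"x{i}" for i in range(self.X.shape[1])]
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match Y")
        for tab, name in ((self.C, "C"), (self.M, "M")):
            if tab is not None and tab.shape[0] != n:
                raise ValueError(f"{name} row count does not match Y")
        unknown = set(self.categorical) - set(self.X.columns)
        if unknown:
            raise ValueError(f"categorical columns not in X: {sorted(unknown)}")
        if not np.isfinite(self.Y).all():
            raise ValueError("Y contains missing or non-finite values")
        for col in self.X.columns:
            if col in self.categorical:
                counts = self.X[col].value_counts()
                if len(counts) < 2:
                    raise ValueError(f"categorical risk factor {col!r} has < 2 levels")
                small = counts[counts < 2]
                if len(small):
                    raise ValueError(
                        f"categorical risk factor {col!r} has levels with < 2 "
                        f"samples: {list(small.index)}"
                    )
            else:
                vals = pd.to_numeric(self.X[col], errors="raise").to_numpy(float)
                if not np.isfinite(vals).all():
                    raise ValueError(f"risk factor {col!r} has missing values")
        for tab, name in ((self.C, "C"), (self.M, "M")):
            if tab is not None and not np.isfinite(tab.to_numpy(float)).all():
                raise ValueError(f"{name} contains missing or non-finite values")
        if not self.gene_ids:
            self.gene_ids = tuple(f"g{k}" for k in range(r))
        if len(self.gene_ids) != r:
            raise ValueError("gene_ids length does not match Y columns")

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Y.shape[1]

    @property
    def all_risk_categorical(self) -> bool:
        return set(self.X.columns) == set(self.categorical)

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Column-augmented mean design ``[1 | X | C | M]``.

        Categorical risk-factor columns are one-hot encoded with the first
        level as reference.  Raises with the names of collinear columns if
        the design is rank deficient.
        """
        cols: list[np.ndarray] = [np.ones(self.n_samples)]
        names: list[str] = ["intercept"]
        for col in self.X.columns:
            if col in self.categorical:
                dummies = pd.get_dummies(self.X[col], drop_first=True)
                for lev in dummies.columns:
                    cols.append(dummies[lev].to_numpy(float))
                    names.append(f"X:{col}[{lev}]")
            else:
                cols.append(pd.to_numeric(self.X[col]).to_numpy(float))
                names.append(f"X:{col}")
        for tab, tag in ((self.C, "C"), (self.M, "M")):
            if tab is not None:
                for col in tab.columns:
                    cols.append(tab[col].to_numpy(float))
                    names.append(f"{tag}:{col}")
        D = np.column_stack(cols)
        if self.n_samples <= D.shape[1]:
            raise ValueError(
                f"n={self.n_samples} samples cannot identify {D.shape[1]} "
                "mean-model columns"
            )
        _check_full_rank(D, names)
        return D, names

    def risk_numeric(self) -> tuple[np.ndarray, list[str]]:
        """Risk-factor columns as a numeric matrix (one-hot for categoricals)."""
        cols: list[np.ndarray] = []
        names: list[str] = []
        for col in self.X.columns:
            if col in self.categorical:
                dummies = pd.get_dummies(self.X[col], drop_first=True)
                for lev in dummies.columns:
                    cols.append(dummies[lev].to_numpy(float))
                    names.append(f"{col}[{lev}]")
            else:
                cols.append(pd.to_numeric(self.X[col]).to_numpy(float))
                names.append(col)
        return np.column_stack(cols), names

    def group_codes(self) -> np.ndarray:
        """Integer group labels from the interaction of categorical risk columns."""
        if not self.categorical:
            raise ValueError("no categorical risk-factor columns")
        key = self.X[list(self.categorical)].astype(str).agg("|".join, axis=1)
        return pd.factorize(key)[0]


def _check_full_rank(D: np.ndarray, names: Sequence[str], tol: float = 1e-10) -> None:
    # QR with pivoting exposes which columns are in the span of the others.
    from scipy.linalg import qr

    _, R, piv = qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = tol * max(diag[0], 1.0)
    bad = diag < thresh
    if bad.any():
        offenders = [names[piv[i]] for i in np.nonzero(bad)[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {offenders}")


@dataclass
class ResidualSet:
    """Residuals and conditional-variance estimates for one pathway."""

    design: DesignInputs
    e: np.ndarray
    mean_coef: pd.DataFrame
    fitted: np.ndarray
    s: np.ndarray | None = None
    e_std: np.ndarray | None = None
    variance_model: str | None = None
    var_coef: pd.DataFrame | None = None
    converged: bool = True
    n_iter: int = 0


def fit_mean_model(design: DesignInputs) -> ResidualSet:
    """Per-gene least-squares fit of the mean model ``[1 | X | C | M]``.

    Returns a :class:`ResidualSet` with raw residuals ``e`` and fitted
    coefficients; conditional standard deviations are left unset.
    """
    D, names = design.design_matrix()
    coef, _, _, _ = np.linalg.lstsq(D, design.Y, rcond=None)
    fitted = D @ coef
    e = design.Y - fitted
    mean_coef = pd.DataFrame(coef, index=names, columns=list(design.gene_ids))
    return ResidualSet(design=design, e=e, mean_coef=mean_coef, fitted=fitted)


def _groupwise_sd(e: np.ndarray, codes: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    s = np.empty_like(e)
    for g in np.unique(codes):
        idx = np.nonzero(codes == g)[0]
        if idx.size < 2:
            raise ValueError(f"group {g} has < 2 samples")
        v = e[idx].var(axis=0, ddof=1)
        if np.any(v <= 0):
            k = int(np.argmax(v <= 0))
            raise ValueError(
                f"zero within-group variance for gene {gene_ids[k]!r} in group {g}"
            )
        s[idx] = np.sqrt(v)
    return s


def estimate_variance_groupwise(residuals: ResidualSet, x_cat: str | None = None) -> ResidualSet:
    """Fill conditional SDs with within-group sample SDs of the residuals.

    ``x_cat`` names a categorical risk-factor column; by default the
    interaction of all categorical risk columns defines the groups.  The
    unbiased ``n_g - 1`` denominator is used.
    """
    design = residuals.design
    if x_cat is not None:
        if x_cat not in design.categorical:
            raise ValueError(f"{x_cat!r} is not a categorical risk-factor column")
        codes = pd.factorize(design.X[x_cat].astype(str))[0]
    else:
        codes = design.group_codes()
    residuals.s = _groupwise_sd(residuals.e, codes, design.gene_ids)
    residuals.variance_model = "groupwise"
    return residuals


# ---------------------------------------------------------------------------
# batched double GLM
# ---------------------------------------------------------------------------

_ETA_CLIP = 60.0  # log-variance bound; exp(60) is far beyond any sane variance


def _gamma_logfit(
    Dv: np.ndarray,
    gram_inv: np.ndarray,
    y: np.ndarray,
    eta: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Gamma GLM with log link, all genes at once.

    For the log link the IRLS working weights are constant, so each Fisher
    scoring step is ``theta += (Dv' Dv)^-1 Dv' ((y - mu)/mu)``.
    """
    m = Dv.shape[1]
    r = y.shape[1]
    if eta is None:
        theta = np.zeros((m, r))
        theta[0] = np.log(y.mean(axis=0))
        eta = Dv @ theta
    else:
        theta = gram_inv @ (Dv.T @ eta)  # recover coefficients from warm start
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        theta = theta + gram_inv @ (Dv.T @ (y / mu - 1.0))
        eta_new = np.clip(Dv @ theta, -_ETA_CLIP, _ETA_CLIP)
        delta = np.abs(eta_new - eta).max()
        eta = eta_new
        if delta < tol:
            break
    return theta, eta


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    ratio = y / mu
    return float(2.0 * np.sum(ratio - np.log(ratio) - 1.0))


def _dglm_batch(
    Y: np.ndarray,
    Dm: np.ndarray,
    Dv: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-6,
    Q: np.ndarray | None = None,
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray, np.ndarray, bool, int]:
    """Double GLM for all genes sharing the same designs.

    Alternates (i) weighted least squares for the mean with weights
    ``1/sigma^2`` and (ii) a gamma GLM (log link) of squared residuals on
    ``Dv``, until the relative change in gamma deviance is below ``tol``.
    ``max_iter=0`` returns the unweighted OLS fit with a single variance fit,
    i.e. weights fixed at one.

    Returns ``(coef, e, s, theta, converged, n_iter)``; ``Q`` may supply a
    precomputed orthonormal basis of ``Dm`` to skip the initial least-squares
    solve (``coef`` is then ``None`` when ``max_iter=0``).
    """
    if Q is not None:
        coef = None
        e = Y - Q @ (Q.T @ Y)
    else:
        coef, _, _, _ = np.linalg.lstsq(Dm, Y, rcond=None)
        e = Y - Dm @ coef
    gram_inv = np.linalg.inv(Dv.T @ Dv)
    y2 = np.maximum(e**2, 1e-30)
    theta, eta = _gamma_logfit(Dv, gram_inv, y2)
    if max_iter == 0:
        return coef, e, np.exp(0.5 * eta), theta, True, 0

    dev_old = _gamma_deviance(y2, np.exp(eta))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.exp(-eta)  # 1 / sigma^2
        # per-gene weighted normal equations, batched via matmul
        Dw = Dm.T[None, :, :] * w.T[:, None, :]        # (r, p, n)
        A = Dw @ Dm                                     # (r, p, p)
        b = (Dm.T @ (w * Y)).T                          # (r, p)
        coef = np.linalg.solve(A, b[..., None])[..., 0].T
        e = Y - Dm @ coef
        y2 = np.maximum(e**2, 1e-30)
        theta, eta = _gamma_logfit(Dv, gram_inv, y2, eta=eta)
        dev = _gamma_deviance(y2, np.exp(eta))
        if abs(dev - dev_old) <= tol * max(abs(dev_old), 1e-12):
            converged = True
            break
        dev_old = dev
    if not converged:
        warnings.warn(
            f"double GLM did not converge in {max_iter} iterations; "
            "returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return coef, e, np.exp(0.5 * eta), theta, converged, it


def variance_design(
    design: DesignInputs, variance_covariates: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Variance-model design ``[1 | covariates]`` for the double GLM.

    By default all risk-factor columns enter the variance model; covariate or
    batch columns can be added by name (prefix-free lookup across X, C, M).
    """
    Xnum, xnames = design.risk_numeric()
    if variance_covariates is None:
        cols = [Xnum[:, i] for i in range(Xnum.shape[1])]
        names = list(xnames)
    else:
        pool: dict[str, np.ndarray] = {
            name: Xnum[:, i] for i, name in enumerate(xnames)
        }
        for tab in (design.C, design.M):
            if tab is not None:
                for col in tab.columns:
                    pool[col] = tab[col].to_numpy(float)
        cols, names = [], []
        for name in variance_covariates:
            if name not in pool:
                raise ValueError(f"unknown variance covariate {name!r}")
            cols.append(pool[name])
            names.append(name)
    Dv = np.column_stack([np.ones(design.n_samples)] + cols)
    return Dv, ["intercept"] + names


def fit_double_glm(
    design: DesignInputs,
    variance_covariates: Sequence[str] | None = None,
    max_iter: int = 25,
    tol: float = 1e-6,
) -> ResidualSet:
    """Fit mean and log-variance models jointly (double GLM) per gene.

    The mean model is the full ``[1 | X | C | M]`` design; the variance model
    regresses squared residuals on ``[1 | variance_covariates]`` with a gamma
    GLM and log link, so fitted variances are positive by construction.
    """
    Dm, mnames = design.design_matrix()
    Dv, vnames = variance_design(design, variance_covariates)
    coef, e, s, theta, converged, n_iter = _dglm_batch(
        design.Y, Dm, Dv, max_iter=max_iter, tol=tol
    )
    genes = list(design.gene_ids)
    return ResidualSet(
        design=design,
        e=e,
        mean_coef=pd.DataFrame(coef, index=mnames, columns=genes),
        fitted=design.Y - e,
        s=s,
        variance_model="dglm",
        var_coef=pd.DataFrame(theta, index=vnames, columns=genes),
        converged=converged,
        n_iter=n_iter,
    )


def estimate_variance_constant(residuals: ResidualSet) -> ResidualSet:
    """Single pooled variance per gene (degrees of freedom = n - p)."""
    design = residuals.design
    p = residuals.mean_coef.shape[0]
    dof = max(design.n_samples - p, 1)
    v = (residuals.e**2).sum(axis=0) / dof
    if np.any(v <= 0):
        k = int(np.argmax(v <= 0))
        raise ValueError(f"zero residual variance for gene {design.gene_ids[k]!r}")
    residuals.s = np.broadcast_to(np.sqrt(v), residuals.e.shape).copy()
    residuals.variance_model = "constant"
    return residuals


def standardize(residuals: ResidualSet) -> ResidualSet:
    """Divide residuals by their conditional SDs: ``e_std = e / s``."""
    if residuals.s is None:
        raise ValueError("conditional SDs not estimated yet")
    if np.any(residuals.s <= 0):
        raise ValueError("non-positive conditional SD")
    residuals.e_std = residuals.e / residuals.s
    return residuals
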