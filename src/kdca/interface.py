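"""File formats, pathway iteration and study-level orchestration.

Expression matrices are TSV with samples in rows (first column = sample ID)
and genes in columns; sample tables are TSV keyed by sample ID with the roles
of columns (risk factor / covariate / batch) declared at call time or in a
YAML config.  Pathways are read from GMT (set name, description, member
genes).  ``run_study`` iterates pathways, runs the kernel test with a
deterministic per-pathway sub-seed, and attaches Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .inference import DEFAULT_KERNELS, kdca_test
from .residualize import DesignInputs

__all__ = [
    "PathwaySet",
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "read_gmt",
    "transform_counts",
    "bh_fdr",
    "storey_qvalue",
    "build_design",
    "run_study",
]

logger = logging.getLogger("kdca")

DEFAULT_MIN_PATHWAY_SIZE = 5


@dataclass
class PathwaySet:
    """Named gene sets with a minimum-size filter record."""

    pathways: dict[str, list[str]]
    source: str = ""
    min_size: int = DEFAULT_MIN_PATHWAY_SIZE
    excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pathways)

    def items(self):
        return self.pathways.items()


def read_expression(path) -> pd.DataFrame:
    """Samples x genes TSV; first column holds sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"no gene columns in {path}")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_samples(path) -> pd.DataFrame:
    """Sample table TSV keyed by sample ID."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path, min_size: int = DEFAULT_MIN_PATHWAY_SIZE) -> PathwaySet:
    """Parse a GMT file, deduplicating genes and dropping small pathways."""
    pathways: dict[str, list[str]] = {}
    excluded: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: malformed GMT line")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "pathway %s: %d duplicate gene(s) removed",
                    name,
                    len(genes) - len(deduped),
                )
            if len(deduped) < min_size:
                logger.info(
                    "pathway %s excluded: size %d < min_size %d",
                    name,
                    len(deduped),
                    min_size,
                )
                excluded.append(name)
                continue
            pathways[name] = deduped
    return PathwaySet(
        pathways=pathways, source=str(path), min_size=min_size, excluded=excluded
    )


def transform_counts(
    counts: pd.DataFrame | np.ndarray, offset: float = 2.0
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """``log2(count + offset)`` plus the log library-size covariate.

    Returns the transformed matrix and per-sample ``log(total counts)``,
    intended as a fixed mean covariate.
    """
    vals = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    if np.any(vals < 0):
        raise ValueError("negative counts")
    log_lib = np.log(vals.sum(axis=1))
    out = np.log2(vals + offset)
    if isinstance(counts, pd.DataFrame):
        out = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out, log_lib


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalue(p: Sequence[float], lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed lambda for the pi0 estimate."""
    p = np.asarray(p, dtype=float)
    m = p.size
    pi0 = min(1.0, np.count_nonzero(p > lambda_) / (m * (1.0 - lambda_)))
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pi0 * m * p[i] / rank)
        q[i] = running
    return q


def build_design(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    risk_factors: Sequence[str],
    covariates: Sequence[str] = (),
    batch: Sequence[str] = (),
    categorical: Sequence[str] = (),
    genes: Sequence[str] | None = None,
) -> DesignInputs:
    """Assemble validated :class:`DesignInputs` from expression + sample tables.

    Sample IDs must match between the two tables (order taken from the
    expression matrix); a mismatch raises with the offending IDs.
    """
    missing = expression.index.difference(samples.index)
    extra = samples.index.difference(expression.index)
    if len(missing) or len(extra):
        raise ValueError(
            "sample-ID mismatch between expression and sample table; "
            f"missing from samples: {list(missing[:5])}, "
            f"missing from expression: {list(extra[:5])}"
        )
    samples = samples.loc[expression.index]
    cols = list(expression.columns) if genes is None else list(genes)
    Y = expression[cols].to_numpy(float)
    X = samples[list(risk_factors)].copy()
    C = samples[list(covariates)].astype(float) if covariates else None
    M = samples[list(batch)].astype(float) if batch else None
    return DesignInputs(
        Y=Y,
        X=X,
        C=C,
        M=M,
        categorical=tuple(c for c in categorical if c in risk_factors),
        gene_ids=tuple(cols),
    )


def pathway_subseed(master_seed: int, name: str) -> int:
    """Deterministic per-pathway sub-seed; independent of pathway order."""
    digest = hashlib.blake2b(f"{master_seed}|{name}".encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_study(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    pathways: PathwaySet,
    risk_factors: Sequence[str],
    covariates: Sequence[str] = (),
    batch: Sequence[str] = (),
    categorical: Sequence[str] = (),
    kernels=DEFAULT_KERNELS,
    B: int = 1000,
    seed: int = 17,
    variance_mode: str = "auto",
    mode: str = "permutation",
    include_eigengene: bool = False,
    early_stop: bool = False,
    alpha: float = 0.05,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Test every pathway and return the study result table.

    One row per tested pathway: per-kernel p-values, the combined p-value,
    the optional eigengene p-value, and BH q-values on the combined column.
    Pathways with fewer than two genes present in the expression matrix are
    skipped (recorded in ``result.attrs['skipped']``); per-pathway failures
    are logged and do not abort the run.
    """
    n_path = len(pathways)
    if n_path and B < n_path / alpha:
        warnings.warn(
            f"B={B} permutations is below R/alpha = {n_path / alpha:.0f} for "
            f"R={n_path} pathways at level {alpha}; the smallest achievable "
            "p-value may be too coarse to control the error rate",
            UserWarning,
            stacklevel=2,
        )
    gene_pool = set(expression.columns)
    tasks = []
    skipped: list[tuple[str, str]] = []
    for name, genes in pathways.items():
        present = [g for g in genes if g in gene_pool]
        if len(present) < len(genes):
            logger.info(
                "pathway %s: %d of %d genes absent from expression matrix",
                name,
                len(genes) - len(present),
                len(genes),
            )
        if len(present) < 2:
            logger.warning("pathway %s skipped: fewer than 2 genes present", name)
            skipped.append((name, "fewer than 2 genes present"))
            continue
        tasks.append((name, present))

    def _one(name: str, present: list[str]):
        sub = pathway_subseed(seed, name)
        design = build_design(
            expression,
            samples,
            risk_factors,
            covariates,
            batch,
            categorical,
            genes=present,
        )
        res = kdca_test(
            design,
            kernels=kernels,
            B=B,
            seed=sub,
            variance_mode=variance_mode,
            mode=mode,
            include_eigengene=include_eigengene,
            early_stop=early_stop,
        )
        row = {"pathway": name, "tested_size": len(present)}
        for pk in res.per_kernel:
            row[f"p_{pk.kernel_name}"] = pk.p_empirical
        row["p_combined"] = res.p_combined
        if res.eigengene is not None:
            row["p_eigengene"] = res.eigengene.p_empirical
        row["B"] = pk.B
        row["converged"] = res.diagnostics.get("dglm_converged", True)
        return row

    if n_jobs != 1 and tasks:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(_one)(n, g) for n, g in tasks)
    else:
        rows = []
        for name, present in tasks:
            try:
                rows.append(_one(name, present))
            except Exception as err:
                logger.error("pathway %s failed: %s", name, err)
                skipped.append((name, f"error: {err}"))
    table = pd.DataFrame(rows)
    if len(table):
        table["q_combined"] = bh_fdr(table["p_combined"].to_numpy())
        table = table.sort_values("p_combined", kind="stable").reset_index(drop=True)
    table.attrs["skipped"] = skipped
    table.attrs["seed"] = seed
    return table
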