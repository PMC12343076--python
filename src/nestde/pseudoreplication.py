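"""Closed-form pseudoreplication arithmetic and an empirical ICC estimator.

Under the mixed-effect model

    Y_cijk = mu_ck + b_cik + eps_cijk,
    b_cik ~ N(0, sigma2_b),  eps_cijk ~ N(0, nu2_eps),

cells j within a sample i share the random sample effect b, so two cells of
the same sample are correlated with intraclass correlation
rho = sigma2_b / (sigma2_b + nu2_eps). Treating the n cells of a sample as
independent replicates understates the variance of condition means by the
factor 1 + (n - 1) * rho and inflates the nominal degrees of freedom from
2N - 2 (samples are the replicates) to 2Nn - 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import CountMatrix, NestedDesign

logger = logging.getLogger("nestde")


@dataclass
class MixedModelSpec:
    """Parameters of the two-level Gaussian mixed model for one gene."""

    mu_c: tuple = (0.0, 0.0)  # fixed condition means
    sigma2_b: float = 0.0  # between-sample variance
    nu2_eps: float = 1.0  # within-sample (cell) residual variance
    N: int = 1  # samples per condition
    n: int = 1  # cells per sample

    def __post_init__(self) -> None:
        if self.sigma2_b < 0 or self.nu2_eps < 0:
            raise ValueError("variances must be nonnegative")
        if self.N < 1 or self.n < 1:
            raise ValueError("N and n must be at least 1")


def icc(sigma2_b: float, nu2_eps: float) -> float:
    """Intraclass correlation rho = sigma2_b / (sigma2_b + nu2_eps)."""
    if sigma2_b < 0 or nu2_eps < 0:
        raise ValueError("variances must be nonnegative")
    total = sigma2_b + nu2_eps
    if total == 0:
        raise ValueError("ICC undefined when both variance components are zero")
    return sigma2_b / total


def total_variance(sigma2_b: float, nu2_eps: float) -> float:
    if sigma2_b < 0 or nu2_eps < 0:
        raise ValueError("variances must be nonnegative")
    return sigma2_b + nu2_eps


def variance_inflation(n: int, rho: float) -> float:
    """Factor 1 + (n - 1) * rho by which within-sample correlation inflates
    the variance of a mean over n cells."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    return 1.0 + (n - 1) * rho


def var_diff_means(spec: MixedModelSpec, rho: float | None = None) -> float:
    """Variance of the difference-in-means estimator between two conditions.

    Var[Ybar_1 - Ybar_2] = (2 / (N n)) * (sigma2_b + nu2_eps) * (1 + (n-1) rho).
    If ``rho`` is omitted it is computed from the spec's variance components.
    """
    if rho is None:
        rho = icc(spec.sigma2_b, spec.nu2_eps)
    total = total_variance(spec.sigma2_b, spec.nu2_eps)
    return 2.0 / (spec.N * spec.n) * total * variance_inflation(spec.n, rho)


def degrees_of_freedom(N: int, n: int) -> tuple[int, int]:
    """(naive, correct) df for a two-sample comparison: 2Nn - 2 treats every
    cell as a replicate; 2N - 2 treats the sample as the replicate."""
    if N < 1 or n < 1:
        raise ValueError("N and n must be at least 1")
    return 2 * N * n - 2, 2 * N - 2


# ---------------------------------------------------------------------------
# Empirical ICC from data
# ---------------------------------------------------------------------------


def log1p_cpm(values: np.ndarray) -> np.ndarray:
    """log(1 + counts-per-million) per column of a gene × cell dense array."""
    values = np.asarray(values, dtype=float)
    totals = values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("columns with zero total cannot be CPM-normalized")
    return np.log1p(values / totals * 1e6)


def empirical_icc(
    cm: CountMatrix | np.ndarray,
    design: NestedDesign,
    transform: bool = True,
    within_batch: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-gene one-way ANOVA ICC(1) with samples as groups, plus the pooled
    (median) estimate.

    With ``within_batch=True`` (default) each gene is centered per batch
    before the ANOVA and the between-group degrees of freedom are summed
    over batches, so multiplicative batch effects do not masquerade as
    sample-level correlation and the estimate isolates the within-sample
    dependence of cells. Uses the n0 correction for unbalanced group sizes
    (n0 = (T - sum n_i^2 / T) / df_between). Estimates are clipped to
    [-1/(n0 - 1), 1]. Samples with a single cell are excluded. By default
    values are log1p-CPM transformed first.
    """
    if isinstance(cm, CountMatrix):
        x = cm.to_dense().astype(float)
        cell_ids = cm.cell_ids
    else:
        x = np.asarray(cm, dtype=float)
        cell_ids = np.array(design.cells, dtype=object)
        if x.shape[1] != len(cell_ids):
            raise ValueError("matrix columns must match design cells")
    if transform:
        x = log1p_cpm(x)

    sample_of = np.array([design.cell_to_sample[c] for c in cell_ids], dtype=object)
    samples, sample_idx = np.unique(sample_of, return_inverse=True)
    sizes = np.bincount(sample_idx, minlength=len(samples))
    usable = sizes >= 2
    if usable.sum() < 2:
        raise ValueError("need at least two samples with >= 2 cells")
    if not usable.all():
        logger.warning(
            "excluding %d single-cell sample(s) from ICC estimation",
            (~usable).sum(),
        )
        keep_cells = usable[sample_idx]
        x = x[:, keep_cells]
        cell_ids = cell_ids[keep_cells]
        sample_of = sample_of[keep_cells]
        samples, sample_idx = np.unique(sample_of, return_inverse=True)
        sizes = np.bincount(sample_idx)

    if within_batch:
        batch_of_cell = np.array(
            [design.sample_to_batch[s] for s in sample_of], dtype=object
        )
        batch_ids = np.unique(batch_of_cell)
    else:
        batch_of_cell = np.full(len(sample_of), "all", dtype=object)
        batch_ids = np.array(["all"], dtype=object)

    G = x.shape[0]
    ssb = np.zeros(G)
    ssw = np.zeros(G)
    df_between = 0
    n_groups = 0
    t_used = 0
    sum_sq_sizes = 0
    for batch in batch_ids:
        in_batch = batch_of_cell == batch
        xb = x[:, in_batch]
        sb_idx = sample_idx[in_batch]
        _, sb_idx = np.unique(sb_idx, return_inverse=True)
        b_sizes = np.bincount(sb_idx)
        if len(b_sizes) < 2:
            continue  # a batch with one sample contributes no between-group df
        group_sums = np.zeros((G, len(b_sizes)))
        np.add.at(group_sums.T, sb_idx, xb.T)
        group_means = group_sums / b_sizes
        batch_mean = xb.mean(axis=1, keepdims=True)
        ssb += (b_sizes * (group_means - batch_mean) ** 2).sum(axis=1)
        ssw += ((xb - group_means[:, sb_idx]) ** 2).sum(axis=1)
        df_between += len(b_sizes) - 1
        n_groups += len(b_sizes)
        t_used += int(b_sizes.sum())
        sum_sq_sizes += int((b_sizes**2).sum())
    if df_between < 1:
        raise ValueError("no batch contains two samples with >= 2 cells")
    msb = ssb / df_between
    msw = ssw / (t_used - n_groups)
    n0 = (t_used - sum_sq_sizes / t_used) / df_between

    denom = msb + (n0 - 1) * msw
    with np.errstate(divide="ignore", invalid="ignore"):
        icc1 = np.where(denom > 0, (msb - msw) / denom, 0.0)
    icc1 = np.clip(icc1, -1.0 / (n0 - 1), 1.0)
    pooled = float(np.median(icc1))
    return icc1, pooled
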