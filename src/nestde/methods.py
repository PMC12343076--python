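"""Differential-expression tests for nested single-cell data.

Three tests are implemented:

* ``permutation_test`` — pseudobulk (per-sample sum, CPM-normalized)
  difference in condition means, with the null obtained by reshuffling
  sample-level condition labels; exhaustive enumeration of all distinct
  label assignments when feasible, Monte Carlo otherwise. The smallest
  attainable p-value is 1/n.
* ``hierarchical_bootstrap`` — resampling that respects the hierarchy:
  within each condition and each batch, samples are drawn with replacement
  and a fixed number of cells is drawn with replacement from each drawn
  sample, with every batch contributing equally many cells; the p-value is
  the smaller of the two directional exceedance counts over n iterations,
  floored at 1/n, with adaptive escalation of n for genes at the floor.
* ``cell_t_test`` — Welch's t-test treating cells as replicates, included
  as the pseudoreplication-biased baseline.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.stats

from .core import CountMatrix, DEResult, NestedDesign, PseudobulkMatrix

logger = logging.getLogger("nestde")

TINY_P = 1e-300  # p-values are reported in (0, 1]


@dataclass
class PermutationConfig:
    n_perm: int = 10_000
    exhaustive_threshold: int = 20_000
    statistic: str = "diff_means"
    normalization: str = "cpm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if self.statistic != "diff_means":
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class BootstrapConfig:
    n_boot_initial: int = 10_000
    n_boot_escalated: int = 100_000
    cells_per_draw: int = 100
    hierarchy: tuple = ("batch", "sample", "cell")
    normalization: str = "cpm"
    two_sided_double: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot_initial < 1:
            raise ValueError("n_boot_initial must be at least 1")
        if self.n_boot_escalated <= self.n_boot_initial:
            raise ValueError("n_boot_escalated must exceed n_boot_initial")
        if self.cells_per_draw < 1:
            raise ValueError("cells_per_draw must be at least 1")


# ---------------------------------------------------------------------------
# Pseudobulk aggregation and normalization
# ---------------------------------------------------------------------------


def pseudobulk(
    cm: CountMatrix, design: NestedDesign, agg: str = "sum"
) -> PseudobulkMatrix:
    """Aggregate cell counts per sample (sum by default; mass-conserving)."""
    if agg not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation {agg!r}")
    samples = design.samples
    sample_pos = {s: i for i, s in enumerate(samples)}
    cell_sample = np.array(
        [sample_pos[design.cell_to_sample[c]] for c in cm.cell_ids]
    )
    n_cells = np.bincount(cell_sample, minlength=len(samples))
    empty = n_cells == 0
    if empty.any():
        logger.warning(
            "dropping %d sample(s) with no cells: %s",
            empty.sum(),
            [samples[i] for i in np.flatnonzero(empty)][:5],
        )
    # indicator matrix cells × samples
    ind = sp.csr_matrix(
        (
            np.ones(cm.n_cells),
            (np.arange(cm.n_cells), cell_sample),
        ),
        shape=(cm.n_cells, len(samples)),
    )
    values = np.asarray((cm.counts @ ind).todense(), dtype=float)
    keep = ~empty
    values = values[:, keep]
    kept_samples = [s for s, k in zip(samples, keep) if k]
    if agg == "mean":
        values = values / n_cells[keep]
    return PseudobulkMatrix(
        values=values,
        gene_ids=cm.gene_ids,
        sample_ids=np.array(kept_samples, dtype=object),
        sample_to_condition={
            s: design.sample_to_condition[s] for s in kept_samples
        },
        sample_to_batch={s: design.sample_to_batch[s] for s in kept_samples},
    )


def normalize_pseudobulk(pb: PseudobulkMatrix, mode: str = "cpm") -> PseudobulkMatrix:
    """Depth-normalize pseudobulk columns: 'cpm' scales each sample to 1e6
    total, 'log1p_cpm' additionally applies log(1+x), 'none' is identity."""
    if mode == "none":
        return pb
    totals = pb.values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("zero-total pseudobulk column cannot be normalized")
    values = pb.values / totals * 1e6
    if mode == "log1p_cpm":
        values = np.log1p(values)
    elif mode != "cpm":
        raise ValueError(f"unknown normalization {mode!r}")
    return PseudobulkMatrix(
        values=values,
        gene_ids=pb.gene_ids,
        sample_ids=pb.sample_ids,
        sample_to_condition=dict(pb.sample_to_condition),
        sample_to_batch=dict(pb.sample_to_batch),
    )


def normalize_cells(cm: CountMatrix, mode: str = "cpm") -> np.ndarray:
    """Per-cell normalized dense matrix (gene × cell, float32)."""
    x = cm.to_dense().astype(np.float64)
    if mode == "raw" or mode == "none":
        return x.astype(np.float32)
    totals = x.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total count cannot be CPM-normalized")
    x = x / totals * 1e6
    if mode == "log1p_cpm":
        x = np.log1p(x)
    elif mode != "cpm":
        raise ValueError(f"unknown normalization {mode!r}")
    return x.astype(np.float32)


# ---------------------------------------------------------------------------
# Permutation test (pseudobulk)
# ---------------------------------------------------------------------------


def _condition_weights(cond_is_1: np.ndarray) -> np.ndarray:
    """Weight vector w with V @ w = mean(cond1) - mean(cond2)."""
    n1 = int(cond_is_1.sum())
    n2 = int((~cond_is_1).sum())
    return np.where(cond_is_1, 1.0 / n1, -1.0 / n2)


def permutation_test(pb: PseudobulkMatrix, cfg: PermutationConfig) -> DEResult:
    """Two-sided pseudobulk permutation test on the difference in means.

    Sample-level condition labels are reshuffled; when the number of
    distinct label assignments is at most ``cfg.exhaustive_threshold`` all
    of them are enumerated (the observed one included), otherwise
    ``cfg.n_perm`` random shuffles are drawn and p = max(b, 1)/n.
    """
    conds = pb.conditions
    if len(conds) != 2:
        raise ValueError("permutation test requires exactly two conditions")
    cond_is_1 = pb.condition_mask(conds[0])
    n1, n2 = int(cond_is_1.sum()), int((~cond_is_1).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both conditions need at least one sample")
    if min(n1, n2) < 2:
        logger.warning("a condition has a single sample; the test has low power")

    V = normalize_pseudobulk(pb, cfg.normalization).values
    S = V.shape[1]
    delta_obs = V @ _condition_weights(cond_is_1)
    # threshold with numerical-noise slack: BLAS evaluates the matrix
    # product in a different order than the observed matvec, so exact ties
    # (the observed assignment, its mirror, constant genes) must not be
    # lost to rounding
    tol = 1e-9 * np.max(np.abs(V), axis=1, initial=0.0)
    thresh = np.abs(delta_obs) - tol

    n_distinct = math.comb(S, n1)
    block = 2000
    if n_distinct <= cfg.exhaustive_threshold:
        b = np.zeros(V.shape[0], dtype=np.int64)
        combos = itertools.combinations(range(S), n1)
        while True:
            chunk = list(itertools.islice(combos, block))
            if not chunk:
                break
            W = np.empty((S, len(chunk)))
            for j, combo in enumerate(chunk):
                mask = np.zeros(S, dtype=bool)
                mask[list(combo)] = True
                W[:, j] = _condition_weights(mask)
            null = V @ W  # genes × assignments
            b += (np.abs(null) >= thresh[:, None]).sum(axis=1)
        n_used = n_distinct
        p = b / n_used  # observed assignment is enumerated, so b >= 1
    else:
        rng = np.random.default_rng(cfg.seed)
        n_used = cfg.n_perm
        b = np.zeros(V.shape[0], dtype=np.int64)
        for start in range(0, n_used, block):
            nb = min(block, n_used - start)
            W = np.empty((S, nb))
            for j in range(nb):
                W[:, j] = _condition_weights(
                    cond_is_1[rng.permutation(S)]
                )
            null = V @ W
            b += (np.abs(null) >= thresh[:, None]).sum(axis=1)
        p = np.maximum(b, 1) / n_used
    return DEResult.from_stats(
        pb.gene_ids, delta_obs, p, method="permutation", n_resamples_used=n_used
    )


# ---------------------------------------------------------------------------
# Hierarchical bootstrap
# ---------------------------------------------------------------------------


def _condition_strata(
    cm: CountMatrix, design: NestedDesign
) -> tuple[list, dict]:
    """Shared batches and, per (condition, batch), the per-sample cell-index
    arrays (positions into cm's columns)."""
    cell_pos = {c: i for i, c in enumerate(cm.cell_ids)}
    cells_by_sample = {s: [] for s in design.samples}
    for c in cm.cell_ids:
        cells_by_sample[design.cell_to_sample[c]].append(cell_pos[c])
    conds = design.conditions
    batches_per_cond = {}
    for cond in conds:
        batches_per_cond[cond] = {
            design.sample_to_batch[s]
            for s in design.samples_of_condition(cond)
            if cells_by_sample[s]
        }
    shared = sorted(batches_per_cond[conds[0]] & batches_per_cond[conds[1]])
    dropped = (batches_per_cond[conds[0]] | batches_per_cond[conds[1]]) - set(shared)
    if dropped:
        logger.warning(
            "batches present in only one condition excluded from bootstrap: %s",
            sorted(dropped),
        )
    if not shared:
        raise ValueError("no batch contains samples from both conditions")
    strata = {}
    for cond in conds:
        for batch in shared:
            arrays = [
                np.array(cells_by_sample[s], dtype=np.int64)
                for s in design.samples_of_condition(cond)
                if design.sample_to_batch[s] == batch and cells_by_sample[s]
            ]
            strata[(cond, batch)] = arrays
    return shared, strata


def _bootstrap_means(
    X: np.ndarray,
    strata: list,
    cells_per_draw: int,
    n_iter: int,
    rng: np.random.Generator,
    block: int = 2000,
) -> np.ndarray:
    """Per-iteration pooled mean expression (n_iter × genes) for one condition.

    ``strata`` is a list (one entry per batch) of lists of per-sample cell
    index arrays. Each iteration draws, per batch, as many samples (with
    replacement) as the batch × condition stratum contains and
    ``cells_per_draw`` cells with replacement from each drawn sample; each
    batch's cell pool is then subsampled (without replacement) to the
    smallest pool size across batches, so every batch contributes equally
    many cells to the pooled mean.
    """
    n_cells_total = X.shape[1]
    m = cells_per_draw * min(len(samples) for samples in strata)
    per_iter = len(strata) * m
    out = np.empty((n_iter, X.shape[0]), dtype=np.float64)
    # flatten each batch's samples into concatenated index arrays
    batch_info = []
    for samples in strata:
        lengths = np.array([len(a) for a in samples], dtype=np.int64)
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        concat = np.concatenate(samples)
        batch_info.append((len(samples), lengths, starts, concat))
    for start in range(0, n_iter, block):
        nb = min(block, n_iter - start)
        rows = []
        for n_samp, lengths, starts, concat in batch_info:
            samp = rng.integers(0, n_samp, size=(nb, n_samp))
            u = rng.random((nb, n_samp, cells_per_draw))
            within = (u * lengths[samp][:, :, None]).astype(np.int64)
            pool = concat[starts[samp][:, :, None] + within].reshape(nb, -1)
            if pool.shape[1] > m:
                keys = rng.random(pool.shape)
                sel = np.argpartition(keys, m - 1, axis=1)[:, :m]
                pool = np.take_along_axis(pool, sel, axis=1)
            rows.append(pool)
        cells_all = np.concatenate(rows, axis=1)  # nb × per_iter
        iter_idx = np.repeat(np.arange(nb), per_iter)
        W = sp.csc_matrix(
            (
                np.ones(cells_all.size, dtype=np.float32),
                (cells_all.ravel(), iter_idx),
            ),
            shape=(n_cells_total, nb),
        )
        out[start : start + nb] = (W.T.tocsr() @ X.T) / per_iter
    return out


def _bootstrap_counts(
    X: np.ndarray,
    strata1: list,
    strata2: list,
    cfg: BootstrapConfig,
    n_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m1 = _bootstrap_means(X, strata1, cfg.cells_per_draw, n_iter, rng)
    m2 = _bootstrap_means(X, strata2, cfg.cells_per_draw, n_iter, rng)
    c1 = (m1 > m2).sum(axis=0)
    c2 = (m2 > m1).sum(axis=0)
    effect = (m1 - m2).mean(axis=0)
    return c1, c2, effect


def _bootstrap_p(c1: np.ndarray, c2: np.ndarray, n: int, double: bool) -> np.ndarray:
    p = np.maximum(np.minimum(c1, c2), 1) / n
    p = np.where((c1 == 0) & (c2 == 0), 1.0, p)  # all ties: no evidence
    if double:
        p = np.minimum(2.0 * p, 1.0)
    return p


def hierarchical_bootstrap(
    cm: CountMatrix, design: NestedDesign, cfg: BootstrapConfig | None = None
) -> DEResult:
    """Hierarchical bootstrap DE test (see module docstring).

    Genes hitting the resolution floor 1/n after the initial iterations are
    re-run at ``cfg.n_boot_escalated`` iterations; ``n_resamples_used``
    records the final iteration count per gene.
    """
    cfg = cfg or BootstrapConfig()
    conds = design.conditions
    shared, strata = _condition_strata(cm, design)
    strata1 = [strata[(conds[0], b)] for b in shared]
    strata2 = [strata[(conds[1], b)] for b in shared]
    if any(not s for s in strata1) or any(not s for s in strata2):
        raise ValueError("a shared batch lacks samples with cells in a condition")

    X = normalize_cells(cm, cfg.normalization)
    rng = np.random.default_rng(cfg.seed)

    n0 = cfg.n_boot_initial
    c1, c2, effect = _bootstrap_counts(X, strata1, strata2, cfg, n0, rng)
    p = _bootstrap_p(c1, c2, n0, cfg.two_sided_double)
    n_used = np.full(cm.n_genes, n0, dtype=int)

    at_floor = (np.minimum(c1, c2) <= 1) & ~((c1 == 0) & (c2 == 0))
    if at_floor.any():
        sub = np.flatnonzero(at_floor)
        c1e, c2e, _ = _bootstrap_counts(
            X[sub], strata1, strata2, cfg, cfg.n_boot_escalated, rng
        )
        pe = _bootstrap_p(c1e, c2e, cfg.n_boot_escalated, cfg.two_sided_double)
        p[sub] = pe
        n_used[sub] = cfg.n_boot_escalated
    return DEResult.from_stats(
        cm.gene_ids, effect, p, method="hierboot", n_resamples_used=n_used
    )


# ---------------------------------------------------------------------------
# Cell-level t-test (pseudoreplication-biased baseline)
# ---------------------------------------------------------------------------


def cell_t_test(
    cm: CountMatrix, design: NestedDesign, normalization: str = "log1p_cpm"
) -> DEResult:
    """Welch two-sample t-test between the cells of the two conditions."""
    conds = design.conditions
    cond_of_cell = np.array(
        [design.sample_to_condition[design.cell_to_sample[c]] for c in cm.cell_ids],
        dtype=object,
    )
    g1 = cond_of_cell == conds[0]
    g2 = cond_of_cell == conds[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each condition needs at least two cells")
    X = normalize_cells(cm, normalization).astype(np.float64)
    x1, x2 = X[:, g1], X[:, g2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = scipy.stats.ttest_ind(x1, x2, axis=1, equal_var=False)
    effect = x1.mean(axis=1) - x2.mean(axis=1)
    # zero variance in both groups: equal means -> no evidence (p = 1);
    # different means -> below resolution (p at the floor)
    nan_p = np.isnan(p)
    p = np.where(nan_p & (effect == 0), 1.0, p)
    p = np.where(nan_p & (effect != 0), TINY_P, p)
    p = np.clip(p, TINY_P, 1.0)
    return DEResult.from_stats(cm.gene_ids, effect, p, method="ttest")
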