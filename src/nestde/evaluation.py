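"""Benchmark statistics: precision–recall/AUPRC against simulated ground
truth, false-positive-rate calibration on null data, dataset splitting and
top-N Jaccard reproducibility, and the scenario × method × replicate
benchmark orchestration."""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, DEResult, NestedDesign, filter_genes
from .methods import (
    BootstrapConfig,
    PermutationConfig,
    cell_t_test,
    hierarchical_bootstrap,
    permutation_test,
    pseudobulk,
)
from .simulate import PRESETS, simulate_scenario

logger = logging.getLogger("nestde")


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    auprc: float
    prevalence: float


@dataclass
class CalibrationCurve:
    cutoffs: np.ndarray
    observed_fpr: np.ndarray


def pr_curve(result: DEResult, truth) -> PRCurve:
    """Precision–recall curve and its area (average precision).

    ``truth`` is a mapping gene → bool or a boolean array aligned with the
    result's gene order. Genes are ranked by ``rank_score`` (ascending
    p-value, ties broken by |effect| then gene id); the area is the
    step-wise average precision, sum of precision × Δrecall over the sweep.
    """
    genes = result.genes
    if isinstance(truth, dict):
        missing = [g for g in genes if g not in truth]
        if missing:
            raise ValueError(f"truth missing {len(missing)} genes")
        if len(truth) != len(genes):
            raise ValueError("truth and result gene sets differ")
        y = np.array([bool(truth[g]) for g in genes])
    else:
        y = np.asarray(truth, dtype=bool)
        if len(y) != len(genes):
            raise ValueError("truth length does not match result")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("precision-recall curve undefined without positives")

    order = np.argsort(result.table["rank_score"].to_numpy())
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    ranks = np.arange(1, len(y) + 1)
    precision = tp / ranks
    recall = tp / n_pos
    auprc = float(precision[y_sorted].sum() / n_pos)
    return PRCurve(
        recall=recall,
        precision=precision,
        auprc=auprc,
        prevalence=n_pos / len(y),
    )


def calibration_curve(
    result: DEResult, cutoffs: np.ndarray | int | None = None
) -> CalibrationCurve:
    """Observed FPR (fraction of genes with p ≤ α) over a cutoff grid.

    Intended for results computed on null data (no true DE); the default
    grid is 2000 equidistant cutoffs in (0, 1].
    """
    if cutoffs is None:
        cutoffs = 2000
    if np.isscalar(cutoffs):
        cutoffs = np.arange(1, int(cutoffs) + 1) / int(cutoffs)
    cutoffs = np.asarray(cutoffs, dtype=float)
    p = result.table["p_value"].to_numpy(dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("calibration requires p-values for every gene")
    p_sorted = np.sort(p)
    fpr = np.searchsorted(p_sorted, cutoffs, side="right") / len(p)
    return CalibrationCurve(cutoffs=cutoffs, observed_fpr=fpr)


def split_dataset(
    cm: CountMatrix,
    design: NestedDesign,
    max_cells: int = 4000,
    min_cells_per_sample: int = 20,
    seed: int = 0,
) -> list:
    """Partition the cells into disjoint subsets of at most ``max_cells``
    cells, each containing at least ``min_cells_per_sample`` cells from
    every sample.

    Each sample's cells are shuffled and dealt round-robin (with a per-sample
    starting offset to balance subset sizes). If a sample is too small to
    supply every subset, the subset count is reduced with a warning; if even
    a single subset is infeasible, the input is rejected.
    """
    rng = np.random.default_rng(seed)
    cells_by_sample = design.cells_of_sample()
    sizes = {s: len(cells) for s, cells in cells_by_sample.items()}
    if min(sizes.values()) < min_cells_per_sample:
        raise ValueError(
            "a sample has fewer cells than min_cells_per_sample"
        )
    total = cm.n_cells
    k_needed = max(1, -(-total // max_cells))
    k_cap = min(sz // min_cells_per_sample for sz in sizes.values())
    k = k_needed
    if k > k_cap:
        logger.warning(
            "reducing subset count from %d to %d so every subset keeps "
            ">= %d cells per sample",
            k,
            k_cap,
            min_cells_per_sample,
        )
        k = k_cap
    cell_pos = {c: i for i, c in enumerate(cm.cell_ids)}

    def assign(k: int) -> list:
        groups = [[] for _ in range(k)]
        for s_idx, sample in enumerate(sorted(cells_by_sample)):
            cells = list(cells_by_sample[sample])
            rng_local = np.random.default_rng(
                np.random.SeedSequence([seed, s_idx]).generate_state(1)[0]
            )
            shuffled = [cells[i] for i in rng_local.permutation(len(cells))]
            for t, cell in enumerate(shuffled):
                groups[(t + s_idx) % k].append(cell)
        return groups

    groups = assign(k)
    while any(len(g) > max_cells for g in groups) and k + 1 <= k_cap:
        k += 1
        groups = assign(k)
    if any(len(g) > max_cells for g in groups) and k > 1:
        raise ValueError(
            "cannot satisfy both the subset size cap and the per-sample minimum"
        )
    out = []
    for group in groups:
        idx = sorted(cell_pos[c] for c in group)
        sub_cm = cm.subset_cells(idx)
        out.append((sub_cm, design.subset_cells(list(sub_cm.cell_ids))))
    return out


def jaccard_top_n(a: DEResult, b: DEResult, n: int = 100) -> float:
    """Jaccard index of the two results' top-n gene sets (by rank_score)."""
    top_a, top_b = a.top_n(n), b.top_n(n)
    return len(top_a & top_b) / len(top_a | top_b)


# ---------------------------------------------------------------------------
# Benchmark orchestration
# ---------------------------------------------------------------------------

METHOD_NAMES = ("permutation", "hierboot", "ttest")


def run_method(
    method: str,
    cm: CountMatrix,
    design: NestedDesign,
    seed: int = 0,
    method_config: dict | None = None,
) -> DEResult:
    """Dispatch one of the built-in DE methods by name."""
    kwargs = dict(method_config or {})
    if method == "permutation":
        cfg = PermutationConfig(seed=seed, **kwargs)
        return permutation_test(pseudobulk(cm, design), cfg)
    if method == "hierboot":
        cfg = BootstrapConfig(seed=seed, **kwargs)
        return hierarchical_bootstrap(cm, design, cfg)
    if method == "ttest":
        return cell_t_test(cm, design, **kwargs)
    raise ValueError(f"unknown method {method!r}; choose from {METHOD_NAMES}")


def _replicate_seed(base_seed: int, scenario: str, replicate: int) -> int:
    ss = np.random.SeedSequence(
        [int(base_seed), zlib.crc32(scenario.encode()), int(replicate)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_benchmark(
    scenarios,
    methods,
    n_replicates: int = 20,
    base_seed: int = 0,
    scenario_overrides: dict | None = None,
    method_configs: dict | None = None,
    min_expressed_fraction: float = 0.10,
) -> pd.DataFrame:
    """Simulate each scenario ``n_replicates`` times, run each method after
    the gene filter, and record AUPRC against the simulated truth as a tidy
    (scenario, method, replicate_seed, metric_name, value) table.

    A method failure on one replicate is recorded as a missing value and the
    run continues.
    """
    for sc in scenarios:
        if sc not in PRESETS:
            raise ValueError(f"unknown scenario {sc!r}")
    records = []
    for scenario in scenarios:
        for rep in range(n_replicates):
            seed = _replicate_seed(base_seed, scenario, rep)
            sim = simulate_scenario(
                scenario, overrides=(scenario_overrides or {}).get(scenario), seed=seed
            )
            filtered = filter_genes(sim.counts, min_expressed_fraction)
            kept = pd.Index(sim.counts.gene_ids).get_indexer(filtered.gene_ids)
            truth = sim.is_de[kept]
            if not truth.any():
                logger.warning(
                    "no DE genes retained for %s replicate %d; skipping AUPRC",
                    scenario,
                    rep,
                )
                continue
            for method in methods:
                try:
                    result = run_method(
                        method,
                        filtered,
                        sim.design,
                        seed=seed,
                        method_config=(method_configs or {}).get(method),
                    )
                    value = pr_curve(result, truth).auprc
                except Exception:
                    logger.exception(
                        "method %s failed on %s replicate %d", method, scenario, rep
                    )
                    value = np.nan
                records.append(
                    {
                        "scenario": scenario,
                        "method": method,
                        "replicate_seed": seed,
                        "metric_name": "auprc",
                        "value": value,
                    }
                )
    table = pd.DataFrame.from_records(
        records,
        columns=["scenario", "method", "replicate_seed", "metric_name", "value"],
    )
    if table.duplicated(["scenario", "method", "replicate_seed", "metric_name"]).any():
        raise RuntimeError("duplicate benchmark records")
    return table


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of each metric per (scenario, method)."""
    return (
        table.groupby(["scenario", "method", "metric_name"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
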