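"""Simulation of hierarchically structured single-cell count data.

The generator produces gene × cell UMI counts with a nested design
(cells within samples, samples within batches, two conditions) and known
differential-expression ground truth, following a gamma-Poisson (negative
binomial) hierarchy:

1. per-gene base means ~ Gamma(shape, rate);
2. a fixed fraction of genes is differentially expressed; their condition-2
   mean is multiplied by a log-normal fold change (moment-matched to a
   natural-scale mean of 13.2 and sd of 5.5), randomly up or down;
3. a multiplicative per-sample × gene random effect (log-normal) induces
   within-sample correlation between cells (pseudoreplication);
4. multiplicative per-batch × gene factors with log-normal magnitude and
   random direction create batch effects;
5. per-cell expected values scale the gene-sample mean by a mean-one
   log-normal library-size factor;
6. counts ~ NB(mean mu, variance mu + bcv^2 mu^2).

Five presets cover the benchmark scenarios: a balanced single-batch
``dataset`` (2 × 5 samples × 250 cells), a three-batch ``atlas`` (3750
cells), ``varying_cells`` (gamma-distributed cells per sample),
``unbalanced_atlas`` (9:1 and 1:9 condition splits in two batches), and a
``negative_control`` (atlas layout with no DE genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .core import CountMatrix, NestedDesign

# Calibrated so that the pooled empirical ICC(1) of log1p-CPM values on
# negative-control data is close to 0.05 (see docs/methods.md).
DEFAULT_SAMPLE_EFFECT_SD = 0.35

DEFAULT_BATCH_EFFECT_PARAMS = ((0.05, 0.1), (0.8, 0.1), (1.45, 0.05))


@dataclass
class ScenarioConfig:
    """Parameters of one simulated benchmark scenario.

    ``batch_layout`` is a list of (batch_id, n_samples_cond1,
    n_samples_cond2). ``cells_per_sample`` is a fixed count, or None to draw
    cell counts from Gamma(cell_count_gamma) rounded to integers with a
    floor. ``batch_effect_params`` are (location, scale) of the log-normal
    batch-effect magnitude for each batch in layout order.
    """

    n_genes: int = 5000
    de_fraction: float = 0.05
    fc_mean: float = 13.2
    fc_sd: float = 5.5
    batch_layout: tuple = (("batch1", 5, 5),)
    cells_per_sample: int | None = 250
    cell_count_gamma: tuple = (0.8, 0.0035)
    cell_count_floor: int = 10
    batch_effect_params: tuple = DEFAULT_BATCH_EFFECT_PARAMS
    sample_effect_sd: float = DEFAULT_SAMPLE_EFFECT_SD
    base_mean_gamma: tuple = (0.6, 0.3)
    libsize_lognormal: tuple = (11.0, 0.2)
    bcv_common: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.fc_mean <= 0 or self.fc_sd < 0:
            raise ValueError("fold-change moments must be positive / nonnegative")
        if self.n_genes < 1:
            raise ValueError("n_genes must be at least 1")
        if self.cells_per_sample is not None and self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be at least 1")
        if len(self.batch_effect_params) < len(self.batch_layout):
            raise ValueError("need batch_effect_params for every batch in layout")
        for batch_id, n1, n2 in self.batch_layout:
            if n1 < 1 or n2 < 1:
                raise ValueError(
                    f"batch {batch_id!r} must contain at least one sample "
                    "from each condition"
                )


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    design: NestedDesign
    is_de: np.ndarray
    fold_change: np.ndarray  # applied factor; 1 for non-DE, <1 for down-regulated
    batch_factors: dict = field(repr=False)
    config: ScenarioConfig = None


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(meanlog, sdlog) of the log-normal with the given natural-scale moments."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    sdlog2 = np.log1p(sd**2 / mean**2)
    meanlog = np.log(mean) - sdlog2 / 2.0
    return float(meanlog), float(np.sqrt(sdlog2))


def draw_fold_changes(
    k: int, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """k i.i.d. fold-change magnitudes from the moment-matched log-normal."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    meanlog, sdlog = lognormal_params_from_moments(config.fc_mean, config.fc_sd)
    return rng.lognormal(meanlog, sdlog, size=k)


def draw_cell_counts(
    n_samples: int,
    shape: float = 0.8,
    rate: float = 0.0035,
    rng: np.random.Generator | None = None,
    floor: int = 10,
) -> np.ndarray:
    """Gamma-distributed cells-per-sample, rounded and floored."""
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be positive")
    if rng is None:
        rng = np.random.default_rng()
    draws = np.rint(rng.gamma(shape, 1.0 / rate, size=n_samples)).astype(int)
    return np.maximum(draws, floor)


PRESETS = ("dataset", "atlas", "varying_cells", "unbalanced_atlas", "negative_control")

_ATLAS_LAYOUT = (("batch1", 3, 2), ("batch2", 2, 3), ("batch3", 3, 2))


def preset_config(preset: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Build the ScenarioConfig for one of the named benchmark presets."""
    if preset == "dataset":
        cfg = ScenarioConfig(seed=seed)
    elif preset == "atlas":
        cfg = ScenarioConfig(batch_layout=_ATLAS_LAYOUT, seed=seed)
    elif preset == "varying_cells":
        cfg = ScenarioConfig(cells_per_sample=None, seed=seed)
    elif preset == "unbalanced_atlas":
        cfg = ScenarioConfig(
            batch_layout=(("batch1", 9, 1), ("batch2", 1, 9)), seed=seed
        )
    elif preset == "negative_control":
        cfg = ScenarioConfig(batch_layout=_ATLAS_LAYOUT, de_fraction=0.0, seed=seed)
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def simulate_scenario(
    preset: str, overrides: dict | None = None, seed: int = 0
) -> SimulatedDataset:
    """Simulate one of the benchmark presets (see module docstring)."""
    cfg = preset_config(preset, seed=seed, **(overrides or {}))
    return simulate(cfg)


def simulate(cfg: ScenarioConfig) -> SimulatedDataset:
    """Run the generative pipeline for an arbitrary ScenarioConfig."""
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes

    # (1) per-gene base means
    shape, rate = cfg.base_mean_gamma
    base_mean = rng.gamma(shape, 1.0 / rate, size=G)

    # (2) DE genes and applied fold changes
    n_de = int(round(cfg.de_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True
    fc_magnitude = draw_fold_changes(n_de, cfg, rng)
    direction_up = rng.random(n_de) < 0.5
    fold_change = np.ones(G)
    fold_change[de_idx] = np.where(direction_up, fc_magnitude, 1.0 / fc_magnitude)

    # sample bookkeeping from the batch layout
    sample_ids, sample_batch, sample_cond = [], [], []
    for batch_id, n1, n2 in cfg.batch_layout:
        for cond, n_cond in (("1", n1), ("2", n2)):
            for _ in range(n_cond):
                sample_ids.append(f"sample{len(sample_ids) + 1:02d}")
                sample_batch.append(batch_id)
                sample_cond.append(cond)
    S = len(sample_ids)

    # (3) per-sample × gene random effect
    sample_effect = np.exp(rng.normal(0.0, cfg.sample_effect_sd, size=(G, S)))

    # (4) per-batch × gene factors: log-normal magnitude, random direction
    batch_factors = {}
    for (batch_id, _, _), (loc, scale) in zip(
        cfg.batch_layout, cfg.batch_effect_params
    ):
        magnitude = rng.lognormal(loc, scale, size=G)
        sign = np.where(rng.random(G) < 0.5, 1.0, -1.0)
        batch_factors[batch_id] = magnitude**sign

    # gene × sample expected means
    mean_gs = base_mean[:, None] * sample_effect
    cond2 = np.array([c == "2" for c in sample_cond])
    mean_gs[:, cond2] *= fold_change[:, None]
    for s_idx, batch_id in enumerate(sample_batch):
        mean_gs[:, s_idx] *= batch_factors[batch_id]

    # cells per sample
    if cfg.cells_per_sample is not None:
        n_cells = np.full(S, cfg.cells_per_sample, dtype=int)
    else:
        g_shape, g_rate = cfg.cell_count_gamma
        n_cells = draw_cell_counts(S, g_shape, g_rate, rng, cfg.cell_count_floor)
    total_cells = int(n_cells.sum())
    cell_sample_idx = np.repeat(np.arange(S), n_cells)

    # (5) mean-one library-size factors
    loc, scale = cfg.libsize_lognormal
    libsize = rng.lognormal(loc, scale, size=total_cells)
    lib_factor = libsize / np.exp(loc + scale**2 / 2.0)

    # (6) gamma-Poisson counts, in gene blocks to bound peak memory
    bcv2 = cfg.bcv_common**2
    blocks = []
    block_size = max(1, int(5e7 // max(total_cells, 1)))
    for g0 in range(0, G, block_size):
        g1 = min(g0 + block_size, G)
        mu = mean_gs[g0:g1, cell_sample_idx] * lib_factor[None, :]
        if bcv2 > 0:
            lam = rng.gamma(1.0 / bcv2, mu * bcv2)
        else:
            lam = mu
        blocks.append(sp.csr_matrix(rng.poisson(lam).astype(np.int64)))
    counts = sp.vstack(blocks, format="csr") if len(blocks) > 1 else blocks[0]

    gene_ids = np.array([f"gene{i + 1:05d}" for i in range(G)], dtype=object)
    cell_ids = np.array(
        [f"cell{i + 1:06d}" for i in range(total_cells)], dtype=object
    )
    design = NestedDesign(
        cell_to_sample={
            cell_ids[i]: sample_ids[cell_sample_idx[i]] for i in range(total_cells)
        },
        sample_to_batch=dict(zip(sample_ids, sample_batch)),
        sample_to_condition=dict(zip(sample_ids, sample_cond)),
    )
    return SimulatedDataset(
        counts=CountMatrix(counts, gene_ids, cell_ids),
        design=design,
        is_de=is_de,
        fold_change=fold_change,
        batch_factors=batch_factors,
        config=cfg,
    )


def permute_condition_labels(design: NestedDesign, seed: int = 0) -> NestedDesign:
    """Uniformly permute the sample-level condition labels; the cell→sample
    structure is untouched."""
    samples = design.samples
    if len(samples) < 2:
        raise ValueError("need at least two samples to permute")
    rng = np.random.default_rng(seed)
    labels = [design.sample_to_condition[s] for s in samples]
    permuted = [labels[i] for i in rng.permutation(len(labels))]
    return NestedDesign(
        cell_to_sample=dict(design.cell_to_sample),
        sample_to_batch=dict(design.sample_to_batch),
        sample_to_condition=dict(zip(samples, permuted)),
    )
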