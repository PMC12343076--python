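"""Data model and I/O for nested single-cell count data.

Counts are stored gene × cell as a sparse integer matrix. The nested design
maps every cell to a biological sample and every sample to a processing
batch and one of exactly two experimental conditions — the two-stage
structure (samples drawn first, cells profiled within samples) that makes
cells pseudoreplicates rather than independent observations.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("nestde")

DE_RESULT_COLUMNS = [
    "gene",
    "effect",
    "p_value",
    "p_adjusted",
    "rank_score",
    "method",
    "n_resamples_used",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class CountMatrix:
    """Gene × cell matrix of nonnegative integer UMI counts."""

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValueError("counts contain negative entries")
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise ValueError("counts contain non-integral entries")
                self.counts = self.counts.astype(np.int64)
        elif not np.issubdtype(data.dtype, np.integer):
            self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        return CountMatrix(self.counts[idx], self.gene_ids[idx], self.cell_ids)

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        return CountMatrix(self.counts[:, idx], self.gene_ids, self.cell_ids[idx])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class NestedDesign:
    """cell → sample → (batch, condition) hierarchy with exactly two conditions."""

    cell_to_sample: dict
    sample_to_batch: dict
    sample_to_condition: dict

    def __post_init__(self) -> None:
        samples = set(self.cell_to_sample.values())
        missing = samples - set(self.sample_to_batch)
        if missing:
            raise ValueError(f"samples without batch assignment: {sorted(missing)[:5]}")
        missing = samples - set(self.sample_to_condition)
        if missing:
            raise ValueError(f"samples without condition: {sorted(missing)[:5]}")
        conds = set(self.sample_to_condition.values())
        if len(conds) != 2:
            raise ValueError(f"expected exactly two conditions, found {sorted(conds)}")

    @property
    def samples(self) -> list:
        return sorted(self.sample_to_condition)

    @property
    def batches(self) -> list:
        return sorted(set(self.sample_to_batch.values()))

    @property
    def conditions(self) -> list:
        """The two condition labels, in sorted order (first is 'condition 1')."""
        return sorted(set(self.sample_to_condition.values()))

    @property
    def cells(self) -> list:
        return list(self.cell_to_sample)

    def samples_of_condition(self, condition) -> list:
        return [s for s in self.samples if self.sample_to_condition[s] == condition]

    def cells_of_sample(self) -> dict:
        out: dict = {s: [] for s in self.samples}
        for cell, s in self.cell_to_sample.items():
            out[s].append(cell)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                c,
                s,
                self.sample_to_batch[s],
                self.sample_to_condition[s],
            )
            for c, s in self.cell_to_sample.items()
        ]
        return pd.DataFrame(rows, columns=["cell", "sample", "batch", "condition"])

    def subset_cells(self, cell_ids) -> "NestedDesign":
        cts = {c: self.cell_to_sample[c] for c in cell_ids}
        samples = set(cts.values())
        return NestedDesign(
            cts,
            {s: self.sample_to_batch[s] for s in samples},
            {s: self.sample_to_condition[s] for s in samples},
        )


@dataclass
class PseudobulkMatrix:
    """Gene × sample aggregate of the cell-level counts."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    sample_to_condition: dict
    sample_to_batch: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("pseudobulk shape mismatch")
        if self.values.size and self.values.min() < 0:
            raise ValueError("pseudobulk values must be nonnegative")

    @property
    def conditions(self) -> list:
        return sorted(set(self.sample_to_condition.values()))

    def condition_mask(self, condition) -> np.ndarray:
        return np.array(
            [self.sample_to_condition[s] == condition for s in self.sample_ids]
        )


@dataclass
class DEResult:
    """Per-gene differential-expression output of one method.

    ``rank_score`` is a total order over genes (1 = most significant),
    derived from the p-value with ties broken by descending |effect| and
    then lexicographic gene id, so top-N selection is deterministic.
    """

    table: pd.DataFrame = field(repr=False)
    method: str = ""

    def __post_init__(self) -> None:
        missing = set(DE_RESULT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"DEResult table missing columns {sorted(missing)}")
        if not self.method:
            self.method = str(self.table["method"].iloc[0]) if len(self.table) else ""

    @classmethod
    def from_stats(
        cls,
        genes,
        effect,
        p_value,
        method: str,
        n_resamples_used=None,
    ) -> "DEResult":
        genes = np.asarray(genes, dtype=object)
        effect = np.asarray(effect, dtype=float)
        p = None if p_value is None else np.asarray(p_value, dtype=float)
        if p is not None:
            p_adj = bh_adjust(p)
        else:
            p_adj = np.full(len(genes), np.nan)
            p = np.full(len(genes), np.nan)
        order = np.lexsort(
            (genes.astype(str), -np.abs(effect), np.where(np.isnan(p), 2.0, p))
        )
        rank = np.empty(len(genes), dtype=float)
        rank[order] = np.arange(1, len(genes) + 1)
        if n_resamples_used is None:
            nres = np.zeros(len(genes), dtype=int)
        else:
            nres = np.broadcast_to(
                np.asarray(n_resamples_used, dtype=int), (len(genes),)
            ).copy()
        table = pd.DataFrame(
            {
                "gene": genes,
                "effect": effect,
                "p_value": p,
                "p_adjusted": p_adj,
                "rank_score": rank,
                "method": method,
                "n_resamples_used": nres,
            }
        )
        return cls(table=table, method=method)

    @property
    def genes(self) -> np.ndarray:
        return self.table["gene"].to_numpy()

    def top_n(self, n: int) -> set:
        if n > len(self.table):
            raise ValueError(f"requested top {n} of only {len(self.table)} genes")
        ordered = self.table.sort_values("rank_score")
        return set(ordered["gene"].iloc[:n])

    def write_tsv(self, path) -> None:
        _atomic_write_df(self.table[DE_RESULT_COLUMNS], path)

    @classmethod
    def read_tsv(cls, path) -> "DEResult":
        table = pd.read_csv(path, sep="\t")
        return cls(table=table)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _atomic_write_df(df: pd.DataFrame, path, sep: str = "\t", **kwargs) -> None:
    tmp = f"{path}.tmp"
    df.to_csv(tmp, sep=sep, index=False, **kwargs)
    os.replace(tmp, path)


def _open_maybe_gz(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find_companion(directory: str, names: list) -> str:
    for name in names:
        for suffix in ("", ".gz"):
            cand = os.path.join(directory, name + suffix)
            if os.path.exists(cand):
                return cand
    raise FileNotFoundError(f"none of {names} found in {directory}")


def read_counts(path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from a 10x-style MTX triple or a dense CSV.

    ``path`` is a directory (MTX triple: matrix.mtx + features/genes TSV +
    barcodes TSV, optionally gzipped) or a CSV file with gene rows and cell
    columns. Negative, non-integral or duplicate-id inputs are rejected.
    """
    if format is None:
        format = "mtx" if os.path.isdir(path) else "csv"
    if format == "mtx":
        directory = path if os.path.isdir(path) else os.path.dirname(path)
        mtx_path = _find_companion(directory, ["matrix.mtx"])
        counts = scipy.io.mmread(mtx_path)
        with _open_maybe_gz(
            _find_companion(directory, ["features.tsv", "genes.tsv"])
        ) as fh:
            gene_ids = np.array([line.rstrip("\n").split("\t")[0] for line in fh])
        with _open_maybe_gz(_find_companion(directory, ["barcodes.tsv"])) as fh:
            cell_ids = np.array([line.rstrip("\n").split("\t")[0] for line in fh])
        return CountMatrix(sp.csr_matrix(counts), gene_ids, cell_ids)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(
            sp.csr_matrix(df.to_numpy()),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
        )
    raise ValueError(f"unknown counts format {format!r}")


def write_counts(cm: CountMatrix, path, format: str = "mtx") -> None:
    """Write counts as an MTX triple (into directory ``path``) or dense CSV."""
    if format == "mtx":
        os.makedirs(path, exist_ok=True)
        scipy.io.mmwrite(
            os.path.join(path, "matrix.mtx"), cm.counts.tocoo(), field="integer"
        )
        feats = pd.DataFrame(
            {"id": cm.gene_ids, "name": cm.gene_ids, "type": "Gene Expression"}
        )
        feats.to_csv(
            os.path.join(path, "features.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(cm.cell_ids).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False
        )
    elif format == "csv":
        df = pd.DataFrame(cm.to_dense(), index=cm.gene_ids, columns=cm.cell_ids)
        df.to_csv(path)
    else:
        raise ValueError(f"unknown counts format {format!r}")


def read_design(path) -> NestedDesign:
    """Read a cell,sample,batch,condition design table (CSV or TSV).

    Rejects samples mapped to more than one batch or condition.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"cell", "sample", "batch", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns {sorted(missing)}")
    return design_from_frame(df)


def design_from_frame(df: pd.DataFrame) -> NestedDesign:
    if df["cell"].duplicated().any():
        raise ValueError("duplicate cells in design table")
    for col in ("batch", "condition"):
        per_sample = df.groupby("sample")[col].nunique()
        bad = per_sample[per_sample > 1]
        if len(bad):
            raise ValueError(
                f"samples mapped to multiple {col}s: {list(bad.index)[:5]}"
            )
    sample_attrs = df.drop_duplicates("sample").set_index("sample")
    return NestedDesign(
        cell_to_sample=dict(zip(df["cell"], df["sample"])),
        sample_to_batch=sample_attrs["batch"].to_dict(),
        sample_to_condition=sample_attrs["condition"].to_dict(),
    )


def write_design(design: NestedDesign, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    _atomic_write_df(design.to_frame(), path, sep=sep)


def align_counts_design(
    cm: CountMatrix, design: NestedDesign, strict: bool = True
) -> tuple[CountMatrix, NestedDesign]:
    """Reconcile the cell sets of counts and design.

    In strict mode any mismatch is an error; in permissive mode the
    intersection is taken with a logged warning.
    """
    count_cells = set(cm.cell_ids)
    design_cells = set(design.cell_to_sample)
    only_counts = count_cells - design_cells
    only_design = design_cells - count_cells
    if not only_counts and not only_design:
        return cm, design
    msg = (
        f"{len(only_counts)} cells only in counts, "
        f"{len(only_design)} only in design"
    )
    if strict:
        raise ValueError(f"counts/design cell mismatch: {msg}")
    logger.warning("intersecting counts and design: %s", msg)
    shared = count_cells & design_cells
    keep = np.array([c in shared for c in cm.cell_ids])
    return cm.subset_cells(keep), design.subset_cells([c for c in cm.cell_ids[keep]])


# ---------------------------------------------------------------------------
# Gene filtering and multiple-testing adjustment
# ---------------------------------------------------------------------------


def filter_genes(cm: CountMatrix, min_expressed_fraction: float = 0.10) -> CountMatrix:
    """Remove genes detected (count > 0) in fewer than the given fraction of cells.

    Genes at exactly the threshold are retained; gene order is preserved.
    An empty matrix passes through unchanged.
    """
    if not 0 <= min_expressed_fraction <= 1:
        raise ValueError("min_expressed_fraction must be in [0, 1]")
    if cm.n_cells == 0 or cm.n_genes == 0:
        return cm
    nonzero_per_gene = cm.counts.getnnz(axis=1)
    frac = nonzero_per_gene / cm.n_cells
    keep = frac >= min_expressed_fraction
    return cm.subset_genes(keep)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to ≤ 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
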