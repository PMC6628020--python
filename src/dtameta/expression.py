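"""Expression matrix I/O and preprocessing.

Expression matrices are plain :class:`pandas.DataFrame` objects with gene
identifiers on the index and sample identifiers on the columns, holding
finite log2 intensities.  Phenotype tables are DataFrames indexed by sample
with at least a ``group`` column ({"case", "control"}) and optionally a
``stage`` column.

Preprocessing follows the standard microarray pipeline: log2 standardization
when the data are still on the linear scale, then quantile normalization so
every array shares the same empirical intensity distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "log_standardize",
    "quantile_normalize",
]

#: Matrices whose maximum exceeds this are assumed to be on the linear
#: (un-logged) intensity scale; log2-transformed microarray data rarely
#: exceed ~20.
LINEAR_SCALE_THRESHOLD = 100.0


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene id, header = sample ids).

    Duplicate gene ids are collapsed by their per-gene mean (with a logged
    warning); duplicate sample columns, non-numeric cells and ragged rows are
    rejected.
    """
    # header=None first: pandas would silently mangle duplicated sample ids
    full = pd.read_csv(path, sep="\t", header=None, dtype=str)
    header = full.iloc[0]
    samples = pd.Index(header.iloc[1:].tolist())
    if samples.duplicated().any():
        dupes = sorted(set(samples[samples.duplicated()]))
        raise ValueError(f"duplicate sample ids: {', '.join(map(str, dupes))}")
    raw = full.iloc[1:].set_index(full.columns[0])
    raw.index.name = None
    raw.columns = samples
    try:
        mat = raw.astype(float)
    except ValueError as exc:
        # locate the offending cell for a useful message
        for i, (gene, row) in enumerate(raw.iterrows(), start=2):
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at line {i} (gene {gene!r}, "
                        f"sample {sample!r}): {cell!r}"
                    ) from exc
        raise
    if mat.isna().any().any():
        bad = int(mat.isna().to_numpy().sum())
        raise ValueError(f"{bad} missing cell(s) in expression matrix")
    if mat.index.duplicated().any():
        dupes = sorted(set(mat.index[mat.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene id(s) by mean: %s",
            len(dupes), ", ".join(dupes),
        )
        mat = mat.groupby(level=0, sort=False).mean()
    if not np.isfinite(mat.to_numpy()).all():
        raise ValueError("non-finite values in expression matrix")
    return mat


def write_expression(mat: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix as TSV (gene id in the first column)."""
    mat.to_csv(path, sep="\t", index_label="gene")


def read_phenotype(path) -> pd.DataFrame:
    """Read a phenotype TSV with columns sample, group[, stage]."""
    pheno = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if pheno.index.duplicated().any():
        dupes = sorted(set(pheno.index[pheno.index.duplicated()]))
        raise ValueError(f"duplicate sample ids in phenotype: {', '.join(dupes)}")
    if "group" not in pheno.columns:
        raise ValueError("phenotype table lacks a 'group' column")
    bad = set(pheno["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    return pheno


def write_phenotype(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="sample")


def log_standardize(
    mat: pd.DataFrame,
    threshold: float = LINEAR_SCALE_THRESHOLD,
    force: bool = False,
) -> pd.DataFrame:
    """log2(x + 1) transform applied only when the data look linear-scale.

    The matrix is transformed when its maximum exceeds ``threshold`` (or
    always, with ``force=True``); otherwise it is returned unchanged.  The
    decision is logged so a pipeline run records, per study, whether the
    transform fired.
    """
    vmax = float(mat.to_numpy().max()) if mat.size else 0.0
    if force or vmax > threshold:
        if (mat.to_numpy() < 0).any():
            raise ValueError("negative values: cannot log-transform")
        logger.info("log2(x+1) transform applied (max value %.3g)", vmax)
        return np.log2(mat + 1.0)
    logger.info("log transform skipped: data already log scale (max %.3g)", vmax)
    return mat


def quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    For each rank r the mean of the r-th smallest values across samples
    replaces each sample's r-th smallest value.  Ties within a sample all
    receive the mean of the rank-mean values over the tied ranks (the
    ``normalizeQuantiles`` convention).  Single-sample matrices are returned
    unchanged with a warning.
    """
    if mat.shape[1] < 2:
        logger.warning("quantile normalization skipped: fewer than 2 samples")
        return mat
    values = mat.to_numpy(dtype=float)
    # mean of the r-th order statistics across samples
    rank_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        # stable sort; runs of equal values share the mean of the rank means
        # over their tied positions
        col = values[:, j]
        out_col = np.empty(n)
        order = np.argsort(col, kind="mergesort")
        sorted_vals = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            group_mean = rank_means[i : k + 1].mean()
            out_col[order[i : k + 1]] = group_mean
            i = k + 1
        out[:, j] = out_col
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)
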