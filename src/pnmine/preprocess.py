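"""Gene filtering and cross-dataset merging ahead of network construction.

The cell-line matrix is filtered by Mean Absolute Deviation (MAD) to enrich
highly expressed, variable genes; the tumor matrix is then subset to the
surviving genes and each dataset is standardized per gene before the
consensus network is built.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MergedExpression, PipelineError

DEFAULT_MAD_THRESHOLD = 1000.0

#: minimum number of shared genes required for a meaningful network
MIN_SHARED_GENES = 200


def gene_mad(values: np.ndarray) -> np.ndarray:
    """Per-row MAD: median of absolute deviations from the row median.

    No consistency constant is applied — the threshold is interpreted on the
    raw expression scale.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    return np.median(np.abs(values - med), axis=1)


def mad_filter(
    expr: ExpressionMatrix, threshold: float = DEFAULT_MAD_THRESHOLD
) -> ExpressionMatrix:
    """Keep genes whose MAD is strictly greater than ``threshold``.

    Gene order is preserved. An empty result is returned (with a warning)
    rather than raised, so callers can decide whether to halt.
    """
    if threshold < 0:
        raise ValueError("MAD threshold must be >= 0")
    mads = gene_mad(expr.values.to_numpy())
    keep = mads > threshold
    if not keep.any():
        warnings.warn(
            f"MAD filter at threshold {threshold} removed every gene",
            stacklevel=2,
        )
    return ExpressionMatrix(expr.values.loc[keep], expr.dataset_tag)


def standardize_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (row) standardization to mean 0, sd 1 (ddof=1)."""
    vals = df.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        zero = df.index[(sd == 0).ravel()].tolist()
        raise PipelineError(
            f"cannot standardize zero-variance genes: {zero[:5]}"
            " (filter them out first)"
        )
    return pd.DataFrame((vals - mean) / sd, index=df.index, columns=df.columns)


def intersect_and_merge(
    cell: ExpressionMatrix,
    tumor: ExpressionMatrix,
    min_shared: int = MIN_SHARED_GENES,
) -> MergedExpression:
    """Intersect gene sets and standardize each dataset per gene.

    Gene order follows the cell-line matrix. Raises if fewer than
    ``min_shared`` genes (default 200) are shared.
    """
    shared = cell.gene_ids[cell.gene_ids.isin(tumor.gene_ids)]
    if len(shared) < min_shared:
        raise PipelineError(
            f"only {len(shared)} genes shared between the two datasets "
            f"(need >= {min_shared}); cell-line universe has "
            f"{cell.n_genes} genes, tumor universe has {tumor.n_genes}"
        )
    cell_block = standardize_genes(cell.values.loc[shared])
    tumor_block = standardize_genes(tumor.values.loc[shared])
    return MergedExpression(
        ExpressionMatrix(cell_block, "cell_line"),
        ExpressionMatrix(tumor_block, "tumor"),
    )
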