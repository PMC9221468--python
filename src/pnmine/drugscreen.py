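"""Drug screen ingest, AUC-type summary responses, and pre-selection filters."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CLINICAL_STATUSES,
    DoseResponsePanel,
    DrugAnnotationTable,
    PipelineError,
)

DEFAULT_VIABILITY_CUTOFF = 55.0
DEFAULT_MIN_PCHEMBL = 6.0


@dataclass
class ResponseSummary:
    """Per-(drug, cell line) AUC-type summary viability on the 0-100 scale."""

    per_line: pd.DataFrame  # drug x cell_line

    @property
    def median_response(self) -> pd.Series:
        """Per-drug median summary response across cell lines."""
        return self.per_line.median(axis=1)


def compute_auc(viability: np.ndarray, concentrations: np.ndarray) -> float:
    """Normalized area under the viability curve over log10 concentration.

    The trapezoidal integral is divided by the log-concentration span, so the
    result lives on the same 0-100 viability scale as the curve itself
    (a flat curve integrates to its own level).
    """
    viability = np.asarray(viability, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if len(conc) < 2:
        raise PipelineError("AUC needs >= 2 concentration points")
    if not np.all(np.diff(conc) > 0):
        raise PipelineError("concentration grid must be strictly increasing")
    logc = np.log10(conc)
    return float(np.trapezoid(viability, logc) / (logc[-1] - logc[0]))


def summarize_responses(
    panel: DoseResponsePanel, summary_column: pd.DataFrame | None = None
) -> ResponseSummary:
    """Per-(drug, line) summary response.

    If the deposited screen already carries a summary (``summary_column``,
    drug x cell_line), it is used verbatim; otherwise the normalized AUC is
    computed from the dose-response curves.
    """
    if summary_column is not None:
        return ResponseSummary(summary_column)
    auc = panel.viability.apply(
        lambda row: compute_auc(row.to_numpy(), panel.concentrations), axis=1
    )
    return ResponseSummary(auc.unstack("cell_line"))


def viability_prefilter(
    summary: ResponseSummary, cutoff: float = DEFAULT_VIABILITY_CUTOFF
) -> set[str]:
    """Drugs whose median-across-lines summary response is strictly < cutoff."""
    if not (0 < cutoff <= 100):
        raise ValueError("cutoff must lie in (0, 100]")
    med = summary.median_response
    return set(med.index[med < cutoff])


def annotation_filter(
    table: DrugAnnotationTable,
    min_pchembl: float = DEFAULT_MIN_PCHEMBL,
    statuses: set[str] | None = None,
    keep_missing_pchembl: bool = True,
) -> set[str]:
    """Drugs passing pChEMBL > min_pchembl and (optionally) a status filter.

    Missing pChEMBL values are kept by default (tool compounds without a
    ChEMBL entry) — set ``keep_missing_pchembl=False`` to drop them.
    """
    if statuses:
        unknown = set(statuses) - set(CLINICAL_STATUSES)
        if unknown:
            raise ValueError(
                f"unknown clinical status {sorted(unknown)}; "
                f"allowed: {list(CLINICAL_STATUSES)}"
            )
    df = table.table
    pc = df["pchembl"]
    keep = (pc > min_pchembl) | (pc.isna() if keep_missing_pchembl else False)
    if statuses:
        keep &= df["status"].isin(statuses)
    return set(df.index[keep])
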