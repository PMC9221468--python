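"""Candidate ranking and fingerprint-similarity queries.

Candidate List-1: within each drug cluster, clinically advanced drugs
(FDA-approved / Phase II / Phase III by default) are ranked by their most
negative preserved-module correlation — a strongly negative correlation
means the module's genes are suppressed as the drug takes effect, marking
the module as a potential treatment target.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ADVANCED_STATUSES, DrugAnnotationTable, PipelineError
from .fingerprint import ConsensusClusterResult, FingerprintMatrix

DEFAULT_TOP_N = 15
DEFAULT_MIN_SIMILARITY = 0.8


def rank_candidates(
    fp: FingerprintMatrix,
    clusters: ConsensusClusterResult,
    ann: DrugAnnotationTable,
    top_n: int = DEFAULT_TOP_N,
    statuses: frozenset[str] = ADVANCED_STATUSES,
) -> pd.DataFrame:
    """Top-``top_n`` advanced-status drugs per cluster by most negative
    module correlation.

    Returns a long-format frame (cluster, drug, score, module, status)
    sorted ascending by score within cluster; drugs whose best correlation
    is not negative are excluded. Deterministic: ties break on drug name.
    """
    rows = []
    fp_rows = fp.complete_rows()
    for cluster_id in sorted(clusters.assignments.unique()):
        members = clusters.assignments.index[clusters.assignments == cluster_id]
        records = []
        for drug in members:
            if drug not in ann.drugs or ann.status_of(drug) not in statuses:
                continue
            if drug not in fp_rows.index:
                continue
            profile = fp_rows.loc[drug]
            score = float(profile.min())
            if score >= 0:
                continue
            records.append(
                {
                    "cluster": int(cluster_id),
                    "drug": drug,
                    "score": score,
                    "module": profile.idxmin(),
                    "status": ann.status_of(drug),
                }
            )
        if not records:
            warnings.warn(
                f"cluster {cluster_id}: no advanced-status drug with a "
                "negative module correlation",
                stacklevel=2,
            )
            continue
        block = pd.DataFrame(records).sort_values(
            ["score", "drug"], kind="stable"
        )
        rows.append(block.head(top_n))
    if not rows:
        return pd.DataFrame(columns=["cluster", "drug", "score", "module", "status"])
    return pd.concat(rows, ignore_index=True)


def similar_fingerprint_drugs(
    fp: FingerprintMatrix,
    anchor_drug: str,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    statuses: frozenset[str] | None = ADVANCED_STATUSES,
    ann: DrugAnnotationTable | None = None,
) -> pd.Series:
    """Drugs whose fingerprint row correlates with the anchor's at
    >= ``min_similarity``, sorted descending by similarity.

    The anchor itself is excluded; when an annotation table and status set
    are given, only drugs with those statuses are returned.
    """
    rows = fp.complete_rows()
    if anchor_drug not in rows.index:
        raise PipelineError(f"anchor drug {anchor_drug!r} not in fingerprint matrix")
    anchor = rows.loc[anchor_drug].to_numpy(dtype=float)
    if anchor.std() == 0:
        raise PipelineError("anchor fingerprint has zero variance")
    sims = {}
    for drug in rows.index:
        if drug == anchor_drug:
            continue
        if statuses is not None and ann is not None:
            if drug not in ann.drugs or ann.status_of(drug) not in statuses:
                continue
        row = rows.loc[drug].to_numpy(dtype=float)
        if row.std() == 0:
            continue
        sims[drug] = float(np.corrcoef(anchor, row)[0, 1])
    out = pd.Series(sims, name="similarity", dtype=float)
    out = out[out >= min_similarity]
    return out.sort_values(ascending=False)
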