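"""Two-drug combination prediction under independent drug action (IDA).

IDA assumes non-interacting drugs: each cell line responds as if it had
received only the drug most effective for it, so the combination viability
per line is the minimum of the two monotherapy viabilities. The IDAcombo
score is the population-mean advantage of that combination over the best
monotherapy, in viability percentage points, maximized over the trimmed
concentration grid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ADVANCED_STATUSES, DoseResponsePanel, DrugAnnotationTable, PipelineError
from .fingerprint import ConsensusClusterResult, FingerprintMatrix
from .candidates import similar_fingerprint_drugs

#: score above which a combination is flagged as worth reporting
DEFAULT_SCORE_THRESHOLD = 1.0


def trim_concentrations(panel: DoseResponsePanel) -> DoseResponsePanel:
    """Drop the lowest and highest concentration columns (positional).

    The screening extremes sit outside the pharmacologically useful range,
    so predictions use the interior grid only.
    """
    if len(panel.concentrations) < 4:
        raise PipelineError("need >= 4 concentrations to trim the extremes")
    keep = panel.viability.columns[1:-1]
    return DoseResponsePanel(panel.viability[keep], panel.concentrations[1:-1])


def _viability_grid(panel: DoseResponsePanel, drug: str) -> pd.DataFrame:
    try:
        grid = panel.viability.xs(drug, level="drug")
    except KeyError:
        raise PipelineError(f"drug {drug!r} not in panel") from None
    return grid  # cell_line x concentration


def ida_combo_viability(
    panel: DoseResponsePanel,
    drug_a: str,
    conc_index_a: int,
    drug_b: str,
    conc_index_b: int,
) -> tuple[pd.Series, float]:
    """Per-line IDA combination viability min(V_A, V_B) and its mean.

    Concentrations are addressed by column index into the panel's grid; the
    two drugs are matched on their shared cell lines.
    """
    va = _viability_grid(panel, drug_a)
    vb = _viability_grid(panel, drug_b)
    shared = va.index.intersection(vb.index)
    if shared.empty:
        raise PipelineError(f"no shared cell lines between {drug_a} and {drug_b}")
    combo = np.minimum(
        va.loc[shared].iloc[:, conc_index_a].to_numpy(),
        vb.loc[shared].iloc[:, conc_index_b].to_numpy(),
    )
    per_line = pd.Series(combo, index=shared, name="combo_viability")
    return per_line, float(per_line.mean())


@dataclass
class ComboPrediction:
    drug_a: str
    drug_b: str
    conc_a_um: float
    conc_b_um: float
    mean_combo_viability: float
    mean_best_monotherapy: float
    score: float  # viability percentage points
    n_shared_lines: int
    per_line: pd.DataFrame
    score_grid: pd.DataFrame  # conc_a x conc_b


def idacombo_score(
    panel: DoseResponsePanel, drug_a: str, drug_b: str
) -> ComboPrediction:
    """Max over concentration pairs of (best monotherapy mean - IDA combo mean).

    mean best-monotherapy viability = min of the two drugs' population-mean
    viabilities at the pair; the IDA combination mean is the population mean
    of per-line minima. The score is non-negative by construction
    (mean of minima <= min of means).
    """
    va = _viability_grid(panel, drug_a)
    vb = _viability_grid(panel, drug_b)
    shared = va.index.intersection(vb.index)
    if shared.empty:
        raise PipelineError(f"no shared cell lines between {drug_a} and {drug_b}")
    a = va.loc[shared].to_numpy(dtype=float)  # lines x nA
    b = vb.loc[shared].to_numpy(dtype=float)  # lines x nB
    combo = np.minimum(a[:, :, None], b[:, None, :]).mean(axis=0)  # nA x nB
    mono = np.minimum(a.mean(axis=0)[:, None], b.mean(axis=0)[None, :])
    grid = mono - combo
    ia, ib = np.unravel_index(np.argmax(grid), grid.shape)
    per_line = pd.DataFrame(
        {
            f"{drug_a}_viability": a[:, ia],
            f"{drug_b}_viability": b[:, ib],
            "combo_viability": np.minimum(a[:, ia], b[:, ib]),
        },
        index=shared,
    )
    return ComboPrediction(
        drug_a=drug_a,
        drug_b=drug_b,
        conc_a_um=float(panel.concentrations[ia]),
        conc_b_um=float(panel.concentrations[ib]),
        mean_combo_viability=float(combo[ia, ib]),
        mean_best_monotherapy=float(mono[ia, ib]),
        score=float(grid[ia, ib]),
        n_shared_lines=len(shared),
        per_line=per_line,
        score_grid=pd.DataFrame(
            grid, index=panel.concentrations, columns=panel.concentrations
        ),
    )


def enumerate_combinations(
    strategy: str,
    clusters: ConsensusClusterResult,
    anchor: str,
    panel: DoseResponsePanel,
    ann: DrugAnnotationTable,
    fp: FingerprintMatrix,
    partner_cluster: int | None = None,
    min_similarity: float = 0.8,
    statuses: frozenset[str] = ADVANCED_STATUSES,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Score fingerprint-guided combinations, ranked by IDAcombo score.

    ``vertical``: all pairs within the anchor plus its fingerprint-similar
    advanced-status drugs (same pathway axis). ``horizontal``: anchor paired
    with every advanced-status member of ``partner_cluster`` (complementary
    axis). Pairs with score > ``score_threshold`` carry a reporting flag.
    """
    panel_drugs = set(panel.drugs)
    if anchor not in panel_drugs:
        raise PipelineError(f"anchor drug {anchor!r} not in dose-response panel")
    if strategy == "vertical":
        similar = similar_fingerprint_drugs(
            fp, anchor, min_similarity=min_similarity, statuses=statuses, ann=ann
        )
        group = [anchor] + [d for d in similar.index if d in panel_drugs]
        pairs = list(itertools.combinations(group, 2))
    elif strategy == "horizontal":
        if partner_cluster is None:
            raise ValueError("horizontal strategy requires partner_cluster")
        members = clusters.assignments.index[clusters.assignments == partner_cluster]
        partners = [
            d
            for d in members
            if d != anchor
            and d in panel_drugs
            and d in ann.drugs
            and ann.status_of(d) in statuses
        ]
        pairs = [(anchor, d) for d in partners]
    else:
        raise ValueError("strategy must be 'vertical' or 'horizontal'")

    if not pairs:
        warnings.warn(f"{strategy}: no candidate pairs to score", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "drugA", "drugB", "strategy", "score", "cA_uM", "cB_uM",
                "mean_combo_viability", "n_shared_lines", "flagged",
            ]
        )
    records = []
    for a, b in pairs:
        pred = idacombo_score(panel, a, b)
        records.append(
            {
                "drugA": a,
                "drugB": b,
                "strategy": strategy,
                "score": pred.score,
                "cA_uM": pred.conc_a_um,
                "cB_uM": pred.conc_b_um,
                "mean_combo_viability": pred.mean_combo_viability,
                "n_shared_lines": pred.n_shared_lines,
                "flagged": pred.score > score_threshold,
            }
        )
    out = pd.DataFrame(records).sort_values(
        ["score", "drugA", "drugB"], ascending=[False, True, True], kind="stable"
    )
    return out.reset_index(drop=True)


def pairwise_score_matrix(panel: DoseResponsePanel, drugs: list[str]) -> pd.DataFrame:
    """Symmetric drug x drug IDAcombo score matrix (vertical heatmap input)."""
    n = len(drugs)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        s = idacombo_score(panel, drugs[i], drugs[j]).score
        mat[i, j] = mat[j, i] = s
    return pd.DataFrame(mat, index=drugs, columns=drugs)
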