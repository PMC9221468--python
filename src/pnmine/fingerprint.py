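"""Drug fingerprints and Monti-style consensus clustering of drugs.

A drug's *fingerprint* is the vector of Pearson correlations between its
per-cell-line summary responses and each preserved module's eigengene.
Drugs are then clustered by resampled consensus clustering on the
correlation distance between fingerprint rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import EigengeneSet, PipelineError
from .drugscreen import ResponseSummary


@dataclass
class FingerprintMatrix:
    """Drug x preserved-module Pearson correlation matrix.

    Entries that cannot be computed (zero variance on either side) are NaN
    with a reason recorded in ``missing_reasons``.
    """

    values: pd.DataFrame
    n_points: int
    missing_reasons: dict[tuple[str, str], str]

    @property
    def drugs(self) -> pd.Index:
        return self.values.index

    @property
    def modules(self) -> pd.Index:
        return self.values.columns

    def complete_rows(self) -> pd.DataFrame:
        """Rows without missing entries (the clustering substrate)."""
        return self.values.dropna(axis=0)


def drug_module_correlations(
    summary: ResponseSummary,
    eig: EigengeneSet,
    preserved: list[str],
) -> FingerprintMatrix:
    """Pearson r between each drug's responses and each preserved eigengene.

    Responses and eigengenes are matched on shared cell lines; fewer than 3
    shared lines is an error. Zero variance on either side yields a missing
    entry with a reason code.
    """
    lines = [s for s in summary.per_line.columns if s in eig.samples]
    if len(lines) < 3:
        raise PipelineError(
            f"only {len(lines)} cell lines shared between responses and "
            "eigengenes; need >= 3 for a correlation"
        )
    missing_modules = [m for m in preserved if m not in eig.modules]
    if missing_modules:
        raise PipelineError(f"modules without eigengenes: {missing_modules}")
    resp = summary.per_line[lines]
    reasons: dict[tuple[str, str], str] = {}
    out = pd.DataFrame(
        np.nan, index=resp.index, columns=pd.Index(preserved, name="module")
    )
    for module in preserved:
        e = eig.scores.loc[module, lines].to_numpy(dtype=float)
        if e.std() == 0:
            for drug in resp.index:
                reasons[(drug, module)] = "zero-variance eigengene"
            continue
        for drug in resp.index:
            r = resp.loc[drug].to_numpy(dtype=float)
            if r.std() == 0:
                reasons[(drug, module)] = "zero-variance drug response"
                continue
            out.loc[drug, module] = pearsonr(r, e).statistic
    return FingerprintMatrix(out, len(lines), reasons)


def _correlation_distance(rows: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows."""
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(rows)
    cor = np.nan_to_num(cor, nan=0.0)
    d = 1.0 - np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


@dataclass
class ConsensusClusterResult:
    assignments: pd.Series  # drug -> cluster id (1..k)
    k: int
    consensus_matrix: pd.DataFrame  # drug x drug co-clustering proportions
    diagnostics: pd.DataFrame  # per-k: area, delta_area
    consensus_by_k: dict[int, pd.DataFrame]
    n_resample: int
    item_fraction: float
    seed: int


class DrugConsensusClusterer(BaseEstimator, ClusterMixin):
    """Monti-style consensus clustering over fingerprint rows.

    For each of ``n_resample`` rounds a fraction ``item_fraction`` of items
    is subsampled without replacement and clustered by average-linkage
    hierarchical clustering on 1 - Pearson row correlation, cut at each k in
    ``k_range``. The consensus matrix is the co-clustering proportion among
    co-sampled rounds; the final partition cuts an average-linkage tree on
    1 - consensus at the chosen k. k is chosen by the delta-area rule on the
    consensus CDF (largest proportional gain in area), unless ``force_k``
    pins it.

    Attributes (after fit): ``labels_``, ``k_``, ``consensus_matrix_``,
    ``diagnostics_``, ``consensus_by_k_``.
    """

    def __init__(
        self,
        k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
        n_resample: int = 100,
        item_fraction: float = 0.8,
        seed: int = 0,
        force_k: int | None = None,
    ):
        self.k_range = k_range
        self.n_resample = n_resample
        self.item_fraction = item_fraction
        self.seed = seed
        self.force_k = force_k

    def fit(self, X, y=None) -> "DrugConsensusClusterer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D fingerprint array")
        n = X.shape[0]
        ks = sorted(set(self.k_range))
        if not ks or ks[0] < 2 or ks[-1] > 12:
            raise ValueError("k_range must lie within [2, 12]")
        if not (0.5 < self.item_fraction <= 1.0):
            raise ValueError("item_fraction must lie in (0.5, 1]")
        if self.n_resample < 20:
            raise ValueError("n_resample < 20 gives an unstable consensus")
        if n < ks[-1] + 1:
            raise ValueError(f"{n} items cannot support k up to {ks[-1]}")

        rng = np.random.default_rng(self.seed)
        m = math.ceil(self.item_fraction * n)
        cosampled = np.zeros((n, n))
        coclustered = {k: np.zeros((n, n)) for k in ks}
        for _ in range(self.n_resample):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            link = average(_correlation_distance(X[idx]))
            pair = np.ix_(idx, idx)
            cosampled[pair] += 1.0
            for k in ks:
                labels = fcluster(link, t=k, criterion="maxclust")
                same = labels[:, None] == labels[None, :]
                coclustered[k][pair] += same
        if np.any(cosampled[np.triu_indices(n, 1)] == 0):
            warnings.warn(
                "some item pairs were never co-sampled; raise n_resample or "
                "item_fraction",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = {
                k: np.nan_to_num(coclustered[k] / cosampled, nan=0.0) for k in ks
            }
        for k in ks:
            np.fill_diagonal(consensus[k], 1.0)
            consensus[k] = (consensus[k] + consensus[k].T) / 2.0

        # area under the consensus CDF: integral of the ECDF over [0, 1]
        # equals 1 - mean of the off-diagonal consensus values
        iu = np.triu_indices(n, 1)
        areas = {k: 1.0 - float(consensus[k][iu].mean()) for k in ks}
        delta = {}
        for i, k in enumerate(ks):
            if i == 0:
                delta[k] = areas[k]
            else:
                prev = areas[ks[i - 1]]
                delta[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
        chosen = self.force_k if self.force_k is not None else max(ks, key=lambda k: delta[k])
        if chosen not in ks:
            raise ValueError(f"force_k={chosen} not in k_range {ks}")

        final_d = 1.0 - consensus[chosen]
        np.fill_diagonal(final_d, 0.0)
        labels = fcluster(
            average(squareform(final_d, checks=False)), t=chosen, criterion="maxclust"
        )
        self.labels_ = labels
        self.k_ = int(chosen)
        self.consensus_matrix_ = consensus[chosen]
        self.consensus_by_k_ = consensus
        self.diagnostics_ = pd.DataFrame(
            {"k": ks, "area": [areas[k] for k in ks], "delta_area": [delta[k] for k in ks]}
        ).set_index("k")
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def consensus_cluster_drugs(
    fp: FingerprintMatrix,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    n_resample: int = 100,
    item_fraction: float = 0.8,
    seed: int = 0,
    force_k: int | None = None,
) -> ConsensusClusterResult:
    """Consensus-cluster drugs by fingerprint; rows with missing entries are
    dropped with a warning (imputed fingerprints would be fabricated)."""
    rows = fp.complete_rows()
    dropped = len(fp.values) - len(rows)
    if dropped:
        warnings.warn(
            f"dropping {dropped} drugs with missing fingerprint entries",
            stacklevel=2,
        )
    if rows.empty:
        raise PipelineError("no complete fingerprint rows to cluster")
    est = DrugConsensusClusterer(
        k_range=tuple(k_range),
        n_resample=n_resample,
        item_fraction=item_fraction,
        seed=seed,
        force_k=force_k,
    ).fit(rows.to_numpy())
    drugs = rows.index
    return ConsensusClusterResult(
        assignments=pd.Series(est.labels_, index=drugs, name="cluster"),
        k=est.k_,
        consensus_matrix=pd.DataFrame(est.consensus_matrix_, index=drugs, columns=drugs),
        diagnostics=est.diagnostics_,
        consensus_by_k={
            k: pd.DataFrame(v, index=drugs, columns=drugs)
            for k, v in est.consensus_by_k_.items()
        },
        n_resample=n_resample,
        item_fraction=item_fraction,
        seed=seed,
    )
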