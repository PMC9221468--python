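"""Consensus weighted co-expression network construction and module analysis.

Pipeline: soft-thresholded adjacency per dataset -> topological overlap
matrix (TOM) -> quantile-scaled elementwise-minimum consensus TOM ->
average-linkage module detection with eigengene merging -> module
eigengenes, eigengene adjacency, and permutation Z-summary module
preservation between the reference (cell-line) and test (tumor) datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import EigengeneSet, ExpressionMatrix, MergedExpression, PipelineError

DEFAULT_SOFT_POWER = 8
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_CUT_HEIGHT = 0.995
DEFAULT_MERGE_CUT = 0.25
DEFAULT_CONSENSUS_QUANTILE = 0.95
SCALE_FREE_R2_TARGET = 0.8

GREY = "grey"

# Deterministic module palette, assigned in descending size order. Mirrors the
# conventional WGCNA color vocabulary but the mapping here is fixed, not random.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
)


@dataclass
class Network:
    """Symmetric gene similarity matrix in [0, 1] with unit diagonal."""

    node_ids: pd.Index
    matrix: np.ndarray
    kind: str  # "adjacency" | "tom" | "consensus_tom"
    beta: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.node_ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match node ids")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("network matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("network diagonal must be 1")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("network entries must lie in [0, 1]")
        self.matrix = np.clip(m, 0.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class SoftPowerReport:
    candidates: list[int]
    r_squared: dict[int, float]  # signed scale-free fit R^2; NaN = undefined
    mean_connectivity: dict[int, float]
    chosen: int
    criterion_met: bool


@dataclass
class ModuleAssignment:
    """Gene -> module color map; ``grey`` collects unassigned genes."""

    labels: pd.Series  # index: gene ids, values: color strings

    @property
    def modules(self) -> list[str]:
        sizes = self.sizes()
        return [m for m in sizes.index if m != GREY]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_in(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("module").rename_axis("gene").reset_index()


@dataclass
class PreservationStats:
    """Permutation Z statistics of module preservation in a test dataset."""

    table: pd.DataFrame  # index: module; columns: z_density, z_connectivity, z_summary
    n_permutations: int
    seed: int

    def preserved(self, threshold: float = 5.0) -> list[str]:
        z = self.table["z_summary"]
        return list(z.index[z > threshold])


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Gene-gene Pearson correlations; zero-variance genes correlate 0."""
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance genes: correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(values)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def adjacency(expr: ExpressionMatrix, beta: float = DEFAULT_SOFT_POWER) -> Network:
    """Unsigned soft-thresholded adjacency a_ij = |cor(i, j)|^beta."""
    if expr.n_samples < 3:
        raise PipelineError("adjacency needs >= 3 samples")
    cor = correlation_matrix(expr.values.to_numpy())
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return Network(expr.gene_ids, adj, "adjacency", beta)


def tom(adj: Network) -> Network:
    """Topological overlap: w_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    L_ij sums shared-neighbor adjacency products over u != i, j and k_i is the
    connectivity of node i (diagonal excluded).
    """
    if adj.kind != "adjacency":
        raise ValueError("tom expects an adjacency-kind network")
    a = adj.matrix.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # with zero diagonal, u=i and u=j terms vanish automatically
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    w = (l + a) / denom
    np.fill_diagonal(w, 1.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    return Network(adj.node_ids, w, "tom", adj.beta)


def consensus_tom(
    tom_cell: Network,
    tom_tumor: Network,
    quantile: float = DEFAULT_CONSENSUS_QUANTILE,
) -> Network:
    """Quantile-scale the tumor TOM to the cell-line TOM, then take the min.

    The tumor TOM is multiplied by the ratio of the two matrices' ``quantile``
    off-diagonal values so that systematic density differences between the
    datasets do not dominate the elementwise minimum.
    """
    if not tom_cell.node_ids.equals(tom_tumor.node_ids):
        raise PipelineError("consensus requires identical node sets in order")
    iu = np.triu_indices(tom_cell.n_nodes, k=1)
    q_cell = np.quantile(tom_cell.matrix[iu], quantile)
    q_tumor = np.quantile(tom_tumor.matrix[iu], quantile)
    scale = 1.0 if q_tumor == 0 else q_cell / q_tumor
    scaled = tom_tumor.matrix * scale
    cons = np.minimum(tom_cell.matrix, scaled)
    np.fill_diagonal(cons, 1.0)
    cons = np.clip(cons, 0.0, 1.0)
    return Network(tom_cell.node_ids, cons, "consensus_tom", tom_cell.beta)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over equal-width connectivity bins.

    Returns NaN when the fit is undefined (too few nodes or occupied bins,
    or degenerate connectivity).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 10 or np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq, centers = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0:
            continue
        freq.append(len(members) / len(k))
        centers.append(members.mean())
    if len(freq) < 3:
        return float("nan")
    x = np.log10(np.asarray(centers))
    y = np.log10(np.asarray(freq))
    if np.ptp(x) == 0:
        return float("nan")
    fit = linregress(x, y)
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def pick_soft_power(
    expr: MergedExpression,
    candidates: list[int] | None = None,
    r2_target: float = SCALE_FREE_R2_TARGET,
    default: int = DEFAULT_SOFT_POWER,
) -> SoftPowerReport:
    """Choose the soft power by the approximate scale-free topology criterion.

    The chosen power is the smallest candidate whose signed scale-free fit
    R^2 reaches ``r2_target`` in *both* datasets; when no candidate
    qualifies, the configured default (8) is used.
    """
    if candidates is None:
        candidates = [1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 18, 20]
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate powers")
    r2: dict[int, float] = {}
    mean_k: dict[int, float] = {}
    chosen, met = default, False
    for beta in candidates:
        fits = []
        ks = []
        for block in (expr.cell, expr.tumor):
            a = adjacency(block, beta).matrix.copy()
            np.fill_diagonal(a, 0.0)
            k = a.sum(axis=1)
            ks.append(k.mean())
            fits.append(_scale_free_fit(k))
        # criterion must hold in both datasets: take the weaker fit,
        # undefined (NaN) in either dataset makes the pair undefined
        r2[beta] = float("nan") if np.any(np.isnan(fits)) else float(min(fits))
        mean_k[beta] = float(np.mean(ks))
        if not met and np.isfinite(r2[beta]) and r2[beta] >= r2_target:
            chosen, met = beta, True
    return SoftPowerReport(list(candidates), r2, mean_k, chosen, met)


def _name_modules(labels: np.ndarray) -> dict[int, str]:
    """Map integer cluster ids (0 = grey) to colors by descending size."""
    ids, counts = np.unique(labels[labels != 0], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    names = {0: GREY}
    for rank, cid in enumerate(order):
        if rank < len(MODULE_COLORS):
            names[cid] = MODULE_COLORS[rank]
        else:
            names[cid] = f"module{rank + 1}"
    return names


def detect_modules(
    consensus: Network,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    merge_cut: float = DEFAULT_MERGE_CUT,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    expr: MergedExpression | None = None,
) -> ModuleAssignment:
    """Detect modules on the consensus TOM.

    Average-linkage hierarchical clustering of 1 - TOM, static tree cut at
    ``cut_height``; clusters below ``min_module_size`` become grey. When the
    merged expression is supplied, modules whose eigengenes correlate above
    ``1 - merge_cut`` (in the cell-line block) are iteratively merged.
    Surviving modules are named from a fixed palette, largest first.
    """
    if consensus.kind not in ("tom", "consensus_tom"):
        raise ValueError("detect_modules expects a TOM-kind network")
    diss = 1.0 - consensus.matrix
    np.fill_diagonal(diss, 0.0)
    link = average(squareform(diss, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = raw.copy()
    for cid, count in zip(*np.unique(raw, return_counts=True)):
        if count < min_module_size:
            labels[raw == cid] = 0
    if (labels == 0).all():
        warnings.warn("no modules found: every gene is grey", stacklevel=2)
        return ModuleAssignment(
            pd.Series(GREY, index=consensus.node_ids, name="module")
        )

    if expr is not None and merge_cut > 0:
        labels = _merge_by_eigengene(labels, consensus.node_ids, expr, merge_cut)

    names = _name_modules(labels)
    assigned = pd.Series(
        [names[c] for c in labels], index=consensus.node_ids, name="module"
    )
    return ModuleAssignment(assigned)


def _merge_by_eigengene(
    labels: np.ndarray,
    node_ids: pd.Index,
    expr: MergedExpression,
    merge_cut: float,
) -> np.ndarray:
    """Iteratively merge module pairs with eigengene correlation > 1 - merge_cut."""
    labels = labels.copy()
    threshold = 1.0 - merge_cut
    while True:
        mods = [c for c in np.unique(labels) if c != 0]
        if len(mods) < 2:
            return labels
        eig = {}
        for cid in mods:
            genes = node_ids[labels == cid]
            block = expr.cell.values.loc[genes].to_numpy()
            eig[cid] = _first_pc(block)[0]
        best, best_r = None, threshold
        for i, ci in enumerate(mods):
            for cj in mods[i + 1:]:
                r = float(np.corrcoef(eig[ci], eig[cj])[0, 1])
                if abs(r) > best_r:
                    best, best_r = (ci, cj), abs(r)
        if best is None:
            return labels
        labels[labels == best[1]] = best[0]


def _first_pc(block: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector of a row-standardized gene block.

    Returns (eigengene over samples scaled to sd 1, variance explained),
    oriented so the mean correlation with the block's rows is >= 0.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] < 2:
        raise PipelineError("eigengene needs >= 2 samples")
    mean = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (block - mean) / sd
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    varexp = float(s[0] ** 2 / np.sum(s**2))
    # orient: mean correlation of module genes with the eigengene >= 0
    cors = np.array([np.corrcoef(row, v)[0, 1] for row in z])
    if np.nanmean(cors) < 0:
        v = -v
    v = v - v.mean()
    v_sd = v.std(ddof=1)
    if v_sd > 0:
        v = v / v_sd
    return v, varexp


def module_eigengenes(
    expr: ExpressionMatrix, modules: ModuleAssignment
) -> EigengeneSet:
    """First-principal-component eigengene per non-grey module.

    Gene rows are standardized within ``expr`` before the SVD; a single-gene
    module's eigengene is that gene's standardized profile.
    """
    scores = {}
    varexp = {}
    for mod in modules.modules:
        genes = modules.genes_in(mod)
        missing = [g for g in genes if g not in expr.gene_ids]
        if missing:
            raise PipelineError(f"module {mod} genes absent from expression: {missing[:5]}")
        block = expr.values.loc[genes].to_numpy(dtype=float)
        if block.shape[0] == 1:
            row = block[0] - block[0].mean()
            sd = row.std(ddof=1)
            scores[mod] = row / sd if sd > 0 else row
            varexp[mod] = 1.0
        else:
            scores[mod], varexp[mod] = _first_pc(block)
    if not scores:
        raise PipelineError("no non-grey modules: cannot compute eigengenes")
    frame = pd.DataFrame(scores, index=expr.sample_ids).T
    return EigengeneSet(frame, pd.Series(varexp, name="variance_explained"))


def eigengene_adjacency(eig: EigengeneSet) -> pd.DataFrame:
    """A_IJ = (1 + cor(E_I, E_J)) / 2 — similarity of module eigengenes."""
    if len(eig.modules) < 2:
        raise PipelineError("eigengene adjacency needs >= 2 modules")
    cor = np.corrcoef(eig.scores.to_numpy())
    adj = (1.0 + np.clip(cor, -1.0, 1.0)) / 2.0
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=eig.modules, columns=eig.modules)


def _module_stats(
    ref_adj: np.ndarray, test_adj: np.ndarray, idx: np.ndarray
) -> tuple[float, float]:
    """(density, connectivity) preservation statistics for one gene set.

    density = mean off-diagonal intramodular adjacency in the test set;
    connectivity = correlation of intramodular connectivity vectors between
    reference and test.
    """
    sub_ref = ref_adj[np.ix_(idx, idx)]
    sub_test = test_adj[np.ix_(idx, idx)]
    n = len(idx)
    off = ~np.eye(n, dtype=bool)
    density = float(sub_test[off].mean())
    k_ref = sub_ref[off].reshape(n, n - 1).sum(axis=1)
    k_test = sub_test[off].reshape(n, n - 1).sum(axis=1)
    if k_ref.std() == 0 or k_test.std() == 0:
        connectivity = 0.0
    else:
        connectivity = float(np.corrcoef(k_ref, k_test)[0, 1])
    return density, connectivity


def preservation_zsummary(
    expr_ref: ExpressionMatrix,
    expr_test: ExpressionMatrix,
    modules: ModuleAssignment,
    n_perm: int = 100,
    seed: int = 0,
    beta: float = DEFAULT_SOFT_POWER,
) -> PreservationStats:
    """Permutation Z-summary of module preservation in the test dataset.

    For each non-grey module the observed density and connectivity statistics
    are compared with a null built from ``n_perm`` random gene sets of equal
    size; Z_summary is the mean of the two Z scores. Modules smaller than 3
    genes are reported as missing.
    """
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50 for a usable null")
    genes = expr_ref.gene_ids
    if not set(modules.labels.index).issubset(set(genes)):
        raise PipelineError("module genes missing from reference expression")
    ref_adj = adjacency(expr_ref, beta).matrix
    test_adj = adjacency(expr_test.subset_genes(genes), beta).matrix
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    rows = {}
    for mod in modules.modules:
        idx = np.array([pos[g] for g in modules.genes_in(mod)])
        if len(idx) < 3:
            rows[mod] = (np.nan, np.nan, np.nan)
            continue
        obs_d, obs_c = _module_stats(ref_adj, test_adj, idx)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for p in range(n_perm):
            rand = rng.choice(len(genes), size=len(idx), replace=False)
            null_d[p], null_c[p] = _module_stats(ref_adj, test_adj, rand)
        sd_d = max(null_d.std(ddof=1), 1e-12)
        sd_c = max(null_c.std(ddof=1), 1e-12)
        z_d = (obs_d - null_d.mean()) / sd_d
        z_c = (obs_c - null_c.mean()) / sd_c
        rows[mod] = (z_d, z_c, (z_d + z_c) / 2.0)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["z_density", "z_connectivity", "z_summary"]
    ).rename_axis("module")
    return PreservationStats(table, n_perm, seed)


class ConsensusModuleDetector(BaseEstimator, ClusterMixin):
    """Consensus co-expression module detection as an sklearn-style estimator.

    Fits on a :class:`MergedExpression` (gene-intersected, per-dataset
    standardized cell-line + tumor blocks): builds soft-thresholded
    adjacencies, per-dataset TOMs, the quantile-scaled consensus TOM, detects
    modules by average-linkage clustering with eigengene merging, and
    computes module eigengenes on each block.

    Parameters
    ----------
    power : soft-thresholding exponent beta (default 8).
    min_module_size : smallest retained module (default 30).
    merge_cut : eigengene-merge dissimilarity cut; modules with eigengene
        correlation > 1 - merge_cut merge (default 0.25).
    cut_height : static tree-cut height on the 1 - TOM dendrogram.
    consensus_quantile : quantile used to scale the tumor TOM.

    Attributes
    ----------
    labels_ : ndarray of module colors per gene.
    modules_ : ModuleAssignment.
    consensus_ : consensus TOM Network.
    eigengenes_cell_, eigengenes_tumor_ : EigengeneSet per dataset.
    """

    def __init__(
        self,
        power: float = DEFAULT_SOFT_POWER,
        min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
        merge_cut: float = DEFAULT_MERGE_CUT,
        cut_height: float = DEFAULT_CUT_HEIGHT,
        consensus_quantile: float = DEFAULT_CONSENSUS_QUANTILE,
    ):
        self.power = power
        self.min_module_size = min_module_size
        self.merge_cut = merge_cut
        self.cut_height = cut_height
        self.consensus_quantile = consensus_quantile

    def fit(self, X: MergedExpression, y=None) -> "ConsensusModuleDetector":
        if not isinstance(X, MergedExpression):
            raise TypeError("ConsensusModuleDetector fits on a MergedExpression")
        adj_cell = adjacency(X.cell, self.power)
        adj_tumor = adjacency(X.tumor, self.power)
        self.tom_cell_ = tom(adj_cell)
        self.tom_tumor_ = tom(adj_tumor)
        self.consensus_ = consensus_tom(
            self.tom_cell_, self.tom_tumor_, self.consensus_quantile
        )
        self.modules_ = detect_modules(
            self.consensus_,
            min_module_size=self.min_module_size,
            merge_cut=self.merge_cut,
            cut_height=self.cut_height,
            expr=X,
        )
        self.labels_ = self.modules_.labels.to_numpy()
        if self.modules_.modules:
            self.eigengenes_cell_ = module_eigengenes(X.cell, self.modules_)
            self.eigengenes_tumor_ = module_eigengenes(X.tumor, self.modules_)
        return self

    def fit_predict(self, X: MergedExpression, y=None) -> np.ndarray:
        return self.fit(X).labels_
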