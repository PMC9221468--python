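"""End-to-end orchestration: files in, ranked candidate lists out.

Each stage reads plain-text inputs (TSV/CSV), writes its outputs into the
artifact directory, and drops a JSON provenance sidecar (parameters, derived
seed, package version, input checksums) next to every file it writes.
Stages are pure functions of (inputs, config, seed): rerunning with the same
config and inputs reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import candidates as candidates_mod
from . import drugscreen, enrichment, fingerprint, idacombo, preprocess
from .containers import (
    DoseResponsePanel,
    DrugAnnotationTable,
    EigengeneSet,
    ExpressionMatrix,
    PipelineError,
)
from .fingerprint import ConsensusClusterResult, FingerprintMatrix
from .network import (
    ConsensusModuleDetector,
    ModuleAssignment,
    pick_soft_power,
    preservation_zsummary,
)

log = logging.getLogger("pnmine")

_STAGE_INDEX = {
    "preprocess": 1,
    "network": 2,
    "screen": 3,
    "fingerprint": 4,
    "cluster": 5,
    "rank": 6,
    "combo": 7,
    "enrich": 8,
}


@dataclass
class PipelineConfig:
    """All file paths and stage parameters for one pipeline run."""

    cell_expression: str
    tumor_expression: str
    screen: str
    annotations: str
    outdir: str
    gmt: str | None = None
    # preprocess
    mad_threshold: float = 1000.0
    log_transform: bool = False
    # network
    power: float = 8.0
    pick_power: bool = False
    min_module_size: int = 30
    merge_cut: float = 0.25
    cut_height: float = 0.995
    consensus_quantile: float = 0.95
    n_perm: int = 100
    preservation_z: float = 5.0
    # screen filters
    viability_cutoff: float = 55.0
    min_pchembl: float = 6.0
    keep_missing_pchembl: bool = True
    advanced_statuses: list[str] = field(
        default_factory=lambda: ["FDA-approved", "Phase II", "Phase III"]
    )
    # clustering
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6, 7, 8])
    n_resample: int = 100
    item_fraction: float = 0.8
    force_k: int | None = None
    # candidates & combinations
    top_n: int = 15
    min_similarity: float = 0.8
    score_threshold: float = 1.0
    anchor_drug: str | None = None
    partner_cluster: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def stage_seed(self, stage: str) -> int:
        """Fixed derivation of per-stage seeds from the global seed."""
        return int(
            np.random.SeedSequence([self.seed, _STAGE_INDEX[stage]]).generate_state(1)[0]
            % (2**31)
        )


def _pkg_version() -> str:
    try:
        return version("pnmine")
    except PackageNotFoundError:
        return "unknown"


def _checksum(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def _write_provenance(
    artifact: Path, stage: str, config: PipelineConfig, inputs: list[Path], **extra
) -> None:
    sidecar = artifact.with_name(artifact.name + ".prov.json")
    payload = {
        "stage": stage,
        "seed": config.stage_seed(stage) if stage in _STAGE_INDEX else config.seed,
        "version": _pkg_version(),
        "parameters": dataclasses.asdict(config),
        "input_checksums": {str(p): _checksum(p) for p in inputs if Path(p).exists()},
        **extra,
    }
    sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------- stages


def stage_preprocess(config: PipelineConfig):
    out = _outdir(config)
    cell = ExpressionMatrix.from_tsv(config.cell_expression, "cell_line")
    tumor = ExpressionMatrix.from_tsv(config.tumor_expression, "tumor")
    if config.log_transform:
        cell = ExpressionMatrix(np.log2(cell.values + 1.0), "cell_line")
        tumor = ExpressionMatrix(np.log2(tumor.values + 1.0), "tumor")
    filtered = preprocess.mad_filter(cell, config.mad_threshold)
    if filtered.n_genes == 0:
        raise PipelineError("MAD filter removed every gene; lower the threshold")
    merged = preprocess.intersect_and_merge(filtered, tumor)
    merged.cell.to_tsv(out / "merged_cell.tsv")
    merged.tumor.to_tsv(out / "merged_tumor.tsv")
    report = {
        "genes_in": cell.n_genes,
        "genes_after_mad": filtered.n_genes,
        "genes_shared": int(len(merged.gene_ids)),
        "mad_threshold": config.mad_threshold,
        "log_transform": config.log_transform,
    }
    (out / "preprocess_report.json").write_text(json.dumps(report, indent=1))
    inputs = [Path(config.cell_expression), Path(config.tumor_expression)]
    for name in ("merged_cell.tsv", "merged_tumor.tsv", "preprocess_report.json"):
        _write_provenance(out / name, "preprocess", config, inputs)
    log.info("preprocess: %s", report)
    return merged


def _load_merged(config: PipelineConfig):
    out = _outdir(config)
    from .containers import MergedExpression

    return MergedExpression(
        ExpressionMatrix.from_tsv(out / "merged_cell.tsv", "cell_line"),
        ExpressionMatrix.from_tsv(out / "merged_tumor.tsv", "tumor"),
    )


def stage_network(config: PipelineConfig, merged=None):
    out = _outdir(config)
    if merged is None:
        merged = _load_merged(config)
    power = config.power
    if config.pick_power:
        report = pick_soft_power(merged, default=int(config.power))
        power = report.chosen
        pd.DataFrame(
            {
                "power": report.candidates,
                "signed_r2": [report.r_squared[b] for b in report.candidates],
                "mean_connectivity": [
                    report.mean_connectivity[b] for b in report.candidates
                ],
            }
        ).to_csv(out / "soft_power.csv", index=False)
        _write_provenance(out / "soft_power.csv", "network", config, [])
    detector = ConsensusModuleDetector(
        power=power,
        min_module_size=config.min_module_size,
        merge_cut=config.merge_cut,
        cut_height=config.cut_height,
        consensus_quantile=config.consensus_quantile,
    ).fit(merged)
    modules = detector.modules_
    if not modules.modules:
        raise PipelineError("network stage found no modules")
    preservation = preservation_zsummary(
        merged.cell,
        merged.tumor,
        modules,
        n_perm=config.n_perm,
        seed=config.stage_seed("network"),
        beta=power,
    )
    modules.to_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
    detector.eigengenes_cell_.to_tsv(out / "eigengenes_cell.tsv")
    detector.eigengenes_tumor_.to_tsv(out / "eigengenes_tumor.tsv")
    preservation.table.to_csv(out / "preservation.tsv", sep="\t")
    for name in (
        "modules.tsv",
        "eigengenes_cell.tsv",
        "eigengenes_tumor.tsv",
        "preservation.tsv",
    ):
        _write_provenance(out / name, "network", config, [], power=power)
    log.info(
        "network: %d modules, %d preserved at Z > %s",
        len(modules.modules),
        len(preservation.preserved(config.preservation_z)),
        config.preservation_z,
    )
    return detector, preservation


def stage_screen(config: PipelineConfig):
    out = _outdir(config)
    panel = DoseResponsePanel.from_csv(config.screen)
    ann = DrugAnnotationTable.from_csv(config.annotations)
    summary = drugscreen.summarize_responses(panel)
    survivors_v = drugscreen.viability_prefilter(summary, config.viability_cutoff)
    survivors_a = drugscreen.annotation_filter(
        ann,
        min_pchembl=config.min_pchembl,
        keep_missing_pchembl=config.keep_missing_pchembl,
    )
    table = pd.DataFrame(
        {
            "median_response": summary.median_response,
            "passes_viability": summary.median_response.index.isin(list(survivors_v)),
            "passes_annotation": summary.median_response.index.isin(list(survivors_a)),
        }
    ).rename_axis("drug")
    table.to_csv(out / "screen_filters.csv")
    summary.per_line.to_csv(out / "response_summary.csv")
    inputs = [Path(config.screen), Path(config.annotations)]
    for name in ("screen_filters.csv", "response_summary.csv"):
        _write_provenance(out / name, "screen", config, inputs)
    log.info(
        "screen: %d/%d drugs pass viability < %s",
        len(survivors_v),
        len(summary.per_line),
        config.viability_cutoff,
    )
    return panel, ann, summary, survivors_v & survivors_a


def stage_fingerprint(config: PipelineConfig, summary, eig: EigengeneSet, preserved, keep):
    out = _outdir(config)
    restricted = drugscreen.ResponseSummary(
        summary.per_line.loc[sorted(keep & set(summary.per_line.index))]
    )
    fp = fingerprint.drug_module_correlations(restricted, eig, list(preserved))
    fp.values.to_csv(out / "fingerprints.tsv", sep="\t", index_label="drug")
    _write_provenance(
        out / "fingerprints.tsv", "fingerprint", config, [], preserved=list(preserved)
    )
    return fp


def stage_cluster(config: PipelineConfig, fp: FingerprintMatrix):
    out = _outdir(config)
    result = fingerprint.consensus_cluster_drugs(
        fp,
        k_range=tuple(config.k_range),
        n_resample=config.n_resample,
        item_fraction=config.item_fraction,
        seed=config.stage_seed("cluster"),
        force_k=config.force_k,
    )
    result.assignments.rename_axis("drug").to_csv(out / "drug_clusters.csv")
    result.consensus_matrix.to_csv(out / "consensus_matrix.tsv", sep="\t")
    result.diagnostics.to_csv(out / "cluster_diagnostics.csv")
    for name in ("drug_clusters.csv", "consensus_matrix.tsv", "cluster_diagnostics.csv"):
        _write_provenance(out / name, "cluster", config, [], chosen_k=result.k)
    log.info("cluster: chose k=%d for %d drugs", result.k, len(result.assignments))
    return result


def stage_rank(config: PipelineConfig, fp, clusters, ann):
    out = _outdir(config)
    ranked = candidates_mod.rank_candidates(
        fp,
        clusters,
        ann,
        top_n=config.top_n,
        statuses=frozenset(config.advanced_statuses),
    )
    ranked.to_csv(out / "candidate_list1.csv", index=False)
    # compact Table-1-style layout: one (drug, score) pair per cluster column
    wide = {
        f"cluster{c}": g[["drug", "score"]].reset_index(drop=True)
        for c, g in ranked.groupby("cluster")
    }
    if wide:
        compact = pd.concat(wide, axis=1)
        compact.to_csv(out / "candidate_list1_wide.csv", index=False)
    _write_provenance(out / "candidate_list1.csv", "rank", config, [])
    return ranked


def _choose_anchor(ranked: pd.DataFrame) -> str:
    if ranked.empty:
        raise PipelineError("cannot choose an anchor drug: empty candidate list")
    return ranked.sort_values(["score", "drug"], kind="stable")["drug"].iloc[0]


def choose_partner_cluster(
    fp: FingerprintMatrix, clusters: ConsensusClusterResult, anchor: str
) -> int:
    """Cluster whose mean fingerprint is most anti-correlated with the
    anchor's cluster mean (the complementary, horizontal-combination axis)."""
    rows = fp.complete_rows()
    anchor_cluster = int(clusters.assignments.loc[anchor])
    means = rows.groupby(clusters.assignments).mean()
    anchor_mean = means.loc[anchor_cluster].to_numpy()
    best, best_r = None, np.inf
    for c in means.index:
        if int(c) == anchor_cluster:
            continue
        r = float(np.corrcoef(anchor_mean, means.loc[c].to_numpy())[0, 1])
        if r < best_r:
            best, best_r = int(c), r
    if best is None:
        raise PipelineError("no partner cluster available")
    return best


def stage_combo(config: PipelineConfig, panel, clusters, ann, fp, ranked):
    out = _outdir(config)
    trimmed = idacombo.trim_concentrations(panel)
    anchor = config.anchor_drug or _choose_anchor(ranked)
    vertical = idacombo.enumerate_combinations(
        "vertical",
        clusters,
        anchor,
        trimmed,
        ann,
        fp,
        min_similarity=config.min_similarity,
        statuses=frozenset(config.advanced_statuses),
        score_threshold=config.score_threshold,
    )
    partner = config.partner_cluster
    if partner is None:
        partner = choose_partner_cluster(fp, clusters, anchor)
    horizontal = idacombo.enumerate_combinations(
        "horizontal",
        clusters,
        anchor,
        trimmed,
        ann,
        fp,
        partner_cluster=partner,
        statuses=frozenset(config.advanced_statuses),
        score_threshold=config.score_threshold,
    )
    combined = pd.concat([vertical, horizontal], ignore_index=True)
    combined.to_csv(out / "candidate_list2.csv", index=False)
    vertical_drugs = sorted(
        set(vertical["drugA"]) | set(vertical["drugB"]) | {anchor}
    )
    matrix = idacombo.pairwise_score_matrix(trimmed, vertical_drugs)
    matrix.to_csv(out / "vertical_score_matrix.tsv", sep="\t")
    for name in ("candidate_list2.csv", "vertical_score_matrix.tsv"):
        _write_provenance(
            out / name, "combo", config, [], anchor=anchor, partner_cluster=partner,
            score_definition=(
                "best monotherapy mean viability - IDA combo mean viability, "
                "maximized over the trimmed concentration grid (percentage points)"
            ),
        )
    log.info("combo: anchor=%s partner_cluster=%d pairs=%d", anchor, partner, len(combined))
    return combined


def stage_enrich(config: PipelineConfig, modules: ModuleAssignment):
    out = _outdir(config)
    if config.gmt is None:
        return None
    collection = enrichment.read_gmt(config.gmt)
    universe = set(modules.labels.index)
    results = {}
    for mod in modules.modules:
        table = enrichment.hypergeom_enrich(
            set(modules.genes_in(mod)), universe, collection
        )
        path = out / f"enrichment_{mod}.csv"
        table.to_csv(path, index=False)
        _write_provenance(path, "enrich", config, [Path(config.gmt)])
        results[mod] = table
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; halts with the stage name on failure."""
    stage = "preprocess"
    try:
        merged = stage_preprocess(config)
        stage = "network"
        detector, preservation = stage_network(config, merged)
        preserved = preservation.preserved(config.preservation_z)
        if not preserved:
            raise PipelineError("no preserved modules above the Z-summary threshold")
        stage = "screen"
        panel, ann, summary, keep = stage_screen(config)
        stage = "fingerprint"
        fp = stage_fingerprint(
            config, summary, detector.eigengenes_cell_, preserved, keep
        )
        stage = "cluster"
        clusters = stage_cluster(config, fp)
        stage = "rank"
        ranked = stage_rank(config, fp, clusters, ann)
        stage = "combo"
        combos = stage_combo(config, panel, clusters, ann, fp, ranked)
        stage = "enrich"
        enrich = stage_enrich(config, detector.modules_)
    except Exception as err:
        raise PipelineError(f"pipeline failed at stage {stage!r}: {err}") from err
    return {
        "merged": merged,
        "detector": detector,
        "preservation": preservation,
        "preserved": preserved,
        "panel": panel,
        "annotations": ann,
        "summary": summary,
        "fingerprints": fp,
        "clusters": clusters,
        "candidate_list1": ranked,
        "candidate_list2": combos,
        "enrichment": enrich,
        "outdir": Path(config.outdir),
    }
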