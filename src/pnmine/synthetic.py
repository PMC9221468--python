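"""Synthetic paired transcriptomes, drug screens, and annotations.

The generator plants known structure so every downstream stage has a
parameter-recovery oracle:

* expression follows a latent-factor (spiked covariance) model — each module
  is one latent factor per dataset with positive gene loadings, so a single
  dominant eigenvector per module exists by construction and eigengene
  recovery is well-defined;
* preserved modules re-use their loading structure in the tumor dataset
  (with an independent per-sample factor), non-preserved modules degrade to
  pure noise there;
* module genes are scaled so they pass the MAD filter while most background
  genes do not;
* drug responses are linear in chosen module eigengenes plus noise, on a
  0-100 viability scale, and the dose-response curves are Hill curves whose
  log-concentration AUC equals the planted summary response exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CLINICAL_STATUSES,
    DoseResponsePanel,
    DrugAnnotationTable,
    EigengeneSet,
    ExpressionMatrix,
    PipelineError,
)
from .network import ModuleAssignment, module_eigengenes

#: the 11-point 3-fold dilution series of the screening panel, in uM,
#: ascending order
DEFAULT_CONCENTRATIONS_UM = (
    0.000780415,
    0.002341244,
    0.007023779,
    0.02107129,
    0.063213917,
    0.189641751,
    0.5689253,
    1.706775899,
    5.120327696,
    15.36098309,
    46.08294931,
)

UNASSIGNED = "unassigned"


@dataclass
class SimConfig:
    """Ground-truth generating configuration.

    ``drug_module_links`` entries are (drug index, module index, coupling)
    with the coupling on the response scale: positive coupling means
    viability rises with the module eigengene. When ``None``, drugs are
    organised into ``n_drug_classes`` classes, each coupling a distinct pair
    of preserved modules at strength ``class_coupling`` (plus per-drug
    jitter), which plants recoverable drug classes for clustering tests.
    """

    n_genes: int = 2000
    n_modules: int = 8
    module_sizes: list[int] | None = None
    preserved_flags: list[bool] | None = None
    n_cell_lines: int = 5
    n_tumors: int = 13
    n_drugs: int = 40
    drug_module_links: list[tuple[int, int, float]] | None = None
    n_concentrations: int = 11
    noise_sd: float = 0.5
    seed: int = 0
    # amplitude of planted module expression relative to background noise;
    # chosen so module genes clear the default MAD > 1000 filter and
    # background genes do not
    module_scale: float = 3000.0
    background_scale: float = 300.0
    baseline_expression: float = 5000.0
    # drug screen shape
    screen_noise_sd: float = 0.1
    response_amplitude: float = 8.0
    base_response_range: tuple[float, float] = (32.0, 68.0)
    n_drug_classes: int = 4
    class_coupling: float = 0.9
    class_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            base = max(30, self.n_genes // (2 * max(self.n_modules, 1)))
            self.module_sizes = [base] * self.n_modules
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if self.preserved_flags is None:
            self.preserved_flags = [True] * self.n_modules
        if len(self.preserved_flags) != self.n_modules:
            raise ValueError("preserved_flags length must equal n_modules")
        if self.drug_module_links is not None:
            for d, m, _ in self.drug_module_links:
                if not (0 <= d < self.n_drugs):
                    raise ValueError(f"link references invalid drug index {d}")
                if not (0 <= m < self.n_modules):
                    raise ValueError(f"link references invalid module index {m}")

    @property
    def module_labels(self) -> list[str]:
        return [f"m{i + 1}" for i in range(self.n_modules)]


@dataclass
class GroundTruth:
    """Planted structure, serializable next to the generated fixtures."""

    true_module_of_gene: pd.Series  # gene -> m1..mK or "unassigned"
    true_preserved: dict[str, bool]
    true_drug_correlations: pd.DataFrame  # drug x module signed coupling
    true_drug_classes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    true_summary: pd.DataFrame | None = None  # planted drug x line summary response

    def module_assignment(self) -> ModuleAssignment:
        """Planted modules as a ModuleAssignment (background genes grey)."""
        labels = self.true_module_of_gene.replace(UNASSIGNED, "grey")
        return ModuleAssignment(labels.rename("module"))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_module_of_gene": self.true_module_of_gene.to_dict(),
            "true_preserved": self.true_preserved,
            "true_drug_correlations": {
                "index": list(self.true_drug_correlations.index),
                "columns": list(self.true_drug_correlations.columns),
                "data": self.true_drug_correlations.to_numpy().tolist(),
            },
            "true_drug_classes": self.true_drug_classes.to_dict(),
        }
        if self.true_summary is not None:
            payload["true_summary"] = {
                "index": list(self.true_summary.index),
                "columns": list(self.true_summary.columns),
                "data": self.true_summary.to_numpy().tolist(),
            }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        corr = payload["true_drug_correlations"]
        summary = None
        if "true_summary" in payload:
            s = payload["true_summary"]
            summary = pd.DataFrame(s["data"], index=s["index"], columns=s["columns"])
        return cls(
            pd.Series(payload["true_module_of_gene"]),
            payload["true_preserved"],
            pd.DataFrame(
                corr["data"], index=corr["index"], columns=corr["columns"]
            ),
            pd.Series(payload["true_drug_classes"], dtype=object),
            true_summary=summary,
        )


def _dataset(
    rng: np.random.Generator,
    config: SimConfig,
    loadings: np.ndarray,
    module_of: np.ndarray,
    samples: list[str],
    active_modules: np.ndarray,
) -> pd.DataFrame:
    """One expression matrix from the latent-factor model.

    Genes in an *active* module follow loading * factor + noise (scaled by
    ``module_scale``); genes of inactive modules and background genes are
    pure noise at ``background_scale``.
    """
    n_samples = len(samples)
    factors = rng.standard_normal((config.n_modules, n_samples))
    values = rng.standard_normal((config.n_genes, n_samples))
    values *= config.background_scale
    for m in range(config.n_modules):
        genes = np.where(module_of == m)[0]
        if not active_modules[m]:
            continue
        noise = rng.standard_normal((len(genes), n_samples)) * config.noise_sd
        signal = loadings[genes, None] * factors[m][None, :] + noise
        values[genes] = config.module_scale * signal
    values += config.baseline_expression
    gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    return pd.DataFrame(values, index=gene_ids, columns=samples)


def generate_expression(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate paired cell-line and tumor expression with planted modules."""
    rng = np.random.default_rng([config.seed, 0])
    module_of = np.full(config.n_genes, -1)
    start = 0
    for m, size in enumerate(config.module_sizes):
        module_of[start:start + size] = m
        start += size
    loadings = rng.uniform(0.6, 1.0, size=config.n_genes)

    cell_samples = [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]
    tumor_samples = [f"TU{i + 1:02d}" for i in range(config.n_tumors)]
    all_active = np.ones(config.n_modules, dtype=bool)
    preserved = np.asarray(config.preserved_flags, dtype=bool)
    cell_df = _dataset(rng, config, loadings, module_of, cell_samples, all_active)
    tumor_df = _dataset(rng, config, loadings, module_of, tumor_samples, preserved)

    labels = pd.Series(
        [config.module_labels[m] if m >= 0 else UNASSIGNED for m in module_of],
        index=cell_df.index,
        name="module",
    )
    truth = GroundTruth(
        true_module_of_gene=labels,
        true_preserved={
            config.module_labels[m]: bool(preserved[m])
            for m in range(config.n_modules)
        },
        true_drug_correlations=pd.DataFrame(
            0.0,
            index=[f"drug{d + 1:04d}" for d in range(config.n_drugs)],
            columns=config.module_labels,
        ),
    )
    return (
        ExpressionMatrix(cell_df, "cell_line"),
        ExpressionMatrix(tumor_df, "tumor"),
        truth,
    )


def _class_couplings(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """Per-drug coupling matrix from planted drug classes.

    Each class couples one pair of preserved modules with a distinct sign
    pattern; drugs inherit their class prototype plus small jitter.
    """
    preserved_idx = [m for m in range(config.n_modules) if config.preserved_flags[m]]
    if len(preserved_idx) < 2:
        raise PipelineError("need >= 2 preserved modules to plant drug classes")
    prototypes = np.zeros((config.n_drug_classes, config.n_modules))
    signs = [(+1, -1), (-1, +1), (+1, +1), (-1, -1)]
    for c in range(config.n_drug_classes):
        pair = (
            preserved_idx[(2 * c) % len(preserved_idx)],
            preserved_idx[(2 * c + 1) % len(preserved_idx)],
        )
        s = signs[c % len(signs)]
        prototypes[c, pair[0]] = s[0] * config.class_coupling
        prototypes[c, pair[1]] = s[1] * config.class_coupling
    classes = [f"class{(d % config.n_drug_classes) + 1}" for d in range(config.n_drugs)]
    couplings = np.stack(
        [prototypes[d % config.n_drug_classes] for d in range(config.n_drugs)]
    )
    couplings += rng.normal(0.0, config.class_jitter_sd, couplings.shape) * (
        couplings != 0
    )
    return couplings, classes


def _solve_ec50(summary: float, conc: np.ndarray) -> float:
    """EC50 (uM) such that the trapezoidal log10-concentration AUC of
    100 - 100 * c/(c + EC50) equals ``summary`` on the given grid."""
    logc = np.log10(conc)
    span = logc[-1] - logc[0]
    target = 1.0 - summary / 100.0  # normalized integral of the Hill term

    def g(log_ec50: float) -> float:
        h = conc / (conc + 10.0**log_ec50)
        return float(np.trapezoid(h, logc) / span)

    lo, hi = logc[0] - 8.0, logc[-1] + 8.0
    if target <= g(hi):
        return 10.0**hi
    if target >= g(lo):
        return 10.0**lo
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if g(mid) > target:
            lo = mid
        else:
            hi = mid
    return 10.0 ** ((lo + hi) / 2.0)


def hill_viability(
    conc: np.ndarray, ec50: float, emax: float = 100.0, slope: float = 1.0
) -> np.ndarray:
    """4-parameter Hill viability curve with top fixed at 100%."""
    conc = np.asarray(conc, dtype=float)
    effect = emax * conc**slope / (conc**slope + ec50**slope)
    return np.clip(100.0 - effect, 0.0, 100.0)


def generate_drug_screen(
    config: SimConfig,
    truth: GroundTruth,
    eigengenes: EigengeneSet,
) -> tuple[DoseResponsePanel, DrugAnnotationTable]:
    """Generate a dose-response panel whose summary responses are linearly
    coupled to module eigengenes, plus a randomized annotation table.

    The planted summary response per (drug, line) is
    ``clip(base + amplitude * (sum_m c_dm * E_m + noise), 0, 100)``; the Hill
    curve for that pair integrates back to exactly this summary, so potency
    is monotone in the planted response. ``truth`` is updated in place with
    the realized couplings and class labels.
    """
    if eigengenes.scores.shape[1] != config.n_cell_lines:
        raise PipelineError(
            f"eigengene sample count {eigengenes.scores.shape[1]} does not "
            f"match n_cell_lines {config.n_cell_lines}"
        )
    rng = np.random.default_rng([config.seed, 1])
    drugs = [f"drug{d + 1:04d}" for d in range(config.n_drugs)]
    lines = list(eigengenes.samples)

    if config.drug_module_links is None:
        couplings, classes = _class_couplings(config, rng)
    else:
        couplings = np.zeros((config.n_drugs, config.n_modules))
        for d, m, c in config.drug_module_links:
            couplings[d, m] += c
        classes = ["custom"] * config.n_drugs

    # eigengene matrix aligned to the configured module order; modules with
    # no eigengene (e.g. not planted) contribute nothing
    e = np.zeros((config.n_modules, config.n_cell_lines))
    for j, label in enumerate(config.module_labels):
        if label in eigengenes.modules:
            e[j] = eigengenes.scores.loc[label].to_numpy()

    base = rng.uniform(*config.base_response_range, size=config.n_drugs)
    noise = rng.normal(0.0, config.screen_noise_sd, (config.n_drugs, len(lines)))
    summary = base[:, None] + config.response_amplitude * (couplings @ e + noise)
    summary = np.clip(summary, 0.0, 100.0)

    conc = _concentration_grid(config.n_concentrations)
    rows = {}
    for d, drug in enumerate(drugs):
        for i, line in enumerate(lines):
            ec50 = _solve_ec50(summary[d, i], conc)
            rows[(drug, line)] = hill_viability(conc, ec50)
    viability = pd.DataFrame.from_dict(rows, orient="index")
    viability.index = pd.MultiIndex.from_tuples(rows, names=["drug", "cell_line"])
    viability.columns = [f"c{i}" for i in range(len(conc))]
    panel = DoseResponsePanel(viability, conc)

    statuses = rng.choice(
        CLINICAL_STATUSES, size=config.n_drugs, p=[0.20, 0.10, 0.15, 0.15, 0.40]
    )
    pchembl = rng.uniform(4.0, 9.5, size=config.n_drugs)
    missing = rng.random(config.n_drugs) < 0.15
    ann = pd.DataFrame(
        {
            "status": statuses,
            "targets": [f"TARGET{(d % 25) + 1}" for d in range(config.n_drugs)],
            "pchembl": np.where(missing, np.nan, pchembl),
        },
        index=pd.Index(drugs, name="drug"),
    )

    truth.true_drug_correlations = pd.DataFrame(
        couplings, index=drugs, columns=config.module_labels
    )
    truth.true_drug_classes = pd.Series(classes, index=drugs, name="class")
    truth.true_summary = pd.DataFrame(summary, index=drugs, columns=lines)
    return panel, DrugAnnotationTable(ann)


def _concentration_grid(n: int) -> np.ndarray:
    if n == len(DEFAULT_CONCENTRATIONS_UM):
        return np.asarray(DEFAULT_CONCENTRATIONS_UM)
    # 3-fold dilution series ending at the default top concentration
    top = DEFAULT_CONCENTRATIONS_UM[-1]
    return top / 3.0 ** np.arange(n - 1, -1, -1)


def planted_fingerprints(
    n_per_class: int = 15,
    n_modules: int = 6,
    effect: float = 0.8,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two planted fingerprint classes with complementary sign patterns.

    Class A's prototype alternates +effect/-effect across modules; class B
    is its negation (the complementary-fingerprint situation the horizontal
    combination strategy exploits). Per-entry Gaussian noise is added; the
    class separation per informative coordinate is ``2 * effect / noise_sd``
    (4x when ``noise_sd == effect / 2``). Entries are clipped to [-1, 1].
    """
    rng = np.random.default_rng(seed)
    proto = effect * np.array([1.0 if j % 2 == 0 else -1.0 for j in range(n_modules)])
    rows = np.vstack(
        [
            proto + rng.normal(0.0, noise_sd, (n_per_class, n_modules)),
            -proto + rng.normal(0.0, noise_sd, (n_per_class, n_modules)),
        ]
    )
    drugs = [f"drug{d + 1:04d}" for d in range(2 * n_per_class)]
    frame = pd.DataFrame(
        np.clip(rows, -1.0, 1.0),
        index=pd.Index(drugs, name="drug"),
        columns=[f"m{j + 1}" for j in range(n_modules)],
    )
    labels = pd.Series(
        ["classA"] * n_per_class + ["classB"] * n_per_class,
        index=frame.index,
        name="class",
    )
    return frame, labels


def truth_eigengenes(cell: ExpressionMatrix, truth: GroundTruth) -> EigengeneSet:
    """Eigengenes of the planted modules on the cell-line samples."""
    return module_eigengenes(cell, truth.module_assignment())


def generate_bundle(config: SimConfig) -> dict:
    """Full synthetic study: expression pair, truth, screen, annotations."""
    cell, tumor, truth = generate_expression(config)
    eig = truth_eigengenes(cell, truth)
    panel, ann = generate_drug_screen(config, truth, eig)
    return {
        "cell": cell,
        "tumor": tumor,
        "truth": truth,
        "eigengenes": eig,
        "panel": panel,
        "annotations": ann,
    }


def write_bundle(bundle: dict, outdir: str | Path) -> dict[str, Path]:
    """Write a generated bundle as plain-text fixtures (TSV/CSV/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cell": outdir / "expression_cell_lines.tsv",
        "tumor": outdir / "expression_tumors.tsv",
        "screen": outdir / "drug_screen.csv",
        "annotations": outdir / "drug_annotations.csv",
        "truth": outdir / "ground_truth.json",
    }
    bundle["cell"].to_tsv(paths["cell"])
    bundle["tumor"].to_tsv(paths["tumor"])
    bundle["panel"].to_csv(paths["screen"])
    bundle["annotations"].to_csv(paths["annotations"])
    bundle["truth"].to_json(paths["truth"])
    return paths
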