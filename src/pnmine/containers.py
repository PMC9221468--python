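"""Shared in-memory containers for the drug-mining pipeline.

Everything is a thin, validated wrapper around a pandas object so that the
standard tabular formats (TSV expression matrices, long-format screens,
annotation CSVs) round-trip without custom parsing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CLINICAL_STATUSES = (
    "FDA-approved",
    "Phase III",
    "Phase II",
    "Phase I",
    "preclinical",
)

#: statuses considered clinically advanced when ranking candidates
ADVANCED_STATUSES = frozenset({"FDA-approved", "Phase II", "Phase III"})


class PipelineError(RuntimeError):
    """Raised when a stage cannot proceed (degenerate or inconsistent input)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a dataset tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are samples.
    dataset_tag : str
        Either ``"cell_line"`` or ``"tumor"``.
    """

    values: pd.DataFrame
    dataset_tag: str = "cell_line"

    def __post_init__(self) -> None:
        if self.dataset_tag not in ("cell_line", "tumor"):
            raise ValueError(f"unknown dataset_tag {self.dataset_tag!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.dataset_tag)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path, dataset_tag: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, dataset_tag)


@dataclass
class MergedExpression:
    """Gene-intersected, per-dataset standardized pair of expression matrices.

    ``cell`` and ``tumor`` share an identical gene index; each block is
    standardized per gene (mean 0, sd 1, ddof=1) within its own dataset.
    ``sample_dataset`` maps every sample id to its dataset tag.
    """

    cell: ExpressionMatrix
    tumor: ExpressionMatrix
    sample_dataset: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cell.gene_ids.equals(self.tumor.gene_ids):
            raise ValueError("cell and tumor blocks must share the same gene index")
        if not self.sample_dataset:
            self.sample_dataset = {
                **{s: "cell_line" for s in self.cell.sample_ids},
                **{s: "tumor" for s in self.tumor.sample_ids},
            }

    @property
    def gene_ids(self) -> pd.Index:
        return self.cell.gene_ids


@dataclass
class DoseResponsePanel:
    """Drug x cell line x concentration viability grid (percent scale).

    ``viability`` is a DataFrame with a (drug, cell_line) MultiIndex and one
    column per concentration (ordered, strictly increasing, in uM). Raw
    readouts above 100% are allowed; values are clipped to [0, 200] on
    construction.
    """

    viability: pd.DataFrame
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.ndim != 1 or len(conc) != self.viability.shape[1]:
            raise ValueError("concentration grid does not match viability columns")
        if not np.all(np.diff(conc) > 0):
            raise ValueError("concentrations must be strictly increasing")
        self.concentrations = conc
        vals = self.viability.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("viability contains non-finite values")
        self.viability = pd.DataFrame(
            np.clip(vals, 0.0, 200.0),
            index=self.viability.index,
            columns=self.viability.columns,
        )

    @property
    def drugs(self) -> list[str]:
        return list(self.viability.index.get_level_values("drug").unique())

    @property
    def cell_lines(self) -> list[str]:
        return list(self.viability.index.get_level_values("cell_line").unique())

    def curve(self, drug: str, cell_line: str) -> np.ndarray:
        return self.viability.loc[(drug, cell_line)].to_numpy(dtype=float)

    def to_long(self) -> pd.DataFrame:
        """Long format: drug, cell_line, concentration_uM, viability_pct."""
        long = self.viability.copy()
        long.columns = self.concentrations
        long = long.stack().rename("viability_pct").reset_index()
        long.columns = ["drug", "cell_line", "concentration_uM", "viability_pct"]
        return long

    def to_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "DoseResponsePanel":
        wide = df.pivot_table(
            index=["drug", "cell_line"],
            columns="concentration_uM",
            values="viability_pct",
        )
        wide = wide.sort_index(axis=1)
        conc = wide.columns.to_numpy(dtype=float)
        wide.columns = [f"c{i}" for i in range(len(conc))]
        return cls(wide, conc)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponsePanel":
        return cls.from_long(pd.read_csv(path))


@dataclass
class DrugAnnotationTable:
    """Per-drug clinical annotation: status, targets, pChEMBL."""

    table: pd.DataFrame  # index: drug id; columns: status, targets, pchembl

    def __post_init__(self) -> None:
        required = {"status", "pchembl"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        bad = set(self.table["status"].dropna()) - set(CLINICAL_STATUSES)
        if bad:
            raise ValueError(
                f"unknown clinical status {sorted(bad)}; allowed: {list(CLINICAL_STATUSES)}"
            )
        pc = self.table["pchembl"]
        if (pc.dropna() < 0).any():
            raise ValueError("pChEMBL must be >= 0 when present")

    @property
    def drugs(self) -> pd.Index:
        return self.table.index

    def status_of(self, drug: str) -> str:
        return self.table.loc[drug, "status"]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="drug")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugAnnotationTable":
        return cls(pd.read_csv(path, index_col="drug"))


@dataclass
class EigengeneSet:
    """Per-module eigengenes: first principal component scores per sample.

    ``scores`` is a module x sample DataFrame; each eigengene is scaled to
    sd 1 and oriented so its mean correlation with the module's genes is
    non-negative.
    """

    scores: pd.DataFrame
    variance_explained: pd.Series

    @property
    def modules(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns

    def restrict_samples(self, samples: Sequence[str]) -> "EigengeneSet":
        return EigengeneSet(self.scores[list(samples)], self.variance_explained)

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="module")


def dataclass_asdict(obj) -> dict:
    return dataclasses.asdict(obj)
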