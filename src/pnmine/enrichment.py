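"""Over-representation analysis of module gene sets.

Generic hypergeometric testing of a module's genes against user-supplied
gene-set collections (GMT format), with Benjamini-Hochberg correction. The
analysis universe should be the network's gene space (the genes surviving
the variability filter), not the whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, genes...), order-preserving.

    Duplicate genes within a set are removed (first occurrence wins).
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
        return GeneSetCollection({}, {})
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: malformed GMT line (need >= 3 tab-separated fields)"
            )
        name, desc, *genes = fields
        sets[name] = list(dict.fromkeys(g for g in genes if g))
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def hypergeom_enrich(
    module_genes: set[str],
    universe: set[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a module in each gene set.

    Sets are intersected with the universe first; p is the probability of
    observing at least the overlap by chance, and q is the BH-adjusted value
    across all tested sets. Sorted ascending by p.
    """
    module_genes = set(module_genes)
    if not module_genes <= set(universe):
        raise ValueError("module genes must be a subset of the universe")
    n_universe = len(universe)
    n_module = len(module_genes)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = set(genes) & set(universe)
        if not in_universe:
            continue
        k = len(module_genes & in_universe)
        big_k = len(in_universe)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_module))
        rows.append(
            {
                "set": name,
                "set_size": big_k,
                "overlap": k,
                "p_value": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["set", "set_size", "overlap", "p_value", "q_value"])
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table.sort_values(["p_value", "set"], kind="stable").reset_index(drop=True)
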