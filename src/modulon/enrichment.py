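"""Regulon / gene-set enrichment of iModulons by exact hypergeometric overlap.

Each iModulon is compared against every regulon (or GO/KEGG-style gene set)
by the one-sided exact hypergeometric test (equivalently a one-sided Fisher
test): with a genome universe of N genes, a gene set of K genes and an
iModulon of n genes, the p-value is P(X ≥ overlap) for X ~
Hypergeom(N, K, n). Benjamini–Hochberg correction is applied jointly across
all (iModulon × set) pairs — zero-overlap pairs contribute to the family
size m even though they are omitted from the output, so q-values do not
depend on output filtering. Precision, recall and F1 of each overlap are
reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ica import PipelineConfig
from .imodulons import IModulon

__all__ = [
    "hypergeometric_pvalue",
    "enrich_against_sets",
    "best_enrichment_per_imodulon",
    "correlate_gene_with_activity",
    "write_enrichment_table",
]

RESULT_COLUMNS = [
    "imodulon_name", "set_name", "overlap", "imodulon_size", "set_size",
    "universe_size", "p_value", "q_value", "precision", "recall", "f1",
    "significant",
]


def hypergeometric_pvalue(
    overlap: int, imodulon_size: int, set_size: int, universe_size: int
) -> float:
    """Exact one-sided survival probability P(X ≥ overlap).

    X is hypergeometric with ``universe_size`` total genes, ``set_size``
    successes and ``imodulon_size`` draws. Exact (no normal approximation).
    """
    if not 0 <= overlap <= min(imodulon_size, set_size):
        raise ValueError(
            f"overlap {overlap} outside [0, min(imodulon_size, set_size)]"
        )
    if imodulon_size > universe_size or set_size > universe_size:
        raise ValueError("set sizes cannot exceed the universe size")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, imodulon_size))


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _sets_from_table(sets: pd.DataFrame) -> dict[str, set]:
    """Accept a TRN table (regulator, gene_id) or generic (set_id, gene_id)."""
    if "regulator" in sets.columns:
        key = "regulator"
    elif "set_id" in sets.columns:
        key = "set_id"
    else:
        raise ValueError("gene-set table needs a 'regulator' or 'set_id' column")
    return {str(name): set(grp["gene_id"]) for name, grp in sets.groupby(key, sort=True)}


def enrich_against_sets(
    imodulons: list[IModulon],
    sets: pd.DataFrame,
    universe,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every iModulon against every gene set.

    ``universe`` is the full gene-id list of the annotation (the genome-scale
    background), which must contain every iModulon member gene; genes of the
    sets outside the universe are dropped. Returns one row per pair with
    overlap > 0, with BH q-values computed over the full
    (non-empty iModulon) × set family and significance at
    ``config.fdr_threshold``. Rows are sorted by q-value then p-value.
    """
    config = config or PipelineConfig()
    universe = list(universe)
    universe_set = set(universe)
    if len(universe_set) != len(universe):
        raise ValueError("universe contains duplicate gene ids")
    n_universe = len(universe_set)

    for im in imodulons:
        stray = [g for g in im.gene_ids if g not in universe_set]
        if stray:
            raise ValueError(
                f"iModulon {im.name!r} has genes outside the universe: {stray}"
            )
    gene_sets = {
        name: genes & universe_set for name, genes in _sets_from_table(sets).items()
    }
    gene_sets = {name: genes for name, genes in gene_sets.items() if genes}

    rows = []
    pvals = []
    for im in imodulons:
        if im.n_members == 0:
            continue
        members = set(im.gene_ids)
        for set_name, set_genes in gene_sets.items():
            overlap = len(members & set_genes)
            p = hypergeometric_pvalue(overlap, len(members), len(set_genes), n_universe)
            precision = overlap / len(members)
            recall = overlap / len(set_genes)
            rows.append(
                (im.name, set_name, overlap, len(members), len(set_genes),
                 n_universe, p, precision, recall, _f1(precision, recall))
            )
            pvals.append(p)

    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    reject, qvals, _, _ = multipletests(
        pvals, alpha=config.fdr_threshold, method="fdr_bh"
    )
    out = pd.DataFrame(
        rows,
        columns=["imodulon_name", "set_name", "overlap", "imodulon_size",
                 "set_size", "universe_size", "p_value", "precision", "recall", "f1"],
    )
    out["q_value"] = qvals
    out["significant"] = out["q_value"] <= config.fdr_threshold
    out = out[out["overlap"] > 0]
    out = out.sort_values(["q_value", "p_value", "imodulon_name", "set_name"])
    return out[RESULT_COLUMNS].reset_index(drop=True)


def best_enrichment_per_imodulon(results: pd.DataFrame) -> pd.DataFrame:
    """Lowest-p overlapping set per iModulon (the candidate regulator label)."""
    if results.empty:
        return results
    idx = results.groupby("imodulon_name")["p_value"].idxmin()
    return results.loc[idx].sort_values("q_value").reset_index(drop=True)


def correlate_gene_with_activity(
    gene_id, compendium, A: pd.DataFrame, imodulon_name
) -> float:
    """Pearson r between a gene's centered expression and one activity row.

    Computed across the samples shared by the compendium and A. Zero
    variance in either vector yields NaN (undefined correlation) rather than
    an error.
    """
    data = compendium.data if hasattr(compendium, "data") else compendium
    if gene_id not in data.index:
        raise KeyError(f"gene {gene_id!r} not in compendium")
    if imodulon_name not in A.index:
        raise KeyError(f"iModulon {imodulon_name!r} not in activity matrix")
    shared = [s for s in data.columns if s in A.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for a correlation")
    x = data.loc[gene_id, shared].to_numpy(dtype=float)
    y = A.loc[imodulon_name, shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def write_enrichment_table(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
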