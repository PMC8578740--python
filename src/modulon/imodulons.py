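"""iModulon extraction: thresholding robust components by 1-D k-means.

Each robust component assigns a signed weight to every gene; only the few
genes with the largest absolute weights belong to the iModulon. The cutoff is
component-specific: the absolute weights are clustered into k groups (k = 3
by default), the cluster with the lowest mean is treated as background, and
its maximum becomes the threshold. Membership is strict — a gene exactly at
the threshold is *not* a member, so a weight of 0.079 against a threshold of
0.08 stays out.

The 1-D k-means is solved exactly by dynamic programming over contiguous
partitions of the sorted weights (optimal 1-D k-means clusters are always
contiguous in sorted order), so the result is deterministic and globally
optimal; the ``seed`` argument is accepted for interface stability but has
no effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ica import IcaDecomposition, PipelineConfig

__all__ = [
    "IModulon",
    "kmeans_threshold",
    "kmeans_1d",
    "extract_imodulons",
    "flag_single_gene",
    "size_distribution",
    "write_imodulon_table",
    "read_imodulon_table",
]

SINGLE_GENE_LABEL = "single-gene"
NEAR_THRESHOLD_BAND = 0.05  # non-members within 5% below the threshold get flagged
ZERO_WEIGHT_RTOL = 1e-5  # |weight| below this fraction of the max is numerical zero


@dataclass
class IModulon:
    """One thresholded component: the genes whose |weight| exceeds the cutoff."""

    name: str
    component_id: str
    members: list  # list of (gene_id, signed weight)
    threshold: float
    annotation: str | None = None
    near_threshold: list = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def gene_ids(self) -> list:
        return [g for g, _ in self.members]

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")
        bad = [g for g, w in self.members if abs(w) <= self.threshold]
        if bad:
            raise ValueError(f"members at or below threshold: {bad}")


def kmeans_1d(values: np.ndarray, k: int) -> list[int]:
    """Exact 1-D k-means on sorted values via dynamic programming.

    Returns the split points ``b_1 < … < b_{k-1}`` (indices into the sorted
    array) such that cluster j is ``sorted_values[b_{j-1}:b_j]``. Ties are
    broken toward the earliest split. O(k·n²) with vectorised inner loops.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if k >= n:
        return list(range(1, n))
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse_row(i: int) -> np.ndarray:
        # within-cluster SS of x[i:j+1] for all j >= i
        j = np.arange(i, n)
        cnt = j - i + 1
        s1 = c1[j + 1] - c1[i]
        s2 = c2[j + 1] - c2[i]
        return s2 - s1 * s1 / cnt

    # D[c, j] = min WCSS of x[0:j+1] split into c+1 clusters
    INF = np.inf
    D_prev = sse_row(0)  # one cluster
    splits = np.zeros((k - 1, n), dtype=int)
    for c in range(1, k):
        D_cur = np.full(n, INF)
        best_i = np.zeros(n, dtype=int)
        for i in range(c, n):  # cluster c starts at index i
            cost = D_prev[i - 1] + sse_row(i)
            j = np.arange(i, n)
            better = cost < D_cur[j]
            D_cur[j] = np.where(better, cost, D_cur[j])
            best_i[j] = np.where(better, i, best_i[j])
        splits[c - 1] = best_i
        D_prev = D_cur

    bounds = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = int(splits[c - 1][j])
        bounds.append(i)
        j = i - 1
    return sorted(bounds)


def kmeans_threshold(weights, k: int = 3, seed: int = 0) -> float:
    """Component-specific membership threshold from 1-D k-means on |weights|.

    The absolute weights are clustered into ``k`` groups; the cluster with
    the lowest mean (the first cluster in sorted order) is the background and
    its maximum absolute weight is returned as the threshold. Membership
    downstream is strict: only |weight| > threshold counts.

    Absolute weights below ``ZERO_WEIGHT_RTOL`` times the maximum are treated
    as exactly zero (they are numerical residue of a noise-free component, not
    structure worth clustering). Degenerate input with fewer than k distinct
    absolute values falls back to k-means at k = n_distinct, whose clusters
    are the distinct values themselves: the threshold becomes the lowest
    distinct value, so an all-equal vector yields an empty iModulon while a
    zeros-plus-one-spike vector keeps the spike as its single member.
    """
    raw = np.abs(np.asarray(weights, dtype=float))
    if raw.size == 0:
        raise ValueError("weights must be non-empty")
    wmax = raw.max()
    dust = raw <= ZERO_WEIGHT_RTOL * wmax if wmax > 0 else np.zeros(raw.shape, bool)
    w = np.where(dust, 0.0, raw)
    distinct = np.unique(w)
    if distinct.size < k:
        warnings.warn(
            f"fewer than k={k} distinct absolute weights; "
            "threshold set to the lowest distinct value",
            stacklevel=2,
        )
        threshold = float(distinct[0])
    else:
        x = np.sort(w)
        bounds = kmeans_1d(x, k)
        threshold = float(x[bounds[0] - 1])
    if threshold == 0.0 and dust.any():
        # the zero cluster's bound in raw units, so dust stays strictly excluded
        threshold = float(raw[dust].max())
    return threshold


def extract_imodulons(
    decomposition: IcaDecomposition, config: PipelineConfig | None = None
) -> list[IModulon]:
    """One iModulon per robust component, named by component id until annotated.

    Empty iModulons are retained (and later flagged) so that component and
    iModulon indices stay aligned with M and A. Non-member genes whose
    absolute weight lies within 5% below the threshold are recorded in
    ``near_threshold`` for curators.
    """
    config = config or PipelineConfig()
    if decomposition.n_components == 0:
        raise ValueError("decomposition has no components")
    imodulons = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-threshold warnings handled via emptiness
        for comp in decomposition.component_ids:
            col = decomposition.M[comp]
            threshold = kmeans_threshold(
                col.to_numpy(), k=config.kmeans_k, seed=config.random_seed
            )
            absw = col.abs()
            members = [
                (gene, float(col[gene])) for gene in col.index[absw > threshold]
            ]
            near = [
                (gene, float(col[gene]))
                for gene in col.index[
                    (absw <= threshold) & (absw >= (1 - NEAR_THRESHOLD_BAND) * threshold)
                ]
                if threshold > 0
            ]
            imodulons.append(
                IModulon(
                    name=comp,
                    component_id=comp,
                    members=members,
                    threshold=threshold,
                    annotation="empty" if not members else None,
                    near_threshold=near,
                )
            )
    return imodulons


def flag_single_gene(imodulons: list[IModulon]) -> list[IModulon]:
    """Label iModulons with exactly one member as single-gene.

    Single-gene iModulons typically capture a knockout/insertion artifact or
    noise in the compendium rather than a regulator. Non-single iModulons are
    returned untouched.
    """
    for im in imodulons:
        if im.n_members == 1:
            im.annotation = SINGLE_GENE_LABEL
    return imodulons


def size_distribution(
    imodulons: list[IModulon], genome_size: int | None = None
) -> pd.DataFrame:
    """Membership sizes sorted descending, with union totals as attrs.

    The returned frame carries ``attrs['n_distinct_genes']`` (genes in at
    least one iModulon) and, when ``genome_size`` is given, the fraction of
    the genome covered by any iModulon in ``attrs['genome_fraction']``.
    """
    rows = sorted(
        ((im.name, im.n_members) for im in imodulons), key=lambda t: (-t[1], t[0])
    )
    table = pd.DataFrame(rows, columns=["imodulon", "n_members"])
    union = set()
    for im in imodulons:
        union.update(im.gene_ids)
    table.attrs["n_distinct_genes"] = len(union)
    if genome_size:
        table.attrs["genome_fraction"] = len(union) / genome_size
    return table


def write_imodulon_table(imodulons: list[IModulon], path) -> None:
    """Membership TSV: one row per (imodulon, gene) with weight and threshold."""
    rows = [
        (im.name, gene, weight, im.threshold)
        for im in imodulons
        for gene, weight in im.members
    ]
    pd.DataFrame(rows, columns=["imodulon", "gene_id", "weight", "threshold"]).to_csv(
        path, sep="\t", index=False
    )


def read_imodulon_table(path) -> list[IModulon]:
    tab = pd.read_csv(path, sep="\t")
    imodulons = []
    for name, grp in tab.groupby("imodulon", sort=True):
        members = list(zip(grp["gene_id"], grp["weight"].astype(float)))
        imodulons.append(
            IModulon(
                name=str(name),
                component_id=str(name),
                members=members,
                threshold=float(grp["threshold"].iloc[0]),
            )
        )
    return imodulons
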