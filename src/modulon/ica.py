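"""Robust independent component analysis of an expression compendium.

The centered compendium X (genes × samples) is factored as X ≈ M·A, where
the columns of M are *robust* independent components over genes (sparse,
heavy-tailed gene-weight vectors) and the rows of A are their activities
across samples. Robustness is obtained by restarting FastICA many times from
different random initialisations, pooling all gene-space components, and
clustering them with the distance 1 − |Pearson r|: only clusters that recur
in at least a configurable fraction of runs survive, and each survivor is
represented by its sign-aligned, renormalised centroid. A is then re-fit by
least squares against the centered X, which guarantees the reconstruction
contract regardless of how the clustering went.

Orientation note: independence is measured *across genes* — each run of
FastICA treats the genes as observations of the sample-space variables, so
the recovered sources are gene-weight vectors (the M columns). This matches
how ICA-based regulon discovery is done on bulk compendia, where there are
far more genes than samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import DBSCAN
from sklearn.decomposition import fastica
from sklearn.exceptions import ConvergenceWarning

from .compendium import ExpressionCompendium

__all__ = [
    "PipelineConfig",
    "IcaDecomposition",
    "RobustICA",
    "whiten",
    "fastica_run",
    "robust_decompose",
    "select_dimension",
    "reconstruction_error",
    "read_config",
    "write_decomposition",
    "read_decomposition",
]


@dataclass
class PipelineConfig:
    """Tunable parameters of the decomposition and characterization pipeline.

    n_runs
        Number of FastICA restarts pooled into the robustness clustering.
    ica_tolerance, ica_max_iter
        FastICA fixed-point stopping rule (log-cosh contrast, symmetric
        decorrelation).
    cluster_distance_cutoff
        DBSCAN eps on the 1 − |Pearson r| distance between pooled components.
    min_cluster_fraction
        A cluster is robust when it draws components from at least this
        fraction of runs.
    kmeans_k
        Number of clusters for the per-component gene-weight threshold.
    fdr_threshold
        Benjamini–Hochberg significance cutoff for enrichment.
    random_seed
        Master seed; per-run FastICA seeds are derived from it.
    """

    n_runs: int = 100
    ica_tolerance: float = 1e-7
    ica_max_iter: int = 1000
    cluster_distance_cutoff: float = 0.1
    min_cluster_fraction: float = 0.5
    kmeans_k: int = 3
    fdr_threshold: float = 0.01
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be a positive integer")
        if self.ica_tolerance <= 0:
            raise ValueError("ica_tolerance must be positive")
        if self.ica_max_iter < 1:
            raise ValueError("ica_max_iter must be a positive integer")
        if not 0 < self.cluster_distance_cutoff < 1:
            raise ValueError("cluster_distance_cutoff must lie in (0, 1)")
        if not 0 < self.min_cluster_fraction <= 1:
            raise ValueError("min_cluster_fraction must lie in (0, 1]")
        if self.kmeans_k < 1:
            raise ValueError("kmeans_k must be a positive integer")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")


def read_config(path) -> PipelineConfig:
    """Read a flat key: value config file; every key optional."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class IcaDecomposition:
    """Robust decomposition X ≈ M·A.

    M: genes × components (unit-L2 columns, largest-magnitude entry positive).
    A: components × samples, the least-squares activities given M.
    robustness: per-component count of distinct contributing runs.
    """

    M: pd.DataFrame
    A: pd.DataFrame
    robustness: pd.Series
    n_runs: int
    dimension: int
    converged_runs: int = 0

    @property
    def component_ids(self) -> list:
        return self.M.columns.tolist()

    @property
    def n_components(self) -> int:
        return self.M.shape[1]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, ExpressionCompendium):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _gene_index(X) -> pd.Index:
    if isinstance(X, ExpressionCompendium):
        return X.data.index
    if isinstance(X, pd.DataFrame):
        return X.index
    return pd.Index([f"g{i:04d}" for i in range(np.asarray(X).shape[0])])


def _sample_index(X) -> pd.Index:
    if isinstance(X, ExpressionCompendium):
        return X.data.columns
    if isinstance(X, pd.DataFrame):
        return X.columns
    return pd.Index([f"s{i:03d}" for i in range(np.asarray(X).shape[1])])


def whiten(X, dimension: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Whiten a centered genes × samples matrix for FastICA.

    Each gene's mean across samples is removed, then an SVD projects onto the
    top ``dimension`` directions. Returns ``(Z, dewhiten)`` where Z has shape
    (dimension, n_genes) with sample covariance over genes exactly the
    identity, and ``dewhiten`` (n_samples × dimension) satisfies
    ``X_rowcentered ≈ (dewhiten @ Z).T`` (exact at full rank). Gene-space
    weight vectors of a whitened-space direction w are ``Z.T @ w / sqrt(n_genes)``.

    dimension=None uses the full numerical rank. A dimension above the
    numerical rank raises, naming the achievable rank (row-centering alone
    caps it at n_samples − 1).
    """
    Xv = _as_matrix(X)
    n_genes, n_samples = Xv.shape
    Xc = Xv - Xv.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    cutoff = s[0] * max(n_genes, n_samples) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > cutoff))
    if dimension is None:
        dimension = rank
    if dimension < 1:
        raise ValueError("dimension must be a positive integer")
    if dimension > rank:
        raise ValueError(
            f"requested dimension {dimension} exceeds numerical rank {rank} "
            f"(row-centering caps rank at n_samples - 1 = {n_samples - 1})"
        )
    Z = math.sqrt(n_genes) * U[:, :dimension].T
    dewhiten = Vt[:dimension].T * s[:dimension] / math.sqrt(n_genes)
    return Z, dewhiten


def fastica_run(whitened: np.ndarray, seed: int, config: PipelineConfig) -> np.ndarray:
    """One FastICA run on pre-whitened data; returns the d × d rotation.

    Symmetric (parallel) fixed-point iteration with the log-cosh contrast,
    stopping when the rotation update falls below ``config.ica_tolerance`` or
    after ``config.ica_max_iter`` sweeps. Rows of the returned matrix are
    unit-norm components in whitened space. Non-convergence is recorded on
    the function attribute used by the robust pipeline, not fatal.
    """
    W, _ = _fastica_rotation(whitened, seed, config)
    return W


def _fastica_rotation(
    Z: np.ndarray, seed: int, config: PipelineConfig
) -> tuple[np.ndarray, bool]:
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _, W, _ = fastica(
            Z.T,
            whiten=False,
            fun="logcosh",
            tol=config.ica_tolerance,
            max_iter=config.ica_max_iter,
            random_state=int(seed),
            compute_sources=False,
        )
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not np.all(np.isfinite(W)):
        raise FloatingPointError(f"FastICA produced non-finite values (run seed {seed})")
    return W, converged


def _orient_columns(G: np.ndarray) -> np.ndarray:
    """Sign-orient each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(G), axis=0)
    signs = np.sign(G[idx, np.arange(G.shape[1])])
    signs[signs == 0] = 1.0
    return G * signs


def _abs_correlation(P: np.ndarray) -> np.ndarray:
    """|Pearson r| between all column pairs of P."""
    Pc = P - P.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Pc, axis=0)
    norms[norms == 0] = 1.0
    Pn = Pc / norms
    C = np.abs(Pn.T @ Pn)
    np.clip(C, 0.0, 1.0, out=C)
    return C


class RobustICA(BaseEstimator, TransformerMixin):
    """Robust ICA over FastICA restarts, scikit-learn estimator style.

    Fit on a centered genes × samples matrix (array, DataFrame, or
    :class:`~modulon.compendium.ExpressionCompendium`). Components that recur
    across restarts (clustered at 1 − |Pearson r| ≤ ``distance_cutoff`` and
    drawn from ≥ ``min_cluster_fraction`` of runs) are kept; each surviving
    cluster's sign-aligned mean, renormalised to unit L2, becomes a column of
    ``M_``. Activities ``A_`` are the least-squares solution of X ≈ M·A.

    Parameters
    ----------
    n_components : int or None
        Whitening dimension; None uses the full numerical rank.
    n_runs : int
        Number of FastICA restarts.
    tol, max_iter : float, int
        FastICA stopping rule.
    distance_cutoff : float
        DBSCAN eps on the 1 − |Pearson r| component distance.
    min_cluster_fraction : float
        Minimum fraction of runs a robust cluster must draw from.
    random_state : int
        Master seed for the per-run FastICA seeds.

    Attributes
    ----------
    M_ : ndarray (n_genes, n_robust)
        Robust gene-weight matrix, unit-norm sign-oriented columns.
    A_ : ndarray (n_robust, n_samples)
        Least-squares activities.
    robustness_ : ndarray (n_robust,)
        Distinct contributing runs per component.
    converged_runs_ : int
        Runs whose FastICA iteration converged within ``max_iter``.
    dimension_ : int
        Whitening dimension actually used.
    """

    def __init__(
        self,
        n_components: int | None = None,
        n_runs: int = 100,
        tol: float = 1e-7,
        max_iter: int = 1000,
        distance_cutoff: float = 0.1,
        min_cluster_fraction: float = 0.5,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_runs = n_runs
        self.tol = tol
        self.max_iter = max_iter
        self.distance_cutoff = distance_cutoff
        self.min_cluster_fraction = min_cluster_fraction
        self.random_state = random_state

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            n_runs=self.n_runs,
            ica_tolerance=self.tol,
            ica_max_iter=self.max_iter,
            cluster_distance_cutoff=self.distance_cutoff,
            min_cluster_fraction=self.min_cluster_fraction,
            random_seed=self.random_state,
        )

    def fit(self, X, y=None):
        cfg = self._config()
        Xv = _as_matrix(X)
        n_genes, n_samples = Xv.shape
        Z, _ = whiten(Xv, self.n_components)
        d = Z.shape[0]

        rng = np.random.default_rng(cfg.random_seed)
        seeds = rng.integers(0, 2**31 - 1, size=cfg.n_runs)
        pooled: list[np.ndarray] = []
        run_of: list[int] = []
        converged = 0
        for run, seed in enumerate(seeds):
            W, ok = _fastica_rotation(Z, seed, cfg)
            converged += int(ok)
            G = _orient_columns(Z.T @ W.T / math.sqrt(n_genes))
            pooled.append(G)
            run_of.extend([run] * d)
        P = np.hstack(pooled)
        run_of = np.asarray(run_of)

        distance = 1.0 - _abs_correlation(P)
        np.fill_diagonal(distance, 0.0)
        min_runs = max(1, math.ceil(cfg.min_cluster_fraction * cfg.n_runs))
        min_samples = 1 if cfg.n_runs == 1 else max(2, min_runs)
        labels = DBSCAN(
            eps=cfg.cluster_distance_cutoff,
            min_samples=min_samples,
            metric="precomputed",
        ).fit_predict(distance)

        centroids = []
        robustness = []
        for label in sorted(set(labels) - {-1}):
            members = np.flatnonzero(labels == label)
            n_distinct_runs = len(set(run_of[members].tolist()))
            if n_distinct_runs < min_runs:
                continue
            block = P[:, members]
            ref = block[:, 0]
            signs = np.sign(ref @ block)
            signs[signs == 0] = 1.0
            centroid = (block * signs).mean(axis=1)
            norm = np.linalg.norm(centroid)
            if norm == 0:
                continue
            centroids.append(centroid / norm)
            robustness.append(n_distinct_runs)

        if not centroids:
            warnings.warn("no robust components found; returning an empty decomposition",
                          stacklevel=2)
            M = np.empty((n_genes, 0))
            A = np.empty((0, n_samples))
            order = []
        else:
            M = _orient_columns(np.column_stack(centroids))
            order = sorted(
                range(M.shape[1]),
                key=lambda j: (-robustness[j], int(np.argmax(np.abs(M[:, j]))),
                               -float(np.max(np.abs(M[:, j])))),
            )
            M = M[:, order]
            A = np.linalg.lstsq(M, Xv, rcond=None)[0]

        self.M_ = M
        self.A_ = A
        self.robustness_ = np.asarray([robustness[j] for j in order], dtype=int)
        self.converged_runs_ = converged
        self.dimension_ = d
        self.n_components_ = M.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Least-squares activities of the fitted components for a new matrix."""
        Xv = _as_matrix(X)
        if self.M_.shape[1] == 0:
            return np.empty((0, Xv.shape[1]))
        return np.linalg.lstsq(self.M_, Xv, rcond=None)[0]

    def inverse_transform(self, A) -> np.ndarray:
        return self.M_ @ np.asarray(A, dtype=float)


def robust_decompose(
    X, dimension: int | None, config: PipelineConfig | None = None
) -> IcaDecomposition:
    """Robust ICA of a centered compendium into labelled M and A frames."""
    config = config or PipelineConfig()
    est = RobustICA(
        n_components=dimension,
        n_runs=config.n_runs,
        tol=config.ica_tolerance,
        max_iter=config.ica_max_iter,
        distance_cutoff=config.cluster_distance_cutoff,
        min_cluster_fraction=config.min_cluster_fraction,
        random_state=config.random_seed,
    ).fit(X)
    comp_ids = [f"IC_{i + 1:02d}" for i in range(est.n_components_)]
    genes = _gene_index(X)
    samples = _sample_index(X)
    M = pd.DataFrame(est.M_, index=genes, columns=comp_ids)
    A = pd.DataFrame(est.A_, index=comp_ids, columns=samples)
    return IcaDecomposition(
        M=M,
        A=A,
        robustness=pd.Series(est.robustness_, index=comp_ids, dtype=int),
        n_runs=config.n_runs,
        dimension=est.dimension_,
        converged_runs=est.converged_runs_,
    )


def select_dimension(
    X, dimension_grid, config: PipelineConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Pick the whitening dimension by robust-component saturation over a grid.

    Runs :func:`robust_decompose` at each grid value and chooses the largest
    dimension at which the robust-component count still increases relative to
    the previous grid point; if the count never increases, the smallest grid
    value is chosen. Returns the chosen dimension and per-grid diagnostics
    (robust count, single-gene-component count, converged runs).
    """
    from .imodulons import extract_imodulons

    grid = sorted(int(d) for d in dimension_grid)
    if not grid:
        raise ValueError("dimension_grid must be non-empty")
    config = config or PipelineConfig()
    records = []
    counts = []
    for dim in grid:
        dec = robust_decompose(X, dim, config)
        n_single = sum(
            1 for im in extract_imodulons(dec, config) if im.n_members == 1
        ) if dec.n_components else 0
        counts.append(dec.n_components)
        records.append((dim, dec.n_components, n_single, dec.converged_runs))
    chosen = grid[0]
    for i in range(1, len(grid)):
        if counts[i] > counts[i - 1]:
            chosen = grid[i]
    diagnostics = pd.DataFrame(
        records,
        columns=["dimension", "n_robust_components", "n_single_gene_components",
                 "converged_runs"],
    )
    return chosen, diagnostics


def reconstruction_error(X, decomposition: IcaDecomposition) -> float:
    """Relative Frobenius reconstruction error ‖X − M·A‖_F / ‖X‖_F."""
    Xv = _as_matrix(X)
    denom = np.linalg.norm(Xv)
    if denom == 0:
        raise ValueError("reconstruction error undefined for an all-zero matrix")
    M = decomposition.M.to_numpy(dtype=float)
    A = decomposition.A.to_numpy(dtype=float)
    if M.shape[1] == 0:
        return 1.0
    return float(np.linalg.norm(Xv - M @ A) / denom)


def write_decomposition(decomposition: IcaDecomposition, m_path, a_path) -> None:
    """Write M (gene_id rows × component columns) and A (component rows × samples) as TSV."""
    M = decomposition.M.copy()
    M.index.name = "gene_id"
    M.to_csv(m_path, sep="\t")
    A = decomposition.A.copy()
    A.index.name = "component"
    A.to_csv(a_path, sep="\t")


def read_decomposition(m_path, a_path, n_runs: int = 0, dimension: int = 0) -> IcaDecomposition:
    M = pd.read_csv(m_path, sep="\t", index_col=0)
    A = pd.read_csv(a_path, sep="\t", index_col=0)
    if list(M.columns) != list(A.index):
        raise ValueError("M columns and A rows disagree")
    robustness = pd.Series(np.zeros(M.shape[1], dtype=int), index=M.columns)
    return IcaDecomposition(M=M, A=A, robustness=robustness,
                            n_runs=n_runs, dimension=dimension)
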