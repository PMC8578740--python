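"""Expression compendium I/O, validation, and reference-condition centering.

A compendium is a genes × samples matrix of log-TPM values (log2(TPM + 1))
assembled from several independent projects. Because each project was
sequenced separately, every project designates a *reference condition* with
at least two replicates; subtracting the per-gene mean of those reference
columns from all of a project's columns removes project-level technical
offsets. After centering, expression (and downstream component activities)
are only comparable *within* a project, relative to its reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ExpressionCompendium",
    "CompendiumFormatError",
    "read_compendium",
    "read_metadata",
    "read_trn",
    "read_gene_table",
    "read_gene_sets",
    "write_compendium",
    "write_metadata",
    "validate_metadata",
    "center_to_reference",
    "ReferenceCenterer",
]

METADATA_COLUMNS = ("sample_id", "project", "condition", "reference")
TRN_COLUMNS = ("regulator", "gene_id", "effect", "evidence")
GENE_TABLE_COLUMNS = ("gene_id", "gene_name", "product", "cog", "start", "strand")
TRN_EFFECTS = frozenset({"activation", "repression", "unknown"})


class CompendiumFormatError(ValueError):
    """Raised when an expression or companion table violates its format contract."""


@dataclass
class ExpressionCompendium:
    """A genes × samples log-TPM matrix with a centering flag.

    Parameters
    ----------
    data : pandas.DataFrame
        Expression values, index = gene ids, columns = sample ids.
    centered : bool
        True once per-project reference means have been subtracted.
    """

    data: pd.DataFrame
    centered: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CompendiumFormatError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise CompendiumFormatError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CompendiumFormatError("expression matrix contains non-numeric cells")
        if not np.all(np.isfinite(values)):
            raise CompendiumFormatError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_compendium(
    expression_path, metadata_path
) -> tuple[ExpressionCompendium, pd.DataFrame]:
    """Read an expression TSV and its sample metadata TSV as a validated pair.

    Samples present in exactly one of the two files are reported and dropped
    with a warning; the intersection must be non-empty.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    if expr.index.name != "gene_id":
        warnings.warn(
            f"expression first column header is {expr.index.name!r}, expected 'gene_id'",
            stacklevel=2,
        )
    try:
        expr = expr.astype(float)
    except (TypeError, ValueError) as exc:
        raise CompendiumFormatError(f"non-numeric expression cell: {exc}") from exc
    meta = read_metadata(metadata_path)

    expr_samples = set(expr.columns)
    meta_samples = set(meta["sample_id"])
    only_expr = sorted(expr_samples - meta_samples)
    only_meta = sorted(meta_samples - expr_samples)
    if only_expr:
        warnings.warn(
            f"dropping {len(only_expr)} sample(s) without metadata: {only_expr}",
            stacklevel=2,
        )
    if only_meta:
        warnings.warn(
            f"dropping {len(only_meta)} metadata row(s) without expression: {only_meta}",
            stacklevel=2,
        )
    shared = [s for s in expr.columns if s in meta_samples]
    if not shared:
        raise CompendiumFormatError("no samples shared between expression and metadata")
    expr = expr[shared]
    meta = meta[meta["sample_id"].isin(shared)].reset_index(drop=True)
    return ExpressionCompendium(expr), meta


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, project, condition, reference, ...)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise CompendiumFormatError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise CompendiumFormatError(f"duplicate sample ids in metadata: {dups}")
    meta["reference"] = _parse_bool(meta["reference"])
    return meta


def _parse_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"TRUE": True, "FALSE": False, "True": True, "False": False}
    out = series.astype(str).map(mapping)
    if out.isna().any():
        bad = series[out.isna()].unique().tolist()
        raise CompendiumFormatError(f"reference column values must be TRUE/FALSE, got {bad}")
    return out.astype(bool)


def read_trn(path) -> pd.DataFrame:
    """Read a regulator→gene interaction table (CSV or TSV, sniffed by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    trn = pd.read_csv(path, sep=sep)
    missing = [c for c in TRN_COLUMNS if c not in trn.columns]
    if missing:
        raise CompendiumFormatError(f"TRN table missing required columns: {missing}")
    pairs = trn[["regulator", "gene_id"]]
    if pairs.duplicated().any():
        raise CompendiumFormatError("duplicate (regulator, gene_id) pairs in TRN table")
    bad = set(trn["effect"]) - TRN_EFFECTS
    if bad:
        raise CompendiumFormatError(f"unknown TRN effect values: {sorted(bad)}")
    return trn


def read_gene_table(path) -> pd.DataFrame:
    """Read a curated gene annotation TSV (gene_id, gene_name, product, cog, start, strand)."""
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in tab.columns]
    if missing:
        raise CompendiumFormatError(f"gene table missing required columns: {missing}")
    if tab["gene_id"].duplicated().any():
        raise CompendiumFormatError("duplicate gene ids in gene table")
    starts = tab["start"].dropna()
    if len(starts) and (starts <= 0).any():
        raise CompendiumFormatError("genomic start coordinates must be positive (1-based)")
    return tab


def read_gene_sets(path) -> pd.DataFrame:
    """Read a generic gene-set TSV (set_id, gene_id); works for regulons, GO, KEGG alike."""
    sets = pd.read_csv(path, sep="\t")
    missing = [c for c in ("set_id", "gene_id") if c not in sets.columns]
    if missing:
        raise CompendiumFormatError(f"gene-set table missing required columns: {missing}")
    return sets


def write_compendium(compendium: ExpressionCompendium, path) -> None:
    out = compendium.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out["reference"] = out["reference"].map({True: "TRUE", False: "FALSE"})
    out.to_csv(path, sep="\t", index=False)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Report, per project, the reference condition and its replicate count.

    Returns a dataframe with one row per project: columns project,
    reference_condition, n_reference_replicates, flagged, reason. A project
    is flagged when it has no reference rows, more than one reference
    condition, or fewer than two reference replicates. Report-only: never
    raises.
    """
    rows = []
    for project, grp in metadata.groupby("project", sort=True):
        refs = grp[grp["reference"]]
        ref_conditions = sorted(refs["condition"].unique())
        if len(ref_conditions) == 0:
            rows.append((project, None, 0, True, "no reference condition"))
        elif len(ref_conditions) > 1:
            rows.append(
                (project, ",".join(map(str, ref_conditions)), len(refs), True,
                 "multiple reference conditions")
            )
        elif len(refs) < 2:
            rows.append(
                (project, ref_conditions[0], len(refs), True,
                 "reference condition has < 2 replicates")
            )
        else:
            rows.append((project, ref_conditions[0], len(refs), False, ""))
    return pd.DataFrame(
        rows,
        columns=["project", "reference_condition", "n_reference_replicates",
                 "flagged", "reason"],
    )


class ReferenceCenterer(BaseEstimator, TransformerMixin):
    """Subtract each project's per-gene reference-condition mean from its samples.

    scikit-learn-style transformer over the genes × samples expression frame.
    The sample→project and reference assignments come from the metadata table
    passed at construction; ``fit`` learns the per-project reference mean
    vectors, ``transform`` subtracts them column-wise.

    Parameters
    ----------
    metadata : pandas.DataFrame
        Sample metadata with columns sample_id, project, condition, reference.
    """

    def __init__(self, metadata: pd.DataFrame | None = None):
        self.metadata = metadata

    def fit(self, X: pd.DataFrame, y=None):
        if self.metadata is None:
            raise ValueError("ReferenceCenterer requires a metadata table")
        report = validate_metadata(self.metadata)
        if report["flagged"].any():
            bad = report.loc[report["flagged"], ["project", "reason"]]
            raise ValueError(
                "metadata fails reference-condition validation:\n" + bad.to_string(index=False)
            )
        meta = self.metadata.set_index("sample_id")
        missing = [s for s in X.columns if s not in meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        self.reference_means_ = {}
        self.project_of_ = meta.loc[list(X.columns), "project"].to_dict()
        for project, grp in self.metadata.groupby("project"):
            ref_samples = [
                s for s in grp.loc[grp["reference"], "sample_id"] if s in X.columns
            ]
            if len(ref_samples) < 2:
                raise ValueError(
                    f"project {project!r} has < 2 reference replicates in the compendium"
                )
            self.reference_means_[project] = X[ref_samples].mean(axis=1)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.astype(float).copy()
        for sample in out.columns:
            project = self.project_of_.get(sample)
            if project is None or project not in self.reference_means_:
                raise ValueError(f"sample {sample!r} not seen at fit time")
            out[sample] = out[sample] - self.reference_means_[project]
        return out


def center_to_reference(
    compendium: ExpressionCompendium, metadata: pd.DataFrame
) -> ExpressionCompendium:
    """Center each project to its reference condition (see module docstring).

    After this transform the per-gene mean over every project's reference
    columns is the zero vector, and within-project differences between any
    two samples are preserved exactly.
    """
    if compendium.centered:
        raise ValueError("compendium is already reference-centered")
    centered = ReferenceCenterer(metadata).fit_transform(compendium.data)
    return ExpressionCompendium(centered, centered=True)
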