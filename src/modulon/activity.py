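"""Explained variance of the decomposition and condition-dependent activity.

Explained variance (EV) of a component subset S is defined through the
Frobenius reconstruction ratio

    EV(S) = 1 − ‖X − M_S·A_S‖²_F / ‖X‖²_F,

with the activities A_S re-solved by least squares for that subset, so EV is
exactly monotone under component addition and the full-set value is
well-defined. Marginal (single-component) EVs used for ranking need not sum
to the total because components are not orthogonal.

Differential activity between two conditions of the *same project* is tested
per iModulon with Welch's t-test on replicate activities, BH-corrected across
iModulons. Cross-project contrasts are refused: after reference centering,
activities are only comparable within a project.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ica import IcaDecomposition, _as_matrix

__all__ = [
    "explained_variance",
    "rank_by_explained_variance",
    "differential_activity",
]


def explained_variance(X, M, A=None, subset=None) -> float:
    """Fraction of ‖X‖²_F captured by the least-squares fit of a component subset.

    ``M`` may be an :class:`~modulon.ica.IcaDecomposition` or a gene × component
    frame/array; ``A`` is accepted for interface symmetry but the activities
    are always re-solved by least squares for the chosen subset. ``subset``
    is a list of component ids (or integer positions for raw arrays); None
    means all components. Clipped below at 0.
    """
    Xv = _as_matrix(X)
    denom = float(np.sum(Xv * Xv))
    if denom == 0:
        raise ValueError("explained variance undefined for an all-zero matrix")
    if isinstance(M, IcaDecomposition):
        M = M.M
    if isinstance(M, pd.DataFrame):
        Ms = M if subset is None else M[list(subset)]
        Ms = Ms.to_numpy(dtype=float)
    else:
        M = np.asarray(M, dtype=float)
        Ms = M if subset is None else M[:, list(subset)]
    if Ms.ndim == 1:
        Ms = Ms[:, None]
    if Ms.shape[1] == 0:
        return 0.0
    As = np.linalg.lstsq(Ms, Xv, rcond=None)[0]
    resid = Xv - Ms @ As
    return float(max(0.0, 1.0 - np.sum(resid * resid) / denom))


def rank_by_explained_variance(X, decomposition: IcaDecomposition) -> pd.DataFrame:
    """Marginal EV per component, sorted descending, with the full-set total.

    The appended ``TOTAL`` row is the EV of the full component set, which is
    always ≥ the largest marginal EV. Marginal EVs need not sum to the total:
    the components are not orthogonal, so shared variance is counted once in
    the total but repeatedly across marginals (noted in ``attrs['note']``).
    """
    if decomposition.n_components == 0:
        raise ValueError("decomposition has no components")
    marginals = [
        (comp, explained_variance(X, decomposition, subset=[comp]))
        for comp in decomposition.component_ids
    ]
    marginals.sort(key=lambda t: (-t[1], t[0]))
    total = explained_variance(X, decomposition)
    table = pd.DataFrame(marginals, columns=["component", "explained_variance"])
    table = pd.concat(
        [table, pd.DataFrame([("TOTAL", total)], columns=table.columns)],
        ignore_index=True,
    )
    table.attrs["note"] = (
        "marginal EVs need not sum to the total: components are not orthogonal"
    )
    return table


def differential_activity(
    A: pd.DataFrame,
    metadata: pd.DataFrame,
    condition_a,
    condition_b,
    project=None,
) -> pd.DataFrame:
    """Welch's t-test per iModulon between two conditions of one project.

    Returns one row per iModulon (activity-matrix row) with the mean
    difference (a − b), Welch p-value, BH q-value across iModulons, and the
    replicate counts. Both conditions must belong to the same project and
    carry ≥ 2 replicates; anything else is a contract error. When condition
    labels are reused across projects, ``project`` selects which one to test.
    """
    if project is not None:
        metadata = metadata[metadata["project"] == project]
        if metadata.empty:
            raise ValueError(f"no samples for project {project!r}")
    meta = metadata.set_index("sample_id")
    samples_a = [s for s in A.columns if s in meta.index and meta.loc[s, "condition"] == condition_a]
    samples_b = [s for s in A.columns if s in meta.index and meta.loc[s, "condition"] == condition_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"both conditions need >= 2 replicates "
            f"(got {len(samples_a)} for {condition_a!r}, {len(samples_b)} for {condition_b!r})"
        )
    projects = set(meta.loc[samples_a, "project"]) | set(meta.loc[samples_b, "project"])
    if len(projects) != 1:
        raise ValueError(
            f"cross-project contrast refused ({sorted(map(str, projects))}): "
            "after reference centering, activities are only comparable within a project"
        )
    rows = []
    for im in A.index:
        a = A.loc[im, samples_a].to_numpy(dtype=float)
        b = A.loc[im, samples_b].to_numpy(dtype=float)
        res = stats.ttest_ind(a, b, equal_var=False)
        p = float(res.pvalue)
        if np.isnan(p):  # both samples constant: no evidence of a difference
            p = 1.0
        rows.append((im, float(a.mean() - b.mean()), p, len(a), len(b)))
    out = pd.DataFrame(
        rows, columns=["imodulon_name", "mean_difference", "p_value", "n_a", "n_b"]
    )
    out["condition_a"] = condition_a
    out["condition_b"] = condition_b
    _, qvals, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["q_value"] = qvals
    return out[
        ["imodulon_name", "condition_a", "condition_b", "mean_difference",
         "p_value", "q_value", "n_a", "n_b"]
    ].sort_values("p_value").reset_index(drop=True)
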