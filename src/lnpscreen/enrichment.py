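"""Decile enrichment of chemical properties among top/bottom delivery performers.

For a chemical property value (a helper lipid, a charge class, a headgroup size
class ...), enrichment in a subset of LNPs is its frequency in the subset
divided by its library-wide frequency, so 1 is chance level.  Fold enrichment
subtracts the bottom-decile enrichment from the top-decile enrichment; positive
values associate the property with efficient delivery.  A label-permutation
test supplies significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "decile_sets",
    "enrichment_score",
    "fold_enrichment",
    "permutation_pvalue",
    "enrich_all",
    "tissue_mean_fold",
    "enrichment_heatmap",
]


def decile_sets(
    scores: pd.Series, fraction: float = 0.1
) -> tuple[list, list]:
    """Index labels of the top and bottom ``ceil(fraction * N)`` scores.

    Ties are broken by stable position in ``scores`` (the library's design
    order): the top set prefers earlier designs, the bottom set is the tail of
    the same stable descending order, so the two sets are always disjoint.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 scored LNPs")
    k = math.ceil(fraction * n)
    if 2 * k > n:
        raise ValueError(
            f"2 * ceil(fraction*N) = {2 * k} exceeds N = {n}; sets would overlap"
        )
    order = np.lexsort((np.arange(n), -scores.to_numpy(dtype=float)))
    top = list(scores.index[order[:k]])
    bottom = list(scores.index[order[-k:]])
    return top, bottom


def enrichment_score(
    subset, labels: pd.Series, value, method: str = "ratio"
) -> float:
    """Frequency of ``value`` in ``subset`` relative to chance.

    ``method="ratio"`` (default) divides the subset frequency by the library
    frequency f (chance level 1; range [0, 1/f]); ``method="difference"``
    subtracts f instead (chance level 0).
    """
    f = float((labels == value).mean())
    if f == 0:
        raise ValueError(f"property value {value!r} absent from the scored library")
    sub_freq = float((labels.loc[list(subset)] == value).mean())
    if method == "ratio":
        return sub_freq / f
    if method == "difference":
        return sub_freq - f
    raise ValueError(f"unknown enrichment method {method!r}")


def fold_enrichment(e_top: float, e_bottom: float) -> float:
    """Top-decile enrichment minus bottom-decile enrichment."""
    return e_top - e_bottom


def _fold_for_sets(z: np.ndarray, top_pos, bottom_pos, f: float, k: int) -> float:
    return (z[top_pos].sum() / k - z[bottom_pos].sum() / k) / f


def permutation_pvalue(
    labels: pd.Series,
    value,
    scores: pd.Series,
    fraction: float = 0.1,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for the fold enrichment of ``value``.

    LNP labels are permuted against the fixed scores; p = (1 + #{permuted
    |fold| >= observed |fold|}) / (1 + n_perm), deterministic under ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not labels.index.equals(scores.index):
        labels = labels.loc[scores.index]
    top, bottom = decile_sets(scores, fraction)
    pos = {lab: i for i, lab in enumerate(scores.index)}
    top_pos = np.array([pos[t] for t in top])
    bottom_pos = np.array([pos[b] for b in bottom])
    z = (labels.to_numpy() == value).astype(np.int8)
    f = z.mean()
    if f == 0:
        raise ValueError(f"property value {value!r} absent from the scored library")
    k = len(top)
    observed = abs(_fold_for_sets(z, top_pos, bottom_pos, f, k))

    rng = np.random.default_rng(seed)
    Z = np.tile(z, (n_perm, 1))
    rng.permuted(Z, axis=1, out=Z)
    folds = (Z[:, top_pos].sum(axis=1) - Z[:, bottom_pos].sum(axis=1)) / (k * f)
    n_extreme = int((np.abs(folds) >= observed - 1e-12).sum())
    return (1 + n_extreme) / (1 + n_perm)


def enrich_all(
    nd_mean: pd.DataFrame,
    properties: pd.DataFrame,
    fraction: float = 0.1,
    n_perm: int | None = None,
    seed: int = 0,
    method: str = "ratio",
) -> pd.DataFrame:
    """Enrichment of every property value in every cell type.

    ``nd_mean`` is a design x cell-type matrix of mouse-averaged normalized
    delivery (see :func:`lnpscreen.normalize.mean_matrix`); ``properties`` a
    design-indexed table of categorical property columns.  One output row per
    (property, value, cell type); ``n_perm`` adds a permutation p-value column.
    Deterministic under ``seed``.
    """
    designs = nd_mean.index
    props = properties.loc[designs]
    rows = []
    for ct in nd_mean.columns:
        scores = nd_mean[ct].dropna()
        top, bottom = decile_sets(scores, fraction)
        for prop in props.columns:
            labels = props.loc[scores.index, prop]
            for value in pd.unique(labels):
                e_top = enrichment_score(top, labels, value, method=method)
                e_bottom = enrichment_score(bottom, labels, value, method=method)
                row = {
                    "property": prop,
                    "value": value,
                    "cell_type": ct,
                    "e_top": e_top,
                    "e_bottom": e_bottom,
                    "fold": fold_enrichment(e_top, e_bottom),
                    "n_top": len(top),
                    "n_bottom": len(bottom),
                }
                if n_perm is not None:
                    row["perm_p"] = permutation_pvalue(
                        labels, value, scores, fraction, n_perm, seed
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def tissue_mean_fold(result: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue fold enrichment: the mean of per-cell-type folds within a
    tissue, each cell type weighted equally (cell types labelled tissue/name)."""
    out = result.copy()
    out["tissue"] = out["cell_type"].str.split("/").str[0]
    return (
        out.groupby(["property", "value", "tissue"])["fold"]
        .mean()
        .reset_index(name="mean_fold")
    )


def enrichment_heatmap(result: pd.DataFrame, property_name: str, ax=None):
    """Optional value x cell-type heatmap of fold enrichment (matplotlib)."""
    import matplotlib.pyplot as plt

    sub = result[result["property"] == property_name]
    mat = sub.pivot(index="value", columns="cell_type", values="fold")
    if ax is None:
        _, ax = plt.subplots(
            figsize=(1 + 0.5 * mat.shape[1], 1 + 0.35 * mat.shape[0])
        )
    vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
    ax.set_title(f"Fold enrichment: {property_name}", fontsize=9)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
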