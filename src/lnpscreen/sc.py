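"""Single-cell delivery readouts: percent reporter-positive cells per cluster,
differential expression between treatment groups, and gene-set
overrepresentation.

The delivery reporter (an aVHH pseudogene appended to the gene list) marks
transfected cells; a cell is "positive" at >= ``min_count`` counts.
Differential expression uses the common scRNA-seq default — two-sided Wilcoxon
rank-sum on library-size-normalized, log-transformed counts with
Benjamini-Hochberg correction — since raw-p volcano filtering and q-values are
both wanted, both columns are emitted.  Overrepresentation is an upper-tail
hypergeometric test of a query gene list against user-supplied GMT gene sets
over an explicit background universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

try:  # gseapy's GMT reader; the format is (set name, description, genes...)
    from gseapy import read_gmt
except ImportError:  # pragma: no cover
    from gseapy.parser import read_gmt

__all__ = [
    "percent_positive",
    "differential_expression",
    "top_upregulated",
    "ora_hypergeometric",
    "read_gene_sets",
]


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def _gene_column(adata, gene: str) -> np.ndarray:
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not present in the matrix")
    return _dense(adata[:, gene].X).ravel()


def percent_positive(
    adata,
    gene: str | None = None,
    min_count: int = 1,
    by_cluster: bool = True,
    by_group: bool = True,
) -> pd.DataFrame:
    """Percent of cells with >= ``min_count`` counts of ``gene`` per stratum.

    ``gene`` defaults to the designated delivery pseudogene
    (``adata.uns["avhh_gene"]``).  Strata with zero cells are absent from the
    output rather than reported as 0%.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if gene is None:
        gene = adata.uns.get("avhh_gene")
        if gene is None:
            raise KeyError("no gene given and no avhh_gene recorded in uns")
    x = _gene_column(adata, gene)
    df = pd.DataFrame({"positive": x >= min_count})
    keys = []
    if by_cluster:
        df["cluster"] = adata.obs["cluster"].to_numpy()
        keys.append("cluster")
    if by_group:
        df["group"] = adata.obs["group"].to_numpy()
        keys.append("group")
    if not keys:
        raise ValueError("at least one of by_cluster/by_group required")
    g = df.groupby(keys, observed=True)["positive"]
    out = g.agg(n_cells="size", n_positive="sum").reset_index()
    out["percent"] = 100.0 * out["n_positive"] / out["n_cells"]
    return out


def differential_expression(
    adata,
    cluster_filter=None,
    group_a: str = "Cat-LNP",
    group_b: str = "PBS",
    min_frac: float = 0.05,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Per-gene rank-sum DE of ``group_a`` vs ``group_b`` within clusters.

    Counts are scaled to ``target_sum`` per cell and log1p-transformed; p is
    the two-sided Wilcoxon rank-sum (asymptotic, tie-corrected), q the BH
    adjustment over tested genes; log2fc compares normalized group means with a
    pseudocount of 1.  Genes expressed in fewer than ``min_frac`` of the
    selected cells are excluded from testing but reported (``tested=False``).
    """
    obs = adata.obs
    mask = np.ones(adata.n_obs, dtype=bool)
    if cluster_filter is not None:
        mask &= obs["cluster"].isin(list(cluster_filter)).to_numpy()
    mask_a = mask & (obs["group"] == group_a).to_numpy()
    mask_b = mask & (obs["group"] == group_b).to_numpy()
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError(f"empty group after filtering ({group_a}: {mask_a.sum()}, "
                         f"{group_b}: {mask_b.sum()})")
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("need >= 3 cells per group after filtering")

    X = _dense(adata.X[mask_a | mask_b])
    sel_a = mask_a[mask_a | mask_b]
    totals = X.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    norm = X / totals * target_sum
    logn = np.log1p(norm)

    expressed_frac = (X > 0).mean(axis=0)
    tested = expressed_frac >= min_frac

    genes = np.asarray(adata.var_names)
    p = np.full(len(genes), np.nan)
    if tested.any():
        res = stats.mannwhitneyu(
            logn[sel_a][:, tested], logn[~sel_a][:, tested],
            axis=0, alternative="two-sided",
        )
        pt = np.asarray(res.pvalue, dtype=float)
        pt[~np.isfinite(pt)] = 1.0  # zero-variance genes carry no evidence
        p[tested] = pt
    mean_a = norm[sel_a].mean(axis=0)
    mean_b = norm[~sel_a].mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    q = np.full(len(genes), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "tested": tested,
            "expressed_frac": expressed_frac,
        }
    ).set_index("gene")
    out["direction"] = np.where(out["log2fc"] > 0, "up",
                                np.where(out["log2fc"] < 0, "down", "none"))
    return out


def top_upregulated(de_result: pd.DataFrame, k: int = 10) -> list[str]:
    """Top ``k`` significantly upregulated genes (positive log2fc, p < 0.05),
    ranked by ascending p then descending |log2fc|; returns all qualifying
    genes when fewer than ``k`` qualify."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = de_result[
        de_result["tested"] & (de_result["p"] < 0.05) & (de_result["log2fc"] > 0)
    ].copy()
    sig["abs_lfc"] = sig["log2fc"].abs()
    sig = sig.sort_values(["p", "abs_lfc"], ascending=[True, False], kind="stable")
    return list(sig.index[:k])


def ora_hypergeometric(
    query_genes,
    gene_sets: dict[str, list[str]],
    background,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of ``query_genes`` in each
    gene set, over the ``background`` universe.

    Sets are intersected with the background before testing; a set with zero
    background overlap scores p = 1.  ``enriched`` flags p < ``alpha``
    (default 0.001).
    """
    background = set(background)
    query = set(query_genes)
    if not background:
        raise ValueError("empty background universe")
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")
    M, n = len(background), len(query)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & background
        K = len(inset)
        k = len(inset & query)
        p = 1.0 if K == 0 else float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": K,
                "background_size": M,
                "p": p,
                "enriched": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("gene_set")


def read_gene_sets(gmt_path) -> dict[str, list[str]]:
    """Gene sets from a GMT file (tab-delimited: name, description, members)."""
    return read_gmt(str(gmt_path))
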