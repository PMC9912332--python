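"""Synthetic screen and single-cell datasets with known ground truth.

Two generators emulate the statistical structure of a pooled DNA-barcode LNP
screen so that every downstream analysis stage can be scored against truth:

* ``simulate_screen_counts`` — barcode x sample count tables for an input pool
  plus per-mouse, per-cell-type sorted samples.  Each LNP's delivery potency to
  a cell type is its baseline times a charge-class x tissue tropism multiplier
  times a per-LNP lognormal factor; the unencapsulated control barcode gets a
  strongly reduced potency.  Replicate-mouse variability is modelled as
  Dirichlet-multinomial overdispersion around the potency-weighted input
  proportions.
* ``simulate_sc_matrix`` — a sparse cell x gene count matrix with cluster and
  treatment-group labels, a delivery-reporter (aVHH) pseudogene concentrated in
  endothelial clusters of the cationic-LNP group, and a planted block of
  treatment-upregulated genes.

Both are pure functions of (config, seed).  Default magnitudes (tropism
multipliers, capture probabilities, depths) are synthetic working values
encoding the qualitative biology, not measured estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .library import LibraryDesign, default_library
from .quant import INPUT_POOL_LABEL, BarcodeCountTable, BarcodeSpec

__all__ = [
    "DEFAULT_CELL_TYPES",
    "DEFAULT_CHARGE_TISSUE_EFFECT",
    "ScreenSimConfig",
    "ScreenTruth",
    "simulate_screen_counts",
    "simulate_screen_fastq",
    "ScSimConfig",
    "simulate_sc_matrix",
    "write_sc_dataset",
    "read_sc_dataset",
]

#: 19 sorted cell types across 5 tissues, mirroring a whole-animal sort panel.
DEFAULT_CELL_TYPES: tuple[tuple[str, str], ...] = (
    ("lung", "endothelial"), ("lung", "dendritic"), ("lung", "T_cell"),
    ("lung", "B_cell"), ("lung", "monocyte"),
    ("liver", "hepatocyte"), ("liver", "endothelial"), ("liver", "Kupffer"),
    ("liver", "dendritic"),
    ("spleen", "endothelial"), ("spleen", "T_cell"), ("spleen", "B_cell"),
    ("spleen", "dendritic"), ("spleen", "macrophage"),
    ("heart", "endothelial"), ("heart", "immune"), ("heart", "fibroblast"),
    ("kidney", "endothelial"), ("kidney", "immune"),
)

#: Qualitative tropism: cationic helper lipids shift delivery to the lung,
#: neutral/anionic to the liver (and mildly the spleen); unlisted pairs are 1.
DEFAULT_CHARGE_TISSUE_EFFECT: dict[tuple[str, str], float] = {
    ("cationic", "lung"): 50.0,
    ("cationic", "heart"): 3.0,
    ("cationic", "kidney"): 3.0,
    ("cationic", "spleen"): 2.0,
    ("neutral", "liver"): 10.0,
    ("neutral", "spleen"): 3.0,
    ("anionic", "liver"): 10.0,
    ("anionic", "spleen"): 3.0,
}

NAKED_ROW = "naked_control"


def _cell_type_id(tissue: str, cell_type: str) -> str:
    return f"{tissue}/{cell_type}"


@dataclass
class ScreenSimConfig:
    """Study conditions for the pooled screen simulator.

    Defaults mirror the screen design: the 137-LNP pooled default library,
    19 cell types in 5 tissues, 4 mice, a naked-barcode control delivered far
    less efficiently than encapsulated barcodes, and strong cationic->lung /
    neutral- and anionic->liver tropism.
    """

    library: LibraryDesign | None = None
    cell_types: tuple[tuple[str, str], ...] = DEFAULT_CELL_TYPES
    n_mice: int = 4
    depth_input: int = 200_000
    depth_sample: int = 100_000
    potency_baseline: float = 1.0
    charge_tissue_effect: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CHARGE_TISSUE_EFFECT)
    )
    naked_control_multiplier: float = 0.02
    lnp_noise_sd: float = 0.3
    overdispersion: float = 200.0  # Dirichlet concentration; inf = multinomial
    input_pool_concentration: float = 400.0  # Dirichlet conc of near-uniform pool
    seed: int = 0

    def __post_init__(self):
        if self.library is None:
            self.library = default_library(seed=self.seed)
        if not self.cell_types:
            raise ValueError("at least one cell type required")
        if not self.library.pooled_designs:
            raise ValueError("library has no pooled designs")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.depth_input < 0 or self.depth_sample < 0:
            raise ValueError("depths must be >= 0")
        if not (0 < self.naked_control_multiplier < 1):
            raise ValueError("naked_control_multiplier must be in (0, 1)")
        if any(v <= 0 for v in self.charge_tissue_effect.values()):
            raise ValueError("tropism multipliers must be positive")


@dataclass
class ScreenTruth:
    """Ground truth of one simulated screen.

    ``potency`` and ``expected_proportions`` are indexed by design_id plus a
    ``naked_control`` row; columns are ``tissue/cell_type`` labels.
    ``expected_proportions`` columns each sum to 1.
    """

    potency: pd.DataFrame
    expected_proportions: pd.DataFrame
    input_proportions: pd.Series

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.potency.to_csv(out / "truth_potency.csv")
        self.expected_proportions.to_csv(out / "truth_expected_proportions.csv")
        self.input_proportions.rename("proportion").to_csv(
            out / "truth_input_proportions.csv"
        )


def simulate_screen_counts(config: ScreenSimConfig) -> tuple[BarcodeCountTable, ScreenTruth]:
    """Draw the input-pool and per-(mouse, cell type) barcode count columns.

    Per sample the barcode proportions are Dirichlet-distributed around the
    potency-weighted input proportions with the configured concentration
    (``overdispersion=inf`` collapses to a plain multinomial), and counts are a
    multinomial of the configured depth, so column sums equal depth exactly.
    """
    lib = config.library
    designs = lib.pooled_designs
    rng = np.random.default_rng(config.seed)

    row_ids = [d.design_id for d in designs] + [NAKED_ROW]
    barcode_ids = [d.barcode_id for d in designs] + [lib.naked_control_barcode]
    n = len(row_ids)
    ct_ids = [_cell_type_id(t, c) for t, c in config.cell_types]

    input_props = rng.dirichlet(np.full(n, config.input_pool_concentration))
    lnp_factor = np.exp(rng.normal(0.0, config.lnp_noise_sd, size=len(designs)))

    potency = np.empty((n, len(ct_ids)))
    for j, (tissue, _) in enumerate(config.cell_types):
        for i, d in enumerate(designs):
            eff = config.charge_tissue_effect.get(
                (d.helper_lipid.charge_class, tissue), 1.0
            )
            potency[i, j] = config.potency_baseline * eff * lnp_factor[i]
        potency[-1, j] = config.potency_baseline * config.naked_control_multiplier

    weighted = input_props[:, None] * potency
    expected = weighted / weighted.sum(axis=0, keepdims=True)

    columns, meta_rows = {}, []
    columns[INPUT_POOL_LABEL] = rng.multinomial(config.depth_input, input_props)
    meta_rows.append(
        {"sample": INPUT_POOL_LABEL, "mouse": 0, "tissue": "pool",
         "cell_type": INPUT_POOL_LABEL}
    )
    for m in range(1, config.n_mice + 1):
        for j, (tissue, cell) in enumerate(config.cell_types):
            if np.isfinite(config.overdispersion):
                p = rng.dirichlet(config.overdispersion * expected[:, j])
            else:
                p = expected[:, j]
            sample = f"m{m}|{tissue}|{cell}"
            columns[sample] = rng.multinomial(config.depth_sample, p)
            meta_rows.append(
                {"sample": sample, "mouse": m, "tissue": tissue, "cell_type": cell}
            )

    counts = pd.DataFrame(columns, index=pd.Index(barcode_ids, name="barcode_id"))
    meta = pd.DataFrame(meta_rows).set_index("sample")
    table = BarcodeCountTable(counts=counts, sample_meta=meta)
    truth = ScreenTruth(
        potency=pd.DataFrame(potency, index=row_ids, columns=ct_ids),
        expected_proportions=pd.DataFrame(expected, index=row_ids, columns=ct_ids),
        input_proportions=pd.Series(input_props, index=row_ids, name="proportion"),
    )
    return table, truth


_BASE_TO_CODE = {b: i for i, b in enumerate("ACGT")}
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_TO_CODE[b] for b in seq], dtype=np.uint8)


def simulate_screen_fastq(
    counts: BarcodeCountTable,
    library: LibraryDesign,
    read_error_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path = ".",
    spec: BarcodeSpec | None = None,
) -> pd.DataFrame:
    """Expand a count table into per-sample FASTQ files with truth alongside.

    Each counted barcode occurrence becomes one read laid out as
    ``upstream_anchor + barcode + downstream_anchor`` per ``spec``; substitution
    errors are injected i.i.d. per base at ``read_error_rate``.  Writes
    ``<sample>.fastq`` per sample plus ``truth_counts.csv``, and returns a
    sample sheet ready for :func:`lnpscreen.quant.count_barcodes`.
    """
    if not 0 <= read_error_rate < 1:
        raise ValueError("read_error_rate must be in [0, 1)")
    missing = set(counts.counts.index) - set(library.barcodes)
    if missing:
        raise ValueError(f"barcodes absent from library: {sorted(missing)[:5]}")
    spec = spec or BarcodeSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    up = spec.upstream_anchor or ""
    down = spec.downstream_anchor or ""
    pad = "A" * (spec.offset - len(up))  # filler before the upstream anchor
    templates = {
        bid: _encode(pad + up + library.barcodes[bid] + down)
        for bid in counts.counts.index
    }
    read_len = spec.offset + spec.length + len(down)
    qual = "I" * read_len

    sheet_rows = []
    for sample in counts.counts.columns:
        col = counts.counts[sample]
        total = int(col.sum())
        reads = np.empty((total, read_len), dtype=np.uint8)
        pos = 0
        for bid, c in col.items():
            if c > 0:
                reads[pos: pos + c] = templates[bid]
                pos += c
        if read_error_rate > 0 and total > 0:
            mask = rng.random(reads.shape) < read_error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            reads[mask] = (reads[mask] + shift) % 4
        seqs = _CODE_TO_BASE[reads]
        safe = sample.replace("|", "_").replace("/", "_")
        path = out / f"{safe}.fastq"
        with open(path, "w") as fh:
            for i in range(total):
                fh.write(
                    f"@{safe}:{i}\n{seqs[i].tobytes().decode()}\n+\n{qual}\n"
                )
        meta = counts.sample_meta.loc[sample]
        sheet_rows.append(
            {"sample": sample, "fastq": str(path), "mouse": meta["mouse"],
             "tissue": meta["tissue"], "cell_type": meta["cell_type"]}
        )
    counts.counts.to_csv(out / "truth_counts.csv")
    return pd.DataFrame(sheet_rows)


# ---------------------------------------------------------------------------
# Single-cell simulator
# ---------------------------------------------------------------------------

#: cluster -> compartment; the aVHH reporter concentrates in endothelial ones.
DEFAULT_CLUSTERS: dict[str, str] = {
    "EC_capillary": "endothelial",
    "EC_vascular": "endothelial",
    "EC_lymphatic": "endothelial",
    "fibroblast": "fibroblast",
    "monocyte": "immune",
    "B_cell": "immune",
    "T_cell": "immune",
    "epithelial": "epithelial",
}

DEFAULT_GROUPS = ("Cat-LNP", "Neu-LNP", "An-LNP", "PBS")

AVHH_GENE = "aVHH"


def default_avhh_capture_prob(
    clusters: dict[str, str] = DEFAULT_CLUSTERS,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    endothelial_prob: float = 0.6,
    other_prob: float = 0.05,
) -> dict[tuple[str, str], float]:
    """Per-(cluster, group) reporter capture probabilities.

    Cationic-LNP animals show strong endothelial capture and weak capture
    elsewhere; neutral/anionic LNPs deliver little to the lung and PBS nothing.
    """
    probs = {}
    for cl, comp in clusters.items():
        for g in groups:
            if g == "Cat-LNP":
                probs[(cl, g)] = endothelial_prob if comp == "endothelial" else other_prob
            elif g == "PBS":
                probs[(cl, g)] = 0.0
            else:
                probs[(cl, g)] = 0.02
    return probs


@dataclass
class ScSimConfig:
    """Study conditions for the single-cell count simulator.

    Per (cluster, group) stratum, ``n_cells_per_cluster[cluster]`` cells are
    drawn; gene counts are negative binomial around per-gene baseline means
    (lognormal-spread defaults) with ``de_block`` genes shifted by ``2**log2fc``
    in their group; the aVHH pseudogene is Bernoulli(capture) x (1 + Poisson).
    """

    clusters: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLUSTERS))
    n_cells_per_cluster: dict[str, int] | int = 150
    treatment_groups: tuple[str, ...] = DEFAULT_GROUPS
    avhh_capture_prob: dict[tuple[str, str], float] | None = None
    n_genes: int = 1200
    de_block: tuple[tuple[str, str, float], ...] | None = None
    baseline_expression: np.ndarray | None = None
    dispersion: float = 0.5
    avhh_extra_mean: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.n_cells_per_cluster, int):
            self.n_cells_per_cluster = {
                cl: self.n_cells_per_cluster for cl in self.clusters
            }
        if any(v < 0 for v in self.n_cells_per_cluster.values()):
            raise ValueError("cell counts must be >= 0")
        if self.avhh_capture_prob is None:
            self.avhh_capture_prob = default_avhh_capture_prob(
                self.clusters, self.treatment_groups
            )
        if any(not 0 <= p <= 1 for p in self.avhh_capture_prob.values()):
            raise ValueError("capture probabilities must be in [0, 1]")
        if self.de_block is None:
            self.de_block = tuple(
                (f"gene{i:04d}", "Cat-LNP", 2.0) for i in range(1, 16)
            )
        if any(not np.isfinite(lfc) for _, _, lfc in self.de_block):
            raise ValueError("log2fc must be finite")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(1, self.n_genes + 1)]


def simulate_sc_matrix(config: ScSimConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Generate the labelled cell x gene matrix and the truth DE table.

    Returns an :class:`anndata.AnnData` (sparse integer counts; ``obs`` carries
    ``cluster`` and ``group``; the aVHH pseudogene is the last var and is named
    in ``uns["avhh_gene"]``) plus a tidy truth table of planted
    (gene, group, log2fc) effects.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, grp, _ in config.de_block:
        if g not in gene_pos:
            raise ValueError(f"de_block gene {g!r} not among simulated genes")
        if grp not in config.treatment_groups:
            raise ValueError(f"de_block group {grp!r} unknown")

    if config.baseline_expression is None:
        base = 10.0 ** rng.uniform(-1.3, 1.0, size=config.n_genes)
    else:
        base = np.asarray(config.baseline_expression, dtype=float)
        if base.shape != (config.n_genes,):
            raise ValueError("baseline_expression must have length n_genes")
    r = 1.0 / config.dispersion  # NB size parameter

    blocks, obs_rows = [], []
    for cluster in config.clusters:
        n_cells = config.n_cells_per_cluster[cluster]
        for group in config.treatment_groups:
            mean = base.copy()
            for g, grp, lfc in config.de_block:
                if grp == group:
                    mean[gene_pos[g]] *= 2.0 ** lfc
            if n_cells == 0:
                continue
            p = r / (r + mean)
            x = rng.negative_binomial(r, p, size=(n_cells, config.n_genes))
            cap = config.avhh_capture_prob.get((cluster, group), 0.0)
            pos = rng.random(n_cells) < cap
            avhh = pos * (1 + rng.poisson(config.avhh_extra_mean, size=n_cells))
            blocks.append(np.column_stack([x, avhh]))
            for _ in range(n_cells):
                obs_rows.append({"cluster": cluster, "group": group})

    X = np.vstack(blocks) if blocks else np.empty((0, config.n_genes + 1), dtype=int)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:05d}" for i in range(len(obs))]
    var = pd.DataFrame(index=pd.Index(genes + [AVHH_GENE], name="gene_id"))
    adata = ad.AnnData(X=sp.csr_matrix(X, dtype=np.int64), obs=obs, var=var)
    adata.uns["avhh_gene"] = AVHH_GENE
    truth = pd.DataFrame(
        [{"gene": g, "group": grp, "log2fc": lfc} for g, grp, lfc in config.de_block]
    )
    return adata, truth


def write_sc_dataset(adata: ad.AnnData, out_dir) -> None:
    """Matrix Market counts + gene/cell label files + cell metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(adata.X))
    (out / "genes.txt").write_text("\n".join(adata.var_names) + "\n")
    (out / "cells.txt").write_text("\n".join(adata.obs_names) + "\n")
    adata.obs[["cluster", "group"]].to_csv(out / "cell_metadata.csv")


def read_sc_dataset(in_dir) -> ad.AnnData:
    src = Path(in_dir)
    X = sp.csr_matrix(mmread(str(src / "matrix.mtx")))
    genes = (src / "genes.txt").read_text().splitlines()
    cells = (src / "cells.txt").read_text().splitlines()
    meta = pd.read_csv(src / "cell_metadata.csv", index_col=0)
    adata = ad.AnnData(
        X=X,
        obs=meta.loc[cells],
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    if AVHH_GENE in adata.var_names:
        adata.uns["avhh_gene"] = AVHH_GENE
    return adata
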