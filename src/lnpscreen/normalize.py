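"""Normalized delivery: deconvolve barcode counts into per-LNP delivery scores.

For each sorted sample, every barcode's proportion is divided by its proportion
in the injected input pool (so doses are accounted for), and the resulting
ratios over the retained LNPs are rescaled to sum to 100.  The unencapsulated
(naked) control barcode is excluded from the rescaling denominator and reported
on the same scale separately, so its inefficiency serves as a floor rather than
inflating LNP scores.  QC drops samples with too few assigned reads and
barcodes underrepresented in the input pool before rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import LibraryDesign
from .quant import BarcodeCountTable

__all__ = [
    "QCThresholds",
    "QCFlags",
    "NormalizedDeliveryTable",
    "proportions",
    "normalized_delivery",
    "apply_qc",
    "normalized_delivery_table",
    "aggregate_mice",
    "mean_matrix",
]


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive QC bounds.

    ``min_input_proportion=None`` defaults to half the uniform expectation over
    the counted barcodes (0.5 / n_barcodes).
    """

    min_input_proportion: float | None = None
    min_reads_per_sample: int = 10_000


@dataclass
class QCFlags:
    excluded_samples: dict[str, str] = field(default_factory=dict)
    excluded_barcodes: dict[str, str] = field(default_factory=dict)


@dataclass
class NormalizedDeliveryTable:
    """Per-LNP normalized delivery (percent scale; retained rows sum to 100
    per sample) with the naked control reported separately."""

    nd: pd.DataFrame  # design_id x sample
    naked_control_nd: pd.Series  # per sample
    sample_meta: pd.DataFrame
    qc: QCFlags = field(default_factory=QCFlags)


def proportions(counts_column: pd.Series) -> pd.Series:
    """Counts over their total; raises on an all-zero column (callers flag and
    exclude such samples rather than propagating NaN)."""
    total = counts_column.sum()
    if total <= 0:
        raise ValueError("all-zero counts column")
    return counts_column / total


def normalized_delivery(
    sample_props: pd.Series, input_pool_props: pd.Series
) -> pd.Series:
    """Per-LNP scores: proportion ratios to the input pool, rescaled to 100.

    Both vectors must share the same barcode index; input proportions must be
    positive for every retained barcode (zero-input barcodes are a QC exclusion
    upstream).
    """
    if not sample_props.index.equals(input_pool_props.index):
        raise ValueError("sample and input-pool vectors must share one index")
    if (input_pool_props <= 0).any():
        bad = list(input_pool_props.index[input_pool_props <= 0])
        raise ValueError(f"zero input-pool proportion for {bad[:5]} (QC-exclude first)")
    ratios = sample_props / input_pool_props
    return 100.0 * ratios / ratios.sum()


def apply_qc(
    counts: BarcodeCountTable,
    thresholds: QCThresholds = QCThresholds(),
) -> QCFlags:
    """Deterministic sample/barcode exclusion flags (inclusive bounds).

    Samples (input pool included) are flagged when assigned reads fall below
    ``min_reads_per_sample``; barcodes when their input-pool proportion falls
    below ``min_input_proportion``.
    """
    flags = QCFlags()
    totals = counts.counts.sum(axis=0)
    for sample, total in totals.items():
        if total < thresholds.min_reads_per_sample:
            flags.excluded_samples[sample] = (
                f"assigned reads {total} < {thresholds.min_reads_per_sample}"
            )
    input_cols = [s for s in counts.input_samples if s not in flags.excluded_samples]
    if input_cols:
        pool = counts.counts[input_cols].sum(axis=1)
        pool_props = pool / pool.sum()
        thr = thresholds.min_input_proportion
        if thr is None:
            thr = 0.5 / len(pool_props)
        for bid, p in pool_props.items():
            if p < thr:
                flags.excluded_barcodes[bid] = (
                    f"input-pool proportion {p:.3g} < {thr:.3g}"
                )
    return flags


def normalized_delivery_table(
    counts: BarcodeCountTable,
    library: LibraryDesign,
    thresholds: QCThresholds = QCThresholds(),
) -> NormalizedDeliveryTable:
    """Full deconvolution of a screen count table into normalized delivery.

    The input pool column(s) define reference proportions; QC-excluded barcodes
    are dropped before rescaling; every retained sample's LNP scores sum to 100.
    """
    input_cols = counts.input_samples
    if not input_cols:
        raise ValueError("count table has no input-pool sample")
    flags = apply_qc(counts, thresholds)
    usable_inputs = [s for s in input_cols if s not in flags.excluded_samples]
    if not usable_inputs:
        raise ValueError("all input-pool samples failed QC")

    naked_bid = library.naked_control_barcode
    bc_to_design = library.barcode_to_design()
    lnp_bids = [
        b for b in counts.counts.index
        if b in bc_to_design and b not in flags.excluded_barcodes
    ]
    pool = counts.counts[usable_inputs].sum(axis=1)
    pool_props = proportions(pool)

    nd_cols, naked = {}, {}
    for sample in counts.sorted_samples:
        if sample in flags.excluded_samples:
            continue
        try:
            props = proportions(counts.counts[sample])
        except ValueError:
            flags.excluded_samples[sample] = "all-zero counts column"
            continue
        ratios = props[lnp_bids] / pool_props[lnp_bids]
        denom = ratios.sum()
        nd_cols[sample] = 100.0 * ratios / denom
        if naked_bid is not None and naked_bid in props.index:
            naked[sample] = float(
                100.0 * (props[naked_bid] / pool_props[naked_bid]) / denom
            )

    nd = pd.DataFrame(nd_cols)
    nd.index = [bc_to_design[b] for b in lnp_bids]
    nd.index.name = "design_id"
    return NormalizedDeliveryTable(
        nd=nd,
        naked_control_nd=pd.Series(naked, dtype=float),
        sample_meta=counts.sample_meta.loc[list(nd.columns)],
        qc=flags,
    )


def aggregate_mice(ndt: NormalizedDeliveryTable) -> pd.DataFrame:
    """Mean, SEM and n over mice per (design, tissue/cell_type).

    SEM is sd/sqrt(n) with ddof=1 and is reported absent (NaN) for n=1.
    Cell types with no retained sample in any mouse are simply absent.
    """
    meta = ndt.sample_meta
    long = (
        ndt.nd.T.join(meta[["tissue", "cell_type"]])
        .melt(id_vars=["tissue", "cell_type"], var_name="design_id", value_name="nd")
    )
    long["cell_type_id"] = long["tissue"] + "/" + long["cell_type"]
    g = long.groupby(["design_id", "cell_type_id"])["nd"]
    out = g.agg(mean="mean", sem="sem", n="count").reset_index()
    return out


def mean_matrix(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Wide design_id x cell_type_id matrix of mean normalized delivery."""
    return aggregated.pivot(index="design_id", columns="cell_type_id", values="mean")
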