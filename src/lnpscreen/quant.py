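"""Barcode extraction from sequencing reads and barcode x sample counting.

Each amplicon read carries a fixed-position DNA barcode, optionally flanked by
constant anchor sequences.  A read is assigned to the unique library barcode
within ``max_mismatch`` substitutions of its barcode window; ambiguous or
unmatched reads are counted as unassigned.  With ``max_mismatch`` below half
the library's minimum pairwise Hamming distance the nearest barcode is provably
unique, so assignment never depends on tie-breaking.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .library import LibraryDesign, hamming

__all__ = ["BarcodeSpec", "BarcodeCountTable", "extract_barcode", "count_barcodes"]

INPUT_POOL_LABEL = "input_pool"


@dataclass(frozen=True)
class BarcodeSpec:
    """Where the barcode sits in a read and how strictly to match it."""

    offset: int = 8
    length: int = 8
    upstream_anchor: str | None = "ACGGTCAT"
    downstream_anchor: str | None = "TGACCGTA"
    max_mismatch: int = 1
    anchor_max_mismatch: int = 2

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("barcode length must be >= 1")
        if self.offset < 0 or self.max_mismatch < 0 or self.anchor_max_mismatch < 0:
            raise ValueError("offset and mismatch budgets must be nonnegative")
        if self.upstream_anchor and len(self.upstream_anchor) > self.offset:
            raise ValueError("upstream anchor longer than the offset it precedes")

    def validate_against(self, library: LibraryDesign) -> None:
        mh = library.min_pairwise_hamming
        if mh is not None and not self.max_mismatch < mh / 2:
            raise ValueError(
                f"max_mismatch={self.max_mismatch} must be < min_pairwise_hamming/2 "
                f"({mh}/2) to guarantee a unique nearest barcode"
            )


@dataclass
class BarcodeCountTable:
    """Raw integer counts (barcodes x samples) plus sample metadata.

    ``sample_meta`` is indexed by sample name with columns ``mouse``, ``tissue``
    and ``cell_type``; the input pool sample carries
    ``cell_type == "input_pool"``.  Per sample, assigned + unassigned reads
    equal the reads processed.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    unassigned: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def __post_init__(self):
        if not set(self.counts.columns) <= set(self.sample_meta.index):
            raise ValueError("every counts column needs a sample_meta row")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.unassigned.empty:
            self.unassigned = pd.Series(0, index=self.counts.columns, dtype=int)

    @property
    def input_samples(self) -> list[str]:
        return [
            s for s in self.counts.columns
            if self.sample_meta.loc[s, "cell_type"] == INPUT_POOL_LABEL
        ]

    @property
    def sorted_samples(self) -> list[str]:
        inputs = set(self.input_samples)
        return [s for s in self.counts.columns if s not in inputs]

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)

    def meta_to_csv(self, path) -> None:
        meta = self.sample_meta.copy()
        meta["unassigned"] = self.unassigned.reindex(meta.index).fillna(0).astype(int)
        meta.to_csv(path)


def _matches_anchor(window: str, anchor: str, budget: int) -> bool:
    return len(window) == len(anchor) and hamming(window, anchor) <= budget


def extract_barcode(
    read_sequence: str,
    spec: BarcodeSpec,
    barcode_universe: dict[str, str],
) -> str | None:
    """Assign one read to a barcode_id, or ``None`` if unassigned.

    Exact window match wins immediately; otherwise the unique barcode within
    Hamming distance ``max_mismatch`` is taken, with equal-minimal-distance
    ambiguity resolved to unassigned.  Configured anchors must match within
    ``anchor_max_mismatch``.  Reads too short for the window are unassigned.
    """
    read = read_sequence.upper()
    end = spec.offset + spec.length
    need = end + (len(spec.downstream_anchor) if spec.downstream_anchor else 0)
    if len(read) < need:
        return None
    if spec.upstream_anchor:
        up = read[spec.offset - len(spec.upstream_anchor): spec.offset]
        if not _matches_anchor(up, spec.upstream_anchor, spec.anchor_max_mismatch):
            return None
    if spec.downstream_anchor:
        down = read[end: end + len(spec.downstream_anchor)]
        if not _matches_anchor(down, spec.downstream_anchor, spec.anchor_max_mismatch):
            return None
    window = read[spec.offset: end]
    exact = barcode_universe.get(window)
    if exact is not None:
        return exact
    if spec.max_mismatch == 0:
        return None
    best_id, best_d, tied = None, spec.max_mismatch + 1, False
    for seq, bid in barcode_universe.items():
        d = hamming(window, seq)
        if d < best_d:
            best_id, best_d, tied = bid, d, False
        elif d == best_d:
            tied = True
    if best_d <= spec.max_mismatch and not tied:
        return best_id
    return None


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_barcodes(
    sample_sheet: pd.DataFrame,
    spec: BarcodeSpec,
    library: LibraryDesign,
    revcomp: bool = False,
) -> BarcodeCountTable:
    """Count every library barcode (zeros included) in each sample's FASTQ.

    ``sample_sheet`` needs columns ``sample, fastq, mouse, tissue, cell_type``.
    The naked control barcode is counted like any other.  Per-file parse errors
    are re-raised with the offending file named.  Reads are used as-is (no
    quality trimming); set ``revcomp`` to demultiplex reverse-complemented reads.
    """
    required = {"sample", "fastq", "mouse", "tissue", "cell_type"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    spec.validate_against(library)
    universe = {seq: bid for bid, seq in library.barcodes.items()}
    barcode_ids = list(library.barcodes)
    counts = pd.DataFrame(
        0, index=pd.Index(barcode_ids, name="barcode_id"),
        columns=list(sample_sheet["sample"]), dtype=int,
    )
    unassigned = pd.Series(0, index=counts.columns, dtype=int)
    for _, row in sample_sheet.iterrows():
        sample = row["sample"]
        tally: dict[str, int] = {}
        n_un = 0
        try:
            with _open_maybe_gzip(row["fastq"]) as fh:
                for rec in SeqIO.parse(fh, "fastq"):
                    seq = str(rec.seq)
                    if revcomp:
                        seq = str(rec.seq.reverse_complement())
                    bid = extract_barcode(seq, spec, universe)
                    if bid is None:
                        n_un += 1
                    else:
                        tally[bid] = tally.get(bid, 0) + 1
        except ValueError as exc:
            raise ValueError(f"FASTQ parse failure in {row['fastq']}: {exc}") from exc
        for bid, n in tally.items():
            counts.loc[bid, sample] = n
        unassigned[sample] = n_un
    meta = sample_sheet.set_index("sample")[["mouse", "tissue", "cell_type"]]
    return BarcodeCountTable(counts=counts, sample_meta=meta, unassigned=unassigned)
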