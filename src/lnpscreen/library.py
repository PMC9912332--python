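"""Full-factorial LNP library enumeration, chemical annotation and barcode assignment.

A four-component lipid nanoparticle (LNP) is defined here by the identity of its
helper lipid (the charge-bearing structural lipid), the molar ratio of the four
components (ionizable lipid : helper lipid : cholesterol : PEG-lipid) and the
PEG-lipid species.  Crossing a helper-lipid panel with a set of molar-ratio arms
and PEG-lipid arms yields the chemically distinct designs of a pooled screen;
each pooled design is tagged with a unique DNA barcode, and one extra barcode is
reserved for the unencapsulated ("naked") negative control that is co-injected
as a delivery floor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HelperLipid",
    "FormulationArm",
    "LNPDesign",
    "LibraryDesign",
    "LibraryError",
    "BarcodeAssignmentError",
    "enumerate_library",
    "assign_barcodes",
    "subset_by_charge",
    "dose_per_lnp",
    "default_lipid_panel",
    "default_ratio_arms",
    "default_peg_arms",
    "default_library",
    "DEFAULT_POOLED_FAILURES",
    "read_lipid_table",
    "write_library_csv",
    "read_library_csv",
    "write_barcodes_fasta",
    "hamming",
]

CHARGE_CLASSES = ("cationic", "neutral", "anionic")
NUCLEOTIDES = "ACGT"
NAKED_CONTROL_ID = "naked_control"


class LibraryError(ValueError):
    """Invalid library construction input."""


class BarcodeAssignmentError(RuntimeError):
    """Barcode assignment infeasible for the requested length / distance."""


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class HelperLipid:
    """One helper lipid with its chemical annotation.

    ``charge_class`` drives tissue tropism in vivo (cationic -> lung,
    neutral/anionic -> liver); ``headgroup_mw`` is the nominal headgroup
    molecular weight in daltons, ``tail_descriptor`` the acyl-chain notation
    (e.g. ``"18:0"`` = fully saturated C18).
    """

    name: str
    charge_class: str
    headgroup_mw: float
    tail_descriptor: str = ""
    headgroup_name: str = ""

    def __post_init__(self):
        if self.charge_class not in CHARGE_CLASSES:
            raise LibraryError(
                f"charge_class {self.charge_class!r} not in {CHARGE_CLASSES}"
            )
        if not self.headgroup_mw > 0:
            raise LibraryError("headgroup_mw must be positive")


@dataclass(frozen=True)
class FormulationArm:
    """A (molar ratio, PEG-lipid) arm of the factorial design.

    The four mole fractions refer to ionizable lipid, helper lipid,
    cholesterol and PEG-lipid and must sum to 1.
    """

    molar_ratio_id: str
    ionizable_frac: float
    helper_frac: float
    chol_frac: float
    peg_frac: float
    peg_lipid: str = ""

    def __post_init__(self):
        total = self.ionizable_frac + self.helper_frac + self.chol_frac + self.peg_frac
        if abs(total - 1.0) > 1e-9:
            raise LibraryError(
                f"mole fractions of arm {self.molar_ratio_id!r} sum to {total}, not 1"
            )
        if min(self.ionizable_frac, self.helper_frac, self.chol_frac, self.peg_frac) < 0:
            raise LibraryError("mole fractions must be nonnegative")


@dataclass(frozen=True)
class LNPDesign:
    design_id: str
    helper_lipid: HelperLipid
    arm: FormulationArm
    barcode_id: str | None = None
    pooled: bool = True


@dataclass(frozen=True)
class LibraryDesign:
    """The enumerated library: designs, barcode sequences, control barcode."""

    designs: tuple[LNPDesign, ...]
    barcodes: dict[str, str] = field(default_factory=dict)  # barcode_id -> sequence
    naked_control_barcode: str | None = None
    barcode_length: int | None = None
    min_pairwise_hamming: int | None = None

    def __post_init__(self):
        ids = [d.design_id for d in self.designs]
        if len(set(ids)) != len(ids):
            raise LibraryError("design_id values must be unique")
        bids = [d.barcode_id for d in self.designs if d.barcode_id is not None]
        if len(set(bids)) != len(bids):
            raise LibraryError("assigned barcode IDs must be distinct")
        if self.naked_control_barcode is not None and self.naked_control_barcode in bids:
            raise LibraryError("naked control barcode assigned to a design")

    def __len__(self) -> int:
        return len(self.designs)

    @property
    def pooled_designs(self) -> tuple[LNPDesign, ...]:
        return tuple(d for d in self.designs if d.pooled)

    def design(self, design_id: str) -> LNPDesign:
        for d in self.designs:
            if d.design_id == design_id:
                return d
        raise KeyError(design_id)

    def barcode_to_design(self) -> dict[str, str]:
        """Map barcode_id -> design_id for pooled designs."""
        return {d.barcode_id: d.design_id for d in self.pooled_designs if d.barcode_id}

    def properties(self, pooled_only: bool = True) -> pd.DataFrame:
        """Chemical-property table (one row per design) used by enrichment."""
        designs = self.pooled_designs if pooled_only else self.designs
        rows = []
        for d in designs:
            rows.append(
                {
                    "design_id": d.design_id,
                    "helper_lipid": d.helper_lipid.name,
                    "charge_class": d.helper_lipid.charge_class,
                    "headgroup_name": d.helper_lipid.headgroup_name,
                    "headgroup_mw": d.helper_lipid.headgroup_mw,
                    "tail": d.helper_lipid.tail_descriptor,
                    "molar_ratio_id": d.arm.molar_ratio_id,
                    "helper_frac": d.arm.helper_frac,
                    "peg_lipid": d.arm.peg_lipid,
                    "barcode_id": d.barcode_id,
                    "pooled": d.pooled,
                }
            )
        return pd.DataFrame(rows).set_index("design_id")


def enumerate_library(
    lipids: list[HelperLipid],
    ratio_arms: list[dict],
    peg_arms: list[str],
) -> LibraryDesign:
    """Cross lipids x molar-ratio arms x PEG arms into a full-factorial library.

    ``ratio_arms`` rows need keys ``molar_ratio_id, ionizable_frac, helper_frac,
    chol_frac, peg_frac``.  The result has ``len(lipids) * len(ratio_arms) *
    len(peg_arms)`` designs, every one carrying its full chemical annotation.
    """
    if not lipids or not ratio_arms or not peg_arms:
        raise LibraryError("lipid panel and both arm tables must be non-empty")
    names = [l.name for l in lipids]
    if len(set(names)) != len(names):
        raise LibraryError("duplicate lipid names in panel")
    designs = []
    for lipid, ratio, peg in itertools.product(lipids, ratio_arms, peg_arms):
        arm = FormulationArm(
            molar_ratio_id=str(ratio["molar_ratio_id"]),
            ionizable_frac=float(ratio["ionizable_frac"]),
            helper_frac=float(ratio["helper_frac"]),
            chol_frac=float(ratio["chol_frac"]),
            peg_frac=float(ratio["peg_frac"]),
            peg_lipid=str(peg),
        )
        design_id = f"{lipid.name}|{arm.molar_ratio_id}|{peg}"
        designs.append(LNPDesign(design_id=design_id, helper_lipid=lipid, arm=arm))
    return LibraryDesign(designs=tuple(designs))


def _random_separated_barcodes(
    n: int, length: int, min_hamming: int, rng: np.random.Generator
) -> list[str]:
    """Rejection-sample ``n`` barcodes, pairwise Hamming-separated by >= min_hamming."""
    accepted: list[str] = []
    max_attempts = max(10_000, 2_000 * n)
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise BarcodeAssignmentError(
                f"could not place {n} barcodes of length {length} at pairwise "
                f"Hamming >= {min_hamming} after {max_attempts} attempts"
            )
        cand = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, b) >= min_hamming for b in accepted):
            accepted.append(cand)
    return accepted


def assign_barcodes(
    library: LibraryDesign,
    length: int = 8,
    min_hamming: int = 3,
    seed: int = 0,
) -> LibraryDesign:
    """Assign one barcode per design plus a reserved naked-control barcode.

    Deterministic under ``seed``.  Default ``min_hamming=3`` permits
    single-substitution error correction during demultiplexing.  Raises
    :class:`BarcodeAssignmentError` when the code cannot be placed rather than
    silently truncating.
    """
    if min_hamming < 1:
        raise LibraryError("min_hamming must be >= 1")
    n_needed = len(library.designs) + 1  # + naked control
    if 4**length < 2 * n_needed:
        raise BarcodeAssignmentError(
            f"4^{length} barcodes cannot comfortably hold {n_needed} sequences"
        )
    rng = np.random.default_rng(seed)
    seqs = _random_separated_barcodes(n_needed, length, min_hamming, rng)
    barcodes = {f"BC{i + 1:03d}": s for i, s in enumerate(seqs[:-1])}
    barcodes[NAKED_CONTROL_ID] = seqs[-1]
    designs = tuple(
        replace(d, barcode_id=f"BC{i + 1:03d}") for i, d in enumerate(library.designs)
    )
    return LibraryDesign(
        designs=designs,
        barcodes=barcodes,
        naked_control_barcode=NAKED_CONTROL_ID,
        barcode_length=length,
        min_pairwise_hamming=min_hamming,
    )


def subset_by_charge(library: LibraryDesign, charge_class: str) -> LibraryDesign:
    """Designs whose helper lipid has ``charge_class``; naked control retained."""
    if charge_class not in CHARGE_CLASSES:
        raise LibraryError(f"unknown charge class {charge_class!r}")
    designs = tuple(
        d for d in library.designs if d.helper_lipid.charge_class == charge_class
    )
    kept_bids = {d.barcode_id for d in designs}
    barcodes = {
        bid: seq
        for bid, seq in library.barcodes.items()
        if bid in kept_bids or bid == library.naked_control_barcode
    }
    return LibraryDesign(
        designs=designs,
        barcodes=barcodes,
        naked_control_barcode=library.naked_control_barcode,
        barcode_length=library.barcode_length,
        min_pairwise_hamming=library.min_pairwise_hamming,
    )


def dose_per_lnp(total_dose_mg_per_kg: float, n_pooled: int) -> float:
    """Average nucleic-acid dose per LNP (mg/kg), to 2 significant figures.

    E.g. a 1.0 mg/kg pool of 23 LNPs doses 0.043 mg/kg per LNP on average.
    """
    if n_pooled < 1:
        raise LibraryError("n_pooled must be >= 1")
    if not total_dose_mg_per_kg > 0:
        raise LibraryError("total dose must be positive")
    return float(f"{total_dose_mg_per_kg / n_pooled:.2g}")


# ---------------------------------------------------------------------------
# Default study-like configuration: 18 helper lipids (3 cationic / 8 neutral /
# 7 anionic), 4 molar-ratio arms x 2 PEG-lipids = 144 designs, 137 pooled.
# The named panel members are representative commercial lipids; headgroup MWs
# are nominal values for the headgroup moiety and are configurable inputs,
# not measured quantities.
# ---------------------------------------------------------------------------

_DEFAULT_PANEL = [
    # name, charge, headgroup_mw (Da), tail, headgroup_name
    ("DDAB", "cationic", 46.0, "18:0", "dimethylammonium"),
    ("DOTAP", "cationic", 103.0, "18:1", "trimethylammonium-propane"),
    ("EPC", "cationic", 198.0, "16:0", "ethylphosphocholine"),
    ("DOPE", "neutral", 141.0, "18:1", "ammonium"),
    ("MePE", "neutral", 155.0, "18:1", "methylamine"),
    ("DiMePE", "neutral", 169.0, "18:1", "dimethylamine"),
    ("DOPC", "neutral", 183.0, "18:1", "trimethylamine"),
    ("DSPC", "neutral", 183.0, "18:0", "trimethylamine"),
    ("DPPC", "neutral", 183.0, "16:0", "trimethylamine"),
    ("DMPC", "neutral", 183.0, "14:0", "trimethylamine"),
    ("POPC", "neutral", 183.0, "16:0-18:1", "trimethylamine"),
    ("DOPA", "anionic", 97.0, "18:1", "phosphate"),
    ("DSPA", "anionic", 97.0, "18:0", "phosphate"),
    ("DMPA", "anionic", 97.0, "14:0", "phosphate"),
    ("DOPG", "anionic", 171.0, "18:1", "glycerophosphate"),
    ("DSPG", "anionic", 171.0, "18:0", "glycerophosphate"),
    ("POPG", "anionic", 171.0, "16:0-18:1", "glycerophosphate"),
    ("DOPS", "anionic", 184.0, "18:1", "phosphoserine"),
]

#: Designs excluded from pooling under the default configuration (stand-ins for
#: formulations failing the <=200 nm monodispersity criterion; which designs
#: fail is an experimental input, so this list is an arbitrary fixed choice:
#: 1 cationic + 5 neutral + 1 anionic, leaving 23 + 59 + 55 = 137 pooled).
DEFAULT_POOLED_FAILURES = (
    "EPC|r44.5|C18PEG2000",
    "DMPC|r12|C14PEG2000",
    "DMPC|r44.5|C18PEG2000",
    "POPC|r20|C14PEG2000",
    "DPPC|r44.5|C14PEG2000",
    "DiMePE|r12|C18PEG2000",
    "DSPA|r44.5|C18PEG2000",
)


def default_lipid_panel() -> list[HelperLipid]:
    return [HelperLipid(*row) for row in _DEFAULT_PANEL]


def default_ratio_arms() -> list[dict]:
    """Four molar-ratio arms; helper-lipid mole fractions 12 / 20 / 27.5 / 44.5 %.

    The 20% arm is a placeholder fourth arm completing the factorial; all arms
    are user-configurable.
    """
    return [
        {"molar_ratio_id": "r12", "ionizable_frac": 0.50, "helper_frac": 0.12,
         "chol_frac": 0.355, "peg_frac": 0.025},
        {"molar_ratio_id": "r20", "ionizable_frac": 0.40, "helper_frac": 0.20,
         "chol_frac": 0.375, "peg_frac": 0.025},
        {"molar_ratio_id": "r27.5", "ionizable_frac": 0.35, "helper_frac": 0.275,
         "chol_frac": 0.35, "peg_frac": 0.025},
        {"molar_ratio_id": "r44.5", "ionizable_frac": 0.25, "helper_frac": 0.445,
         "chol_frac": 0.28, "peg_frac": 0.025},
    ]


def default_peg_arms() -> list[str]:
    return ["C14PEG2000", "C18PEG2000"]


def default_library(
    seed: int = 0,
    barcode_length: int = 8,
    min_hamming: int = 3,
    pooled_failures: tuple[str, ...] = DEFAULT_POOLED_FAILURES,
) -> LibraryDesign:
    """The default 144-design library with barcodes assigned and 137 pooled."""
    lib = enumerate_library(default_lipid_panel(), default_ratio_arms(), default_peg_arms())
    lib = assign_barcodes(lib, length=barcode_length, min_hamming=min_hamming, seed=seed)
    failures = set(pooled_failures)
    unknown = failures - {d.design_id for d in lib.designs}
    if unknown:
        raise LibraryError(f"pooled_failures not in library: {sorted(unknown)}")
    designs = tuple(replace(d, pooled=d.design_id not in failures) for d in lib.designs)
    return LibraryDesign(
        designs=designs,
        barcodes=lib.barcodes,
        naked_control_barcode=lib.naked_control_barcode,
        barcode_length=lib.barcode_length,
        min_pairwise_hamming=lib.min_pairwise_hamming,
    )


# -------------------------------- I/O --------------------------------------

def read_lipid_table(path) -> list[HelperLipid]:
    """Read a helper-lipid panel from CSV with columns
    name, charge_class, headgroup_mw, tail_descriptor, headgroup_name."""
    df = pd.read_csv(path)
    required = {"name", "charge_class", "headgroup_mw"}
    missing = required - set(df.columns)
    if missing:
        raise LibraryError(f"lipid table missing columns {sorted(missing)}")
    return [
        HelperLipid(
            name=str(r["name"]),
            charge_class=str(r["charge_class"]),
            headgroup_mw=float(r["headgroup_mw"]),
            tail_descriptor=str(r.get("tail_descriptor", "") or ""),
            headgroup_name=str(r.get("headgroup_name", "") or ""),
        )
        for _, r in df.iterrows()
    ]


def write_library_csv(library: LibraryDesign, path) -> None:
    """One design per row with full chemical annotation and barcode assignment."""
    library.properties(pooled_only=False).to_csv(path)


def read_library_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="design_id")


def write_barcodes_fasta(library: LibraryDesign, path) -> None:
    """Barcode sequences as FASTA, record ID = barcode_id."""
    records = [
        SeqRecord(Seq(seq), id=bid, description="")
        for bid, seq in library.barcodes.items()
    ]
    SeqIO.write(records, path, "fasta")
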