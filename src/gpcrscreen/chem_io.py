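"""Compound and activity record I/O.

Reads compound libraries from SMI/CSV/SDF, validates and canonicalizes
SMILES, and deduplicates chemically identical entries.  All downstream
stages (featurization, model training, docking) consume the canonical
records produced here; a record that leaves this module always carries a
SMILES string that round-trips through the cheminformatics toolkit.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

__all__ = [
    "CompoundRecord",
    "ActivityRecord",
    "SiteMode",
    "SmilesError",
    "EmptyInputError",
    "canonicalize",
    "is_valid_smiles",
    "read_compounds",
    "write_compounds",
    "read_activities",
    "write_activities",
    "deduplicate",
]

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparseable SMILES; we log skips ourselves.
RDLogger.DisableLog("rdApp.error")


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be turned into a molecule."""

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"unparseable SMILES: {smiles!r}")


class EmptyInputError(ValueError):
    """Raised when an input file yields zero parseable records."""


class SiteMode(str, Enum):
    """Binding-site mode of an activity measurement or docking task."""

    ORTHOSTERIC = "orthosteric"
    ALLOSTERIC = "allosteric"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def canonicalize(smiles: str) -> str:
    """Return the toolkit-canonical SMILES for ``smiles``.

    Stereochemistry is retained.  Idempotent: canonical input maps to
    itself, and any two spellings of the same molecule map to the same
    string.

    Raises
    ------
    SmilesError
        If the string does not parse to a molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:  # "" parses to an empty mol
        raise SmilesError(smiles)
    return Chem.MolToSmiles(mol)


def is_valid_smiles(smiles: str) -> bool:
    """True if ``smiles`` parses to a molecule."""
    return Chem.MolFromSmiles(smiles) is not None


@dataclass(frozen=True)
class CompoundRecord:
    """One ligand — small molecule or peptide-derived.

    ``smiles`` is stored in canonical form.  ``source_sequence`` holds the
    original (untruncated) one-letter residue string for peptide-derived
    records and is ``None`` otherwise.  Records containing multiple
    fragments ("." in the SMILES) are kept verbatim and flagged via
    :attr:`is_multifragment`.
    """

    compound_id: str
    smiles: str
    is_peptide_derived: bool = False
    source_sequence: str | None = None

    def __post_init__(self) -> None:
        canon = canonicalize(self.smiles)
        if canon != self.smiles:
            raise ValueError(
                f"record {self.compound_id!r}: smiles is not canonical "
                f"({self.smiles!r} != {canon!r}); use CompoundRecord.create"
            )
        if self.is_peptide_derived != (self.source_sequence is not None):
            raise ValueError(
                f"record {self.compound_id!r}: source_sequence must be set "
                "iff is_peptide_derived"
            )

    @classmethod
    def create(
        cls,
        compound_id: str,
        smiles: str,
        *,
        is_peptide_derived: bool = False,
        source_sequence: str | None = None,
    ) -> "CompoundRecord":
        """Build a record, canonicalizing ``smiles`` first."""
        return cls(
            compound_id=compound_id,
            smiles=canonicalize(smiles),
            is_peptide_derived=is_peptide_derived,
            source_sequence=source_sequence,
        )

    @property
    def is_multifragment(self) -> bool:
        """True for salts/mixtures (multiple disconnected fragments)."""
        return "." in self.smiles


@dataclass(frozen=True)
class ActivityRecord:
    """One (compound, receptor, site) activity measurement.

    ``pchembl`` is the ChEMBL-normalized potency, -log10 of the molar
    half-maximal measure; 0 denotes a negative (inactive) data point.
    """

    compound_id: str
    receptor_id: str
    site_mode: SiteMode
    assay_type: str
    pchembl: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pchembl <= 14.0):
            raise ValueError(
                f"pchembl {self.pchembl} outside the sanity bound [0, 14]"
            )
        if len(self.assay_type) != 1 or not self.assay_type.isupper():
            raise ValueError(
                f"assay_type must be a single uppercase character, got "
                f"{self.assay_type!r}"
            )
        object.__setattr__(self, "site_mode", SiteMode(self.site_mode))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_COMPOUND_COLUMNS = ("compound_id", "smiles")
_ACTIVITY_COLUMNS = (
    "compound_id",
    "smiles",
    "receptor_id",
    "site_mode",
    "assay_type",
    "pchembl",
)


def read_compounds(path: str | Path, format: str | None = None) -> list[CompoundRecord]:
    """Read compound records from an SMI, CSV or SDF file.

    Unparseable entries are skipped and logged with their record number;
    the reader does not deduplicate.  CSV files may carry a ``sequence``
    column with one-letter peptide sequences, which are truncated and
    assembled into SMILES (see :mod:`gpcrscreen.peptide`).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    EmptyInputError
        If no entry parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "smi"
    format = format.lower()
    if format == "smi":
        records = _read_smi(path)
    elif format == "csv":
        records = _read_csv(path)
    elif format == "sdf":
        records = _read_sdf(path)
    else:
        raise ValueError(f"unsupported compound format: {format!r}")
    if not records:
        raise EmptyInputError(f"no parseable compound records in {path}")
    return records


def _read_smi(path: Path) -> list[CompoundRecord]:
    records: list[CompoundRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            try:
                records.append(CompoundRecord.create(cid, smiles))
            except SmilesError:
                logger.warning("%s line %d: skipped unparseable SMILES %r",
                               path, lineno, smiles)
    return records


def _read_csv(path: Path) -> list[CompoundRecord]:
    from . import peptide as _peptide  # local import: peptide imports chem_io

    records: list[CompoundRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rowno, row in enumerate(reader, start=2):
            cid = (row.get("compound_id") or f"row{rowno}").strip()
            seq = (row.get("sequence") or "").strip()
            smiles = (row.get("smiles") or "").strip()
            try:
                if seq:
                    records.append(_peptide.peptide_record(seq, cid))
                elif smiles:
                    records.append(CompoundRecord.create(cid, smiles))
                else:
                    logger.warning("%s row %d: neither smiles nor sequence",
                                   path, rowno)
            except (SmilesError, ValueError) as exc:
                logger.warning("%s row %d: skipped (%s)", path, rowno, exc)
    return records


def _read_sdf(path: Path) -> list[CompoundRecord]:
    records: list[CompoundRecord] = []
    supplier = Chem.SDMolSupplier(str(path))
    for idx, mol in enumerate(supplier):
        if mol is None:
            logger.warning("%s entry %d: skipped unparseable molecule", path, idx)
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"entry{idx}"
        records.append(CompoundRecord.create(cid, Chem.MolToSmiles(mol)))
    return records


def write_compounds(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Write compound records to CSV (canonical SMILES preserved exactly)."""
    rows = [
        {
            "compound_id": r.compound_id,
            "smiles": r.smiles,
            "is_peptide_derived": r.is_peptide_derived,
            "source_sequence": r.source_sequence or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["compound_id", "smiles", "is_peptide_derived",
                                "source_sequence"]).to_csv(path, index=False)


def read_activities(path: str | Path) -> list[ActivityRecord]:
    """Read an activity table (ChEMBL-export-style CSV).

    Expected columns: compound_id, receptor_id, site_mode, assay_type,
    pchembl.  Rows whose fields do not validate are skipped and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = {"compound_id", "receptor_id", "site_mode", "assay_type",
               "pchembl"} - set(df.columns)
    if missing:
        raise ValueError(f"activity CSV missing columns: {sorted(missing)}")
    records: list[ActivityRecord] = []
    for rowno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(ActivityRecord(
                compound_id=str(row.compound_id),
                receptor_id=str(row.receptor_id),
                site_mode=SiteMode(row.site_mode),
                assay_type=str(row.assay_type),
                pchembl=float(row.pchembl),
            ))
        except (ValueError, TypeError) as exc:
            logger.warning("%s row %d: skipped (%s)", path, rowno, exc)
    return records


def write_activities(records: Sequence[ActivityRecord], path: str | Path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "receptor_id": r.receptor_id,
            "site_mode": r.site_mode.value,
            "assay_type": r.assay_type,
            "pchembl": r.pchembl,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_ACTIVITY_COLUMNS[:1] + _ACTIVITY_COLUMNS[2:])
                 ).to_csv(path, index=False)


def deduplicate(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Drop chemical duplicates, keeping the first occurrence.

    The equality key is the canonical SMILES alone — two records with
    different ids but the same molecule are duplicates.  Order preserved;
    idempotent.
    """
    seen: set[str] = set()
    out: list[CompoundRecord] = []
    for rec in records:
        if rec.smiles not in seen:
            seen.add(rec.smiles)
            out.append(rec)
    return out
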