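"""Dataset curation, pChEMBL handling, activity classes, and splits.

Training tables are curated by three rules before any model sees them:
only functional-assay measurements (assay type 'F') are kept, every
compound SMILES must parse, and duplicate (molecule, receptor, site)
triples are collapsed to their first occurrence.  Potencies are expressed
as pChEMBL (-log10 molar), binned into six activity classes with a
dedicated class for negative data points (pChEMBL = 0), and split 80/20
with seeded 10-fold cross-validation partitions over the training side.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, train_test_split

from .chem_io import ActivityRecord, CompoundRecord, SiteMode, is_valid_smiles

__all__ = [
    "ActivityClass",
    "DEFAULT_CLASS_SCHEME",
    "CurationReport",
    "DatasetSplit",
    "curate",
    "pchembl_from_potency",
    "assign_class",
    "split",
    "N_FOLDS",
]

logger = logging.getLogger(__name__)

N_FOLDS = 10

#: Conversion factors to molar for the supported potency units.
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class ActivityClass:
    """One pChEMBL bin: label and (lower, upper] interval.

    Class 0 is the degenerate bin {0} holding negative data points.
    """

    label: int
    lower: float  # exclusive
    upper: float  # inclusive

    def contains(self, pchembl: float) -> bool:
        if self.lower == self.upper:  # degenerate point bin, e.g. {0}
            return pchembl == self.lower
        return self.lower < pchembl <= self.upper


#: Six classes: inactive {0}, then unit-width bins over the
#: pharmacologically standard 5-8 range, open-ended above 8.
DEFAULT_CLASS_SCHEME: tuple[ActivityClass, ...] = (
    ActivityClass(0, 0.0, 0.0),
    ActivityClass(1, 0.0, 5.0),
    ActivityClass(2, 5.0, 6.0),
    ActivityClass(3, 6.0, 7.0),
    ActivityClass(4, 7.0, 8.0),
    ActivityClass(5, 8.0, math.inf),
)


def pchembl_from_potency(value: float, unit: str) -> float:
    """-log10 of a potency expressed in molar, clipped below at 0.

    ``10 nM -> 8.0``, ``1 uM -> 6.0``, ``1 M -> 0.0``.
    """
    if value <= 0:
        raise ValueError(f"potency must be positive, got {value}")
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown unit {unit!r}; supported: {sorted(_UNIT_TO_MOLAR)}")
    return max(0.0, -math.log10(value * _UNIT_TO_MOLAR[unit]))


def assign_class(pchembl: float,
                 scheme: Sequence[ActivityClass] = DEFAULT_CLASS_SCHEME
                 ) -> ActivityClass:
    """Map a pChEMBL value to its unique activity class.

    The scheme must cover [0, inf) without gaps; a value matching no bin
    is a configuration error, not a data error.
    """
    if pchembl < 0:
        raise ValueError(f"pchembl must be >= 0, got {pchembl}")
    for cls in scheme:
        if cls.contains(pchembl):
            return cls
    raise ValueError(
        f"class scheme does not cover pchembl={pchembl}; bins must "
        "partition [0, inf)"
    )


@dataclass
class CurationReport:
    """Counts of records removed per curation rule."""

    n_input: int = 0
    n_kept: int = 0
    removed_assay: int = 0
    removed_smiles: int = 0
    removed_duplicate: int = 0
    conflicts: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def curate(records: Sequence[ActivityRecord],
           compounds: Sequence[CompoundRecord],
           ) -> tuple[list[ActivityRecord], CurationReport]:
    """Apply the three curation rules; report removals per rule.

    Keeps functional-assay records ('F') whose compound SMILES validates,
    then collapses duplicate (canonical SMILES, receptor, site) triples
    first-wins.  A duplicate whose pChEMBL conflicts with the kept record
    is logged in the report.  Idempotent; an empty result is allowed
    (with a warning), not an error.
    """
    by_id = {c.compound_id: c for c in compounds}
    report = CurationReport(n_input=len(records))
    kept: list[ActivityRecord] = []
    seen: dict[tuple[str, str, SiteMode], float] = {}
    for rec in records:
        if rec.assay_type != "F":
            report.removed_assay += 1
            continue
        comp = by_id.get(rec.compound_id)
        if comp is None or not is_valid_smiles(comp.smiles):
            report.removed_smiles += 1
            continue
        key = (comp.smiles, rec.receptor_id, rec.site_mode)
        if key in seen:
            report.removed_duplicate += 1
            if seen[key] != rec.pchembl:
                report.conflicts.append(
                    f"{rec.compound_id}@{rec.receptor_id}/{rec.site_mode.value}: "
                    f"kept pchembl {seen[key]}, dropped {rec.pchembl}"
                )
            continue
        seen[key] = rec.pchembl
        kept.append(rec)
    report.n_kept = len(kept)
    if not kept:
        logger.warning("curation removed every record")
    return kept, report


@dataclass(frozen=True)
class DatasetSplit:
    """A seeded 80/20 split plus 10 CV folds over the training side.

    ``folds`` are disjoint validation-index lists that partition
    ``train_indices``; fold sizes differ by at most one.
    """

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    seed: int
    folds: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        train, test = set(self.train_indices), set(self.test_indices)
        if train & test:
            raise ValueError("train and test overlap")
        flat = [i for fold in self.folds for i in fold]
        if sorted(flat) != sorted(self.train_indices):
            raise ValueError("folds must partition the training indices")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "seed": self.seed,
            "train_indices": list(self.train_indices),
            "test_indices": list(self.test_indices),
            "folds": [list(f) for f in self.folds],
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["train_indices"]), tuple(d["test_indices"]),
                   d["seed"], tuple(tuple(f) for f in d["folds"]))


def split(records: Sequence, seed: int, train_fraction: float = 0.8,
          n_folds: int = N_FOLDS) -> DatasetSplit:
    """Random 80/20 record-level split with 10-fold CV partitions.

    Reproducible for a given seed; the training size is
    ``floor(train_fraction * n)``.
    """
    n = len(records)
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} records to split, got {n}")
    n_train = int(math.floor(train_fraction * n))
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, train_size=n_train, random_state=seed, shuffle=True)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = tuple(tuple(int(train_idx[i]) for i in val)
                  for _, val in kf.split(train_idx))
    return DatasetSplit(
        train_indices=tuple(int(i) for i in train_idx),
        test_indices=tuple(int(i) for i in test_idx),
        seed=seed,
        folds=folds,
    )
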