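"""Synthetic compound libraries with planted structure-activity signal.

Real per-receptor training sets are ChEMBL exports in which activity
tracks shared substructures.  This module emulates that statistical
structure without any download: "carrier" molecules get a receptor-
specific pharmacophore grafted onto a random drug-like scaffold and a
pChEMBL lift over baseline, non-carriers get the scaffold chemistry
only.  Because the signal is planted, every downstream stage — curation,
featurization, model training, importance decoding, consensus — can be
tested against a known ground truth.

The generator makes no attempt to mimic real ChEMBL chemistry
distributions or receptor pharmacology; see the methods note for what
that does and does not validate.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import ActivityRecord, CompoundRecord, SiteMode, canonicalize
from .peptide import STANDARD_RESIDUES, PeptideSequence

__all__ = [
    "PlantedSAR",
    "BenchmarkBundle",
    "generate_library",
    "generate_peptide_library",
    "generate_multireceptor_benchmark",
    "contains_pharmacophore",
    "SCAFFOLDS",
]

logger = logging.getLogger(__name__)

#: Fixed list of 20 small drug-like cores used as decoration targets.
SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc2occc2c1",       # benzofuran
    "c1ccc2sccc2c1",       # benzothiophene
    "c1ccoc1",             # furan
    "c1ccsc1",             # thiophene
    "c1cc[nH]c1",          # pyrrole
    "c1cnc[nH]1",          # imidazole
    "C1CCCCC1",            # cyclohexane
    "C1CCNCC1",            # piperidine
    "C1CCOCC1",            # tetrahydropyran
    "C1CNCCN1",            # piperazine
    "C1COCCN1",            # morpholine
    "c1ccc(-c2ccccc2)cc1", # biphenyl
    "c1cnccn1",            # pyrazine
    "c1ccnnc1",            # pyridazine
    "C1CCC2CCCCC2C1",      # decalin
    "c1cncnc1",            # pyrimidine
)

#: Small substituents used to diversify scaffolds.
_DECORATIONS: tuple[str, ...] = ("C", "CC", "CCC", "C(C)C", "O", "OC", "N",
                                 "F", "Cl", "Br", "C#N", "C(F)(F)F")


@dataclass(frozen=True)
class PlantedSAR:
    """Specification of one receptor's planted activity relationship.

    Carrier molecules contain ``pharmacophore_smiles`` and draw
    ``pchembl = baseline + effect_size + N(0, noise_sd)``; non-carriers
    draw ``baseline + N(0, noise_sd)``.  Values are clipped into the
    valid pChEMBL range.
    """

    receptor_id: str
    site_mode: SiteMode = SiteMode.ORTHOSTERIC
    pharmacophore_smiles: str = "NC(=O)c1ccco1"
    effect_size: float = 3.0
    baseline: float = 5.0
    noise_sd: float = 0.2
    n_actives: int = 100
    n_inactives: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if Chem.MolFromSmiles(self.pharmacophore_smiles) is None:
            raise ValueError(
                f"pharmacophore does not parse: {self.pharmacophore_smiles!r}"
            )
        object.__setattr__(self, "site_mode", SiteMode(self.site_mode))

    @property
    def pharmacophore_query(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.pharmacophore_smiles)


def contains_pharmacophore(smiles: str, pharmacophore_smiles: str) -> bool:
    """Substructure oracle: does the molecule carry the pharmacophore?"""
    mol = Chem.MolFromSmiles(smiles)
    query = Chem.MolFromSmiles(pharmacophore_smiles)
    return bool(mol and query and mol.HasSubstructMatch(query))


def _attachable_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]


def _graft(core: Chem.Mol, group_smiles: str,
           rng: np.random.Generator) -> Chem.Mol | None:
    """Attach a group to a random substitutable core atom by a single bond."""
    group = Chem.MolFromSmiles(group_smiles)
    sites = _attachable_atoms(core)
    g_sites = _attachable_atoms(group)
    if not sites or not g_sites:
        return None
    combo = Chem.RWMol(Chem.CombineMols(core, group))
    si = int(rng.choice(sites))
    gi = core.GetNumAtoms() + g_sites[0]
    combo.AddBond(si, gi, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _random_molecule(rng: np.random.Generator,
                     pharmacophores: Sequence[str] = (),
                     forbidden: Sequence[str] = (),
                     max_attempts: int = 100) -> str | None:
    """Build one decorated scaffold, grafting the given pharmacophores.

    Returns a canonical SMILES guaranteed to contain every SMILES in
    ``pharmacophores`` and none in ``forbidden``, or None if the attempt
    budget is exhausted.
    """
    for _ in range(max_attempts):
        mol = Chem.MolFromSmiles(str(rng.choice(SCAFFOLDS)))
        # decorate first, then graft: pharmacophore interiors stay intact,
        # so carrier molecules share constant pharmacophore environments
        for _ in range(int(rng.integers(0, 4))):
            decorated = _graft(mol, str(rng.choice(_DECORATIONS)), rng)
            if decorated is not None:
                mol = decorated
        ok = True
        for pharm in pharmacophores:
            mol = _graft(mol, pharm, rng)
            if mol is None:
                ok = False
                break
        if not ok:
            continue
        smiles = Chem.MolToSmiles(mol)
        if any(not contains_pharmacophore(smiles, p) for p in pharmacophores):
            continue
        if any(contains_pharmacophore(smiles, p) for p in forbidden):
            continue
        return smiles
    return None


def _build_compounds(rng, n, prefix, pharmacophores, forbidden,
                     seen: set[str]) -> list[CompoundRecord]:
    out: list[CompoundRecord] = []
    attempts = 0
    while len(out) < n and attempts < 200 * n:
        attempts += 1
        smiles = _random_molecule(rng, pharmacophores, forbidden)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        out.append(CompoundRecord.create(f"{prefix}{len(out):04d}", smiles))
    if len(out) < n:
        raise RuntimeError(
            f"could not generate {n} distinct molecules for {prefix!r} "
            f"(got {len(out)})"
        )
    return out


def generate_library(sar: PlantedSAR
                     ) -> tuple[list[CompoundRecord], list[ActivityRecord]]:
    """Generate one receptor's compound library and activity table.

    Deterministic given ``sar.seed``.  Every carrier contains the
    pharmacophore and no non-carrier does (checked by the substructure
    oracle during generation); all records use assay type 'F'.
    """
    rng = np.random.default_rng(sar.seed)
    seen: set[str] = set()
    carriers = _build_compounds(rng, sar.n_actives,
                                f"{sar.receptor_id}-act-",
                                [sar.pharmacophore_smiles], [], seen)
    inactives = _build_compounds(rng, sar.n_inactives,
                                 f"{sar.receptor_id}-inact-",
                                 [], [sar.pharmacophore_smiles], seen)
    compounds = carriers + inactives
    activities = []
    for rec, is_carrier in [(c, True) for c in carriers] + [
            (c, False) for c in inactives]:
        value = sar.baseline + (sar.effect_size if is_carrier else 0.0)
        if sar.noise_sd > 0:
            value += rng.normal(0.0, sar.noise_sd)
        activities.append(ActivityRecord(
            compound_id=rec.compound_id,
            receptor_id=sar.receptor_id,
            site_mode=sar.site_mode,
            assay_type="F",
            pchembl=float(np.clip(value, 0.0, 14.0)),
        ))
    return compounds, activities


def generate_classification_embedding(
        n: int, n_bits: int = 512, n_classes: int = 6,
        background_density: float = 0.05, seed: int = 0
        ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free planted multiclass problem in fingerprint space.

    Each class ``c`` owns one indicator bit; a sample of class ``c`` has
    that bit on, the other indicator bits off, and random background
    bits elsewhere.  The mapping from features to label is exact, so a
    capable classifier should approach perfect cross-validated accuracy;
    used as the oracle for the classifier leg.
    """
    if n_classes > n_bits:
        raise ValueError("need at least one bit per class")
    rng = np.random.default_rng(seed)
    indicator = rng.choice(n_bits, size=n_classes, replace=False)
    y = rng.integers(0, n_classes, size=n)
    X = (rng.random((n, n_bits)) < background_density).astype(np.uint8)
    X[:, indicator] = 0
    X[np.arange(n), indicator[y]] = 1
    return X, y.astype(int)


def generate_peptide_library(n: int, length_range: tuple[int, int] = (4, 30),
                             seed: int = 0) -> list[PeptideSequence]:
    """Uniform random peptides over the 20-letter alphabet.

    Lengths are drawn uniformly from ``length_range`` (inclusive), which
    by default straddles the 6-residue truncation point up to the ~30
    residues typical of peptide GPCR ligands.
    """
    lo, hi = length_range
    if lo < 1:
        raise ValueError("peptide lengths must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = list(STANDARD_RESIDUES)
    out = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append(PeptideSequence(
            "".join(rng.choice(alphabet) for _ in range(length))))
    return out


@dataclass
class BenchmarkBundle:
    """A multi-receptor benchmark: compounds, activities, truth, registry."""

    compounds: list[CompoundRecord]
    activities: list[ActivityRecord]
    truth: pd.DataFrame  # compound_id, true_targets (|-joined), true_class
    receptor_classes: dict[str, str]

    def truth_for(self, compound_id: str) -> tuple[list[str], str]:
        row = self.truth[self.truth.compound_id == compound_id].iloc[0]
        return row.true_targets.split("|"), row.true_class


def generate_multireceptor_benchmark(
        sars: Sequence[PlantedSAR],
        receptor_classes: dict[str, str],
        n_dual: int = 10,
        seed: int = 0) -> BenchmarkBundle:
    """Benchmark with receptor-selective and non-selective compounds.

    Each receptor's activity table holds its own carriers (active), its
    own scaffold-only decoys (baseline activity), and the other
    receptors' selective carriers as negative data points (pChEMBL 0) so
    models can learn to discriminate.  ``n_dual`` compounds carry two
    pharmacophores and are active for both receptors.  The truth table
    records all true targets per compound ("|"-joined) and the GPCR
    class of the first.
    """
    if len(sars) < 2:
        raise ValueError("need >= 2 receptors for a benchmark")
    for sar in sars:
        if sar.receptor_id not in receptor_classes:
            raise ValueError(f"{sar.receptor_id} missing from the class "
                             "registry")
    pharms = [s.pharmacophore_smiles for s in sars]
    for i, a in enumerate(pharms):
        for j, b in enumerate(pharms):
            if i != j and contains_pharmacophore(a, b):
                raise ValueError(
                    f"pharmacophores overlap: {b!r} is a substructure of {a!r}"
                )

    rng = np.random.default_rng(seed)
    compounds: list[CompoundRecord] = []
    activities: list[ActivityRecord] = []
    truth_rows = []
    per_receptor_carriers: dict[str, list[CompoundRecord]] = {}
    seen: set[str] = set()

    for sar in sars:
        others = [p for p in pharms if p != sar.pharmacophore_smiles]
        receptor_tag = zlib.crc32(sar.receptor_id.encode()) % 2 ** 16
        sub_rng = np.random.default_rng((seed, sar.seed, receptor_tag))
        carriers = _build_compounds(sub_rng, sar.n_actives,
                                    f"{sar.receptor_id}-act-",
                                    [sar.pharmacophore_smiles], others, seen)
        decoys = _build_compounds(sub_rng, sar.n_inactives,
                                  f"{sar.receptor_id}-inact-", [], pharms, seen)
        per_receptor_carriers[sar.receptor_id] = carriers
        compounds.extend(carriers + decoys)
        for rec in carriers:
            truth_rows.append({
                "compound_id": rec.compound_id,
                "true_targets": sar.receptor_id,
                "true_class": receptor_classes[sar.receptor_id],
            })
        for rec, is_carrier in [(c, True) for c in carriers] + [
                (c, False) for c in decoys]:
            value = sar.baseline + (sar.effect_size if is_carrier else 0.0)
            if sar.noise_sd > 0:
                value += sub_rng.normal(0.0, sar.noise_sd)
            activities.append(ActivityRecord(
                rec.compound_id, sar.receptor_id, sar.site_mode, "F",
                float(np.clip(value, 0.0, 14.0))))

    # dual-pharmacophore (non-selective) compounds: active for both of the
    # first two receptors
    first, second = sars[0], sars[1]
    duals = _build_compounds(
        rng, n_dual, "dual-",
        [first.pharmacophore_smiles, second.pharmacophore_smiles],
        [p for p in pharms if p not in (first.pharmacophore_smiles,
                                        second.pharmacophore_smiles)],
        seen)
    compounds.extend(duals)
    for rec in duals:
        truth_rows.append({
            "compound_id": rec.compound_id,
            "true_targets": f"{first.receptor_id}|{second.receptor_id}",
            "true_class": receptor_classes[first.receptor_id],
        })
        for sar in (first, second):
            value = sar.baseline + sar.effect_size
            if sar.noise_sd > 0:
                value += rng.normal(0.0, sar.noise_sd)
            activities.append(ActivityRecord(
                rec.compound_id, sar.receptor_id, sar.site_mode, "F",
                float(np.clip(value, 0.0, 14.0))))

    # cross-receptor negatives: selective carriers of other receptors enter
    # each table as negative data points (pChEMBL = 0)
    for sar in sars:
        for other_id, other_carriers in per_receptor_carriers.items():
            if other_id == sar.receptor_id:
                continue
            for rec in other_carriers:
                activities.append(ActivityRecord(
                    rec.compound_id, sar.receptor_id, sar.site_mode, "F",
                    0.0))

    truth = pd.DataFrame(truth_rows,
                         columns=["compound_id", "true_targets", "true_class"])
    return BenchmarkBundle(compounds=compounds, activities=activities,
                           truth=truth,
                           receptor_classes=dict(receptor_classes))
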