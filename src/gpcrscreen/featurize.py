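"""ECFP4 fingerprints and bit-to-fragment decoding.

Extended-connectivity fingerprints with bond diameter 4 (Morgan radius 2)
are the single feature representation shared by the classifier and the
regressor legs.  Each on bit hashes a circular atom environment; the
reverse mapping (bit -> environment substructure, with attachment points
marked) is what makes gain-based feature importance chemically readable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .chem_io import CompoundRecord, SmilesError

__all__ = [
    "FingerprintSpec",
    "Fingerprint",
    "FragmentImportance",
    "BitNotSetError",
    "MorganFingerprinter",
    "ecfp4",
    "fragment_for_bit",
    "featurize_set",
]

logger = logging.getLogger(__name__)


class BitNotSetError(LookupError):
    """Requested a fragment for a bit the molecule does not set."""


@dataclass(frozen=True)
class FingerprintSpec:
    """Parameters of the folded Morgan fingerprint.

    ``radius`` is half the bond diameter (ECFP4 -> radius 2).  ``n_bits``
    is the folded length and must be a power of two; 2048 is the de-facto
    ECFP4 standard.  Chirality is off by default (classic ECFP4).
    """

    radius: int = 2
    n_bits: int = 2048
    use_chirality: bool = False

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.n_bits < 1 or self.n_bits & (self.n_bits - 1):
            raise ValueError(f"n_bits must be a power of two, got {self.n_bits}")

    def generator(self):
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius,
            fpSize=self.n_bits,
            includeChirality=self.use_chirality,
        )


@dataclass(frozen=True)
class Fingerprint:
    """A folded bit vector plus the bit -> atom-environment map."""

    bits: np.ndarray
    on_bits: tuple[int, ...]
    bit_environments: dict[int, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        on = tuple(int(i) for i in np.flatnonzero(self.bits))
        if on != self.on_bits:
            raise ValueError("on_bits inconsistent with bits")
        if set(self.on_bits) != set(self.bit_environments):
            raise ValueError("every on bit needs >= 1 environment entry")


@dataclass(frozen=True)
class FragmentImportance:
    """One row of a gain-importance report: a bit, its gain, its fragment."""

    bit: int
    gain: float
    fragment_smiles: str
    rank: int

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.rank < 1:
            raise ValueError("rank starts at 1")


def _mol_from_record(record: "CompoundRecord | str") -> Chem.Mol:
    smiles = record.smiles if isinstance(record, CompoundRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(smiles)
    return mol


def ecfp4(record: "CompoundRecord | str",
          spec: FingerprintSpec = FingerprintSpec()) -> Fingerprint:
    """Fingerprint one molecule, keeping the bit-environment map.

    Deterministic and a function of the molecule only: any SMILES
    spelling of the same structure yields the same fingerprint.
    """
    mol = _mol_from_record(record)
    gen = spec.generator()
    extra = rdFingerprintGenerator.AdditionalOutput()
    extra.AllocateBitInfoMap()
    bv = gen.GetFingerprint(mol, additionalOutput=extra)
    bits = np.zeros(spec.n_bits, dtype=np.uint8)
    on = sorted(bv.GetOnBits())
    bits[on] = 1
    envs = {
        int(bit): tuple((int(a), int(r)) for a, r in entries)
        for bit, entries in extra.GetBitInfoMap().items()
    }
    collisions = [b for b, e in envs.items() if len({
        _environment_key(mol, a, r, spec.radius) for a, r in e}) > 1]
    if collisions:
        logger.debug("folding collisions on bits %s", collisions)
    return Fingerprint(bits=bits, on_bits=tuple(on), bit_environments=envs)


def _environment_key(mol: Chem.Mol, atom: int, radius: int, max_radius: int) -> str:
    """Canonical key for one circular environment (collision detection)."""
    return f"{radius}:{_environment_smiles(mol, atom, radius)}"


def _environment_smiles(mol: Chem.Mol, atom: int, radius: int) -> str:
    """Substructure SMILES of a circular environment, dummies at the rim.

    The environment is the center atom plus all bonds within ``radius``;
    every bond leaving it is replaced by a bond to a ``*`` attachment
    point, matching how fragment depictions mark the continuation of the
    molecule.
    """
    if radius > 0:
        bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom)
        atom_ids = {atom}
        for b in bond_ids:
            bond = mol.GetBondWithIdx(b)
            atom_ids.add(bond.GetBeginAtomIdx())
            atom_ids.add(bond.GetEndAtomIdx())
        bond_ids = set(bond_ids)
    else:
        atom_ids = {atom}
        bond_ids = set()

    em = Chem.RWMol()
    amap: dict[int, int] = {}
    for aid in sorted(atom_ids):
        src = mol.GetAtomWithIdx(aid)
        a = Chem.Atom(src.GetAtomicNum())
        a.SetFormalCharge(src.GetFormalCharge())
        a.SetIsAromatic(src.GetIsAromatic())
        amap[aid] = em.AddAtom(a)
    for bid in bond_ids:
        bond = mol.GetBondWithIdx(bid)
        em.AddBond(amap[bond.GetBeginAtomIdx()], amap[bond.GetEndAtomIdx()],
                   bond.GetBondType())
    # rim: bonds from environment atoms to the outside become attachments
    for aid in sorted(atom_ids):
        for bond in mol.GetAtomWithIdx(aid).GetBonds():
            other = bond.GetOtherAtomIdx(aid)
            if other not in atom_ids:
                dummy = em.AddAtom(Chem.Atom(0))
                em.AddBond(amap[aid], dummy, bond.GetBondType())
    frag = em.GetMol()
    Chem.SanitizeMol(
        frag,
        Chem.SanitizeFlags.SANITIZE_ALL
        ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
        ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY,
        catchErrors=True,
    )
    return Chem.MolToSmiles(frag)


def fragment_for_bit(record: "CompoundRecord | str", bit: int,
                     spec: FingerprintSpec = FingerprintSpec()) -> str:
    """Return the substructure SMILES behind one on bit of a molecule.

    Attachment points are marked with ``*``.  If folding has hashed
    several distinct environments onto the bit, the first environment is
    returned and the collision is logged.

    Raises
    ------
    BitNotSetError
        If ``bit`` is not set for this molecule.
    """
    fp = ecfp4(record, spec)
    if bit not in fp.bit_environments:
        raise BitNotSetError(
            f"bit {bit} is not set for this molecule (on bits: {fp.on_bits})"
        )
    mol = _mol_from_record(record)
    envs = fp.bit_environments[bit]
    smis = [_environment_smiles(mol, a, r) for a, r in envs]
    if len(set(smis)) > 1:
        logger.info("bit %d carries %d distinct environments (folding "
                    "collision); reporting the first", bit, len(set(smis)))
    return smis[0]


class MorganFingerprinter(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: SMILES/records -> binary ECFP matrix.

    Parameters mirror :class:`FingerprintSpec`.  ``fit`` only validates;
    ``transform`` accepts a sequence of :class:`CompoundRecord` or SMILES
    strings and returns an ``(n, n_bits)`` uint8 array, row order
    preserved.  Invalid input fails fast, naming the offending record.
    """

    def __init__(self, radius: int = 2, n_bits: int = 2048,
                 use_chirality: bool = False):
        self.radius = radius
        self.n_bits = n_bits
        self.use_chirality = use_chirality

    @property
    def spec(self) -> FingerprintSpec:
        return FingerprintSpec(self.radius, self.n_bits, self.use_chirality)

    def fit(self, X, y=None):
        self.spec  # validates parameters
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        spec = self.spec
        gen = spec.generator()
        rows = np.zeros((len(X), spec.n_bits), dtype=np.uint8)
        for i, item in enumerate(X):
            try:
                mol = _mol_from_record(item)
            except SmilesError as exc:
                ident = item.compound_id if isinstance(item, CompoundRecord) else repr(item)
                raise SmilesError(exc.smiles,
                                  f"record {ident} (row {i}): {exc}") from exc
            rows[i, list(gen.GetFingerprint(mol).GetOnBits())] = 1
        return rows

    def get_feature_names_out(self, input_features=None):
        return np.array([f"bit_{i}" for i in range(self.n_bits)])


def featurize_set(records, spec: FingerprintSpec = FingerprintSpec()) -> np.ndarray:
    """Fingerprint a record list into an ``(n, n_bits)`` binary matrix."""
    t = MorganFingerprinter(spec.radius, spec.n_bits, spec.use_chirality)
    return t.fit(records).transform(records)
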