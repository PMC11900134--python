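"""Peptide truncation and SMILES assembly.

Peptide GPCR ligands carry their receptor-activating "message" in a short
terminal fragment, while the rest of the chain (the "address") mostly
drives binding orientation.  Truncating a peptide to its six terminal
residues and assembling the fragment into a SMILES string puts peptides
into the same ECFP feature space as small molecules, so one model can be
trained on both.

Residues are assembled neutral, with L-configuration stereocenters by
default, a free-amine N-terminus, and (by default) a free carboxylic-acid
C-terminus; the C-terminal cap is configurable as acid or amide.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from rdkit import Chem

from .chem_io import CompoundRecord, canonicalize

__all__ = [
    "TerminusRule",
    "CTerminusCap",
    "PeptideSequence",
    "ResidueError",
    "truncate",
    "peptide_to_smiles",
    "peptide_record",
    "read_fasta",
    "DEFAULT_FRAGMENT_LENGTH",
]

#: Number of residues kept by default — the activation "message" fragment.
DEFAULT_FRAGMENT_LENGTH = 6

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Backbone+side-chain SMILES fragments.  Each residue contributes
# N-[C@@H](R)-C(=O) so that plain concatenation performs the amide
# condensation; the chain is terminated with "O" (acid) or "N" (amide).
# Glycine is achiral; proline's side chain closes back onto its backbone
# nitrogen.  Verified residue-by-residue against the toolkit's own
# sequence parser in the test suite.
_RESIDUE_SMILES = {
    "A": "N[C@@H](C)C(=O)",
    "R": "N[C@@H](CCCNC(=N)N)C(=O)",
    "N": "N[C@@H](CC(N)=O)C(=O)",
    "D": "N[C@@H](CC(O)=O)C(=O)",
    "C": "N[C@@H](CS)C(=O)",
    "E": "N[C@@H](CCC(O)=O)C(=O)",
    "Q": "N[C@@H](CCC(N)=O)C(=O)",
    "G": "NCC(=O)",
    "H": "N[C@@H](Cc1c[nH]cn1)C(=O)",
    "I": "N[C@@H]([C@@H](C)CC)C(=O)",
    "L": "N[C@@H](CC(C)C)C(=O)",
    "K": "N[C@@H](CCCCN)C(=O)",
    "M": "N[C@@H](CCSC)C(=O)",
    "F": "N[C@@H](Cc1ccccc1)C(=O)",
    "P": "N1[C@@H](CCC1)C(=O)",
    "S": "N[C@@H](CO)C(=O)",
    "T": "N[C@@H]([C@H](O)C)C(=O)",
    "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)",
    "Y": "N[C@@H](Cc1ccc(O)cc1)C(=O)",
    "V": "N[C@@H](C(C)C)C(=O)",
}

# Achiral variants, used when stereo encoding is switched off.
_RESIDUE_SMILES_FLAT = {
    aa: smi.replace("[C@@H]", "C").replace("[C@H]", "C")
    for aa, smi in _RESIDUE_SMILES.items()
}


class TerminusRule(str, Enum):
    """Which terminus carries the activation fragment."""

    N_TERMINAL = "N_terminal"
    C_TERMINAL = "C_terminal"


class CTerminusCap(str, Enum):
    """Cap chemistry of the (possibly newly created) C-terminus."""

    ACID = "acid"
    AMIDE = "amide"


class ResidueError(ValueError):
    """A residue code outside the 20-letter standard alphabet."""

    def __init__(self, code: str, position: int):
        self.code = code
        self.position = position
        super().__init__(
            f"non-standard residue code {code!r} at position {position}"
        )


@dataclass(frozen=True)
class PeptideSequence:
    """A linear peptide over the 20 standard one-letter codes."""

    residues: str
    terminus_rule: TerminusRule = TerminusRule.N_TERMINAL

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty peptide sequence")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in STANDARD_RESIDUES:
                raise ResidueError(aa, pos)
        object.__setattr__(self, "terminus_rule", TerminusRule(self.terminus_rule))

    def __len__(self) -> int:
        return len(self.residues)


def _as_sequence(seq: "PeptideSequence | str") -> PeptideSequence:
    return seq if isinstance(seq, PeptideSequence) else PeptideSequence(seq)


def truncate(seq: "PeptideSequence | str",
             n: int = DEFAULT_FRAGMENT_LENGTH) -> PeptideSequence:
    """Keep the ``n``-residue activation fragment.

    Under the N-terminal rule (the default, appropriate for opioid,
    chemokine and secretin-family ligands) the first ``n`` residues are
    kept; under the C-terminal rule (apelin/endothelin-like ligands) the
    last ``n``.  Sequences of length <= ``n`` pass through unchanged.
    Idempotent at fixed ``n``.
    """
    seq = _as_sequence(seq)
    if n < 1:
        raise ValueError(f"fragment length must be >= 1, got {n}")
    if len(seq) <= n:
        return seq
    if seq.terminus_rule is TerminusRule.N_TERMINAL:
        kept = seq.residues[:n]
    else:
        kept = seq.residues[-n:]
    return PeptideSequence(kept, seq.terminus_rule)


def peptide_to_smiles(seq: "PeptideSequence | str",
                      cterm: CTerminusCap | str = CTerminusCap.ACID,
                      stereo: bool = True) -> str:
    """Assemble a linear peptide into canonical SMILES.

    The chain is built by amide condensation of residue building blocks:
    free amine N-terminus, acid (default) or amide C-terminus.  The
    molecular formula therefore equals the sum of the residue formulas
    minus one water per peptide bond.
    """
    seq = _as_sequence(seq)
    table = _RESIDUE_SMILES if stereo else _RESIDUE_SMILES_FLAT
    cap = "O" if CTerminusCap(cterm) is CTerminusCap.ACID else "N"
    smiles = "".join(table[aa] for aa in seq.residues) + cap
    return canonicalize(smiles)


def peptide_record(seq: "PeptideSequence | str", compound_id: str,
                   n: int = DEFAULT_FRAGMENT_LENGTH,
                   cterm: CTerminusCap | str = CTerminusCap.ACID,
                   stereo: bool = True) -> CompoundRecord:
    """Truncate, assemble, and wrap a peptide as a compound record.

    The record's ``source_sequence`` keeps the original untruncated
    sequence so provenance survives the truncation.
    """
    seq = _as_sequence(seq)
    fragment = truncate(seq, n)
    smiles = peptide_to_smiles(fragment, cterm=cterm, stereo=stereo)
    return CompoundRecord(
        compound_id=compound_id,
        smiles=smiles,
        is_peptide_derived=True,
        source_sequence=seq.residues,
    )


def read_fasta(path: str | Path,
               terminus_rule: TerminusRule = TerminusRule.N_TERMINAL
               ) -> list[PeptideSequence]:
    """Read peptide sequences from a FASTA file."""
    from Bio import SeqIO

    out: list[PeptideSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(PeptideSequence(str(rec.seq).upper(), terminus_rule))
    return out
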