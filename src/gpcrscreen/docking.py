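"""Ligand-centered docking boxes, ligand preparation, and score parsing.

The third decision leg positions a compound in every orthosteric and
allosteric binding site of every receptor and keeps the best predicted
binding affinity per site.  The search volume is a 30 Å cube centered on
the centroid of the site's reference-ligand coordinates.  The docking
engine itself is pluggable: the ``vina`` backend shells out to an
external AutoDock Vina binary and parses its score table, while the
deterministic ``stub`` backend maps a hash of (molecule, receptor, site)
into a plausible score range so the full pipeline runs and tests without
any external binary.
"""

from __future__ import annotations

import hashlib
import logging
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

from .chem_io import CompoundRecord, SiteMode, SmilesError

__all__ = [
    "BindingSite",
    "DockingBox",
    "DockingResult",
    "DockingFailure",
    "BackendUnavailableError",
    "LigandPreparationError",
    "DEFAULT_BOX_EDGE",
    "make_box",
    "prepare_ligand",
    "dock",
    "dock_all",
    "parse_vina_log",
    "stub_score",
]

logger = logging.getLogger(__name__)

#: Cubic search-box edge, in Å.
DEFAULT_BOX_EDGE = 30.0

#: Stub scores span typical small-molecule binding affinities (kcal/mol).
_STUB_RANGE = (-12.0, -2.0)


class BackendUnavailableError(RuntimeError):
    """The requested docking engine is not installed."""


class LigandPreparationError(RuntimeError):
    """3D embedding or charge assignment failed for one compound."""


@dataclass(frozen=True)
class BindingSite:
    """One docking task target: a receptor structure plus a site location."""

    receptor_id: str
    site_mode: SiteMode
    receptor_file: Path | None
    reference_ligand_coords: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_mode", SiteMode(self.site_mode))
        coords = tuple(tuple(float(x) for x in p)
                       for p in self.reference_ligand_coords)
        if not coords:
            raise ValueError("binding site needs >= 1 reference coordinate")
        if not all(np.isfinite(x) for p in coords for x in p):
            raise ValueError("reference coordinates must be finite")
        object.__setattr__(self, "reference_ligand_coords", coords)


@dataclass(frozen=True)
class DockingBox:
    """A cubic search volume centered on the reference ligand."""

    center: tuple[float, float, float]
    edge: float = DEFAULT_BOX_EDGE

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("box edge must be positive")


@dataclass(frozen=True)
class DockingResult:
    """Scores for one (compound, site) docking task; lower is better."""

    receptor_id: str
    site_mode: SiteMode
    best_score: float
    poses: tuple[tuple[float, str], ...]
    backend: str

    def __post_init__(self) -> None:
        scores = [s for s, _ in self.poses]
        if scores != sorted(scores):
            raise ValueError("poses must be sorted by score ascending")
        if scores and self.best_score != scores[0]:
            raise ValueError("best_score must equal the top pose score")


@dataclass(frozen=True)
class DockingFailure:
    """A per-site failure record from a batch docking run."""

    receptor_id: str
    site_mode: SiteMode
    error: str


def make_box(site: BindingSite, edge: float = DEFAULT_BOX_EDGE) -> DockingBox:
    """Center a cubic box on the centroid of the reference-ligand atoms."""
    coords = np.asarray(site.reference_ligand_coords, dtype=float)
    center = coords.mean(axis=0)
    return DockingBox(center=tuple(float(x) for x in center), edge=edge)


# ---------------------------------------------------------------------------
# ligand preparation
# ---------------------------------------------------------------------------

# Minimal element -> AutoDock atom-type mapping (aromatic carbon handled
# separately; polar H is HD).
_AD_TYPES = {"C": "C", "N": "N", "O": "OA", "S": "SA", "H": "HD", "F": "F",
             "Cl": "Cl", "Br": "Br", "I": "I", "P": "P"}


def prepare_ligand(record: CompoundRecord, out_path: str | Path,
                   seed: int = 42) -> Path:
    """Write a flexible-ligand PDBQT file for one compound.

    Embeds a 3D conformer (seeded distance-geometry), adds hydrogens,
    assigns Gasteiger partial charges, and annotates the rotatable-bond
    count in the torsion header.  Failures raise per compound rather than
    aborting a batch — 3D embedding is the step most real compounds fail.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise SmilesError(record.smiles)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise LigandPreparationError(
            f"3D embedding failed for {record.compound_id} ({record.smiles})"
        )
    AllChem.MMFFOptimizeMolecule(mol)
    AllChem.ComputeGasteigerCharges(mol)
    n_rot = rdMolDescriptors.CalcNumRotatableBonds(mol)

    conf = mol.GetConformer()
    lines = [f"REMARK  Name = {record.compound_id}",
             f"REMARK  {n_rot} active torsions:",
             "ROOT"]
    for i, atom in enumerate(mol.GetAtoms(), start=1):
        pos = conf.GetAtomPosition(atom.GetIdx())
        q = float(atom.GetProp("_GasteigerCharge"))
        if not np.isfinite(q):
            q = 0.0
        sym = atom.GetSymbol()
        ad = "A" if sym == "C" and atom.GetIsAromatic() else _AD_TYPES.get(sym, sym)
        lines.append(
            f"ATOM  {i:>5} {sym:<4} LIG A   1    "
            f"{pos.x:8.3f}{pos.y:8.3f}{pos.z:8.3f}  1.00  0.00    "
            f"{q:6.3f} {ad}"
        )
    lines += ["ENDROOT", f"TORSDOF {n_rot}", ""]
    out_path = Path(out_path)
    out_path.write_text("\n".join(lines))
    return out_path


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------

def stub_score(smiles: str, receptor_id: str, site_mode: SiteMode) -> float:
    """Deterministic pseudo-score from a hash of the docking task.

    Uniform-ish over the typical affinity range; stable across runs and
    platforms.  Used as the test-time docking backend.
    """
    key = f"{smiles}|{receptor_id}|{SiteMode(site_mode).value}".encode()
    digest = hashlib.sha256(key).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64
    lo, hi = _STUB_RANGE
    return round(lo + u * (hi - lo), 3)


_VINA_MODE_RE = re.compile(r"^\s*(\d+)\s+(-?\d+\.\d+)\s+[\d.]+\s+[\d.]+\s*$")


def parse_vina_log(text: str) -> list[float]:
    """Extract the per-mode affinity column from engine stdout."""
    scores = []
    for line in text.splitlines():
        m = _VINA_MODE_RE.match(line)
        if m:
            scores.append(float(m.group(2)))
    return scores


def _run_vina(record: CompoundRecord, site: BindingSite, box: DockingBox,
              workdir: Path, exhaustiveness: int, seed: int,
              vina_binary: str) -> DockingResult:
    if shutil.which(vina_binary) is None:
        raise BackendUnavailableError(
            f"docking engine {vina_binary!r} not found on PATH; use "
            "backend='stub' for engine-free runs"
        )
    if site.receptor_file is None or not Path(site.receptor_file).exists():
        raise FileNotFoundError(f"receptor file missing for {site.receptor_id}")
    workdir.mkdir(parents=True, exist_ok=True)
    ligand = prepare_ligand(record, workdir / f"{record.compound_id}.pdbqt",
                            seed=seed)
    out = workdir / f"{record.compound_id}_{site.receptor_id}_{site.site_mode.value}_out.pdbqt"
    cmd = [vina_binary,
           "--receptor", str(site.receptor_file),
           "--ligand", str(ligand),
           "--center_x", str(box.center[0]),
           "--center_y", str(box.center[1]),
           "--center_z", str(box.center[2]),
           "--size_x", str(box.edge), "--size_y", str(box.edge),
           "--size_z", str(box.edge),
           "--exhaustiveness", str(exhaustiveness),
           "--seed", str(seed),
           "--out", str(out)]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"docking engine failed (exit {proc.returncode}):\n{proc.stderr}"
        )
    scores = sorted(parse_vina_log(proc.stdout))
    if not scores:
        raise RuntimeError("no docking modes parsed from engine output")
    poses = tuple((s, str(out)) for s in scores)
    return DockingResult(site.receptor_id, site.site_mode, scores[0], poses,
                         backend="vina")


def dock(record: CompoundRecord, site: BindingSite,
         box: DockingBox | None = None, backend: str = "stub",
         workdir: str | Path = "docking_runs", exhaustiveness: int = 8,
         seed: int = 42, vina_binary: str = "vina") -> DockingResult:
    """Dock one compound into one site.

    ``backend='vina'`` invokes the external engine on prepared PDBQT
    files; ``backend='stub'`` (default) returns the deterministic hash
    score with a single synthetic pose and no file I/O.
    """
    if box is None:
        box = make_box(site)
    if backend == "stub":
        score = stub_score(record.smiles, site.receptor_id, site.site_mode)
        return DockingResult(site.receptor_id, site.site_mode, score,
                             poses=((score, "<stub>"),), backend="stub")
    if backend == "vina":
        return _run_vina(record, site, box, Path(workdir), exhaustiveness,
                         seed, vina_binary)
    raise ValueError(f"unknown backend {backend!r}")


def dock_all(record: CompoundRecord, sites: Sequence[BindingSite],
             backend: str = "stub", **kwargs
             ) -> tuple[list[DockingResult], list[DockingFailure]]:
    """Dock one compound into every site; per-site failures are recorded.

    Raises only if every site fails.
    """
    if not sites:
        raise ValueError("need >= 1 binding site")
    results: list[DockingResult] = []
    failures: list[DockingFailure] = []
    for site in sites:
        try:
            results.append(dock(record, site, backend=backend, **kwargs))
        except Exception as exc:  # per-site isolation is the contract
            logger.warning("docking failed for %s/%s: %s", site.receptor_id,
                           site.site_mode.value, exc)
            failures.append(DockingFailure(site.receptor_id, site.site_mode,
                                           str(exc)))
    if not results:
        raise RuntimeError(
            f"docking failed for all {len(sites)} sites; first error: "
            f"{failures[0].error}"
        )
    return results, failures
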