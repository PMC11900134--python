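"""Three-leg compound profiles, k-of-3 consensus, and precision evaluation.

A query compound is profiled against every trained (receptor, site)
model pair and every docking site.  Each of the three legs — six-class
classifier, pChEMBL regressor, docking — then nominates one receptor:
the classifier the receptor with the highest predicted activity class,
the regressor the receptor with the highest predicted pChEMBL, docking
the receptor with the best (lowest) score.  Consensus requires k of the
three legs to agree; evaluation reports precision = TP/(TP+FP) per leg
and per consensus rule, stratified by target vs target class (GPCR class
A or B) and by binding-site mode.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_io import CompoundRecord, SiteMode
from .docking import DockingResult
from .models import TrainedModelBundle, predict_profile_leg

__all__ = [
    "DEFAULT_RECEPTOR_CLASSES",
    "ProfileEntry",
    "CompoundProfile",
    "ConsensusDecision",
    "EvaluationReport",
    "LEGS",
    "RULES",
    "build_profile",
    "assign_targets",
    "evaluate",
    "compare_to_known",
    "load_receptor_registry",
]

logger = logging.getLogger(__name__)

LEGS = ("classifier", "regressor", "docking")
RULES = ("all3", "atleast2", "atleast1")

#: GPCR class registry for the receptors the system ships with:
#: chemokine receptors are class A; the secretin receptor family
#: (glucagon-like, corticotropin-releasing factor, etc.) is class B.
DEFAULT_RECEPTOR_CLASSES: dict[str, str] = {
    "CCR1": "A", "CCR2": "A", "CCR3": "A", "CCR4": "A", "CCR5": "A",
    "CCR6": "A", "CCR7": "A", "CCR8": "A", "CCR9": "A", "CCR10": "A",
    "CXCR1": "A", "CXCR2": "A", "CXCR3": "A", "CXCR4": "A", "CXCR5": "A",
    "CXCR6": "A", "ACKR3": "A",
    "CRF1R": "B", "CRF2R": "B", "GCGR": "B", "GLP1R": "B", "GLP2R": "B",
    "GIPR": "B", "VPAC1": "B", "VPAC2": "B", "PAC1R": "B", "GHRHR": "B",
    "SCTR": "B", "PTH1R": "B", "CALCR": "B", "AM1": "B", "AM2": "B",
    "AMY1": "B", "AMY2": "B", "AMY3": "B", "CTR": "B",
}


def load_receptor_registry(path: str | Path | None = None) -> dict[str, str]:
    """Receptor -> GPCR class (A/B) table; shipped default or JSON file."""
    if path is None:
        return dict(DEFAULT_RECEPTOR_CLASSES)
    return json.loads(Path(path).read_text())


@dataclass(frozen=True)
class ProfileEntry:
    """Predictions of all available legs for one (receptor, site)."""

    receptor_id: str
    site_mode: SiteMode
    class_probs: tuple[float, ...]
    predicted_class: int
    predicted_pchembl: float
    docking_score: float | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-6:
            raise ValueError("class probabilities must sum to 1")


@dataclass(frozen=True)
class CompoundProfile:
    """Per-receptor-site predictions for one query compound."""

    compound_id: str
    entries: tuple[ProfileEntry, ...]

    def __post_init__(self) -> None:
        keys = [(e.receptor_id, e.site_mode) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (receptor, site) entries in profile")


@dataclass(frozen=True)
class ConsensusDecision:
    """Per-leg nominated receptors and the k-of-3 consensus."""

    compound_id: str
    leg_targets: dict  # leg -> receptor_id or None (no call)
    leg_target_classes: dict  # leg -> "A"/"B" or None
    consensus_target: str | None
    agreement_k: int


def build_profile(record: CompoundRecord,
                  bundles: Sequence[TrainedModelBundle],
                  docking_results: Sequence[DockingResult] = (),
                  ) -> CompoundProfile:
    """Run both ML legs for every bundle and join docking scores.

    One entry per (receptor, site) present in ``bundles``; docking scores
    are attached where a matching result exists and left absent
    otherwise.  Duplicate bundles for the same (receptor, site) are a
    configuration error.
    """
    if not bundles:
        raise ValueError("need >= 1 trained bundle to build a profile")
    keys = [(b.receptor_id, b.site_mode) for b in bundles]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate bundle for the same (receptor, site)")
    dock_by_key = {(d.receptor_id, d.site_mode): d.best_score
                   for d in docking_results}
    entries = []
    for bundle in bundles:
        probs, pchembl = predict_profile_leg(bundle, record)
        entries.append(ProfileEntry(
            receptor_id=bundle.receptor_id,
            site_mode=bundle.site_mode,
            class_probs=tuple(float(p) for p in probs),
            predicted_class=int(np.argmax(probs)),
            predicted_pchembl=pchembl,
            docking_score=dock_by_key.get((bundle.receptor_id,
                                           bundle.site_mode)),
        ))
    return CompoundProfile(record.compound_id, tuple(entries))


def _best_entry_per_receptor(entries: Sequence[ProfileEntry],
                             key) -> dict[str, ProfileEntry]:
    """Collapse orthosteric/allosteric entries: most active one wins."""
    best: dict[str, ProfileEntry] = {}
    for e in entries:
        cur = best.get(e.receptor_id)
        if cur is None or key(e) > key(cur):
            best[e.receptor_id] = e
    return best


def assign_targets(profile: CompoundProfile,
                   receptor_classes: Mapping[str, str] | None = None
                   ) -> ConsensusDecision:
    """Nominate one receptor per leg and compute the k-of-3 consensus.

    Classifier leg: the receptor with the highest predicted class, ties
    broken by the probability mass above the inactive class, then
    lexicographically.  Regressor leg: the highest predicted pChEMBL.
    Docking leg: the lowest (best) score, or "no call" if no entry has a
    score.  A receptor's orthosteric and allosteric entries are collapsed
    to whichever looks more active for that leg.  ``agreement_k`` is the
    size of the largest group of legs naming the same receptor.
    """
    if not profile.entries:
        raise ValueError("profile has no entries")
    registry = dict(DEFAULT_RECEPTOR_CLASSES)
    if receptor_classes:
        registry.update(receptor_classes)

    def cls_key(e: ProfileEntry):
        return (e.predicted_class, sum(e.class_probs[1:]))

    by_cls = _best_entry_per_receptor(profile.entries, cls_key)
    classifier_target = min(
        by_cls, key=lambda r: (-by_cls[r].predicted_class,
                               -sum(by_cls[r].class_probs[1:]), r))

    by_reg = _best_entry_per_receptor(profile.entries,
                                      lambda e: e.predicted_pchembl)
    regressor_target = min(
        by_reg, key=lambda r: (-by_reg[r].predicted_pchembl, r))

    scored = [e for e in profile.entries if e.docking_score is not None]
    if scored:
        by_dock = _best_entry_per_receptor(scored,
                                           lambda e: -e.docking_score)
        docking_target = min(
            by_dock, key=lambda r: (by_dock[r].docking_score, r))
    else:
        docking_target = None

    leg_targets = {"classifier": classifier_target,
                   "regressor": regressor_target,
                   "docking": docking_target}
    leg_classes = {leg: registry.get(t) if t is not None else None
                   for leg, t in leg_targets.items()}

    votes = [t for t in leg_targets.values() if t is not None]
    counts: dict[str, int] = {}
    for t in votes:
        counts[t] = counts.get(t, 0) + 1
    agreement_k = max(counts.values()) if counts else 0
    leaders = sorted(t for t, c in counts.items() if c == agreement_k)
    consensus = leaders[0] if agreement_k >= 2 else None
    return ConsensusDecision(
        compound_id=profile.compound_id,
        leg_targets=leg_targets,
        leg_target_classes=leg_classes,
        consensus_target=consensus,
        agreement_k=agreement_k,
    )


@dataclass
class EvaluationReport:
    """Precision per (rule-or-leg, target vs class, site-mode stratum).

    ``table`` maps (rule, level, stratum) -> {"tp", "fp", "precision"};
    precision is NaN (flagged) when no prediction fell in the stratum.
    """

    table: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "level": level, "stratum": stratum, **counts}
            for (rule, level, stratum), counts in self.table.items()
        ]
        return pd.DataFrame(rows)

    def precision(self, rule: str, level: str = "target",
                  stratum: str = "all") -> float:
        return self.table[(rule, level, stratum)]["precision"]

    def tp(self, rule: str, level: str = "target",
           stratum: str = "all") -> int:
        return self.table[(rule, level, stratum)]["tp"]


def _leg_correct(decision: ConsensusDecision, leg: str, truth: str,
                 level: str, registry: Mapping[str, str]) -> bool:
    named = decision.leg_targets.get(leg)
    if named is None:
        return False
    if level == "target":
        return named == truth
    return registry.get(named) == registry.get(truth)


def evaluate(decisions: Sequence[tuple[ConsensusDecision, str, str]],
             receptor_classes: Mapping[str, str] | None = None,
             strata: Mapping[str, str] | None = None) -> EvaluationReport:
    """Score decisions against the truth table.

    ``decisions`` holds (decision, true_target, true_class) triples; the
    true class must match the registry's class for the true target.  For
    each rule — ``all3`` (every leg correct), ``atleast2``, ``atleast1``
    — and each individual leg, a compound counts as TP when the rule is
    met at the given level (exact target, or GPCR class A/B) and FP
    otherwise; precision = TP/(TP+FP).  ``strata`` optionally maps
    compound_id -> stratum label (e.g. the site mode of its true ligand
    set) to split the report; an "all" stratum is always present.
    """
    if not decisions:
        raise ValueError("empty decision list")
    registry = dict(DEFAULT_RECEPTOR_CLASSES)
    if receptor_classes:
        registry.update(receptor_classes)
    for _, truth, true_class in decisions:
        if truth not in registry:
            raise ValueError(f"unknown true_target {truth!r}: not in the "
                             "receptor registry")
        if registry[truth] != true_class:
            raise ValueError(
                f"true_class {true_class!r} contradicts registry class "
                f"{registry[truth]!r} for {truth}"
            )

    rules = RULES + LEGS
    table: dict = {}
    for rule in rules:
        for level in ("target", "class"):
            buckets: dict[str, list[bool]] = {"all": []}
            for decision, truth, _ in decisions:
                n_correct = sum(
                    _leg_correct(decision, leg, truth, level, registry)
                    for leg in LEGS)
                if rule == "all3":
                    hit = n_correct == 3
                elif rule == "atleast2":
                    hit = n_correct >= 2
                elif rule == "atleast1":
                    hit = n_correct >= 1
                else:  # individual leg
                    hit = _leg_correct(decision, rule, truth, level, registry)
                buckets["all"].append(hit)
                if strata and decision.compound_id in strata:
                    buckets.setdefault(strata[decision.compound_id],
                                       []).append(hit)
            for stratum, hits in buckets.items():
                tp = int(sum(hits))
                fp = len(hits) - tp
                precision = tp / (tp + fp) if (tp + fp) else math.nan
                table[(rule, level, stratum)] = {
                    "tp": tp, "fp": fp, "precision": precision,
                    "defined": (tp + fp) > 0,
                }
    return EvaluationReport(table=table)


def compare_to_known(profile: CompoundProfile,
                     reference_profiles: Sequence[CompoundProfile]
                     ) -> pd.DataFrame:
    """Rank a query against known-active reference compounds per receptor.

    For every (receptor, site) in the query profile, the query's
    predicted pChEMBL is placed within the reference distribution as a
    percentile (fraction of references at or below the query, in %) and
    a z-score.  Receptors with no reference predictions are omitted with
    a warning.
    """
    rows = []
    for entry in profile.entries:
        ref_vals = [
            e.predicted_pchembl
            for ref in reference_profiles
            for e in ref.entries
            if (e.receptor_id, e.site_mode) == (entry.receptor_id,
                                                entry.site_mode)
        ]
        if not ref_vals:
            logger.warning("no reference predictions for %s/%s; omitted",
                           entry.receptor_id, entry.site_mode.value)
            continue
        ref = np.asarray(ref_vals)
        pct = 100.0 * np.mean(ref <= entry.predicted_pchembl)
        sd = ref.std()
        z = ((entry.predicted_pchembl - ref.mean()) / sd) if sd > 0 else math.nan
        rows.append({
            "receptor_id": entry.receptor_id,
            "site_mode": entry.site_mode.value,
            "predicted_pchembl": entry.predicted_pchembl,
            "predicted_class": entry.predicted_class,
            "n_references": len(ref_vals),
            "percentile": float(pct),
            "z_score": float(z),
        })
    return pd.DataFrame(rows, columns=["receptor_id", "site_mode",
                                       "predicted_pchembl", "predicted_class",
                                       "n_references", "percentile",
                                       "z_score"])
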