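"""End-to-end orchestration: curate -> featurize -> train -> profile -> evaluate.

Thin layer over the library modules.  Every run writes its configuration
and seeds next to its outputs so any result directory is reproducible
from its own contents.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_io import (ActivityRecord, CompoundRecord, SiteMode, SmilesError,
                      deduplicate)
from .curation import (DEFAULT_CLASS_SCHEME, assign_class, curate, split)
from .decision import (CompoundProfile, ConsensusDecision, assign_targets,
                       build_profile, compare_to_known, evaluate,
                       load_receptor_registry)
from .docking import BindingSite, dock_all
from .featurize import FingerprintSpec, featurize_set
from .models import (ActivityClassifier, ClassifierSearchSpace,
                     DegenerateLabelsError, PChEMBLRegressor,
                     RegressorSearchSpace, TrainedModelBundle)

__all__ = ["RunConfig", "run_train", "run_predict", "run_synthetic_benchmark",
           "MIN_RECORDS_PER_MODEL"]

logger = logging.getLogger(__name__)

#: Below this many curated records a (receptor, site) pair is skipped:
#: 10-fold cross-validation is undefined and the fit would be anecdotal.
MIN_RECORDS_PER_MODEL = 10


@dataclass
class RunConfig:
    """All knobs of a pipeline run, serialized alongside every output."""

    radius: int = 2
    n_bits: int = 2048
    use_chirality: bool = False
    n_trials_classifier: int = 25
    n_trials_regressor: int = 25
    classifier_layers: tuple[int, int] = (5, 20)
    classifier_units: tuple[int, int] = (16, 2048)
    regressor_estimators: tuple[int, int] = (50, 50_000)
    seed: int = 0
    docking_backend: str = "stub"
    receptor_registry: str | None = None
    output_dir: str = "runs"

    @property
    def fingerprint_spec(self) -> FingerprintSpec:
        return FingerprintSpec(self.radius, self.n_bits, self.use_chirality)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("classifier_layers", "classifier_units",
                    "regressor_estimators"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _group_records(activities: Sequence[ActivityRecord]):
    groups: dict[tuple[str, SiteMode], list[ActivityRecord]] = {}
    for rec in activities:
        groups.setdefault((rec.receptor_id, rec.site_mode), []).append(rec)
    return groups


def run_train(config: RunConfig,
              activities: Sequence[ActivityRecord],
              compounds: Sequence[CompoundRecord],
              out_dir: str | Path | None = None) -> Path:
    """Curate, split 80/20, and train one model pair per (receptor, site).

    Writes one bundle directory per trained pair, a held-out metrics CSV,
    the curation report, and the exact configuration used.  Receptors
    with fewer than ten curated records, or with degenerate labels, are
    skipped with a warning.
    """
    out_dir = Path(out_dir or config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.save(out_dir / "config.json")

    compounds = deduplicate(compounds)
    curated, report = curate(activities, compounds)
    report.to_json(out_dir / "curation_report.json")
    logger.info("curation: %d/%d records kept", report.n_kept, report.n_input)

    by_id = {c.compound_id: c for c in compounds}
    spec = config.fingerprint_spec
    metrics_rows = []
    for (receptor_id, site_mode), group in _group_records(curated).items():
        if len(group) < MIN_RECORDS_PER_MODEL:
            logger.warning("skipping %s/%s: only %d curated records",
                           receptor_id, site_mode.value, len(group))
            continue
        records = [by_id[r.compound_id] for r in group]
        y_reg = np.array([r.pchembl for r in group])
        y_cls = np.array([assign_class(v).label for v in y_reg])
        X = featurize_set(records, spec)
        ds = split(group, seed=config.seed)
        tr = list(ds.train_indices)
        te = list(ds.test_indices)
        try:
            clf = ActivityClassifier(
                n_hidden_layers=config.classifier_layers,
                units_per_layer=config.classifier_units,
                n_trials=config.n_trials_classifier,
                random_state=config.seed,
            ).fit(X[tr], y_cls[tr])
        except DegenerateLabelsError as exc:
            logger.warning("skipping %s/%s: %s", receptor_id,
                           site_mode.value, exc)
            continue
        reg = PChEMBLRegressor(
            n_estimators=config.regressor_estimators,
            n_trials=config.n_trials_regressor,
            random_state=config.seed,
        ).fit(X[tr], y_reg[tr])

        test_acc = float(np.mean(clf.predict(X[te]) == y_cls[te]))
        test_rmse = float(np.sqrt(np.mean((reg.predict(X[te]) - y_reg[te]) ** 2)))
        bundle = TrainedModelBundle(
            receptor_id=receptor_id,
            site_mode=site_mode,
            classifier=clf,
            regressor=reg,
            cv_metrics={"classifier_accuracy": clf.cv_scores_,
                        "regressor_rmse": reg.cv_scores_},
            best_hyperparameters={"classifier": clf.best_params_,
                                  "regressor": reg.best_params_},
            spec=spec,
            class_scheme=DEFAULT_CLASS_SCHEME,
            seed=config.seed,
        )
        bundle.save(out_dir / f"{receptor_id}__{site_mode.value}")
        metrics_rows.append({
            "receptor_id": receptor_id,
            "site_mode": site_mode.value,
            "n_train": len(tr), "n_test": len(te),
            "cv_accuracy_mean": float(np.mean(clf.cv_scores_)),
            "cv_rmse_mean": float(np.mean(reg.cv_scores_)),
            "test_accuracy": test_acc,
            "test_rmse": test_rmse,
        })
    pd.DataFrame(metrics_rows).to_csv(out_dir / "metrics.csv", index=False)
    return out_dir


def load_bundles(bundle_dir: str | Path) -> list[TrainedModelBundle]:
    """Load every bundle directory under ``bundle_dir``."""
    bundle_dir = Path(bundle_dir)
    bundles = []
    for sub in sorted(bundle_dir.iterdir()):
        if (sub / "metadata.json").exists():
            bundles.append(TrainedModelBundle.load(sub))
    if not bundles:
        raise FileNotFoundError(f"no model bundles under {bundle_dir}")
    return bundles


def _stub_sites(bundles: Sequence[TrainedModelBundle]) -> list[BindingSite]:
    """Placeholder sites so the stub docking leg covers every bundle."""
    return [BindingSite(b.receptor_id, b.site_mode, None, ((0.0, 0.0, 0.0),))
            for b in bundles]


def run_predict(config: RunConfig,
                bundle_dir: str | Path,
                queries: Sequence[CompoundRecord],
                sites: Sequence[BindingSite] | None = None,
                references: Sequence[CompoundRecord] = (),
                out_dir: str | Path | None = None,
                ) -> tuple[list[CompoundProfile], list[ConsensusDecision]]:
    """Profile query compounds against every trained bundle.

    Each query gets a three-leg profile (classifier, regressor, and the
    configured docking backend), a consensus decision, and — when
    reference compounds are supplied — a ranking against the reference
    predictions per receptor.  Per-compound failures are recorded and do
    not abort the run.
    """
    bundles = load_bundles(bundle_dir)
    spec = config.fingerprint_spec
    for b in bundles:
        if b.spec != spec:
            raise ValueError(
                f"fingerprint spec mismatch: config {spec} vs bundle "
                f"{b.receptor_id}/{b.site_mode.value} {b.spec}"
            )
    if sites is None:
        sites = _stub_sites(bundles)
    registry = load_receptor_registry(config.receptor_registry)

    reference_profiles = []
    for ref in references:
        results, _ = dock_all(ref, sites, backend=config.docking_backend,
                              seed=config.seed)
        reference_profiles.append(build_profile(ref, bundles, results))

    profiles: list[CompoundProfile] = []
    decisions: list[ConsensusDecision] = []
    errors: list[dict] = []
    comparisons: dict[str, pd.DataFrame] = {}
    for query in queries:
        try:
            results, failures = dock_all(query, sites,
                                         backend=config.docking_backend,
                                         seed=config.seed)
            profile = build_profile(query, bundles, results)
            decision = assign_targets(profile, registry)
        except (SmilesError, ValueError, RuntimeError) as exc:
            logger.warning("query %s failed: %s", query.compound_id, exc)
            errors.append({"compound_id": query.compound_id,
                           "error": str(exc)})
            continue
        profiles.append(profile)
        decisions.append(decision)
        if reference_profiles:
            comparisons[query.compound_id] = compare_to_known(
                profile, reference_profiles)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.save(out_dir / "config.json")
        payload = {
            "profiles": [
                {"compound_id": p.compound_id,
                 "entries": [
                     {"receptor_id": e.receptor_id,
                      "site_mode": e.site_mode.value,
                      "class_probs": list(e.class_probs),
                      "predicted_class": e.predicted_class,
                      "predicted_pchembl": e.predicted_pchembl,
                      "docking_score": e.docking_score}
                     for e in p.entries]}
                for p in profiles],
            "decisions": [
                {"compound_id": d.compound_id,
                 "leg_targets": d.leg_targets,
                 "leg_target_classes": d.leg_target_classes,
                 "consensus_target": d.consensus_target,
                 "agreement_k": d.agreement_k}
                for d in decisions],
            "errors": errors,
        }
        (out_dir / "predictions.json").write_text(
            json.dumps(payload, indent=2))
        for cid, frame in comparisons.items():
            frame.to_csv(out_dir / f"compare_{cid}.csv", index=False)
    return profiles, decisions


def run_synthetic_benchmark(seed: int = 0,
                            n_actives: int = 60,
                            n_inactives: int = 60,
                            n_dual: int = 10,
                            noise_sd: float = 0.2,
                            holdout_every: int = 5,
                            config: RunConfig | None = None,
                            work_dir: str | Path | None = None) -> dict:
    """Train and evaluate the full system on a two-receptor planted benchmark.

    Builds a benchmark with one class-A receptor (CCR6, furanamide
    pharmacophore) and one class-B receptor (GLP1R, sulfonamide
    pharmacophore), holds out every ``holdout_every``-th selective
    carrier plus all dual-pharmacophore compounds as queries, trains the
    per-receptor model pairs on the remaining activity records, profiles
    the queries with the stub docking leg, and scores target and
    target-class precision under each consensus rule.

    Returns a dictionary of the headline numbers (per-rule and per-leg
    precisions, model CV metrics, importance-decoding check) for
    reporting; dual compounds are scored against the first of their true
    targets.
    """
    import tempfile

    from .models import gain_importance
    from .synthetic import (PlantedSAR, contains_pharmacophore,
                            generate_multireceptor_benchmark)

    registry = {"CCR6": "A", "GLP1R": "B"}
    sars = [
        PlantedSAR(receptor_id="CCR6", pharmacophore_smiles="NC(=O)c1ccco1",
                   n_actives=n_actives, n_inactives=n_inactives,
                   noise_sd=noise_sd, seed=seed),
        PlantedSAR(receptor_id="GLP1R", pharmacophore_smiles="CS(=O)(=O)N",
                   n_actives=n_actives, n_inactives=n_inactives,
                   noise_sd=noise_sd, seed=seed + 1),
    ]
    bench = generate_multireceptor_benchmark(sars, registry, n_dual=n_dual,
                                             seed=seed)

    query_ids = {
        rec.compound_id
        for rec in bench.compounds
        if rec.compound_id.startswith("dual")
        or ("-act-" in rec.compound_id
            and int(rec.compound_id.rsplit("-", 1)[1]) % holdout_every == 0)
    }
    train_acts = [a for a in bench.activities
                  if a.compound_id not in query_ids]
    queries = [c for c in bench.compounds if c.compound_id in query_ids]

    if config is None:
        config = RunConfig(
            n_bits=512,
            n_trials_classifier=2, n_trials_regressor=2,
            classifier_layers=(5, 6), classifier_units=(16, 64),
            regressor_estimators=(50, 500),
            seed=seed, docking_backend="stub",
        )
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(work_dir) if work_dir is not None else Path(tmp)
        bundle_dir = run_train(config, train_acts, bench.compounds,
                               out_dir=out / "bundles")
        metrics = pd.read_csv(bundle_dir / "metrics.csv")
        _, decisions = run_predict(config, bundle_dir, queries,
                                   out_dir=out / "predictions")

        triples = []
        for d in decisions:
            targets, true_class = bench.truth_for(d.compound_id)
            triples.append((d, targets[0], true_class))
        report = evaluate(triples, registry)

        # importance decoding on the class-A receptor's regressor; with
        # cross-receptor negatives in the table, either pharmacophore is a
        # legitimate top signal (one separates actives, the other negatives)
        bundles = {b.receptor_id: b for b in load_bundles(bundle_dir)}
        ranked = gain_importance(bundles["CCR6"].regressor, top_k=1)
        top_bit_is_planted = False
        if ranked:
            spec = config.fingerprint_spec
            X = featurize_set(bench.compounds, spec)
            bit = ranked[0][0]
            on = X[:, bit].astype(bool)
            for sar in sars:
                carrier = np.array([
                    contains_pharmacophore(c.smiles, sar.pharmacophore_smiles)
                    for c in bench.compounds])
                if on[carrier].mean() >= 0.5 and on[~carrier].mean() <= 0.05:
                    top_bit_is_planted = True
                    break

    return {
        "n_train_records": len(train_acts),
        "n_queries": len(queries),
        "target_precision_atleast1": report.precision("atleast1", "target"),
        "target_precision_atleast2": report.precision("atleast2", "target"),
        "target_precision_all3": report.precision("all3", "target"),
        "class_precision_atleast1": report.precision("atleast1", "class"),
        "target_precision_classifier": report.precision("classifier", "target"),
        "target_precision_regressor": report.precision("regressor", "target"),
        "target_precision_docking": report.precision("docking", "target"),
        "class_precision_docking": report.precision("docking", "class"),
        "cv_accuracy_mean": float(metrics.cv_accuracy_mean.mean()),
        "cv_rmse_mean": float(metrics.cv_rmse_mean.mean()),
        "test_rmse_mean": float(metrics.test_rmse.mean()),
        "top_gain_bit_is_planted": top_bit_is_planted,
    }
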