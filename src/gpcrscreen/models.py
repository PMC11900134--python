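"""Per-receptor activity models: six-class classifier and pChEMBL regressor.

Each (receptor, binding-site mode) pair gets two independently trained
models over the same ECFP4 feature space: a feed-forward multilayer
network classifying compounds into six pChEMBL activity classes, and a
gradient-boosted decision-tree ensemble regressing the pChEMBL value
itself.  Hyperparameters are chosen by seeded random search scored with
10-fold cross-validation; the regressor additionally exposes gain-based
feature importance, which the fragment decoder turns into substructures.

The estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``get_params``; fitted attributes end in an underscore) and compose with
sklearn model-selection utilities.  The neural leg is pluggable behind
the predictor contract; the default backend is scikit-learn's
``MLPClassifier`` (Adam optimizer, softmax readout via ``predict_proba``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from lightgbm import LGBMRegressor
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .chem_io import CompoundRecord, SiteMode
from .curation import ActivityClass, DEFAULT_CLASS_SCHEME
from .featurize import (FingerprintSpec, FragmentImportance, ecfp4,
                        fragment_for_bit, featurize_set)

__all__ = [
    "ClassifierSearchSpace",
    "RegressorSearchSpace",
    "ActivityClassifier",
    "PChEMBLRegressor",
    "TrainedModelBundle",
    "DegenerateLabelsError",
    "UnsupportedModelError",
    "train_classifier",
    "train_regressor",
    "gain_importance",
    "importance_report",
    "predict_profile_leg",
    "N_CLASSES",
]

logger = logging.getLogger(__name__)

N_CLASSES = 6

# Hard bound on the tree count a search space may request.
_N_ESTIMATORS_BOUND = (50, 50_000)


class DegenerateLabelsError(ValueError):
    """Training labels contain a single class."""


class UnsupportedModelError(TypeError):
    """Gain importance requested from a non-tree predictor."""


@dataclass(frozen=True)
class ClassifierSearchSpace:
    """Random-search space for the neural activity classifier.

    Architectures have 5-20 hidden layers whose widths are drawn from
    16-2048 units, one of {relu, tanh, sigmoid} activations, and an Adam
    learning rate drawn log-uniformly.  The loss is fixed to categorical
    cross-entropy (the backend's multiclass log-loss).
    """

    n_hidden_layers: tuple[int, int] = (5, 20)
    units_per_layer: tuple[int, int] = (16, 2048)
    activations: tuple[str, ...] = ("relu", "tanh", "sigmoid")
    learning_rate: tuple[float, float] = (1e-4, 1e-2)
    n_trials: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for lo, hi in (self.n_hidden_layers, self.units_per_layer):
            if lo > hi:
                raise ValueError("empty range in search space")
        if not self.activations:
            raise ValueError("need at least one activation")


@dataclass(frozen=True)
class RegressorSearchSpace:
    """Random-search space for the gradient-boosting regressor."""

    n_estimators: tuple[int, int] = (50, 50_000)
    learning_rate: tuple[float, float] = (0.01, 0.3)
    num_leaves: tuple[int, int] = (8, 256)
    subsample: tuple[float, float] = (0.5, 1.0)
    n_trials: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_estimators
        if lo > hi:
            raise ValueError("empty n_estimators range")
        if lo < _N_ESTIMATORS_BOUND[0] or hi > _N_ESTIMATORS_BOUND[1]:
            raise ValueError(
                f"n_estimators range {self.n_estimators} outside the "
                f"allowed bound {_N_ESTIMATORS_BOUND}"
            )
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


# sklearn's name for the sigmoid activation
_ACTIVATION_ALIASES = {"sigmoid": "logistic", "relu": "relu", "tanh": "tanh",
                       "logistic": "logistic"}


class ActivityClassifier(ClassifierMixin, BaseEstimator):
    """Six-class activity classifier with seeded random architecture search.

    ``fit`` samples ``n_trials`` architectures from the search space,
    scores each by mean 10-fold cross-validated accuracy, and refits the
    best on the full data.  ``predict_proba`` always returns a
    probability vector over all ``n_classes`` labels (0..5), with zero
    mass on labels absent from training, so downstream consensus logic
    sees a fixed-width softmax-style output.

    Attributes (after fit)
    ----------------------
    best_params_ : dict — winning architecture and learning rate.
    cv_scores_ : ndarray of shape (cv,) — per-fold accuracy of the winner.
    model_ : the refitted backend network.
    """

    def __init__(self, n_hidden_layers=(5, 20), units_per_layer=(16, 2048),
                 activations=("relu", "tanh", "sigmoid"),
                 learning_rate=(1e-4, 1e-2), n_trials=25, cv=10,
                 max_iter=200, n_classes=N_CLASSES, random_state=0):
        self.n_hidden_layers = n_hidden_layers
        self.units_per_layer = units_per_layer
        self.activations = activations
        self.learning_rate = learning_rate
        self.n_trials = n_trials
        self.cv = cv
        self.max_iter = max_iter
        self.n_classes = n_classes
        self.random_state = random_state

    @classmethod
    def from_space(cls, space: ClassifierSearchSpace, **kwargs) -> "ActivityClassifier":
        return cls(n_hidden_layers=space.n_hidden_layers,
                   units_per_layer=space.units_per_layer,
                   activations=space.activations,
                   learning_rate=space.learning_rate,
                   n_trials=space.n_trials,
                   random_state=space.seed, **kwargs)

    def _sample_params(self, rng: np.random.Generator) -> dict:
        lo_l, hi_l = self.n_hidden_layers
        lo_u, hi_u = self.units_per_layer
        n_layers = int(rng.integers(lo_l, hi_l + 1))
        # widths drawn log-uniformly: wide and narrow nets equally likely
        widths = tuple(int(round(np.exp(rng.uniform(np.log(lo_u), np.log(hi_u)))))
                       for _ in range(n_layers))
        return {
            "hidden_layer_sizes": widths,
            "activation": str(rng.choice(list(self.activations))),
            "learning_rate_init": float(np.exp(rng.uniform(
                np.log(self.learning_rate[0]), np.log(self.learning_rate[1])))),
        }

    def _build(self, params: dict, seed: int) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=params["hidden_layer_sizes"],
            activation=_ACTIVATION_ALIASES[params["activation"]],
            solver="adam",
            learning_rate_init=params["learning_rate_init"],
            max_iter=self.max_iter,
            random_state=seed,
        )

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y, dtype=int)
        labels = np.unique(y)
        if labels.size < 2:
            raise DegenerateLabelsError(
                f"need >= 2 distinct classes, got {labels.tolist()}"
            )
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError(f"labels must lie in 0..{self.n_classes - 1}")
        if len(y) < self.cv:
            raise ValueError(f"need >= {self.cv} samples for {self.cv}-fold CV")

        rng = np.random.default_rng(self.random_state)
        kf = KFold(n_splits=self.cv, shuffle=True,
                   random_state=self.random_state)
        fold_index = list(kf.split(X))
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for trial in range(self.n_trials):
                params = self._sample_params(rng)
                scores = []
                for tr, va in fold_index:
                    net = self._build(params, seed=self.random_state + trial)
                    if np.unique(y[tr]).size < 2:
                        scores.append(0.0)
                        continue
                    net.fit(X[tr], y[tr])
                    scores.append(float(np.mean(net.predict(X[va]) == y[va])))
                mean = float(np.mean(scores))
                if best is None or mean > best[0]:
                    best = (mean, params, np.asarray(scores))
            _, self.best_params_, self.cv_scores_ = best
            self.model_ = self._build(self.best_params_, seed=self.random_state)
            self.model_.fit(X, y)
        self.classes_ = np.arange(self.n_classes)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        raw = self.model_.predict_proba(X)
        out = np.zeros((X.shape[0], self.n_classes))
        out[:, self.model_.classes_] = raw
        return out

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


class PChEMBLRegressor(RegressorMixin, BaseEstimator):
    """Gradient-boosted pChEMBL regressor with seeded random search.

    Trials draw tree count (log-uniform within [50, 50000]), learning
    rate, leaf count and row subsampling; each is scored by mean 10-fold
    cross-validated RMSE and the best is refit on the full data.  Runs
    single-threaded and deterministic for a given seed.

    Attributes (after fit): ``best_params_``, ``cv_scores_`` (per-fold
    RMSE of the winner), ``model_`` (the LightGBM ensemble).
    """

    def __init__(self, n_estimators=(50, 50_000), learning_rate=(0.01, 0.3),
                 num_leaves=(8, 256), subsample=(0.5, 1.0), n_trials=25,
                 cv=10, random_state=0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.num_leaves = num_leaves
        self.subsample = subsample
        self.n_trials = n_trials
        self.cv = cv
        self.random_state = random_state

    @classmethod
    def from_space(cls, space: RegressorSearchSpace, **kwargs) -> "PChEMBLRegressor":
        return cls(n_estimators=space.n_estimators,
                   learning_rate=space.learning_rate,
                   num_leaves=space.num_leaves,
                   subsample=space.subsample,
                   n_trials=space.n_trials,
                   random_state=space.seed, **kwargs)

    def _validate_space(self) -> None:
        lo, hi = self.n_estimators
        if lo < _N_ESTIMATORS_BOUND[0] or hi > _N_ESTIMATORS_BOUND[1] or lo > hi:
            raise ValueError(
                f"n_estimators range {self.n_estimators} outside the "
                f"allowed bound {_N_ESTIMATORS_BOUND}"
            )

    def _sample_params(self, rng: np.random.Generator) -> dict:
        lo_e, hi_e = self.n_estimators
        sub = float(rng.uniform(*self.subsample))
        return {
            "n_estimators": int(round(np.exp(rng.uniform(np.log(lo_e),
                                                         np.log(hi_e))))),
            "learning_rate": float(np.exp(rng.uniform(
                np.log(self.learning_rate[0]), np.log(self.learning_rate[1])))),
            "num_leaves": int(rng.integers(self.num_leaves[0],
                                           self.num_leaves[1] + 1)),
            "subsample": sub,
            "subsample_freq": 1 if sub < 1.0 else 0,
        }

    def _build(self, params: dict) -> LGBMRegressor:
        return LGBMRegressor(
            **params,
            random_state=self.random_state,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            importance_type="gain",
            verbose=-1,
        )

    def fit(self, X, y):
        self._validate_space()
        X, y = validate_data(self, X, y)
        y = np.asarray(y, dtype=float)
        if len(y) < self.cv:
            raise ValueError(f"need >= {self.cv} samples for {self.cv}-fold CV")
        if np.all(X == X[0]):
            warnings.warn("constant feature matrix: gain importance will be "
                          "empty; model fits the mean", UserWarning)
        rng = np.random.default_rng(self.random_state)
        kf = KFold(n_splits=self.cv, shuffle=True,
                   random_state=self.random_state)
        fold_index = list(kf.split(X))
        best = None
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper warns about feature names when fed
            # plain arrays; feature identity here is positional by design
            warnings.filterwarnings(
                "ignore", message=".*does not have valid feature names.*")
            for trial in range(self.n_trials):
                params = self._sample_params(rng)
                rmses = []
                for tr, va in fold_index:
                    model = self._build(params)
                    model.fit(X[tr], y[tr])
                    pred = model.predict(X[va])
                    rmses.append(float(np.sqrt(np.mean((pred - y[va]) ** 2))))
                mean = float(np.mean(rmses))
                if best is None or mean < best[0]:
                    best = (mean, params, np.asarray(rmses))
            _, self.best_params_, self.cv_scores_ = best
            self.model_ = self._build(self.best_params_)
            self.model_.fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message=".*does not have valid feature names.*")
            return self.model_.predict(X)

    def gain_importance(self, top_k: int | None = None) -> list[tuple[int, float]]:
        """Bits ranked by total split gain, zero-gain bits excluded."""
        check_is_fitted(self)
        return gain_importance(self, top_k)


def _booster_of(predictor):
    if isinstance(predictor, PChEMBLRegressor):
        check_is_fitted(predictor)
        return predictor.model_
    if isinstance(predictor, LGBMRegressor):
        return predictor
    raise UnsupportedModelError(
        f"gain importance requires a tree-ensemble regressor, got "
        f"{type(predictor).__name__}"
    )


def gain_importance(predictor, top_k: int | None = None
                    ) -> list[tuple[int, float]]:
    """Rank features by total gain (loss reduction over all splits).

    Returns ``(bit, gain)`` pairs sorted by descending gain with
    zero-gain bits excluded; ties broken by bit index for determinism.
    A model that never split (constant target) yields an empty list.
    """
    model = _booster_of(predictor)
    gains = model.booster_.feature_importance(importance_type="gain")
    order = sorted((int(b) for b in np.flatnonzero(gains > 0)),
                   key=lambda b: (-gains[b], b))
    if top_k is not None:
        order = order[:top_k]
    return [(b, float(gains[b])) for b in order]


def importance_report(predictor, records: Sequence[CompoundRecord],
                      spec: FingerprintSpec, top_k: int = 10
                      ) -> list[FragmentImportance]:
    """Decode the top-gain bits into substructure fragments.

    Each bit is resolved against the first provided training molecule
    that sets it; fragments carry ``*`` attachment points.  Bits no
    provided molecule sets are reported with fragment ``"unresolved"``.
    """
    ranked = gain_importance(predictor, top_k)
    fps = [ecfp4(r, spec) for r in records]
    out: list[FragmentImportance] = []
    for rank, (bit, gain) in enumerate(ranked, start=1):
        fragment = "unresolved"
        for rec, fp in zip(records, fps):
            if bit in fp.bit_environments:
                fragment = fragment_for_bit(rec, bit, spec)
                break
        out.append(FragmentImportance(bit=bit, gain=gain,
                                      fragment_smiles=fragment, rank=rank))
    return out


# ---------------------------------------------------------------------------
# spec-surface wrappers and the per-receptor bundle
# ---------------------------------------------------------------------------

def train_classifier(X, y, space: ClassifierSearchSpace = ClassifierSearchSpace(),
                     **kwargs):
    """Random-search-train the classifier; return (predictor, cv, params)."""
    est = ActivityClassifier.from_space(space, **kwargs).fit(X, y)
    return est, est.cv_scores_, est.best_params_


def train_regressor(X, y, space: RegressorSearchSpace = RegressorSearchSpace(),
                    **kwargs):
    """Random-search-train the regressor; return (predictor, cv, params)."""
    est = PChEMBLRegressor.from_space(space, **kwargs).fit(X, y)
    return est, est.cv_scores_, est.best_params_


@dataclass
class TrainedModelBundle:
    """Both trained legs for one (receptor, site mode), plus provenance.

    Carries the fingerprint spec and class scheme the models were trained
    under so prediction can refuse mismatched configurations, and the CV
    metrics and winning hyperparameters for auditability.
    """

    receptor_id: str
    site_mode: SiteMode
    classifier: ActivityClassifier
    regressor: PChEMBLRegressor
    cv_metrics: dict
    best_hyperparameters: dict
    spec: FingerprintSpec
    class_scheme: tuple[ActivityClass, ...] = DEFAULT_CLASS_SCHEME
    seed: int = 0

    def __post_init__(self) -> None:
        self.site_mode = SiteMode(self.site_mode)

    def predict_profile_leg(self, record: CompoundRecord
                            ) -> tuple[np.ndarray, float]:
        return predict_profile_leg(self, record)

    # -- persistence: metadata as JSON, models via joblib -------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "receptor_id": self.receptor_id,
            "site_mode": self.site_mode.value,
            "cv_metrics": {k: list(np.asarray(v, dtype=float))
                           for k, v in self.cv_metrics.items()},
            "best_hyperparameters": self.best_hyperparameters,
            "fingerprint_spec": asdict(self.spec),
            "class_scheme": [asdict(c) for c in self.class_scheme],
            "seed": self.seed,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2,
                                                            default=float))
        joblib.dump(self.classifier, directory / "classifier.joblib")
        joblib.dump(self.regressor, directory / "regressor.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        scheme = tuple(ActivityClass(**{**c, "upper": float(c["upper"])})
                       for c in meta["class_scheme"])
        return cls(
            receptor_id=meta["receptor_id"],
            site_mode=SiteMode(meta["site_mode"]),
            classifier=joblib.load(directory / "classifier.joblib"),
            regressor=joblib.load(directory / "regressor.joblib"),
            cv_metrics=meta["cv_metrics"],
            best_hyperparameters=meta["best_hyperparameters"],
            spec=FingerprintSpec(**meta["fingerprint_spec"]),
            class_scheme=scheme,
            seed=meta["seed"],
        )


def predict_profile_leg(bundle: TrainedModelBundle, record: CompoundRecord
                        ) -> tuple[np.ndarray, float]:
    """Run both ML legs on one compound from the identical fingerprint.

    Returns the six-class probability vector and the predicted pChEMBL.
    Raises a configuration error if the bundle's fingerprint width does
    not match what its models were trained on.
    """
    X = featurize_set([record], bundle.spec)
    for est in (bundle.classifier, bundle.regressor):
        if getattr(est, "n_features_in_", X.shape[1]) != X.shape[1]:
            raise ValueError(
                f"fingerprint spec mismatch: bundle spec gives {X.shape[1]} "
                f"bits but model expects {est.n_features_in_}"
            )
    probs = bundle.classifier.predict_proba(X)[0]
    pchembl = float(bundle.regressor.predict(X)[0])
    return probs, pchembl
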