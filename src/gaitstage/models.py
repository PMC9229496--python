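"""Stage classifiers, grid search, learning curves and good-fit selection.

Three classifier families are supported — k-nearest neighbours (KNN), a
support-vector machine (SVM) with linear or RBF kernel, and gradient-boosted
trees (GB).  Hyper-parameters are tuned by exhaustive grid search scored with
mean stratified 10-fold cross-validated accuracy.  A model is accepted only
when its learning curve looks like a good fit: a small terminal gap between
training and validation accuracy, a validation curve that has plateaued, and
performance clearly above chance.  The selection loop scans candidate
synthetic-dataset sizes (numbers of omega combinations) in ascending order
and keeps the first size whose best configuration passes the diagnosis.

KNN and SVM operate on z-scored features (fit on training folds only, inside
the CV pipeline); the tree-based GB model uses raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    learning_curve as _sk_learning_curve,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, StratificationError
from .features import FEATURE_NAMES, feature_matrix
from .synthesis import STAGE_ORDER

ARCHIVE_VERSION = 1

#: Default hyper-parameter grids per family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "KNN": {
        "n_neighbors": [1, 3, 5, 7, 9, 11, 13, 15],
        "metric": ["euclidean", "manhattan", "minkowski"],
        "weights": ["uniform", "distance"],
    },
    "SVM": {
        "C": [0.01, 0.1, 1, 10, 100],
        "kernel": ["linear", "rbf"],
        "gamma": ["scale"],
    },
    "GB": {
        "n_estimators": [1, 2, 5, 20, 50, 100],
    },
}


@dataclass
class ModelConfig:
    """Family, grid and CV settings for one training run."""

    family: str = "KNN"
    grid: dict[str, list] | None = None
    cv_folds: int = 10
    seed: int = 22
    standardize: bool | None = None  # None -> per-family default

    def __post_init__(self) -> None:
        self.family = self.family.upper()
        if self.family not in DEFAULT_GRIDS:
            raise ConfigError(
                f"unknown model family {self.family!r}; choose from {sorted(DEFAULT_GRIDS)}"
            )
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ConfigError("hyper-parameter grid must be non-empty")
        if self.standardize is None:
            self.standardize = self.family in ("KNN", "SVM")


@dataclass
class LearningCurve:
    """Train/validation accuracy trajectories versus training-set size."""

    train_sizes: np.ndarray
    train_scores: np.ndarray
    val_scores: np.ndarray
    val_score_sd: np.ndarray

    @property
    def final_gap(self) -> float:
        return float(self.train_scores[-1] - self.val_scores[-1])


@dataclass
class FitDiagnosis:
    """Verdict of the learning-curve good-fit rule."""

    final_gap: float
    val_plateau_delta: float
    final_val_score: float
    chance_level: float
    gap_tol: float
    plateau_tol: float
    verdict: str  # good_fit | overfit | underfit

    def as_dict(self) -> dict:
        return {
            "final_gap": self.final_gap,
            "val_plateau_delta": self.val_plateau_delta,
            "final_val_score": self.final_val_score,
            "chance_level": self.chance_level,
            "gap_tol": self.gap_tol,
            "plateau_tol": self.plateau_tol,
            "verdict": self.verdict,
        }


@dataclass
class TrainedModel:
    """A fitted pipeline plus everything needed to reproduce it.

    cv_results holds every grid point's mean CV accuracy and per-fold
    scores, descending by mean, so callers can re-examine non-best combos.
    """

    family: str
    estimator: Pipeline
    best_params: dict
    cv_fold_scores: np.ndarray
    mean_cv_accuracy: float
    train_accuracy: float
    classes: list[str]
    config: ModelConfig
    cv_results: list[dict] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores usable for one-vs-rest ROC ranking."""
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)
        return est.decision_function(X)


def _build_estimator(cfg: ModelConfig) -> Pipeline:
    if cfg.family == "KNN":
        clf = KNeighborsClassifier()
    elif cfg.family == "SVM":
        # one-vs-one fitting internally; "ovr"-shaped decision values give one
        # monotone score column per class for ROC ranking
        clf = SVC(random_state=cfg.seed, decision_function_shape="ovr")
    else:
        clf = GradientBoostingClassifier(random_state=cfg.seed)
    steps = []
    if cfg.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", clf))
    return Pipeline(steps)


def _labeled_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "stage" not in table.columns:
        raise ConfigError("table has no 'stage' label column")
    X = feature_matrix(table)
    y = table["stage"].astype(str).to_numpy()
    return X, y


def _check_stratifiable(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    bad = classes[counts < folds]
    if len(bad):
        raise StratificationError(
            f"class(es) {list(bad)} have fewer than cv_folds={folds} rows"
        )


def grid_search_train(table: pd.DataFrame, cfg: ModelConfig) -> TrainedModel:
    """Exhaustive grid search under stratified k-fold CV; refit on all data.

    Deterministic given the seed: fold assignment is seeded, and so is every
    stochastic model component.
    """
    X, y = _labeled_xy(table)
    _check_stratifiable(y, cfg.cv_folds)
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    param_grid = {f"clf__{k}": v for k, v in cfg.grid.items()}
    search = GridSearchCV(
        _build_estimator(cfg),
        param_grid,
        scoring="accuracy",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(X, y)
    results = search.cv_results_
    all_combos = []
    for i, params in enumerate(results["params"]):
        all_combos.append(
            {
                "params": {k.removeprefix("clf__"): v for k, v in params.items()},
                "mean_cv_accuracy": float(results["mean_test_score"][i]),
                "fold_scores": np.array(
                    [results[f"split{j}_test_score"][i] for j in range(cfg.cv_folds)]
                ),
            }
        )
    all_combos.sort(key=lambda r: -r["mean_cv_accuracy"])
    best_idx = search.best_index_
    fold_scores = np.array(
        [search.cv_results_[f"split{i}_test_score"][best_idx] for i in range(cfg.cv_folds)]
    )
    best_params = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
    est: Pipeline = search.best_estimator_
    return TrainedModel(
        family=cfg.family,
        estimator=est,
        best_params=best_params,
        cv_fold_scores=fold_scores,
        mean_cv_accuracy=float(search.best_score_),
        train_accuracy=float(est.score(X, y)),
        classes=[str(c) for c in est.named_steps["clf"].classes_],
        config=cfg,
        cv_results=all_combos,
    )


def learning_curve(
    table: pd.DataFrame,
    cfg: ModelConfig,
    fractions: Sequence[float] = tuple(np.linspace(0.1, 1.0, 10)),
    params: dict | None = None,
) -> LearningCurve:
    """Stratified-CV train/validation accuracy at increasing training sizes.

    params, when given, pins the estimator's hyper-parameters (e.g. the grid
    search winner); otherwise the family defaults are used.
    """
    X, y = _labeled_xy(table)
    _check_stratifiable(y, cfg.cv_folds)
    est = _build_estimator(cfg)
    if params:
        est.set_params(**{f"clf__{k}": v for k, v in params.items()})
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    sizes, train_sc, val_sc = _sk_learning_curve(
        est,
        X,
        y,
        train_sizes=np.asarray(list(fractions)),
        cv=cv,
        scoring="accuracy",
        shuffle=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    return LearningCurve(
        train_sizes=sizes,
        train_scores=train_sc.mean(axis=1),
        val_scores=val_sc.mean(axis=1),
        val_score_sd=val_sc.std(axis=1),
    )


def diagnose_fit(
    lc: LearningCurve,
    gap_tol: float = 0.05,
    plateau_tol: float = 0.01,
    chance: float = 0.25,
) -> FitDiagnosis:
    """Classify a learning curve as good_fit, overfit or underfit.

    good_fit requires (a) final train−validation gap <= gap_tol, (b) the
    validation score improved by <= plateau_tol over the last third of the
    size axis (it has plateaued), and (c) a final validation score above
    chance.  A gap beyond tolerance is an overfit; a final score within 0.05
    of chance is an underfit; a curve that is still climbing is also reported
    as underfit (more data would change the answer).
    """
    n = len(lc.val_scores)
    if n < 4:
        raise ConfigError("need >= 4 training sizes to diagnose a learning curve")
    k = max(2, int(np.ceil(n / 3)))
    plateau_delta = float(lc.val_scores[-1] - lc.val_scores[-k])
    gap = lc.final_gap
    final_val = float(lc.val_scores[-1])

    if gap > gap_tol:
        verdict = "overfit"
    elif final_val <= chance + 0.05:
        verdict = "underfit"
    elif plateau_delta <= plateau_tol:
        verdict = "good_fit"
    else:
        verdict = "underfit"
    return FitDiagnosis(
        final_gap=gap,
        val_plateau_delta=plateau_delta,
        final_val_score=final_val,
        chance_level=chance,
        gap_tol=gap_tol,
        plateau_tol=plateau_tol,
        verdict=verdict,
    )


def _refit_combo(table: pd.DataFrame, cfg: ModelConfig, combo: dict) -> TrainedModel:
    """Refit one grid point on the full table, keeping its CV fold scores."""
    X, y = _labeled_xy(table)
    est = _build_estimator(cfg)
    est.set_params(**{f"clf__{k}": v for k, v in combo["params"].items()})
    est.fit(X, y)
    return TrainedModel(
        family=cfg.family,
        estimator=est,
        best_params=dict(combo["params"]),
        cv_fold_scores=np.asarray(combo["fold_scores"]),
        mean_cv_accuracy=combo["mean_cv_accuracy"],
        train_accuracy=float(est.score(X, y)),
        classes=[str(c) for c in est.named_steps["clf"].classes_],
        config=cfg,
    )


def train_with_fit_selection(
    table: pd.DataFrame,
    cfg: ModelConfig,
    gap_tol: float = 0.05,
    plateau_tol: float = 0.01,
) -> tuple[TrainedModel, LearningCurve, FitDiagnosis]:
    """Grid search, then pick the best-scoring combo whose learning curve is
    a good fit.

    Every hyper-parameter combination has its own learning curve; the CV-best
    combination is often a memorizer (e.g. 1-NN) whose training accuracy is
    pinned at 1, so combos are examined in descending CV-accuracy order and
    the first good-fit one wins.  When none passes, the CV-best combo is
    returned with its (non-good-fit) diagnosis so callers can see why.
    """
    search = grid_search_train(table, cfg)
    chance = 1.0 / table["stage"].nunique()
    fallback: tuple[TrainedModel, LearningCurve, FitDiagnosis] | None = None
    for combo in search.cv_results:
        with warnings.catch_warnings():
            # combos that cannot be scored at a size (e.g. k-NN with k larger
            # than the smallest training subset) yield NaN points there
            warnings.filterwarnings("ignore", message="Scoring failed")
            lc = learning_curve(table, cfg, params=combo["params"])
        if np.isnan(lc.train_scores).any() or np.isnan(lc.val_scores).any():
            continue  # not diagnosable over the full size axis
        diag = diagnose_fit(lc, gap_tol=gap_tol, plateau_tol=plateau_tol, chance=chance)
        if diag.verdict == "good_fit":
            model = _refit_combo(table, cfg, combo)
            model.cv_results = search.cv_results
            return model, lc, diag
        if fallback is None:
            fallback = (search, lc, diag)
    if fallback is None:
        raise ConfigError(
            "no hyper-parameter combination could be scored across the whole "
            "learning-curve size axis; the dataset is too small for this grid"
        )
    return fallback


@dataclass
class CandidateResult:
    """Outcome of one (family, dataset size) candidate."""

    n_combinations: int
    model: TrainedModel | None
    diagnosis: FitDiagnosis | None
    error: str | None = None


@dataclass
class SelectionResult:
    """Per-family outcome of the dataset-size scan."""

    family: str
    chosen_n_combinations: int | None
    chosen: CandidateResult | None
    candidates: list[CandidateResult] = field(default_factory=list)


#: Candidate numbers of linear combinations scanned by default.
DEFAULT_CANDIDATE_COUNTS: tuple[int, ...] = (20, 40, 60, 80, 100, 200, 250)


def select_model_and_dataset(
    dataset_builder,
    families: Sequence[str],
    candidate_counts: Sequence[int] = DEFAULT_CANDIDATE_COUNTS,
    cv_folds: int = 10,
    seed: int = 22,
    gap_tol: float = 0.05,
    plateau_tol: float = 0.01,
) -> dict[str, SelectionResult]:
    """Scan dataset sizes per family; keep the first good-fit size.

    dataset_builder(n_combinations) must return a labeled feature table.
    At each size the good-fit rule is applied per hyper-parameter combination
    (see train_with_fit_selection).  Training errors on a candidate are
    recorded and the scan continues.
    """
    if not candidate_counts:
        raise ConfigError("candidate_counts must be non-empty")
    datasets: dict[int, pd.DataFrame] = {}
    results: dict[str, SelectionResult] = {}
    for family in families:
        sel = SelectionResult(family=family.upper(), chosen_n_combinations=None, chosen=None)
        for n in candidate_counts:
            if n not in datasets:
                datasets[n] = dataset_builder(n)
            table = datasets[n]
            cfg = ModelConfig(family=family, cv_folds=cv_folds, seed=seed)
            try:
                model, _lc, diag = train_with_fit_selection(
                    table, cfg, gap_tol=gap_tol, plateau_tol=plateau_tol
                )
                cand = CandidateResult(n_combinations=n, model=model, diagnosis=diag)
            except Exception as exc:  # noqa: BLE001 - recorded, scan continues
                cand = CandidateResult(n_combinations=n, model=None, diagnosis=None,
                                       error=f"{type(exc).__name__}: {exc}")
            sel.candidates.append(cand)
            if (
                sel.chosen is None
                and cand.diagnosis is not None
                and cand.diagnosis.verdict == "good_fit"
            ):
                sel.chosen = cand
                sel.chosen_n_combinations = n
        results[family.upper()] = sel
    return results


def predict_stage(model: TrainedModel, table: pd.DataFrame) -> dict:
    """Per-row stage predictions plus a vote summary and the modal stage.

    Modal-stage ties break toward the lowest (least severe) stage.
    """
    if len(table) == 0:
        raise ConfigError("cannot predict on an empty feature table")
    X = feature_matrix(table)
    pred = [str(p) for p in model.predict(X)]
    counts = {s.name: pred.count(s.name) for s in STAGE_ORDER if pred.count(s.name) > 0}
    modal = max(STAGE_ORDER, key=lambda s: (counts.get(s.name, 0), -s.ordinal)).name
    return {"per_row": pred, "counts": counts, "modal_stage": modal, "n_rows": len(pred)}


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist the trained model as a versioned joblib archive."""
    path = Path(path)
    payload = {
        "archive_version": ARCHIVE_VERSION,
        "family": model.family,
        "estimator": model.estimator,
        "best_params": model.best_params,
        "cv_fold_scores": model.cv_fold_scores,
        "mean_cv_accuracy": model.mean_cv_accuracy,
        "train_accuracy": model.train_accuracy,
        "classes": model.classes,
        "feature_names": list(FEATURE_NAMES),
        "config": {
            "family": model.config.family,
            "grid": model.config.grid,
            "cv_folds": model.config.cv_folds,
            "seed": model.config.seed,
            "standardize": model.config.standardize,
        },
    }
    joblib.dump(payload, path)
    return path


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("archive_version")
    if version != ARCHIVE_VERSION:
        raise ConfigError(f"unsupported model archive version {version!r}")
    cfg = ModelConfig(**payload["config"])
    return TrainedModel(
        family=payload["family"],
        estimator=payload["estimator"],
        best_params=payload["best_params"],
        cv_fold_scores=np.asarray(payload["cv_fold_scores"]),
        mean_cv_accuracy=payload["mean_cv_accuracy"],
        train_accuracy=payload["train_accuracy"],
        classes=payload["classes"],
        config=cfg,
    )


def training_report(model: TrainedModel, lc: LearningCurve | None = None,
                    diagnosis: FitDiagnosis | None = None) -> dict:
    """JSON-serializable training summary."""
    report = {
        "family": model.family,
        "best_params": model.best_params,
        "cv_fold_scores": [float(s) for s in model.cv_fold_scores],
        "mean_cv_accuracy": model.mean_cv_accuracy,
        "train_accuracy": model.train_accuracy,
        "classes": model.classes,
        "seed": model.config.seed,
        "cv_folds": model.config.cv_folds,
    }
    if lc is not None:
        report["learning_curve"] = {
            "train_sizes": [int(s) for s in lc.train_sizes],
            "train_scores": [float(s) for s in lc.train_scores],
            "val_scores": [float(s) for s in lc.val_scores],
            "val_score_sd": [float(s) for s in lc.val_score_sd],
        }
    if diagnosis is not None:
        report["diagnosis"] = diagnosis.as_dict()
    return report
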