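"""Classifier fitting and evaluation for presence/background tables.

Three classifier families are supported — random forest (RF), boosted
regression trees (BRT), and a support-vector machine (SVM) — behind one
contract: fit on a labelled predictor table, emit suitability scores in
[0, 1].  Evaluation uses replicated stratified 70/30 splits with AUC
(Mann-Whitney form, ties counted half) and the true skill statistic
(sensitivity + specificity - 1) on the held-out 30%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from zonesdm.grids import EnvStack
from zonesdm.occurrences import BackgroundSet, OccurrenceSet

FAMILIES = ("RF", "BRT", "SVM")

DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    # Community defaults for presence/background SDM; all overridable.
    "RF": {"n_estimators": 500, "max_features": "sqrt"},
    "BRT": {
        "learning_rate": 0.01,
        "max_depth": 3,
        "max_iter": 5000,
        "early_stopping": True,
        "validation_fraction": 0.1,
        "n_iter_no_change": 10,
        "min_samples_leaf": 10,
    },
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
}


@dataclass
class ModelTable:
    """Labelled predictor table: presences (1) stacked over background (0)."""

    X: pd.DataFrame
    y: np.ndarray
    scope: str = "combined"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.X.isna().any().any():
            raise ValueError("missing predictor values in model table")

    @property
    def predictors(self) -> list[str]:
        return list(self.X.columns)

    @property
    def prevalence(self) -> float:
        return float(self.y.mean())


def build_model_table(
    stack: EnvStack,
    presences: OccurrenceSet,
    background: BackgroundSet,
    predictors: list[str] | None = None,
    scope: str = "combined",
) -> ModelTable:
    """Extract predictor values at presence and background points."""
    names = predictors if predictors is not None else stack.layer_names
    pres_xy = presences.xy
    Xp = stack.extract(pres_xy[:, 0], pres_xy[:, 1], names)
    Xb = stack.extract(background.points[:, 0], background.points[:, 1], names)
    X = pd.DataFrame(np.vstack([Xp, Xb]), columns=names)
    y = np.concatenate([np.ones(len(Xp), dtype=int), np.zeros(len(Xb), dtype=int)])
    return ModelTable(X=X, y=y, scope=scope)


@dataclass
class ModelSpec:
    """Recipe for one classifier family with [0,1] score contract."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    def make_estimator(self, random_state: int):
        hp = self.hyperparameters
        if self.family == "RF":
            return RandomForestClassifier(random_state=random_state, n_jobs=1, **hp)
        if self.family == "BRT":
            return HistGradientBoostingClassifier(random_state=random_state, **hp)
        # RBF SVM with probability calibration so scores land in [0,1]
        return make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(SVC(random_state=random_state, **hp), ensemble=False),
        )


def score(estimator, X: pd.DataFrame) -> np.ndarray:
    """Positive-class probability of a fitted estimator."""
    proba = estimator.predict_proba(X)
    pos = list(estimator.classes_).index(1)
    return proba[:, pos]


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form (ties count half).

    The probability that a randomly chosen presence outscores a randomly
    chosen background point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def sensitivity_specificity(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    sens = float(pred[labels == 1].sum() / n1)
    spec = float((~pred)[labels == 0].sum() / n0)
    return sens, spec


def tss(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """True skill statistic: sensitivity + specificity - 1 at ``threshold``."""
    sens, spec = sensitivity_specificity(scores, labels, threshold)
    return sens + spec - 1.0


def best_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the distinct observed scores; ties are broken toward
    the smallest threshold (favouring suitability).
    """
    scores = np.asarray(scores, dtype=float)
    candidates = np.unique(scores)
    best_t, best_val = candidates[0], -np.inf
    for t in candidates:
        sens, spec = sensitivity_specificity(scores, labels, t)
        val = sens + spec
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return float(best_t)


@dataclass
class FitReplicate:
    """One trained split replicate with its out-of-sample metrics."""

    family: str
    index: int
    split_seed: int
    estimator: Any
    auc: float
    tss: float


def fit_replicates(
    table: ModelTable,
    spec: ModelSpec,
    n_reps: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
) -> list[FitReplicate]:
    """Replicated stratified train/test fitting of one family.

    Each replicate draws a stratified ``train_frac`` / ``1 - train_frac``
    split (label proportions preserved to within a row), fits the family on
    the training rows, and records test AUC and TSS.  TSS is evaluated at
    the replicate's own max(sensitivity + specificity) threshold,
    consistent with the ensemble binarization rule.  Degenerate splits
    (single-class test set) are redrawn.
    """
    if int(table.y.sum()) < 10:
        raise ValueError("need at least 10 presences to fit replicates")
    rng = np.random.default_rng(seed)
    reps: list[FitReplicate] = []
    for i in range(n_reps):
        for _attempt in range(20):
            split_seed = int(rng.integers(0, 2**31 - 1))
            X_tr, X_te, y_tr, y_te = train_test_split(
                table.X,
                table.y,
                train_size=train_frac,
                stratify=table.y,
                random_state=split_seed,
            )
            if len(np.unique(y_te)) == 2 and len(np.unique(y_tr)) == 2:
                break
        else:  # pragma: no cover - unreachable with stratification
            raise RuntimeError("could not draw a two-class split")
        est = spec.make_estimator(random_state=split_seed % (2**31 - 1))
        est.fit(X_tr, y_tr)
        s = score(est, X_te)
        t_star = best_threshold(s, y_te)
        reps.append(
            FitReplicate(
                family=spec.family,
                index=i,
                split_seed=split_seed,
                estimator=est,
                auc=auc(s, y_te),
                tss=tss(s, y_te, t_star),
            )
        )
    return reps


def refit_full(table: ModelTable, spec: ModelSpec, seed: int = 0) -> Any:
    """Refit one family on the full table (the scorer the ensemble deploys)."""
    est = spec.make_estimator(random_state=seed)
    est.fit(table.X, table.y)
    return est


def evaluation_report(replicates: list[FitReplicate]) -> pd.DataFrame:
    """Per-family mean/SD/min/max of AUC and TSS across replicates."""
    df = pd.DataFrame(
        [{"family": r.family, "auc": r.auc, "tss": r.tss} for r in replicates]
    )
    return (
        df.groupby("family")
        .agg(
            auc_mean=("auc", "mean"),
            auc_sd=("auc", "std"),
            auc_min=("auc", "min"),
            auc_max=("auc", "max"),
            tss_mean=("tss", "mean"),
            tss_sd=("tss", "std"),
            tss_min=("tss", "min"),
            tss_max=("tss", "max"),
            n_reps=("auc", "size"),
        )
        .reset_index()
    )
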