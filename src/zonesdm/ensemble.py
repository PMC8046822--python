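"""AUC-weighted ensemble construction, prediction, and binarization.

Candidate family scorers are admitted when their AUC exceeds a cutoff
(default 0.75) and combined as a weighted average,

    E = sum_i(AUC_i * M_i) / sum_i(AUC_i),

so better-discriminating members contribute proportionally more.  The
continuous ensemble map is converted to binary suitable/unsuitable by the
sensitivity + specificity sum-maximization threshold evaluated at the
presence and background points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from zonesdm.fitting import best_threshold, score, sensitivity_specificity
from zonesdm.grids import EnvStack, SuitabilityMap
from zonesdm.occurrences import BackgroundSet, OccurrenceSet


@dataclass
class EnsembleMember:
    family: str
    scorer: Any
    auc: float


@dataclass
class EnsembleModel:
    """Admitted members with AUC-derived weights and a frozen threshold."""

    members: list[EnsembleMember]
    weights: np.ndarray
    cutoff: float = 0.75
    threshold: float | None = None
    predictors: list[str] = field(default_factory=list)

    def member_aucs(self) -> list[float]:
        return [m.auc for m in self.members]

    def predict_table(self, X: pd.DataFrame) -> np.ndarray:
        """Weighted-average ensemble score for a predictor table."""
        if self.predictors:
            missing = [p for p in self.predictors if p not in X.columns]
            if missing:
                raise KeyError(f"missing predictors: {missing}")
            X = X[self.predictors]
        parts = np.stack([score(m.scorer, X) for m in self.members])
        return np.asarray(self.weights @ parts)

    def manifest(self) -> dict:
        return {
            "members": [
                {"family": m.family, "auc": m.auc, "weight": float(w)}
                for m, w in zip(self.members, self.weights)
            ],
            "cutoff": self.cutoff,
            "threshold": self.threshold,
            "predictors": self.predictors,
        }

    def write_manifest(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def build_ensemble(
    candidates: list[tuple[str, Any, float]],
    cutoff: float = 0.75,
    predictors: list[str] | None = None,
) -> EnsembleModel:
    """Admit candidates with AUC above ``cutoff`` and normalize weights.

    ``candidates`` are ``(family, scorer, AUC)`` triples; the AUC is
    typically the family's mean test AUC over the evaluation replicates.
    """
    admitted = [EnsembleMember(f, s, a) for f, s, a in candidates if a > cutoff]
    if not admitted:
        raise ValueError(
            f"no candidate exceeded the AUC cutoff {cutoff}; inspect the fits"
        )
    aucs = np.array([m.auc for m in admitted], dtype=float)
    weights = aucs / aucs.sum()
    return EnsembleModel(
        members=admitted,
        weights=weights,
        cutoff=cutoff,
        predictors=list(predictors) if predictors else [],
    )


def predict_ensemble(
    model: EnsembleModel, stack: EnvStack, scope: str = "combined", scenario: str | None = None
) -> SuitabilityMap:
    """Cellwise ensemble suitability over the masked grid."""
    names = model.predictors or stack.layer_names
    missing = [n for n in names if n not in stack.layer_names]
    if missing:
        raise KeyError(f"stack is missing predictor layer(s): {missing}")
    flat = stack.values[stack.mask]
    idx = [stack.index(n) for n in names]
    X = pd.DataFrame(flat[:, idx], columns=names)
    scores = model.predict_table(X)
    grid = np.full(stack.shape, np.nan)
    grid[stack.mask] = scores
    return SuitabilityMap(
        continuous=grid, cell_km=stack.cell_km, mask=stack.mask.copy(),
        scope=scope, scenario=scenario,
    )


def binarize(
    smap: SuitabilityMap,
    presences: OccurrenceSet,
    background: BackgroundSet,
    model: EnsembleModel | None = None,
) -> SuitabilityMap:
    """Threshold the continuous map by sensitivity+specificity maximization.

    The threshold candidates are the distinct ensemble scores observed at
    the presence and background points; ties go to the smallest threshold
    (favouring suitability).  When a model is passed, its ``threshold`` is
    set so scenario projections can reuse it frozen.
    """
    if len(presences) == 0 or len(background) == 0:
        raise ValueError("presences and background must both be non-empty")

    def _at(points: np.ndarray) -> np.ndarray:
        col = np.floor(points[:, 0] / smap.cell_km).astype(int)
        row = np.floor(points[:, 1] / smap.cell_km).astype(int)
        vals = smap.continuous[row, col]
        if np.any(~np.isfinite(vals)):
            raise ValueError("evaluation point outside the masked domain")
        return vals

    s_pres = _at(presences.xy)
    s_bg = _at(np.asarray(background.points))
    scores = np.concatenate([s_pres, s_bg])
    labels = np.concatenate([np.ones(len(s_pres), int), np.zeros(len(s_bg), int)])
    if np.unique(scores).size == 1:
        warnings.warn("all evaluation scores identical; degenerate threshold", stacklevel=2)
        t_star = float(scores[0])
    else:
        t_star = best_threshold(scores, labels)
    if model is not None:
        model.threshold = t_star
    out = smap.with_threshold(t_star)
    return out


def max_sens_spec(smap: SuitabilityMap, presences: OccurrenceSet, background: BackgroundSet) -> tuple[float, float]:
    """Sensitivity and specificity achieved at the map's threshold."""
    if smap.threshold is None:
        raise ValueError("map has no threshold")

    def _at(points: np.ndarray) -> np.ndarray:
        col = np.floor(points[:, 0] / smap.cell_km).astype(int)
        row = np.floor(points[:, 1] / smap.cell_km).astype(int)
        return smap.continuous[row, col]

    s_pres = _at(presences.xy)
    s_bg = _at(np.asarray(background.points))
    scores = np.concatenate([s_pres, s_bg])
    labels = np.concatenate([np.ones(len(s_pres), int), np.zeros(len(s_bg), int)])
    return sensitivity_specificity(scores, labels, smap.threshold)
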