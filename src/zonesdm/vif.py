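"""Variance-inflation-factor collinearity screening.

VIF(x_j) = 1 / (1 - R²) where R² is the coefficient of determination of an
ordinary least-squares regression (with intercept) of the focal predictor
on all remaining predictors.  Values of 10 and above flag collinearity; the
iterative eliminator drops the worst offender until every retained
predictor is below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class VifReport:
    """History of an iterative VIF elimination."""

    history: pd.DataFrame  # columns: iteration, variable, vif
    dropped: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    threshold: float = 10.0


def vif(values: pd.DataFrame, focal: str) -> float:
    """VIF of ``focal`` regressed on all other columns of ``values``.

    Returns ``inf`` when the remaining predictors explain the focal
    variable perfectly (R² within 1e-12 of 1).
    """
    df = pd.DataFrame(values)
    if focal not in df.columns:
        raise KeyError(f"focal variable {focal!r} not in table")
    others = [c for c in df.columns if c != focal]
    y = df[focal].to_numpy(dtype=float)
    n = len(y)
    if n < len(df.columns) + 2:
        raise ValueError("need at least (number of variables + 2) cases")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError(f"focal variable {focal!r} is constant")
    if not others:
        return 1.0
    X = np.column_stack([np.ones(n), df[others].to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ssr = float(np.sum((y - X @ beta) ** 2))
    r2 = 1.0 - ssr / sst
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def vif_eliminate(values: pd.DataFrame, threshold: float = 10.0) -> VifReport:
    """Iteratively drop the highest-VIF variable until all are below
    ``threshold``.

    Ties on the maximum VIF are broken lexicographically by variable name,
    so reports are deterministic.
    """
    df = pd.DataFrame(values)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    current = list(df.columns)
    rows = []
    dropped: list[str] = []
    iteration = 0
    while len(current) >= 2:
        vifs = {v: vif(df[current], v) for v in current}
        for v in sorted(current):
            rows.append({"iteration": iteration, "variable": v, "vif": vifs[v]})
        worst = max(vifs.values())
        if worst < threshold:
            break
        candidates = sorted(v for v, val in vifs.items() if val == worst)
        victim = candidates[0]
        dropped.append(victim)
        current.remove(victim)
        iteration += 1
    history = pd.DataFrame(rows, columns=["iteration", "variable", "vif"])
    return VifReport(history=history, dropped=dropped, retained=current, threshold=threshold)
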