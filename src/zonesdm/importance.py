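"""Permutation variable importance as 1 - correlation of predictions.

Shuffling an influential predictor changes the model's predictions, so the
correlation between original and permuted-column predictions drops;
``1 - correlation`` is therefore a per-variable, per-model importance in
[0, 2].  Family-level tables are averaged across families and normalized
to percent contributions, then aggregated into group shares
(climate vs soil vs topography).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from zonesdm.fitting import ModelTable, score
from zonesdm.grids import layer_group


@dataclass
class ImportanceTable:
    """Per-variable importances, cross-family means, percent contributions."""

    per_family: pd.DataFrame  # rows: variables, columns: families
    mean: pd.Series
    percent: pd.Series

    def as_frame(self) -> pd.DataFrame:
        out = self.per_family.copy()
        out["mean"] = self.mean
        out["percent"] = self.percent
        return out


def permutation_importance(
    scorer,
    table: ModelTable,
    variable: str,
    n_perm: int = 10,
    seed: int = 0,
    base_scores: np.ndarray | None = None,
    rows: np.ndarray | None = None,
) -> float:
    """Mean over permutations of 1 - Pearson r(original, permuted) predictions.

    ``rows`` optionally restricts evaluation to a subset of table rows
    (importance is a correlation; it stabilizes quickly with row count).
    ``base_scores`` lets callers reuse precomputed unpermuted predictions.
    """
    if variable not in table.X.columns:
        raise KeyError(f"variable {variable!r} not in table")
    X = table.X if rows is None else table.X.iloc[rows]
    if base_scores is None:
        base_scores = score(scorer, X)
    base_scores = np.asarray(base_scores, dtype=float)
    if np.std(base_scores) == 0:
        warnings.warn("zero-variance predictions; importance set to 0", stacklevel=2)
        return 0.0
    rng = np.random.default_rng(seed)
    vals = []
    col = X[variable].to_numpy()
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[variable] = rng.permutation(col)
        perm_scores = score(scorer, Xp)
        if np.std(perm_scores) == 0:
            vals.append(0.0 if np.allclose(perm_scores, base_scores) else 1.0)
            continue
        r = float(np.corrcoef(base_scores, perm_scores)[0, 1])
        vals.append(1.0 - r)
    return float(np.clip(np.mean(vals), 0.0, 2.0))


def importance_by_family(
    scorers: dict[str, object],
    table: ModelTable,
    n_perm: int = 10,
    seed: int = 0,
    n_rows: int | None = None,
) -> pd.DataFrame:
    """Permutation importance of every predictor for every family scorer.

    ``n_rows`` caps the number of (seeded, uniformly chosen) table rows
    used for the prediction correlations.
    """
    rng = np.random.default_rng(seed)
    if n_rows is not None and n_rows < len(table.X):
        rows = rng.choice(len(table.X), size=n_rows, replace=False)
    else:
        rows = None
    data = {}
    for family in sorted(scorers):
        scorer = scorers[family]
        X = table.X if rows is None else table.X.iloc[rows]
        base = score(scorer, X)
        data[family] = {
            var: permutation_importance(
                scorer,
                table,
                var,
                n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)),
                base_scores=base,
                rows=rows,
            )
            for var in table.predictors
        }
    return pd.DataFrame(data, index=table.predictors)


def aggregate_importance(per_family: pd.DataFrame) -> ImportanceTable:
    """Average importances across families and normalize to percents.

    All-zero importances degrade gracefully to uniform percents (with a
    warning): no variable is distinguishable from any other.
    """
    df = pd.DataFrame(per_family)
    if df.isna().any().any():
        raise ValueError("mismatched variable sets across families")
    mean = df.mean(axis=1)
    total = mean.sum()
    if total == 0:
        warnings.warn("all importances zero; reporting uniform percents", stacklevel=2)
        percent = pd.Series(100.0 / len(mean), index=mean.index)
    else:
        percent = 100.0 * mean / total
    return ImportanceTable(per_family=df, mean=mean, percent=percent)


def group_shares(
    table: ImportanceTable, grouping: dict[str, str] | None = None
) -> dict[str, float]:
    """Percent share per variable group, plus the climate : soil+topo split.

    With no explicit grouping, variables are classified by their layer
    names (Bio* = climate; elevation/slope/aspect = topography; the rest
    soil).
    """
    if grouping is None:
        grouping = {v: layer_group(v) for v in table.percent.index}
    missing = [v for v in table.percent.index if v not in grouping]
    if missing:
        raise ValueError(f"variables without a group: {missing}")
    shares: dict[str, float] = {}
    for var, pct in table.percent.items():
        g = grouping[var]
        shares[g] = shares.get(g, 0.0) + float(pct)
    shares["soil+topography"] = shares.get("soil", 0.0) + shares.get("topography", 0.0)
    return shares
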