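"""Scenario projection and per-zone impact accounting.

Future climate surfaces are built by delta (change-factor) downscaling:
the GCM-simulated change between its own baseline and future runs is added
onto the observed baseline, keeping the observations' spatial detail while
inheriting the GCM's trend.  Projected maps are thresholded at the
baseline-fitted value, and impacts are summarized as per-zone suitable
areas, percent changes (per GCM, then averaged), overlap statistics
between zone models, and GCM direction-agreement counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from zonesdm.ensemble import EnsembleModel, predict_ensemble
from zonesdm.grids import CLIMATE_LAYERS, PRECIPITATION_LAYERS, EnvStack, SuitabilityMap

SCENARIO_IDS = ("SSP126", "SSP245", "SSP370", "SSP585")
PERIODS = ("2030s", "2050s", "2070s", "2090s")


@dataclass(frozen=True)
class ScenarioSpec:
    """One (GCM, SSP-RCP combination, period) cell of the scenario matrix."""

    gcm_id: str
    scenario_id: str
    period: str

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario {self.scenario_id!r}; expected {SCENARIO_IDS}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}; expected {PERIODS}")

    @property
    def tag(self) -> str:
        return f"{self.gcm_id}_{self.scenario_id}_{self.period}"


def delta_downscale(
    obs_baseline: EnvStack, gcm_baseline: EnvStack, gcm_future: EnvStack
) -> EnvStack:
    """future = observations + (GCM future - GCM baseline), per climate layer.

    Precipitation-type layers are floored at zero; soil and topographic
    layers pass through unchanged from the observations.
    """
    for other in (gcm_baseline, gcm_future):
        if other.shape != obs_baseline.shape:
            raise ValueError("grids of the observation and GCM stacks differ")
    climate = [n for n in obs_baseline.layer_names if n in CLIMATE_LAYERS]
    for name in climate:
        gcm_baseline.index(name)
        gcm_future.index(name)
    out = obs_baseline.copy()
    for name in climate:
        i = out.index(name)
        delta = gcm_future.layer(name) - gcm_baseline.layer(name)
        shifted = out.values[:, :, i] + delta
        if name in PRECIPITATION_LAYERS:
            shifted = np.maximum(shifted, 0.0)
        out.values[:, :, i] = shifted
    return out


def project_scenario(
    model: EnsembleModel, future: EnvStack, scope: str = "combined", scenario: str | None = None
) -> SuitabilityMap:
    """Project the ensemble onto a future stack at the frozen baseline t*."""
    if model.threshold is None:
        raise ValueError("model has no fitted binarization threshold; binarize the baseline first")
    smap = predict_ensemble(model, future, scope=scope, scenario=scenario)
    return smap.with_threshold(model.threshold)


def area_km2(smap: SuitabilityMap, zone_mask: np.ndarray | None = None) -> float:
    """Total suitable area: cell area summed over suitable masked cells."""
    if smap.binary is None:
        raise ValueError("map has no binary layer; binarize first")
    suitable = smap.binary & smap.mask
    if zone_mask is not None:
        suitable = suitable & np.asarray(zone_mask, dtype=bool)
    return float(suitable.sum() * smap.cell_area_km2)


def percent_change(future_area: float, baseline_area: float) -> float:
    """100 * (future - baseline) / baseline; NaN with a warning at baseline 0."""
    if baseline_area == 0:
        warnings.warn("baseline area is zero; percent change undefined", stacklevel=2)
        return float("nan")
    return 100.0 * (future_area - baseline_area) / baseline_area


class Agreement(NamedTuple):
    """GCM direction-agreement: size of the majority-direction camp."""

    count: int
    tie: bool
    n_positive: int
    n_negative: int
    n_zero: int


def gcm_agreement(changes: Iterable[float]) -> Agreement:
    """Count GCMs agreeing with the majority direction of change.

    Zero changes side with the majority; an exact positive/negative tie is
    flagged and the (equal) larger count reported.
    """
    changes = list(changes)
    if not changes:
        raise ValueError("need at least one change value")
    n_pos = sum(1 for c in changes if c > 0)
    n_neg = sum(1 for c in changes if c < 0)
    n_zero = len(changes) - n_pos - n_neg
    tie = n_pos == n_neg and n_pos > 0
    count = max(n_pos, n_neg) + n_zero
    return Agreement(count=count, tie=tie, n_positive=n_pos, n_negative=n_neg, n_zero=n_zero)


def zone_share_table(areas: dict[str, float]) -> pd.DataFrame:
    """Areas plus percent-of-total shares (1-decimal rounding for report).

    Full-precision percents are retained in the ``percent`` column;
    ``percent_rounded`` is the reporting value.
    """
    if any(a < 0 for a in areas.values()):
        raise ValueError("areas must be non-negative")
    total = float(sum(areas.values()))
    if total == 0:
        raise ValueError("zero total area")
    rows = [
        {
            "scope": k,
            "area_km2": float(v),
            "percent": 100.0 * v / total,
            "percent_rounded": round(100.0 * v / total, 1),
        }
        for k, v in areas.items()
    ]
    return pd.DataFrame(rows)


class OverlapStats(NamedTuple):
    overlap_km2: float
    pct_of_a: float
    pct_of_b: float


def overlap_stats(map_a: SuitabilityMap, map_b: SuitabilityMap) -> OverlapStats:
    """Intersection area of two binary maps and its share of each."""
    if map_a.binary is None or map_b.binary is None:
        raise ValueError("both maps must be binarized")
    if map_a.binary.shape != map_b.binary.shape:
        raise ValueError("maps are on different grids")
    both = map_a.binary & map_b.binary & map_a.mask & map_b.mask
    overlap = float(both.sum() * map_a.cell_area_km2)
    area_a = float((map_a.binary & map_a.mask).sum() * map_a.cell_area_km2)
    area_b = float((map_b.binary & map_b.mask).sum() * map_b.cell_area_km2)
    pct_a = 100.0 * overlap / area_a if area_a > 0 else 0.0
    pct_b = 100.0 * overlap / area_b if area_b > 0 else 0.0
    return OverlapStats(overlap_km2=overlap, pct_of_a=pct_a, pct_of_b=pct_b)


def summarize_impacts(
    baseline_area: float,
    future_areas: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Per (scenario, period) impact summary across GCMs for one scope.

    ``future_areas`` maps ``"{scenario}_{period}"`` to ``{gcm: area_km2}``.
    Percent change is computed per GCM and then averaged; spread is
    reported as min-max; agreement is the GCM direction count.
    """
    rows = []
    for key in sorted(future_areas):
        scenario, period = key.rsplit("_", 1)
        per_gcm = future_areas[key]
        changes = {g: percent_change(a, baseline_area) for g, a in per_gcm.items()}
        vals = list(changes.values())
        agree = gcm_agreement(vals)
        rows.append(
            {
                "scenario": scenario,
                "period": period,
                "baseline_area_km2": baseline_area,
                "mean_future_area_km2": float(np.mean(list(per_gcm.values()))),
                "mean_percent_change": float(np.mean(vals)),
                "min_percent_change": float(np.min(vals)),
                "max_percent_change": float(np.max(vals)),
                "gcm_agreement": agree.count,
                "gcm_tie": agree.tie,
                "n_gcms": len(per_gcm),
            }
        )
    return pd.DataFrame(rows)
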