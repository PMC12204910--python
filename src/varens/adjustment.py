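"""Analysis of method-of-adjustment data (the color and size adjustment tasks).

Each participant's adjusted iteration differences are regressed on the set
variability with both sides offset by the lowest level shown (2)::

    (adjusted_diff - 2) = intercept + slope * (d - 2) + error

so the intercept directly reads out estimated variability at the lowest level,
minus 2 — a level participants actually saw, rather than the unseen d = 0.
Back-transforming (adding 2) gives the estimated variability of a set whose
true variability is 2; values above 2 are overestimation.

Group-level estimates use the same two-stage recipe as the 2-AFC branch:
per-subject ordinary least squares, a Tukey-fence screen on the coefficient
pairs (k = 1.5 by convention for these tasks), unweighted pooling of the
surviving coefficients, and a subject-resampling percentile bootstrap.

Per-level percent bias is computed from raw per-level mean adjustments, not
from model predictions, so it reflects the data even where the linear model
bends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, InsufficientSampleError, PoolingError
from .psychometrics import tukey_fences

#: Offset applied to both sides of the regression (the lowest level shown).
OFFSET = 2.0


@dataclass(frozen=True)
class AdjustmentFit:
    """Per-subject offset-2 linear fit plus raw per-level mean adjustments."""

    participant_id: str
    intercept_offset2: float
    slope: float
    per_level_means: dict[float, float]
    n_trials: int

    @property
    def estimated_at_lowest(self) -> float:
        """Estimated variability of a set whose true variability is 2."""
        return back_transform_intercept(self.intercept_offset2)


@dataclass(frozen=True)
class PooledAdjustment:
    """Screened, pooled adjustment estimates with subject-bootstrap 95% CIs."""

    intercept_offset2: float
    slope: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    per_level_means: dict[float, float]
    n_participants: int
    excluded: tuple[str, ...]
    exclusion_reasons: dict[str, list[str]]
    n_bootstrap: int
    seed: int

    @property
    def estimated_at_lowest(self) -> float:
        return back_transform_intercept(self.intercept_offset2)


def back_transform_intercept(intercept_offset2: float, lowest_level: float = OFFSET) -> float:
    """Undo the offset-2 coding: estimated variability at the lowest level."""
    return intercept_offset2 + lowest_level


def fit_adjustment(records: pd.DataFrame, participant_id: str = "") -> AdjustmentFit:
    """OLS of ``(adjusted_diff - 2)`` on ``(d - 2)`` for one participant."""
    if not participant_id and "participant_id" in records:
        ids = records["participant_id"].unique()
        participant_id = str(ids[0]) if len(ids) == 1 else ""
    d = records["iteration_diff"].to_numpy(dtype=float)
    y = records["adjusted_diff"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise EstimationError("adjusted_diff missing on some trials")
    if len(np.unique(d)) < 2:
        raise EstimationError(
            "adjustment fit needs at least two distinct variability levels"
        )
    res = stats.linregress(d - OFFSET, y - OFFSET)
    means = (
        pd.Series(y).groupby(pd.Series(d)).mean().to_dict()
    )
    return AdjustmentFit(
        participant_id=participant_id,
        intercept_offset2=float(res.intercept),
        slope=float(res.slope),
        per_level_means={float(k): float(v) for k, v in means.items()},
        n_trials=len(d),
    )


def fit_participants(records: pd.DataFrame) -> list[AdjustmentFit]:
    return [
        fit_adjustment(group, participant_id=str(pid))
        for pid, group in records.groupby("participant_id", sort=True)
    ]


def pool_adjustment(
    fits: Sequence[AdjustmentFit],
    k_outlier: float = 1.5,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> PooledAdjustment:
    """Screen coefficient pairs at Tukey k=1.5, pool the rest, bootstrap CIs."""
    if len(fits) < 4:
        raise InsufficientSampleError(
            f"pooling needs >= 4 participant fits, got {len(fits)}"
        )
    intercepts = np.array([f.intercept_offset2 for f in fits])
    slopes = np.array([f.slope for f in fits])
    i_lo, i_hi = tukey_fences(intercepts, k_outlier)
    s_lo, s_hi = tukey_fences(slopes, k_outlier)

    keep, excluded, reasons = [], [], {}
    for f in fits:
        why = []
        if not i_lo <= f.intercept_offset2 <= i_hi:
            why.append(
                f"intercept_offset2={f.intercept_offset2:.4g} outside [{i_lo:.4g}, {i_hi:.4g}]"
            )
        if not s_lo <= f.slope <= s_hi:
            why.append(f"slope={f.slope:.4g} outside [{s_lo:.4g}, {s_hi:.4g}]")
        if why:
            excluded.append(f.participant_id)
            reasons[f.participant_id] = why
        else:
            keep.append(f)
    if not keep:
        raise PoolingError("every participant was screened out")

    kept_i = np.array([f.intercept_offset2 for f in keep])
    kept_s = np.array([f.slope for f in keep])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(keep), size=(n_bootstrap, len(keep)))
    ci_i = np.percentile(kept_i[idx].mean(axis=1), [2.5, 97.5])
    ci_s = np.percentile(kept_s[idx].mean(axis=1), [2.5, 97.5])

    levels = sorted({lv for f in keep for lv in f.per_level_means})
    pooled_means = {
        lv: float(np.mean([f.per_level_means[lv] for f in keep if lv in f.per_level_means]))
        for lv in levels
    }
    return PooledAdjustment(
        intercept_offset2=float(kept_i.mean()),
        slope=float(kept_s.mean()),
        intercept_ci=(float(ci_i[0]), float(ci_i[1])),
        slope_ci=(float(ci_s[0]), float(ci_s[1])),
        per_level_means=pooled_means,
        n_participants=len(keep),
        excluded=tuple(excluded),
        exclusion_reasons=reasons,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def percent_bias_by_level(per_level_means: Mapping[float, float]) -> dict[float, float]:
    """Signed percent bias ``(mean adjusted - d) / d * 100`` per level.

    Positive values are overestimation. Undefined (and rejected) at d = 0.
    """
    out = {}
    for d, m in sorted(per_level_means.items()):
        if d <= 0:
            raise EstimationError("percent bias undefined at zero variability")
        out[float(d)] = float((m - d) / d * 100.0)
    return out
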