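"""Psychometric-function analysis of the 2-AFC trial tables.

Per participant (and condition) a two-parameter logistic model

    P(respond "more variable") = 1 / (1 + exp(-(beta0 + beta1 * d)))

is fit by maximum likelihood to the binary responses as a function of the
iteration difference ``d``. From the coefficients we derive

* PSE  = -beta0 / beta1 — the set variability judged "more variable" half the
  time; comparing it to the point of objective equality quantifies bias,
* JND  = ln(3) / beta1 — half the 25%-75% width of the logistic, an
  inverse-sensitivity measure (lower = more sensitive).

Group-level inference uses a two-stage approximation to a random-slope
logistic mixed model: per-subject ML fits are pooled by unweighted averaging
of the coefficients, and uncertainty comes from a percentile bootstrap that
resamples subjects with replacement. Participants whose fitted measures fall
outside Tukey fences (|measure - quartile| beyond k interquartile ranges) are
screened out before pooling, as are backwards responders (negative slope).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    EstimationError,
    InsufficientSampleError,
    PoolingError,
    UndefinedJNDError,
    UndefinedPSEError,
)

logger = logging.getLogger(__name__)

LN3 = float(np.log(3.0))

#: Measures entered into outlier screening, mirroring the four fit-derived
#: quantities used to judge aberrant participants.
SCREENED_MEASURES = ("beta0", "beta1", "pse", "jnd")


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic coefficients for one participant x condition, plus PSE/JND."""

    participant_id: str
    condition: str
    beta0: float
    beta1: float
    pse: float
    jnd: float
    n_trials: int
    converged: bool


@dataclass(frozen=True)
class PooledFit:
    """Two-stage pooled psychometric estimate with a subject-bootstrap PSE CI."""

    condition: str
    beta0: float
    beta1: float
    pse: float
    jnd: float
    pse_ci: tuple[float, float]
    n_participants: int
    n_bootstrap: int
    seed: int


@dataclass(frozen=True)
class OutlierReport:
    """Which participants the Tukey-fence screen flags, and why."""

    k: float
    flags: dict[str, bool]
    reasons: dict[str, list[str]]
    fences: dict[tuple[str, str], tuple[float, float]]

    @property
    def flagged(self) -> list[str]:
        return sorted(p for p, f in self.flags.items() if f)

    @property
    def kept(self) -> list[str]:
        return sorted(p for p, f in self.flags.items() if not f)


def _as_xy(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        d = trials["iteration_diff"].to_numpy(dtype=float)
        y = (trials["response"].to_numpy() == "more").astype(int)
    else:
        arr = np.asarray(list(trials), dtype=float)
        d, y = arr[:, 0], arr[:, 1].astype(int)
    return d, y


def fit_logistic(
    trials, participant_id: str = "", condition: str = ""
) -> PsychometricFit:
    """Maximum-likelihood logistic fit of P("more") against iteration difference.

    Accepts a trial DataFrame (columns ``iteration_diff``, ``response``) or an
    iterable of ``(d, binary response)`` pairs. Fitting uses iteratively
    reweighted least squares on per-level aggregated counts (log-likelihood
    tolerance 1e-8, at most 100 iterations).

    Completely separated data — every "less" below every "more" — admit no
    finite ML estimate; the fit is flagged non-converged and carries a
    sign-correct infinite slope with the PSE at the separating midpoint, the
    deterministic-observer limit.
    """
    d, y = _as_xy(trials)
    levels = np.unique(d)
    if len(levels) < 2:
        raise EstimationError("need at least two distinct variability levels")
    if y.min() == y.max():
        raise EstimationError("responses contain a single class; slope inestimable")

    less_max, more_min = d[y == 0].max(), d[y == 1].min()
    if less_max < more_min:  # complete separation, ascending
        pse = (less_max + more_min) / 2.0
        return PsychometricFit(participant_id, condition, -np.inf, np.inf,
                               float(pse), 0.0, len(d), converged=False)
    more_max, less_min = d[y == 1].max(), d[y == 0].min()
    if more_max < less_min:  # complete separation, backwards responder
        pse = (more_max + less_min) / 2.0
        return PsychometricFit(participant_id, condition, np.inf, -np.inf,
                               float(pse), np.nan, len(d), converged=False)

    # aggregate to per-level success counts: identical likelihood, cheaper IRLS
    n_per = np.array([np.sum(d == lv) for lv in levels], dtype=float)
    k_per = np.array([np.sum(y[d == lv]) for lv in levels], dtype=float)
    exog = sm.add_constant(levels)
    endog = np.column_stack([k_per, n_per - k_per])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8
            )
            beta0, beta1 = (float(b) for b in res.params)
            converged = bool(getattr(res, "converged", True))
        except Exception:  # numerically degenerate (e.g. quasi-separation)
            beta0, beta1, converged = np.nan, np.nan, False

    if converged and beta1 != 0 and np.isfinite(beta1):
        pse = -beta0 / beta1
        jnd = LN3 / beta1 if beta1 > 0 else np.nan
    else:
        pse, jnd = np.nan, np.nan
    return PsychometricFit(participant_id, condition, beta0, beta1,
                           float(pse), float(jnd), len(d), converged)


def derive_pse(fit: PsychometricFit) -> float:
    """The iteration difference at which the fit predicts P("more") = 0.5."""
    if np.isinf(fit.beta1):
        return fit.pse  # separation sentinel: midpoint stored at fit time
    if fit.beta1 == 0 or not np.isfinite(fit.beta1):
        raise UndefinedPSEError("PSE undefined for a flat psychometric function")
    return -fit.beta0 / fit.beta1


def derive_jnd(fit: PsychometricFit) -> float:
    """Half the 25%-75% width of the logistic: ln(3)/beta1."""
    if fit.beta1 == np.inf:
        return 0.0
    if not (np.isfinite(fit.beta1) and fit.beta1 > 0):
        raise UndefinedJNDError("JND undefined for a non-increasing fit")
    return LN3 / fit.beta1


def tukey_fences(values: Sequence[float], k: float) -> tuple[float, float]:
    """``(Q1 - k*IQR, Q3 + k*IQR)`` with linearly interpolated quartiles."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    q1, q3 = np.percentile(vals, [25, 75])  # type-7 linear interpolation
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def screen_outliers(fits: Sequence[PsychometricFit], k: float = 3.0) -> OutlierReport:
    """Tukey-fence screen over beta0, beta1, PSE and JND, per condition.

    A participant is flagged when any measure in any of their condition fits
    lies outside ``[Q1 - k*IQR, Q3 + k*IQR]`` (fences computed across
    participants within the condition), or when they respond backwards
    (negative slope) — a supplementary sign check, since a backwards but
    otherwise typical-magnitude slope can sit inside the fences.
    """
    if k <= 0:
        raise InsufficientSampleError("fence multiplier k must be positive")
    participants = sorted({f.participant_id for f in fits})
    if len(participants) < 4:
        raise InsufficientSampleError(
            f"outlier screening needs >= 4 participants, got {len(participants)}"
        )
    flags = {p: False for p in participants}
    reasons: dict[str, list[str]] = {p: [] for p in participants}
    fences: dict[tuple[str, str], tuple[float, float]] = {}

    for condition in sorted({f.condition for f in fits}):
        cond_fits = [f for f in fits if f.condition == condition]
        for measure in SCREENED_MEASURES:
            vals = [getattr(f, measure) for f in cond_fits]
            lo, hi = tukey_fences(vals, k)
            fences[(condition, measure)] = (lo, hi)
            for f in cond_fits:
                v = getattr(f, measure)
                if np.isnan(v):
                    continue
                if v < lo or v > hi:
                    flags[f.participant_id] = True
                    reasons[f.participant_id].append(
                        f"{condition}/{measure}={v:.4g} outside [{lo:.4g}, {hi:.4g}]"
                    )
        for f in cond_fits:
            if f.beta1 < 0:
                flags[f.participant_id] = True
                reasons[f.participant_id].append(
                    f"{condition}/backwards responder (beta1={f.beta1:.4g} < 0)"
                )
    return OutlierReport(k=k, flags=flags, reasons=reasons, fences=fences)


def _pooled_point(beta0s: np.ndarray, beta1s: np.ndarray) -> tuple[float, float, float]:
    b0, b1 = float(beta0s.mean()), float(beta1s.mean())
    pse = -b0 / b1 if b1 != 0 else np.nan
    return b0, b1, pse


def pool_fits(
    fits: Sequence[PsychometricFit],
    n_bootstrap: int = 2000,
    seed: int = 0,
    condition: str = "",
) -> PooledFit:
    """Unweighted coefficient pooling across subjects with a bootstrap PSE CI.

    The pooled curve uses the mean intercept and mean slope of the converged
    per-subject fits (the fixed-effect analogue of a random-slope logistic
    mixed model under the two-stage approximation). The 95% CI on the pooled
    PSE is a seeded percentile bootstrap resampling subjects with replacement.
    """
    usable = [f for f in fits if f.converged and np.isfinite(f.beta1)]
    if not usable:
        raise PoolingError("no converged participant fits to pool")
    if not condition:
        conds = {f.condition for f in usable}
        condition = conds.pop() if len(conds) == 1 else "pooled"
    beta0s = np.array([f.beta0 for f in usable])
    beta1s = np.array([f.beta1 for f in usable])
    b0, b1, pse = _pooled_point(beta0s, beta1s)
    jnd = LN3 / b1 if b1 > 0 else np.nan

    rng = np.random.default_rng(seed)
    n = len(usable)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    bs_b0 = beta0s[idx].mean(axis=1)
    bs_b1 = beta1s[idx].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bs_pse = -bs_b0 / bs_b1
    lo, hi = np.nanpercentile(bs_pse, [2.5, 97.5])
    return PooledFit(condition, b0, b1, float(pse), float(jnd),
                     (float(lo), float(hi)), n, n_bootstrap, seed)


@dataclass(frozen=True)
class SplitResult:
    """Pooled fits for the two halves of a within-participant split."""

    splitter: str
    first: PooledFit
    second: PooledFit
    pse_diff: float                 # second - first
    pse_diff_ci: tuple[float, float]
    dropped: tuple[str, ...]


def _fit_half(group: pd.DataFrame, pid: str) -> Optional[PsychometricFit]:
    try:
        return fit_logistic(group, participant_id=pid)
    except EstimationError as err:
        logger.warning("participant %s dropped from split: %s", pid, err)
        return None


def split_analysis(
    records: pd.DataFrame,
    splitter: str,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> SplitResult:
    """Median-RT or first/second-half split, pooled separately per half.

    ``median_rt`` puts each participant's strictly-below-median-RT trials in
    the first half (their faster responses); ``half_by_trial_index`` splits
    each participant's trials by within-participant presentation order.
    Participants with an empty or single-class half are dropped with a logged
    warning. The CI on the PSE difference (second minus first) comes from a
    paired bootstrap: the same subject resample is applied to both halves.
    """
    if splitter not in ("median_rt", "half_by_trial_index"):
        raise EstimationError(f"unknown splitter {splitter!r}")
    if splitter == "median_rt" and records["rt_ms"].isna().any():
        raise EstimationError("median_rt split requires RTs on every trial")

    first_fits, second_fits, dropped = [], [], []
    for pid, group in records.groupby("participant_id", sort=True):
        group = group.sort_values(["block", "trial_index"], kind="stable")
        if splitter == "median_rt":
            med = group["rt_ms"].median()
            mask_first = (group["rt_ms"] < med).to_numpy()
        else:
            mask_first = np.arange(len(group)) < len(group) // 2
        g_first, g_second = group[mask_first], group[~mask_first]
        if len(g_first) == 0 or len(g_second) == 0:
            logger.warning("participant %s dropped from split: empty half", pid)
            dropped.append(pid)
            continue
        f1, f2 = _fit_half(g_first, pid), _fit_half(g_second, pid)
        if f1 is None or f2 is None or not (f1.converged and f2.converged):
            dropped.append(pid)
            continue
        first_fits.append(f1)
        second_fits.append(f2)

    if not first_fits:
        raise PoolingError("no participants usable for the split analysis")

    b0_1 = np.array([f.beta0 for f in first_fits])
    b1_1 = np.array([f.beta1 for f in first_fits])
    b0_2 = np.array([f.beta0 for f in second_fits])
    b1_2 = np.array([f.beta1 for f in second_fits])

    rng = np.random.default_rng(seed)
    n = len(first_fits)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        pse1 = -b0_1[idx].mean(axis=1) / b1_1[idx].mean(axis=1)
        pse2 = -b0_2[idx].mean(axis=1) / b1_2[idx].mean(axis=1)
    diff = pse2 - pse1

    def _pooled(b0s, b1s, bs_pse, label) -> PooledFit:
        b0, b1, pse = _pooled_point(b0s, b1s)
        lo, hi = np.nanpercentile(bs_pse, [2.5, 97.5])
        return PooledFit(label, b0, b1, float(pse),
                         LN3 / b1 if b1 > 0 else np.nan,
                         (float(lo), float(hi)), n, n_bootstrap, seed)

    lo_d, hi_d = np.nanpercentile(diff, [2.5, 97.5])
    point_diff = _pooled_point(b0_2, b1_2)[2] - _pooled_point(b0_1, b1_1)[2]
    return SplitResult(
        splitter=splitter,
        first=_pooled(b0_1, b1_1, pse1, f"{splitter}:first"),
        second=_pooled(b0_2, b1_2, pse2, f"{splitter}:second"),
        pse_diff=float(point_diff),
        pse_diff_ci=(float(lo_d), float(hi_d)),
        dropped=tuple(dropped),
    )


def fit_participants(
    records: pd.DataFrame, by_condition: bool = True
) -> list[PsychometricFit]:
    """Per-participant (and optionally per-condition) logistic fits.

    The condition label is the color channel for color experiments and the
    set mean for size experiments.
    """
    fits = []
    for pid, group in records.groupby("participant_id", sort=True):
        if by_condition:
            for cond, sub in group.groupby(condition_labels(group), sort=True):
                fits.append(fit_logistic(sub, participant_id=pid, condition=str(cond)))
        else:
            fits.append(fit_logistic(group, participant_id=pid, condition="all"))
    return fits


def condition_labels(records: pd.DataFrame) -> pd.Series:
    """Condition label per row: channel for color, mean size otherwise."""
    is_color = records["feature"] == "color_value"
    labels = np.where(
        is_color,
        records["channel"].astype(str),
        "mean=" + records["mean_value"].map(lambda v: f"{float(v):g}"),
    )
    return pd.Series(labels, index=records.index, name="condition")
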