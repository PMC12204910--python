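"""Synthetic observers for the ensemble-variability tasks.

An observer forms a noisy percept of a set's iteration difference ``d``::

    v_hat = D(d) + eps,   eps ~ Normal(0, sigma^2),  floored at 0

where the deterministic distortion ``D`` is one of four families motivated by
candidate mechanisms for the variability-overestimation effect:

``veridical``
    ``D(d) = d`` — an unbiased observer.
``linear``
    ``D(d) = a + b*d`` — constant offset plus gain; with ``b < 1`` this yields
    overestimation at low ``d`` that shrinks (and eventually reverses) as ``d``
    grows, the signature pattern of the effect.
``boundary``
    ``D(d) = d + k*exp(-d/tau)`` — additive repulsion from the "sameness"
    category boundary at ``d = 0``, strongest for the most similar sets.
``central_tendency``
    ``D(d) = (1-w)*d + w*anchor`` — shrinkage toward the mean of the
    experienced stimulus distribution (anchor 9 for levels 2..16).

For 2-AFC tasks the observer answers "more variable" when the percept exceeds
a fixed criterion (by default the midpoint of the two comparison variabilities,
or the stimulus mean for verbal labels); for adjustment tasks the percept is
rounded to the response grid and clipped to the adjustable range. Response
times are lognormal and stochastically faster the further the percept is from
the criterion.

All randomness flows through explicit :class:`numpy.random.Generator` states;
a simulation is fully reproducible from ``(design.seed, observer.seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd

from . import design as _design
from .errors import DomainError, UnsupportedDesignError

DISTORTIONS = ("veridical", "linear", "boundary", "central_tendency")

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one synthetic observer.

    Defaults describe a realistic unbiased participant: internal noise of
    3 iteration-difference units (matching human-scale discrimination widths
    of roughly 2 units), a 2% lapse rate, and ~800 ms median response times.
    """

    distortion: str = "veridical"
    a: float = 0.0          # linear offset (feature units)
    b: float = 1.0          # linear gain (unitless, > 0)
    k: float = 0.0          # boundary repulsion magnitude (feature units)
    tau: float = 4.0        # boundary repulsion scale (feature units, > 0)
    w: float = 0.0          # central-tendency shrink weight in [0, 1]
    anchor: float = 9.0     # central-tendency anchor (mean stimulus level)
    sigma: float = 3.0      # internal noise SD (feature units)
    lapse: float = 0.02     # probability of a stimulus-independent coin flip
    criterion: float | None = None  # 2-AFC decision point; None = task default
    rt_mu: float = 6.7      # lognormal location: exp(6.7) ~ 812 ms
    rt_sigma: float = 0.35  # lognormal scale
    rt_slope: float = 0.04  # RT speed-up per unit percept-criterion distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distortion not in DISTORTIONS:
            raise DomainError(f"unknown distortion {self.distortion!r}")
        if self.sigma < 0:
            raise DomainError("sigma must be non-negative")
        if not 0.0 <= self.lapse <= 0.5:
            raise DomainError("lapse must lie in [0, 0.5]")
        if self.b <= 0:
            raise DomainError("gain b must be positive")
        if self.tau <= 0:
            raise DomainError("tau must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise DomainError("shrink weight w must lie in [0, 1]")


def distortion_mean(d: ArrayLike, params: ObserverParams) -> ArrayLike:
    """The noiseless distorted percept ``D(d)`` (deterministic given params)."""
    d = np.asarray(d, dtype=float)
    if params.distortion == "veridical":
        out = d.copy()
    elif params.distortion == "linear":
        out = params.a + params.b * d
    elif params.distortion == "boundary":
        out = d + params.k * np.exp(-d / params.tau)
    else:  # central_tendency
        out = (1.0 - params.w) * d + params.w * params.anchor
    return out if out.ndim else float(out)


def perceived_variability(
    d: ArrayLike, params: ObserverParams, rng: np.random.Generator
) -> ArrayLike:
    """Noisy percept ``D(d) + Normal(0, sigma^2)``, floored at zero."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise DomainError("iteration difference must be positive")
    v = np.asarray(distortion_mean(d_arr, params), dtype=float)
    if params.sigma > 0:
        v = v + rng.normal(0.0, params.sigma, size=d_arr.shape)
    v = np.maximum(v, 0.0)
    return v if np.ndim(d) else float(v)


def decide_2afc(
    v_hat: ArrayLike, params: ObserverParams, rng: np.random.Generator
) -> Union[str, np.ndarray]:
    """2-AFC choice: "more" iff the percept exceeds the criterion.

    Exact ties are resolved by a fair coin, and with probability ``lapse`` the
    whole choice is replaced by a fair coin (the standard lapse convention).
    """
    if params.criterion is None:
        raise DomainError("decide_2afc needs an explicit criterion")
    v = np.atleast_1d(np.asarray(v_hat, dtype=float))
    more = v > params.criterion
    ties = v == params.criterion
    if ties.any():
        more = np.where(ties, rng.random(v.shape) < 0.5, more)
    if params.lapse > 0:
        lapsed = rng.random(v.shape) < params.lapse
        coin = rng.random(v.shape) < 0.5
        more = np.where(lapsed, coin, more)
    out = np.where(more, "more", "less")
    return out if np.ndim(v_hat) else str(out[0])


def adjust_response(
    v_hat: ArrayLike, spec: _design.AdjustmentSpec, rng: np.random.Generator | None = None
) -> ArrayLike:
    """Ideal adjustment: round the percept to the key-press grid and clip.

    Rounding is round-half-even, which is unbiased under symmetric noise. The
    response is independent of the counterbalanced starting variability; the
    rng argument is accepted for interface symmetry (and future anchoring
    models) but unused.
    """
    v = np.asarray(v_hat, dtype=float)
    snapped = np.round(v / spec.step) * spec.step
    clipped = np.clip(snapped, spec.min_diff, spec.max_diff)
    return clipped if v.ndim else float(clipped)


def simulate_rt(
    v_hat: ArrayLike, params: ObserverParams, rng: np.random.Generator
) -> ArrayLike:
    """Lognormal response time in ms, faster for easier (far-from-criterion) percepts."""
    v = np.asarray(v_hat, dtype=float)
    c = params.criterion if params.criterion is not None else params.anchor
    mu = params.rt_mu - params.rt_slope * np.abs(v - c)
    rt = np.exp(rng.normal(mu, params.rt_sigma, size=v.shape))
    return rt if v.ndim else float(rt)


def default_criterion(design: _design.ExperimentDesign) -> float:
    """Task-implied neutral decision point.

    Visual 2-AFC: midpoint of the two comparison variabilities. Verbal 2-AFC
    and adjustment: the mean stimulus level (there is no visual reference).
    """
    if design.response_mode == "afc_visual":
        return design.comparison.midpoint  # type: ignore[union-attr]
    return float(np.mean(design.levels))


def _participant_id(index: int) -> str:
    return f"s{index + 1:03d}"


def simulate_observer(
    design: _design.ExperimentDesign, params: ObserverParams, participant_id: str
) -> pd.DataFrame:
    """Trial records for a single observer run through the full design."""
    ss = np.random.SeedSequence(entropy=[design.seed & 0x7FFFFFFF, params.seed & 0x7FFFFFFF])
    order_ss, resp_ss = ss.spawn(2)
    order_seed = int(order_ss.generate_state(1)[0] % (2**31))
    trials = _design.enumerate_trials(_design.with_seed(design, order_seed))
    rng = np.random.default_rng(resp_ss)

    eff = params if params.criterion is not None else replace(
        params, criterion=default_criterion(design)
    )
    d = trials["iteration_diff"].to_numpy()
    v_hat = perceived_variability(d, eff, rng)
    if design.response_mode == "adjustment":
        response = np.full(len(trials), "", dtype=object)
        adjusted = adjust_response(v_hat, design.comparison, rng)  # type: ignore[arg-type]
    else:
        response = decide_2afc(v_hat, eff, rng)
        adjusted = np.full(len(trials), np.nan)
    rt = simulate_rt(v_hat, eff, rng)

    out = trials.copy()
    out.insert(0, "experiment_id", design.experiment_id)
    out.insert(1, "participant_id", participant_id)
    out["response"] = response
    out["adjusted_diff"] = adjusted
    out["rt_ms"] = np.round(rt, 1)
    return out


def simulate_experiment(
    design: _design.ExperimentDesign, observers: Sequence[ObserverParams]
) -> pd.DataFrame:
    """Simulate every observer through the design; one row per observer x trial."""
    frames = [
        simulate_observer(design, obs, _participant_id(i))
        for i, obs in enumerate(observers)
    ]
    if not frames:
        from .cli_io import TRIAL_COLUMNS

        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def make_observers(
    n: int,
    spec: dict | None = None,
    seed: int = 0,
    **overrides,
) -> list[ObserverParams]:
    """Build an observer population from a flat parameter spec.

    Each entry of ``spec`` maps an :class:`ObserverParams` field to either a
    constant or ``{"mean": m, "sd": s}`` for a Normal population distribution
    (sampled once per observer, truncated to the field's legal range).
    """
    if n < 0:
        raise UnsupportedDesignError("observer count must be non-negative")
    spec = dict(spec or {})
    spec.update(overrides)
    ss = np.random.SeedSequence(seed)
    pop_rng = np.random.default_rng(ss)
    obs_seeds = ss.generate_state(n + 1)[1:] % (2**31)

    bounds = {
        "sigma": (0.0, np.inf),
        "lapse": (0.0, 0.5),
        "b": (1e-9, np.inf),
        "tau": (1e-9, np.inf),
        "w": (0.0, 1.0),
    }
    observers = []
    for i in range(n):
        kwargs = {}
        for name, value in spec.items():
            if isinstance(value, dict):
                draw = pop_rng.normal(value["mean"], value.get("sd", 0.0))
                lo, hi = bounds.get(name, (-np.inf, np.inf))
                draw = float(np.clip(draw, lo, hi))
                kwargs[name] = draw
            else:
                kwargs[name] = value
        kwargs["seed"] = int(obs_seeds[i])
        observers.append(ObserverParams(**kwargs))
    return observers
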