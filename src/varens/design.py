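"""Stimulus construction and trial enumeration for the six ensemble-variability experiments.

Each experiment shows nine-item "target sets" whose items form an arithmetic
sequence around a fixed mean; the constant increment between adjacent items is
the *iteration difference* ``d``, the operational measure of set variability.
Observers then report perceived variability either by a two-alternative forced
choice between a low- and a high-variability comparison set (visual or verbal
labels) or by adjusting a comparison set (method of adjustment).

Presets E1-E6 reproduce the published factorial designs:

=====  ============  ===========  ==========================  ===============
 id    feature       response     conditions                  trials
=====  ============  ===========  ==========================  ===============
 E1    color value   2-AFC        R/G/B channel, mean 130     6 x 48 = 288
 E2    color value   2-AFC text   R/G/B channel, mean 130     6 x 48 = 288
 E3    color value   adjustment   G channel, mean 130         4 x 32 = 128
 E4    size (px)     2-AFC        mean 100 / 150 / 200        3 x 96 = 288
 E5    size (px)     2-AFC text   mean 100 / 150 / 200        3 x 96 = 288
 E6    size (px)     adjustment   mean 100                    4 x 32 = 128
=====  ============  ===========  ==========================  ===============
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DomainError, UnsupportedDesignError

#: The eight variability levels used by every experiment.
LEVELS: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16)

RGB_MIN, RGB_MAX = 0.0, 255.0


@dataclass(frozen=True)
class FeatureSpec:
    """The varied visual feature of one condition.

    Parameters
    ----------
    feature
        ``"color_value"`` (a single RGB channel intensity, 0-255) or
        ``"size"`` (circle diameter in pixels).
    channel
        ``"R"``, ``"G"`` or ``"B"`` for color; ``"none"`` for size.
    mean_value
        The fixed arithmetic mean of every target set in this condition.
    """

    feature: str
    channel: str
    mean_value: float

    def __post_init__(self) -> None:
        if self.feature not in ("color_value", "size"):
            raise DomainError(f"unknown feature {self.feature!r}")
        if self.feature == "size":
            if self.channel != "none":
                raise DomainError("size stimuli carry no color channel")
            if self.mean_value <= 0:
                raise DomainError("size mean must be positive")
        else:
            if self.channel not in ("R", "G", "B"):
                raise DomainError(f"invalid color channel {self.channel!r}")
            if not (RGB_MIN <= self.mean_value <= RGB_MAX):
                raise DomainError(
                    f"color mean {self.mean_value} outside [{RGB_MIN:g}, {RGB_MAX:g}]"
                )

    def check_value(self, value: float) -> None:
        """Raise :class:`DomainError` if *value* is outside the feature bounds."""
        if self.feature == "color_value":
            if not (RGB_MIN <= value <= RGB_MAX):
                raise DomainError(
                    f"color value {value:g} outside [{RGB_MIN:g}, {RGB_MAX:g}]"
                )
        elif value <= 0:
            raise DomainError(f"size value {value:g} is not positive")


@dataclass(frozen=True)
class ComparisonSpec:
    """The two five-item 2-AFC comparison sets (low and high variability).

    ``center`` is the value the comparison sequences are built around; when
    ``None`` the target-set mean of the current condition is used, which keeps
    the mean constant so that only variability differs between options.
    """

    n_items: int = 5
    low_diff: float = 6.0
    high_diff: float = 18.0
    center: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_items != 5:
            raise UnsupportedDesignError("comparison sets contain five items")
        if not self.low_diff < self.high_diff:
            raise DomainError("low comparison variability must be below the high one")

    @property
    def midpoint(self) -> float:
        return (self.low_diff + self.high_diff) / 2.0


@dataclass(frozen=True)
class AdjustmentSpec:
    """Key-press adjustment of a comparison set's iteration difference.

    ``initial_diffs`` are the two counterbalanced starting variabilities
    (low start, high start). A start outside ``[min_diff, max_diff]`` is legal
    (the high start of the size task exceeds the ceiling) and is clipped on the
    first render.
    """

    initial_diffs: tuple[float, float] = (2.0, 20.0)
    step: float = 1.0
    min_diff: float = 1.0
    max_diff: float = 31.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise DomainError("adjustment step must be positive")
        if self.min_diff > self.max_diff:
            raise DomainError("min_diff exceeds max_diff")
        lo, hi = self.initial_diffs
        if not lo < hi:
            raise DomainError("initial_diffs must be (low start, high start)")


@dataclass(frozen=True)
class ExperimentDesign:
    experiment_id: str
    response_mode: str  # afc_visual | afc_verbal | adjustment
    conditions: tuple[FeatureSpec, ...]
    repetitions_per_block: int
    n_blocks: int
    comparison: Union[ComparisonSpec, AdjustmentSpec, None]
    levels: tuple[int, ...] = LEVELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response_mode not in ("afc_visual", "afc_verbal", "adjustment"):
            raise UnsupportedDesignError(
                f"unknown response mode {self.response_mode!r}"
            )
        if self.response_mode == "adjustment" and not isinstance(
            self.comparison, AdjustmentSpec
        ):
            raise UnsupportedDesignError("adjustment designs need an AdjustmentSpec")
        if self.response_mode == "afc_visual" and not isinstance(
            self.comparison, ComparisonSpec
        ):
            raise UnsupportedDesignError("visual 2-AFC designs need a ComparisonSpec")

    @property
    def trials_per_block(self) -> int:
        n = len(self.levels) * len(self.conditions) * self.repetitions_per_block
        if self.response_mode == "adjustment":
            n *= len(self.comparison.initial_diffs)  # type: ignore[union-attr]
        return n

    @property
    def n_trials(self) -> int:
        return self.trials_per_block * self.n_blocks


def generate_target_values(
    spec: FeatureSpec, iteration_diff: float, n_items: int = 9
) -> np.ndarray:
    """The canonical (ascending) target-set values ``mean + k*d``.

    ``k`` runs from ``-(n-1)/2`` to ``+(n-1)/2`` so the arithmetic mean equals
    ``spec.mean_value`` exactly and the range equals ``(n-1)*d``. Presentation
    shuffling is a separate concern (see :func:`shuffle_presentation`).
    """
    if n_items % 2 == 0:
        raise UnsupportedDesignError(
            f"target sets need an odd item count to keep the mean on-grid, got {n_items}"
        )
    if iteration_diff <= 0:
        raise DomainError("iteration difference must be positive")
    half = (n_items - 1) // 2
    values = spec.mean_value + iteration_diff * np.arange(-half, half + 1, dtype=float)
    for v in (values[0], values[-1]):
        spec.check_value(v)
    return values


def generate_comparison_values(
    spec: FeatureSpec, comparison: ComparisonSpec, which: str, center: Optional[float] = None
) -> np.ndarray:
    """Values of the five-item low- or high-variability comparison set."""
    if which not in ("low", "high"):
        raise UnsupportedDesignError(f"which must be 'low' or 'high', got {which!r}")
    diff = comparison.low_diff if which == "low" else comparison.high_diff
    c = center if center is not None else comparison.center
    if c is None:
        c = spec.mean_value
    half = (comparison.n_items - 1) // 2
    values = c + diff * np.arange(-half, half + 1, dtype=float)
    for v in (values[0], values[-1]):
        spec.check_value(v)
    return values


def shuffle_presentation(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random presentation order of the target items for one trial."""
    return rng.permutation(values)


#: Columns of an enumerated trial design, in serialization order.
TRIAL_DESIGN_COLUMNS = [
    "block",
    "trial_index",
    "feature",
    "channel",
    "mean_value",
    "iteration_diff",
    "comparison_low",
    "comparison_high",
    "initial_adjustment_diff",
]


def enumerate_trials(design: ExperimentDesign) -> pd.DataFrame:
    """Full factorial trial list, independently shuffled within each block.

    The shuffle is driven entirely by ``design.seed``; the same seed yields
    the same order. ``trial_index`` restarts at 0 inside each block.
    """
    if design.response_mode == "adjustment":
        initials: Sequence[Optional[float]] = design.comparison.initial_diffs  # type: ignore[union-attr]
    else:
        initials = [None]
    cells = list(
        itertools.product(design.conditions, design.levels, initials,
                          range(design.repetitions_per_block))
    )
    rng = np.random.default_rng(design.seed)
    rows = []
    for block in range(design.n_blocks):
        order = rng.permutation(len(cells))
        for idx, cell_i in enumerate(order):
            cond, level, initial, _rep = cells[cell_i]
            if isinstance(design.comparison, ComparisonSpec):
                lo, hi = design.comparison.low_diff, design.comparison.high_diff
            else:
                lo = hi = np.nan
            rows.append(
                (block, idx, cond.feature, cond.channel, cond.mean_value,
                 float(level), lo, hi,
                 np.nan if initial is None else float(initial))
            )
    return pd.DataFrame(rows, columns=TRIAL_DESIGN_COLUMNS)


def _color_conditions(channels: str = "RGB", mean: float = 130.0) -> tuple[FeatureSpec, ...]:
    return tuple(FeatureSpec("color_value", ch, mean) for ch in channels)


def _size_conditions(means: Sequence[float]) -> tuple[FeatureSpec, ...]:
    return tuple(FeatureSpec("size", "none", m) for m in means)


_PRESETS = {
    "E1": dict(
        response_mode="afc_visual",
        conditions=_color_conditions(),
        repetitions_per_block=2,
        n_blocks=6,
        comparison=ComparisonSpec(),
    ),
    "E2": dict(
        response_mode="afc_verbal",
        conditions=_color_conditions(),
        repetitions_per_block=2,
        n_blocks=6,
        comparison=None,
    ),
    "E3": dict(
        response_mode="adjustment",
        conditions=_color_conditions("G"),
        repetitions_per_block=2,
        n_blocks=4,
        comparison=AdjustmentSpec((2.0, 20.0), step=1.0, min_diff=1.0, max_diff=31.0),
    ),
    "E4": dict(
        response_mode="afc_visual",
        conditions=_size_conditions((100.0, 150.0, 200.0)),
        repetitions_per_block=4,
        n_blocks=3,
        comparison=ComparisonSpec(),
    ),
    "E5": dict(
        response_mode="afc_verbal",
        conditions=_size_conditions((100.0, 150.0, 200.0)),
        repetitions_per_block=4,
        n_blocks=3,
        comparison=None,
    ),
    "E6": dict(
        response_mode="adjustment",
        conditions=_size_conditions((100.0,)),
        repetitions_per_block=2,
        n_blocks=4,
        comparison=AdjustmentSpec((2.0, 40.0), step=1.0, min_diff=0.0, max_diff=24.0),
    ),
}

EXPERIMENT_IDS = tuple(_PRESETS)


def preset(experiment_id: str, seed: int = 0) -> ExperimentDesign:
    """Published design for one of the experiments ``E1``-``E6``."""
    try:
        kwargs = _PRESETS[experiment_id]
    except KeyError:
        raise UnsupportedDesignError(
            f"unknown experiment {experiment_id!r}; choose from {EXPERIMENT_IDS}"
        ) from None
    return ExperimentDesign(experiment_id=experiment_id, seed=seed, **kwargs)


def with_seed(design: ExperimentDesign, seed: int) -> ExperimentDesign:
    return replace(design, seed=seed)
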