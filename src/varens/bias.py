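"""Points of objective equality and percent-bias statistics.

The point of objective equality (POE) is the veridical neutral variability an
unbiased observer's PSE should sit at. Two conventions are supported:

* ``visual_midpoint`` — the mean of the two 2-AFC comparison variabilities
  (12 for the standard 6/18 pair); applicable when the response options are
  visual sets.
* ``stimulus_mean`` — the mean iteration difference across the design levels
  (9 for levels 2..16); the only option for verbal labels, and the more
  conservative choice overall.

Percent bias standardizes the discrepancy between estimated and actual
variability so it can be compared across features and tasks::

    percent_bias = |estimated - actual| / actual * 100

The absolute form cannot express the direction of the effect, so a signed
companion ``(estimated - actual)/actual * 100`` (positive = overestimation)
is reported by default. For 2-AFC summaries the estimate enters as the PSE
and the actual as the POE, with the sign flipped so that a PSE *below* the
POE — the observer needing less true variability to say "more variable" —
counts as overestimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import DomainError

POE_KINDS = ("visual_midpoint", "stimulus_mean")


class PercentBias(NamedTuple):
    absolute: float
    signed: float


def poe_visual(low_diff: float, high_diff: float) -> float:
    """POE of a visual 2-AFC pair: the mean of the two comparison variabilities."""
    if not low_diff < high_diff:
        raise DomainError("low comparison variability must be below the high one")
    return (low_diff + high_diff) / 2.0


def poe_stimulus_mean(levels: Sequence[float]) -> float:
    """POE as the mean iteration difference across the design levels."""
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise DomainError("levels must be non-empty")
    return float(levels.mean())


def percent_bias(estimated: float, actual: float) -> PercentBias:
    """Absolute and signed percent bias of an estimate against truth."""
    if actual <= 0:
        raise DomainError("actual variability must be positive")
    signed = (estimated - actual) / actual * 100.0
    return PercentBias(absolute=abs(signed), signed=signed)


def percent_bias_2afc(poe: float, pse: float) -> PercentBias:
    """Percent bias of a 2-AFC PSE against a POE (positive = overestimation).

    The observer's *estimate* of the neutral point is the PSE; a PSE below the
    POE means sets were judged more variable than they were, so the signed
    bias is ``(POE - PSE)/POE * 100``.
    """
    if poe <= 0:
        raise DomainError("POE must be positive")
    signed = (poe - pse) / poe * 100.0
    return PercentBias(absolute=abs(signed), signed=signed)


@dataclass(frozen=True)
class BiasSummary:
    """PSE-vs-POE comparison for one condition under one POE convention."""

    condition: str
    pse: float
    poe: float
    poe_kind: str
    percent_bias_abs: float
    percent_bias_signed: float


def summarize_2afc(
    condition: str,
    pse: float,
    levels: Sequence[float],
    comparison_low: Optional[float] = None,
    comparison_high: Optional[float] = None,
    poe_kind: str = "both",
) -> list[BiasSummary]:
    """Bias summaries for a pooled 2-AFC PSE under the requested POE convention(s)."""
    if poe_kind not in POE_KINDS + ("both",):
        raise DomainError(f"unknown POE convention {poe_kind!r}")
    rows = []
    wanted = POE_KINDS if poe_kind == "both" else (poe_kind,)
    for kind in wanted:
        if kind == "visual_midpoint":
            if comparison_low is None or comparison_high is None:
                continue  # verbal task: no visual reference exists
            poe = poe_visual(comparison_low, comparison_high)
        else:
            poe = poe_stimulus_mean(levels)
        pb = percent_bias_2afc(poe, pse)
        rows.append(
            BiasSummary(condition, float(pse), float(poe), kind,
                        pb.absolute, pb.signed)
        )
    return rows
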