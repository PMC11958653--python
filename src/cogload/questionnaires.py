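"""NASA-TLX and short-DSSQ scoring.

The NASA-TLX rates six workload subscales (mental, physical, temporal
demand, performance, effort, frustration) on 0-100.  The overall
cognitive load is the unweighted mean of the six in raw (RTLX) mode, or
the pairwise-weight average in weighted mode.  Performance is entered
as rated — on this instrument a higher performance rating means *worse*
self-assessed performance, so it contributes to workload in the same
direction as the other subscales; reversing it is a display-only
transform for radar charts.

The short DSSQ yields three state scores (engagement, distress, worry),
each the sum of eight 0-4 items, hence bounded on [0, 32].  Reverse-keyed
items are assumed to be pre-coded in the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TLX_SUBSCALES = ("mental", "physical", "temporal", "performance", "effort", "frustration")
DSSQ_STATES = ("engagement", "distress", "worry")
DSSQ_ITEMS_PER_STATE = 8
DSSQ_ITEM_MAX = 4


@dataclass(frozen=True)
class TLXResponse:
    """One NASA-TLX administration: six 0-100 ratings, optional weights."""

    mental: float
    physical: float
    temporal: float
    performance: float
    effort: float
    frustration: float
    pairwise_weights: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for name in TLX_SUBSCALES:
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} rating {v} outside [0, 100]")
        if self.pairwise_weights is not None:
            if set(self.pairwise_weights) != set(TLX_SUBSCALES):
                raise ValueError("weights must cover exactly the six subscales")
            total = sum(self.pairwise_weights.values())
            if total != 15:
                raise ValueError(f"pairwise weights must sum to 15, got {total}")

    def subscales(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in TLX_SUBSCALES}


@dataclass(frozen=True)
class DSSQResponse:
    """One short-DSSQ administration: eight 0-4 items per state."""

    engagement: tuple[int, ...]
    distress: tuple[int, ...]
    worry: tuple[int, ...]

    def __post_init__(self) -> None:
        for state in DSSQ_STATES:
            items = tuple(getattr(self, state))
            object.__setattr__(self, state, items)
            if len(items) != DSSQ_ITEMS_PER_STATE:
                raise ValueError(
                    f"{state} needs {DSSQ_ITEMS_PER_STATE} items, got {len(items)}"
                )
            if any(not (0 <= v <= DSSQ_ITEM_MAX) for v in items):
                raise ValueError(f"{state} items must lie in 0..{DSSQ_ITEM_MAX}")


def score_tlx(resp: TLXResponse, mode: str = "raw") -> dict[str, float]:
    """Overall cognitive load plus the six subscale scores.

    ``raw`` mode returns the unweighted subscale mean; ``weighted`` mode
    computes ``sum(weight_i * rating_i) / 15`` and requires pairwise
    weights on the response.
    """
    scores = resp.subscales()
    if mode == "raw":
        cl = float(np.mean(list(scores.values())))
    elif mode == "weighted":
        if resp.pairwise_weights is None:
            raise ValueError("weighted mode requires pairwise_weights")
        cl = sum(resp.pairwise_weights[k] * scores[k] for k in TLX_SUBSCALES) / 15.0
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'raw' or 'weighted'")
    return {"cognitive_load": cl, **scores}


def reverse_performance_for_display(subscales: dict[str, float]) -> dict[str, float]:
    """Radar-chart convenience: flip performance to 100 - performance.

    Presentation-only; the cognitive-load score is computed on the
    unreversed ratings.  Applying it twice is the identity.
    """
    out = dict(subscales)
    out["performance"] = 100.0 - out["performance"]
    return out


def score_dssq(resp: DSSQResponse) -> dict[str, int]:
    """State scores: item sums, each in [0, 32]."""
    return {state: int(sum(getattr(resp, state))) for state in DSSQ_STATES}
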