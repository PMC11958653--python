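"""Assembly-precision scoring from marker-center coordinates.

Each assembled pattern is reported as the 2-D centers of its pieces'
fiducial markers.  Precision is measured against a reference layout
through pairwise geometry only: for every unordered pair of pieces the
Euclidean center-to-center distance is computed in both patterns, and
the per-pair deviation (observed minus reference) summarizes local
placement error.  The trial statistic is the sample standard deviation
of these deviations — zero for a perfect (or rigidly moved / reflected)
assembly, growing with placement noise; lower is more precise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np


@dataclass(frozen=True)
class MarkerPattern:
    """Piece-id → marker-center mapping for one assembled pattern."""

    centers: dict[object, tuple[float, float]]
    pattern_id: object = None

    def __post_init__(self) -> None:
        if len(self.centers) < 2:
            raise ValueError("pattern needs at least 2 pieces")

    @property
    def piece_ids(self) -> list:
        return sorted(self.centers, key=str)


@dataclass(frozen=True)
class PrecisionResult:
    """Per-trial deviations and their standard deviation."""

    trial_id: object
    deviations: dict[tuple, float]
    sd: float


def pattern_distances(p: MarkerPattern) -> dict[tuple, float]:
    """All C(n, 2) unordered-pair Euclidean distances, keyed by id pair."""
    ids = p.piece_ids
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate piece ids")
    out = {}
    for a, b in combinations(ids, 2):
        xa, ya = p.centers[a]
        xb, yb = p.centers[b]
        out[(a, b)] = float(np.hypot(xb - xa, yb - ya))
    return out


def precision_sd(
    observed: MarkerPattern, reference: MarkerPattern, trial_id: object = None
) -> PrecisionResult:
    """Sample SD of observed-minus-reference pairwise distances.

    Invariant to any rigid motion or reflection of the observed
    pattern; zero iff the observed pairwise distances equal the
    reference ones exactly.
    """
    missing = set(reference.centers) ^ set(observed.centers)
    if missing:
        raise ValueError(f"piece-id mismatch: {sorted(missing, key=str)}")
    d_obs = pattern_distances(observed)
    d_ref = pattern_distances(reference)
    deviations = {pair: d_obs[pair] - d_ref[pair] for pair in d_ref}
    values = np.array(list(deviations.values()))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return PrecisionResult(trial_id=trial_id, deviations=deviations, sd=sd)


def session_precision(trials: list[PrecisionResult]) -> float:
    """Arithmetic mean of per-trial precision SDs within a session."""
    if not trials:
        raise ValueError("need at least one trial")
    return float(np.mean([t.sd for t in trials]))
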