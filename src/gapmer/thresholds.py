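"""Score thresholds from the empirical distribution of known-site scores.

A threshold position ``x`` in [0, 1] is a percentile of the scores that the
aligned known sites themselves attain under a weight matrix.  The score
threshold ``tau(x)`` is the highest observed score at which sites at
percentile ``x`` are still called: the largest observed score ``s`` such
that the fraction of sites scoring strictly below ``s`` is at most ``x``
(nearest-rank, no interpolation — an interpolated value could exceed every
observed score at that rank and silently drop the sites defining it).
``x = 0`` keeps every known site; ``x = 1`` keeps only the strongest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif import AlignedSites, WeightMatrix

__all__ = [
    "ThresholdSpec",
    "site_score_distribution",
    "threshold_from_position",
    "threshold_grid",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Either an absolute score threshold or a percentile position.

    mode='absolute': value is tau itself.  mode='percentile': value is x and
    tau is computed from the known-site score distribution at run time.
    """

    mode: str
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "percentile"):
            raise ValueError(f"mode must be 'absolute' or 'percentile', got {self.mode!r}")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(
                f"{self.mode} threshold value must be in [0, 1], got {self.value}"
            )

    def resolve(self, scores: np.ndarray | None = None) -> float:
        """The score threshold tau, computing the percentile if needed."""
        if self.mode == "absolute":
            return float(self.value)
        if scores is None:
            raise ValueError("percentile threshold requires known-site scores")
        return threshold_from_position(scores, self.value)


def site_score_distribution(sites: AlignedSites, wm: WeightMatrix) -> np.ndarray:
    """Ascending scores of all L aligned sites under a weight matrix."""
    return np.sort([wm.score(s) for s in sites])


def threshold_from_position(scores, x: float) -> float:
    """Score threshold tau at percentile position x (nearest-rank).

    Returns the largest observed score s with ``#{scores < s} / L <= x``.
    Monotone non-decreasing in x; tau(0) is the minimum score, tau(1) the
    maximum.  Ties are safe: sites with equal scores are all called or none.
    """
    arr = np.sort(np.asarray(scores, dtype=float))
    if arr.size == 0:
        raise ValueError("cannot take a threshold of an empty score list")
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"threshold position must be in [0, 1], got {x}")
    L = arr.size
    # fraction strictly below arr[i] is searchsorted(arr, arr[i], 'left') / L
    below = np.searchsorted(arr, arr, side="left") / L
    eligible = arr[below <= x]
    return float(eligible[-1])


def threshold_grid(scores, step: float) -> list[tuple[float, float]]:
    """(x, tau) pairs for x from 0 to 1 inclusive at the given step."""
    if not 0.0 < step <= 1.0:
        raise ValueError(f"step must be in (0, 1], got {step}")
    xs = np.arange(0.0, 1.0 + step / 2, step)
    xs[-1] = min(xs[-1], 1.0)
    if xs[-1] < 1.0:
        xs = np.append(xs, 1.0)
    return [(float(x), threshold_from_position(scores, float(x))) for x in xs]
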