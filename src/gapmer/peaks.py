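"""ChIP peak preparation, scrambled nulls, and binding-site prediction.

True peaks are the central ``center_length`` bases (default 100) of each raw
ChIP interval; shorter intervals are excluded.  The null model for false
positives is composition-preserving scrambling: each true peak gives ``P``
independent uniform permutations of its nucleotides, so every scramble has
exactly the same base counts but no positional structure.

Prediction slides a length-l window one base at a time along a peak; every
window whose normalized score meets the threshold is a predicted site.  A
peak is classified positive when it contains at least one predicted site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .motif import WeightMatrix

__all__ = [
    "ChipPeak",
    "ScrambleSet",
    "PredictionResult",
    "prepare_peaks",
    "scramble_peak",
    "predict_sites",
    "classify_peak",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChipPeak:
    """A prepared (center-trimmed) ChIP peak sequence."""

    peak_id: str
    sequence: str
    source: tuple[str, int, int] | None = None  # (chrom, start, end), 0-based half-open


@dataclass(frozen=True)
class ScrambleSet:
    """P composition-preserving permutations of one true peak."""

    peak_id: str
    scrambles: tuple[str, ...]
    seed: int

    @property
    def P(self) -> int:
        return len(self.scrambles)


@dataclass(frozen=True)
class PredictionResult:
    """Predicted sites along one sequence at one threshold.

    ``coverage[j]`` counts the distinct predicted sites whose window covers
    position j; its sum equals site_count * l when no window is truncated.
    """

    peak_id: str
    threshold: float
    site_starts: tuple[int, ...]
    coverage: np.ndarray

    @property
    def site_count(self) -> int:
        return len(self.site_starts)


def prepare_peaks(
    raw: list[tuple[str, str]], center_length: int = 100
) -> list[ChipPeak]:
    """Trim raw peaks to their central ``center_length`` bases.

    Peaks shorter than ``center_length`` are dropped (the count is logged).
    A length-q peak keeps bases ``floor((q - center_length)/2)`` onward.
    Sequences are upper-cased; ambiguous characters are retained here and
    handled symmetrically at scan time.
    """
    kept: list[ChipPeak] = []
    dropped = 0
    for peak_id, seq in raw:
        q = len(seq)
        if q < center_length:
            dropped += 1
            continue
        start = (q - center_length) // 2
        kept.append(
            ChipPeak(peak_id=peak_id, sequence=seq[start : start + center_length].upper())
        )
    if dropped:
        logger.info(
            "excluded %d peak(s) shorter than %d bp", dropped, center_length
        )
    if not kept:
        raise ValueError(
            f"no peaks of length >= {center_length} remain after preparation"
        )
    return kept


def _peak_rng(seed: int, peak_id: str) -> np.random.Generator:
    # one independent stream per peak, order-independent
    return np.random.default_rng([seed, *peak_id.encode("utf-8")])


def scramble_peak(peak: ChipPeak, P: int, seed: int) -> ScrambleSet:
    """P independent uniform permutations of the peak's characters.

    Deterministic for a fixed seed; the per-peak stream is derived from
    (seed, peak_id) so results do not depend on peak order.
    """
    if P < 1:
        raise ValueError(f"number of scrambles P must be >= 1, got {P}")
    rng = _peak_rng(seed, peak.peak_id)
    chars = np.frombuffer(peak.sequence.encode("ascii"), dtype="S1")
    out = []
    for _ in range(P):
        out.append(b"".join(rng.permutation(chars)).decode("ascii"))
    return ScrambleSet(peak_id=peak.peak_id, scrambles=tuple(out), seed=seed)


def predict_sites(
    sequence: str,
    wm: WeightMatrix,
    tau: float,
    peak_id: str = "",
    both_strands: bool = False,
) -> PredictionResult:
    """Call every length-l window scoring >= tau as a predicted site.

    Windows containing non-ACGT characters are skipped.  With
    ``both_strands=True`` each window's score is the maximum over the
    forward and reverse-complement readings.
    """
    l = wm.site_length
    if len(sequence) < l:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than the site "
            f"length {l}"
        )
    scores, valid = wm.window_scores(sequence)
    if both_strands:
        from ._seq import reverse_complement

        rc_scores, rc_valid = wm.window_scores(reverse_complement(sequence))
        scores = np.fmax(scores, rc_scores[::-1])
        valid = valid & rc_valid[::-1]
    hits = np.flatnonzero(valid & (np.nan_to_num(scores, nan=-1.0) >= tau))
    coverage = np.zeros(len(sequence), dtype=np.int64)
    for s in hits:
        coverage[s : s + l] += 1
    return PredictionResult(
        peak_id=peak_id,
        threshold=float(tau),
        site_starts=tuple(int(s) for s in hits),
        coverage=coverage,
    )


def classify_peak(result: PredictionResult) -> bool:
    """True (positive) iff at least one site was predicted."""
    return result.site_count >= 1
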