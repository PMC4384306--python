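"""Matrix performance evaluation: TPR/FPR, ROC/AUROC, and the RZ score.

Two complementary measures are computed against the scrambled-peak null.

ROC/AUROC treats each peak (true or scrambled) as one binary trial — positive
when it contains any predicted site — and integrates TPR against FPR over a
threshold sweep with the trapezoidal rule, appending the theoretical
endpoints (0,0) and (1,1) when the sweep does not produce them.

The RZ score works per peak at one fixed threshold.  For true peak C_i with
r predicted sites and its P scrambles averaging a sites, the peak
contributes

    z = 1    if r - a >  0.5   (the matrix tells true from scrambled)
    z = 0.5  if -0.5 < r - a <= 0.5   (borderline)
    z = 0    if r - a <= -0.5  (the scrambles look better than the peak)

and RZ is the mean of z over peaks.  r is an integer and a a rational with
denominator P, so the +/-0.5 margins are decidable exactly; comparisons here
use exact integer arithmetic (2*(P*r - sum) vs P) to avoid floating-point
misclassification on the boundaries.  A guesser calling each window a site
with probability 0.5 has expected RZ 0.5, the natural baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational

import numpy as np

from .motif import WeightMatrix
from .peaks import ChipPeak, ScrambleSet, predict_sites

__all__ = [
    "ROCCurve",
    "RZResult",
    "compute_rates",
    "roc_and_auroc",
    "rz_component",
    "rz_score",
    "random_guesser_rz",
]


@dataclass(frozen=True)
class ROCCurve:
    """ROC points (FPR, TPR) sorted by FPR, with trapezoidal AUROC."""

    points: tuple[tuple[float, float], ...]
    auroc: float


@dataclass(frozen=True)
class RZResult:
    """Per-peak z values and the overall RZ score at one threshold."""

    per_peak_z: tuple[float, ...]
    rz: float
    hits: int
    borderlines: int
    misses: int
    threshold: float

    @property
    def n_peaks(self) -> int:
        return len(self.per_peak_z)


def compute_rates(
    true_calls: list[bool], scrambled_calls: list[bool]
) -> tuple[float, float]:
    """(TPR, FPR) from per-peak positive/negative calls.

    TPR = positives among the N true peaks / N; FPR = positives among the
    P*N scrambles / (P*N).
    """
    if not true_calls:
        raise ValueError("no true peaks: rates are undefined")
    tpr = sum(map(bool, true_calls)) / len(true_calls)
    fpr = (
        sum(map(bool, scrambled_calls)) / len(scrambled_calls)
        if scrambled_calls
        else 0.0
    )
    return tpr, fpr


def roc_and_auroc(rates_by_threshold: list[tuple[float, float]]) -> ROCCurve:
    """Assemble a ROC curve from (FPR, TPR) pairs and integrate it.

    Appends (0,0) and (1,1) when absent, sorts by FPR (TPR as tiebreak),
    and applies the trapezoidal rule.
    """
    if not rates_by_threshold:
        raise ValueError("at least one (FPR, TPR) pair is required")
    pts = {(float(f), float(t)) for f, t in rates_by_threshold}
    pts |= {(0.0, 0.0), (1.0, 1.0)}
    ordered = tuple(sorted(pts))
    fpr = np.array([p[0] for p in ordered])
    tpr = np.array([p[1] for p in ordered])
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=ordered, auroc=auroc)


def rz_component(r: int, a) -> float:
    """z contribution of one peak from its site count r and scramble mean a.

    The boundaries follow the defining inequalities exactly: a difference of
    exactly +0.5 is borderline (z = 0.5) and exactly -0.5 is a miss (z = 0).
    """
    if isinstance(a, Rational):
        diff = Fraction(r) - Fraction(a)
    else:
        diff = Fraction(r) - Fraction(float(a))  # exact binary value of a
    half = Fraction(1, 2)
    if diff > half:
        return 1.0
    if diff > -half:
        return 0.5
    return 0.0


def rz_score(
    peaks: list[ChipPeak],
    scrambles: list[ScrambleSet],
    wm: WeightMatrix,
    tau: float,
    both_strands: bool = False,
) -> RZResult:
    """RZ score of one matrix at one threshold over a peak set."""
    if len(peaks) != len(scrambles):
        raise ValueError(
            f"{len(peaks)} peaks but {len(scrambles)} scramble sets"
        )
    if not peaks:
        raise ValueError("no peaks: RZ is undefined")
    P = scrambles[0].P
    zs: list[float] = []
    for peak, sset in zip(peaks, scrambles):
        if sset.peak_id != peak.peak_id:
            raise ValueError(
                f"scramble set {sset.peak_id!r} does not match peak "
                f"{peak.peak_id!r}"
            )
        if sset.P != P:
            raise ValueError("all scramble sets must share one P")
        r = predict_sites(
            peak.sequence, wm, tau, peak.peak_id, both_strands
        ).site_count
        counts = [
            predict_sites(s, wm, tau, peak.peak_id, both_strands).site_count
            for s in sset.scrambles
        ]
        zs.append(rz_component(r, Fraction(sum(counts), P)))
    return _summarize_z(zs, tau)


def _summarize_z(zs: list[float], tau: float) -> RZResult:
    zs_t = tuple(zs)
    return RZResult(
        per_peak_z=zs_t,
        rz=float(np.mean(zs_t)),
        hits=sum(z == 1.0 for z in zs_t),
        borderlines=sum(z == 0.5 for z in zs_t),
        misses=sum(z == 0.0 for z in zs_t),
        threshold=float(tau),
    )


def rz_from_counts(
    true_counts, scramble_counts, tau: float = float("nan")
) -> RZResult:
    """RZ from precomputed integer site counts.

    ``true_counts`` has shape (N,), ``scramble_counts`` shape (N, P).
    Uses the same exact integer boundary arithmetic as :func:`rz_score`;
    useful for threshold sweeps where window scores are computed once.
    """
    r = np.asarray(true_counts, dtype=np.int64)
    sc = np.asarray(scramble_counts, dtype=np.int64)
    if sc.ndim != 2 or sc.shape[0] != r.shape[0]:
        raise ValueError(
            f"scramble_counts shape {sc.shape} does not match "
            f"{r.shape[0]} true peaks"
        )
    P = sc.shape[1]
    d2 = 2 * (P * r - sc.sum(axis=1))
    zs = np.where(d2 > P, 1.0, np.where(d2 > -P, 0.5, 0.0))
    return _summarize_z(list(zs), tau)


def random_guesser_rz(
    N: int,
    P: int,
    windows_per_peak: int,
    rate: float = 0.5,
    seed: int = 0,
) -> RZResult:
    """Simulated RZ of a guesser calling each window with probability ``rate``.

    Each true peak and each of its P scrambles receives an independent
    Binomial(windows_per_peak, rate) site count; z is computed with exact
    integer comparisons.  Expected RZ is 0.5 at rate 0.5 (and trivially 0.5
    at rates 0 and 1, where every peak is borderline).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    r_true = rng.binomial(windows_per_peak, rate, size=N).astype(np.int64)
    r_scram = rng.binomial(windows_per_peak, rate, size=(N, P)).astype(np.int64)
    sums = r_scram.sum(axis=1)
    # z branches on r - sum/P against +/-1/2: compare 2*(P*r - sum) with P
    d2 = 2 * (P * r_true - sums)
    zs = np.where(d2 > P, 1.0, np.where(d2 > -P, 0.5, 0.0))
    return _summarize_z(list(zs), tau=float("nan"))
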