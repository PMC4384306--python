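"""Synthetic data generation: planted-motif sites, peaks, and background.

Emulates the three inputs of the pipeline: aligned known binding sites
sampled position-independently from a probabilistic motif, ChIP peaks of
fixed length carrying a controlled number of planted sites at non-overlapping
uniform positions over an i.i.d. background, and an i.i.d. background
sequence with configurable base composition.

Defaults mirror a 7-bp site study: site length 7, 101 aligned sites, 100-bp
peaks, a strongly T-rich motif concentrated on the consensus TTTTTTG, and a
uniform background.  Everything is deterministic under the given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import ALPHABET
from .motif import AlignedSites

__all__ = ["SyntheticSpec", "generate_fixtures", "consensus_motif"]


def consensus_motif(consensus: str, dominance: float = 0.8) -> np.ndarray:
    """Per-position probability matrix concentrated on a consensus sequence.

    Each row gives probability ``dominance`` to the consensus base and
    splits the remainder evenly over the other three.
    """
    if not 0.25 <= dominance <= 1.0:
        raise ValueError(f"dominance must be in [0.25, 1], got {dominance}")
    rows = []
    rest = (1.0 - dominance) / 3.0
    for ch in consensus.upper():
        row = [rest] * 4
        row[ALPHABET.index(ch)] = dominance
        rows.append(row)
    return np.array(rows)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    motif :
        (site_length x 4) per-position probabilities over A, C, G, T.
    n_sites :
        Number of aligned known sites L (default 101).
    n_peaks :
        Number of true ChIP peaks N (default 3142).
    peak_length :
        Length l_c of every peak (default 100).
    sites_per_peak :
        Planted sites per true peak (default 2).
    background_composition :
        Base probabilities of the i.i.d. background (default uniform).
    background_length :
        Length of the generated background sequence (default 100000).
    """

    motif: np.ndarray = field(
        default_factory=lambda: consensus_motif("TTTTTTG", 0.8)
    )
    n_sites: int = 101
    n_peaks: int = 3142
    peak_length: int = 100
    sites_per_peak: int = 2
    background_composition: tuple[float, float, float, float] = (
        0.25,
        0.25,
        0.25,
        0.25,
    )
    background_length: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        motif = np.asarray(self.motif, dtype=float)
        if motif.ndim != 2 or motif.shape[1] != 4:
            raise ValueError(f"motif must be (l, 4), got shape {motif.shape}")
        if np.any(motif < 0) or not np.allclose(motif.sum(axis=1), 1.0):
            raise ValueError("motif rows must be probability distributions")
        object.__setattr__(self, "motif", motif)
        comp = np.asarray(self.background_composition, dtype=float)
        if np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("background composition must sum to 1")
        for name in ("n_sites", "n_peaks", "peak_length", "background_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sites_per_peak < 0:
            raise ValueError("sites_per_peak must be >= 0")
        if self.sites_per_peak * self.site_length > self.peak_length:
            raise ValueError(
                f"{self.sites_per_peak} non-overlapping sites of length "
                f"{self.site_length} cannot fit in a {self.peak_length} bp peak"
            )

    @property
    def site_length(self) -> int:
        return self.motif.shape[0]


def _sample_motif(rng: np.random.Generator, motif: np.ndarray, n: int) -> list[str]:
    l = motif.shape[0]
    cols = np.empty((n, l), dtype="U1")
    for j in range(l):
        cols[:, j] = rng.choice(list(ALPHABET), size=n, p=motif[j])
    return ["".join(row) for row in cols]


def _nonoverlapping_starts(
    rng: np.random.Generator, k: int, l: int, total: int
) -> np.ndarray:
    """k uniform non-overlapping start positions for length-l sites."""
    # classic gap construction: sample in the collapsed space then re-expand
    slack = total - k * l
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    return cuts + np.arange(k) * l


def generate_fixtures(
    spec: SyntheticSpec,
) -> tuple[AlignedSites, list[tuple[str, str]], str]:
    """Generate (aligned sites, raw true peaks, background sequence).

    Peaks carry ``sites_per_peak`` fresh draws from the motif planted at
    non-overlapping uniform positions; all other peak bases and the
    background are i.i.d. from ``background_composition``.
    """
    rng = np.random.default_rng(spec.seed)
    bases = list(ALPHABET)
    comp = np.asarray(spec.background_composition, dtype=float)

    sites = AlignedSites(_sample_motif(rng, spec.motif, spec.n_sites))

    l = spec.site_length
    peaks: list[tuple[str, str]] = []
    for i in range(spec.n_peaks):
        seq = rng.choice(bases, size=spec.peak_length, p=comp)
        if spec.sites_per_peak:
            starts = _nonoverlapping_starts(
                rng, spec.sites_per_peak, l, spec.peak_length
            )
            planted = _sample_motif(rng, spec.motif, spec.sites_per_peak)
            for s, site in zip(starts, planted):
                seq[s : s + l] = list(site)
        peaks.append((f"peak_{i:05d}", "".join(seq)))

    background = "".join(
        rng.choice(bases, size=spec.background_length, p=comp)
    )
    return sites, peaks, background
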