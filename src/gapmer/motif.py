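"""Weight-matrix construction and scoring for gapped n-mer motif models.

A motif model is specified by a gapped n-mer pattern (which frame positions
are considered), a set of aligned known binding sites of common length ``l``,
and a background sequence supplying expected word frequencies.  The model is
a ``4**mu x (l - l_n + 1)`` table of log-weights: one row per word over the
considered positions, one column per frame start.  Weights are shifted so
the maximum in each column is exactly 0; the normalized score of a length-l
sequence then lies in [0, 1], with the consensus scoring 1 and the
worst-possible sequence scoring 0.

The weight of word ``b`` at frame start ``i`` is

    w_bi = ln((n_bi + e_b) / (e_b * (L + 1))) + c_i

where ``n_bi`` counts sites carrying word ``b`` at start ``i``, ``e_b`` is
the smoothed background frequency of ``b``, ``L`` the number of sites, and
``c_i = -max_b ln(...)`` the per-column shift.  Background frequencies carry
a Dirichlet pseudocount of ``1/4**mu`` per word (denominator ``total + 1``)
so every ``e_b`` is strictly positive and they sum exactly to 1.

The normalized score of a sequence ``sigma`` of length ``l`` is

    S_sigma = 1 - (sum_i w[word_i, i]) / (sum_i min_b w_bi)

summing over all ``l - l_n + 1`` frame starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import (
    all_words,
    encode_seq,
    index_to_word,
    reverse_complement,
    window_word_codes,
    word_index,
)
from .patterns import GappedNmer

__all__ = [
    "AlignedSites",
    "BackgroundModel",
    "WeightMatrix",
    "estimate_background",
    "build_weight_matrix",
    "score_sequence",
]


@dataclass(frozen=True)
class AlignedSites:
    """Aligned known binding-site sequences of identical length.

    Sequences are upper-cased at construction; any sequence containing a
    non-ACGT character is rejected, since the weight formulas are defined
    only over the four-letter alphabet.
    """

    sequences: tuple[str, ...]

    def __init__(self, sequences: Iterable[str]):
        seqs = tuple(s.upper() for s in sequences)
        if not seqs:
            raise ValueError("aligned site set is empty")
        length = len(seqs[0])
        for idx, s in enumerate(seqs, start=1):
            if len(s) != length:
                raise ValueError(
                    f"aligned sites must share one length: record {idx} has "
                    f"length {len(s)}, expected {length}"
                )
            if set(s) - set("ACGT"):
                bad = sorted(set(s) - set("ACGT"))
                raise ValueError(
                    f"record {idx} contains non-ACGT characters {bad}; "
                    "aligned sites must be unambiguous nucleotides"
                )
        object.__setattr__(self, "sequences", seqs)

    @property
    def site_length(self) -> int:
        """Common site length l."""
        return len(self.sequences[0])

    @property
    def count(self) -> int:
        """Number of sites L."""
        return len(self.sequences)

    def __len__(self) -> int:
        return self.count

    def __iter__(self):
        return iter(self.sequences)


@dataclass(frozen=True)
class BackgroundModel:
    """Smoothed background frequencies e_b of the 4**mu gapped words.

    ``freqs[j]`` is e_b for the word with lexicographic index ``j``
    (A<C<G<T, leftmost considered position most significant).
    """

    pattern: GappedNmer
    freqs: np.ndarray
    total_windows: int

    def freq(self, word: str) -> float:
        return float(self.freqs[word_index(word)])

    def as_dict(self) -> dict[str, float]:
        return {w: float(f) for w, f in zip(all_words(self.pattern.mu), self.freqs)}

    @classmethod
    def from_frequencies(
        cls, pattern: GappedNmer, freqs: Mapping[str, float] | np.ndarray
    ) -> "BackgroundModel":
        """Build from user-supplied word frequencies.

        Every word must have a strictly positive frequency; frequencies are
        normalized to sum to 1.
        """
        n_words = 4**pattern.mu
        if isinstance(freqs, Mapping):
            arr = np.zeros(n_words)
            seen = set()
            for w, f in freqs.items():
                arr[word_index(w)] = f
                seen.add(w.upper())
            missing = set(all_words(pattern.mu)) - seen
            if missing:
                raise ValueError(
                    f"missing frequencies for {len(missing)} words, e.g. "
                    f"{sorted(missing)[:3]}"
                )
        else:
            arr = np.asarray(freqs, dtype=float)
            if arr.shape != (n_words,):
                raise ValueError(
                    f"expected {n_words} frequencies for mu={pattern.mu}, "
                    f"got shape {arr.shape}"
                )
        if np.any(arr <= 0):
            raise ValueError("background frequencies must all be > 0")
        return cls(pattern=pattern, freqs=arr / arr.sum(), total_windows=0)


def estimate_background(
    background: str | Sequence[str], pattern: GappedNmer
) -> BackgroundModel:
    """Estimate smoothed word frequencies from a background sequence.

    For each word ``b`` over the pattern's considered positions,

        e_b = (count of frames matching b + 1/4**mu) / (total frames + 1)

    where a frame of length l_n matches ``b`` iff its nucleotides at the
    considered positions equal ``b``.  Frames containing any non-ACGT
    character are excluded from both the counts and the total.  Multiple
    background records are counted independently: frames never span record
    boundaries.

    The pseudocount guarantees e_b > 0 for every word and sum(e_b) = 1.
    """
    records = [background] if isinstance(background, str) else list(background)
    n_words = 4**pattern.mu
    counts = np.zeros(n_words, dtype=np.int64)
    total = 0
    for rec in records:
        codes = encode_seq(rec)
        words, valid = window_word_codes(
            codes, pattern.m_offsets, pattern.frame_length
        )
        if words.size:
            counts += np.bincount(words[valid], minlength=n_words)
            total += int(valid.sum())
    if total == 0:
        raise ValueError(
            f"background contains no valid window of length "
            f"{pattern.frame_length} (pattern {pattern.pattern!r})"
        )
    freqs = (counts + 1.0 / n_words) / (total + 1)
    return BackgroundModel(pattern=pattern, freqs=freqs, total_windows=total)


@dataclass(frozen=True)
class WeightMatrix:
    """Log-weight table for one gapped n-mer pattern.

    ``weights`` has 4**mu rows (words, lexicographic) and ``l - l_n + 1``
    columns (frame starts).  Every entry is <= 0 and each column's maximum
    is exactly 0.  ``counts`` holds the site word counts n_bi (None when the
    matrix was loaded from disk without them).
    """

    pattern: GappedNmer
    site_length: int
    n_sites: int
    weights: np.ndarray
    counts: np.ndarray | None = None
    _col_min: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 4**self.pattern.mu:
            raise ValueError(
                f"weights must have {4**self.pattern.mu} rows for pattern "
                f"{self.pattern.pattern!r}, got shape {w.shape}"
            )
        expected_cols = self.site_length - self.pattern.frame_length + 1
        if w.shape[1] != expected_cols:
            raise ValueError(
                f"weights must have {expected_cols} columns for site length "
                f"{self.site_length}, got {w.shape[1]}"
            )
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "_col_min", w.min(axis=0))

    @property
    def n_rows(self) -> int:
        return self.weights.shape[0]

    @property
    def n_frames(self) -> int:
        return self.weights.shape[1]

    @property
    def row_words(self) -> list[str]:
        return all_words(self.pattern.mu)

    @property
    def consensus(self) -> str | None:
        """A length-l sequence attaining score 1, when one exists.

        Built by placing the argmax word of each frame; returns None when
        overlapping frames disagree on a shared position (possible for
        kappa >= 1 patterns).
        """
        filled: dict[int, str] = {}
        for i in range(self.n_frames):
            best = index_to_word(int(np.argmax(self.weights[:, i])), self.pattern.mu)
            for off, ch in zip(self.pattern.m_offsets, best):
                pos = i + off
                if filled.setdefault(pos, ch) != ch:
                    return None
        return "".join(filled.get(p, "A") for p in range(self.site_length))

    # -- scoring ---------------------------------------------------------

    def score(self, sequence: str, both_strands: bool = False) -> float:
        """Normalized score S in [0, 1] of one length-l sequence."""
        return score_sequence(sequence, self, both_strands=both_strands)

    def window_scores(self, sequence: str) -> tuple[np.ndarray, np.ndarray]:
        """Scores of every length-l window of a longer sequence.

        Returns ``(scores, valid)`` over window starts ``0 .. len - l``;
        ``valid`` is False for windows containing non-ACGT characters
        (their score entry is NaN).
        """
        codes = encode_seq(sequence.upper())
        if len(codes) < self.site_length:
            raise ValueError(
                f"sequence of length {len(codes)} is shorter than the site "
                f"length {self.site_length}"
            )
        words, frame_ok = window_word_codes(
            codes, self.pattern.m_offsets, self.pattern.frame_length
        )
        n_win = len(codes) - self.site_length + 1
        numer = np.zeros(n_win)
        valid = np.ones(n_win, dtype=bool)
        for i in range(self.n_frames):
            numer += self.weights[words[i : i + n_win], i]
            valid &= frame_ok[i : i + n_win]
        denom = float(self._col_min.sum())
        if denom == 0.0:
            # degenerate: all words equally weighted in every column
            scores = np.ones(n_win)
        else:
            scores = 1.0 - numer / denom
        return np.where(valid, scores, np.nan), valid

    # -- persistence -----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the weight table as TSV with '#' metadata header lines.

        Rows are words in lexicographic A<C<G<T order, columns frame starts.
        Full float precision is kept so a reloaded matrix scores
        bit-identically.
        """
        with open(path, "w") as fh:
            fh.write(f"# pattern\t{self.pattern.pattern}\n")
            fh.write(f"# type_id\t{self.pattern.type_id}\n")
            fh.write(f"# site_length\t{self.site_length}\n")
            fh.write(f"# n_sites\t{self.n_sites}\n")
            fh.write(
                "word\t" + "\t".join(str(i) for i in range(self.n_frames)) + "\n"
            )
            for word, row in zip(self.row_words, self.weights):
                fh.write(word + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "WeightMatrix":
        meta: dict[str, str] = {}
        rows: list[list[float]] = []
        words: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("\t")
                    meta[key.strip()] = val.strip()
                elif line.startswith("word\t"):
                    continue
                else:
                    parts = line.split("\t")
                    words.append(parts[0])
                    rows.append([float(v) for v in parts[1:]])
        pattern = GappedNmer(meta["pattern"], int(meta["type_id"]))
        expected = all_words(pattern.mu)
        if words != expected:
            raise ValueError(f"{path}: word rows are not in lexicographic order")
        return cls(
            pattern=pattern,
            site_length=int(meta["site_length"]),
            n_sites=int(meta["n_sites"]),
            weights=np.array(rows),
        )


def build_weight_matrix(
    sites: AlignedSites, pattern: GappedNmer, bg: BackgroundModel
) -> WeightMatrix:
    """Build the log-weight matrix for one pattern from aligned sites.

    Counts n_bi (sites carrying word b at frame start i), applies the
    pseudocounted log-odds formula against the background frequencies, and
    shifts each column by c_i so its maximum weight is exactly 0.
    """
    if bg.pattern.pattern != pattern.pattern:
        raise ValueError(
            f"background was built for pattern {bg.pattern.pattern!r}, "
            f"not {pattern.pattern!r}"
        )
    l = sites.site_length
    l_n = pattern.frame_length
    if l_n > l:
        raise ValueError(
            f"pattern frame length {l_n} exceeds the site length {l}"
        )
    n_words = 4**pattern.mu
    n_cols = l - l_n + 1
    counts = np.zeros((n_words, n_cols), dtype=np.int64)
    for seq in sites:
        words, valid = window_word_codes(
            encode_seq(seq), pattern.m_offsets, l_n
        )
        # sites are validated ACGT-only, so every frame is valid
        counts[words, np.arange(n_cols)] += 1
    L = sites.count
    e = bg.freqs[:, None]
    raw = np.log((counts + e) / (e * (L + 1)))
    weights = raw - raw.max(axis=0, keepdims=True)
    return WeightMatrix(
        pattern=pattern,
        site_length=l,
        n_sites=L,
        weights=weights,
        counts=counts,
    )


def score_sequence(
    sequence: str, wm: WeightMatrix, both_strands: bool = False
) -> float:
    """Normalized weight score S of a length-l sequence under a matrix.

    S = 1 - (sum of matched weights over all frames) / (sum of per-column
    minima); the consensus scores 1 and the all-worst sequence scores 0.
    With ``both_strands=True`` the reverse complement is also scored and the
    larger value returned.
    """
    seq = sequence.upper()
    if len(seq) != wm.site_length:
        raise ValueError(
            f"sequence length {len(seq)} does not match the matrix site "
            f"length {wm.site_length}"
        )
    if set(seq) - set("ACGT"):
        raise ValueError(f"sequence contains non-ACGT characters: {sequence!r}")
    scores, _ = wm.window_scores(seq)
    fwd = float(scores[0])
    if both_strands:
        rev, _ = wm.window_scores(reverse_complement(seq))
        return max(fwd, float(rev[0]))
    return fwd
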