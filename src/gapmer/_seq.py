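"""Nucleotide encoding helpers shared across the package.

Sequences are handled case-insensitively and encoded as int8 arrays with
A=0, C=1, G=2, T=3 and -1 for any other character.  Gapped words are indexed
lexicographically (A<C<G<T) over the considered positions, most significant
position first, so row ``0`` of a matrix is ``AA..A`` and row ``4**mu - 1``
is ``TT..T``.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (-1 for non-ACGT)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def is_valid_acgt(seq: str) -> bool:
    return bool(np.all(encode_seq(seq) >= 0)) if seq else True


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


def word_index(word: str) -> int:
    """Lexicographic index of an ACGT word (A<C<G<T, first char most significant)."""
    codes = encode_seq(word)
    if np.any(codes < 0):
        raise ValueError(f"word {word!r} contains non-ACGT characters")
    idx = 0
    for c in codes:
        idx = idx * 4 + int(c)
    return idx


def index_to_word(idx: int, mu: int) -> str:
    """Inverse of :func:`word_index` for words of length ``mu``."""
    chars = []
    for _ in range(mu):
        chars.append(ALPHABET[idx % 4])
        idx //= 4
    return "".join(reversed(chars))


def all_words(mu: int) -> list[str]:
    """The 4**mu ACGT words of length mu in lexicographic order."""
    return [index_to_word(i, mu) for i in range(4**mu)]


def window_word_codes(
    codes: np.ndarray, m_offsets: tuple[int, ...], frame_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gapped-word index at every frame start of an encoded sequence.

    Parameters
    ----------
    codes :
        int8 array from :func:`encode_seq`.
    m_offsets :
        Offsets of considered positions within the frame.
    frame_length :
        Frame width l_n; there are ``len(codes) - frame_length + 1`` starts.

    Returns
    -------
    words, valid :
        ``words[s]`` is the word index of the frame starting at ``s``
        (meaningless where invalid); ``valid[s]`` is False when the frame
        contains any non-ACGT character.
    """
    n = len(codes) - frame_length + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    ok = codes >= 0
    # a frame is valid iff every one of its frame_length positions is ACGT
    valid = np.ones(n, dtype=bool)
    for j in range(frame_length):
        valid &= ok[j : j + n]
    words = np.zeros(n, dtype=np.int64)
    clipped = np.where(ok, codes, 0).astype(np.int64)
    for j in m_offsets:
        words = words * 4 + clipped[j : j + n]
    return words, valid
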