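"""Gapped n-mer pattern algebra.

A gapped n-mer is a string over ``{k, m}`` describing which positions inside a
fixed scoring frame are considered (``m``) and which are ignored (``k``).
Patterns always begin and end with ``m``: a leading or trailing ignored
position would just shorten the frame without changing the model.

Every pattern has a unique integer *type ID*.  The codec works on the binary
expansion of the ID: each ``0`` becomes a ``k`` and each ``1`` an ``m``,
leading ``k``'s are stripped (the first frame position is always considered),
and a terminal ``m`` is appended (the last frame position is always
considered).  With a maximum frame of ``f`` the IDs ``0 .. 2**(f-1) - 1``
enumerate every admissible pattern exactly once; the default maximum frame of
6 yields 32 patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GappedNmer",
    "decode_type_id",
    "encode_pattern",
    "enumerate_patterns",
]

DEFAULT_MAX_FRAME = 6


@dataclass(frozen=True)
class GappedNmer:
    """A gapped n-mer pattern together with its integer type ID.

    Attributes
    ----------
    pattern :
        String over ``{k, m}``; begins and ends with ``m``.
    type_id :
        Non-negative integer encoding the pattern (see module docstring).
    mu :
        Number of considered (``m``) positions.
    kappa :
        Number of ignored (``k``) positions.
    frame_length :
        ``mu + kappa`` — the width of the sliding scoring frame.
    """

    pattern: str
    type_id: int = field(default=-1)

    def __post_init__(self) -> None:
        p = self.pattern
        if not p or set(p) - {"k", "m"}:
            raise ValueError(
                f"pattern must be a non-empty string over {{k, m}}, got {p!r}"
            )
        if p[0] != "m" or p[-1] != "m":
            raise ValueError(
                f"pattern must begin and end with 'm', got {p!r}"
            )
        if self.type_id == -1:
            object.__setattr__(self, "type_id", encode_pattern(p))
        elif encode_pattern(p) != self.type_id:
            raise ValueError(
                f"type_id {self.type_id} does not encode pattern {p!r}"
            )

    @property
    def mu(self) -> int:
        return self.pattern.count("m")

    @property
    def kappa(self) -> int:
        return self.pattern.count("k")

    @property
    def frame_length(self) -> int:
        return len(self.pattern)

    @property
    def m_offsets(self) -> tuple[int, ...]:
        """0-based offsets of the considered positions within the frame."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "m")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.pattern


def decode_type_id(type_id: int, max_frame: int = DEFAULT_MAX_FRAME) -> GappedNmer:
    """Decode an integer type ID into its gapped n-mer pattern.

    The ID is written in binary on ``max_frame - 1`` digits, each ``0``
    becomes ``k`` and each ``1`` becomes ``m``, leading ``k``'s are stripped
    and a terminal ``m`` is appended.

    Parameters
    ----------
    type_id :
        Integer in ``[0, 2**(max_frame - 1))``.
    max_frame :
        Maximum frame length (default 6, giving IDs 0..31).

    Examples
    --------
    >>> decode_type_id(16).pattern
    'mkkkkm'
    >>> decode_type_id(0).pattern
    'm'
    """
    if max_frame < 1:
        raise ValueError(f"max_frame must be >= 1, got {max_frame}")
    n_ids = 1 << (max_frame - 1)
    if not 0 <= type_id < n_ids:
        raise ValueError(
            f"type_id {type_id} out of range: valid IDs for max_frame "
            f"{max_frame} are 0..{n_ids - 1}"
        )
    bits = format(type_id, "b") if max_frame > 1 else ""
    body = bits.translate(str.maketrans("01", "km")).lstrip("k")
    return GappedNmer(pattern=body + "m", type_id=type_id)


def encode_pattern(pattern: str) -> int:
    """Return the unique type ID whose decoding is ``pattern``.

    Inverse of :func:`decode_type_id`: strip the terminal ``m``, map
    ``m -> 1`` and ``k -> 0``, and read the result as a binary integer
    (the empty string reads as 0).

    Examples
    --------
    >>> encode_pattern("mkkkkm")
    16
    >>> encode_pattern("m")
    0
    """
    if not pattern or set(pattern) - {"k", "m"}:
        raise ValueError(
            f"pattern must be a non-empty string over {{k, m}}, got {pattern!r}"
        )
    if pattern[0] != "m" or pattern[-1] != "m":
        raise ValueError(f"pattern must begin and end with 'm', got {pattern!r}")
    body = pattern[:-1]
    if not body:
        return 0
    bits = body.translate(str.maketrans("km", "01"))
    return int(bits, 2)


def enumerate_patterns(max_frame: int = DEFAULT_MAX_FRAME) -> list[GappedNmer]:
    """All gapped n-mers of frame length <= ``max_frame``, in type-ID order.

    Returns ``2**(max_frame - 1)`` patterns; 32 for the default frame of 6.
    """
    if max_frame < 1:
        raise ValueError(f"max_frame must be >= 1, got {max_frame}")
    return [decode_type_id(i, max_frame) for i in range(1 << (max_frame - 1))]
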