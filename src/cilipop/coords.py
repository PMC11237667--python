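"""Coordinate conventions.

External formats (VCF, GFF3) are 1-based with inclusive interval ends;
everything inside the package is 0-based half-open.  The two converters below
are the only place the +/-1 arithmetic is allowed to live.
"""

from __future__ import annotations


def to_internal(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [start, end)."""
    if start_1based < 1 or end_1based_inclusive < start_1based:
        raise ValueError(
            f"invalid 1-based interval [{start_1based}, {end_1based_inclusive}]"
        )
    return start_1based - 1, end_1based_inclusive


def to_external(start_0based: int, end_0based_exclusive: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive [start, end]."""
    if start_0based < 0 or end_0based_exclusive <= start_0based:
        raise ValueError(
            f"invalid 0-based interval [{start_0based}, {end_0based_exclusive})"
        )
    return start_0based + 1, end_0based_exclusive


def pos_to_internal(pos_1based: int) -> int:
    """Single 1-based position -> 0-based index."""
    if pos_1based < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos_1based}")
    return pos_1based - 1


def pos_to_external(idx_0based: int) -> int:
    """0-based index -> 1-based position."""
    if idx_0based < 0:
        raise ValueError(f"0-based index must be >= 0, got {idx_0based}")
    return idx_0based + 1
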