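"""Reading-frame arithmetic for six-frame codon grids.

A genome position can start a codon in one of six reading frames: three on
the plus strand and three on the minus strand. A frame is identified by its
strand and *phase* — the left-edge genomic coordinate of each of its codons,
modulo 3. Minus-strand codons are keyed by the genomic left edge of their
3-bp span, which is the codon's biological third position (the strand reads
right to left). This convention makes the antisense pairing below a clean
coordinate involution.

The *antisense frame* of a frame is the opposite-strand frame whose codons
share third-codon-position genomic coordinates with it. Because the third
position is the most degenerate, genuine coding signal leaks into the
antisense frame as a spurious "ghost" signal, which downstream filtering
must recognize.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Frame",
    "FRAMES",
    "frame_of_codon",
    "antisense_frame",
    "paired_antisense_codon",
]


@dataclass(frozen=True, order=True)
class Frame:
    """One of the six reading frames.

    ``frame_id`` is the canonical integer 0-5: ids 0-2 are plus-strand
    frames with phase equal to the id; ids 3-5 are minus-strand frames
    with phase ``id - 3``.
    """

    strand: str
    phase: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase!r}")

    @property
    def frame_id(self) -> int:
        return self.phase if self.strand == "+" else 3 + self.phase

    @classmethod
    def from_id(cls, frame_id: int) -> "Frame":
        if not 0 <= frame_id <= 5:
            raise ValueError(f"frame_id must be in 0..5, got {frame_id}")
        return cls("+", frame_id) if frame_id < 3 else cls("-", frame_id - 3)

    def __str__(self) -> str:  # e.g. "+0", "-2"
        return f"{self.strand}{self.phase}"


#: The six frames in canonical frame_id order.
FRAMES: tuple[Frame, ...] = tuple(Frame.from_id(i) for i in range(6))


def frame_of_codon(codon_start: int, strand: str) -> Frame:
    """Frame containing the codon whose 3-bp span starts at ``codon_start``."""
    if codon_start < 0:
        raise ValueError("codon_start must be non-negative")
    return Frame(strand, codon_start % 3)


def antisense_frame(frame: Frame) -> Frame:
    """The opposite-strand frame sharing third codon positions.

    A plus-strand codon at ``s`` has its third position at ``s + 2``; the
    minus-strand codon keyed at left edge ``s + 2`` has its third position
    at exactly that coordinate. Hence ``(+, p) <-> (-, (p + 2) % 3)``, an
    involution with no fixed points.
    """
    if frame.strand == "+":
        return Frame("-", (frame.phase + 2) % 3)
    return Frame("+", (frame.phase + 1) % 3)


def paired_antisense_codon(codon_start: int, frame: Frame) -> int:
    """Left edge of the antisense-frame codon sharing this codon's third position.

    Plus-strand codon at ``s`` pairs with the minus codon keyed at ``s + 2``;
    minus codon keyed at ``s`` pairs with the plus codon at ``s - 2``. The
    two codon spans overlap in exactly one base — the shared third position.
    Applying the pairing twice returns the original codon start.
    """
    if codon_start % 3 != frame.phase:
        raise ValueError(
            f"codon_start {codon_start} is not on the grid of frame {frame}"
        )
    if frame.strand == "+":
        return codon_start + 2
    start = codon_start - 2
    if start < 0:
        raise ValueError("paired codon would start before the sequence origin")
    return start
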