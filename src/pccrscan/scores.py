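"""Per-codon score and power tracks: reading, writing, validation, masking.

Scores are in decibans (10·log10 of the coding/noncoding likelihood ratio),
one per codon of a single reading frame of a single chromosome. On disk the
tracks are fixedStep wiggle (``step=3 span=3``; 1-based, per UCSC) or
bedGraph with 3-bp features (0-based half-open). Internally everything is
0-based half-open; the conversion happens only in this module.

Missing scores are first-class: a codon can be present on the grid with a
NaN score (e.g. after power masking), and codons absent from a file are
missing. The two representations are semantically identical; ``dropna``
normalizes to the absent form, which is also what the writer emits (gaps
between fixedStep blocks).

The power track holds the relative branch length of the local alignment in
[0, 1] per codon — the statistical power available to the scorer. Codons
with power below 0.1 are conventionally left unscored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .frames import Frame

__all__ = [
    "CodonScoreTrack",
    "PowerTrack",
    "TrackFormatError",
    "read_codon_track",
    "read_power_track",
    "write_codon_track",
    "mask_low_power",
]

DEFAULT_POWER_CUTOFF = 0.1


class TrackFormatError(ValueError):
    """Malformed or coordinate-inconsistent track file."""


def _validate_grid(codon_starts: np.ndarray, phase: int | None) -> None:
    if codon_starts.size == 0:
        return
    if np.any(codon_starts < 0):
        raise TrackFormatError("codon starts must be non-negative")
    d = np.diff(codon_starts)
    if np.any(d <= 0):
        raise TrackFormatError("codon starts must be strictly increasing")
    if np.any(d % 3 != 0):
        raise TrackFormatError("same-frame codon starts must differ by multiples of 3")
    if phase is not None and np.any(codon_starts % 3 != phase):
        bad = int(codon_starts[np.flatnonzero(codon_starts % 3 != phase)[0]])
        raise TrackFormatError(
            f"codon start {bad} is not congruent to phase {phase} (mod 3)"
        )


@dataclass
class CodonScoreTrack:
    """Per-codon scores of one reading frame of one chromosome.

    ``codon_starts`` are ascending 0-based genomic left edges of 3-bp codon
    spans, each congruent to the frame's phase mod 3. ``scores`` are decibans,
    NaN where missing.
    """

    chrom: str
    frame: Frame
    codon_starts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    scores: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))

    def __post_init__(self) -> None:
        self.codon_starts = np.asarray(self.codon_starts, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.codon_starts.shape != self.scores.shape:
            raise ValueError("codon_starts and scores must have equal length")
        _validate_grid(self.codon_starts, self.frame.phase)
        if np.any(np.isinf(self.scores)):
            raise ValueError("scores must be finite where present")

    def __len__(self) -> int:
        return self.codon_starts.size

    @property
    def frame_id(self) -> int:
        return self.frame.frame_id

    def dropna(self) -> "CodonScoreTrack":
        """Normalize missing-by-NaN to missing-by-absence."""
        keep = ~np.isnan(self.scores)
        return CodonScoreTrack(
            self.chrom, self.frame, self.codon_starts[keep], self.scores[keep]
        )

    def dense(self) -> "CodonScoreTrack":
        """Fill grid gaps with NaN so consecutive codons differ by exactly 3."""
        if len(self) == 0:
            return self
        grid = np.arange(self.codon_starts[0], self.codon_starts[-1] + 3, 3)
        scores = np.full(grid.size, np.nan)
        scores[(self.codon_starts - grid[0]) // 3] = self.scores
        return CodonScoreTrack(self.chrom, self.frame, grid, scores)

    def score_at(self, starts: np.ndarray) -> np.ndarray:
        """Scores at the given codon starts; NaN where absent from the track."""
        starts = np.asarray(starts, dtype=np.int64)
        out = np.full(starts.shape, np.nan)
        if len(self) == 0:
            return out
        idx = np.searchsorted(self.codon_starts, starts)
        ok = (idx < len(self)) & (self.codon_starts[np.minimum(idx, len(self) - 1)] == starts)
        out[ok] = self.scores[idx[ok]]
        return out

    def content_equal(self, other: "CodonScoreTrack") -> bool:
        """Equality on non-missing content (the round-trip invariant)."""
        a, b = self.dropna(), other.dropna()
        return (
            a.chrom == b.chrom
            and a.frame == b.frame
            and np.array_equal(a.codon_starts, b.codon_starts)
            and np.allclose(a.scores, b.scores, rtol=0, atol=1e-9)
        )


@dataclass
class PowerTrack:
    """Per-codon relative branch length in [0, 1].

    Stored on a single codon grid (conventionally frame +0). Lookups for
    other frames resolve each query codon to the power block containing its
    left edge, since alignment power varies on scales far larger than one
    codon.
    """

    chrom: str
    codon_starts: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.codon_starts = np.asarray(self.codon_starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.codon_starts.shape != self.values.shape:
            raise ValueError("codon_starts and values must have equal length")
        _validate_grid(self.codon_starts, phase=None)
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("power values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.codon_starts.size

    def at(self, starts: np.ndarray) -> np.ndarray:
        """Power at arbitrary codon starts (containing-block lookup).

        Returns NaN for positions outside the track's coverage.
        """
        starts = np.asarray(starts, dtype=np.int64)
        out = np.full(starts.shape, np.nan)
        if len(self) == 0:
            return out
        idx = np.searchsorted(self.codon_starts, starts, side="right") - 1
        ok = idx >= 0
        covered = np.zeros(starts.shape, bool)
        covered[ok] = starts[ok] < self.codon_starts[idx[ok]] + 3
        out[covered] = self.values[idx[covered]]
        return out


# ---------------------------------------------------------------------------
# File I/O


def _parse_kv(tokens: list[str], lineno: int) -> dict[str, str]:
    out = {}
    for tok in tokens:
        if "=" not in tok:
            raise TrackFormatError(f"line {lineno}: malformed header token {tok!r}")
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def _read_track_lines(handle, expect_phase: int | None):
    """Parse wiggle fixedStep / bedGraph lines into (chrom, starts, values)."""
    chrom = None
    starts: list[int] = []
    values: list[float] = []
    mode = None  # "fixed" | "bedgraph"
    cur_start = step = None
    for lineno, raw in enumerate(handle, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("variableStep"):
            raise TrackFormatError(f"line {lineno}: variableStep wiggle not supported")
        if line.startswith("fixedStep"):
            kv = _parse_kv(line.split()[1:], lineno)
            try:
                block_chrom = kv["chrom"]
                cur_start = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", "1"))
                span = int(kv.get("span", "1"))
            except (KeyError, ValueError) as exc:
                raise TrackFormatError(f"line {lineno}: malformed fixedStep header") from exc
            if step != 3 or span != 3:
                raise TrackFormatError(
                    f"line {lineno}: codon track requires step=3 span=3, got step={step} span={span}"
                )
            if chrom is None:
                chrom = block_chrom
            elif block_chrom != chrom:
                raise TrackFormatError(f"line {lineno}: multiple chromosomes in one track")
            if expect_phase is not None and cur_start % 3 != expect_phase:
                raise TrackFormatError(
                    f"line {lineno}: block start {cur_start} not congruent to frame phase {expect_phase}"
                )
            mode = "fixed"
            continue
        fields = line.split()
        if mode == "fixed" and len(fields) == 1:
            starts.append(cur_start)
            values.append(float(fields[0]))
            cur_start += step
            continue
        if len(fields) == 4:  # bedGraph: chrom start end value (0-based half-open)
            mode = "bedgraph"
            c, s, e, v = fields
            s, e = int(s), int(e)
            if e - s != 3:
                raise TrackFormatError(
                    f"line {lineno}: bedGraph feature width {e - s} != 3 (codon span)"
                )
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise TrackFormatError(f"line {lineno}: multiple chromosomes in one track")
            if expect_phase is not None and s % 3 != expect_phase:
                raise TrackFormatError(
                    f"line {lineno}: feature start {s} not congruent to frame phase {expect_phase}"
                )
            starts.append(s)
            values.append(float(v))
            continue
        raise TrackFormatError(f"line {lineno}: unparseable line {line!r}")
    return chrom, np.array(starts, np.int64), np.array(values, np.float64)


def read_codon_track(path: str | Path, frame_id: int, chrom: str | None = None) -> CodonScoreTrack:
    """Read a per-codon score track (fixedStep wiggle or 3-bp bedGraph)."""
    frame = Frame.from_id(frame_id)
    with open(path) as handle:
        file_chrom, starts, values = _read_track_lines(handle, frame.phase)
    if file_chrom is None:
        file_chrom = chrom or "unknown"
    order = np.argsort(starts, kind="stable")
    return CodonScoreTrack(file_chrom, frame, starts[order], values[order])


def read_power_track(path: str | Path, chrom: str | None = None) -> PowerTrack:
    """Read a per-codon power track (same formats, no frame-phase constraint)."""
    with open(path) as handle:
        file_chrom, starts, values = _read_track_lines(handle, None)
    if file_chrom is None:
        file_chrom = chrom or "unknown"
    order = np.argsort(starts, kind="stable")
    return PowerTrack(file_chrom, starts[order], values[order])


def _write_fixedstep(out: io.TextIOBase, chrom: str, starts: np.ndarray, values: np.ndarray) -> None:
    if starts.size == 0:
        return
    block_break = np.flatnonzero(np.diff(starts) != 3)
    for lo, hi in zip(
        np.concatenate(([0], block_break + 1)),
        np.concatenate((block_break + 1, [starts.size])),
    ):
        out.write(f"fixedStep chrom={chrom} start={starts[lo] + 1} step=3 span=3\n")
        out.write("".join(f"{v:.12g}\n" for v in values[lo:hi]))


def write_codon_track(track: CodonScoreTrack, path: str | Path, name: str | None = None) -> None:
    """Write a score track as fixedStep wiggle; missing codons become block gaps."""
    t = track.dropna()
    with open(path, "w") as out:
        if name:
            out.write(f"track type=wiggle_0 name={name}\n")
        _write_fixedstep(out, t.chrom, t.codon_starts, t.scores)


def write_power_track(power: PowerTrack, path: str | Path, name: str | None = None) -> None:
    keep = ~np.isnan(power.values)
    with open(path, "w") as out:
        if name:
            out.write(f"track type=wiggle_0 name={name}\n")
        _write_fixedstep(out, power.chrom, power.codon_starts[keep], power.values[keep])


def mask_low_power(
    track: CodonScoreTrack, power: PowerTrack, cutoff: float = DEFAULT_POWER_CUTOFF
) -> CodonScoreTrack:
    """Set scores of codons with power below ``cutoff`` to missing.

    Power is resolved on the track's own grid when the grids coincide, and
    by containing-block lookup otherwise (a genome has one power track but
    six frame grids). Codons without power coverage are left untouched.
    Idempotent; ``cutoff <= 0`` is the identity.
    """
    if track.chrom != power.chrom:
        raise ValueError(
            f"chromosome mismatch: track {track.chrom!r} vs power {power.chrom!r}"
        )
    if cutoff <= 0 or len(track) == 0:
        return track
    p = power.at(track.codon_starts)
    masked = np.where(~np.isnan(p) & (p < cutoff), np.nan, track.scores)
    return CodonScoreTrack(track.chrom, track.frame, track.codon_starts.copy(), masked)
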