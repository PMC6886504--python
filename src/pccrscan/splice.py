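"""Position-weight scoring of candidate splice donors (GT) and acceptors (AG).

Exon-boundary hypotheses for candidate coding regions are supported by
scoring every GT (donor) and AG (acceptor) dinucleotide with a
position-specific log-odds model over a fixed window around the site. The
default model is a position-weight matrix trained from annotated splice
sites (pseudocount 1, background from genome composition); an externally
derived table — e.g. a maximum-entropy score table — can be loaded behind
the same interface.

Window geometry (positions relative to the intron boundary):

* donor: 3 exonic bases, then the intron's first 6 (``GT`` at intron
  positions 0-1) — a 9-mer;
* acceptor: the intron's last 20 bases (``AG`` at positions 18-19 of the
  window), then 3 exonic bases — a 23-mer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpliceModel", "train_splice_model", "scan_splice_sites", "MIN_TRAINING_SITES"]

MIN_TRAINING_SITES = 50
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: (exonic bases upstream of the intron boundary, intronic bases) per site kind
_WINDOWS = {"donor": (3, 6), "acceptor": (20, 3)}
#: offset of the GT/AG dinucleotide within the window
_DINUC_OFFSET = {"donor": 3, "acceptor": 18}
_DINUC = {"donor": "GT", "acceptor": "AG"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SpliceModel:
    """Position-specific log-odds table for one splice-site kind."""

    kind: str  # "donor" | "acceptor"
    log_odds: np.ndarray = field(repr=False)  # (window, 4)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25), repr=False)

    def __post_init__(self) -> None:
        if self.kind not in _WINDOWS:
            raise ValueError(f"kind must be 'donor' or 'acceptor', got {self.kind!r}")
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log-odds must be finite (apply pseudocounts)")

    @property
    def window(self) -> int:
        return self.log_odds.shape[0]

    @property
    def dinuc_offset(self) -> int:
        return _DINUC_OFFSET[self.kind]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds.argmax(axis=1))

    def score_kmer(self, kmer: str) -> float:
        """Score a window-length k-mer (sum of per-position log-odds, nats)."""
        if len(kmer) != self.window:
            raise ValueError(f"expected a {self.window}-mer, got length {len(kmer)}")
        total = 0.0
        for pos, base in enumerate(kmer.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                return float("nan")  # ambiguous base
            total += self.log_odds[pos, idx]
        return total

    # -- persistence (also the loader for externally supplied tables) -------

    def save(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "log_odds": self.log_odds.tolist(),
            "background": self.background.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SpliceModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            kind=payload["kind"],
            log_odds=np.asarray(payload["log_odds"]),
            background=np.asarray(payload.get("background", [0.25] * 4)),
        )


def _site_windows(sequence: str, ann, kind: str):
    """Extract training windows around annotated introns, sense orientation."""
    up, down = _WINDOWS[kind]
    length = up + down
    windows = []
    for tx in ann.transcripts.values():
        for intron_start, intron_end in tx.introns():
            if tx.strand == "+":
                pos = intron_start if kind == "donor" else intron_end
                lo = pos - up
                w = sequence[lo : lo + length]
            else:
                # biological donor is at the intron's right edge on minus strand
                pos = intron_end if kind == "donor" else intron_start
                if kind == "donor":
                    w = revcomp(sequence[pos - down : pos + up])
                else:
                    w = revcomp(sequence[pos - down : pos + up])
            if len(w) == length and set(w.upper()) <= set(_BASES):
                windows.append(w.upper())
    return windows


def train_splice_model(sequence: str, ann, kind: str) -> SpliceModel:
    """Train a position-weight model from annotated sites of one kind.

    Requires at least 50 training sites; counts get pseudocount 1 and the
    background is the overall base composition of ``sequence``.
    """
    windows = _site_windows(sequence, ann, kind)
    if len(windows) < MIN_TRAINING_SITES:
        raise ValueError(
            f"need >= {MIN_TRAINING_SITES} annotated {kind} sites, found {len(windows)}"
        )
    length = sum(_WINDOWS[kind])
    counts = np.ones((length, 4))  # pseudocount 1
    for w in windows:
        for pos, base in enumerate(w):
            counts[pos, _BASE_INDEX[base]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    upper = sequence.upper()
    bg_counts = np.array([upper.count(b) for b in _BASES], dtype=float) + 1.0
    background = bg_counts / bg_counts.sum()
    return SpliceModel(kind=kind, log_odds=np.log(freqs / background), background=background)


def scan_splice_sites(sequence: str, model: SpliceModel, strand: str = "+"):
    """Score every GT/AG site on one strand.

    Returns ``(positions, scores)``: 0-based genomic positions of the first
    base of the dinucleotide (on the forward coordinate system for both
    strands) and the window log-odds score. Sites whose window extends past
    the sequence ends are skipped. Scanning the minus strand of a sequence
    equals scanning the plus strand of its reverse complement, with
    coordinates mapped back.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    seq = sequence.upper() if strand == "+" else revcomp(sequence).upper()
    dinuc = _DINUC[model.kind]
    off = model.dinuc_offset
    length = model.window
    positions, scores = [], []
    start = seq.find(dinuc)
    while start != -1:
        lo = start - off
        if lo >= 0 and lo + length <= len(seq):
            s = model.score_kmer(seq[lo : lo + length])
            if not np.isnan(s):
                if strand == "+":
                    positions.append(start)
                else:
                    # first dinucleotide base on the scanned strand maps to
                    # the genomic position of its complement's left edge
                    positions.append(len(sequence) - start - 2)
                scores.append(s)
        start = seq.find(dinuc, start + 1)
    pos = np.asarray(positions, dtype=np.int64)
    sc = np.asarray(scores, dtype=float)
    if strand == "-":
        order = np.argsort(pos)
        pos, sc = pos[order], sc[order]
    return pos, sc
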