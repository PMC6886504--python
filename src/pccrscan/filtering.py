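"""Annotation-aware exclusion cascade turning raw regions into PCCRs.

A candidate list built genome-wide is dominated by already-annotated coding
sequence, by its antisense-frame "ghost" signal, and by pseudogenes (whose
alignments often retain a protein-coding signature even though the locus no
longer codes). The cascade removes, in order: (1) codons overlapping
annotated CDS in the *same* frame, (2) codons overlapping CDS in the
*antisense* frame, (3) codons overlapping pseudogene annotation in any
frame on either strand, then (4) regions shorter than nine codons, and
(5) regions the antisense SVM scores below threshold. Finally (6)
non-overlapping fragments of partially excluded regions are added back,
provided they pass the length and antisense conditions — such fragments can
be extensions of known exons or ORFs. Survivors are PhyloCSF Candidate
Coding Regions (PCCRs).

Trimming is at whole-codon granularity: a codon is overlapped if any of its
three bases intersects the annotation feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .frames import FRAMES, Frame, antisense_frame
from .hmm import PhyloCSFRegion

__all__ = [
    "AnnotationSet",
    "Transcript",
    "Pccr",
    "OverlapReport",
    "ExclusionTally",
    "read_annotation",
    "classify_overlap",
    "build_pccrs",
    "MIN_CODONS",
    "ANTISENSE_THRESHOLD",
]

MIN_CODONS = 9
ANTISENSE_THRESHOLD = 0.3


@dataclass
class Transcript:
    """Coding transcript: ordered CDS intervals on the genome (0-based half-open)."""

    tid: str
    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]  # sorted by genomic start
    biotype: str = "protein_coding"

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.cds[i][1], self.cds[i + 1][0]) for i in range(len(self.cds) - 1)
        ]


def _cds_codon_span(start: int, end: int, strand: str, phase: int):
    """Complete-codon span and frame of a CDS exon given its GTF phase.

    Phase counts bases at the feature's 5' end belonging to the previous
    exon's codon. Returns (span_start, span_end, frame_id) or None when the
    feature holds no complete codon.
    """
    if strand == "+":
        first = start + phase
        n = (end - first) // 3
        if n < 1:
            return None
        return first, first + 3 * n, Frame("+", first % 3).frame_id
    first_left = end - phase - 3  # left edge of 5'-most complete codon
    n = (end - phase - start) // 3
    if n < 1:
        return None
    span_start = end - phase - 3 * n
    return span_start, end - phase, Frame("-", first_left % 3).frame_id


@dataclass
class AnnotationSet:
    """Indexed CDS and pseudogene annotation for overlap queries.

    ``cds_frames[(chrom, frame_id)]`` holds the complete-codon spans of CDS
    exons assigned to that frame; ``pseudogenes[chrom]`` holds pseudogene
    exon intervals, strand- and frame-agnostic. ``transcripts`` carry full
    CDS structure for the variant module; ``gene_cds`` maps gene id to its
    framed CDS intervals for gene-rank queries.
    """

    cds_frames: dict = field(default_factory=dict)
    pseudogenes: dict = field(default_factory=dict)
    transcripts: dict = field(default_factory=dict)
    gene_cds: dict = field(default_factory=dict)

    def _tree(self, chrom: str, frame_id: int) -> IntervalTree:
        return self.cds_frames.get((chrom, frame_id), IntervalTree())

    def add_cds_exon(self, chrom: str, start: int, end: int, strand: str, phase: int,
                     gene_id: str | None = None) -> None:
        span = _cds_codon_span(start, end, strand, phase)
        if span is None:
            return
        s, e, fid = span
        self.cds_frames.setdefault((chrom, fid), IntervalTree()).addi(s, e)
        if gene_id is not None:
            self.gene_cds.setdefault(gene_id, []).append((chrom, s, e, fid))

    def add_pseudogene_exon(self, chrom: str, start: int, end: int) -> None:
        if end > start:
            self.pseudogenes.setdefault(chrom, IntervalTree()).addi(start, end)

    # -- queries ------------------------------------------------------------

    def overlaps_same_frame(self, chrom: str, frame_id: int, start: int, end: int):
        return sorted(
            (max(iv.begin, start), min(iv.end, end))
            for iv in self._tree(chrom, frame_id).overlap(start, end)
        )

    def overlaps_antisense_frame(self, chrom: str, frame_id: int, start: int, end: int):
        anti = antisense_frame(Frame.from_id(frame_id)).frame_id
        return self.overlaps_same_frame(chrom, anti, start, end)

    def overlaps_pseudogene(self, chrom: str, start: int, end: int):
        tree = self.pseudogenes.get(chrom, IntervalTree())
        return sorted(
            (max(iv.begin, start), min(iv.end, end)) for iv in tree.overlap(start, end)
        )

    # -- summaries feeding HMM initialization -------------------------------

    def cds_exon_codon_lengths(self) -> np.ndarray:
        lens = []
        for tree in self.cds_frames.values():
            lens.extend((iv.end - iv.begin) // 3 for iv in tree)
        return np.asarray(lens, dtype=float)

    def same_frame_gap_lengths(self) -> np.ndarray:
        """Base gaps between consecutive CDS spans in the same (chrom, frame)."""
        gaps = []
        for tree in self.cds_frames.values():
            ivs = sorted(tree)
            for a, b in zip(ivs, ivs[1:]):
                if b.begin > a.end:
                    gaps.append(b.begin - a.end)
        return np.asarray(gaps, dtype=float)


def _attr(feature, *names, default=None):
    for n in names:
        if n in feature.attributes:
            v = feature.attributes[n]
            return v[0] if isinstance(v, list) else v
    return default


def read_annotation(path) -> AnnotationSet:
    """Read GTF/GFF3 into an :class:`AnnotationSet`.

    CDS features need a phase (GTF frame column); a missing phase is
    inferred from the running CDS length of the transcript, with a warning.
    Genes whose biotype contains the substring "pseudogene" contribute
    their exon intervals (or the gene span, if exon-less) to the pseudogene
    index and nothing to the coding frames.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    ann = AnnotationSet()

    pseudo_genes = set()
    for gene in db.features_of_type(("gene",)):
        biotype = _attr(gene, "gene_biotype", "gene_type", "biotype", default="") or ""
        gid = _attr(gene, "gene_id", "ID", default=gene.id)
        if "pseudogene" in biotype:
            pseudo_genes.add(gid)
            exons = list(db.children(gene, featuretype="exon"))
            if exons:
                for ex in exons:
                    ann.add_pseudogene_exon(ex.seqid, ex.start - 1, ex.end)
            else:
                ann.add_pseudogene_exon(gene.seqid, gene.start - 1, gene.end)

    for tx in db.features_of_type(("transcript", "mRNA")):
        gid = _attr(tx, "gene_id", "Parent", default="")
        if gid in pseudo_genes:
            continue
        tid = _attr(tx, "transcript_id", "ID", default=tx.id)
        cds_feats = sorted(db.children(tx, featuretype="CDS"), key=lambda f: f.start)
        if not cds_feats:
            continue  # noncoding transcript: contributes nothing to coding frames
        strand = tx.strand
        # infer missing phases from the running CDS length (5' to 3')
        ordered = cds_feats if strand == "+" else cds_feats[::-1]
        running = 0
        phases = {}
        for f in ordered:
            inferred = (3 - running % 3) % 3
            if f.frame in (".", None, ""):
                warnings.warn(
                    f"CDS of {tid} at {f.seqid}:{f.start}-{f.end} lacks phase; "
                    f"inferred {inferred} from transcript structure"
                )
                phases[id(f)] = inferred
            else:
                phases[id(f)] = int(f.frame)
            running += f.end - f.start + 1
        cds_list = []
        for f in cds_feats:
            start0, end0 = f.start - 1, f.end  # GTF is 1-based closed
            ann.add_cds_exon(f.seqid, start0, end0, strand, phases[id(f)], gene_id=gid)
            cds_list.append((start0, end0))
        biotype = _attr(tx, "transcript_biotype", "transcript_type", default="protein_coding")
        ann.transcripts[tid] = Transcript(
            tid=tid, gene_id=gid, chrom=tx.seqid, strand=strand,
            cds=cds_list, biotype=biotype or "protein_coding",
        )
    return ann


# ---------------------------------------------------------------------------
# Overlap classification


_CATEGORIES = ("same_frame_cds", "antisense_frame_cds", "pseudogene_any")


@dataclass
class OverlapReport:
    """Which annotation categories a region touches, with sub-intervals."""

    same_frame_cds: list = field(default_factory=list)
    antisense_frame_cds: list = field(default_factory=list)
    pseudogene_any: list = field(default_factory=list)

    @property
    def category(self) -> str:
        for name in _CATEGORIES:
            if getattr(self, name):
                return name
        return "none"


def classify_overlap(region: PhyloCSFRegion, ann: AnnotationSet) -> OverlapReport:
    """Report annotation overlap of a region (cascade priority order).

    Same-frame requires identical strand and phase (codon grids coincide);
    antisense uses the third-position-sharing frame; pseudogene overlap is
    frame- and strand-agnostic.
    """
    return OverlapReport(
        same_frame_cds=ann.overlaps_same_frame(
            region.chrom, region.frame.frame_id, region.start, region.end
        ),
        antisense_frame_cds=ann.overlaps_antisense_frame(
            region.chrom, region.frame.frame_id, region.start, region.end
        ),
        pseudogene_any=ann.overlaps_pseudogene(region.chrom, region.start, region.end),
    )


# ---------------------------------------------------------------------------
# The cascade


@dataclass
class Pccr:
    """A surviving candidate coding region with provenance and rank slots."""

    region: PhyloCSFRegion
    provenance: str  # untouched | trimmed | added_back_fragment
    exclusion_history: list = field(default_factory=list)
    source_index: int | None = None
    features: object | None = None
    antisense_prob: float | None = None
    svm_score: float | None = None
    rank: int | None = None
    cluster_id: int | None = None

    # convenience passthroughs
    @property
    def chrom(self):
        return self.region.chrom

    @property
    def frame(self):
        return self.region.frame

    @property
    def start(self):
        return self.region.start

    @property
    def end(self):
        return self.region.end

    @property
    def n_codons(self):
        return self.region.n_codons

    @property
    def strand(self):
        return self.region.frame.strand


@dataclass
class ExclusionTally:
    """Per-step bookkeeping of the cascade (counts of *input regions*,
    except ``added_back_fragments`` which counts surviving fragments and
    ``n_pccrs`` which counts output records)."""

    n_input: int = 0
    excluded_same_frame: int = 0
    excluded_antisense_frame: int = 0
    excluded_pseudogene: int = 0
    excluded_short: int = 0
    excluded_antisense_svm: int = 0
    kept_untouched: int = 0
    kept_via_fragments: int = 0
    added_back_fragments: int = 0
    n_pccrs: int = 0

    @property
    def fully_excluded(self) -> int:
        return (
            self.excluded_same_frame
            + self.excluded_antisense_frame
            + self.excluded_pseudogene
            + self.excluded_short
            + self.excluded_antisense_svm
        )

    @property
    def kept(self) -> int:
        return self.kept_untouched + self.kept_via_fragments

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_regions", self.n_input),
            ("excluded_same_frame_cds", self.excluded_same_frame),
            ("excluded_antisense_frame_cds", self.excluded_antisense_frame),
            ("excluded_pseudogene", self.excluded_pseudogene),
            ("excluded_shorter_than_min", self.excluded_short),
            ("excluded_antisense_svm", self.excluded_antisense_svm),
            ("added_back_fragments", self.added_back_fragments),
            ("kept_regions", self.kept),
            ("pccrs", self.n_pccrs),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


def _codon_overlap_mask(codon_starts: np.ndarray, intervals) -> np.ndarray:
    """True where a codon's 3-bp span intersects any interval."""
    mask = np.zeros(codon_starts.size, dtype=bool)
    for s, e in intervals:
        mask |= (codon_starts < e) & (codon_starts + 3 > s)
    return mask


def build_pccrs(
    regions,
    ann: AnnotationSet | None,
    antisense_prob=None,
    min_codons: int = MIN_CODONS,
    antisense_threshold: float = ANTISENSE_THRESHOLD,
):
    """Run the exclusion cascade; returns ``(pccrs, tally)``.

    ``antisense_prob`` is a callable mapping a region to its antisense-SVM
    probability of being sense-coding (``None`` = pass-through, for testing
    or unranked runs). With ``ann=None`` the cascade reduces to the length
    and antisense-SVM filters. Output is deterministic given the callable.
    """
    prob = antisense_prob if antisense_prob is not None else (lambda region: 1.0)
    tally = ExclusionTally(n_input=len(regions))
    pccrs: list[Pccr] = []

    def passes(candidate: PhyloCSFRegion, history: list) -> Pccr | None:
        if candidate.n_codons < min_codons:
            history.append("shorter_than_min")
            return None
        p = float(prob(candidate))
        if p < antisense_threshold:
            history.append("antisense_svm")
            return None
        prov = "untouched" if not history else "added_back_fragment"
        return Pccr(
            region=candidate,
            provenance=prov,
            exclusion_history=list(history),
            antisense_prob=p,
        )

    for idx, region in enumerate(regions):
        starts = region.codon_starts()
        excl = np.zeros(starts.size, dtype=np.int8)
        if ann is not None:
            report = classify_overlap(region, ann)
            for step, name in enumerate(_CATEGORIES, start=1):
                mask = _codon_overlap_mask(starts, getattr(report, name))
                excl[(excl == 0) & mask] = step
        touched = sorted({int(v) for v in excl if v})
        history = [_CATEGORIES[v - 1] for v in touched]
        if np.all(excl != 0):
            # fully removed by annotation overlap; tallied at the first
            # cascade step that touched it
            first = touched[0]
            if first == 1:
                tally.excluded_same_frame += 1
            elif first == 2:
                tally.excluded_antisense_frame += 1
            else:
                tally.excluded_pseudogene += 1
            continue
        free = excl == 0
        diff = np.diff(np.concatenate(([0], free.astype(np.int8), [0])))
        frag_bounds = list(zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)))
        kept_here = []
        drop_reason = None
        for lo, hi in frag_bounds:
            if free.all():
                candidate = region
            else:
                candidate = replace(
                    region,
                    start=int(starts[lo]),
                    end=int(starts[hi - 1]) + 3,
                    n_codons=int(hi - lo),
                )
            p = passes(candidate, list(history))
            if p is None:
                drop_reason = (
                    "short" if candidate.n_codons < min_codons else "svm"
                )
            else:
                p.source_index = idx
                kept_here.append(p)
        if kept_here:
            if free.all():
                tally.kept_untouched += 1
            else:
                tally.kept_via_fragments += 1
                tally.added_back_fragments += len(kept_here)
            pccrs.extend(kept_here)
        else:
            if touched:
                first = touched[0]
                if first == 1:
                    tally.excluded_same_frame += 1
                elif first == 2:
                    tally.excluded_antisense_frame += 1
                else:
                    tally.excluded_pseudogene += 1
            elif drop_reason == "short":
                tally.excluded_short += 1
            else:
                tally.excluded_antisense_svm += 1
    tally.n_pccrs = len(pccrs)
    return pccrs, tally
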