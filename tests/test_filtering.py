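"""Annotation parsing and the exclusion cascade."""

import numpy as np
import pytest

from pccrscan.filtering import (
    AnnotationSet,
    Pccr,
    build_pccrs,
    classify_overlap,
    read_annotation,
)
from pccrscan.frames import Frame, antisense_frame
from pccrscan.hmm import PhyloCSFRegion


def region(start, n_codons, frame_id=0, chrom="chr1", post=0.9, mean=5.0):
    f = Frame.from_id(frame_id)
    assert start % 3 == f.phase
    return PhyloCSFRegion(chrom, f, start, start + 3 * n_codons, n_codons, post, mean)


GTF_SINGLE = (
    'chr1\tx\tgene\t101\t130\t.\t+\t.\tgene_id "g1"; gene_biotype "protein_coding";\n'
    'chr1\tx\ttranscript\t101\t130\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";\n'
    'chr1\tx\texon\t101\t130\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";\n'
    'chr1\tx\tCDS\t101\t130\t.\t+\t0\tgene_id "g1"; transcript_id "g1.t1";\n'
)


def test_read_annotation_single_exon_cds(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(GTF_SINGLE)
    ann = read_annotation(p)
    # 1-based 101-130 -> 0-based [100, 130): 10 codons in plus frame 100 % 3 == 1
    fid = Frame("+", 100 % 3).frame_id
    assert ann.overlaps_same_frame("chr1", fid, 100, 130) == [(100, 130)]
    assert ann.cds_exon_codon_lengths().tolist() == [10.0]
    assert ann.transcripts["g1.t1"].cds == [(100, 130)]


def test_read_annotation_two_exon_phase_arithmetic(tmp_path):
    # exon1: 1-based 101-110 (10 bp, phase 0 -> 3 complete codons at [100,109));
    # 10 bp leaves 1 base, so exon2 phase is 2; exon2 1-based 202-217:
    # first complete codon starts at 0-based 203, a different frame class.
    gtf = (
        'chr1\tx\tgene\t101\t217\t.\t+\t.\tgene_id "g2"; gene_biotype "protein_coding";\n'
        'chr1\tx\ttranscript\t101\t217\t.\t+\t.\tgene_id "g2"; transcript_id "g2.t1";\n'
        'chr1\tx\tCDS\t101\t110\t.\t+\t0\tgene_id "g2"; transcript_id "g2.t1";\n'
        'chr1\tx\tCDS\t202\t217\t.\t+\t2\tgene_id "g2"; transcript_id "g2.t1";\n'
    )
    p = tmp_path / "a.gtf"
    p.write_text(gtf)
    ann = read_annotation(p)
    f1 = Frame("+", 100 % 3).frame_id
    f2 = Frame("+", 203 % 3).frame_id
    assert ann.overlaps_same_frame("chr1", f1, 0, 1000) == [(100, 109)]
    assert ann.overlaps_same_frame("chr1", f2, 0, 1000) == [(203, 215)]
    assert f1 != f2  # the frame changed across the intron


def test_read_annotation_exon_only_contributes_nothing(tmp_path):
    gtf = (
        'chr1\tx\tgene\t101\t130\t.\t+\t.\tgene_id "g3"; gene_biotype "lincRNA";\n'
        'chr1\tx\ttranscript\t101\t130\t.\t+\t.\tgene_id "g3"; transcript_id "g3.t1";\n'
        'chr1\tx\texon\t101\t130\t.\t+\t.\tgene_id "g3"; transcript_id "g3.t1";\n'
    )
    p = tmp_path / "a.gtf"
    p.write_text(gtf)
    ann = read_annotation(p)
    assert not ann.cds_frames
    assert not ann.transcripts  # no CDS -> not a coding transcript


def test_missing_phase_inferred_with_warning(tmp_path):
    gtf = GTF_SINGLE.replace("\t+\t0\tgene_id", "\t+\t.\tgene_id")
    p = tmp_path / "a.gtf"
    p.write_text(gtf)
    with pytest.warns(UserWarning, match="lacks phase"):
        ann = read_annotation(p)
    fid = Frame("+", 100 % 3).frame_id
    assert ann.overlaps_same_frame("chr1", fid, 100, 130) == [(100, 130)]


def test_pseudogene_biotype_substring_match(tmp_path):
    gtf = (
        'chr1\tx\tgene\t51\t110\t.\t-\t.\tgene_id "ps"; gene_biotype "unprocessed_pseudogene";\n'
        'chr1\tx\ttranscript\t51\t110\t.\t-\t.\tgene_id "ps"; transcript_id "ps.t1";\n'
        'chr1\tx\texon\t51\t80\t.\t-\t.\tgene_id "ps"; transcript_id "ps.t1";\n'
    )
    p = tmp_path / "a.gtf"
    p.write_text(gtf)
    ann = read_annotation(p)
    assert ann.overlaps_pseudogene("chr1", 0, 200) == [(50, 80)]
    assert not ann.cds_frames


def _toy_ann():
    ann = AnnotationSet()
    # CDS of 20 codons at [300, 360) on +, phase 0 -> frame id (300 % 3) = 0
    ann.add_cds_exon("chr1", 300, 360, "+", 0, gene_id="g")
    return ann


def test_classify_overlap_same_frame_requires_strand_and_phase():
    ann = _toy_ann()
    inside = region(312, 5, frame_id=0)
    rep = classify_overlap(inside, ann)
    assert rep.category == "same_frame_cds"
    assert rep.same_frame_cds == [(312, 327)]
    # same strand, different phase: neither same-frame nor antisense
    other_phase = region(313, 5, frame_id=1)
    assert classify_overlap(other_phase, ann).category == "none"


def test_classify_overlap_antisense_via_frame_pairing():
    ann = _toy_ann()
    cds_frame = Frame.from_id(0)
    anti = antisense_frame(cds_frame)  # the minus frame sharing third positions
    r = region(302, 5, frame_id=anti.frame_id)
    assert r.frame.strand == "-"
    rep = classify_overlap(r, ann)
    assert rep.category == "antisense_frame_cds"


def test_classify_overlap_pseudogene_any_frame():
    ann = AnnotationSet()
    ann.add_pseudogene_exon("chr1", 100, 200)
    for fid in range(6):
        f = Frame.from_id(fid)
        start = 99 + ((f.phase - 99) % 3)
        rep = classify_overlap(region(start, 10, frame_id=fid), ann)
        assert rep.category == "pseudogene_any"


def test_nine_codon_rule():
    pccrs, tally = build_pccrs([region(0, 8)], None)
    assert pccrs == [] and tally.excluded_short == 1
    pccrs, tally = build_pccrs([region(0, 9)], None)
    assert len(pccrs) == 1 and pccrs[0].provenance == "untouched"


def test_partial_same_frame_overlap_yields_added_back_fragment():
    ann = AnnotationSet()
    ann.add_cds_exon("chr1", 0, 45, "+", 0)  # covers the left 15 codons
    pccrs, tally = build_pccrs([region(0, 30)], ann)
    assert len(pccrs) == 1
    frag = pccrs[0]
    assert frag.provenance == "added_back_fragment"
    assert (frag.start, frag.end, frag.n_codons) == (45, 90, 15)
    assert frag.exclusion_history == ["same_frame_cds"]
    assert tally.added_back_fragments == 1 and tally.kept_via_fragments == 1


def test_codon_granularity_trimming():
    ann = AnnotationSet()
    # pseudogene feature ends one base into codon 10 of the region
    ann.add_pseudogene_exon("chr1", 0, 31)
    pccrs, _ = build_pccrs([region(0, 30)], ann)
    # codon [30, 33) intersects feature base 30 -> whole codon trimmed
    assert pccrs[0].start == 33
    assert pccrs[0].n_codons == 19
    assert pccrs[0].exclusion_history == ["pseudogene_any"]


def test_antisense_svm_threshold_applied():
    weak = region(0, 20, mean=1.0)
    strong = region(60, 20, mean=9.0)
    prob = lambda r: 0.1 if r.mean_score < 5 else 0.9
    pccrs, tally = build_pccrs([weak, strong], None, antisense_prob=prob)
    assert [p.start for p in pccrs] == [60]
    assert tally.excluded_antisense_svm == 1
    assert pccrs[0].antisense_prob == pytest.approx(0.9)


def test_cascade_conservation_and_requery(small_scan, small_ann):
    tally = small_scan.tally
    assert tally.n_input == tally.kept + tally.fully_excluded
    for p in small_scan.pccrs:
        assert p.n_codons >= 9
        rep = classify_overlap(p.region, small_ann)
        assert rep.category == "none"  # no residual overlap of any kind
        assert p.antisense_prob is None or p.antisense_prob >= 0.3


def test_trimmed_codon_accounting(small_scan, small_ann):
    """For every input region, surviving + excluded codons == original codons."""
    by_source = {}
    for p in small_scan.pccrs:
        by_source.setdefault(p.source_index, []).append(p)
    for idx, parts in by_source.items():
        src = small_scan.regions[idx]
        kept = sum(p.n_codons for p in parts)
        starts = src.codon_starts()
        from pccrscan.filtering import _codon_overlap_mask

        rep = classify_overlap(src, small_ann)
        excluded = (
            _codon_overlap_mask(starts, rep.same_frame_cds)
            | _codon_overlap_mask(starts, rep.antisense_frame_cds)
            | _codon_overlap_mask(starts, rep.pseudogene_any)
        ).sum()
        dropped_short_or_svm = src.n_codons - excluded - kept
        assert dropped_short_or_svm >= 0
        assert kept + excluded + dropped_short_or_svm == src.n_codons


def test_no_annotation_reduces_to_length_and_svm_filters():
    regions = [region(0, 5), region(30, 12), region(90, 40)]
    pccrs, tally = build_pccrs(regions, None)
    assert [p.n_codons for p in pccrs] == [12, 40]
    assert all(p.provenance == "untouched" for p in pccrs)
    assert tally.excluded_short == 1
    assert tally.fully_excluded + tally.kept == len(regions)


def test_cascade_deterministic(small_scan, small_ann):
    pccrs1, t1 = build_pccrs(small_scan.regions, small_ann)
    pccrs2, t2 = build_pccrs(small_scan.regions, small_ann)
    assert [(p.start, p.end, p.frame.frame_id) for p in pccrs1] == [
        (p.start, p.end, p.frame.frame_id) for p in pccrs2
    ]
    assert t1 == t2
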