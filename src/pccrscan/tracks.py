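"""Browser-track emission: wiggle, BED and track-hub descriptors.

One bundle collects everything a genome browser needs to inspect the scan:
per-frame raw score wiggle, per-frame HMM-smoothed log-odds wiggle,
per-frame region BED shaded by maximum coding posterior (score column =
round(1000 * posterior)), a single combined PCCR track with the rank in the
name field and strand-colored items (green = plus, red = minus), splice
prediction bedGraphs, and a UCSC-style hub.txt / genomes.txt / trackDb.txt
trio. All BED records are 0-based half-open and sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scores import CodonScoreTrack, PowerTrack, write_codon_track, write_power_track

__all__ = ["TrackBundle", "write_bundle", "read_bed"]

_PLUS_RGB = "0,128,0"
_MINUS_RGB = "200,0,0"


@dataclass
class TrackBundle:
    """Paths of the files a :func:`write_bundle` call produced."""

    out_dir: Path
    raw_wiggles: dict = field(default_factory=dict)
    smoothed_wiggles: dict = field(default_factory=dict)
    region_beds: dict = field(default_factory=dict)
    pccr_bed: Path | None = None
    splice_bedgraphs: dict = field(default_factory=dict)
    power_wiggle: Path | None = None
    hub_files: list = field(default_factory=list)


def _bed_score(posterior: float) -> int:
    return int(np.clip(round(1000 * posterior), 0, 1000))


def _write_region_bed(regions, path: Path) -> None:
    rows = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as out:
        for r in rows:
            out.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.frame}\t"
                f"{_bed_score(r.max_coding_posterior)}\t{r.frame.strand}\n"
            )


def _write_pccr_bed(pccrs, path: Path) -> None:
    rows = sorted(pccrs, key=lambda p: (p.chrom, p.start, p.end))
    with open(path, "w") as out:
        for p in rows:
            rgb = _PLUS_RGB if p.strand == "+" else _MINUS_RGB
            score = _bed_score(p.svm_score if p.svm_score is not None else 0.0)
            name = str(p.rank) if p.rank is not None else "."
            out.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\t{p.strand}\t"
                f"{p.start}\t{p.end}\t{rgb}\n"
            )


def _write_bedgraph(chrom: str, positions, values, path: Path, span: int = 2) -> None:
    with open(path, "w") as out:
        for pos, val in zip(positions, values):
            out.write(f"{chrom}\t{pos}\t{pos + span}\t{val:g}\n")


def read_bed(path) -> list[tuple]:
    """Parse a BED file back into (chrom, start, end, name, score, strand) rows."""
    rows = []
    with open(path) as handle:
        for line in handle:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            rows.append(
                (
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    f[3] if len(f) > 3 else ".",
                    int(f[4]) if len(f) > 4 else 0,
                    f[5] if len(f) > 5 else ".",
                )
            )
    return rows


def write_bundle(
    out_dir,
    raw_tracks: dict[int, CodonScoreTrack] | None = None,
    smoothed_tracks: dict[int, CodonScoreTrack] | None = None,
    regions_by_frame: dict[int, list] | None = None,
    pccrs=None,
    splice_scores: dict[str, tuple] | None = None,
    power: PowerTrack | None = None,
    genome_name: str = "synthetic",
) -> TrackBundle:
    """Write all browser artifacts under ``out_dir`` and describe them in a hub.

    ``splice_scores`` maps a label (e.g. ``"donor_plus"``) to
    ``(chrom, positions, scores)``. Every PCCR appears on exactly one line
    of the combined track, its rank in the name field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = TrackBundle(out_dir=out_dir)
    track_decls = []

    for fid, track in (raw_tracks or {}).items():
        path = out_dir / f"phylocsf_raw_f{fid}.wig"
        write_codon_track(track, path, name=f"PhyloCSFraw{fid}")
        bundle.raw_wiggles[fid] = path
        track_decls.append((path.name, f"PhyloCSFraw{fid}", "wig"))
    for fid, track in (smoothed_tracks or {}).items():
        path = out_dir / f"phylocsf_smoothed_f{fid}.wig"
        write_codon_track(track, path, name=f"PhyloCSF{fid}")
        bundle.smoothed_wiggles[fid] = path
        track_decls.append((path.name, f"PhyloCSF{fid}", "wig"))
    for fid, regions in (regions_by_frame or {}).items():
        path = out_dir / f"phylocsf_regions_f{fid}.bed"
        _write_region_bed(regions, path)
        bundle.region_beds[fid] = path
        track_decls.append((path.name, f"PhyloCSFRegns{fid}", "bed"))
    if pccrs is not None:
        path = out_dir / "pccrs.bed"
        _write_pccr_bed(pccrs, path)
        bundle.pccr_bed = path
        track_decls.append((path.name, "PhyloCSFNovel", "bed"))
    for label, (chrom, positions, values) in (splice_scores or {}).items():
        path = out_dir / f"splice_{label}.bedGraph"
        _write_bedgraph(chrom, positions, values, path)
        bundle.splice_bedgraphs[label] = path
        track_decls.append((path.name, f"SplicePred_{label}", "bedGraph"))
    if power is not None:
        path = out_dir / "power.wig"
        write_power_track(power, path, name="PhyloCSFpower")
        bundle.power_wiggle = path
        track_decls.append((path.name, "PhyloCSFpower", "wig"))

    hub = out_dir / "hub.txt"
    hub.write_text(
        "hub pccrscan\nshortLabel pccrscan\nlongLabel candidate coding region scan\n"
        "genomesFile genomes.txt\nemail nobody@example.org\n"
    )
    genomes = out_dir / "genomes.txt"
    genomes.write_text(f"genome {genome_name}\ntrackDb trackDb.txt\n")
    trackdb = out_dir / "trackDb.txt"
    with open(trackdb, "w") as out:
        for fname, label, kind in track_decls:
            out.write(
                f"track {label}\nshortLabel {label}\nlongLabel {label}\n"
                f"type {kind}\nbigDataUrl {fname}\nvisibility full\n\n"
            )
    bundle.hub_files = [hub, genomes, trackdb]
    return bundle
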