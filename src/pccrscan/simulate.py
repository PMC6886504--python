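"""Synthetic genomes with planted ground truth for end-to-end testing.

Generates a coherent set of inputs — genome FASTA, GTF annotation, six
per-frame score wiggles, a power wiggle, and an SNV table — in which every
downstream call has a known right answer. The construction mirrors the
structures the scan exploits in real data:

* coding exons carry per-codon scores drawn from a coding distribution in
  their true genomic frame (default N(+4, 6) decibans; single codons are
  deliberately uninformative, regions are not);
* each coding codon's *antisense-frame* partner carries an attenuated copy
  of the sense score over a contiguous sub-stretch of the exon — the
  "ghost" signal, shorter and weaker than the sense region;
* pseudogene exons carry coding-like scores (their alignments retain a
  protein-coding signature) but are annotated with a pseudogene biotype;
* inter-exon gaps are drawn from a three-component exponential mixture, the
  structure the HMM's three noncoding states model;
* splice dinucleotides are planted with consensus context, SNVs with known
  consequence classes and class-specific derived-allele-frequency
  distributions, and a fraction of them with genome-wide significant
  association p-values.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .frames import Frame, antisense_frame
from .scores import CodonScoreTrack, PowerTrack, write_codon_track, write_power_track
from .splice import revcomp
from .variants import SnvRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate",
    "simulate_gap_track",
    "evaluate_recovery",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions of the synthetic genome (defaults are the ones used
    throughout the test suite; see docs/methods.md for rationale)."""

    seed: int
    genome_length: int = 2_500_000
    chrom: str = "chr1"
    n_genes: int = 60
    n_pseudogenes: int = 10
    n_lncrnas: int = 20
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_codons: tuple[int, int] = (15, 60)
    pseudogene_codons: tuple[int, int] = (20, 80)
    coding_score_mean: float = 4.0
    coding_score_sd: float = 6.0
    noncoding_score_mean: float = -4.0
    noncoding_score_sd: float = 6.0
    ghost_factor: float = 0.5
    ghost_fraction: float = 0.6
    n_decoys: int = 500
    decoy_codons: tuple[int, int] = (5, 25)
    decoy_score_mean: float = 2.0
    gap_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    gap_means_codons: tuple[float, float, float] = (10.0, 300.0, 10_000.0)
    intron_bp_bounds: tuple[int, int] = (60, 30_000)
    power_segment_bp: int = 5_000
    low_power_fraction: float = 0.05
    low_power_range: tuple[float, float] = (0.02, 0.08)
    high_power_range: tuple[float, float] = (0.6, 1.0)
    snvs_per_class: dict = field(
        default_factory=lambda: {
            "synonymous": 250,
            "missense": 250,
            "nonsense": 120,
            "splice_disrupting": 20,
            "noncoding": 200,
        }
    )
    daf_beta: dict = field(
        default_factory=lambda: {
            "synonymous": (0.8, 2.2),
            "missense": (0.5, 3.5),
            "nonsense": (0.3, 6.0),
            "splice_disrupting": (0.3, 6.0),
            "noncoding": (1.0, 1.0),
        }
    )
    gwas_per_class: dict = field(
        default_factory=lambda: {
            "missense": 15,
            "nonsense": 3,
            "splice_disrupting": 2,
            "synonymous": 5,
            "noncoding": 5,
        }
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if abs(sum(self.gap_weights) - 1.0) > 1e-9:
            raise ValueError("gap_weights must sum to 1")
        if not 0.0 <= self.ghost_factor <= 1.0:
            raise ValueError("ghost_factor must lie in [0, 1]")


@dataclass
class GeneTruth:
    gene_id: str
    strand: str
    span: tuple[int, int]
    exons: list  # genomic (start, end) per exon, ascending
    coding_spans: list  # complete-codon (start, end, frame_id) per exon
    cds_length: int = 0


@dataclass
class SimTruth:
    """Planted ground truth, serialized alongside the generated files."""

    chrom: str
    genes: list = field(default_factory=list)
    pseudogenes: list = field(default_factory=list)
    decoys: list = field(default_factory=list)  # unannotated false-positive bait
    gap_weights: tuple = ()
    gap_means_codons: tuple = ()
    intron_gaps_codons: list = field(default_factory=list)
    snv_truth: list = field(default_factory=list)  # dicts with pos/class/daf/p
    splice_donors: list = field(default_factory=list)  # (pos, strand)
    splice_acceptors: list = field(default_factory=list)
    expected_protein_altering_flagged: int = 0

    def coding_codon_spans(self) -> list:
        """All planted coding-codon spans as (start, end, frame_id)."""
        return [tuple(span) for g in self.genes for span in g.coding_spans]

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, default=int)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        payload["genes"] = [GeneTruth(**g) for g in payload["genes"]]
        return cls(**payload)


@dataclass
class SimResult:
    config: SimConfig
    sequence: str
    tracks: dict  # frame_id -> CodonScoreTrack (dense)
    power: PowerTrack
    gtf_text: str
    snvs: list
    truth: SimTruth
    paths: dict = field(default_factory=dict)

    @property
    def genome(self) -> dict:
        return {self.config.chrom: self.sequence}


# ---------------------------------------------------------------------------
# helpers


def _draw_gap_codons(rng, weights, means) -> int:
    k = rng.choice(len(weights), p=weights)
    return int(rng.geometric(1.0 / means[k]))


def _random_cds(rng, n_codons: int) -> str:
    """Random CDS: ATG, non-stop internal codons, terminal stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _noisy_donor(rng) -> str:
    tail = ["A", "A", "G", "T"]
    return "GT" + "".join(
        b if rng.random() < 0.8 else rng.choice(list("ACGT")) for b in tail
    )


def _noisy_acceptor(rng) -> str:
    ppt = "".join(
        rng.choice(["C", "T"]) if rng.random() < 0.8 else rng.choice(list("ACGT"))
        for _ in range(18)
    )
    return ppt + "AG"


def _cds_exon_layout(rng, cfg) -> tuple[list[int], list[int], list[int]]:
    """Exon bp lengths (5'->3'), per-exon phases, intron bp lengths."""
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    codons = rng.integers(cfg.exon_codons[0], cfg.exon_codons[1] + 1, size=n_ex)
    bp = (3 * codons).astype(int).tolist()
    for j in range(n_ex - 1):  # shift junctions off codon boundaries
        d = int(rng.integers(0, 3))
        bp[j] += d
        bp[j + 1] -= d
    phases, cum = [], 0
    for length in bp:
        phases.append((3 - cum % 3) % 3)
        cum += length
    introns = []
    for _ in range(n_ex - 1):
        gap = 3 * _draw_gap_codons(rng, cfg.gap_weights, cfg.gap_means_codons)
        introns.append(int(np.clip(gap, *cfg.intron_bp_bounds)))
    return bp, phases, introns


def _codon_span(start: int, end: int, strand: str, phase: int):
    """Complete-codon span and frame of one CDS exon (mirrors GTF phase rules)."""
    if strand == "+":
        first = start + phase
        n = (end - first) // 3
        if n < 1:
            return None
        return first, first + 3 * n, Frame("+", first % 3).frame_id
    n = (end - phase - start) // 3
    if n < 1:
        return None
    return end - phase - 3 * n, end - phase, Frame("-", (end - phase - 3) % 3).frame_id


# ---------------------------------------------------------------------------
# the generator


def simulate(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Generate a synthetic genome, annotation, tracks and SNVs with truth.

    Deterministic given ``config.seed``; with ``out_dir`` the standard files
    (genome.fa, annotation.gtf, scores_f*.wig, power.wig, snvs.tsv,
    truth.json) are also written.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    G = cfg.genome_length
    seq = rng.choice(_BASES, size=G)

    truth = SimTruth(
        chrom=cfg.chrom,
        gap_weights=tuple(cfg.gap_weights),
        gap_means_codons=tuple(cfg.gap_means_codons),
    )
    gtf_lines: list[str] = []

    def put(start: int, s: str) -> None:
        seq[start : start + len(s)] = np.frombuffer(s.encode(), dtype="S1")

    # ---- feature placement ------------------------------------------------
    cursor = 1000
    features = []  # (kind, payload)

    def advance(span: int) -> int:
        nonlocal cursor
        start = cursor
        cursor = start + span + int(rng.integers(3_000, 20_000))
        if cursor > G - 1000:
            raise ValueError(
                f"features do not fit in genome of length {G}; "
                "increase genome_length or reduce feature counts"
            )
        return start

    for gi in range(cfg.n_genes):
        bp, phases, introns = _cds_exon_layout(rng, cfg)
        truth.intron_gaps_codons.extend(i // 3 for i in introns)
        strand = "+" if rng.random() < 0.5 else "-"
        span = sum(bp) + sum(introns)
        start = advance(span)
        features.append(("gene", (f"gene{gi + 1}", strand, start, bp, phases, introns)))
    for pi in range(cfg.n_pseudogenes):
        n_cod = int(rng.integers(cfg.pseudogene_codons[0], cfg.pseudogene_codons[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        start = advance(3 * n_cod)
        features.append(("pseudogene", (f"pseudo{pi + 1}", strand, start, n_cod)))
    for li in range(cfg.n_lncrnas):
        n_ex = int(rng.integers(1, 4))
        ex_bp = rng.integers(200, 1000, size=n_ex).astype(int).tolist()
        intr = rng.integers(200, 3000, size=max(n_ex - 1, 0)).astype(int).tolist()
        strand = "+" if rng.random() < 0.5 else "-"
        start = advance(sum(ex_bp) + sum(intr))
        features.append(("lncrna", (f"lnc{li + 1}", strand, start, ex_bp, intr)))

    # ---- materialize genes -------------------------------------------------
    for kind, payload in features:
        if kind != "gene":
            continue
        gid, strand, g0, bp, phases, introns = payload
        n_codons = sum(bp) // 3
        cds = _random_cds(rng, n_codons)
        # genomic exon intervals, ascending; bp list is biological 5'->3'
        bp_genomic = bp if strand == "+" else bp[::-1]
        intr_genomic = introns if strand == "+" else introns[::-1]
        exons = []
        pos = g0
        for i, length in enumerate(bp_genomic):
            exons.append((pos, pos + length))
            pos += length
            if i < len(intr_genomic):
                pos += intr_genomic[i]
        gene_end = pos
        # write CDS bases: plus-strand concatenation over exons equals the
        # sense sequence (plus gene) or its reverse complement (minus gene)
        concat = cds if strand == "+" else revcomp(cds)
        offset = 0
        for s, e in exons:
            put(s, concat[offset : offset + (e - s)])
            offset += e - s
        # splice dinucleotides with consensus context
        for s, e in ((exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)):
            donor, acceptor = _noisy_donor(rng), _noisy_acceptor(rng)
            if strand == "+":
                put(s, donor)
                put(e - 20, acceptor)
                truth.splice_donors.append((s, "+"))
                truth.splice_acceptors.append((e - 2, "+"))
            else:
                put(e - 6, revcomp(donor))
                put(s, revcomp(acceptor))
                truth.splice_donors.append((e - 2, "-"))
                truth.splice_acceptors.append((s, "-"))
        # per-exon complete-codon spans in the genomic frame
        phases_genomic = phases if strand == "+" else phases[::-1]
        coding_spans = []
        for (s, e), ph in zip(exons, phases_genomic):
            span = _codon_span(s, e, strand, ph)
            if span is not None:
                coding_spans.append(span)
        truth.genes.append(
            GeneTruth(
                gene_id=gid,
                strand=strand,
                span=(g0, gene_end),
                exons=exons,
                coding_spans=coding_spans,
                cds_length=sum(bp),
            )
        )
        # GTF records (1-based closed; CDS includes the stop codon)
        tid = f"{gid}.t1"
        attrs = (
            f'gene_id "{gid}"; transcript_id "{tid}"; gene_biotype "protein_coding";'
        )
        gtf_lines.append(
            f"{cfg.chrom}\tsim\tgene\t{g0 + 1}\t{gene_end}\t.\t{strand}\t.\t"
            f'gene_id "{gid}"; gene_biotype "protein_coding";'
        )
        gtf_lines.append(
            f"{cfg.chrom}\tsim\ttranscript\t{g0 + 1}\t{gene_end}\t.\t{strand}\t.\t{attrs}"
        )
        for (s, e), ph in zip(exons, phases_genomic):
            gtf_lines.append(
                f"{cfg.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
            )
            gtf_lines.append(
                f"{cfg.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{ph}\t{attrs}"
            )

    # ---- pseudogenes and lncRNAs ------------------------------------------
    for kind, payload in features:
        if kind == "pseudogene":
            pid, strand, start, n_cod = payload
            end = start + 3 * n_cod
            fid = Frame(strand, start % 3).frame_id
            truth.pseudogenes.append(
                {"id": pid, "strand": strand, "span": (start, end), "frame_id": fid}
            )
            attrs = (
                f'gene_id "{pid}"; transcript_id "{pid}.t1"; '
                f'gene_biotype "processed_pseudogene";'
            )
            gtf_lines.append(
                f"{cfg.chrom}\tsim\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f'gene_id "{pid}"; gene_biotype "processed_pseudogene";'
            )
            gtf_lines.append(
                f"{cfg.chrom}\tsim\ttranscript\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"
            )
            gtf_lines.append(
                f"{cfg.chrom}\tsim\texon\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"
            )
        elif kind == "lncrna":
            lid, strand, start, ex_bp, intr = payload
            attrs = f'gene_id "{lid}"; transcript_id "{lid}.t1"; gene_biotype "lincRNA";'
            pos = start
            exon_lines = []
            for i, length in enumerate(ex_bp):
                exon_lines.append((pos, pos + length))
                pos += length + (intr[i] if i < len(intr) else 0)
            gtf_lines.append(
                f"{cfg.chrom}\tsim\tgene\t{start + 1}\t{pos}\t.\t{strand}\t.\t"
                f'gene_id "{lid}"; gene_biotype "lincRNA";'
            )
            gtf_lines.append(
                f"{cfg.chrom}\tsim\ttranscript\t{start + 1}\t{pos}\t.\t{strand}\t.\t{attrs}"
            )
            for s, e in exon_lines:
                gtf_lines.append(
                    f"{cfg.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
                )

    sequence = seq.tobytes().decode()

    # ---- score tracks ------------------------------------------------------
    grids = {}
    scores = {}
    for fid in range(6):
        phase = Frame.from_id(fid).phase
        n = (G - phase) // 3
        grids[fid] = phase + 3 * np.arange(n, dtype=np.int64)
        scores[fid] = rng.normal(cfg.noncoding_score_mean, cfg.noncoding_score_sd, n)

    def plant(fid: int, span_start: int, span_end: int) -> np.ndarray:
        phase = Frame.from_id(fid).phase
        i0 = (span_start - phase) // 3
        n = (span_end - span_start) // 3
        vals = rng.normal(cfg.coding_score_mean, cfg.coding_score_sd, n)
        scores[fid][i0 : i0 + n] = vals
        return vals

    ghost_jobs = []
    for g in truth.genes:
        for s, e, fid in g.coding_spans:
            vals = plant(fid, s, e)
            ghost_jobs.append((fid, s, e, vals))
    for p in truth.pseudogenes:
        s, e = p["span"]
        plant(p["frame_id"], s, e)

    # decoys: unannotated stretches of weaker, shorter coding-like signal —
    # the false-positive population a whole-genome scan must rank against
    occupied = sorted(
        [g.span for g in truth.genes] + [p["span"] for p in truth.pseudogenes]
    )
    occ_starts = np.asarray([s for s, _ in occupied])
    occ_ends = np.asarray([e for _, e in occupied])
    placed_decoys = 0
    attempts = 0
    while placed_decoys < cfg.n_decoys and attempts < 50 * cfg.n_decoys:
        attempts += 1
        n_cod = int(rng.integers(cfg.decoy_codons[0], cfg.decoy_codons[1] + 1))
        fid = int(rng.integers(0, 6))
        phase = Frame.from_id(fid).phase
        s = phase + 3 * int(rng.integers(0, (G - 3 * n_cod - phase) // 3))
        e = s + 3 * n_cod
        hit = np.any((occ_starts < e + 3) & (occ_ends > s - 3))
        if hit:
            continue
        i0 = (s - phase) // 3
        scores[fid][i0 : i0 + n_cod] = rng.normal(
            cfg.decoy_score_mean, cfg.coding_score_sd, n_cod
        )
        truth.decoys.append({"span": (s, e), "frame_id": fid, "n_codons": n_cod})
        placed_decoys += 1
    if placed_decoys < cfg.n_decoys:
        raise ValueError("could not place all decoys; genome too crowded")

    for fid, s, e, vals in ghost_jobs:
        frame = Frame.from_id(fid)
        anti = antisense_frame(frame)
        offset = 2 if frame.strand == "+" else -2
        n = vals.size
        m = int(round(cfg.ghost_fraction * n))
        if m < 1:
            continue
        lo = int(rng.integers(0, n - m + 1))
        sense_starts = s + 3 * np.arange(n)[lo : lo + m]
        anti_starts = sense_starts + offset
        idx = (anti_starts - anti.phase) // 3
        ok = (idx >= 0) & (idx < scores[anti.frame_id].size)
        scores[anti.frame_id][idx[ok]] = cfg.ghost_factor * vals[lo : lo + m][ok]

    tracks = {
        fid: CodonScoreTrack(cfg.chrom, Frame.from_id(fid), grids[fid], scores[fid])
        for fid in range(6)
    }

    # ---- power --------------------------------------------------------------
    n_seg = int(np.ceil(G / cfg.power_segment_bp))
    seg_vals = np.where(
        rng.random(n_seg) < cfg.low_power_fraction,
        rng.uniform(*cfg.low_power_range, n_seg),
        rng.uniform(*cfg.high_power_range, n_seg),
    )
    p_grid = grids[0]
    power = PowerTrack(cfg.chrom, p_grid, seg_vals[p_grid // cfg.power_segment_bp])

    # ---- SNVs ---------------------------------------------------------------
    snvs, used = [], set()
    gene_spans = [g.span for g in truth.genes]
    other_spans = [p["span"] for p in truth.pseudogenes]
    splice_positions = set()
    for pos, _ in truth.splice_donors:
        splice_positions.update((pos, pos + 1))
    for pos, _ in truth.splice_acceptors:
        splice_positions.update((pos, pos + 1))

    def cds_positions(g: GeneTruth) -> np.ndarray:
        pos = np.concatenate([np.arange(s, e) for s, e in g.exons])
        return pos[::-1] if g.strand == "-" else pos

    coding_classes = ("synonymous", "missense", "nonsense")
    for klass, count in cfg.snvs_per_class.items():
        a, b = cfg.daf_beta[klass]
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 200 * count:
                raise ValueError(f"could not place {count} {klass} SNVs")
            daf = float(rng.beta(a, b))
            if klass in coding_classes:
                g = truth.genes[int(rng.integers(0, len(truth.genes)))]
                positions = cds_positions(g)
                n_cod = positions.size // 3
                ci = int(rng.integers(1, n_cod - 1))
                within = int(rng.integers(0, 3))
                gpos = int(positions[3 * ci + within])
                if gpos in used or gpos in splice_positions:
                    continue
                codon_pos = positions[3 * ci : 3 * ci + 3]
                sense_codon = "".join(
                    sequence[p] if g.strand == "+" else revcomp(sequence[p])
                    for p in codon_pos
                )
                ref_aa = str(Seq(sense_codon).translate())
                choices = []
                for alt_sense in "ACGT":
                    if alt_sense == sense_codon[within]:
                        continue
                    alt_codon = (
                        sense_codon[:within] + alt_sense + sense_codon[within + 1 :]
                    )
                    alt_aa = str(Seq(alt_codon).translate())
                    if alt_aa == ref_aa:
                        k = "synonymous"
                    elif alt_aa == "*":
                        k = "nonsense"
                    else:
                        k = "missense"
                    if k == klass and ref_aa != "*":
                        choices.append(alt_sense)
                if not choices:
                    continue
                alt_sense = str(rng.choice(choices))
                ref = sequence[gpos]
                alt = alt_sense if g.strand == "+" else revcomp(alt_sense)
            elif klass == "splice_disrupting":
                if not splice_positions:
                    raise ValueError("no planted splice sites to disrupt")
                gpos = int(rng.choice(sorted(splice_positions)))
                if gpos in used:
                    continue
                ref = sequence[gpos]
                alt = str(rng.choice([b_ for b_ in "ACGT" if b_ != ref]))
            else:  # noncoding: intergenic, outside genes/pseudogenes/splice sites
                gpos = int(rng.integers(0, G))
                if gpos in used or gpos in splice_positions:
                    continue
                if any(s <= gpos < e for s, e in gene_spans + other_spans):
                    continue
                ref = sequence[gpos]
                alt = str(rng.choice([b_ for b_ in "ACGT" if b_ != ref]))
            used.add(gpos)
            snvs.append(
                {"pos": gpos, "ref": ref, "alt": alt, "klass": klass, "daf": daf}
            )
            placed += 1

    # association p-values: a fixed count per class is genome-wide significant
    by_class: dict[str, list] = {}
    for rec in snvs:
        by_class.setdefault(rec["klass"], []).append(rec)
    for klass, recs in by_class.items():
        k = min(cfg.gwas_per_class.get(klass, 0), len(recs))
        for i, rec in enumerate(recs):
            if i < k:
                rec["p"] = float(10.0 ** -rng.uniform(8.5, 14.0))
                rec["trait"] = f"trait_{klass}"
            else:
                rec["p"] = float(10.0 ** -rng.uniform(0.1, 6.9))
                rec["trait"] = ""
    truth.snv_truth = snvs
    truth.expected_protein_altering_flagged = sum(
        min(cfg.gwas_per_class.get(k, 0), len(by_class.get(k, [])))
        for k in ("missense", "nonsense", "splice_disrupting")
    )

    snv_records = [
        SnvRecord(
            chrom=cfg.chrom,
            pos=rec["pos"],
            ref=rec["ref"],
            alt=rec["alt"],
            daf=rec["daf"],
            p_value=rec["p"],
            trait=rec["trait"] or None,
        )
        for rec in snvs
    ]

    gtf_text = "\n".join(gtf_lines) + "\n"
    result = SimResult(
        config=cfg,
        sequence=sequence,
        tracks=tracks,
        power=power,
        gtf_text=gtf_text,
        snvs=snv_records,
        truth=truth,
    )
    if out_dir is not None:
        result.paths = _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: SimResult, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths = {}
    fasta = out_dir / "genome.fa"
    with open(fasta, "w") as out:
        out.write(f">{cfg.chrom}\n")
        for i in range(0, len(result.sequence), 60):
            out.write(result.sequence[i : i + 60] + "\n")
    paths["genome"] = fasta
    gtf = out_dir / "annotation.gtf"
    gtf.write_text(result.gtf_text)
    paths["annotation"] = gtf
    for fid, track in result.tracks.items():
        p = out_dir / f"scores_f{fid}.wig"
        write_codon_track(track, p, name=f"raw_f{fid}")
        paths[f"scores_f{fid}"] = p
    p = out_dir / "power.wig"
    write_power_track(result.power, p, name="power")
    paths["power"] = p
    tsv = out_dir / "snvs.tsv"
    with open(tsv, "w") as out:
        out.write("chrom\tpos\tref\talt\tdaf\tp_value\ttrait\n")
        for s in result.snvs:
            out.write(
                f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.daf:.6g}\t"
                f"{s.p_value:.6g}\t{s.trait or ''}\n"
            )
    paths["snvs"] = tsv
    tj = out_dir / "truth.json"
    tj.write_text(result.truth.to_json())
    paths["truth"] = tj
    return paths


# ---------------------------------------------------------------------------
# focused generators and evaluation


def simulate_gap_track(
    n_gaps: int,
    weights=(0.5, 0.3, 0.2),
    means=(10.0, 300.0, 10_000.0),
    coding_mean: float = 50.0,
    coding_score: float = 10.0,
    noncoding_score: float = -10.0,
    sd: float = 5.0,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[CodonScoreTrack, np.ndarray]:
    """Alternating gap/coding track with gaps from the exponential mixture.

    Strong emissions by default, so the segmentation is essentially known
    and parameter recovery isolates the EM machinery. Returns the track and
    the array of planted gap lengths (codons).
    """
    rng = np.random.default_rng(seed)
    segs, gaps = [], []
    weights = np.asarray(weights, dtype=float)
    for _ in range(n_gaps):
        gap = _draw_gap_codons(rng, weights, means)
        gaps.append(gap)
        segs.append(rng.normal(noncoding_score, sd, gap))
        segs.append(rng.normal(coding_score, sd, int(rng.geometric(1.0 / coding_mean))))
    values = np.concatenate(segs)
    track = CodonScoreTrack(
        chrom, Frame.from_id(0), 3 * np.arange(values.size, dtype=np.int64), values
    )
    return track, np.asarray(gaps)


def evaluate_recovery(
    truth: SimTruth,
    regions,
    pccrs,
    region_prob=None,
) -> dict:
    """Score the pipeline against planted truth.

    * ``gene_overlap_fraction``: planted coding genes with at least one
      region overlapping a coding exon in the same frame;
    * ``top1pct_fraction``: of those genes, the share whose best
      overlapping region scores at or above the 99th percentile of PCCR
      ranking scores — i.e. would rank in the top 1% of candidates had the
      gene not been annotated (requires ``region_prob``, a callable mapping
      a region to its ranking-SVM probability, and ranked PCCRs);
    * base-level precision/recall of regions against true coding codons.
    """
    by_frame: dict[int, list] = {}
    for r in regions:
        by_frame.setdefault(r.frame.frame_id, []).append(r)

    def overlapping_regions(g: GeneTruth):
        out = []
        for s, e, fid in g.coding_spans:
            for r in by_frame.get(fid, []):
                if r.start < e and r.end > s:
                    out.append(r)
        return out

    overlapped = {g.gene_id: overlapping_regions(g) for g in truth.genes}
    n_overlap = sum(bool(v) for v in overlapped.values())
    report = {
        "n_genes": len(truth.genes),
        "n_genes_overlapped": n_overlap,
        "gene_overlap_fraction": n_overlap / len(truth.genes) if truth.genes else np.nan,
    }

    if region_prob is not None and pccrs:
        pccr_scores = np.asarray(
            [p.svm_score for p in pccrs if p.svm_score is not None]
        )
        threshold = np.percentile(pccr_scores, 99) if pccr_scores.size else np.inf
        hits = 0
        for g in truth.genes:
            regs = overlapped[g.gene_id]
            if not regs:
                continue
            best = max(float(region_prob(r)) for r in regs)
            if best >= threshold:
                hits += 1
        report["top1pct_fraction"] = hits / n_overlap if n_overlap else np.nan
        report["pccr_score_p99"] = float(threshold)

    # base-level precision/recall on coding codon bases, frame-aware
    true_bases = {fid: set() for fid in range(6)}
    for s, e, fid in truth.coding_codon_spans():
        true_bases[fid].update(range(s, e))
    called = {fid: set() for fid in range(6)}
    for r in regions:
        called[r.frame.frame_id].update(range(r.start, r.end))
    tp = sum(len(true_bases[f] & called[f]) for f in range(6))
    n_true = sum(len(true_bases[f]) for f in range(6))
    n_called = sum(len(called[f]) for f in range(6))
    report["base_recall"] = tp / n_true if n_true else np.nan
    report["base_precision"] = tp / n_called if n_called else np.nan
    return report
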