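"""SNV consequence classification against coding models, and selection tests.

Variants falling in (newly) called coding sequence are translated in the
predicted reading frame with the standard genetic code and classified as
synonymous, missense, nonsense, splice-disrupting (the canonical GT/AG
intron dinucleotides), or noncoding. Two population-genetic signals of
genuine protein-coding selection are computed: an excess of synonymous
changes relative to the two alternate same-strand frames, and the ordering
of derived allele frequencies (DAF) across consequence classes —
purifying selection pushes nonsense below missense below synonymous.
Trait-associated protein-altering variants are flagged at the conventional
genome-wide significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .filtering import Transcript
from .splice import revcomp

__all__ = [
    "SnvRecord",
    "SnvConsequence",
    "read_snvs",
    "classify_snv",
    "synonymous_bias",
    "daf_comparison",
    "find_protein_altering_associated",
    "GWAS_P_THRESHOLD",
    "PROTEIN_ALTERING",
]

GWAS_P_THRESHOLD = 5e-8
PROTEIN_ALTERING = frozenset({"missense", "nonsense", "splice_disrupting"})
_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class SnvRecord:
    """A single-nucleotide variant (0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    daf: float | None = None
    p_value: float | None = None
    trait: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in _ALLELES or self.alt not in _ALLELES:
            raise ValueError(f"alleles must be single bases in ACGT, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.daf is not None and not 0.0 <= self.daf <= 1.0:
            raise ValueError("derived allele frequency must lie in [0, 1]")


@dataclass(frozen=True)
class SnvConsequence:
    """Classification of one SNV against one coding model."""

    snv: SnvRecord
    klass: str  # synonymous | missense | nonsense | splice_disrupting | noncoding
    codon_index: int | None = None  # 0-based within the CDS
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def is_protein_altering(self) -> bool:
        return self.klass in PROTEIN_ALTERING


def read_snvs(path: str | Path) -> list[SnvRecord]:
    """Read SNVs from a TSV (chrom/pos/ref/alt[/daf/p_value/trait], 0-based pos)
    or a VCF text file (1-based POS; DAF/P/TRAIT picked up from INFO keys).
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SnvRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                daf=float(row.daf) if "daf" in df.columns and pd.notna(row.daf) else None,
                p_value=float(row.p_value)
                if "p_value" in df.columns and pd.notna(row.p_value)
                else None,
                trait=str(row.trait)
                if "trait" in df.columns and pd.notna(row.trait)
                else None,
            )
        )
    return records


def _read_vcf(path: Path) -> list[SnvRecord]:
    records = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alts = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in (fields[7].split(";") if len(fields) > 7 and fields[7] != "." else [])
            )
            for alt in alts.split(","):
                if len(ref) != 1 or len(alt) != 1 or alt not in _ALLELES:
                    continue  # SNVs only
                records.append(
                    SnvRecord(
                        chrom=chrom,
                        pos=pos - 1,  # VCF is 1-based
                        ref=ref,
                        alt=alt,
                        daf=float(info["DAF"]) if "DAF" in info else None,
                        p_value=float(info["P"]) if "P" in info else None,
                        trait=info.get("TRAIT"),
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Classification


def _cds_positions(tx: Transcript) -> np.ndarray:
    """Genomic positions of the CDS bases in transcript (5'->3') order."""
    pos = np.concatenate([np.arange(s, e) for s, e in tx.cds])
    return pos[::-1] if tx.strand == "-" else pos


def _splice_dinucleotides(tx: Transcript) -> set[int]:
    sites = set()
    for s, e in tx.introns():
        sites.update((s, s + 1, e - 2, e - 1))
    return sites


def classify_snv(
    snv: SnvRecord,
    tx: Transcript,
    genome,
    frame_shift: int = 0,
) -> SnvConsequence:
    """Classify one SNV against one transcript's CDS model.

    ``genome`` maps chromosome name to sequence (e.g. a pyfaidx.Fasta or a
    plain dict of strings). ``frame_shift`` of 1 or 2 re-reads the CDS in an
    alternate same-strand frame (the null construction for the synonymous-
    bias test); splice classification applies only in the annotated frame.

    Positions in an intron's canonical 2-bp donor/acceptor dinucleotides are
    splice-disrupting; CDS positions are translated with the standard code;
    everything else is noncoding.
    """
    if tx.cds_length % 3 != 0:
        raise ValueError(f"CDS of transcript {tx.tid} is not a whole number of codons")
    if snv.chrom != tx.chrom:
        return SnvConsequence(snv, "noncoding")
    if frame_shift == 0 and snv.pos in _splice_dinucleotides(tx):
        return SnvConsequence(snv, "splice_disrupting")
    positions = _cds_positions(tx)
    hit = np.flatnonzero(positions == snv.pos)
    if hit.size == 0:
        return SnvConsequence(snv, "noncoding")
    cds_index = int(hit[0]) - frame_shift
    if cds_index < 0 or cds_index >= (len(positions) - frame_shift) // 3 * 3:
        return SnvConsequence(snv, "noncoding")  # partial codon in shifted frame
    codon_index = cds_index // 3
    within = cds_index % 3
    codon_pos = positions[frame_shift + 3 * codon_index : frame_shift + 3 * codon_index + 3]
    seq = genome[snv.chrom]
    bases = [str(seq[int(p)]).upper() for p in codon_pos]
    ref_base, alt_base = snv.ref, snv.alt
    if tx.strand == "-":  # sense-strand view of both the codon and the alleles
        bases = [revcomp(b) for b in bases]
        ref_base, alt_base = revcomp(ref_base), revcomp(alt_base)
    if bases[within] != ref_base:
        raise ValueError(
            f"reference mismatch at {snv.chrom}:{snv.pos}: genome has "
            f"{bases[within]} (stranded), variant ref is {ref_base}"
        )
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        klass = "synonymous"
    elif alt_aa == "*":
        klass = "nonsense"
    else:
        klass = "missense"  # includes stop-loss
    return SnvConsequence(snv, klass, codon_index, ref_aa, alt_aa)


def _classify_all(snvs, transcripts, genome, frame_shift=0):
    """Best consequence of each SNV over the transcripts containing it.

    Consequence classes partition classifiable SNVs: each SNV gets exactly
    one class, the most severe across transcripts
    (splice > nonsense > missense > synonymous > noncoding).
    """
    severity = {
        "splice_disrupting": 0,
        "nonsense": 1,
        "missense": 2,
        "synonymous": 3,
        "noncoding": 4,
    }
    out = []
    for snv in snvs:
        best = SnvConsequence(snv, "noncoding")
        for tx in transcripts:
            if tx.chrom != snv.chrom or tx.cds_length % 3 != 0:
                continue
            c = classify_snv(snv, tx, genome, frame_shift=frame_shift)
            if severity[c.klass] < severity[best.klass]:
                best = c
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# Selection statistics


def synonymous_bias(snvs, transcripts, genome) -> dict:
    """Synonymous fraction in the annotated frame vs the two alternate frames.

    The null re-classifies the same SNVs with the codon grid shifted by one
    and two bases on the same strand; under no frame-specific selection all
    three fractions agree within sampling noise. A one-sided binomial test
    (pooled alternate-frame fraction as the null probability) summarizes the
    excess of synonymous variants in the annotated frame.
    """
    if not snvs:
        raise ValueError("no SNVs to classify")
    coding_classes = {"synonymous", "missense", "nonsense"}

    def frac(frame_shift):
        cons = _classify_all(snvs, transcripts, genome, frame_shift=frame_shift)
        coding = [c for c in cons if c.klass in coding_classes]
        if not coding:
            return np.nan, 0, 0
        k = sum(c.klass == "synonymous" for c in coding)
        return k / len(coding), k, len(coding)

    f0, k0, n0 = frac(0)
    f1, k1, n1 = frac(1)
    f2, k2, n2 = frac(2)
    if n0 == 0:
        raise ValueError("no classifiable SNVs in the annotated frame")
    pooled = (k1 + k2) / (n1 + n2) if (n1 + n2) else np.nan
    p = (
        stats.binomtest(k0, n0, pooled, alternative="greater").pvalue
        if np.isfinite(pooled) and 0 < pooled < 1
        else np.nan
    )
    return {
        "synonymous_fraction": f0,
        "alt_frame_fractions": (f1, f2),
        "n_classified": (n0, n1, n2),
        "null_fraction": pooled,
        "p_value": p,
    }


def daf_comparison(consequences) -> dict:
    """One-sided rank tests for the purifying-selection DAF ordering.

    Tests DAF(nonsense) < DAF(missense) and DAF(missense) < DAF(synonymous)
    with one-sided Mann–Whitney U. A missing class leaves that comparison
    undefined (NaN) without failing the other. Returns per-class medians.
    """
    groups = {k: [] for k in ("synonymous", "missense", "nonsense")}
    for c in consequences:
        if c.klass in groups and c.snv.daf is not None:
            groups[c.klass].append(c.snv.daf)

    def one_sided_less(a, b):
        if not a or not b:
            return np.nan
        return float(stats.mannwhitneyu(a, b, alternative="less").pvalue)

    return {
        "p_nonsense_lt_missense": one_sided_less(groups["nonsense"], groups["missense"]),
        "p_missense_lt_synonymous": one_sided_less(groups["missense"], groups["synonymous"]),
        "medians": {
            k: (float(np.median(v)) if v else np.nan) for k, v in groups.items()
        },
        "n": {k: len(v) for k, v in groups.items()},
    }


def find_protein_altering_associated(
    snvs, transcripts, genome, p_threshold: float = GWAS_P_THRESHOLD
) -> pd.DataFrame:
    """Flag protein-altering variants with genome-wide significant association.

    Returns a table of variants with ``p_value < p_threshold`` whose
    consequence is missense, nonsense, or splice-disrupting, with class
    counts available via the ``klass`` column.
    """
    candidates = [s for s in snvs if s.p_value is not None and s.p_value < p_threshold]
    rows = []
    for cons in _classify_all(candidates, transcripts, genome):
        if cons.is_protein_altering:
            rows.append(
                {
                    "chrom": cons.snv.chrom,
                    "pos": cons.snv.pos,
                    "ref": cons.snv.ref,
                    "alt": cons.snv.alt,
                    "klass": cons.klass,
                    "aa_change": (
                        f"{cons.ref_aa}>{cons.alt_aa}" if cons.ref_aa else ""
                    ),
                    "p_value": cons.snv.p_value,
                    "trait": cons.snv.trait or "",
                    "daf": cons.snv.daf,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "klass", "aa_change", "p_value", "trait", "daf"],
    )
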