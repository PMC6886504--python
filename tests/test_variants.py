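"""SNV consequence classification and selection statistics."""

import numpy as np
import pytest

from pccrscan.filtering import Transcript
from pccrscan.variants import (
    SnvConsequence,
    SnvRecord,
    classify_snv,
    daf_comparison,
    find_protein_altering_associated,
    read_snvs,
    synonymous_bias,
    _classify_all,
)

# toy genome: CDS "ATG GAA TAA" at [10, 19) on the plus strand
TOY = "A" * 10 + "ATGGAATAA" + "C" * 10
TX = Transcript(tid="t", gene_id="g", chrom="chr1", strand="+", cds=[(10, 19)])
GENOME = {"chr1": TOY}


def snv(pos, ref, alt, **kw):
    return SnvRecord("chr1", pos, ref, alt, **kw)


# all 9 single-base changes of the GAA codon (positions 13,14,15), by hand:
GAA_TRUTH = [
    (13, "G", "A", "missense"),  # AAA Lys
    (13, "G", "C", "missense"),  # CAA Gln
    (13, "G", "T", "nonsense"),  # TAA stop
    (14, "A", "C", "missense"),  # GCA Ala
    (14, "A", "G", "missense"),  # GGA Gly
    (14, "A", "T", "missense"),  # GTA Val
    (15, "A", "C", "missense"),  # GAC Asp
    (15, "A", "G", "synonymous"),  # GAG Glu
    (15, "A", "T", "missense"),  # GAT Asp
]


@pytest.mark.parametrize("pos,ref,alt,expected", GAA_TRUTH)
def test_gaa_codon_truth_table(pos, ref, alt, expected):
    cons = classify_snv(snv(pos, ref, alt), TX, GENOME)
    assert cons.klass == expected
    assert cons.codon_index == 1
    assert cons.ref_aa == "E"


def test_classification_is_strand_correct():
    """A minus-strand transcript over the reverse-complemented CDS yields the
    same consequences for the corresponding (complemented) variants."""
    rc = "T" * 10 + "TTATTCCAT" + "G" * 10  # revcomp of ATGGAATAA at [10,19)
    tx_minus = Transcript(tid="tm", gene_id="g", chrom="chr1", strand="-", cds=[(10, 19)])
    genome = {"chr1": rc}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for pos, ref, alt, expected in GAA_TRUTH:
        # sense position p in [10,19) maps to genomic 28 - p on the rc layout
        gpos = 28 - pos
        cons = classify_snv(snv(gpos, comp[ref], comp[alt]), tx_minus, genome)
        assert cons.klass == expected


def test_splice_dinucleotide_positions():
    tx2 = Transcript(
        tid="t2", gene_id="g", chrom="chr1", strand="+", cds=[(10, 16), (100, 106)]
    )
    genome = {"chr1": "A" * 10 + "ATGGAA" + "GT" + "A" * 80 + "AG" + "GAATAA" + "C" * 10}
    for pos in (16, 17, 98, 99):  # GT..AG of the intron
        ref = genome["chr1"][pos]
        alt = "A" if ref != "A" else "C"
        assert classify_snv(snv(pos, ref, alt), tx2, genome).klass == "splice_disrupting"
    # deep intronic position is noncoding
    ref = genome["chr1"][50]
    assert classify_snv(snv(50, ref, "T" if ref != "T" else "G"), tx2, genome).klass == "noncoding"


def test_cds_not_multiple_of_three_errors():
    bad = Transcript(tid="bad", gene_id="g", chrom="chr1", strand="+", cds=[(10, 18)])
    with pytest.raises(ValueError, match="bad"):
        classify_snv(snv(13, "G", "A"), bad, GENOME)


def test_classes_partition_classifiable_snvs(small_sim, small_ann):
    txs = list(small_ann.transcripts.values())
    cons = _classify_all(small_sim.snvs, txs, small_sim.genome)
    assert len(cons) == len(small_sim.snvs)
    truth = {r["pos"]: r["klass"] for r in small_sim.truth.snv_truth}
    agree = sum(truth[c.snv.pos] == c.klass for c in cons)
    assert agree == len(cons)  # planted classes recovered exactly


def test_synonymous_bias_under_selection_and_null(small_sim, small_ann):
    txs = list(small_ann.transcripts.values())
    report = synonymous_bias(small_sim.snvs, txs, small_sim.genome)
    # planted SNVs are synonymous-enriched relative to what random changes
    # would give; both alternate frames must show less synonymy
    assert report["synonymous_fraction"] > max(report["alt_frame_fractions"])
    assert report["p_value"] < 1e-4

    # null: uniformly random coding SNVs show no frame preference
    rng = np.random.default_rng(0)
    tx = txs[0]
    from pccrscan.variants import _cds_positions

    positions = _cds_positions(tx)[3:-3]
    rand_snvs = []
    seen = set()
    for _ in range(400):
        p = int(rng.choice(positions))
        if p in seen:
            continue
        seen.add(p)
        ref = small_sim.genome[tx.chrom][p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        rand_snvs.append(SnvRecord(tx.chrom, p, ref, alt))
    null = synonymous_bias(rand_snvs, [tx], small_sim.genome)
    fracs = [null["synonymous_fraction"], *null["alt_frame_fractions"]]
    n = null["n_classified"][0]
    spread = max(fracs) - min(fracs)
    assert spread < 4 * np.sqrt(0.25 / n) + 0.05  # binomial-noise agreement


def test_synonymous_bias_empty_errors():
    with pytest.raises(ValueError):
        synonymous_bias([], [TX], GENOME)


def _daf_consequences(rng, n, klass, a, b):
    out = []
    for daf in rng.beta(a, b, n):
        out.append(SnvConsequence(snv(13, "G", "A", daf=float(daf)), klass))
    return out


def test_daf_ordering_detected():
    rng = np.random.default_rng(7)
    cons = (
        _daf_consequences(rng, 500, "synonymous", 0.8, 2.2)
        + _daf_consequences(rng, 500, "missense", 0.5, 3.5)
        + _daf_consequences(rng, 500, "nonsense", 0.3, 6.0)
    )
    report = daf_comparison(cons)
    assert report["p_nonsense_lt_missense"] < 0.01
    assert report["p_missense_lt_synonymous"] < 0.01
    med = report["medians"]
    assert med["nonsense"] < med["missense"] < med["synonymous"]


def test_daf_null_calibrated():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        cons = _daf_consequences(rng, 60, "missense", 1.0, 1.0) + _daf_consequences(
            rng, 60, "synonymous", 1.0, 1.0
        )
        if daf_comparison(cons)["p_missense_lt_synonymous"] > 0.05:
            hits += 1
    assert hits >= 90


def test_daf_single_variant_class_no_crash():
    rng = np.random.default_rng(8)
    cons = _daf_consequences(rng, 1, "nonsense", 1, 1) + _daf_consequences(
        rng, 50, "missense", 1, 1
    )
    report = daf_comparison(cons)
    assert 0.0 <= report["p_nonsense_lt_missense"] <= 1.0
    assert np.isnan(report["p_missense_lt_synonymous"])  # missing class


def test_daf_invariant_to_monotone_transform():
    rng = np.random.default_rng(9)
    cons = _daf_consequences(rng, 100, "missense", 0.5, 3.5) + _daf_consequences(
        rng, 100, "synonymous", 0.8, 2.2
    )
    squared = [
        SnvConsequence(snv(13, "G", "A", daf=c.snv.daf**2), c.klass) for c in cons
    ]
    assert daf_comparison(cons)["p_missense_lt_synonymous"] == pytest.approx(
        daf_comparison(squared)["p_missense_lt_synonymous"]
    )


def test_protein_altering_threshold_rules():
    variants = [
        snv(13, "G", "A", p_value=1e-9),  # missense, significant
        snv(14, "A", "C", p_value=1e-6),  # missense, not significant
        snv(15, "A", "G", p_value=1e-12),  # synonymous, significant
    ]
    table = find_protein_altering_associated(variants, [TX], GENOME)
    assert len(table) == 1
    assert table.iloc[0]["pos"] == 13 and table.iloc[0]["klass"] == "missense"


def test_flagged_counts_on_synthetic(small_sim, small_ann):
    txs = list(small_ann.transcripts.values())
    table = find_protein_altering_associated(small_sim.snvs, txs, small_sim.genome)
    assert len(table) == small_sim.truth.expected_protein_altering_flagged


def test_read_snvs_tsv_and_vcf(tmp_path):
    tsv = tmp_path / "v.tsv"
    tsv.write_text(
        "chrom\tpos\tref\talt\tdaf\tp_value\ttrait\n"
        "chr1\t13\tG\tA\t0.25\t1e-9\tmyopia\n"
    )
    [rec] = read_snvs(tsv)
    assert (rec.pos, rec.ref, rec.alt, rec.daf, rec.trait) == (13, "G", "A", 0.25, "myopia")

    vcf = tmp_path / "v.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t14\trs1\tG\tA\t.\t.\tDAF=0.1;P=2e-10;TRAIT=height\n"
    )
    [rec] = read_snvs(vcf)
    assert rec.pos == 13  # VCF is 1-based
    assert rec.daf == 0.1 and rec.p_value == 2e-10 and rec.trait == "height"


def test_snv_record_validation():
    with pytest.raises(ValueError):
        SnvRecord("chr1", 5, "G", "G")
    with pytest.raises(ValueError):
        SnvRecord("chr1", 5, "N", "A")
    with pytest.raises(ValueError):
        SnvRecord("chr1", 5, "G", "A", daf=1.5)
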