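# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `pccrscan`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external data.

## Coordinate and frame conventions

Internally all coordinates are 0-based half-open; conversions happen only
at file boundaries (wiggle is 1-based, GTF 1-based closed, BED 0-based
half-open). A reading frame is (strand, phase) with phase = codon left-edge
coordinate mod 3; frame ids 0–2 are the plus-strand frames, 3–5 minus.
Minus-strand codons are keyed by the genomic *left* edge of their 3-bp
span, which is the codon's biological third position. Under this keying the
antisense frame — the opposite-strand frame sharing third codon positions —
is the involution (+, p) ↔ (−, (p+2) mod 3), and the paired antisense codon
of a codon at `s` is at `s+2` (plus) / `s−2` (minus). The test suite
verifies by exhaustive enumeration over a 30-nt toy that this is the unique
third-position-sharing pairing.

## The smoothing HMM

States: coding `C`; noncoding `N₁..N₃` with identical emissions, able to
transition only to `C`. Parameters:

| parameter | meaning | default | unit |
|---|---|---|---|
| `emission_scale` | nats per deciban | ln(10)/10 | — |
| `coding_stay` | P(C→C); mean coding run 1/(1−c) | 1 − 1/50 | codons |
| `gap_weights` | mixture over N₁..N₃ | (⅓, ⅓, ⅓) | — |
| `gap_stays` | P(Nₖ→Nₖ); mean gap 1/(1−pₖ) | means 100 / 3,000 / 100,000 | codons |
| `initial_coding` | prior P(start in C) | 0.01 | — |

Because the input score is already a log-likelihood ratio, only the
emission *ratio* is modelled: the coding state's log emission is
`s·ln(10)/10` nats and each noncoding state's is 0. All likelihoods are
therefore ratio-likelihoods relative to the noncoding emission measure;
Viterbi paths, posteriors and EM are unaffected by this common factor.
Missing scores emit ratio 1 in every state rather than being skipped, so
gap-length bookkeeping is preserved across masked (power < 0.1) codons.

Exponential gap components are realized as geometric dwell times, the
discrete analogue in a per-codon chain; means are quoted in codons.

Numerics: everything runs in log space (no scaling factors), so tracks of
≤ 7 codons agree with brute-force enumeration over all 4ⁿ paths to 1e−9 —
this is the oracle test. The recursions are numba kernels exploiting the
sparse transition structure (forward/backward cost ~10 log-add-exp per
codon), which makes EM over ~10⁷-codon tracks take a couple of minutes.

EM is Baum–Welch restricted to transition parameters (emissions fixed).
The M-step ties the gap weights to both the initial distribution and the
C→Nₖ transitions (the weight update uses both expected-count terms, so the
log-likelihood is monotone). `coding_stay` is re-estimated by default
(`update_coding_stay=False` freezes it); `initial_coding` is held fixed —
with one long sequence per (chromosome, frame) its single expected count is
uninformative. Gap components are relabelled ascending by mean at
convergence for identifiability. Probabilities are clipped to
[1e−12, 1−1e−12] in the M-step; ties in emissions are resolved by the
deterministic max in the Viterbi recursion (first state wins), which only
matters on measure-zero inputs. EM runs genome-wide (expected counts summed
across the six per-frame tracks) rather than per chromosome; per-track
fitting is available by passing a single track.

With annotation available, initialization uses the mean annotated
coding-exon length for the coding dwell and the tertile means of
same-frame inter-exon gaps for the three gap scales; on well-separated
synthetic data the EM fixed point is insensitive to initialization (tested
from three distinct starting points).

The HMM deliberately ignores start codons, stop codons and splice sites:
it smooths evolutionary signal only.

## Filter cascade

Order: same-frame CDS, antisense-frame CDS, pseudogene (any frame, either
strand), 9-codon minimum, antisense-SVM threshold 0.3, then add-back of
non-overlapping fragments that pass the last two conditions. Trimming is at
whole-codon granularity — a codon is overlapped if any of its three bases
intersects the feature; base-level trimming would break frame alignment.
"Pseudogene" means any gene biotype containing the substring `pseudogene`
(GTF biotype vocabularies vary; the substring is the robust superset).
Same-frame CDS intervals are indexed by their complete-codon spans (a
feature's partial edge codons belong to codons spanning the intron and
carry no frame of their own). A region fully removed by annotation overlap
is tallied at the first cascade step that touched it; the tally satisfies
|input| = |kept| + |fully excluded| exactly, with per-codon accounting for
trimmed regions (asserted in tests). Fragments that survive carry
provenance `added_back_fragment` and the list of categories that removed
their siblings.

## SVMs

Both classifiers are RBF-kernel SVMs with cost 1, kernel width
1/n_features, features standardized on the training set only, and sigmoid
(Platt) probability calibration — the classical defaults of the
statistics-package SVM this kind of analysis is normally run with
(implemented with scikit-learn's `SVC(probability=True)` inside a
`StandardScaler` pipeline; random_state fixed by the pipeline seed).

* Antisense SVM: features (mean score/codon, mean per-codon difference to
  the antisense-frame score, length). Positives are regions overlapping
  annotated CDS in the same frame; negatives overlap CDS in the antisense
  frame. The 0.3 exclusion threshold is interpreted as a calibrated
  probability (it lies in [0,1]); the alternative reading as a raw decision
  value was considered and rejected.
* Ranking SVM: the same three features plus mean relative branch length
  (power) over the region, used as a proxy for the alignment's absolute
  tree branch length, which is alignment-specific and not available from
  the tracks. Negatives are regions overlapping no CDS in either frame and
  no pseudogene. Positives are resampled independently of the antisense
  SVM's (same definition, same seed stream position — the classes, not the
  draws, are what matters).

Training samples default to 10,000 per class; when fewer distinct regions
exist the class is resampled with replacement and a warning is issued (the
desk-scale runs use 2,000 per class). Ranks 1..N are assigned by descending
probability with deterministic tie-breaks (mean score, then coordinate).
Clustering is single-linkage chaining of PCCRs within 10 kb on a
chromosome, strand-blind; the cluster inherits its best member rank.

The "rank of a gene" used for evaluation is the rank its best same-frame
overlapping region *would* have among the PCCRs had the gene not been
annotated: the region's ranking-SVM score is compared against the PCCR
score distribution (top 1% = at or above the 99th percentile).

## Splice model

Default model is a position-weight (log-odds) matrix — donor: 3 exonic +
6 intronic positions around GT; acceptor: 20 intronic (ending AG) + 3
exonic — trained from annotated introns with pseudocount 1 against the
genome's base composition, requiring ≥ 50 sites. An externally derived
table (e.g. maximum-entropy scores) can be loaded through the same
interface; full maximum-entropy inference is out of scope, keeping the
package download-free.

## Variant module

Classification translates reference and alternate codons with the standard
genetic code in the transcript's annotated frame; stop-gain is `nonsense`,
stop-loss is folded into `missense`; positions in an intron's first/last
two bases are `splice_disrupting`; a CDS whose length is not a multiple of
three is an error naming the transcript. The synonymous-bias null
re-classifies the same SNVs with the codon grid shifted by one and two
bases on the same strand — the natural frame-specific control — and a
one-sided binomial test against the pooled alternate-frame fraction
summarizes the excess. The DAF ordering uses one-sided Mann–Whitney tests
(the classical choice for stochastic ordering; the underlying claim does
not name a specific test, so the rank test is our substitution), which
makes the result invariant to monotone transforms of DAF.

## Synthetic data: what it emulates, and what it does not

The generator plants, in a single 2.5-Mb chromosome (default; 60 coding
genes, 10 pseudogenes, 20 lincRNAs):

* coding exons with per-codon scores N(+4, 6²) db in their true genomic
  frame, noncoding background N(−4, 6²) — chosen so single codons are
  uninformative (the distributions overlap heavily) while regions are
  detectable;
* antisense ghosts: an attenuated copy (factor 0.5) of the sense scores on
  the paired antisense codons over a contiguous ~60% of each exon — ghosts
  are shorter and weaker than their sense regions;
* pseudogene exons with coding-like scores (their alignments retain the
  signature), annotated with a pseudogene biotype;
* decoy segments (500 per genome, 5–25 codons, mean +2 db): unannotated
  stretches of weak coding-like signal modelling alignment artifacts and
  spurious conserved elements. These supply the false-positive population
  that dominates a real whole-genome scan; without them Gaussian noise
  alone yields almost no false regions and the ranking problem would be
  vacuous;
* intron lengths drawn (in codons × 3) from the 3-exponential gap mixture
  w=(0.5, 0.3, 0.2), means (10, 300, 10,000) codons, truncated to
  [60 bp, 30 kb] so genes fit the chromosome;
* piecewise-constant alignment power (5-kb segments, 5% of them below the
  0.1 cutoff) and consensus-context GT/AG splice dinucleotides;
* SNVs with known consequence classes, class-specific Beta-distributed
  DAFs ordered nonsense < missense < synonymous, and a fixed count per
  class with genome-wide-significant association p-values.

Exon/intron junctions are shifted off codon boundaries so GTF phases 1 and
2 actually occur. Everything is deterministic given the seed; truth is
serialized as JSON beside the generated files.

What the generator does **not** emulate: sequence-level evolution (scores
are drawn, not computed from alignments), indels/frameshifts, overlapping
genes and alternative isoforms, heavy-tailed or autocorrelated score noise,
chromosome-scale heterogeneity, and any real-genome annotation idiosyncrasy.
Passing the recovery tests therefore shows the machinery is correct and
well-calibrated under its own model assumptions — not that real-data
performance figures would match.

## Problem sizes used in tests

The shared unit-test fixture uses a 700-kb genome (15 genes); the
acceptance tests and the acceptance script use the full default conditions
(2.5 Mb, 60 genes) with 2,000 SVM training samples per class, EM capped at
30 iterations for the genome scan and 60 for the dedicated mixture-recovery
run (5,000 planted gaps, ~10⁷ codons, strong ±10 db emissions so that
parameter recovery isolates the EM machinery). These sizes are the
package's chosen desk-scale study conditions; all statistics the tests
assert are computed at these sizes.

## Known limitations

* The HMM treats each (chromosome, frame) track independently; there is no
  cross-frame coupling, so the same locus can be called in several frames.
* Probability calibration via Platt scaling is approximate for small or
  heavily resampled training sets.
* Fragments created by trimming inherit their source region's maximum
  coding posterior (the posterior is not re-computed on the fragment).
* The splice PWM is a deliberately simple stand-in for richer models; its
  scores are comparable only within one trained model.
* VCF input is parsed minimally (single-nucleotide records, DAF/P/TRAIT
  INFO keys); anything richer should be converted to the TSV form.
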