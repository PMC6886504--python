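"""End-to-end orchestration of the candidate-coding-region scan.

Stages: mask low-power codons, fit the HMM transition structure by EM
(genome-wide across the six frame tracks), decode regions and smoothed
log-odds per frame, build SVM training sets against the annotation, train
the antisense and ranking SVMs, run the exclusion cascade, rank and
cluster the surviving PCCRs, and compute gene ranks. The variant and
splice stages plug in downstream of the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .filtering import (
    ANTISENSE_THRESHOLD,
    MIN_CODONS,
    AnnotationSet,
    ExclusionTally,
    Pccr,
    build_pccrs,
    read_annotation,
)
from .hmm import CodingHMM, HmmParams, _ctor_kwargs, default_params, fit_transitions_em
from .ranking import (
    CLUSTER_WINDOW,
    AntisenseSVM,
    RankingSVM,
    build_training_sets,
    cluster_pccrs,
    extract_features,
    gene_rank,
    rank_pccrs,
)
from .scores import (
    CodonScoreTrack,
    PowerTrack,
    mask_low_power,
    read_codon_track,
    read_power_track,
)
from .variants import GWAS_P_THRESHOLD

log = logging.getLogger("pccrscan")

__all__ = ["PipelineConfig", "ScanResult", "run_scan", "load_tracks"]


@dataclass
class PipelineConfig:
    """All tunable pipeline constants, with their conventional defaults.

    Every constant the method fixes is surfaced here by name: power cutoff
    0.1, minimum region length 9 codons, antisense probability threshold
    0.3, 10,000 training regions per class, 10-kb cluster window, and the
    genome-wide significance threshold 5e-8.
    """

    tracks_dir: str | None = None
    annotation: str | None = None
    genome: str | None = None
    variants: str | None = None
    out_dir: str | None = None
    power_cutoff: float = 0.1
    min_codons: int = MIN_CODONS
    antisense_threshold: float = ANTISENSE_THRESHOLD
    n_per_class: int = 10_000
    seed: int = 0
    cluster_window: int = CLUSTER_WINDOW
    p_threshold: float = GWAS_P_THRESHOLD
    fit_em: bool = True
    em_max_iter: int = 30
    em_tol: float = 1e-6
    update_coding_stay: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ScanResult:
    params0: HmmParams
    params: HmmParams
    loglik_trace: np.ndarray | None
    masked_tracks: dict
    regions: list
    regions_by_frame: dict
    smoothed: dict
    antisense_model: AntisenseSVM
    ranking_model: RankingSVM
    pccrs: list
    tally: ExclusionTally
    clusters: dict
    gene_ranks: dict
    power: PowerTrack | None = None
    feature_cache: dict = field(default_factory=dict)
    training_positives: list = field(default_factory=list)
    training_antisense_negatives: list = field(default_factory=list)
    training_ranking_negatives: list = field(default_factory=list)

    def antisense_prob(self, region) -> float:
        """Antisense-SVM probability that a region is sense-coding."""
        feats = _cached(region, self.masked_tracks, self.power, self.feature_cache)
        return float(
            self.antisense_model.prob_positive(
                feats.to_array(include_branch_length=False)
            )[0]
        )

    def region_prob(self, region) -> float:
        """Ranking-SVM probability of any region (also unranked ones)."""
        feats = _cached(region, self.masked_tracks, self.power, self.feature_cache)
        return float(
            self.ranking_model.prob_positive(feats.to_array(include_branch_length=True))[0]
        )


def _cached(region, tracks, power, cache):
    key = (region.frame.frame_id, region.start, region.end)
    if key not in cache:
        cache[key] = extract_features(region, tracks, power)
    return cache[key]


def load_tracks(tracks_dir: str | Path, pattern: str = "scores_f{fid}.wig"):
    """Load the six per-frame score wiggles and the power wiggle from a directory."""
    tracks_dir = Path(tracks_dir)
    tracks = {
        fid: read_codon_track(tracks_dir / pattern.format(fid=fid), fid)
        for fid in range(6)
    }
    power_path = tracks_dir / "power.wig"
    power = read_power_track(power_path) if power_path.exists() else None
    return tracks, power


def run_scan(
    tracks: dict[int, CodonScoreTrack],
    power: PowerTrack | None,
    ann: AnnotationSet | None,
    cfg: PipelineConfig | None = None,
) -> ScanResult:
    """Run the full scan over in-memory tracks and annotation."""
    cfg = cfg or PipelineConfig()
    if power is not None:
        masked = {
            fid: mask_low_power(t, power, cfg.power_cutoff) for fid, t in tracks.items()
        }
    else:
        masked = dict(tracks)

    params0 = default_params(ann)
    trace = None
    if cfg.fit_em:
        params, trace = fit_transitions_em(
            list(masked.values()),
            params0,
            max_iter=cfg.em_max_iter,
            tol=cfg.em_tol,
            update_coding_stay=cfg.update_coding_stay,
        )
        log.info(
            "EM: %d iterations, gap means %s codons, coding mean %.1f",
            len(trace),
            np.round(params.gap_means, 1),
            params.coding_mean,
        )
    else:
        params = params0

    model = CodingHMM(**_ctor_kwargs(params))
    regions_by_frame, smoothed = {}, {}
    all_regions = []
    for fid, track in sorted(masked.items()):
        _, regions, gamma, _ = model.analyze(track)
        regions_by_frame[fid] = regions
        all_regions.extend(regions)
        dense = track.dense()
        g = np.clip(gamma[:, 0], 1e-12, 1 - 1e-12)
        smoothed[fid] = CodonScoreTrack(
            dense.chrom, dense.frame, dense.codon_starts, 10.0 * np.log10(g / (1.0 - g))
        )
        log.info("frame %d: %d regions over %d codons", fid, len(regions), len(dense))

    cache: dict = {}
    if ann is None:
        raise ValueError("run_scan requires an annotation for SVM training")
    positives, anti_negs, rank_negs = build_training_sets(
        all_regions, ann, n_per_class=cfg.n_per_class, seed=cfg.seed
    )

    def matrix(regions, wide):
        return np.vstack(
            [
                _cached(r, masked, power, cache).to_array(include_branch_length=wide)
                for r in regions
            ]
        )

    X_anti = np.vstack([matrix(positives, False), matrix(anti_negs, False)])
    y_anti = np.concatenate([np.ones(len(positives), int), np.zeros(len(anti_negs), int)])
    antisense_model = AntisenseSVM(random_state=cfg.seed).fit(X_anti, y_anti)
    log.info("antisense SVM trained on %d + %d regions", len(positives), len(anti_negs))

    def anti_prob(region) -> float:
        feats = _cached(region, masked, power, cache)
        return float(
            antisense_model.prob_positive(feats.to_array(include_branch_length=False))[0]
        )

    pccrs, tally = build_pccrs(
        all_regions,
        ann,
        antisense_prob=anti_prob,
        min_codons=cfg.min_codons,
        antisense_threshold=cfg.antisense_threshold,
    )
    for step, count in tally.to_frame().itertuples(index=False):
        log.info("cascade %s: %d", step, count)

    X_rank = np.vstack([matrix(positives, True), matrix(rank_negs, True)])
    y_rank = np.concatenate([np.ones(len(positives), int), np.zeros(len(rank_negs), int)])
    ranking_model = RankingSVM(random_state=cfg.seed).fit(X_rank, y_rank)

    for p in pccrs:
        p.features = _cached(p.region, masked, power, cache)
    ranked = rank_pccrs(ranking_model, pccrs, masked, power)
    clusters = cluster_pccrs(ranked, window=cfg.cluster_window)
    gene_ranks = {
        gid: gene_rank(spans, ranked) for gid, spans in ann.gene_cds.items()
    }
    log.info("%d PCCRs in %d clusters", len(ranked), len(clusters))

    return ScanResult(
        params0=params0,
        params=params,
        loglik_trace=trace,
        masked_tracks=masked,
        regions=all_regions,
        regions_by_frame=regions_by_frame,
        smoothed=smoothed,
        antisense_model=antisense_model,
        ranking_model=ranking_model,
        pccrs=ranked,
        tally=tally,
        clusters=clusters,
        gene_ranks=gene_ranks,
        power=power,
        feature_cache=cache,
        training_positives=positives,
        training_antisense_negatives=anti_negs,
        training_ranking_negatives=rank_negs,
    )
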