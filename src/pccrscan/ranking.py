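"""Region features, SVM training sets, antisense and ranking classifiers.

Two RBF-kernel SVMs operate on simple per-region summaries:

* the *antisense* SVM separates regions translated on their own strand from
  regions that are merely the antisense "ghost" of a coding region, using
  the mean score per codon, the mean per-codon difference between the score
  and the antisense-frame score, and the region length (ghosts tend to be
  shorter and to score higher on the opposite strand);
* the *ranking* SVM separates true coding regions from false positives
  using those three features plus the mean relative branch length (power)
  of the local alignment, and orders the surviving candidates.

Positive examples are regions overlapping annotated CDS in the same frame;
antisense negatives overlap CDS in the antisense frame; ranking negatives
overlap no CDS in either frame and no pseudogene. Both SVMs use cost 1,
kernel width 1/n_features, internally standardized features, and sigmoid
(Platt) probability calibration — the defaults of the classical statistics
packages this kind of analysis is usually run with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .filtering import AnnotationSet, Pccr, classify_overlap
from .frames import antisense_frame
from .hmm import PhyloCSFRegion
from .scores import CodonScoreTrack, PowerTrack

__all__ = [
    "RegionFeatures",
    "AntisenseSVM",
    "RankingSVM",
    "extract_features",
    "build_training_sets",
    "train_antisense_svm",
    "train_ranking_svm",
    "apply_svm",
    "rank_pccrs",
    "gene_rank",
    "cluster_pccrs",
    "CLUSTER_WINDOW",
]

CLUSTER_WINDOW = 10_000  # bp


@dataclass(frozen=True)
class RegionFeatures:
    """Per-region SVM features.

    ``mean_score``: decibans/codon over non-missing codons.
    ``mean_antisense_diff``: mean of (score - antisense-frame score) per
    codon, missing antisense scores counted as 0 db.
    ``length``: codons. ``branch_length``: mean relative power in [0, 1].
    """

    mean_score: float
    mean_antisense_diff: float
    length: int
    branch_length: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1 codon")
        if not 0.0 <= self.branch_length <= 1.0:
            raise ValueError("branch_length must lie in [0, 1]")
        if not (np.isfinite(self.mean_score) and np.isfinite(self.mean_antisense_diff)):
            raise ValueError("features must be finite")

    def to_array(self, include_branch_length: bool = False) -> np.ndarray:
        base = [self.mean_score, self.mean_antisense_diff, float(self.length)]
        if include_branch_length:
            base.append(self.branch_length)
        return np.asarray(base)


def extract_features(
    region: PhyloCSFRegion,
    tracks: dict[int, CodonScoreTrack],
    power: PowerTrack | None = None,
) -> RegionFeatures:
    """Compute the four SVM features for one region from the six frame tracks."""
    starts = region.codon_starts()
    sense = tracks[region.frame.frame_id].score_at(starts)
    present = ~np.isnan(sense)
    if not present.any():
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} has no scored codons"
        )
    anti_fid = antisense_frame(region.frame).frame_id
    offset = 2 if region.frame.strand == "+" else -2
    anti_starts = starts + offset
    anti = np.full(starts.size, np.nan)
    valid = anti_starts >= 0
    if anti_fid in tracks and valid.any():
        anti[valid] = tracks[anti_fid].score_at(anti_starts[valid])
    anti = np.where(np.isnan(anti), 0.0, anti)  # missing antisense treated as 0 db
    mean_score = float(sense[present].mean())
    mean_diff = float((sense[present] - anti[present]).mean())
    if power is not None:
        pw = power.at(starts)
        branch = float(np.nanmean(pw)) if not np.all(np.isnan(pw)) else 1.0
    else:
        branch = 1.0
    return RegionFeatures(
        mean_score=mean_score,
        mean_antisense_diff=mean_diff,
        length=region.n_codons,
        branch_length=min(max(branch, 0.0), 1.0),
    )


def build_training_sets(
    regions,
    ann: AnnotationSet,
    n_per_class: int = 10_000,
    seed: int = 0,
):
    """Sample (positives, antisense_negatives, ranking_negatives) region lists.

    Positives overlap annotated CDS in the same frame; antisense negatives
    overlap CDS in the antisense frame (and not the same frame); ranking
    negatives overlap no CDS in either frame and no pseudogene. Classes are
    disjoint by construction. If a class holds fewer than ``n_per_class``
    distinct regions, it is resampled with replacement (with a warning);
    an empty class is an error. Reproducible given ``seed``.
    """
    pos, anti_neg, rank_neg = [], [], []
    for region in regions:
        report = classify_overlap(region, ann)
        if report.same_frame_cds:
            pos.append(region)
        elif report.antisense_frame_cds:
            anti_neg.append(region)
        elif not report.pseudogene_any:
            rank_neg.append(region)
    rng = np.random.default_rng(seed)
    out = []
    for name, pool in (("positive", pos), ("antisense-negative", anti_neg),
                       ("ranking-negative", rank_neg)):
        if not pool:
            raise ValueError(f"empty {name} training class")
        if len(pool) < n_per_class:
            warnings.warn(
                f"{name} class has {len(pool)} regions < n_per_class={n_per_class}; "
                "sampling with replacement"
            )
            idx = rng.integers(0, len(pool), size=n_per_class)
        else:
            idx = rng.choice(len(pool), size=n_per_class, replace=False)
        out.append([pool[i] for i in idx])
    return tuple(out)


class _RbfSvm(BaseEstimator, ClassifierMixin):
    """Standardized RBF SVM with Platt-calibrated probabilities."""

    n_features_expected: int | None = None

    def __init__(self, C: float = 1.0, random_state: int = 0):
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if self.n_features_expected is not None and X.shape[1] != self.n_features_expected:
            raise ValueError(
                f"expected {self.n_features_expected} features, got {X.shape[1]}"
            )
        self.pipeline_ = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    SVC(
                        C=self.C,
                        kernel="rbf",
                        gamma=1.0 / X.shape[1],  # kernel width 1/n_features
                        probability=True,
                        random_state=self.random_state,
                    ),
                ),
            ]
        )
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.named_steps["svc"].classes_
        self.n_features_in_ = X.shape[1]
        self.n_per_class_ = {int(c): int((y == c).sum()) for c in self.classes_}
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(np.asarray(X, dtype=float))

    def prob_positive(self, X) -> np.ndarray:
        """Probability of the positive (label 1) class."""
        proba = self.predict_proba(np.atleast_2d(X))
        col = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, col]

    def save(self, path) -> None:
        joblib.dump({"format_version": 1, "model": self}, path)

    @classmethod
    def load(cls, path) -> "_RbfSvm":
        payload = joblib.load(path)
        if payload.get("format_version") != 1:
            raise ValueError("unsupported model archive version")
        model = payload["model"]
        if not isinstance(model, cls):
            raise TypeError(f"archive holds {type(model).__name__}, expected {cls.__name__}")
        return model


class AntisenseSVM(_RbfSvm):
    """Sense-vs-antisense classifier on (mean_score, mean_antisense_diff, length)."""

    n_features_expected = 3


class RankingSVM(_RbfSvm):
    """Coding-vs-false-positive classifier on the four region features."""

    n_features_expected = 4


def _feature_matrix(regions, tracks, power, include_branch_length):
    return np.vstack(
        [
            extract_features(r, tracks, power).to_array(include_branch_length)
            for r in regions
        ]
    )


def train_antisense_svm(
    positives, negatives, tracks, power=None, random_state: int = 0
) -> AntisenseSVM:
    Xp = _feature_matrix(positives, tracks, power, include_branch_length=False)
    Xn = _feature_matrix(negatives, tracks, power, include_branch_length=False)
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(len(Xp), int), np.zeros(len(Xn), int)])
    return AntisenseSVM(random_state=random_state).fit(X, y)


def train_ranking_svm(
    positives, negatives, tracks, power=None, random_state: int = 0
) -> RankingSVM:
    Xp = _feature_matrix(positives, tracks, power, include_branch_length=True)
    Xn = _feature_matrix(negatives, tracks, power, include_branch_length=True)
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(len(Xp), int), np.zeros(len(Xn), int)])
    return RankingSVM(random_state=random_state).fit(X, y)


def apply_svm(model: _RbfSvm, features: RegionFeatures) -> float:
    """Calibrated probability that the region is sense-coding / true-coding."""
    wide = isinstance(model, RankingSVM) or model.n_features_in_ == 4
    return float(model.prob_positive(features.to_array(include_branch_length=wide))[0])


def rank_pccrs(
    model: RankingSVM,
    pccrs: list[Pccr],
    tracks: dict[int, CodonScoreTrack],
    power: PowerTrack | None = None,
) -> list[Pccr]:
    """Score every PCCR with the ranking SVM and assign ranks 1..N.

    Rank order is descending probability; ties break by descending mean
    score, then genomic coordinate — fully deterministic and invariant to
    input order.
    """
    if not pccrs:
        return []
    for p in pccrs:
        if p.features is None:
            p.features = extract_features(p.region, tracks, power)
    X = np.vstack([p.features.to_array(include_branch_length=True) for p in pccrs])
    probs = model.prob_positive(X)
    for p, prob in zip(pccrs, probs):
        p.svm_score = float(prob)
    ordered = sorted(
        pccrs,
        key=lambda p: (
            -p.svm_score,
            -p.features.mean_score,
            p.chrom,
            p.start,
            p.frame.frame_id,
        ),
    )
    for i, p in enumerate(ordered, start=1):
        p.rank = i
    return ordered


def gene_rank(gene_cds, pccrs: list[Pccr]):
    """Best (lowest) rank of any PCCR overlapping the gene's CDS in the same frame.

    ``gene_cds`` is a list of ``(chrom, start, end, frame_id)`` spans.
    Returns ``None`` when no ranked PCCR overlaps.
    """
    best = None
    for chrom, start, end, fid in gene_cds:
        for p in pccrs:
            if p.rank is None:
                continue
            if p.chrom == chrom and p.frame.frame_id == fid and p.start < end and p.end > start:
                if best is None or p.rank < best:
                    best = p.rank
    return best


def cluster_pccrs(pccrs: list[Pccr], window: int = CLUSTER_WINDOW) -> dict[int, int]:
    """Single-linkage chaining of PCCRs within ``window`` bp on a chromosome.

    PCCRs on opposite strands may share a cluster (clustering is purely
    positional). Sets ``cluster_id`` on each PCCR and returns a map from
    cluster id to the best (lowest) member rank (None-safe).
    """
    by_pos = sorted(pccrs, key=lambda p: (p.chrom, p.start, p.end))
    cluster_id = -1
    prev_chrom, prev_end = None, None
    for p in by_pos:
        if p.chrom != prev_chrom or p.start - prev_end > window:
            cluster_id += 1
            prev_end = p.end
        else:
            prev_end = max(prev_end, p.end)
        prev_chrom = p.chrom
        p.cluster_id = cluster_id
    best: dict[int, int] = {}
    for p in by_pos:
        if p.rank is not None:
            cur = best.get(p.cluster_id)
            best[p.cluster_id] = p.rank if cur is None else min(cur, p.rank)
        else:
            best.setdefault(p.cluster_id, None)
    return best
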