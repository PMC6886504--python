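"""Region features, SVM training sets, ranking, gene rank and clustering."""

import warnings

import numpy as np
import pytest

from pccrscan.filtering import Pccr
from pccrscan.frames import Frame
from pccrscan.hmm import PhyloCSFRegion
from pccrscan.ranking import (
    AntisenseSVM,
    RankingSVM,
    RegionFeatures,
    apply_svm,
    build_training_sets,
    cluster_pccrs,
    extract_features,
    gene_rank,
    rank_pccrs,
    train_antisense_svm,
)
from pccrscan.scores import PowerTrack

from conftest import make_track


def region(start, n_codons, frame_id=0, chrom="chr1"):
    f = Frame.from_id(frame_id)
    return PhyloCSFRegion(chrom, f, start, start + 3 * n_codons, n_codons, 0.9, 0.0)


def tracks_with(sense, anti=None, frame_id=0):
    """Six tracks: constant `sense` scores in frame_id, `anti` in its
    antisense frame, noncoding (-4) elsewhere, over 200 codons."""
    from pccrscan.frames import antisense_frame

    out = {}
    anti_fid = antisense_frame(Frame.from_id(frame_id)).frame_id
    for fid in range(6):
        if fid == frame_id:
            vals = np.full(200, float(sense))
        elif fid == anti_fid and anti is not None:
            vals = np.full(200, float(anti))
        else:
            vals = np.full(200, -4.0)
        out[fid] = make_track(vals, frame_id=fid)
    return out


def test_extract_features_constant_score_missing_antisense():
    tracks = tracks_with(6.0)
    # blank the antisense frame entirely
    from pccrscan.frames import antisense_frame

    anti_fid = antisense_frame(Frame.from_id(0)).frame_id
    tracks[anti_fid] = make_track([], frame_id=anti_fid)
    f = extract_features(region(30, 10), tracks)
    assert f.mean_score == pytest.approx(6.0)
    assert f.mean_antisense_diff == pytest.approx(6.0)  # missing antisense = 0 db
    assert f.length == 10


def test_extract_features_ghost_factor_half():
    tracks = tracks_with(8.0, anti=4.0)
    f = extract_features(region(30, 10), tracks)
    assert f.mean_antisense_diff == pytest.approx(0.5 * f.mean_score)


def test_extract_features_power_mean():
    tracks = tracks_with(5.0)
    n = len(tracks[0])
    power = PowerTrack("chr1", tracks[0].codon_starts, np.full(n, 0.8))
    f = extract_features(region(30, 10), tracks, power)
    assert f.branch_length == pytest.approx(0.8)


def test_extract_features_all_missing_errors():
    tracks = tracks_with(5.0)
    tracks[0] = make_track([np.nan] * 200, frame_id=0)
    with pytest.raises(ValueError, match="no scored codons"):
        extract_features(region(30, 10), tracks)


def test_training_set_memberships_and_determinism(small_scan, small_ann):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pos, anti, neg = build_training_sets(
            small_scan.regions, small_ann, n_per_class=50, seed=4
        )
        pos2, anti2, neg2 = build_training_sets(
            small_scan.regions, small_ann, n_per_class=50, seed=4
        )
        pos3, _, _ = build_training_sets(
            small_scan.regions, small_ann, n_per_class=50, seed=5
        )
    from pccrscan.filtering import classify_overlap

    for r in pos:
        assert classify_overlap(r, small_ann).same_frame_cds
    for r in anti:
        rep = classify_overlap(r, small_ann)
        assert rep.antisense_frame_cds and not rep.same_frame_cds
    for r in neg:
        assert classify_overlap(r, small_ann).category == "none"
    key = lambda rs: [(r.start, r.frame.frame_id) for r in rs]
    assert key(pos) == key(pos2) and key(anti) == key(anti2) and key(neg) == key(neg2)
    assert key(pos) != key(pos3)  # different seed, different sample


def test_training_resampling_warns(small_scan, small_ann):
    with pytest.warns(UserWarning, match="replacement"):
        build_training_sets(small_scan.regions, small_ann, n_per_class=10_000, seed=0)


def test_svm_separable_classes_high_accuracy():
    rng = np.random.default_rng(0)
    X0 = rng.normal(-3, 0.5, size=(300, 3))
    X1 = rng.normal(3, 0.5, size=(300, 3))
    X = np.vstack([X1, X0])
    y = np.concatenate([np.ones(300, int), np.zeros(300, int)])
    model = AntisenseSVM(random_state=0).fit(X, y)
    assert (model.predict(X) == y).mean() >= 0.99
    assert np.median(model.prob_positive(X1)) > 0.5


def test_svm_rejects_single_class_and_wrong_width():
    with pytest.raises(ValueError, match="both classes"):
        AntisenseSVM().fit(np.zeros((10, 3)), np.zeros(10))
    with pytest.raises(ValueError, match="features"):
        AntisenseSVM().fit(np.zeros((4, 2)), np.array([0, 1, 0, 1]))


def test_train_antisense_svm_on_regions_and_apply():
    sense_tracks = tracks_with(8.0, anti=4.0)
    positives = [region(s, 20) for s in range(0, 300, 60)]
    ghost_tracks = tracks_with(4.0, anti=8.0)  # stronger on the other strand
    negatives = [region(s, 8, frame_id=0) for s in range(0, 300, 60)]
    # train on a merged picture: positives from sense-dominant tracks,
    # negatives re-extracted from ghost-dominant tracks
    import numpy as np

    Xp = np.vstack(
        [extract_features(r, sense_tracks).to_array() for r in positives]
    )
    Xn = np.vstack(
        [extract_features(r, ghost_tracks).to_array() for r in negatives]
    )
    model = AntisenseSVM(random_state=0).fit(
        np.vstack([Xp, Xn]),
        np.concatenate([np.ones(len(Xp), int), np.zeros(len(Xn), int)]),
    )
    f_pos = extract_features(region(30, 20), sense_tracks)
    f_neg = extract_features(region(30, 8), ghost_tracks)
    assert apply_svm(model, f_pos) > apply_svm(model, f_neg)


def test_rank_pccrs_order_and_permutation_invariance(small_scan):
    ranked = small_scan.pccrs
    assert [p.rank for p in ranked] == list(range(1, len(ranked) + 1))
    scores = [p.svm_score for p in ranked]
    assert scores == sorted(scores, reverse=True)
    # re-rank a shuffled copy: identical (region -> rank) mapping
    rng = np.random.default_rng(1)
    shuffled = [
        Pccr(region=p.region, provenance=p.provenance, features=p.features)
        for p in rng.permutation(np.asarray(ranked, dtype=object))
    ]
    reranked = rank_pccrs(
        small_scan.ranking_model, shuffled, small_scan.masked_tracks, small_scan.power
    )
    want = {(p.chrom, p.start, p.frame.frame_id): p.rank for p in ranked}
    got = {(p.chrom, p.start, p.frame.frame_id): p.rank for p in reranked}
    assert want == got


def test_ranking_separates_planted_from_decoys(small_scan, small_sim):
    """ROC of planted-gene regions vs decoy regions under the ranking SVM."""
    from sklearn.metrics import roc_auc_score

    true_spans = small_sim.truth.coding_codon_spans()
    decoy_spans = [(d["span"][0], d["span"][1], d["frame_id"]) for d in small_sim.truth.decoys]

    def hits(region, spans):
        return any(
            region.frame.frame_id == fid and region.start < e and region.end > s
            for s, e, fid in spans
        )

    y, scores = [], []
    for r in small_scan.regions:
        is_true = hits(r, true_spans)
        is_decoy = hits(r, decoy_spans)
        if is_true == is_decoy:
            continue
        y.append(1 if is_true else 0)
        scores.append(small_scan.region_prob(r))
    assert roc_auc_score(y, scores) >= 0.95


def test_gene_rank_minimum_and_undefined():
    f = Frame.from_id(0)

    def pccr(start, rank):
        p = Pccr(region=region(start, 10), provenance="untouched")
        p.rank = rank
        return p

    pccrs = [pccr(0, 120), pccr(60, 5)]
    gene = [("chr1", 0, 90, 0)]
    assert gene_rank(gene, pccrs) == 5
    assert gene_rank([("chr1", 500, 600, 0)], pccrs) is None
    # same interval, different frame: no overlap in the frame sense
    assert gene_rank([("chr1", 0, 90, 1)], pccrs) is None


def test_cluster_window_semantics():
    def pccr(start, n=10):
        return Pccr(region=region(start, n), provenance="untouched")

    a, b = pccr(0), pccr(30 + 9000)  # 9 kb gap
    cluster_pccrs([a, b])
    assert a.cluster_id == b.cluster_id
    c, d = pccr(0), pccr(30 + 11001)  # 11 kb gap
    cluster_pccrs([c, d])
    assert c.cluster_id != d.cluster_id


def test_cluster_single_linkage_chain():
    def pccr(start):
        return Pccr(region=region(start, 10), provenance="untouched")

    # A-B and B-C gaps 9 kb, A-C gap ~18 kb: single linkage joins all three
    a = pccr(0)
    b = pccr(30 + 9000)
    c = pccr(30 + 9000 + 30 + 9000)
    best = cluster_pccrs([a, b, c])
    assert a.cluster_id == b.cluster_id == c.cluster_id
    assert len(best) == 1


def test_features_validation():
    with pytest.raises(ValueError):
        RegionFeatures(1.0, 1.0, 0, 0.5)
    with pytest.raises(ValueError):
        RegionFeatures(1.0, 1.0, 5, 1.5)
    arr = RegionFeatures(2.0, 1.0, 5, 0.5).to_array(include_branch_length=True)
    assert arr.tolist() == [2.0, 1.0, 5.0, 0.5]


def test_model_persistence_round_trip(tmp_path, small_scan):
    path = tmp_path / "anti.joblib"
    small_scan.antisense_model.save(path)
    loaded = AntisenseSVM.load(path)
    X = np.array([[5.0, 3.0, 20.0], [-2.0, -1.0, 9.0]])
    assert np.allclose(
        loaded.prob_positive(X), small_scan.antisense_model.prob_positive(X)
    )
    with pytest.raises(TypeError):
        RankingSVM.load(path)
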