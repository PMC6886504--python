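"""Hidden Markov smoothing of per-codon coding-evolution scores.

Single codons rarely carry enough evolutionary signal to call coding vs
noncoding on their own, so scores of nearby codons in the same frame are
combined with a four-state HMM: one *coding* state and three *noncoding*
(gap) states. The three gap states share emissions but have different
self-transition probabilities and can transition only to the coding state;
their geometric dwell times form a discrete three-component approximation
of the multimodal distribution of gaps between same-frame coding exons
(consecutive exons of a gene, nonconsecutive exons, different genes). The
gap mixture — and optionally the coding dwell — is fitted by expectation
maximization (Baum–Welch restricted to transition parameters, emissions
held fixed).

Because a score *is* a log-likelihood ratio (in decibans) of coding vs
noncoding evolution, the ratio of coding to noncoding emission densities is
taken directly from it: a codon scoring ``s`` db contributes
``s·ln(10)/10`` nats to the coding state's log emission and 0 to each
noncoding state. Missing scores are uninformative (ratio 1) in every state,
which preserves gap-length bookkeeping. All computation is in log space
with no rescaling, so small instances agree exactly with brute-force path
enumeration.

*PhyloCSF Regions* are the maximal intervals where the Viterbi path is in
the coding state, decorated with the maximum per-codon posterior
probability of coding from forward–backward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .frames import Frame
from .scores import CodonScoreTrack

__all__ = [
    "HmmParams",
    "PhyloCSFRegion",
    "CodingHMM",
    "emission_log_ratio",
    "viterbi_decode",
    "forward_backward",
    "fit_transitions_em",
    "default_params",
]

#: nats per deciban: a score of 10 db is an odds ratio of 10, i.e. ln(10) nats.
NATS_PER_DECIBAN = math.log(10.0) / 10.0


@dataclass(frozen=True)
class HmmParams:
    """Transition structure and emission scale of the 4-state smoother.

    ``coding_stay`` is the coding self-transition probability (mean coding
    run ``1/(1-coding_stay)`` codons). ``gap_weights`` are the mixture
    weights over the three noncoding states (sum 1); ``gap_stays`` their
    self-transition probabilities (component mean gap ``1/(1-p)`` codons).
    ``initial_coding`` is the prior probability of starting in coding.
    """

    coding_stay: float = 1.0 - 1.0 / 50.0
    gap_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    gap_stays: tuple[float, float, float] = (
        1.0 - 1.0 / 100.0,
        1.0 - 1.0 / 3000.0,
        1.0 - 1.0 / 100000.0,
    )
    initial_coding: float = 0.01
    emission_scale: float = NATS_PER_DECIBAN

    def __post_init__(self) -> None:
        probs = (self.coding_stay, self.initial_coding, *self.gap_weights, *self.gap_stays)
        if not all(0.0 < p < 1.0 for p in probs):
            raise ValueError("all probabilities must lie strictly in (0, 1)")
        if abs(sum(self.gap_weights) - 1.0) > 1e-9:
            raise ValueError("gap_weights must sum to 1")
        if self.emission_scale <= 0:
            raise ValueError("emission_scale must be positive")

    @property
    def gap_means(self) -> tuple[float, float, float]:
        """Mean dwell (codons) of each gap component: 1/(1 - stay)."""
        return tuple(1.0 / (1.0 - p) for p in self.gap_stays)

    @property
    def coding_mean(self) -> float:
        return 1.0 / (1.0 - self.coding_stay)

    def sorted_by_gap_mean(self) -> "HmmParams":
        """Relabel gap components so means are ascending (identifiability)."""
        order = np.argsort(self.gap_means)
        return replace(
            self,
            gap_weights=tuple(self.gap_weights[i] for i in order),
            gap_stays=tuple(self.gap_stays[i] for i in order),
        )

    # -- dense representations used by the kernels and by brute-force oracles

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 4x4 matrix; state 0 is coding, 1-3 the gap states."""
        A = np.zeros((4, 4))
        A[0, 0] = self.coding_stay
        for k in range(3):
            A[0, k + 1] = (1.0 - self.coding_stay) * self.gap_weights[k]
            A[k + 1, k + 1] = self.gap_stays[k]
            A[k + 1, 0] = 1.0 - self.gap_stays[k]
        return A

    def initial_distribution(self) -> np.ndarray:
        pi = np.empty(4)
        pi[0] = self.initial_coding
        pi[1:] = (1.0 - self.initial_coding) * np.asarray(self.gap_weights)
        return pi


@dataclass(frozen=True)
class PhyloCSFRegion:
    """Maximal Viterbi-coding interval in one frame (0-based half-open)."""

    chrom: str
    frame: Frame
    start: int
    end: int
    n_codons: int
    max_coding_posterior: float
    mean_score: float

    def __post_init__(self) -> None:
        if self.end - self.start != 3 * self.n_codons or self.n_codons < 1:
            raise ValueError("region must span exactly 3 * n_codons bases, n_codons >= 1")
        if not 0.0 <= self.max_coding_posterior <= 1.0:
            raise ValueError("max_coding_posterior must lie in [0, 1]")

    @property
    def strand(self) -> str:
        return self.frame.strand

    def codon_starts(self) -> np.ndarray:
        return np.arange(self.start, self.end, 3, dtype=np.int64)


def emission_log_ratio(score: float, params: HmmParams) -> float:
    """Log (nats) of the coding/noncoding emission ratio for one codon.

    Missing scores (NaN) are uninformative: ratio 1, i.e. 0 nats.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return 0.0
    if math.isinf(score):
        raise ValueError("score must be finite or missing")
    return float(score) * params.emission_scale


# ---------------------------------------------------------------------------
# numba kernels (state 0 = coding; states 1..3 = gaps)


@njit(cache=True)
def _lse2(a, b):
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    m = a if a > b else b
    return m + np.log(np.exp(a - m) + np.exp(b - m))


@njit(cache=True)
def _viterbi_kernel(e, log_c, log_cw, log_p, log_q, log_pi):
    """Max-probability path. e: coding log emission ratio per codon.

    log_c = ln coding_stay; log_cw[k] = ln((1-c) w_k); log_p[k] = ln p_k;
    log_q[k] = ln(1-p_k); log_pi: initial log distribution (4,).
    """
    T = e.shape[0]
    bp = np.empty((T, 4), np.uint8)
    v = np.empty(4)
    v[0] = log_pi[0] + e[0]
    for k in range(3):
        v[k + 1] = log_pi[k + 1]
    nv = np.empty(4)
    for t in range(1, T):
        # into coding: from coding (stay) or any gap state (exit)
        best = v[0] + log_c
        arg = 0
        for k in range(3):
            cand = v[k + 1] + log_q[k]
            if cand > best:
                best = cand
                arg = k + 1
        nv[0] = best + e[t]
        bp[t, 0] = arg
        # into gap k: from coding or stay
        for k in range(3):
            a = v[0] + log_cw[k]
            b = v[k + 1] + log_p[k]
            if a > b:
                nv[k + 1] = a
                bp[t, k + 1] = 0
            else:
                nv[k + 1] = b
                bp[t, k + 1] = k + 1
        for s in range(4):
            v[s] = nv[s]
    best = v[0]
    last = 0
    for s in range(1, 4):
        if v[s] > best:
            best = v[s]
            last = s
    path = np.empty(T, np.uint8)
    path[T - 1] = last
    for t in range(T - 1, 0, -1):
        last = bp[t, last]
        path[t - 1] = last
    return path, best


@njit(cache=True)
def _forward_kernel(e, log_c, log_cw, log_p, log_q, log_pi):
    T = e.shape[0]
    alpha = np.empty((T, 4))
    alpha[0, 0] = log_pi[0] + e[0]
    for k in range(3):
        alpha[0, k + 1] = log_pi[k + 1]
    for t in range(1, T):
        acc = alpha[t - 1, 0] + log_c
        for k in range(3):
            acc = _lse2(acc, alpha[t - 1, k + 1] + log_q[k])
        alpha[t, 0] = acc + e[t]
        for k in range(3):
            alpha[t, k + 1] = _lse2(
                alpha[t - 1, 0] + log_cw[k], alpha[t - 1, k + 1] + log_p[k]
            )
    ll = alpha[T - 1, 0]
    for s in range(1, 4):
        ll = _lse2(ll, alpha[T - 1, s])
    return alpha, ll


@njit(cache=True)
def _backward_counts_kernel(e, alpha, ll, log_c, log_cw, log_p, log_q):
    """Backward pass computing posteriors and expected transition counts.

    Returns gamma (T,4) and xi (4,4) = expected transition counts summed
    over time (only the structurally allowed cells are nonzero).
    """
    T = e.shape[0]
    gamma = np.empty((T, 4))
    xi = np.zeros((4, 4))
    beta = np.zeros(4)  # log beta_{T-1} = 0
    for s in range(4):
        gamma[T - 1, s] = np.exp(alpha[T - 1, s] + beta[s] - ll)
    nb = np.empty(4)
    for t in range(T - 2, -1, -1):
        bc = e[t + 1] + beta[0]  # into coding at t+1
        # beta_t(coding): stay coding or enter any gap
        acc = log_c + bc
        for k in range(3):
            acc = _lse2(acc, log_cw[k] + beta[k + 1])
        nb[0] = acc
        # beta_t(gap k): stay or exit to coding
        for k in range(3):
            nb[k + 1] = _lse2(log_p[k] + beta[k + 1], log_q[k] + bc)
        # transition posteriors at t -> t+1
        xi[0, 0] += np.exp(alpha[t, 0] + log_c + bc - ll)
        for k in range(3):
            xi[0, k + 1] += np.exp(alpha[t, 0] + log_cw[k] + beta[k + 1] - ll)
            xi[k + 1, k + 1] += np.exp(alpha[t, k + 1] + log_p[k] + beta[k + 1] - ll)
            xi[k + 1, 0] += np.exp(alpha[t, k + 1] + log_q[k] + bc - ll)
        for s in range(4):
            beta[s] = nb[s]
            gamma[t, s] = np.exp(alpha[t, s] + beta[s] - ll)
    return gamma, xi


def _log_params(params: HmmParams):
    w = np.asarray(params.gap_weights)
    p = np.asarray(params.gap_stays)
    return (
        math.log(params.coding_stay),
        np.log((1.0 - params.coding_stay) * w),
        np.log(p),
        np.log1p(-p),
        np.log(params.initial_distribution()),
    )


def _emissions(track: CodonScoreTrack, params: HmmParams) -> np.ndarray:
    e = track.scores * params.emission_scale
    return np.where(np.isnan(e), 0.0, e)


# ---------------------------------------------------------------------------
# Estimator


class CodingHMM:
    """Coding/noncoding smoother with sklearn-style fit/decode surface.

    Parameters mirror :class:`HmmParams`; ``fit`` runs Baum–Welch on the
    transition structure (emissions fixed), after which fitted attributes
    ``params_``, ``loglik_trace_`` and ``n_iter_`` are available. ``decode``
    and ``predict_proba`` work with either the constructor parameters or
    the fitted ones.
    """

    def __init__(
        self,
        coding_stay: float = HmmParams.coding_stay,
        gap_weights: tuple[float, float, float] = HmmParams.gap_weights,
        gap_stays: tuple[float, float, float] = HmmParams.gap_stays,
        initial_coding: float = HmmParams.initial_coding,
        emission_scale: float = NATS_PER_DECIBAN,
        max_iter: int = 50,
        tol: float = 1e-6,
        update_coding_stay: bool = True,
    ):
        self.coding_stay = coding_stay
        self.gap_weights = gap_weights
        self.gap_stays = gap_stays
        self.initial_coding = initial_coding
        self.emission_scale = emission_scale
        self.max_iter = max_iter
        self.tol = tol
        self.update_coding_stay = update_coding_stay

    # -- sklearn plumbing ---------------------------------------------------

    _param_names = (
        "coding_stay",
        "gap_weights",
        "gap_stays",
        "initial_coding",
        "emission_scale",
        "max_iter",
        "tol",
        "update_coding_stay",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **kwargs) -> "CodingHMM":
        for key, value in kwargs.items():
            if key not in self._param_names:
                raise ValueError(f"invalid parameter {key!r} for CodingHMM")
            setattr(self, key, value)
        return self

    # -- parameter access ---------------------------------------------------

    @property
    def init_params(self) -> HmmParams:
        return HmmParams(
            coding_stay=self.coding_stay,
            gap_weights=tuple(self.gap_weights),
            gap_stays=tuple(self.gap_stays),
            initial_coding=self.initial_coding,
            emission_scale=self.emission_scale,
        )

    def _active_params(self) -> HmmParams:
        return getattr(self, "params_", self.init_params)

    # -- core ---------------------------------------------------------------

    @staticmethod
    def _as_tracks(X) -> list[CodonScoreTrack]:
        if isinstance(X, CodonScoreTrack):
            return [X]
        return list(X)

    def fit(self, X, y=None) -> "CodingHMM":
        """Fit gap mixture (and optionally coding dwell) by Baum–Welch.

        ``X`` is a dense :class:`CodonScoreTrack` or an iterable of them
        (genome-wide fit sums expected counts across tracks). The
        log-likelihood is non-decreasing across iterations.
        """
        tracks = [t.dense() for t in self._as_tracks(X)]
        if not tracks or all(len(t) == 0 for t in tracks):
            raise ValueError("cannot fit on empty input")
        if all(np.all(np.isnan(t.scores)) for t in tracks):
            raise ValueError("degenerate input: all scores missing")
        params = self.init_params
        emissions = [_emissions(t, params) for t in tracks if len(t) > 0]
        trace: list[float] = []
        for _ in range(self.max_iter):
            lp = _log_params(params)
            total_ll = 0.0
            xi = np.zeros((4, 4))
            gamma0 = np.zeros(4)
            for e in emissions:
                alpha, ll = _forward_kernel(e, *lp)
                g, x = _backward_counts_kernel(e, alpha, ll, *lp[:-1])
                total_ll += ll
                xi += x
                gamma0 += g[0]
            trace.append(total_ll)
            if len(trace) > 1 and trace[-1] - trace[-2] < self.tol * abs(trace[-2]):
                break
            params = self._m_step(params, xi, gamma0)
        self.params_ = params.sorted_by_gap_mean()
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        return self

    def _m_step(self, params: HmmParams, xi: np.ndarray, gamma0: np.ndarray) -> HmmParams:
        eps = 1e-12
        if self.update_coding_stay:
            out_c = xi[0, 0] + xi[0, 1:].sum()
            coding_stay = (xi[0, 0] + eps) / (out_c + 4 * eps)
            coding_stay = float(np.clip(coding_stay, eps, 1 - eps))
        else:
            coding_stay = params.coding_stay
        # w_k ties the initial distribution of gap states to coding->gap
        # transitions; both expected-count terms enter the update.
        num = xi[0, 1:] + gamma0[1:]
        w = (num + eps) / (num.sum() + 3 * eps)
        stays = []
        for k in range(3):
            denom = xi[k + 1, k + 1] + xi[k + 1, 0]
            p = (xi[k + 1, k + 1] + eps) / (denom + 2 * eps)
            stays.append(float(np.clip(p, eps, 1 - eps)))
        return replace(
            params,
            coding_stay=coding_stay,
            gap_weights=tuple(float(x) for x in w / w.sum()),
            gap_stays=tuple(stays),
        )

    def decode(self, track: CodonScoreTrack):
        """Viterbi path and the maximal coding runs as regions.

        Returns ``(path, regions)``: ``path`` is the per-codon state array
        (0 = coding) over the densified grid, and each region carries its
        maximum coding posterior from forward–backward and its mean score
        (decibans/codon over non-missing codons).
        """
        if len(track) == 0:
            raise ValueError("cannot decode an empty track")
        params = self._active_params()
        dense = track.dense()
        e = _emissions(dense, params)
        lp = _log_params(params)
        path, _ = _viterbi_kernel(e, *lp)
        gamma, _ = self._posteriors(e, lp)
        regions = self._regions_from_path(dense, path, gamma[:, 0])
        return path, regions

    def analyze(self, track: CodonScoreTrack):
        """One-pass decode + posteriors: ``(path, regions, gamma, loglik)``."""
        if len(track) == 0:
            raise ValueError("cannot analyze an empty track")
        params = self._active_params()
        dense = track.dense()
        e = _emissions(dense, params)
        lp = _log_params(params)
        path, _ = _viterbi_kernel(e, *lp)
        gamma, ll = self._posteriors(e, lp)
        regions = self._regions_from_path(dense, path, gamma[:, 0])
        return path, regions, gamma, ll

    def predict_proba(self, track: CodonScoreTrack):
        """Per-codon posterior state probabilities (T, 4) over the dense grid.

        Also returns the total data log-likelihood: ``(gamma, loglik)``.
        """
        if len(track) == 0:
            raise ValueError("cannot compute posteriors of an empty track")
        params = self._active_params()
        e = _emissions(track.dense(), params)
        return self._posteriors(e, _log_params(params))

    @staticmethod
    def _posteriors(e: np.ndarray, lp) -> tuple[np.ndarray, float]:
        alpha, ll = _forward_kernel(e, *lp)
        gamma, _ = _backward_counts_kernel(e, alpha, ll, *lp[:-1])
        return gamma, float(ll)

    @staticmethod
    def _regions_from_path(
        dense: CodonScoreTrack, path: np.ndarray, coding_post: np.ndarray
    ) -> list[PhyloCSFRegion]:
        coding = (path == 0).astype(np.int8)
        if not coding.any():
            return []
        diff = np.diff(np.concatenate(([0], coding, [0])))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)
        regions = []
        for lo, hi in zip(run_starts, run_ends):
            seg = dense.scores[lo:hi]
            mean_score = float(np.nanmean(seg)) if not np.all(np.isnan(seg)) else float("nan")
            regions.append(
                PhyloCSFRegion(
                    chrom=dense.chrom,
                    frame=dense.frame,
                    start=int(dense.codon_starts[lo]),
                    end=int(dense.codon_starts[hi - 1]) + 3,
                    n_codons=int(hi - lo),
                    max_coding_posterior=float(coding_post[lo:hi].max()),
                    mean_score=mean_score,
                )
            )
        return regions


# ---------------------------------------------------------------------------
# Functional wrappers (module-level operation surface)


def viterbi_decode(track: CodonScoreTrack, params: HmmParams):
    """Most likely state path and the coding-state runs as regions."""
    model = CodingHMM(**_ctor_kwargs(params))
    return model.decode(track)


def forward_backward(track: CodonScoreTrack, params: HmmParams):
    """Posterior P(state) per codon, smoothed log-odds track, and log-likelihood.

    Returns ``(gamma, logodds_track, loglik)`` where ``gamma[:, 0]`` is the
    coding posterior and the log-odds track holds
    ``10·log10(P(coding)/(1-P(coding)))`` per codon (deciban scale, clipped).
    """
    model = CodingHMM(**_ctor_kwargs(params))
    gamma, ll = model.predict_proba(track)
    dense = track.dense()
    g = np.clip(gamma[:, 0], 1e-12, 1.0 - 1e-12)
    logodds = 10.0 * np.log10(g / (1.0 - g))
    lo_track = CodonScoreTrack(dense.chrom, dense.frame, dense.codon_starts, logodds)
    return gamma, lo_track, ll


def fit_transitions_em(
    tracks,
    params0: HmmParams | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    update_coding_stay: bool = True,
):
    """EM fit of the transition structure; returns (params, loglik_trace)."""
    params0 = params0 or HmmParams()
    model = CodingHMM(
        **_ctor_kwargs(params0),
        max_iter=max_iter,
        tol=tol,
        update_coding_stay=update_coding_stay,
    )
    model.fit(tracks)
    return model.params_, model.loglik_trace_


def _ctor_kwargs(params: HmmParams) -> dict:
    return dict(
        coding_stay=params.coding_stay,
        gap_weights=tuple(params.gap_weights),
        gap_stays=tuple(params.gap_stays),
        initial_coding=params.initial_coding,
        emission_scale=params.emission_scale,
    )


def default_params(annotation=None) -> HmmParams:
    """Documented default parameters, optionally initialized from annotation.

    Without annotation: mean coding run 50 codons, gap means 100 / 3,000 /
    100,000 codons, uniform weights. With an annotation, the coding dwell is
    the mean annotated coding-exon length (codons) and the gap means are the
    tertile means of same-frame inter-exon gaps. These only initialize EM;
    on well-separated data they do not change its fixed point.
    """
    if annotation is None:
        return HmmParams()
    exon_codons = annotation.cds_exon_codon_lengths()
    if exon_codons.size == 0:
        return HmmParams()
    coding_mean = max(float(exon_codons.mean()), 2.0)
    gaps = annotation.same_frame_gap_lengths() / 3.0
    gaps = gaps[gaps >= 1]
    if gaps.size < 9:
        return HmmParams(coding_stay=1.0 - 1.0 / coding_mean)
    gaps = np.sort(gaps)
    thirds = np.array_split(gaps, 3)
    means = [max(float(t.mean()), 2.0) for t in thirds]
    if len(set(np.round(means, 6))) < 3:
        warnings.warn("degenerate empirical gap scales; falling back to defaults")
        return HmmParams(coding_stay=1.0 - 1.0 / coding_mean)
    return HmmParams(
        coding_stay=1.0 - 1.0 / coding_mean,
        gap_stays=tuple(1.0 - 1.0 / m for m in means),
    )
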