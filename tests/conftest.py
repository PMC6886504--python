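"""Shared fixtures: a small synthetic genome and a completed scan over it.

The small genome (700 kb, 15 genes) keeps per-test cost low; the acceptance
tests build their own full-size genome.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from pccrscan.filtering import read_annotation
from pccrscan.frames import Frame
from pccrscan.pipeline import PipelineConfig, run_scan
from pccrscan.scores import CodonScoreTrack
from pccrscan.simulate import SimConfig, simulate

SMALL_SIM_KWARGS = dict(
    seed=11,
    genome_length=700_000,
    n_genes=15,
    n_pseudogenes=4,
    n_lncrnas=5,
    n_decoys=150,
)


def make_track(scores, frame_id=0, chrom="chr1", start=0):
    """Dense codon track from a plain list of scores (NaN = missing)."""
    frame = Frame.from_id(frame_id)
    first = start + ((frame.phase - start) % 3)
    starts = first + 3 * np.arange(len(scores), dtype=np.int64)
    return CodonScoreTrack(chrom, frame, starts, np.asarray(scores, dtype=float))


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    out = tmp_path_factory.mktemp("smallsim")
    return simulate(SimConfig(**SMALL_SIM_KWARGS), out_dir=out)


@pytest.fixture(scope="session")
def small_ann(small_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return read_annotation(small_sim.paths["annotation"])


@pytest.fixture(scope="session")
def small_scan(small_sim, small_ann):
    cfg = PipelineConfig(n_per_class=400, seed=11, em_max_iter=15)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_scan(small_sim.tracks, small_sim.power, small_ann, cfg)
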