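"""Shared fixtures: small bin grids, fast simulation configs, and one
session-wide default synthetic study analyzed end to end."""

from __future__ import annotations

import numpy as np
import pytest

from chromband.genomic_io import build_bins
from chromband.synthetic import SimConfig


@pytest.fixture
def small_bins():
    return build_bins({"chrX": 1000, "chr2L": 400}, 200)


def fast_config(**overrides) -> SimConfig:
    """Small 1.6 Mb genome for quick pipeline-level tests."""
    defaults = dict(
        chrom_sizes={"chrX": 1_000_000, "chr2L": 600_000},
        n_insertions=600,
        n_dhs=150, n_orc2=100, n_h1_dips=150, n_boundaries=80,
        n_broad_promoters=120, n_peaked_promoters=70, n_unknown_promoters=15,
        n_curated_interbands=8, n_interbands_with_broad=6, n_ih_bands=8,
        n_hh_pairs=60, n_hh_pairs_far=8, n_single_genes=80,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default 10 Mb synthetic study (fixed seed)."""
    from chromband.pipeline import simulate_and_run

    outdir = tmp_path_factory.mktemp("default_run")
    return simulate_and_run(seed=7, outdir=outdir)


def align_accuracy(true_states: np.ndarray, decoded: np.ndarray, k_true: int,
                   k_dec: int) -> float:
    """Bin-level agreement after optimal one-to-one label alignment."""
    from scipy.optimize import linear_sum_assignment

    ok = (true_states >= 0) & (decoded >= 0)
    conf = np.zeros((k_true, k_dec))
    np.add.at(conf, (true_states[ok], decoded[ok]), 1)
    r, c = linear_sum_assignment(-conf)
    return float(conf[r, c].sum() / conf.sum())
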