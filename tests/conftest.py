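"""Shared fixtures: one default scenario and its derived products, computed
once per session so the heavier stages (simulation, peak calling, window
testing) are shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from deltadnase import delta_dnase, peaks
from deltadnase.synthetic_data import (
    INDUCED,
    UNTREATED,
    build_scenario,
    simulate_all_cuts,
)

SCENARIO_SEED = 11


@pytest.fixture(scope="session")
def scenario():
    return build_scenario(SCENARIO_SEED)


@pytest.fixture(scope="session")
def profiles(scenario):
    return simulate_all_cuts(scenario)


@pytest.fixture(scope="session")
def peaksets(scenario, profiles):
    out = {}
    for cond in (UNTREATED, INDUCED):
        track = peaks.kde_signal(peaks.pooled_profile(profiles[cond]))
        thr = peaks.gamma_threshold(track, 0.05)
        out[cond] = peaks.call_peaks(track, thr)
    return out


@pytest.fixture(scope="session")
def delta_results(scenario, profiles, peaksets):
    union = delta_dnase.union_regions(peaksets[UNTREATED], peaksets[INDUCED])
    windows = delta_dnase.tile_regions(union, chrom_sizes=scenario.chrom_sizes)
    matrix = delta_dnase.count_and_filter(
        windows, profiles[UNTREATED] + profiles[INDUCED]
    )
    diff = delta_dnase.nb_exact_test(matrix)
    sets = delta_dnase.classify_and_merge(diff)
    return {
        "union": union,
        "windows": windows,
        "matrix": matrix,
        "diff": diff,
        "sets": sets,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
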