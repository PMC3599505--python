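import itertools

import numpy as np
import pytest
from hypothesis import settings

import bivarseg as bv

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_random_series(rng, n, missing_lrr=0.0, missing_imbaf=0.3):
    """Random bivariate series with controllable missingness fractions."""
    lrr = rng.normal(0.0, 1.0, n)
    imbaf = rng.uniform(0.5, 1.0, n)
    mr = rng.random(n) >= missing_lrr
    mb = rng.random(n) >= missing_imbaf
    if not mr.any():
        mr[int(rng.integers(n))] = True
    if not mb.any():
        mb[int(rng.integers(n))] = True
    return bv.BivariateSeries(lrr, imbaf, mr, mb)


def brute_force_min(series, n_segments, params, max_len):
    """Exhaustive minimum of cost_of_segmentation over all valid tilings."""
    n = series.n
    best = np.inf
    best_cps = None
    for cuts in itertools.combinations(range(1, n), n_segments - 1):
        cps = np.array((0,) + cuts + (n,), dtype=np.int64)
        if np.diff(cps).max() > max_len:
            continue
        c = bv.cost_of_segmentation(series, cps, params)
        if c < best:
            best = c
            best_cps = cps
    return best, best_cps


def segmented_sample(pattern, contamination, seed, *, max_segment_length=400,
                     max_segments=80, penalty_k=1.0, **config_overrides):
    """Simulate one benchmark sample and segment it end to end."""
    cfg = bv.GeneratorConfig(pattern=pattern, contamination=contamination,
                             seed=seed, **config_overrides)
    specs, truth = bv.generate_profile(cfg)
    track = bv.simulate_sample(truth, cfg)
    series = bv.impute_constant(bv.to_imbaf(track))
    dp = bv.DPConfig(max_segments=max_segments,
                     max_segment_length=min(series.n, max_segment_length))
    results = bv.optimal_segmentation(series, dp)
    best = bv.select_model(results, series.n_observed, penalty_k)
    return cfg, specs, truth, series, best


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
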