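"""Shared fixtures: synthetic movies and pre-paced fibers.

Fiber fixtures pre-pace for 60 beats: the alternans pattern and snapshot
parity converge well before that, and the session-scoped results are shared
across the fiber, vulnerability and acceptance tests.
"""

import numpy as np
import pytest

import cardalt as ca
from cardalt.fiber import FiberConfig
from cardalt.mapping import AnalysisSettings
from cardalt.vulnerability import (block_snapshot, min_propagating_ci,
                                   prepace_fiber, pvc_snapshot,
                                   scan_block_window)

PREPACE_BEATS = 60
PVC_RANGE = (140.0, 340.0)
BLOCK_RANGE = (150.0, 320.0)


@pytest.fixture(scope="session")
def base_config():
    return FiberConfig(n_prepace_beats=PREPACE_BEATS)


@pytest.fixture(scope="session")
def prepaced(base_config):
    """Pre-paced recordings of the five named fibers."""
    return {fid: prepace_fiber(fid, base_config) for fid in "ABCDE"}


@pytest.fixture(scope="session")
def pvc_results(prepaced):
    """PVC coupling-interval scans (1 ms grid) for every fiber."""
    out = {}
    for fid, rec in prepaced.items():
        out[fid] = min_propagating_ci(pvc_snapshot(rec), rec.config,
                                      ci_range=PVC_RANGE,
                                      stop_after_full=8)
    return out


@pytest.fixture(scope="session")
def block_results(prepaced):
    """Conduction-block scans for the control (A) and β-AR (E) fibers."""
    out = {}
    for fid in ("A", "E"):
        rec = prepaced[fid]
        out[fid] = scan_block_window(block_snapshot(rec), rec.config,
                                     ci_range=BLOCK_RANGE,
                                     stop_after_full=15)
    return out


@pytest.fixture(scope="session")
def uniform_field():
    cfg = ca.SyntheticProtocolConfig()
    return ca.make_uniform_field(cfg.grid, 0.3, 0.1)


@pytest.fixture(scope="session")
def noiseless_movie(uniform_field):
    cfg = ca.SyntheticProtocolConfig(noise_sd=0.0, seed=11)
    return ca.synthesize_movie(cfg, uniform_field, bcl=100.0)


@pytest.fixture(scope="session")
def noisy_movie(uniform_field):
    cfg = ca.SyntheticProtocolConfig(noise_sd=0.05, seed=12)
    return ca.synthesize_movie(cfg, uniform_field, bcl=100.0)


@pytest.fixture(scope="session")
def raw_settings():
    return AnalysisSettings.raw()
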