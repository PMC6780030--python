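"""Shared fixtures: expensive simulations are session-scoped and reused.

The population fixture reproduces the study conditions (150 candidates,
default variability ranges and calibration windows, 500 pre-pacing beats at
1 Hz); drug-trial tests run on random subsamples of it to stay within desk
time scales.
"""

import numpy as np
import pytest

import emwtrials as e


@pytest.fixture(scope="session")
def baseline_control():
    """Baseline endocardial model paced 500 beats: (trace, state, biomarkers)."""
    tr, y = e.simulate_paced(protocol=e.StimulusProtocol(n_beats=500))
    return tr, y, e.extract_all(tr)


@pytest.fixture(scope="session")
def population():
    """Calibrated control population under the default study conditions."""
    cfg = e.RunConfig()
    return e.build_population(ranges=cfg.sampling_ranges(),
                              windows=cfg.calibration_windows(),
                              protocol=cfg.control_protocol(),
                              solver=cfg.solver())


@pytest.fixture(scope="session")
def grid_subpop(population):
    """Desk-scale subsample used by the block-grid checks."""
    return population.subsample(30, seed=0)


@pytest.fixture(scope="session")
def grid_controls(grid_subpop):
    return e.control_arm(grid_subpop)


@pytest.fixture(scope="session")
def trial_subpop(population):
    """Smaller subsample for multi-concentration drug trials."""
    return population.subsample(10, seed=7)


@pytest.fixture(scope="session")
def trial_controls(trial_subpop):
    return e.control_arm(trial_subpop)


@pytest.fixture(scope="session")
def trace_fixtures():
    return e.make_trace_fixtures(seed=0)
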