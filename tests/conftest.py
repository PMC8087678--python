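"""Shared fixtures: one full-size default run (reused by several suites) and
a small fast cohort for unit-level checks."""

import warnings

import pytest

from cgiplast.pipeline import analyze, compare_to_truth
from cgiplast.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_bundle():
    """Default study conditions: 3 cancer types, 2000 genes, 40 tumors / 10
    normals per type, seed 1."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_results(default_bundle):
    annotation, cohorts, _ = default_bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze(annotation, cohorts)


@pytest.fixture(scope="session")
def default_performance(default_bundle, default_results):
    _, _, truth = default_bundle
    return compare_to_truth(default_results["class_calls"], truth)


@pytest.fixture(scope="session")
def null_bundle():
    """Same conditions with nothing planted."""
    cfg = SimulationConfig(
        seed=1,
        f_hyper_prc2=0.0,
        f_up_prc2=0.0,
        f_up_prc2neg=0.0,
        f_plastic=0.0,
        f_restricted=0.0,
    )
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def null_results(null_bundle):
    annotation, cohorts, _ = null_bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze(annotation, cohorts)


@pytest.fixture(scope="session")
def small_bundle():
    """A light cohort for unit tests that only need realistic shapes."""
    cfg = SimulationConfig(seed=11, n_genes=300, n_tumor=20, n_normal=8)
    return simulate_all(cfg)
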