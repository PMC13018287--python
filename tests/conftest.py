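"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import epistab as es


@pytest.fixture(scope="session")
def healthy_cohort():
    """Young-healthy cohort: 2000 probes (10% planted stable), 200 samples."""
    cfg = es.SimulationConfig(n_probes=2000, n_samples=200)
    return es.simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def esl_table(healthy_cohort):
    matrix, _, _ = healthy_cohort
    return es.discover_esls(matrix, fraction=0.10)


@pytest.fixture(scope="session")
def unmeth_probes(esl_table):
    return esl_table.index[esl_table["esl_class"] == "unmethylated"]


@pytest.fixture(scope="session")
def threshold(unmeth_probes):
    """Destabilization threshold calibrated from three control cohorts."""
    cfg = es.SimulationConfig(n_probes=2000, n_samples=100)
    controls = [
        es.simulate_cohort(cfg, seed=s)[0].select_probes(unmeth_probes)
        for s in (21, 22, 23)
    ]
    return es.calibrate_threshold(controls, percentile=99.9)


@pytest.fixture(scope="session")
def cancer_cohort(unmeth_probes):
    """Coupled-perturbation malignant cohort over the same probe layout."""
    cfg = es.SimulationConfig.cancer_cohort(
        n_probes=2000, n_samples=150, coupled_perturbation=True
    )
    return es.simulate_cohort(cfg, seed=31)


@pytest.fixture
def tiny_matrix():
    return es.BetaMatrix(
        pd.DataFrame(
            [[0.01, 0.02], [0.97, 0.96], [0.50, 0.51]],
            index=["cgA", "cgB", "cgC"],
            columns=["s1", "s2"],
        )
    )
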