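"""Shared fixtures: one default-scale cohort analyzed once per session.

The default cohort is the package's reference study design (2,000 genes, 53
paired samples over 8 datasets, 200 cells per sample, 5% of genes carrying a
planted 3' poly(T) capture defect); the exchangeable cohort switches the
defect and all batch/sample effects off, making the sample pairing
uninformative by construction.
"""

import numpy as np
import pytest

import dropgate as dg


@pytest.fixture(scope="session")
def default_cohort():
    return dg.simulate_cohort(dg.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    return dg.run_analysis(default_cohort, dg.AnalysisParams(seed=1), with_null=True)


@pytest.fixture(scope="session")
def motif_result(default_cohort, default_result):
    return dg.run_motif_stage(
        default_result, default_cohort.sequences, dg.AnalysisParams(seed=1)
    )


@pytest.fixture(scope="session")
def exchangeable_result():
    cfg = dg.CohortConfig(
        capture_beta=0.0, dataset_scale_sigma=0.0, sample_effect_sigma=0.0, seed=3
    )
    data = dg.simulate_cohort(cfg)
    return dg.run_analysis(data, dg.AnalysisParams(seed=3), with_null=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
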