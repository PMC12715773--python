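import numpy as np
import pytest

from strqc.failure import build_inspection_manifest
from strqc.qc import qc_table
from strqc.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_inspection_labels,
    qc_panel,
)


@pytest.fixture(scope="session")
def qc_cohort():
    """A read-level cohort with planted genotyping failures, shared across tests."""
    cfg = SimulationConfig(
        n_cases=600, n_controls=300, loci=qc_panel(n_loci=6, failure_freq=0.05), seed=11
    )
    return generate_cohort(cfg, with_reads=True)


@pytest.fixture(scope="session")
def qc_frame(qc_cohort):
    return qc_table(qc_cohort.genotypes, qc_cohort.sample_info)


@pytest.fixture(scope="session")
def inspection(qc_cohort, qc_frame):
    manifest = build_inspection_manifest(qc_frame, seed=7)
    labels = generate_inspection_labels(qc_cohort, manifest)
    return manifest, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
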