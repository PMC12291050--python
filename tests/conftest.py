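import numpy as np
import pytest

from imconform.conformer_curation import CurationConfig, curate
from imconform.evidence_io import Observation, PeptideIon, RunTable
from imconform.run_alignment import align_all
from imconform.synthetic_data import GeneratorConfig, generate_cohort


def make_obs(pform, charge, run_id, ccs, intensity=1000.0, **kw):
    return Observation(
        ion=PeptideIon(pform, charge), run_id=run_id, ccs=ccs,
        intensity=intensity, **kw,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Modest synthetic cohort with planted truth, reused across tests."""
    cfg = GeneratorConfig(
        seed=11, n_peptides=400, n_runs=8, multiconf_base_rate=0.08,
        dropout=0.15,
    )
    runs, truth = generate_cohort(cfg)
    return cfg, runs, truth


@pytest.fixture(scope="session")
def curated_small(small_cohort):
    _, runs, truth = small_cohort
    aligned = align_all(runs, min_overlap=50)
    result = curate(aligned, CurationConfig())
    return result, truth


@pytest.fixture(scope="session")
def model_cohort():
    """Larger cohort with more multiconformers for model tests."""
    cfg = GeneratorConfig(
        seed=21, n_peptides=1500, n_runs=8, multiconf_base_rate=0.3,
    )
    runs, truth = generate_cohort(cfg)
    aligned = align_all(runs, min_overlap=50)
    result = curate(aligned, CurationConfig())
    return result, truth
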