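from __future__ import annotations

import pytest

from snppanel import SimConfig, run_pipeline
from snppanel.simgenome import simulate_reference, spike_variants


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A quick two-scaffold cross used by most unit tests."""
    return SimConfig(
        seed=11,
        n_scaffolds=2,
        scaffold_length=10_000,
        snp_density=2e-3,
        indel_density=3e-4,
        repeat_segments=((150, 2),),
        homopolymer_runs=(("T", 7),),
        mean_depth=20.0,
        error_rate=0.01,
    )


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    return simulate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_reference):
    return spike_variants(small_reference, small_cfg)


@pytest.fixture(scope="session")
def small_result(small_cfg):
    return run_pipeline(small_cfg)


@pytest.fixture(scope="session")
def study_cfg() -> SimConfig:
    """The reference study condition: 8 x 50 kb scaffolds, depth 20, eps 1%."""
    return SimConfig(seed=202, n_scaffolds=8, scaffold_length=50_000,
                     mean_depth=20.0, error_rate=0.01)


@pytest.fixture(scope="session")
def study_result(study_cfg):
    return run_pipeline(study_cfg)
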