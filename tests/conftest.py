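"""Shared fixtures: a small synthetic patient and one cached pipeline run."""

from __future__ import annotations

import pytest

from tumorevo import PipelineConfig, run_pipeline
from tumorevo.simulate import SimConfig, simulate_patient

# Two tumors with two regions each: the smallest config the simulator
# accepts, used wherever a full end-to-end run would be overkill.
SMALL_OVERRIDES = dict(
    n_tumors=2,
    regions_per_tumor=2,
    topologies=("linear", "branched"),
    ploidy_per_tumor=(2.0, 2.0),
    breakpoint_3p=(1_200_001, 2_400_001),
)
SMALL_SEED = 3


@pytest.fixture(scope="session")
def small_truth():
    return simulate_patient(SimConfig(seed=SMALL_SEED, **SMALL_OVERRIDES))


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """One cached end-to-end run on the two-tumor config."""
    out = tmp_path_factory.mktemp("pipeline_small")
    config = PipelineConfig(out_dir=out, seed=SMALL_SEED,
                            sim_overrides=dict(SMALL_OVERRIDES),
                            make_plots=False)
    report = run_pipeline(config)
    return config, report
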