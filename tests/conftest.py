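"""Shared fixtures: a small noise-free simulated treatment course
exported to disk, reused by the en face, longitudinal and acceptance
tests."""

from __future__ import annotations

import numpy as np
import pytest

from octanv.synthetic import SimulatedCase, SynthParams, export_case, simulate_case

#: Regression schedule 1.0 -> 0.2 across an initial block of monthly
#: injections (weeks 0/4/8), with posttreatment at week 13 and a late
#: follow-up at week 17.
REGRESSION_SCHEDULE = {0: 1.0, 4: 0.7, 8: 0.45, 13: 0.3, 17: 0.2}


@pytest.fixture(scope="session")
def regression_params() -> SynthParams:
    return SynthParams(
        nx=192, ny=192, nz=96, ilm_z=24, depth=5, noise_level=0.0,
        perfusion_schedule=dict(REGRESSION_SCHEDULE), seed=1,
    )


@pytest.fixture(scope="session")
def regression_case(regression_params) -> SimulatedCase:
    return simulate_case(regression_params)


@pytest.fixture(scope="session")
def exported_case(regression_case, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("case")
    export_case(regression_case, outdir)
    return outdir


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
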