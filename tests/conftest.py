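"""Shared fixtures: deterministic toy patients and a small synthetic cohort."""

import numpy as np
import pytest

from seegsp.core import FrameworkConfig, PatientData
from seegsp.synthetic import CohortConfig, generate_cohort

from helpers import build_patient


@pytest.fixture()
def cfg() -> FrameworkConfig:
    return FrameworkConfig(rng_seed=7)


@pytest.fixture()
def power_law_patient() -> PatientData:
    """Noiseless power law: rates fall exactly as d^-2 from channel 'ref'.

    'ref' is the SOZ maximum; every other channel's rate is determined by
    its distance to it, so the log-log system is exactly linear.
    """
    coords = {
        "ref": (0.0, 0.0, 0.0),
        "a": (1.0, 0.0, 0.0),
        "b": (0.0, 2.0, 0.0),
        "c": (0.0, 0.0, 4.0),
        "d": (8.0, 0.0, 0.0),
        "e": (0.0, 16.0, 0.0),
    }
    rates = {"ref": 50.0}
    for cid, xyz in coords.items():
        if cid != "ref":
            d = float(np.linalg.norm(np.asarray(xyz)))
            rates[cid] = 40.0 * d ** -2.0
    return build_patient(coords, rates, soz={"ref"})


@pytest.fixture(scope="session")
def small_cohort():
    """6 well-sampled + 6 poorly sampled synthetic patients, fixed seed."""
    return generate_cohort(6, 6, CohortConfig(), np.random.default_rng(11))
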