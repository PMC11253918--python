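"""Shared fixtures: canonical peptides, models, and simulated datasets.

Heavy simulated datasets and fits are session-scoped so that the
acceptance-style tests can share them instead of refitting.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from fluorfit import (
    ChannelModel,
    ErrorModel,
    fit_baum_welch,
    parse_peptide,
    simulate_reads,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

#: the six true rates used throughout simulation-recovery tests, all inside
#: [0.01, 0.2] and near the magnitudes reported for real sequencing runs
TRUE_RATES = {
    "edman_failure": 0.06,
    "dye_loss": 0.05,
    "detach": 0.02,
    "dud": 0.10,
    "initial_block": 0.08,
    "cyclic_block": 0.03,
}


def rates_vector(m: ErrorModel) -> np.ndarray:
    """Single-channel parameter vector in canonical order."""
    return np.array(
        [
            m.edman_failure,
            float(m.dye_loss[0]),
            m.detach,
            float(m.dud[0]),
            m.initial_block,
            m.cyclic_block,
        ]
    )


@pytest.fixture(scope="session")
def two_label():
    return parse_peptide("NH2-G{azK}*AG{azK}*|")


@pytest.fixture(scope="session")
def one_label():
    return parse_peptide("fmoc-APK*|")


@pytest.fixture(scope="session")
def truth():
    return ErrorModel(
        edman_failure=TRUE_RATES["edman_failure"],
        dye_loss=[TRUE_RATES["dye_loss"]],
        detach=TRUE_RATES["detach"],
        dud=[TRUE_RATES["dud"]],
        initial_block=TRUE_RATES["initial_block"],
        cyclic_block=TRUE_RATES["cyclic_block"],
    )


@pytest.fixture(scope="session")
def channels():
    # one-fluorophore peak at 6000 AU with sd 900 (mu/sigma ~ 6.7) and equal
    # background sd, matching well-separated single-dye intensity histograms
    return ChannelModel(mu=[6000.0], sigma=[900.0], bg_sigma=[900.0])


@pytest.fixture(scope="session")
def reads_10k(two_label, truth, channels):
    rng = np.random.default_rng(0)
    return simulate_reads(two_label, truth, channels, 10_000, 10, rng)


@pytest.fixture(scope="session")
def bw_fit_10k(reads_10k, two_label, channels):
    return fit_baum_welch(reads_10k, two_label, channels)
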