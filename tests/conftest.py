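"""Session-scoped study fixtures.

The end-to-end studies (K3/K5 pulse-motif recovery, dose-response motif
isolation, grouped module selection) are expensive relative to unit tests,
so each is run once per session and shared between the scientific tests
and the acceptance checks.  All seeds are fixed.
"""

import numpy as np
import pytest

from ptlasso import studies


@pytest.fixture(scope="session")
def k3_data():
    return studies.k3_dataset(data_seed=1)


@pytest.fixture(scope="session")
def k3_runs(k3_data):
    """Two independently seeded PTLasso fits of the same K3 dataset."""
    return (
        studies.run_k3(seed=101, dataset=k3_data),
        studies.run_k3(seed=202, dataset=k3_data),
    )


@pytest.fixture(scope="session")
def k3_pt_run(k3_data):
    """Unregularized (uniform-prior) PT fit of the same dataset."""
    return studies.run_k3(seed=303, dataset=k3_data, mode="pt")


@pytest.fixture(scope="session")
def k3_param_noise_run():
    """PTLasso fit of data generated with noise on parameters (log-sd 0.05)."""
    return studies.run_k3(seed=404, dataset=studies.k3_param_noise_dataset(data_seed=1),
                          n_swaps=1500, burn_in=250)


@pytest.fixture(scope="session")
def k5_combined():
    """Three gated-and-combined K5 PTLasso runs plus the per-run results."""
    combined, report, results = studies.run_k5_combined(seed=500, m=3)
    return combined, report, results


@pytest.fixture(scope="session")
def dose_linear_run():
    return studies.run_dose_linear(seed=31)


@pytest.fixture(scope="session")
def dose_adapting_run():
    return studies.run_dose_adapting(seed=41)


@pytest.fixture(scope="session")
def toy_pulse_run():
    return studies.run_toy_grouped(seed=51, protocol="pulse")


@pytest.fixture(scope="session")
def toy_continuous_run():
    return studies.run_toy_grouped(seed=51, protocol="continuous")
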