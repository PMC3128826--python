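import math

import numpy as np
import pytest
from hypothesis import settings

from opioidpk import Patient, load_opioid_table

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table():
    return load_opioid_table()


@pytest.fixture(scope="session")
def morphine(table):
    return table.lookup("morphine")


@pytest.fixture(scope="session")
def oxycodone_ir(table):
    return table.lookup("oxycodone IR")


@pytest.fixture(scope="session")
def male():
    return Patient(sex="male")


@pytest.fixture(scope="session")
def female():
    return Patient(sex="female")


def superposition_peak_trough(c0, k_e, tau, n_doses=None):
    """Brute-force steady-state peak/trough: sum of shifted single-dose
    exponentials, independent of the closed-form accumulation ratio.

    ``c0`` is the single-dose concentration jump F·Dose/V_d.  ``n_doses`` is
    chosen so the geometric tail is negligible (< 1e-6 relative).
    """
    if n_doses is None:
        n_doses = max(60, int(math.ceil(14.0 / (k_e * tau))))
    ages = tau * np.arange(n_doses)  # time since each past dose, at a peak
    peak = c0 * np.exp(-k_e * ages).sum()
    trough = peak * math.exp(-k_e * tau)
    return peak, trough


def superposition_time_average(c0, k_e, tau, n_doses=None, n_grid=20001):
    """Numeric time-average of one steady-state interval of the brute-force
    superposition profile."""
    peak, _ = superposition_peak_trough(c0, k_e, tau, n_doses)
    t = np.linspace(0.0, tau, n_grid)
    return float(np.trapezoid(peak * np.exp(-k_e * t), t) / tau)
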