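import warnings

import pytest

import tkicea as tk


@pytest.fixture(scope="session")
def spec():
    """The built-in calibrated base-case scenario."""
    return tk.base_case_scenario()


@pytest.fixture(scope="session")
def base_results(spec):
    """Per-arm discounted totals for the base case (both arms)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for arm in spec.arm_names:
            trace = tk.run_cohort(spec, arm)
            out[arm] = tk.accumulate_arm(trace, spec, arm)
    return out


@pytest.fixture(scope="session")
def exp_fixture():
    """The seeded exponential digitized-figure fixture used in round-trips."""
    import numpy as np

    ipd = tk.simulate_ipd("exponential", (0.2,), n=200, censor_rate=0.05, seed=0)
    curve = tk.make_digitized_fixture(
        ipd, n_points=25, risk_times=np.arange(0.0, ipd.time.max(), 1.0)
    )
    return ipd, curve
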