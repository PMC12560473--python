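import math

import numpy as np
import pytest

from sdc_glioma import (
    DWISeries,
    TissueParams,
    default_cohort_spec,
    default_phantom_spec,
    simulate_cohort,
    simulate_phantom,
)


def mono_exp_series(s0=1000.0, d=1.0e-3,
                    b_values=(0.0, 10.0, 500.0, 750.0, 1000.0),
                    shape=(4, 4, 2)) -> DWISeries:
    """Uniform mono-exponential decay series: S(b) = s0 * exp(-b * d)."""
    b = np.asarray(b_values, dtype=float)
    sig = s0 * np.exp(-b * d)
    data = np.broadcast_to(sig, shape + (b.size,)).copy()
    return DWISeries(b_values=b, data=data)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default three-region phantom without noise, plus its region labels."""
    spec = default_phantom_spec(snr=math.inf, seed=0)
    series, labels = simulate_phantom(spec)
    return spec, series, labels


@pytest.fixture(scope="session")
def default_cohort():
    """One calibrated 63-subject synthetic cohort (33 wildtype, 30 mutant)."""
    return simulate_cohort(default_cohort_spec(seed=20240901))


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)


def make_tissue(**kw) -> TissueParams:
    base = dict(s0=1000.0, f=0.1, d_star=50e-3, d_t=1.0e-3, snr=math.inf)
    base.update(kw)
    return TissueParams(**base)
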