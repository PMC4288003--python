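import numpy as np
import pytest

from oatp_pbpk import (
    NoiseModel,
    default_human_physiology,
    generate_dataset,
    make_fixture,
)
from oatp_pbpk.fitting import FITTABLE, FitProblem

#: Clinical-style sampling schedule (hours post dose).
SAMPLING_TIMES = np.array(
    [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0])


@pytest.fixture(scope="session")
def physiology():
    return default_human_physiology()


@pytest.fixture(scope="session")
def pravastatin():
    return make_fixture("pravastatin_like")


@pytest.fixture(scope="session")
def rosuvastatin():
    return make_fixture("rosuvastatin_like")


@pytest.fixture(scope="session")
def fluvastatin():
    return make_fixture("fluvastatin_like")


@pytest.fixture(scope="session")
def sampling_times():
    return SAMPLING_TIMES


def recovery_problem(physiology, compound, regimens, cv=0.0, seed=0,
                     maxiter=60, bound_span=10.0):
    """IV + oral synthetic datasets from known parameters, with bounds
    spanning `bound_span`-fold around the truth."""
    noise_iv = NoiseModel(cv=cv, seed=seed)
    noise_po = NoiseModel(cv=cv, seed=seed + 1000)
    ds_iv = generate_dataset(compound, physiology, regimens["iv"],
                             SAMPLING_TIMES, noise_iv)
    ds_po = generate_dataset(compound, physiology, regimens["oral"],
                             SAMPLING_TIMES, noise_po)
    bounds = {}
    for p in FITTABLE:
        v = getattr(compound, p)
        hi = v * bound_span
        if p == "FaFg":
            hi = min(hi, 1.0)
        bounds[p] = (v / bound_span, hi)
    return FitProblem(
        datasets=[ds_iv, ds_po], compound=compound, physiology=physiology,
        bounds=bounds, maxiter=maxiter, seed=seed,
    )


@pytest.fixture(scope="session")
def noise_free_fit(physiology, pravastatin):
    """One noise-free recovery fit, shared by recovery + bootstrap tests."""
    compound, _, regimens = pravastatin
    problem = recovery_problem(physiology, compound, regimens, cv=0.0,
                               seed=1)
    return problem, problem.fit(), compound
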