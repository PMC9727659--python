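"""Shared fixtures: seeded synthetic datasets and cached fits.

Expensive objects (MLE fits, profiles) are session-scoped; every dataset is
generated programmatically from a recorded seed, so the suite needs no data
files.
"""

import numpy as np
import pytest

import biphasefit as bf
from biphasefit.models import GrowthModel


@pytest.fixture(scope="session")
def coral_spec():
    return bf.case_study_fixture("coral")


@pytest.fixture(scope="session")
def coral_model(coral_spec):
    return bf.get_model(coral_spec.model_kind)


@pytest.fixture(scope="session")
def coral_data(coral_spec):
    return bf.dataset_from_fixture(coral_spec)


@pytest.fixture(scope="session")
def coral_fit(coral_model, coral_data, coral_spec):
    fit = bf.fit_mle(
        coral_model,
        coral_data,
        start=coral_spec.full_params,
        bounds=coral_spec.bounds,
        solver="closed_form",
    )
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def coral_profiles(coral_model, coral_data, coral_fit, coral_spec):
    """Profiles of every coral parameter at a reduced mesh (kept cheap)."""
    return {
        name: bf.profile_parameter(
            coral_model,
            coral_data,
            coral_fit,
            name,
            bounds=coral_spec.bounds,
            points_per_side=20,
            solver="closed_form",
            concentrate_sigma=True,
        )
        for name in ("T", "C0", "r", "K", "sigma")
    }


def _zero(C, p):
    return 0.0


@pytest.fixture(scope="session")
def constant_model():
    """Flat model C(t) = C0: the Gaussian-mean oracle case."""
    return GrowthModel(
        name="constant",
        phase1_rate=_zero,
        phase2_rate=_zero,
        param_names=("C0",),
        default_bounds={"C0": (-1e6, 1e6)},
        closed_form=lambda p, t: np.full(np.asarray(t, float).shape, float(p["C0"])),
    )


@pytest.fixture(scope="session")
def gaussian_data():
    """Ten draws from N(10, 1.5^2) at arbitrary times."""
    rng = np.random.default_rng(42)
    t = np.arange(10.0)
    y = 10.0 + 1.5 * rng.standard_normal(10)
    return bf.Dataset(times=t, observations=y)
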