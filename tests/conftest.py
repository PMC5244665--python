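"""Shared fixtures: schemes, caches, and synthetic voxels."""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("repeatable", derandomize=True)
hyp_settings.load_profile("repeatable")

from mcdmri import compartments as cpt
from mcdmri import fitting as fit
from mcdmri import protocol as proto
from mcdmri import synthgen


@pytest.fixture(scope="session")
def study_scheme():
    return proto.build_study_protocol()


@pytest.fixture(scope="session")
def full_scheme():
    """Study DWI protocol + the two 42-direction DTI shells (226 rows)."""
    return proto.build_full_protocol()


@pytest.fixture(scope="session")
def full_cache(full_scheme):
    return cpt.PrecomputedScheme(full_scheme)


@pytest.fixture(scope="session")
def zs_truth():
    """Ground-truth Zeppelin-Sphere parameters for recovery tests."""
    return cpt.ParamVector(
        D1=0.95, D2=0.6, theta=1.0, phi=0.7,
        D_I=1.0, R=7.5, f_I=0.44, S0=1.0, T2=0.07,
    )


@pytest.fixture(scope="session")
def zs_clean_signal(full_cache, zs_truth):
    spec = cpt.get_model("Zeppelin-Sphere")
    return cpt.predict_scheme(spec, zs_truth.to_array(spec), full_cache)


def make_noisy(signal, snr, seed, n_avg=None):
    rng = np.random.default_rng(seed)
    return synthgen.add_rician_noise(signal, 1.0 / snr, rng, n_avg=n_avg)


@pytest.fixture(scope="session")
def random_measurements():
    """100 random PGSE measurements spanning the protocol's ranges."""
    rng = np.random.default_rng(42)
    out = []
    for _ in range(100):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        delta = rng.uniform(2.0, 10.0)
        Delta = delta + rng.uniform(2.0, 70.0)
        out.append(
            proto.Measurement(
                tuple(d),
                float(rng.uniform(0.0, 400.0)),
                delta,
                Delta,
                Delta + rng.uniform(2.0, 15.0),
            )
        )
    return out


@pytest.fixture(scope="session")
def small_phantom():
    return synthgen.make_phantom(shape=(24, 24, 2), seed=0)
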