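"""Shared fixtures: random-parameter factories and small synthetic boards."""

import numpy as np
import pytest

from combosurf import HillParams, SurfaceParams, half_log_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_hill(rng, e_zero=(0.95, 1.05), e_inf=(0.0, 0.4),
                log10_ec50=(1.0, 3.0), hill=(0.5, 4.0)) -> HillParams:
    """One random inhibitory Hill curve inside the default fit box."""
    return HillParams(
        e_zero=rng.uniform(*e_zero),
        e_inf=rng.uniform(*e_inf),
        ec50=10.0 ** rng.uniform(*log10_ec50),
        hill=rng.uniform(*hill),
    )


def random_surface(rng, alpha=(0.5, 4.0), e_inf=(0.05, 0.3),
                   log10_ec50=(1.7, 2.6), hill=(0.7, 2.5),
                   u_inf_ab=(0.3, 0.9)) -> SurfaceParams:
    """One random interaction surface; alpha may be pinned by passing a tuple
    with equal endpoints."""
    einf_a = rng.uniform(*e_inf)
    einf_b = rng.uniform(*e_inf)
    return SurfaceParams(
        e_zero=1.0,
        e_inf_a=einf_a,
        ec50_a=10.0 ** rng.uniform(*log10_ec50),
        hill_a=rng.uniform(*hill),
        e_inf_b=einf_b,
        ec50_b=10.0 ** rng.uniform(*log10_ec50),
        hill_b=rng.uniform(*hill),
        alpha=rng.uniform(*alpha),
        e_inf_ab=rng.uniform(*u_inf_ab) * min(einf_a, einf_b),
    )


def deep_grids(params: SurfaceParams, n=8, depth=100.0):
    """Half-log dose grids reaching ``depth`` times each ec50."""
    return (half_log_grid(depth * params.ec50_a, n),
            half_log_grid(depth * params.ec50_b, n))


@pytest.fixture
def hill_factory():
    return random_hill


@pytest.fixture
def surface_factory():
    return random_surface


@pytest.fixture
def grids_factory():
    return deep_grids
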