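"""Shared fixtures: small, fast synthetic embryos and deterministic settings."""

import numpy as np
import pytest

from gastrumorph import synthgen

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


#: compact embryo used where full-size cohorts would be wasteful
SMALL_KWARGS = dict(
    embryo_half_axes=(70.0, 40.0, 36.0),
    n_rows_ap=13,
    nucleus_diameter=8.0,
    furrow_halfwidth=14.0,
)


def small_params(mode: str, seed: int = 0, **overrides) -> synthgen.GenParams:
    kwargs = dict(SMALL_KWARGS)
    kwargs.update(overrides)
    return synthgen.GenParams.for_mode(mode, seed=seed, **kwargs)


@pytest.fixture
def small_invagination():
    return synthgen.generate_embryo(small_params("invagination", seed=3))


@pytest.fixture
def small_ingression():
    return synthgen.generate_embryo(small_params("ingression", seed=3))


@pytest.fixture
def small_flat():
    return synthgen.generate_embryo(small_params("flat", seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
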