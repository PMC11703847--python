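"""Shared fixtures: seeded generators, micro networks, noise-free specs."""

from dataclasses import replace

import numpy as np
import pytest

import fearsim as fs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def full_spec():
    return fs.default_network_spec("full")


@pytest.fixture(scope="session")
def quarter_spec():
    return fs.default_network_spec("quarter")


def noise_free(spec):
    """Copy of a network spec with all membrane noise removed."""
    defaults = replace(spec.defaults, noise_sd=0.0)
    regions = tuple(
        replace(
            r,
            neuron_params=(
                replace(r.neuron_params, noise_sd=0.0) if r.neuron_params else None
            ),
        )
        for r in spec.regions
    )
    return replace(spec, defaults=defaults, regions=regions)


@pytest.fixture
def quarter_noise_free(quarter_spec):
    return noise_free(quarter_spec)
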