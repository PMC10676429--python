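import numpy as np
import pytest

from fishmorph import (FaunaSpec, default_fauna_spec, default_modes,
                       default_scheme, default_template, generate)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def template(scheme):
    return default_template(scheme)


@pytest.fixture(scope="session")
def modes(scheme, template):
    return default_modes(scheme, template)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def single_group_spec(modes, template, scheme, *, mode_sd, n_species,
                      noise=0.0, nuisance=True, seed=0, specimens=1):
    """A one-group fauna recipe used across recovery tests."""
    mode_sd = np.atleast_1d(np.asarray(mode_sd, dtype=float))
    return FaunaSpec(
        template=template,
        modes=list(modes[: len(mode_sd)]),
        mode_sd=mode_sd,
        group_offsets={"synthetic": np.zeros(len(mode_sd))},
        n_species={"synthetic": n_species},
        specimens_per_species=specimens,
        landmark_noise_sd=noise,
        nuisance=nuisance,
        seed=seed,
        scheme=scheme,
    )


@pytest.fixture(scope="session")
def small_fauna(scheme):
    """A down-scaled default fauna (4 groups, ~20 species) with ground truth."""
    spec = default_fauna_spec(seed=42)
    spec.n_species = {g: max(2, n // 10) for g, n in spec.n_species.items()}
    return generate(spec)
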