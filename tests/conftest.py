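import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import citescan as cs
from citescan.simulate import (build_toy_refdb, em11_fractions,
                               mixture_from_refdb, simulate_mixture)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

logging.getLogger("citescan").setLevel(logging.WARNING)


@pytest.fixture
def params():
    return cs.PipelineParams()


@pytest.fixture(scope="session")
def refdb():
    return build_toy_refdb(1)


@pytest.fixture(scope="session")
def refdb_paths(refdb, tmp_path_factory):
    return refdb.write(tmp_path_factory.mktemp("refdb"))


@pytest.fixture(scope="session")
def panel():
    return cs.load_marker_panel()


@pytest.fixture(scope="session")
def em11_small(refdb, tmp_path_factory):
    """A modest 10-component mixture exercising every stage."""
    spec = mixture_from_refdb(refdb, em11_fractions(), 2000, 1)
    paths = simulate_mixture(spec, tmp_path_factory.mktemp("em11_small"))
    return spec, paths


@pytest.fixture(scope="session")
def em11_result(em11_small, refdb_paths, tmp_path_factory):
    _spec, paths = em11_small
    out = tmp_path_factory.mktemp("em11_out")
    return cs.run_pipeline(paths["r1"], paths["r2"], refdb_paths["fasta"],
                           refdb_paths["acc2taxid"], refdb_paths["taxonomy"],
                           refdb_paths["cites"], out)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
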