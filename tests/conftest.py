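import numpy as np
import pytest
from hypothesis import settings

import holespec as hs

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def nd1_sequence():
    return hs.load_nd1()


@pytest.fixture(scope="session")
def nd1_spectrum(nd1_sequence):
    """Full default-parameter hole spectrum of the ND1 ladder (one
    1912x1912 eigensolve, shared across the session)."""
    es = hs.diagonalize(hs.build_hamiltonian(hs.build_duplex(nd1_sequence)))
    return es, hs.hole_spectrum(es)


@pytest.fixture(scope="session")
def nd1_tracks(nd1_spectrum):
    _, spec = nd1_spectrum
    return {
        "both": hs.normalize_track(spec, "both_strands"),
        "L": hs.normalize_track(spec, "L_only"),
        "H": hs.normalize_track(spec, "H_only"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_duplex_sequence(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
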