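import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tendonfit as tf
from tendonfit.data import load_fixtures

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def index_chain():
    return tf.build_finger_chain(finger=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150408)


def random_pair_path(rng, chain, joint="MCP", muscle="FDS"):
    """A random two-point path straddling one joint, attachment-scale coords."""
    from tendonfit.musclepath import AttachmentPoint, CrossingPair, MusclePath

    seg_pairs = {"MCP": ("metacarpal", "proximal"), "PIP": ("proximal", "middle"),
                 "DIP": ("middle", "distal")}
    sp, sd = seg_pairs[joint]
    prox = rng.uniform([-10.0, -30.0, -12.0], [10.0, -5.0, 12.0])
    dist = rng.uniform([-10.0, -25.0, -12.0], [10.0, -4.0, 12.0])
    return MusclePath(
        muscle,
        chain.finger,
        (CrossingPair(joint, AttachmentPoint(sp, tuple(prox)), AttachmentPoint(sd, tuple(dist))),),
    )
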