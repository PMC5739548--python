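import zlib

import numpy as np
import pytest

#: one fixed root seed for the whole suite; individual tests derive
#: independent streams from it so no test depends on execution order
GLOBAL_SEED = 20260930


def rng_for(name: str) -> np.random.Generator:
    """A reproducible RNG derived from the global seed and a label."""
    return np.random.default_rng(
        np.random.SeedSequence([GLOBAL_SEED, zlib.crc32(name.encode())])
    )


@pytest.fixture
def rng(request):
    """A per-test RNG seeded from the global seed and the test's name."""
    return rng_for(request.node.name)
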