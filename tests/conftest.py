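import numpy as np
import pytest


class ScriptedRNG:
    """Duck-typed stand-in for numpy Generator with scripted draws.

    ``random()`` pops from ``uniforms``; ``integers(...)`` pops from
    ``ints`` (each entry a scalar or array matching the requested size).
    Lets tests force the r / guide / prey draws of a lifecycle phase.
    """

    def __init__(self, uniforms=(), ints=()):
        self._uniforms = list(uniforms)
        self._ints = list(ints)

    def random(self, size=None):
        value = self._uniforms.pop(0)
        return value if size is None else np.full(size, value)

    def integers(self, low, high=None, size=None):
        value = np.asarray(self._ints.pop(0))
        if size is not None:
            value = np.broadcast_to(value, (size,) if np.isscalar(size) else size).copy()
        return value if value.ndim else int(value)


@pytest.fixture
def scripted_rng():
    return ScriptedRNG


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
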