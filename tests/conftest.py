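import numpy as np
import pytest

from polysim import lattice_sim as ls


@pytest.fixture
def build_state():
    """Factory for lattice states with explicit strand lengths and sites."""

    def _build(side: int, lengths, sites, seed: int = 0) -> ls.PolymerState:
        lengths = np.asarray(lengths, dtype=np.int64)
        sites = np.asarray(sites, dtype=np.int64)
        assert lengths.shape == sites.shape
        cfg = ls.LatticeConfig(side)
        state = ls.init_random(cfg, int(lengths.sum()), seed)
        n = lengths.size
        state._lengths[:n] = lengths
        state._sites[:n] = sites
        state.n_strands = n
        return state

    return _build
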