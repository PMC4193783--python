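import numpy as np
import pytest

from pottsort.lattice_core import (CellTable, GridSpec, Lattice, PottsParams,
                                   PottsSystem, init_cells)


def random_system(seed: int, height: int = 12, width: int = 12,
                  n_cells: int = 6, n_t: int = 4, j: float = 1.0,
                  mu0: float = 0.7, lam: float = 0.2,
                  a_target: float = 20.0) -> PottsSystem:
    """Small system with random (possibly fragmented) cell domains and a
    linear concentration field — a worst-case fixture for energy oracles."""
    rng = np.random.default_rng(seed)
    labels = np.zeros((height, width), dtype=np.int32)
    # every cell owns at least one interior site; the rest are random
    interior = labels[1:-1, 1:-1]
    flat = rng.integers(1, n_cells + 1, size=interior.size).astype(np.int32)
    flat[rng.choice(interior.size, size=n_cells, replace=False)] = \
        np.arange(1, n_cells + 1)
    interior[...] = flat.reshape(interior.shape)
    lattice = Lattice(labels, n_cells)
    types = rng.integers(1, n_t + 1, size=n_cells).astype(np.int32)
    cells = CellTable.from_lattice(lattice, types)
    params = PottsParams.default(j=j, mu0=mu0, lam=lam, a_target=a_target)
    field = np.tile(np.linspace(0.0, 3.0, width), (height, 1))
    return PottsSystem(lattice, cells, params, field)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_system():
    return random_system(seed=7)
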