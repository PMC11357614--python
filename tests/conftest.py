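import numpy as np
import pytest
from hypothesis import settings

from triblock.forcefield import ChainTopology, InteractionParams
from triblock.simulate import SimulationState

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return InteractionParams()


@pytest.fixture
def small_topology():
    return ChainTopology(n_B_per_end=2, n_A=4)


def make_free_state(n: int, box: float, temperature: float, seed: int) -> SimulationState:
    """Ideal-gas state: beads far apart, no bonds — forces are exactly zero."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(n ** (1 / 3)))
    grid = np.stack(
        np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)[:n]
    pos = (grid + 0.5) * (box / side)
    vel = rng.normal(0.0, np.sqrt(temperature), (n, 3))
    return SimulationState(
        positions=pos.astype(float),
        velocities=vel,
        box_edge=box,
        time=0.0,
        chain_index=np.arange(n),
        bead_type=np.zeros(n, dtype=np.uint8),
        bonds=np.zeros((0, 2), dtype=np.int64),
        rng=rng,
    )


def make_random_state(
    n: int, box: float, seed: int, bonded_chains: int = 0, chain_len: int = 0
) -> SimulationState:
    """Random mixed A/B state (optionally with chains) for force oracles.

    Positions are drawn with a minimum separation of 0.85 sigma so energies
    stay finite; bonds connect consecutive beads of the first
    ``bonded_chains * chain_len`` beads at ~1 sigma spacing.
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    count = 0
    bonds = []

    def clear(p, exclude=None):
        if count == 0:
            return True
        d = pos[:count] - p
        d -= box * np.round(d / box)
        dist = np.linalg.norm(d, axis=1)
        if exclude is not None:
            dist[exclude] = np.inf
        return bool(np.min(dist) > 0.85)

    for _ in range(bonded_chains):
        chain_start = count
        ok = False
        while not ok:  # restart the chain if the walk boxes itself in
            count = chain_start
            bonds = [b for b in bonds if b[0] < chain_start]
            ok = True
            for k in range(chain_len):
                for _ in range(200):
                    if k == 0:
                        p = rng.uniform(0, box, 3)
                        if clear(p):
                            break
                    else:
                        step = rng.normal(size=3)
                        p = pos[count - 1] + step / np.linalg.norm(step) * 0.97
                        if clear(p, exclude=count - 1):
                            break
                else:
                    ok = False
                    break
                pos[count] = p
                if k > 0:
                    bonds.append((count - 1, count))
                count += 1
    while count < n:
        p = rng.uniform(0, box, 3)
        if clear(p):
            pos[count] = p
            count += 1
    types = rng.integers(0, 2, size=n).astype(np.uint8)
    return SimulationState(
        positions=pos % box,
        velocities=rng.normal(0, 1, (n, 3)),
        box_edge=box,
        time=0.0,
        chain_index=np.zeros(n, dtype=np.int64),
        bead_type=types,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        rng=rng,
    )
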