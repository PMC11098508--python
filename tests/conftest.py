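import numpy as np
import pytest

from trapopt import (
    DispersalKernel,
    FixtureSpec,
    Landscape,
    Site,
    Trap,
    TrapKernel,
    make_landscape,
)


def random_landscape(
    seed: int,
    n_sites: int | None = None,
    kernel_family: str | None = None,
    extent: float = 5.0,
) -> Landscape:
    """A seeded random planar landscape for property tests."""
    rng = np.random.default_rng(seed)
    n = n_sites if n_sites is not None else int(rng.integers(3, 13))
    sites = [
        Site(i, float(x), float(y))
        for i, (x, y) in enumerate(rng.uniform(0, extent, (n, 2)))
    ]
    fam = kernel_family or rng.choice(
        ["exponential", "zero_inflated_exponential", "long_tailed"]
    )
    kernel = DispersalKernel(
        family=str(fam),
        mean_distance=float(rng.uniform(0.5, 3.0)),
        zero_inflation=float(rng.uniform(0.1, 0.9)),
        shape=float(rng.uniform(1.5, 6.0)),
    )
    return Landscape(sites=sites, kernel=kernel)


def random_traps(seed: int, landscape: Landscape, n_traps: int | None = None):
    """Seeded random trap set (mix of node and coordinate placements)."""
    rng = np.random.default_rng(seed + 10_000)
    k = n_traps if n_traps is not None else int(rng.integers(1, 4))
    traps = []
    for t in range(k):
        kernel = TrapKernel(
            family=str(rng.choice(["exponential", "sigmoidal"])),
            A=float(rng.uniform(0.2, 0.9)),
            radius=float(rng.uniform(0.5, 3.0)),
            shape=float(rng.uniform(0.5, 3.0)),
        )
        if rng.random() < 0.5:
            placement = int(rng.integers(0, landscape.n_sites))
        else:
            placement = tuple(rng.uniform(0, 5.0, 2))
        traps.append(Trap(id=t, placement=placement, kernel=kernel))
    return traps


@pytest.fixture
def hexad_sites():
    return make_landscape(FixtureSpec(layout="hexad"))


@pytest.fixture
def hexad_landscape(hexad_sites):
    kernel = DispersalKernel(
        family="zero_inflated_exponential", zero_inflation=0.75, mean_distance=1.0
    )
    return Landscape(sites=hexad_sites, kernel=kernel)


@pytest.fixture
def single_site_landscape():
    return Landscape(sites=[Site(0, 0.0, 0.0)], kernel=DispersalKernel())
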