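"""Synthetic landscapes and scenario generators.

Everything here is generated programmatically and deterministically from a
seed — no external data. The layouts cover the geometries the framework is
exercised on: regular grids, uniform scatters, clustered settlements with
resource types, and a six-node demonstration metapopulation with alternating
blood-feeding / water (egg-laying) resources.

Two scaled-down scenarios mirror published use-cases:

``suburb_small``
    A household-scale suburb (think *Aedes aegypti* surveillance): 60
    household sites scattered in a 1 km x 1 km box; zero-inflated exponential
    movement with daily staying probability 0.72 and mean dispersal distance
    (conditional on movement) of 54 m; 16 movable traps of two types — eight
    exponential (max attractiveness 0.5, mean radius 15.88 m) and eight
    sigmoidal (max 0.5, inflection radius 16 m, shape 0.25 per metre).

``island_small``
    A village-scale island (think *Anopheles* surveillance): 30 sites in
    elongated clusters; exponential movement kernel; exponential trap kernel
    (max 0.5, mean radius 24 m); two immovable traps pinned at the
    northernmost and southernmost sites, remaining traps movable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .landscape import DispersalKernel, InvalidInputError, Landscape, Site
from .traps import Trap, TrapKernel

__all__ = ["FixtureSpec", "Scenario", "make_landscape", "make_scenario"]

LAYOUTS = ("grid", "uniform_random", "clustered", "two_clusters", "hexad")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic site set."""

    layout: str = "uniform_random"
    n_sites: int = 10
    n_types: int = 1
    extent: tuple[float, float, float, float] = (0.0, 0.0, 10.0, 10.0)
    cluster_count: int = 3
    cluster_spread: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise InvalidInputError(f"unknown layout {self.layout!r}")
        if self.n_sites < 1:
            raise InvalidInputError("n_sites must be >= 1")
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise InvalidInputError("extent must be nondegenerate")


def make_landscape(spec: FixtureSpec) -> list[Site]:
    """Generate the site list for a fixture spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    xmin, ymin, xmax, ymax = spec.extent

    if spec.layout == "hexad":
        # six nodes on a unit-circumradius hexagon, alternating resource
        # types: blood-feeding (0) and water/egg-laying (1)
        ang = np.pi / 2 + np.arange(6) * (np.pi / 3)
        return [
            Site(i, float(np.cos(a)), float(np.sin(a)), i % 2)
            for i, a in enumerate(ang)
        ]

    if spec.layout == "grid":
        side = int(np.ceil(np.sqrt(spec.n_sites)))
        xs = np.linspace(xmin, xmax, side)
        ys = np.linspace(ymin, ymax, side)
        pts = [(x, y) for y in ys for x in xs][: spec.n_sites]
    elif spec.layout == "uniform_random":
        pts = list(
            zip(
                rng.uniform(xmin, xmax, spec.n_sites),
                rng.uniform(ymin, ymax, spec.n_sites),
            )
        )
    elif spec.layout in ("clustered", "two_clusters"):
        k = 2 if spec.layout == "two_clusters" else spec.cluster_count
        centers = np.column_stack(
            [rng.uniform(xmin, xmax, k), rng.uniform(ymin, ymax, k)]
        )
        if spec.layout == "two_clusters":
            # well-separated pair at opposite thirds of the extent
            centers = np.array(
                [
                    [xmin + 0.2 * (xmax - xmin), ymin + 0.2 * (ymax - ymin)],
                    [xmin + 0.8 * (xmax - xmin), ymin + 0.8 * (ymax - ymin)],
                ]
            )
        assign = rng.integers(0, k, spec.n_sites)
        pts = [
            tuple(centers[c] + rng.normal(0.0, spec.cluster_spread, 2))
            for c in assign
        ]
    else:  # pragma: no cover - guarded by FixtureSpec
        raise InvalidInputError(spec.layout)

    types = rng.integers(0, spec.n_types, spec.n_sites)
    return [
        Site(i, float(x), float(y), int(t))
        for i, ((x, y), t) in enumerate(zip(pts, types))
    ]


@dataclass
class Scenario:
    """Bundle of sites, movement kernel and trap definitions for a use-case."""

    name: str
    sites: list[Site]
    kernel: DispersalKernel
    movable_kernels: list[TrapKernel]
    fixed_traps: list[Trap] = field(default_factory=list)
    distance_mode: str = "euclidean"

    def build_landscape(self) -> Landscape:
        return Landscape(
            sites=self.sites, kernel=self.kernel, distance_mode=self.distance_mode
        )


def make_scenario(
    name: str, seed: int = 2024, n_traps: Optional[int] = None
) -> Scenario:
    """Construct a named scenario; ``n_traps`` is the total trap count for
    ``island_small`` (including its two immovable traps; default 5)."""
    if name == "suburb_small":
        spec = FixtureSpec(
            layout="uniform_random",
            n_sites=60,
            extent=(0.0, 0.0, 1000.0, 1000.0),
            seed=seed,
        )
        sites = make_landscape(spec)
        kernel = DispersalKernel(
            family="zero_inflated_exponential",
            zero_inflation=0.72,
            mean_distance=54.0,
        )
        exp_trap = TrapKernel(family="exponential", A=0.5, radius=15.88)
        sig_trap = TrapKernel(family="sigmoidal", A=0.5, radius=16.0, shape=0.25)
        movable = [exp_trap] * 8 + [sig_trap] * 8
        return Scenario(name, sites, kernel, movable)

    if name == "island_small":
        total = 5 if n_traps is None else int(n_traps)
        if total < 3:
            raise InvalidInputError("island_small needs >= 3 traps (2 immovable)")
        spec = FixtureSpec(
            layout="clustered",
            n_sites=30,
            extent=(0.0, 0.0, 3000.0, 5000.0),
            cluster_count=4,
            cluster_spread=250.0,
            seed=seed,
        )
        sites = make_landscape(spec)
        kernel = DispersalKernel(family="exponential", mean_distance=700.0)
        trap_kernel = TrapKernel(family="exponential", A=0.5, radius=24.0)
        ys = np.array([s.y for s in sites])
        north, south = int(np.argmax(ys)), int(np.argmin(ys))
        fixed = [
            Trap(id=0, placement=north, kernel=trap_kernel, immovable=True),
            Trap(id=1, placement=south, kernel=trap_kernel, immovable=True),
        ]
        movable = [trap_kernel] * (total - 2)
        return Scenario(name, sites, kernel, movable, fixed_traps=fixed)

    raise InvalidInputError(f"unknown scenario {name!r}")
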