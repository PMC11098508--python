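"""Traps and the trap-augmented absorbing Markov chain.

Each trap has an attractiveness kernel giving the raw odds weight that a
mosquito at distance ``d`` enters the trap within a day. Traps are appended to
the landscape's movement matrix as absorbing states, producing the block
matrix::

    [[ Q, R ],
     [ 0, I ]]

where ``Q`` (tau', site-to-site) and ``R`` (nu', site-to-trap) are the
renormalized transient blocks and the identity rows encode absorption: a
mosquito that enters a trap never leaves.

Integration rule: the raw attractiveness weights are appended to the unit-sum
movement row and the whole row divided by ``1 + sum(nu_raw)``. A trap of
maximum attractiveness ``A`` co-located with a site therefore captures with
daily probability ``A / (1 + A)`` — the odds of entering versus not entering
are ``A : 1``. Multiple traps share the denominator, so nearby traps compete
for the same mosquitoes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.special

from .landscape import InvalidInputError, Landscape, ParameterError, Site

__all__ = [
    "TrapKernel",
    "Trap",
    "AugmentedChain",
    "trap_attractiveness",
    "resolve_trap_coordinates",
    "augment_with_traps",
    "read_traps_csv",
    "write_traps_csv",
]


@dataclass(frozen=True)
class TrapKernel:
    """Distance-decay attractiveness profile of a trap.

    ``exponential``: ``A * exp(-d / radius)`` with mean radius of
    attractiveness ``radius``. ``sigmoidal``: ``A / (1 + exp(shape * (d -
    radius)))`` with inflection radius ``radius`` and steepness ``shape``;
    note the sigmoid at d = 0 evaluates below ``A`` — "maximum attractiveness"
    is the supremum parameter, not the value at contact. ``custom`` takes any
    vectorized callable of distance returning values in [0, A].

    ``type_multipliers`` optionally scales attractiveness by the resource type
    of the mosquito's current site (e.g. an ovitrap appealing most to gravid
    females leaving blood-feeding sites); defaults to no modulation.
    """

    family: str = "exponential"
    A: float = 0.5
    radius: float = 1.0
    shape: float = 1.0
    func: object = None
    type_multipliers: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "sigmoidal", "custom"):
            raise ParameterError(f"unknown trap kernel family {self.family!r}")
        if not 0.0 <= self.A <= 1.0:
            raise ParameterError("maximum attractiveness A must lie in [0, 1]")
        if self.radius <= 0:
            raise ParameterError("radius must be > 0")
        if self.family == "sigmoidal" and self.shape <= 0:
            raise ParameterError("sigmoidal shape must be > 0")
        if self.family == "custom" and not callable(self.func):
            raise ParameterError("custom trap kernel requires func")
        if self.type_multipliers is not None and any(
            m < 0 for m in self.type_multipliers
        ):
            raise ParameterError("type multipliers must be >= 0")


def trap_attractiveness(d, kernel: TrapKernel) -> np.ndarray:
    """Raw attractiveness (odds weight) at distance(s) ``d`` >= 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise InvalidInputError("distance must be nonnegative")
    if kernel.family == "exponential":
        return kernel.A * np.exp(-d / kernel.radius)
    if kernel.family == "sigmoidal":
        v = kernel.A * scipy.special.expit(-kernel.shape * (d - kernel.radius))
        return np.minimum(v, kernel.A)
    v = np.asarray(kernel.func(d), dtype=float)
    if np.any(v < 0) or np.any(v > kernel.A):
        raise ParameterError("custom trap kernel must map into [0, A]")
    return v


@dataclass(frozen=True)
class Trap:
    """A trap placed either on a node (discrete) or at free coordinates.

    ``placement`` is a node index (int) or an ``(x, y)`` pair. ``immovable``
    traps are excluded from optimization.
    """

    id: int
    placement: Union[int, tuple[float, float]]
    kernel: TrapKernel
    immovable: bool = False

    @property
    def is_discrete(self) -> bool:
        return isinstance(self.placement, (int, np.integer))


def resolve_trap_coordinates(
    traps: Sequence[Trap], sites: Sequence[Site]
) -> np.ndarray:
    """(n_traps, 2) coordinates: node traps inherit the host site's point."""
    coords = np.empty((len(traps), 2), dtype=float)
    for k, trap in enumerate(traps):
        if trap.is_discrete:
            idx = int(trap.placement)
            if not 0 <= idx < len(sites):
                raise InvalidInputError(
                    f"trap {trap.id}: node {idx} out of range [0, {len(sites)})"
                )
            coords[k] = (sites[idx].x, sites[idx].y)
        else:
            x, y = trap.placement  # type: ignore[misc]
            if not (math.isfinite(x) and math.isfinite(y)):
                raise InvalidInputError(f"trap {trap.id}: non-finite coordinates")
            coords[k] = (x, y)
    return coords


@dataclass
class AugmentedChain:
    """Absorbing chain ``[[Q, R], [0, I]]`` over sites then traps.

    ``Q[i, j]``: daily probability of moving site *i* -> site *j* without
    being trapped; ``R[i, k]``: daily probability of falling into trap *k*
    from site *i*. Site rows of ``[Q | R]`` sum to 1.
    """

    Q: np.ndarray
    R: np.ndarray
    traps: list[Trap]

    @property
    def n_sites(self) -> int:
        return self.Q.shape[0]

    @property
    def n_traps(self) -> int:
        return self.R.shape[1]

    def full_matrix(self) -> np.ndarray:
        n, t = self.n_sites, self.n_traps
        full = np.zeros((n + t, n + t))
        full[:n, :n] = self.Q
        full[:n, n:] = self.R
        full[n:, n:] = np.eye(t)
        return full


def _trap_site_distances(
    landscape: Landscape, trap_coords: np.ndarray
) -> np.ndarray:
    """(n_sites, n_traps) distances in the landscape's distance mode."""
    site_xy = landscape.coords
    if landscape.distance_mode == "euclidean":
        diff = site_xy[:, None, :] - trap_coords[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])
    # haversine: reuse the pairwise routine on the stacked point set
    from .landscape import EARTH_RADIUS_M

    lon1, lat1 = np.radians(site_xy[:, 0]), np.radians(site_xy[:, 1])
    lon2, lat2 = np.radians(trap_coords[:, 0]), np.radians(trap_coords[:, 1])
    dlat = lat1[:, None] - lat2[None, :]
    dlon = lon1[:, None] - lon2[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat1)[:, None] * np.cos(lat2)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def augment_with_traps(landscape: Landscape, traps: Sequence[Trap]) -> AugmentedChain:
    """Extend tau with absorbing trap states.

    Raw ``nu[i, k]`` is the trap kernel evaluated at the site-to-trap distance
    (times the per-resource-type multiplier, if any); site row *i* of the full
    matrix is ``[tau_i, nu_i] / (1 + sum_k nu[i, k])``.
    """
    if len(traps) == 0:
        raise InvalidInputError("need at least one trap")
    coords = resolve_trap_coordinates(traps, landscape.sites)
    dist = _trap_site_distances(landscape, coords)
    nu = np.column_stack(
        [trap_attractiveness(dist[:, k], trap.kernel) for k, trap in enumerate(traps)]
    )
    types = np.array([s.resource_type for s in landscape.sites], dtype=int)
    for k, trap in enumerate(traps):
        mult = trap.kernel.type_multipliers
        if mult is not None:
            if types.max() >= len(mult):
                raise InvalidInputError(
                    f"trap {trap.id}: type multipliers cover {len(mult)} types, "
                    f"landscape has type {types.max()}"
                )
            nu[:, k] *= np.asarray(mult, dtype=float)[types]
    denom = 1.0 + nu.sum(axis=1)
    Q = landscape.tau / denom[:, None]
    R = nu / denom[:, None]
    return AugmentedChain(Q=Q, R=R, traps=list(traps))


# ---------------------------------------------------------------------------
# Traps CSV: id,placement_kind,node_or_x,y,kernel,A,radius,shape,immovable
# ---------------------------------------------------------------------------

def read_traps_csv(path) -> list[Trap]:
    df = pd.read_csv(path)
    traps = []
    for _, row in df.iterrows():
        kind = str(row["placement_kind"]).strip().lower()
        if kind == "node":
            placement: Union[int, tuple[float, float]] = int(row["node_or_x"])
        elif kind == "coord":
            placement = (float(row["node_or_x"]), float(row["y"]))
        else:
            raise InvalidInputError(f"placement_kind must be node|coord, got {kind!r}")
        kernel = TrapKernel(
            family=str(row["kernel"]).strip().lower(),
            A=float(row["A"]),
            radius=float(row["radius"]),
            shape=float(row["shape"]) if not pd.isna(row.get("shape")) else 1.0,
        )
        traps.append(
            Trap(
                id=int(row["id"]),
                placement=placement,
                kernel=kernel,
                immovable=bool(row["immovable"]),
            )
        )
    return traps


def write_traps_csv(traps: Sequence[Trap], path) -> None:
    rows = []
    for trap in traps:
        if trap.is_discrete:
            kind, nx, y = "node", int(trap.placement), ""
        else:
            kind, (nx, y) = "coord", trap.placement  # type: ignore[misc]
        rows.append(
            {
                "id": trap.id,
                "placement_kind": kind,
                "node_or_x": nx,
                "y": y,
                "kernel": trap.kernel.family,
                "A": trap.kernel.A,
                "radius": trap.kernel.radius,
                "shape": trap.kernel.shape,
                "immovable": trap.immovable,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
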