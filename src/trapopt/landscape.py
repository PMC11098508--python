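"""Landscape model: sites, dispersal kernels, masking, and the movement matrix.

A landscape is a finite set of point sites (mosquito population nodes). Daily
per-capita movement between sites is Markovian: the probability of moving from
site *i* to site *j* depends only on the current site and is derived from a
dispersal kernel applied to the pairwise distance, optionally modulated by a
resource-type masking matrix. The result is the row-stochastic movement matrix
``tau`` (one row per site, rows summing to 1).

Built-in dispersal kernels
--------------------------
``exponential``
    ``w(d) = exp(-d / m)`` with mean dispersal distance ``m``. The diagonal
    weight is ``w(0) = 1`` and the whole row is normalized.
``zero_inflated_exponential``
    An explicit staying probability ``z`` is reserved for the diagonal; the
    remaining mass ``1 - z`` is distributed over other sites proportionally to
    ``exp(-d / m)``, where ``m`` is the mean dispersal distance conditional on
    movement. Models taxa that dwell at a site and occasionally hop (e.g.
    *Aedes aegypti*).
``long_tailed``
    A Lomax (shifted power-law) kernel ``w(d) = (1 + d/(m (b-1)))^(-b)`` with
    mean ``m`` and shape ``b > 1``; heavier-tailed than the exponential and
    converging to it as ``b`` grows. Models longer-ranging dispersers.
``custom``
    Any callable mapping a nonnegative distance (array) to nonnegative
    weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "Site",
    "DispersalKernel",
    "MaskMatrix",
    "Landscape",
    "distance_matrix",
    "kernel_weights",
    "apply_mask",
    "build_movement_matrix",
    "read_sites_csv",
    "write_sites_csv",
    "write_movement_matrix_csv",
    "read_movement_matrix_csv",
]

#: Mean spherical Earth radius in metres (IUGG).
EARTH_RADIUS_M = 6_371_008.8


class InvalidInputError(ValueError):
    """Raised when inputs violate an operation's preconditions."""


class ParameterError(ValueError):
    """Raised when kernel parameters are out of their valid domain."""


class DegenerateLandscapeError(ValueError):
    """Raised when a site row has no positive movement weight at all."""


@dataclass(frozen=True)
class Site:
    """A population node: planar (x, y) or geographic (lon, lat) point.

    ``resource_type`` is a small integer label (e.g. 0 = blood-feeding,
    1 = water/egg-laying); landscapes without resource heterogeneity use a
    single universal type 0.
    """

    id: int
    x: float
    y: float
    resource_type: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidInputError(f"site {self.id}: non-finite coordinates")


@dataclass(frozen=True)
class DispersalKernel:
    """Distance-decay kernel for daily site-to-site movement propensity.

    Parameters
    ----------
    family
        One of ``exponential``, ``zero_inflated_exponential``, ``long_tailed``
        or ``custom``.
    mean_distance
        Mean dispersal distance ``m`` (coordinate units; conditional upon
        movement for the zero-inflated family). Must be positive.
    zero_inflation
        Staying probability ``z`` in [0, 1] (zero-inflated family only).
    shape
        Tail shape ``b > 1`` (long-tailed family only).
    func
        Weight callable for ``family='custom'``; vectorized over distances.
    """

    family: str = "exponential"
    mean_distance: float = 1.0
    zero_inflation: float = 0.0
    shape: float = 3.0
    func: Optional[Callable[[np.ndarray], np.ndarray]] = None

    _FAMILIES = ("exponential", "zero_inflated_exponential", "long_tailed", "custom")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ParameterError(f"unknown kernel family {self.family!r}")
        if self.family != "custom" and self.mean_distance <= 0:
            raise ParameterError("mean_distance must be > 0")
        if self.family == "zero_inflated_exponential" and not (
            0.0 <= self.zero_inflation <= 1.0
        ):
            raise ParameterError("zero_inflation must lie in [0, 1]")
        if self.family == "long_tailed" and self.shape <= 1:
            raise ParameterError("long_tailed shape must be > 1 (finite mean)")
        if self.family == "custom" and self.func is None:
            raise ParameterError("custom kernel requires func")

    def eval(self, d: np.ndarray) -> np.ndarray:
        """Unnormalized movement weight at distance(s) ``d`` (>= 0)."""
        d = np.asarray(d, dtype=float)
        if self.family == "exponential":
            return np.exp(-d / self.mean_distance)
        if self.family == "zero_inflated_exponential":
            # conditional-on-movement decay; the point mass z is applied
            # separately in build_movement_matrix
            return np.exp(-d / self.mean_distance)
        if self.family == "long_tailed":
            b, m = self.shape, self.mean_distance
            return (1.0 + d / (m * (b - 1.0))) ** (-b)
        w = np.asarray(self.func(d), dtype=float)  # type: ignore[misc]
        if np.any(w < 0):
            raise ParameterError("custom kernel returned negative weights")
        return w


@dataclass(frozen=True)
class MaskMatrix:
    """Resource-type masking: entry (s, t) multiplies movement weight from a
    site of type ``s`` to a site of type ``t``.

    The mosquito's *current* node determines the row (e.g. a blood-fed female
    at a blood-feeding site up-weights water/egg-laying destinations).
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError("mask must be square")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise InvalidInputError("mask entries must be finite and >= 0")
        if np.any(m.sum(axis=1) <= 0):
            raise InvalidInputError("every mask row needs a positive entry")
        object.__setattr__(self, "entries", m)

    @property
    def n_types(self) -> int:
        return self.entries.shape[0]


def distance_matrix(sites: Sequence[Site], mode: str = "euclidean") -> np.ndarray:
    """Pairwise distances between sites.

    ``euclidean`` treats (x, y) as planar coordinates; ``haversine`` treats
    them as (longitude, latitude) degrees and returns great-circle metres on a
    sphere of radius :data:`EARTH_RADIUS_M`.
    """
    if len(sites) < 1:
        raise InvalidInputError("need at least one site")
    xy = np.array([(s.x, s.y) for s in sites], dtype=float)
    if not np.all(np.isfinite(xy)):
        raise InvalidInputError("non-finite coordinates")
    if mode == "euclidean":
        diff = xy[:, None, :] - xy[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])
    if mode == "haversine":
        lon, lat = np.radians(xy[:, 0]), np.radians(xy[:, 1])
        if np.any(np.abs(xy[:, 1]) > 90.0):
            raise InvalidInputError("haversine latitude outside [-90, 90]")
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        )
        d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
        np.fill_diagonal(d, 0.0)
        return d
    raise InvalidInputError(f"unknown distance mode {mode!r}")


def kernel_weights(dist: np.ndarray, kernel: DispersalKernel) -> np.ndarray:
    """Entry-wise kernel weights for a distance matrix.

    For the zero-inflated family only the off-diagonal decay weights are
    meaningful here; the diagonal point mass is imposed during row
    normalization in :func:`build_movement_matrix`, so the diagonal is
    returned as 0.
    """
    dist = np.asarray(dist, dtype=float)
    w = kernel.eval(dist)
    if kernel.family == "zero_inflated_exponential":
        w = w.copy()
        np.fill_diagonal(w, 0.0)
    return w


def apply_mask(
    weights: np.ndarray, sites: Sequence[Site], mask: MaskMatrix
) -> np.ndarray:
    """Multiply weight (i, j) by ``mask[type(i), type(j)]`` (no normalization)."""
    types = np.array([s.resource_type for s in sites], dtype=int)
    if types.min() < 0 or types.max() >= mask.n_types:
        raise InvalidInputError(
            f"resource type {types.max()} not covered by {mask.n_types}x"
            f"{mask.n_types} mask"
        )
    return np.asarray(weights, dtype=float) * mask.entries[np.ix_(types, types)]


@dataclass
class Landscape:
    """Site set plus kernel/mask; ``tau`` is derived on construction.

    ``tau[i, j]`` is the daily probability a mosquito currently at site *i*
    is at site *j* tomorrow; each row sums to 1.
    """

    sites: list[Site]
    kernel: DispersalKernel
    mask: Optional[MaskMatrix] = None
    distance_mode: str = "euclidean"
    tau: np.ndarray = field(init=False, repr=False)
    distances: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sites]
        if ids != list(range(len(self.sites))):
            raise InvalidInputError("site ids must be contiguous from 0")
        self.distances = distance_matrix(self.sites, self.distance_mode)
        self.tau = build_movement_matrix(self)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def coords(self) -> np.ndarray:
        return np.array([(s.x, s.y) for s in self.sites], dtype=float)

    def bounding_box(self, pad_fraction: float = 0.0) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax), optionally padded per side by a fraction
        of the corresponding extent (degenerate extents padded by 0.5)."""
        c = self.coords
        xmin, ymin = c.min(axis=0)
        xmax, ymax = c.max(axis=0)
        if pad_fraction:
            dx = (xmax - xmin) or 1.0
            dy = (ymax - ymin) or 1.0
            xmin -= pad_fraction * dx
            xmax += pad_fraction * dx
            ymin -= pad_fraction * dy
            ymax += pad_fraction * dy
        return float(xmin), float(ymin), float(xmax), float(ymax)


def build_movement_matrix(landscape: Landscape) -> np.ndarray:
    """Row-stochastic daily movement matrix ``tau``.

    Plain kernels: the kernel is evaluated on every entry (diagonal at d = 0),
    the optional mask applied, and each row normalized to 1. Zero-inflated
    kernel: the diagonal is pinned to the staying probability ``z`` and the
    masked off-diagonal weights are normalized to share ``1 - z``. A site with
    no positive off-diagonal weight is isolated and keeps self-probability 1.
    """
    sites, kernel, mask = landscape.sites, landscape.kernel, landscape.mask
    dist = landscape.distances
    n = len(sites)
    w = kernel_weights(dist, kernel)
    if mask is not None:
        w = apply_mask(w, sites, mask)

    if kernel.family == "zero_inflated_exponential":
        z = kernel.zero_inflation
        off = w.copy()
        np.fill_diagonal(off, 0.0)
        row = off.sum(axis=1)
        tau = np.zeros((n, n))
        reachable = row > 0
        tau[reachable] = off[reachable] * ((1.0 - z) / row[reachable, None])
        diag = np.where(reachable, z, 1.0)
        tau[np.arange(n), np.arange(n)] = diag
        return tau

    row = w.sum(axis=1)
    if np.any(row <= 0):
        bad = int(np.flatnonzero(row <= 0)[0])
        raise DegenerateLandscapeError(
            f"site {bad} has zero total movement weight (check mask/kernel)"
        )
    return w / row[:, None]


# ---------------------------------------------------------------------------
# CSV interfaces: sites are `lon,lat,t` (t optional); tau is headerless CSV.
# ---------------------------------------------------------------------------

def read_sites_csv(path) -> list[Site]:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    try:
        lon, lat = cols["lon"], cols["lat"]
    except KeyError as exc:
        raise InvalidInputError(f"sites CSV needs lon,lat columns: {path}") from exc
    types = df[cols["t"]].astype(int) if "t" in cols else np.zeros(len(df), int)
    return [
        Site(i, float(x), float(y), int(t))
        for i, (x, y, t) in enumerate(zip(df[lon], df[lat], types))
    ]


def write_sites_csv(sites: Sequence[Site], path) -> None:
    pd.DataFrame(
        {
            "lon": [s.x for s in sites],
            "lat": [s.y for s in sites],
            "t": [s.resource_type for s in sites],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_movement_matrix_csv(tau: np.ndarray, path) -> None:
    """Plain headerless CSV of tau for downstream spatial simulators."""
    np.savetxt(path, np.asarray(tau, dtype=float), delimiter=",", fmt="%.17g")


def read_movement_matrix_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def read_mask_csv(path) -> MaskMatrix:
    """Square numeric mask CSV with a header row of type labels."""
    df = pd.read_csv(path)
    return MaskMatrix(df.to_numpy(dtype=float))


def write_mask_csv(mask: MaskMatrix, path) -> None:
    n = mask.n_types
    pd.DataFrame(mask.entries, columns=[str(t) for t in range(n)]).to_csv(
        path, index=False
    )
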