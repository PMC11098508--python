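"""Expected time-to-trapping and the scalar optimization objectives.

For an absorbing Markov chain with transient (site-to-site) block ``Q``, the
expected number of steps to absorption starting from each site is the row sum
of the fundamental matrix ``N = (I - Q)^{-1}``, i.e. the solution of::

    (I - Q) t = 1

Because the movement matrix holds *daily* probabilities, the entries of ``t``
are expected days until the mosquito falls into some trap. Sites from which
absorption is not certain (no path to any trap, or positive probability of
entering a trap-free closed region) get ``+inf`` rather than raising, so an
optimizer can rank and discard such configurations.

A count-based Monte-Carlo simulator (:func:`simulate_walkers`) serves as an
independent check of the linear-algebra route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .landscape import InvalidInputError
from .traps import AugmentedChain

__all__ = [
    "AbsorptionProfile",
    "expected_absorption_time",
    "fitness_mean",
    "fitness_max",
    "simulate_walkers",
    "WalkerSummary",
]

#: (I - Q) condition-number threshold beyond which the solve is distrusted.
CONDITION_LIMIT = 1e12


@dataclass
class AbsorptionProfile:
    """Expected days-to-trapping per origin site (+inf where unreachable)."""

    t: np.ndarray

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"site_id": np.arange(len(self.t)), "expected_days": self.t}
        ).to_csv(path, index=False)


def _certain_absorption_mask(Q: np.ndarray, capture: np.ndarray) -> np.ndarray:
    """Boolean mask of sites from which absorption has probability 1.

    A site is *trap-blind* if no directed path (through positive Q entries)
    leads to a site with positive capture probability; trap-blind sites form a
    closed set, so any site that can step into it is absorbed with probability
    < 1 and has infinite expected time.
    """
    adj = Q > 0
    reaches_trap = capture.copy()
    while True:  # fixed point; n is small so O(n^3) worst case is fine
        new = reaches_trap | (adj @ reaches_trap)
        if np.array_equal(new, reaches_trap):
            break
        reaches_trap = new
    blind = ~reaches_trap
    hits_blind = blind.copy()
    while True:
        new = hits_blind | (adj @ hits_blind)
        if np.array_equal(new, hits_blind):
            break
        hits_blind = new
    return ~hits_blind


def expected_absorption_time(chain: AugmentedChain) -> AbsorptionProfile:
    """Solve ``(I - Q) t = 1`` for the expected days-to-trapping vector.

    Uses a direct linear solve (never an explicit inverse). Origins without
    certain absorption — and all origins if the restricted system is
    numerically singular (condition estimate above ``1e12``) — receive the
    ``+inf`` sentinel.
    """
    Q = np.asarray(chain.Q, dtype=float)
    n = Q.shape[0]
    capture = chain.R.sum(axis=1) > 0
    ok = _certain_absorption_mask(Q, capture)
    t = np.full(n, np.inf)
    if not ok.any():
        return AbsorptionProfile(t)
    sub = np.ix_(ok, ok)
    A = np.eye(int(ok.sum())) - Q[sub]
    try:
        if np.linalg.cond(A, 1) > CONDITION_LIMIT:
            return AbsorptionProfile(t)
        t_sub = scipy.linalg.solve(A, np.ones(A.shape[0]))
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        return AbsorptionProfile(t)
    if not np.all(np.isfinite(t_sub)) or np.any(t_sub <= 0):
        return AbsorptionProfile(t)
    t[ok] = t_sub
    return AbsorptionProfile(t)


def fitness_mean(profile: AbsorptionProfile) -> float:
    """Mean expected trapping time over all origin sites (days)."""
    if len(profile.t) == 0:
        raise InvalidInputError("empty absorption profile")
    return float(np.mean(profile.t))


def fitness_max(profile: AbsorptionProfile) -> float:
    """Worst-origin expected trapping time (days)."""
    if len(profile.t) == 0:
        raise InvalidInputError("empty absorption profile")
    return float(np.max(profile.t))


@dataclass
class WalkerSummary:
    """Per-origin empirical days-to-trapping from simulated random walks."""

    mean: np.ndarray
    se: np.ndarray
    n_absorbed: np.ndarray
    n_censored: np.ndarray


def simulate_walkers(
    chain: AugmentedChain,
    n_walkers: int,
    max_steps: int = 100_000,
    seed: int = 0,
) -> WalkerSummary:
    """Monte-Carlo estimate of days-to-trapping from every origin site.

    Releases ``n_walkers`` independent walkers at each site and steps them
    through the chain until absorption (all traps lumped together) or
    ``max_steps``, whichever comes first. Walkers still at large at the cap
    are censored and excluded from the mean. Implemented with per-site
    occupancy counts and multinomial draws, so cost scales with the number of
    steps, not the number of walkers.
    """
    if n_walkers < 1:
        raise InvalidInputError("n_walkers must be >= 1")
    rng = np.random.default_rng(seed)
    Q, R = chain.Q, chain.R
    n = chain.n_sites
    # transition rows over [sites..., absorbed]; clip tiny negative rounding
    p_abs = R.sum(axis=1)
    P = np.concatenate([Q, p_abs[:, None]], axis=1)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)

    counts = np.full((n, n), 0, dtype=np.int64)
    np.fill_diagonal(counts, n_walkers)
    sum_t = np.zeros(n)
    sum_t2 = np.zeros(n)
    n_abs = np.zeros(n, dtype=np.int64)
    step = 0
    while counts.sum() > 0 and step < max_steps:
        step += 1
        draws = rng.multinomial(counts, P[None, :, :])  # (origin, site, dest+1)
        absorbed = draws[:, :, -1].sum(axis=1)
        sum_t += step * absorbed
        sum_t2 += (step**2) * absorbed
        n_abs += absorbed
        counts = draws[:, :, :-1].sum(axis=1)
    n_censored = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sum_t / n_abs
        var = (sum_t2 - n_abs * mean**2) / np.maximum(n_abs - 1, 1)
        se = np.sqrt(np.maximum(var, 0.0) / np.maximum(n_abs, 1))
    mean = np.where(n_abs > 0, mean, np.inf)
    se = np.where(n_abs > 0, se, np.nan)
    return WalkerSummary(mean=mean, se=se, n_absorbed=n_abs, n_censored=n_censored)
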