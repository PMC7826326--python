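"""Monte-Carlo simulators of valence-gated retroactive interference.

A memory system acquires one item per discrete time step.  Each item
carries an i.i.d. valence vector ``v`` (importance scores, one per
dimension).  Three forgetting processes are implemented:

``full_erasure``
    A newly acquired item erases *every* stored item it strictly dominates
    in all ``n`` valence dimensions.  For ``n = 1`` the retained valences
    strictly increase with item age and retention follows ``1/(t+1)``; for
    ``n >= 2`` the store is at all times an antichain of the componentwise
    strict-dominance partial order.

``single_erasure``
    A newly acquired item erases only the stored item with the smallest
    valence, and only if the new item is not itself the minimum.  The store
    grows linearly, with ``N(T)/T -> 1/e``.

``linear_decay``
    A non-interacting baseline: each item has strength ``a - b * age`` with
    random positive ``a`` (initial strength) and ``b`` (decay rate) and is
    erased at the first step where the strength reaches zero.  When the
    density of ``b`` at zero is positive, retention scales like
    ``P_b(0) <a> / tau`` for large ``tau``.

All randomness flows through a single seeded :class:`numpy.random.Generator`
per simulation; replicate runs use ``seed + replicate_index``, making every
result reproducible bit-for-bit from ``(config, seed)``.
"""

from __future__ import annotations

import heapq
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .distributions import (
    DistributionSpec,
    require_continuous,
    require_nonnegative,
    resolve_distribution,
)

__all__ = [
    "SURVIVED",
    "VARIANTS",
    "SimulationConfig",
    "SimulationResult",
    "simulate",
    "simulate_full_erasure",
    "simulate_single_erasure",
    "simulate_linear_decay",
    "present_in_order",
    "dominators_first_order",
    "empirical_retention",
    "replicate_retention",
]

#: Sentinel erasure time for items still in memory at the end of the horizon.
SURVIVED: int = -1

VARIANTS = ("full_erasure", "single_erasure", "linear_decay")

_UNIFORM = DistributionSpec("uniform", {})


@dataclass
class SimulationConfig:
    """Configuration of one erasure-process simulation.

    Parameters
    ----------
    variant:
        One of ``full_erasure``, ``single_erasure``, ``linear_decay``.
    T:
        Horizon in steps; one item is acquired per step.
    n_dims:
        Valence dimensionality ``n >= 1`` (must be 1 for the single-erasure
        and linear-decay variants).
    valence_distribution:
        Continuous distribution for each valence component (i.i.d. across
        items and dimensions).  The retention behaviour of the interference
        models is distribution-free, so the default uniform(0, 1) is merely
        a convenient choice.
    strength_distribution, decay_distribution:
        Distributions of the initial strength ``a`` and decay rate ``b``
        for the linear-decay variant; both must have non-negative support.
    seed:
        Seed of the simulation's random generator.
    """

    variant: str
    T: int
    n_dims: int = 1
    valence_distribution: object = field(default=_UNIFORM)
    strength_distribution: object = field(default=_UNIFORM)
    decay_distribution: object = field(default=_UNIFORM)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if int(self.T) < 1:
            raise ValueError("horizon T must be >= 1")
        self.T = int(self.T)
        if int(self.n_dims) < 1:
            raise ValueError("n_dims must be >= 1")
        self.n_dims = int(self.n_dims)
        if self.variant in ("single_erasure", "linear_decay") and self.n_dims != 1:
            raise ValueError(f"{self.variant} is defined for n_dims = 1 only")
        if self.variant in ("full_erasure", "single_erasure"):
            self.valence_distribution = require_continuous(
                resolve_distribution(self.valence_distribution), "valence"
            )
        else:
            self.strength_distribution = require_nonnegative(
                resolve_distribution(self.strength_distribution), "initial strength"
            )
            self.decay_distribution = require_nonnegative(
                resolve_distribution(self.decay_distribution), "decay rate"
            )


@dataclass
class SimulationResult:
    """Outcome of one simulated acquisition/erasure history.

    ``acquisition_time`` and ``erasure_time`` are 1-based step indices;
    ``erasure_time`` is :data:`SURVIVED` for items still stored at the end.
    ``store_size[t-1]`` is the number of retained items after step ``t``'s
    acquisition and erasures.  ``valences`` (when available) holds the
    sampled valence matrix, one row per item.
    """

    variant: str
    n_dims: int
    T: int
    seed: int | None
    acquisition_time: np.ndarray
    erasure_time: np.ndarray
    store_size: np.ndarray
    valences: np.ndarray | None = None

    @property
    def survived(self) -> np.ndarray:
        """Boolean mask of items never erased within the horizon."""
        return self.erasure_time == SURVIVED

    @property
    def erasure_age(self) -> np.ndarray:
        """Age at erasure (float; ``inf`` for surviving items)."""
        age = np.where(
            self.survived, np.inf, self.erasure_time - self.acquisition_time
        )
        return age.astype(float)

    def stored_at(self, step: int) -> np.ndarray:
        """Indices of items in memory just after ``step`` (1-based)."""
        return np.nonzero(
            (self.acquisition_time <= step)
            & (self.survived | (self.erasure_time > step))
        )[0]


# ---------------------------------------------------------------------------
# engines


def _full_erasure_1d(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scalar-valence full erasure via a monotone stack (amortised O(T)).

    The store, read in acquisition order, always has strictly decreasing
    valences, so the items dominated by a new arrival form a suffix that a
    binary search locates.
    """
    T = v.shape[0]
    erasure = np.full(T, SURVIVED, dtype=np.int64)
    store_size = np.empty(T, dtype=np.int64)
    neg: list[float] = []  # negated valences, increasing in acquisition order
    ids: list[int] = []
    for t0 in range(T):
        x = -float(v[t0])
        cut = bisect_right(neg, x)
        if cut < len(ids):
            step = t0 + 1
            for j in ids[cut:]:
                erasure[j] = step
            del neg[cut:]
            del ids[cut:]
        neg.append(x)
        ids.append(t0)
        store_size[t0] = len(ids)
    return erasure, store_size


def _full_erasure_nd(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """General full erasure; the store stays small (≈ log^n T / n!)."""
    T, n = v.shape
    erasure = np.full(T, SURVIVED, dtype=np.int64)
    store_size = np.empty(T, dtype=np.int64)
    cap = 64
    sv = np.empty((cap, n))
    sid = np.empty(cap, dtype=np.int64)
    k = 0
    for t0 in range(T):
        x = v[t0]
        if k:
            dominated = (sv[:k] < x).all(axis=1)
            if dominated.any():
                erasure[sid[:k][dominated]] = t0 + 1
                keep = ~dominated
                m = int(keep.sum())
                sv[:m] = sv[:k][keep]
                sid[:m] = sid[:k][keep]
                k = m
        if k == cap:
            cap *= 2
            sv = np.resize(sv, (cap, n))
            sid = np.resize(sid, cap)
        sv[k] = x
        sid[k] = t0
        k += 1
        store_size[t0] = k
    return erasure, store_size


def _sample_valences(config: SimulationConfig, rng: np.random.Generator):
    v = config.valence_distribution.rvs(
        size=(config.T, config.n_dims), random_state=rng
    )
    return np.asarray(v, dtype=float)


def simulate_full_erasure(config: SimulationConfig) -> SimulationResult:
    """Run the full-erasure interference process.

    At each step the new item is stored and every stored item strictly
    dominated by it in *all* dimensions is erased.  The new item can never
    be erased on its own acquisition step.
    """
    if config.variant != "full_erasure":
        raise ValueError("config.variant must be 'full_erasure'")
    rng = np.random.default_rng(config.seed)
    v = _sample_valences(config, rng)
    if config.n_dims == 1:
        erasure, store_size = _full_erasure_1d(v[:, 0])
    else:
        erasure, store_size = _full_erasure_nd(v)
    return SimulationResult(
        variant=config.variant,
        n_dims=config.n_dims,
        T=config.T,
        seed=config.seed,
        acquisition_time=np.arange(1, config.T + 1, dtype=np.int64),
        erasure_time=erasure,
        store_size=store_size,
        valences=v,
    )


def _single_erasure_engine(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-erasure process on an explicit valence sequence (min-heap)."""
    T = v.shape[0]
    erasure = np.full(T, SURVIVED, dtype=np.int64)
    store_size = np.empty(T, dtype=np.int64)
    heap: list[tuple[float, int]] = []
    for t0 in range(T):
        x = float(v[t0])
        if heap and heap[0][0] < x:
            _, j = heapq.heappop(heap)
            erasure[j] = t0 + 1
        heapq.heappush(heap, (x, t0))
        store_size[t0] = len(heap)
    return erasure, store_size


def simulate_single_erasure(config: SimulationConfig) -> SimulationResult:
    """Run the single-erasure variant (scalar valence).

    Each step stores the new item; if its valence exceeds the current
    stored minimum, exactly that minimum item is erased, otherwise nothing
    is.  The store size never decreases.
    """
    if config.variant != "single_erasure":
        raise ValueError("config.variant must be 'single_erasure'")
    rng = np.random.default_rng(config.seed)
    v = _sample_valences(config, rng)[:, 0]
    T = config.T
    erasure, store_size = _single_erasure_engine(v)
    return SimulationResult(
        variant=config.variant,
        n_dims=1,
        T=T,
        seed=config.seed,
        acquisition_time=np.arange(1, T + 1, dtype=np.int64),
        erasure_time=erasure,
        store_size=store_size,
        valences=v[:, None],
    )


def simulate_linear_decay(config: SimulationConfig) -> SimulationResult:
    """Run the non-interacting linearly-decaying-strength baseline.

    An item acquired at step ``s`` with strength ``a - b * age`` is erased
    at the first step where the strength is <= 0, i.e. at age
    ``ceil(a / b)`` (never, if ``b = 0``).
    """
    if config.variant != "linear_decay":
        raise ValueError("config.variant must be 'linear_decay'")
    rng = np.random.default_rng(config.seed)
    T = config.T
    a = np.asarray(
        config.strength_distribution.rvs(size=T, random_state=rng), dtype=float
    )
    b = np.asarray(
        config.decay_distribution.rvs(size=T, random_state=rng), dtype=float
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        age = np.ceil(a / b)
    age[b == 0] = np.inf
    age[age < 1] = 1  # a = 0 items are gone one step after acquisition
    acquisition = np.arange(1, T + 1, dtype=np.int64)
    absolute = acquisition + age
    erasure = np.where(absolute <= T, absolute, SURVIVED).astype(np.int64)
    erased_steps = erasure[erasure != SURVIVED]
    counts = np.bincount(erased_steps, minlength=T + 1)
    store_size = acquisition - np.cumsum(counts)[1:]
    return SimulationResult(
        variant=config.variant,
        n_dims=1,
        T=T,
        seed=config.seed,
        acquisition_time=acquisition,
        erasure_time=erasure,
        store_size=store_size,
        valences=None,
    )


_DISPATCH = {
    "full_erasure": simulate_full_erasure,
    "single_erasure": simulate_single_erasure,
    "linear_decay": simulate_linear_decay,
}


def simulate(config: SimulationConfig) -> SimulationResult:
    """Dispatch to the simulator matching ``config.variant``."""
    return _DISPATCH[config.variant](config)


def present_in_order(items: Sequence | np.ndarray) -> SimulationResult:
    """Run the full-erasure process on an explicit item sequence.

    No sampling takes place: ``items`` is an ``(T, n)`` array (or a length-T
    vector for ``n = 1``) of valences presented in the given order.  When
    the sequence is ordered dominators-first (a reverse linear extension of
    the dominance partial order), no item is ever erased, because erasure is
    purely retroactive.
    """
    v = np.asarray(items, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.ndim != 2 or v.shape[0] < 1:
        raise ValueError("items must be a non-empty (T, n) array")
    if not np.isfinite(v).all():
        raise ValueError("valences must be finite")
    erasure, store_size = _full_erasure_nd(v)
    return SimulationResult(
        variant="full_erasure",
        n_dims=v.shape[1],
        T=v.shape[0],
        seed=None,
        acquisition_time=np.arange(1, v.shape[0] + 1, dtype=np.int64),
        erasure_time=erasure,
        store_size=store_size,
        valences=v,
    )


def dominators_first_order(items: np.ndarray) -> np.ndarray:
    """Indices ordering ``items`` so every dominator precedes its dominated.

    Sorting in decreasing order of the first valence component is a linear
    extension of the strict-dominance order: if ``x`` dominates ``y`` then
    ``x[0] > y[0]``, so ``x`` sorts first; items tied on the first component
    cannot dominate each other.  Presented in this order, the full-erasure
    process erases nothing.
    """
    v = np.asarray(items, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    return np.argsort(-v[:, 0], kind="stable")


# ---------------------------------------------------------------------------
# empirical retention


def empirical_retention(
    result: SimulationResult, max_lag: int, ci_alpha: float = 0.05
) -> pd.DataFrame:
    """Empirical retention curve from simulated erasure times.

    Only items acquired at or before ``T - max_lag`` contribute, so every
    contributing item is observed for the full ``max_lag`` window and the
    estimate has no right-censoring bias.  Returns one row per lag ``t`` in
    ``0..max_lag`` with the survival fraction (share of eligible items whose
    erasure age exceeds ``t``), the contributing-item count and a Wilson
    binomial confidence interval.
    """
    if max_lag >= result.T:
        raise ValueError(
            f"max_lag {max_lag} leaves no fully-observed items at horizon "
            f"T={result.T}; use max_lag < T"
        )
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    eligible = result.acquisition_time <= result.T - max_lag
    n = int(eligible.sum())
    ages = np.where(
        result.survived, max_lag + 1, result.erasure_time - result.acquisition_time
    )[eligible]
    ages = np.minimum(ages, max_lag + 1)
    erased_by = np.cumsum(np.bincount(ages, minlength=max_lag + 2))[: max_lag + 1]
    surviving = n - erased_by
    frac = surviving / n
    ci_low, ci_high = proportion_confint(surviving, n, alpha=ci_alpha, method="wilson")
    return pd.DataFrame(
        {
            "lag": np.arange(max_lag + 1),
            "survival_fraction": frac,
            "n_at_risk": n,
            "ci_low": ci_low,
            "ci_high": ci_high,
        }
    )


def replicate_retention(
    config: SimulationConfig, n_replicates: int, lags: Sequence[int]
) -> pd.DataFrame:
    """Mean empirical retention across seeded replicate simulations.

    Replicate ``i`` runs with ``seed + i``.  Returns one row per requested
    lag with the across-replicate mean survival fraction and the Monte-Carlo
    standard error of that mean.
    """
    lags = np.asarray(lags, dtype=int)
    max_lag = int(lags.max())
    mat = np.empty((n_replicates, lags.size))
    for i in range(n_replicates):
        cfg = replace(config, seed=config.seed + i)
        res = simulate(cfg)
        curve = empirical_retention(res, max_lag)
        mat[i] = curve["survival_fraction"].to_numpy()[lags]
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / np.sqrt(n_replicates)
    return pd.DataFrame(
        {"lag": lags, "mean_survival": mean, "se": se, "n_replicates": n_replicates}
    )
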