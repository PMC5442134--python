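"""Deterministic environment of the common-pool resource game.

A renewable stock ``N`` regenerates logistically and is depleted by the
joint harvest of a group of agents.  Harvest is a Cobb-Douglas production
of cumulative effort ``X`` ("labour") and stock ``N`` ("capital"):

    G(N)    = r_g * N * (1 - N / N_max)
    H(X, N) = beta * X**alpha * N**(1 - alpha)
    N_t     = N_{t-1} + G(N_{t-1}) - H(X_t, N_{t-1})

Each agent earns a payoff proportional to its share of the total effort,
minus a linear effort cost:

    pi_i = (x_i / X) * H(X, N) - c * x_i,      Pi = H - c * X

This module is purely deterministic bookkeeping; learning and action
selection live in :mod:`cprg.learning`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GameParams",
    "ResourceState",
    "RoundOutcome",
    "growth",
    "harvest",
    "cumulative_effort",
    "step_resource",
    "payoffs",
    "update_assets",
]


@dataclass(frozen=True)
class GameParams:
    """Environment constants of the game.

    Defaults are the reference parameterization used throughout the
    analysis and simulation experiments.

    Attributes
    ----------
    N_max : float
        Resource carrying capacity (stock units), > 0.
    r_g : float
        Intrinsic replenishment rate per round, >= 0.
    alpha : float
        Cobb-Douglas effort elasticity, in [0, 1].  Low ``alpha`` means
        the harvest depends more on the stock than on effort.
    beta : float
        Cobb-Douglas scale factor, in [0, 1].
    X_min, X_max : float
        Lower and upper bounds on the cumulative effort of the group,
        0 < X_min <= X_max.
    c : float
        Cost per unit of effort invested (currency / effort), >= 0.
    """

    N_max: float = 1000.0
    r_g: float = 0.5
    alpha: float = 0.35
    beta: float = 0.4
    X_min: float = 100.0
    X_max: float = 500.0
    c: float = 0.5

    def __post_init__(self) -> None:
        if not self.N_max > 0:
            raise ValueError(f"N_max must be > 0, got {self.N_max}")
        if self.r_g < 0:
            raise ValueError(f"r_g must be >= 0, got {self.r_g}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0 < self.X_min <= self.X_max:
            raise ValueError(
                f"need 0 < X_min <= X_max, got X_min={self.X_min}, X_max={self.X_max}"
            )
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")


@dataclass
class ResourceState:
    """Current stock level and round index; 0 <= N <= N_max always."""

    N: float
    t: int = 0


@dataclass
class RoundOutcome:
    """Diagnostics of one resource update.

    ``G``, ``H`` and ``net_growth`` are the *raw* (unclamped) quantities
    of the round, so reward signals and analysis see the true net growth
    even when the stock update had to be clamped to [0, N_max].
    """

    G: float
    H: float
    net_growth: float
    X: float
    Pi: float
    pi: np.ndarray


def growth(N: float, params: GameParams) -> float:
    """Logistic growth ``r_g * N * (1 - N/N_max)``; zero at N=0 and N=N_max."""
    if N < 0 or N > params.N_max:
        raise ValueError(f"N must lie in [0, {params.N_max}], got {N}")
    return params.r_g * N * (1.0 - N / params.N_max)


def harvest(X: float, N: float, params: GameParams) -> float:
    """Cobb-Douglas harvest ``beta * X**alpha * N**(1-alpha)``.

    Returns 0 whenever ``X == 0`` or ``N == 0`` (no effort or no stock
    means no harvest, regardless of exponent edge cases); never negative.
    """
    if X < 0:
        raise ValueError(f"effort X must be >= 0, got {X}")
    if N < 0:
        raise ValueError(f"resource N must be >= 0, got {N}")
    if X == 0.0 or N == 0.0:
        return 0.0
    return params.beta * X**params.alpha * N ** (1.0 - params.alpha)


def cumulative_effort(efforts: Sequence[float]) -> float:
    """Total effort ``X = sum_i x_i`` of the group; empty group -> 0."""
    arr = np.asarray(efforts, dtype=float)
    if arr.size and (arr < 0).any():
        raise ValueError("all individual efforts must be >= 0")
    return float(arr.sum())


def step_resource(
    state: ResourceState, X: float, params: GameParams
) -> tuple[ResourceState, RoundOutcome]:
    """Advance the stock one round under cumulative effort ``X``.

    The raw update ``N + G - H`` is clamped to [0, N_max]: negative stock
    is physically meaningless and N = 0 is absorbing (both growth and
    harvest vanish there).  The returned :class:`RoundOutcome` carries the
    unclamped ``G``, ``H`` and ``net_growth``.
    """
    G = growth(state.N, params)
    H = harvest(X, state.N, params)
    raw = state.N + G - H
    N_new = min(max(raw, 0.0), params.N_max)
    outcome = RoundOutcome(
        G=G, H=H, net_growth=G - H, X=X, Pi=float("nan"), pi=np.empty(0)
    )
    return ResourceState(N=N_new, t=state.t + 1), outcome


def payoffs(
    efforts: Sequence[float], N: float, params: GameParams
) -> tuple[np.ndarray, float]:
    """Per-agent payoffs and total payoff at stock level ``N``.

    ``pi_i = (x_i / X) * H(X, N) - c * x_i`` and ``Pi = H - c X``; the
    individual payoffs sum to the total by construction.  If nobody
    invests (X = 0) every payoff is zero.
    """
    x = np.asarray(efforts, dtype=float)
    if x.size and (x < 0).any():
        raise ValueError("all individual efforts must be >= 0")
    X = float(x.sum())
    if X == 0.0:
        return np.zeros_like(x), 0.0
    H = harvest(X, N, params)
    pi = (x / X) * H - params.c * x
    Pi = H - params.c * X
    return pi, Pi


def update_assets(A_prev: float, pi_prev: float) -> float:
    """Credit last round's payoff: ``A_t = A_{t-1} + pi_{t-1}``.

    Assets may go negative; there is no bankruptcy rule in the game.
    """
    return A_prev + pi_prev
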