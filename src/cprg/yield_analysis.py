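"""Bioeconomic analysis of the effort-resource action space.

For a stock at level ``N`` the group's cumulative effort ``X`` is

* *sustainable* when net growth ``G(N) - H(X, N) >= 0``, and
* *profitable* when total profit ``H(X, N) - c X >= 0``.

Both conditions invert to closed-form effort bounds.  The sustainable
bound comes from the maximum-sustainable-yield (MSY) condition,

    X <= ( r_g N (1 - N/N_max) / (beta N^(1-alpha)) )^(1/alpha),

and the profitable bound from the maximum-economic-yield (MEY) condition,

    X <= ( beta N^(1-alpha) / c )^(1/(1-alpha)),

which is exactly linear in ``N``.  Where the two bounds and the feasible
effort window ``[X_min, X_max]`` overlap, harvesting is viable; this
module locates the equilibria that frame that region and measures its
area fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .dynamics import GameParams, growth, harvest

__all__ = [
    "EffortBounds",
    "Equilibria",
    "sustainable_effort_bound",
    "profitable_effort_bound",
    "msy",
    "mey",
    "mey_effort",
    "individual_best_response",
    "equilibria",
    "viable_fraction",
    "classification_grid",
    "analyze",
]


@dataclass(frozen=True)
class EffortBounds:
    """Largest sustainable and profitable cumulative efforts at stock ``N``."""

    N: float
    X_sustainable_max: float
    X_profitable_max: float


@dataclass(frozen=True)
class Equilibria:
    """Resource levels that frame the viable (sustainable & profitable) region.

    ``E1_sustainable`` / ``E2_sustainable`` are the lowest and highest
    stock levels at which the minimum feasible effort ``X_min`` is still
    sustainable (growth matches harvest there).  ``E_profitable`` is the
    lowest stock level at which ``X_min`` turns profitable.  ``E_optimal``
    is the stock level offering the widest interval of efforts that are
    simultaneously feasible, sustainable and profitable — the safest
    operating point, most robust to individual over- or under-shooting.
    """

    E1_sustainable: float
    E2_sustainable: float
    E_profitable: float
    E_optimal: float
    X_e_range: tuple[float, float]


def sustainable_effort_bound(N: float, params: GameParams) -> float:
    """Largest cumulative effort with non-negative net growth at stock ``N``.

    Zero at ``N = 0`` and ``N = N_max`` where logistic growth vanishes.
    Efforts strictly below the bound give positive net growth, efforts
    above give negative net growth.
    """
    if N < 0 or N > params.N_max:
        raise ValueError(f"N must lie in [0, {params.N_max}], got {N}")
    if N == 0.0 or N == params.N_max:
        return 0.0
    g = growth(N, params)
    return float((g / (params.beta * N ** (1.0 - params.alpha))) ** (1.0 / params.alpha))


def profitable_effort_bound(N: float, params: GameParams) -> float:
    """Largest cumulative effort with non-negative total profit at stock ``N``.

    Equals ``(beta / c)**(1/(1-alpha)) * N`` — linear in the stock.  With
    zero cost every effort is profitable and the bound is undefined.
    """
    if N < 0 or N > params.N_max:
        raise ValueError(f"N must lie in [0, {params.N_max}], got {N}")
    if params.c == 0.0:
        raise ValueError("profitable effort is unbounded when cost c = 0")
    return float((params.beta / params.c) ** (1.0 / (1.0 - params.alpha)) * N)


def msy(N: float, params: GameParams) -> tuple[float, float]:
    """Maximize net growth ``G(N) - H(X, N)`` over ``X in [X_min, X_max]``.

    Harvest increases strictly with effort, so the maximizer is always the
    lower effort bound ``X_min``; the maximum net growth may be negative
    (e.g. at carrying capacity, where growth is zero but harvest is not).

    Returns
    -------
    (argmax_effort, max_net_growth)
    """
    X = params.X_min
    return X, growth(N, params) - harvest(X, N, params)


def mey_effort(N: float, params: GameParams) -> float:
    """Profit-maximizing effort: interior stationary point clipped to bounds.

    Setting d/dX of ``beta X^alpha N^(1-alpha) - c X`` to zero gives
    ``X* = (alpha beta / c)^(1/(1-alpha)) * N``.
    """
    if params.c == 0.0:
        return params.X_max
    x_star = (params.alpha * params.beta / params.c) ** (
        1.0 / (1.0 - params.alpha)
    ) * N
    return float(min(max(x_star, params.X_min), params.X_max))


def mey(N: float, params: GameParams) -> tuple[float, float]:
    """Maximize total profit ``H(X, N) - c X`` over ``X in [X_min, X_max]``.

    Returns
    -------
    (argmax_effort, max_total_profit)
        The profit at the argmax may be negative when the stock is low.
    """
    X = mey_effort(N, params)
    return X, harvest(X, N, params) - params.c * X


def individual_best_response(
    x_grid: np.ndarray | list[float],
    others_X: float,
    N: float,
    params: GameParams,
) -> float:
    """Effort maximizing *individual* profit given the others' total effort.

    Evaluates ``(x / (x + others_X)) H(x + others_X, N) - c x`` over the
    candidate actions; ties break toward the smaller action.  With
    ``others_X = 0`` this reduces to the MEY objective restricted to the
    grid — the wedge between the two is the commons dilemma.
    """
    grid = np.asarray(x_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("candidate action set must be non-empty")
    if others_X < 0:
        raise ValueError(f"others_X must be >= 0, got {others_X}")
    X = grid + others_X
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(X > 0, params.beta * X**params.alpha * N ** (1 - params.alpha), 0.0)
        share = np.where(X > 0, grid / X, 0.0)
    profit = share * H - params.c * grid
    order = np.argsort(grid, kind="stable")  # ties -> smaller action
    best = order[np.argmax(profit[order])]
    return float(grid[best])


def equilibria(params: GameParams, resolution: float = 0.5) -> Equilibria:
    """Locate the four equilibria framing the viable region.

    ``E1/E2_sustainable`` solve ``sustainable_effort_bound(N) = X_min`` by
    bisection; ``E_profitable`` has the closed form
    ``X_min * (c / beta)^(1/(1-alpha))``; ``E_optimal`` maximizes, over a
    dense ``N`` scan with step ``resolution``, the length of the interval
    of efforts in ``[X_min, X_max]`` below both bounds (first maximum wins
    on ties, for determinism).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    X_min = params.X_min

    def excess(N: float) -> float:
        return sustainable_effort_bound(N, params) - X_min

    # the sustainable bound is unimodal in N: rises from 0, falls back to 0
    Ns = np.arange(resolution, params.N_max, resolution)
    vals = np.array([excess(N) for N in Ns])
    above = np.flatnonzero(vals > 0)
    if above.size == 0:
        raise ValueError("empty viable region: no stock level sustains X_min")
    lo_bracket = (max(Ns[above[0]] - resolution, 1e-12), Ns[above[0]])
    hi_bracket = (Ns[above[-1]], min(Ns[above[-1]] + resolution, params.N_max - 1e-12))
    E1 = brentq(excess, *lo_bracket, xtol=1e-6)
    E2 = brentq(excess, *hi_bracket, xtol=1e-6)

    E_prof = params.X_min * (params.c / params.beta) ** (1.0 / (1.0 - params.alpha))

    def viable_interval(N: float) -> tuple[float, float]:
        ub = min(
            sustainable_effort_bound(N, params),
            profitable_effort_bound(N, params),
            params.X_max,
        )
        return (X_min, max(ub, X_min))

    lengths = np.array([np.diff(viable_interval(N))[0] for N in Ns])
    if lengths.max() <= 0:
        raise ValueError("empty viable region: no effort is both sustainable and profitable")
    i_opt = int(np.argmax(lengths))  # argmax takes the first (smallest N) on ties
    E_opt = float(Ns[i_opt])
    return Equilibria(
        E1_sustainable=float(E1),
        E2_sustainable=float(E2),
        E_profitable=float(E_prof),
        E_optimal=E_opt,
        X_e_range=tuple(float(v) for v in viable_interval(E_opt)),
    )


def viable_fraction(params: GameParams, resolution: int = 2001) -> float:
    """Fraction of the action rectangle that is sustainable *and* profitable.

    Classifies a ``resolution x resolution`` grid over
    ``[X_min, X_max] x [0, N_max]`` and returns the marked-cell fraction.
    The reference area is the full feasible rectangle; the default grid is
    fine enough that halving the step changes the result by well under
    0.1 percentage point.
    """
    X = np.linspace(params.X_min, params.X_max, resolution)
    N = np.linspace(0.0, params.N_max, resolution)
    XX, NN = np.meshgrid(X, N)
    G = params.r_g * NN * (1.0 - NN / params.N_max)
    H = params.beta * XX**params.alpha * NN ** (1.0 - params.alpha)
    net = G - H
    profit = H - params.c * XX
    return float(np.mean((net >= 0.0) & (profit >= 0.0)))


def classification_grid(params: GameParams, resolution: int = 201):
    """Tidy (N, X) classification table for external contour plotting.

    Returns a DataFrame with columns ``N, X, net_growth, profit,
    sustainable, profitable, viable``.
    """
    import pandas as pd

    X = np.linspace(params.X_min, params.X_max, resolution)
    N = np.linspace(0.0, params.N_max, resolution)
    XX, NN = np.meshgrid(X, N)
    G = params.r_g * NN * (1.0 - NN / params.N_max)
    H = params.beta * XX**params.alpha * NN ** (1.0 - params.alpha)
    net = G - H
    profit = H - params.c * XX
    return pd.DataFrame(
        {
            "N": NN.ravel(),
            "X": XX.ravel(),
            "net_growth": net.ravel(),
            "profit": profit.ravel(),
            "sustainable": (net >= 0).ravel(),
            "profitable": (profit >= 0).ravel(),
            "viable": ((net >= 0) & (profit >= 0)).ravel(),
        }
    )


def analyze(params: GameParams, n_grid: int = 101, resolution: float = 0.5) -> dict:
    """Full analysis report: bounds on an N grid, equilibria, yields, viability.

    The report is JSON-serializable; it backs the ``analyze`` CLI command.
    """
    eq = equilibria(params, resolution=resolution)
    Ns = np.linspace(0.0, params.N_max, n_grid)
    report = {
        "params": {
            "N_max": params.N_max,
            "r_g": params.r_g,
            "alpha": params.alpha,
            "beta": params.beta,
            "X_min": params.X_min,
            "X_max": params.X_max,
            "c": params.c,
        },
        "equilibria": {
            "E1_sustainable": eq.E1_sustainable,
            "E2_sustainable": eq.E2_sustainable,
            "E_profitable": eq.E_profitable,
            "E_optimal": eq.E_optimal,
            "X_e_range": list(eq.X_e_range),
        },
        "viable_fraction": viable_fraction(params),
        "grid": {
            "N": Ns.tolist(),
            "X_sustainable_max": [sustainable_effort_bound(N, params) for N in Ns],
            "X_profitable_max": [profitable_effort_bound(N, params) for N in Ns],
            "msy_net_growth": [msy(N, params)[1] for N in Ns],
            "mey_effort": [mey(N, params)[0] for N in Ns],
            "mey_profit": [mey(N, params)[1] for N in Ns],
        },
    }
    return report
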