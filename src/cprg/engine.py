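"""Round loop coupling learning agents to the shared resource.

One *condition* is a fixed (game parameters, group size, reward weight)
triple, run for a number of rounds and repeated over independent seeded
replicates.  The per-round order is:

1. agents observe the current stock level,
2. each selects an effort (epsilon-greedy over its Q table),
3. harvest and payoffs are computed at the observed stock,
4. the stock is stepped (logistic growth minus harvest, clamped),
5. trend rewards are computed from the raw net growth and payoffs,
6. Q tables are updated,
7. payoffs are credited to assets.

Two experiment harnesses sweep group size and the cost x reward-weight
grid, summarizing late-window resource and asset levels per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import GameParams, ResourceState, payoffs, step_resource
from .learning import (
    AgentState,
    LearnerConfig,
    RewardSpec,
    action_grid,
    discretize_state,
    init_q_table,
    profit_signal,
    reward,
    select_action,
    q_update,
    sustainability_signal,
)
from .yield_analysis import equilibria

__all__ = [
    "ExperimentSpec",
    "SimulationResult",
    "run_game",
    "experiment_group_size",
    "experiment_cost_weight",
    "phase_series",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Scale and seeding of a simulation experiment.

    ``n_sweep``, ``cost_values`` and ``weight_values`` configure the two
    sweep harnesses; a single run uses ``n_agents`` only.  The reference
    scale is 5,000 rounds repeated 50 times with an initial endowment of
    1,000 per agent; the stock starts pristine at carrying capacity.
    ``late_window`` defines the "after learning" rounds used in summary
    statistics.
    """

    n_agents: int = 10
    rounds: int = 5000
    replicates: int = 50
    base_seed: int = 0
    n_sweep: tuple[int, ...] = tuple(range(1, 16))
    cost_values: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))
    weight_values: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))
    initial_assets: float = 1000.0
    initial_resource: float | None = None  # None -> N_max
    late_window: int = 1000

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError(f"rounds must be >= 1, got {self.rounds}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.n_agents < 1:
            raise ValueError(f"n_agents must be >= 1, got {self.n_agents}")
        for name in ("n_sweep", "cost_values", "weight_values"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if not 1 <= self.late_window <= self.rounds:
            raise ValueError(
                f"late_window must be in [1, rounds], got {self.late_window}"
            )


@dataclass
class SimulationResult:
    """Trajectories of a single condition.

    ``trajectories``: one row per (replicate, round) with the stock level
    observed that round, cumulative effort, growth, harvest and total
    payoff.  ``agent_trajectories``: one row per (replicate, round, agent)
    with effort, payoff, post-credit assets and reward.  ``summary``:
    late-window aggregates over replicates.
    """

    trajectories: pd.DataFrame
    agent_trajectories: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _run_replicate(
    params: GameParams,
    spec: ExperimentSpec,
    learner: LearnerConfig,
    reward_spec: RewardSpec,
    rep: int,
    n_agents: int,
):
    """One seeded replicate; returns per-round and per-agent record arrays."""
    seed_seq = np.random.SeedSequence(spec.base_seed + rep)
    rngs = [np.random.default_rng(child) for child in seed_seq.spawn(n_agents)]
    grid = action_grid(learner, params, n_agents)
    agents = [
        AgentState(agent_id=i, assets=spec.initial_assets, q_table=init_q_table(learner))
        for i in range(n_agents)
    ]
    N0 = params.N_max if spec.initial_resource is None else spec.initial_resource
    state = ResourceState(N=N0, t=0)

    T = spec.rounds
    rec_N = np.empty(T)
    rec_X = np.empty(T)
    rec_G = np.empty(T)
    rec_H = np.empty(T)
    rec_Pi = np.empty(T)
    rec_x = np.empty((T, n_agents))
    rec_pi = np.empty((T, n_agents))
    rec_A = np.empty((T, n_agents))
    rec_R = np.empty((T, n_agents))

    for t in range(T):
        s_bin = discretize_state(state.N, learner, params)
        eps = learner.epsilon_at(t)
        actions = [
            select_action(agents[i], s_bin, learner, rngs[i], epsilon=eps)
            for i in range(n_agents)
        ]
        efforts = grid[np.asarray(actions)]
        pi, Pi = payoffs(efforts, state.N, params)
        new_state, outcome = step_resource(state, float(efforts.sum()), params)
        lam = sustainability_signal(outcome.net_growth)
        s_next = discretize_state(new_state.N, learner, params)
        for i, agent in enumerate(agents):
            xi = profit_signal(pi[i])
            R = reward(xi, lam, reward_spec)
            q_update(agent, s_bin, actions[i], R, s_next, learner)
            agent.assets += pi[i]
            agent.last_effort = efforts[i]
            agent.last_payoff = pi[i]
            rec_R[t, i] = R
        rec_N[t] = state.N
        rec_X[t] = outcome.X
        rec_G[t] = outcome.G
        rec_H[t] = outcome.H
        rec_Pi[t] = Pi
        rec_x[t] = efforts
        rec_pi[t] = pi
        rec_A[t] = [a.assets for a in agents]
        state = new_state

    return rec_N, rec_X, rec_G, rec_H, rec_Pi, rec_x, rec_pi, rec_A, rec_R


def run_game(
    params: GameParams,
    spec: ExperimentSpec,
    learner: LearnerConfig | None = None,
    reward_spec: RewardSpec | None = None,
    n_agents: int | None = None,
) -> SimulationResult:
    """Run one condition: ``spec.replicates`` seeded replicates of the loop.

    Deterministic given ``spec.base_seed``: replicate ``r`` seeds its own
    generator tree from ``base_seed + r``, with one independent stream per
    agent, so adding agents never perturbs the draws of existing ones.
    """
    learner = learner or LearnerConfig()
    reward_spec = reward_spec or RewardSpec()
    n = spec.n_agents if n_agents is None else n_agents

    frames = []
    agent_frames = []
    for rep in range(spec.replicates):
        rec = _run_replicate(params, spec, learner, reward_spec, rep, n)
        rec_N, rec_X, rec_G, rec_H, rec_Pi, rec_x, rec_pi, rec_A, rec_R = rec
        T = spec.rounds
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "t": np.arange(T),
                    "N": rec_N,
                    "X": rec_X,
                    "G": rec_G,
                    "H": rec_H,
                    "Pi": rec_Pi,
                }
            )
        )
        agent_frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "t": np.repeat(np.arange(T), n),
                    "agent": np.tile(np.arange(n), T),
                    "x": rec_x.ravel(),
                    "pi": rec_pi.ravel(),
                    "A": rec_A.ravel(),
                    "R": rec_R.ravel(),
                }
            )
        )
    traj = pd.concat(frames, ignore_index=True)
    agents = pd.concat(agent_frames, ignore_index=True)

    late = traj[traj["t"] >= spec.rounds - spec.late_window]
    final_A = agents[agents["t"] == spec.rounds - 1].groupby("replicate")["A"].mean()
    summary = {
        "n_agents": n,
        "late_mean_N": float(late["N"].mean()),
        "late_median_N": float(late.groupby("replicate")["N"].mean().median()),
        "final_mean_assets": float(final_A.mean()),
        "final_median_assets": float(final_A.median()),
    }
    return SimulationResult(trajectories=traj, agent_trajectories=agents, summary=summary)


def experiment_group_size(
    params: GameParams,
    spec: ExperimentSpec,
    learner: LearnerConfig | None = None,
    reward_spec: RewardSpec | None = None,
) -> pd.DataFrame:
    """Sweep the number of harvesters; summarize each group size.

    Returns one row per group size with late-window resource statistics,
    final per-agent assets, and a flag for conditions where the group can
    no longer maintain a profit (final mean assets below the endowment).
    """
    reward_spec = reward_spec or RewardSpec(w=0.5)
    rows = []
    for n in spec.n_sweep:
        res = run_game(params, spec, learner, reward_spec, n_agents=n)
        s = dict(res.summary)
        s["profit_maintained"] = s["final_mean_assets"] >= spec.initial_assets
        rows.append(s)
    return pd.DataFrame(rows)


def experiment_cost_weight(
    params: GameParams,
    spec: ExperimentSpec,
    learner: LearnerConfig | None = None,
) -> pd.DataFrame:
    """Sweep cost ``c`` and reward weight ``w`` on a grid (default 9 x 9).

    Each cell runs a full condition at the spec's group size and reports
    late-window mean stock and final per-agent assets, as a tidy table.
    """
    rows = []
    for c in spec.cost_values:
        cell_params = dc_replace(params, c=float(c))
        for w in spec.weight_values:
            res = run_game(
                cell_params, spec, learner, RewardSpec(w=float(w)), n_agents=spec.n_agents
            )
            rows.append(
                {
                    "c": float(c),
                    "w": float(w),
                    **{k: v for k, v in res.summary.items() if k != "n_agents"},
                }
            )
    return pd.DataFrame(rows)


def phase_series(
    result: SimulationResult,
    params: GameParams | None = None,
    late_window: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Per-round (growth, harvest) pairs for phase plotting, plus gap stats.

    Averages G and H over replicates at each round.  The statistics
    report how tightly the population tracks the growth curve late in the
    run: the late-window mean absolute harvest-growth gap, and (when game
    parameters are given) the late-window mean distance of the stock from
    the optimal equilibrium.
    """
    per_round = result.trajectories.groupby("t")[["G", "H", "N"]].mean().reset_index()
    T = int(per_round["t"].max()) + 1
    w = min(late_window, T)
    late = per_round[per_round["t"] >= T - w]
    stats = {
        "late_mean_abs_gap": float((late["H"] - late["G"]).abs().mean()),
        "early_mean_abs_gap": float(
            (per_round.head(w)["H"] - per_round.head(w)["G"]).abs().mean()
        ),
    }
    if params is not None:
        eq = equilibria(params)
        stats["late_mean_N_minus_E_optimal"] = float(late["N"].mean() - eq.E_optimal)
    return per_round[["t", "G", "H"]], stats
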