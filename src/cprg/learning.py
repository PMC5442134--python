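"""Harvesting agents: trend rewards and tabular Q-learning.

Agents never see magnitudes — only *trends*.  Each round the environment
emits two sign signals: the collective sustainability signal

    lambda = sign(net growth)   in {-1, 0, +1}

and the individual wealth signal

    xi = sign(pi_i)             in {-1, 0, +1}

which are blended into a single scalar reward

    R = w * xi + (1 - w) * lambda,       w in [0, 1].

``w`` weighs the *profit* trend; an optional convention switch flips the
blend for the opposite reading (``w`` on sustainability).  Action values
are learned with the standard tabular Watkins update over a discretized
resource level; action selection is epsilon-greedy with seeded random
tie-breaking.

An agent observes only the resource level, the cumulative effort, and its
own effort and payoff — never the other agents' actions or payoffs.  The
:class:`Observation` container enforces that contract structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import GameParams

__all__ = [
    "RewardSpec",
    "LearnerConfig",
    "AgentState",
    "Observation",
    "sustainability_signal",
    "profit_signal",
    "reward",
    "discretize_state",
    "action_grid",
    "select_action",
    "q_update",
]


@dataclass(frozen=True)
class RewardSpec:
    """Reward blend ``R = w * xi + (1 - w) * lambda``.

    ``weight_on`` selects which trend ``w`` multiplies: ``"profit"``
    (default, the formula as written above) or ``"sustainability"``
    (the mirrored convention, ``R = w * lambda + (1 - w) * xi``).
    """

    w: float = 0.5
    weight_on: str = "profit"

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")
        if self.weight_on not in ("profit", "sustainability"):
            raise ValueError(
                f"weight_on must be 'profit' or 'sustainability', got {self.weight_on!r}"
            )


@dataclass(frozen=True)
class LearnerConfig:
    """Tabular Q-learning hyperparameters.

    The defaults encode *restraint-first* exploration: action values
    start optimistic (``q_init`` above any reachable discounted return of
    the trend reward) and exact ties resolve toward the smallest effort,
    so a fresh population begins at minimum effort and works upward as
    optimism erodes.  This matters structurally: the expected cumulative
    effort of uniformly random play exceeds the largest sustainable
    effort at *every* stock level, and a depleted stock is absorbing, so
    a population that explores uniformly from the start destroys the
    resource before any values have been learned.  Set
    ``tie_break="random"`` for unbiased (seeded) tie resolution.
    """

    n_actions: int = 10
    n_state_bins: int = 10
    learning_rate: float = 0.1
    discount: float = 0.9
    epsilon_initial: float = 0.1
    epsilon_decay: float = 0.999
    epsilon_floor: float = 0.01
    q_init: float = 5.0
    tie_break: str = "smallest"

    def __post_init__(self) -> None:
        if self.n_actions < 2:
            raise ValueError(f"n_actions must be >= 2, got {self.n_actions}")
        if self.n_state_bins < 1:
            raise ValueError(f"n_state_bins must be >= 1, got {self.n_state_bins}")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError(f"learning_rate must be in (0, 1], got {self.learning_rate}")
        if not 0.0 <= self.discount < 1.0:
            raise ValueError(f"discount must be in [0, 1), got {self.discount}")
        for name in ("epsilon_initial", "epsilon_decay", "epsilon_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tie_break not in ("smallest", "random"):
            raise ValueError(
                f"tie_break must be 'smallest' or 'random', got {self.tie_break!r}"
            )

    def epsilon_at(self, t: int) -> float:
        """Exploration probability in round ``t`` (geometric decay, floored)."""
        return max(self.epsilon_floor, self.epsilon_initial * self.epsilon_decay**t)


@dataclass(frozen=True)
class Observation:
    """Everything an agent is allowed to see after a round — nothing else."""

    N: float
    X: float
    x_i: float
    pi_i: float
    Pi: float


@dataclass
class AgentState:
    """One harvester: identity, wealth, last move, and its learned values."""

    agent_id: int
    assets: float
    last_effort: float = 0.0
    last_payoff: float = 0.0
    q_table: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


def sustainability_signal(net_growth: float) -> int:
    """Trend of the resource: sign of the round's (unclamped) net growth."""
    return int(np.sign(net_growth))


def profit_signal(pi: float) -> int:
    """Trend of the agent's wealth: sign of its payoff."""
    return int(np.sign(pi))


def reward(xi: int, lam: int, spec: RewardSpec) -> float:
    """Blend the two trends into a scalar reward in [-1, 1]."""
    if spec.weight_on == "profit":
        return spec.w * xi + (1.0 - spec.w) * lam
    return spec.w * lam + (1.0 - spec.w) * xi


def discretize_state(N: float, config: LearnerConfig, params: GameParams) -> int:
    """Equal-width bin index of the stock level over [0, N_max].

    ``N = N_max`` belongs to the top bin (right edge included).
    """
    if N < 0 or N > params.N_max:
        raise ValueError(f"N must lie in [0, {params.N_max}], got {N}")
    return min(int(N / params.N_max * config.n_state_bins), config.n_state_bins - 1)


def action_grid(
    config: LearnerConfig, params: GameParams, n_agents: int
) -> np.ndarray:
    """Per-agent effort levels: evenly spaced over [X_min/n, X_max/n].

    Scaling the group bounds by 1/n makes symmetric play span exactly
    [X_min, X_max] in cumulative effort, for any group size.
    """
    if n_agents < 1:
        raise ValueError(f"n_agents must be >= 1, got {n_agents}")
    return np.linspace(
        params.X_min / n_agents, params.X_max / n_agents, config.n_actions
    )


def init_q_table(config: LearnerConfig) -> np.ndarray:
    """Fresh action-value table, shape (n_state_bins, n_actions)."""
    return np.full((config.n_state_bins, config.n_actions), config.q_init, dtype=float)


def select_action(
    agent: AgentState,
    state_bin: int,
    config: LearnerConfig,
    rng: np.random.Generator,
    epsilon: float | None = None,
) -> int:
    """Epsilon-greedy action index from the agent's Q row.

    With probability epsilon a uniformly random action; otherwise the
    greedy action.  Exact ties among maximal entries resolve per
    ``config.tie_break``: toward the smallest effort (default, so that
    untried actions are probed from restraint upward) or uniformly at
    random from the tied set (seeded).
    """
    eps = config.epsilon_initial if epsilon is None else epsilon
    if rng.random() < eps:
        return int(rng.integers(config.n_actions))
    row = agent.q_table[state_bin]
    if config.tie_break == "smallest":
        return int(np.argmax(row))
    best = np.flatnonzero(row == row.max())
    if best.size == 1:
        return int(best[0])
    return int(rng.choice(best))


def q_update(
    agent: AgentState,
    state_bin: int,
    action: int,
    reward_value: float,
    next_state_bin: int,
    config: LearnerConfig,
) -> AgentState:
    """Watkins update: ``Q(s,a) += eta * (R + gamma * max_a' Q(s',a') - Q(s,a))``.

    Mutates only the single (state, action) entry; returns the agent for
    chaining.
    """
    q = agent.q_table
    target = reward_value + config.discount * q[next_state_bin].max()
    q[state_bin, action] += config.learning_rate * (target - q[state_bin, action])
    return agent
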