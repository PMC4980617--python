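"""Ising-type peer influence on a binary health behaviour.

Each agent carries a binary smoking state ``s_i`` and an exogenous smoking
disposition ``gamma_i`` in [0, 1].  Once per step, every agent that had at
least one encounter reconsiders its behaviour.  The switching probability is
bilinear in the disposition and the smoking share ``f`` of its interaction
neighbourhood, scaled by the noise amplitude ``C``:

    non-smoker starts:  p = C * gamma * f
    smoker stops:       p = C * (1 - gamma) * (1 - f)

so committed agents (gamma near 0 or 1) are nearly immune to peer pressure
and ``p <= C`` always.  Partial-model variants replace the local field:
``mean_field`` uses the global prevalence S/N for ``f``; ``network`` ignores
peers entirely and sets ``s_i = Theta(gamma_i - 0.5)`` deterministically;
``interaction`` uses the same rule as ``coupled`` (it differs in the contact
layer, not here).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._graphs import as_adjacency
from .errors import ConfigurationError

#: Recognised behaviour-selection variants.
VARIANTS = ("coupled", "network", "interaction", "mean_field")


@dataclass
class AgentPopulation:
    """Per-agent degree preference ``q_i``, disposition ``gamma_i(t)`` and
    smoking state ``s_i(t)``."""

    degree_preference: np.ndarray
    disposition: np.ndarray
    smoking_state: np.ndarray

    def __post_init__(self) -> None:
        n = self.degree_preference.shape[0]
        if self.disposition.shape != (n,) or self.smoking_state.shape != (n,):
            raise ConfigurationError("population arrays must share one length")
        if np.any(self.degree_preference < 1) or np.any(self.degree_preference > n - 1):
            raise ConfigurationError("degree preferences must lie in [1, N-1]")
        if np.any((self.disposition < 0) | (self.disposition > 1)):
            raise ConfigurationError("dispositions must lie in [0, 1]")

    @property
    def n_agents(self) -> int:
        return self.degree_preference.shape[0]

    @property
    def smoker_count(self) -> int:
        return int(self.smoking_state.sum())


@dataclass(frozen=True)
class InfluenceParams:
    """``switch_scale`` = C, the amplitude of the equilibrium behavioural
    noise; ``variant`` selects the (partial) model."""

    switch_scale: float = 0.1
    variant: str = "coupled"

    def __post_init__(self) -> None:
        if not 0.0 <= self.switch_scale <= 1.0:
            raise ConfigurationError("switch_scale must be in [0, 1]")
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )


def sample_degree_preferences(
    n: int, mean: float = 10.0, sd: float = 3.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Discretised-Gaussian degree preferences, truncated to [1, N-1]."""
    rng = np.random.default_rng() if rng is None else rng
    q = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.clip(q, 1, n - 1)


def initialise_behaviour(disposition) -> np.ndarray:
    """Heaviside initialisation: smoke iff gamma >= 0.5 (Theta(0) = 1)."""
    gamma = np.asarray(disposition, dtype=float)
    if np.any((gamma < 0) | (gamma > 1)):
        raise ConfigurationError("dispositions must lie in [0, 1]")
    return (gamma >= 0.5).astype(np.int8)


def switching_probability(state, disposition, peer_smoking_fraction, switch_scale: float = 0.1):
    """Probability of flipping the behaviour this step (vectorised)."""
    s = np.asarray(state)
    gamma = np.asarray(disposition, dtype=float)
    f = np.asarray(peer_smoking_fraction, dtype=float)
    p = np.where(s == 0, switch_scale * gamma * f, switch_scale * (1.0 - gamma) * (1.0 - f))
    return p if p.ndim else float(p)


def update_behaviours(
    pop: AgentPopulation,
    interaction,
    params: InfluenceParams,
    rng: np.random.Generator,
) -> AgentPopulation:
    """One synchronous behaviour-update sweep.

    All switching probabilities are evaluated on the previous states, then the
    independent Bernoulli flips are applied at once.  Agents without any
    interaction this step keep their state — except under the ``network``
    variant, which tracks the disposition threshold deterministically and
    ignores the interaction layer.
    """
    if params.variant == "network":
        return replace(pop, smoking_state=initialise_behaviour(pop.disposition))

    adj = as_adjacency(interaction)
    states = pop.smoking_state
    degree = adj.sum(axis=1)
    active = degree > 0

    if params.variant == "mean_field":
        f = np.full(pop.n_agents, states.mean(dtype=float))
    else:  # coupled / interaction: local smoking share among peers
        smokers_nearby = adj @ states.astype(np.int64)
        f = smokers_nearby / np.maximum(degree, 1)

    p = switching_probability(states, pop.disposition, f, params.switch_scale)
    flips = active & (rng.random(pop.n_agents) < p)
    new_states = np.where(flips, 1 - states, states).astype(np.int8)
    return replace(pop, smoking_state=new_states)
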