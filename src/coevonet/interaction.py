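"""Distance-dependent interaction probabilities and the fast interaction layer.

Encounters between agents are sampled afresh every time step from a
probability matrix Pi(t) built on shortest-path distances in the (slow)
contact network.  Reflecting the empirical "three degrees of separation" decay
of social influence, the probability falls off exponentially with distance,
normalised by the number of pairs in each distance shell so that direct
neighbours always interact with probability ``beta``:

    pi_ij = beta                                            d_ij = 1
    pi_ij = clip(beta * L(1)/L(d) * exp(-(d-1)/delta),
                 eps, beta)                                 1 < d_ij < inf
    pi_ij = eps                                             d_ij = inf

``L(d)`` counts unordered node pairs at distance exactly ``d``.  The positive
baseline ``eps`` allows incidental meetings between distant or disconnected
agents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from ._graphs import as_adjacency
from .errors import ConfigurationError, InternalModelError


@dataclass(frozen=True)
class InteractionParams:
    """``scale`` = beta (direct-neighbour probability), ``baseline`` = eps,
    ``decay_distance`` = delta (e-folding distance of the decay)."""

    scale: float = 0.8
    baseline: float = 0.03
    decay_distance: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline <= self.scale <= 1.0:
            raise ConfigurationError("require 0 < baseline <= scale <= 1")
        if self.decay_distance <= 0:
            raise ConfigurationError("decay_distance must be positive")


@dataclass
class DistanceSummary:
    """All-pairs shortest-path lengths plus per-shell pair counts.

    ``distances`` is symmetric with zero diagonal and ``inf`` for pairs in
    different components.  ``shell_counts[d]`` is the number of *unordered*
    pairs at distance exactly ``d``.
    """

    distances: np.ndarray
    shell_counts: dict[int, int]

    @property
    def n_agents(self) -> int:
        return self.distances.shape[0]


def shortest_path_distances(contact) -> DistanceSummary:
    """BFS all-pairs distances of the contact network with shell tallies."""
    adj = as_adjacency(contact)
    dist = shortest_path(csr_array(adj), method="D", unweighted=True)
    iu = np.triu_indices(dist.shape[0], k=1)
    upper = dist[iu]
    finite = upper[np.isfinite(upper)]
    values, counts = np.unique(finite.astype(np.int64), return_counts=True)
    return DistanceSummary(
        distances=dist,
        shell_counts={int(d): int(c) for d, c in zip(values, counts)},
    )


def interaction_probabilities(
    dist: DistanceSummary, params: InteractionParams = InteractionParams()
) -> np.ndarray:
    """Interaction probability matrix Pi from a distance summary."""
    d = dist.distances
    beta, eps, delta = params.scale, params.baseline, params.decay_distance
    pi = np.full(d.shape, eps)  # default: disconnected pairs
    shells = dist.shell_counts
    l1 = shells.get(1, 0)
    for shell, count in shells.items():
        if count <= 0:  # impossible by construction; guard anyway
            raise InternalModelError(f"occupied shell d={shell} with zero count")
        mask = d == shell
        if shell == 1:
            pi[mask] = beta
        else:
            value = beta * (l1 / count) * math.exp(-(shell - 1) / delta)
            # sparse far shells can over-normalise; probabilities stay in
            # [eps, beta] with beta reserved for direct neighbours
            pi[mask] = min(beta, max(eps, value))
    np.fill_diagonal(pi, 0.0)
    return pi


def sample_interaction_network(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample the interaction adjacency: each unordered pair independently
    with its entry of ``probs``.  Returns a symmetric boolean matrix."""
    probs = np.asarray(probs, dtype=float)
    n = probs.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    iu = np.triu_indices(n, k=1)
    adj[iu] = rng.random(iu[0].size) < probs[iu]
    adj |= adj.T
    return adj
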