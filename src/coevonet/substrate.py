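"""Small-world substrate and time-invariant background proximity.

The position of agents in social space is anchored by a static *background
proximity* matrix ``B``: pairwise similarities in [floor, 1] that stand in for
everything the model does not resolve explicitly (family ties, socio-economic
status, shared history).  ``B`` is derived from shortest-path distances on a
Watts–Strogatz small-world graph — the canonical generator for the high
clustering and short path lengths of empirical social networks — perturbed by
symmetric uniform noise and clipped from below:

    B_ij = max(floor, 1 - c_d * (d_ij - 1) - c_zeta * zeta_ij)

where ``d_ij`` is the substrate distance, ``c_d`` the proximity lost per
degree of separation, and ``zeta_ij = zeta_ji ~ U[0, 1)`` drawn once at
initialisation (``B`` is time-invariant).  The floor encodes that beyond a few
degrees of separation no further meaningful distinction exists; disconnected
pairs sit exactly at the floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from ._graphs import as_adjacency
from .errors import ConfigurationError

DEFAULT_FLOOR = 0.2


@dataclass(frozen=True)
class SubstrateParams:
    """Watts–Strogatz substrate: ``n_agents`` nodes, even ``mean_degree``,
    rewiring probability ``rewiring_prob``."""

    n_agents: int
    mean_degree: int = 10
    rewiring_prob: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ConfigurationError("n_agents must be at least 2")
        if self.mean_degree <= 0 or self.mean_degree % 2 != 0:
            raise ConfigurationError(
                f"mean_degree must be a positive even integer, got {self.mean_degree}"
            )
        if self.mean_degree >= self.n_agents:
            raise ConfigurationError("mean_degree must be smaller than n_agents")
        if not 0.0 <= self.rewiring_prob <= 1.0:
            raise ConfigurationError("rewiring_prob must be in [0, 1]")


@dataclass
class BackgroundProximity:
    """Symmetric background-proximity matrix with zero diagonal.

    Off-diagonal entries lie in ``[floor, 1]``.
    """

    values: np.ndarray
    distance_decrement: float
    noise_amplitude: float
    floor: float = DEFAULT_FLOOR

    @property
    def n_agents(self) -> int:
        return self.values.shape[0]


def generate_ws_network(params: SubstrateParams) -> nx.Graph:
    """Seeded Watts–Strogatz graph with exactly ``n_agents*mean_degree/2``
    edges (rewiring preserves the edge count)."""
    return nx.watts_strogatz_graph(
        params.n_agents, params.mean_degree, params.rewiring_prob, seed=params.seed
    )


def substrate_distances(substrate) -> np.ndarray:
    """All-pairs shortest-path lengths (``inf`` for disconnected pairs)."""
    adj = as_adjacency(substrate)
    return shortest_path(csr_array(adj), method="D", unweighted=True)


def build_background_proximity(
    substrate,
    decrement: float = 0.25,
    noise_amp: float = 0.1,
    floor: float = DEFAULT_FLOOR,
    seed: int = 0,
) -> BackgroundProximity:
    """Background proximity from substrate distances plus symmetric noise.

    Parameters
    ----------
    substrate
        networkx graph or adjacency matrix of the small-world substrate.
    decrement
        Proximity lost per degree of social separation (``c_d``).
    noise_amp
        Amplitude of the uniform pair noise (``c_zeta``).
    floor
        Lower clip; disconnected pairs land exactly here.
    seed
        Seeds the one-off noise draw; the result is deterministic.
    """
    if decrement <= 0:
        raise ConfigurationError("decrement must be positive")
    if noise_amp < 0:
        raise ConfigurationError("noise_amp must be nonnegative")
    if not 0.0 <= floor <= 1.0:
        raise ConfigurationError("floor must be in [0, 1]")

    dist = substrate_distances(substrate)
    n = dist.shape[0]
    rng = np.random.default_rng(seed)
    zeta = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    zeta[iu] = rng.random(iu[0].size)
    zeta += zeta.T

    with np.errstate(invalid="ignore"):
        raw = 1.0 - decrement * (dist - 1.0) - noise_amp * zeta
    values = np.maximum(raw, floor)  # -inf for disconnected pairs -> floor
    np.fill_diagonal(values, 0.0)
    return BackgroundProximity(
        values=values, distance_decrement=decrement, noise_amplitude=noise_amp, floor=floor
    )
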