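"""Time-dependent proximity and the ranked, reciprocal contact update.

Social proximity mixes the static background with current behaviour
co-occurrence,

    P_ij(t) = alpha * [s_i == s_j] + (1 - alpha) * B_ij,

so adopting a new behaviour shifts an agent's proximities by ``alpha`` — with
the defaults, roughly the background-proximity gain of moving one to two
degrees closer in the substrate.

The contact network is the slow layer.  Each agent ranks the union of its
current contacts and this step's interaction partners by proximity
(descending; ties broken by ascending agent index) and keeps the top ``q_i``
as its preferred list.  An edge exists iff each agent appears on the other's
list (reciprocity): ties are lost actively (ego drops alter) or passively
(alter drops ego).  No "second-best" refill happens after the reciprocity
pruning — unfilled capacity waits for future interactions.
"""

from __future__ import annotations

import numpy as np

from ._graphs import as_adjacency
from .errors import ConfigurationError
from .substrate import BackgroundProximity


def proximity_matrix(background, states, alpha: float = 0.2) -> np.ndarray:
    """Convex combination of behaviour match and background proximity."""
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError("alpha must be in [0, 1]")
    b = background.values if isinstance(background, BackgroundProximity) else np.asarray(background, dtype=float)
    s = np.asarray(states)
    match = s[:, None] == s[None, :]
    p = alpha * match + (1.0 - alpha) * b
    np.fill_diagonal(p, 0.0)
    return p


def _ranked_reciprocal(candidates: np.ndarray, proximity: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Edges surviving the top-q ranking of ``candidates`` plus reciprocity."""
    n = proximity.shape[0]
    key = np.where(candidates, proximity, -np.inf)
    # stable sort of -key: descending proximity, ties by ascending index
    order = np.argsort(-key, axis=1, kind="stable")
    ranks = np.empty((n, n), dtype=np.int64)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(n), (n, n)), axis=1)
    preferred = candidates & (ranks < np.asarray(q)[:, None])
    return preferred & preferred.T


def update_contact_network(previous, interaction, proximity: np.ndarray, q) -> np.ndarray:
    """One contact-network update step.

    Candidates for agent ``i`` are its previous contacts plus this step's
    interaction partners, so new ties can only form between agents that
    interacted in the same step while any existing tie may be displaced.
    Returns a symmetric boolean adjacency with ``degree(i) <= q_i``.
    """
    prev = as_adjacency(previous)
    inter = as_adjacency(interaction)
    candidates = prev | inter
    np.fill_diagonal(candidates, False)
    return _ranked_reciprocal(candidates, np.asarray(proximity, dtype=float), np.asarray(q))


def initial_contact_network(proximity: np.ndarray, q) -> np.ndarray:
    """Initial contact network from a fully connected interaction network:
    every other agent is a candidate."""
    proximity = np.asarray(proximity, dtype=float)
    n = proximity.shape[0]
    candidates = np.ones((n, n), dtype=bool)
    np.fill_diagonal(candidates, False)
    return _ranked_reciprocal(candidates, proximity, np.asarray(q))
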