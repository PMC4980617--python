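"""Observables: prevalence, eigenvector centrality, conditional smoking
probability by social distance, and bootstrap summaries.

The conditional probability ``P(d)`` is the probability that a randomly drawn
ego smokes given a randomly drawn alter at shortest-path distance exactly
``d`` smokes — a clustering diagnostic: behavioural homophily raises it at
short distances.  Eigenvector centrality locates agents in dense,
well-connected parts of the contact network; tracking its mean separately for
smokers and non-smokers exposes the marginalization of the remaining
minority.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg

from ._graphs import as_adjacency
from .interaction import DistanceSummary, shortest_path_distances


def prevalence(states) -> float:
    """Fraction of smokers, S/N."""
    return float(np.asarray(states).mean(dtype=float))


def eigenvector_centrality(contact, normalization: str = "max") -> np.ndarray:
    """Leading-eigenvector components of the contact adjacency matrix.

    Computed with a dense symmetric eigensolver restricted to the largest
    eigenpair; components are nonnegative and rescaled so the maximum equals
    1 (``normalization="l2"`` gives a unit-norm vector instead).  An empty
    graph yields all zeros with a warning.
    """
    adj = as_adjacency(contact).astype(float)
    n = adj.shape[0]
    if not adj.any():
        warnings.warn("eigenvector centrality of an empty graph is all-zero")
        return np.zeros(n)
    _, vec = linalg.eigh(adj, subset_by_index=[n - 1, n - 1])
    v = np.abs(vec[:, 0])  # Perron vector of the dominant component
    if normalization == "max":
        return v / v.max()
    if normalization == "l2":
        return v / np.linalg.norm(v)
    raise ValueError(f"unknown normalization {normalization!r}")


def conditional_smoking_probability(contact, states, d: int, per_ego: bool = False) -> float:
    """P(ego smokes | alter at distance ``d`` smokes); NaN if undefined.

    ``contact`` may be a graph, an adjacency matrix, a distance matrix (float,
    ``inf`` for disconnected pairs) or a :class:`DistanceSummary`.  The
    default pools all ordered (ego, alter) pairs; ``per_ego=True`` instead
    averages the ego smoking indicator over egos that have at least one
    smoking alter in the shell.
    """
    if d < 1:
        raise ValueError("social distance d must be >= 1")
    if isinstance(contact, DistanceSummary):
        dist = contact.distances
    else:
        arr = np.asarray(contact)
        if arr.ndim == 2 and np.issubdtype(arr.dtype, np.floating) and arr.max(initial=0) > 1:
            dist = arr  # already a distance matrix
        else:
            dist = shortest_path_distances(contact).distances
    s = np.asarray(states).astype(bool)
    shell = dist == d
    conditioning = shell & s[None, :]  # alter j smokes
    if per_ego:
        has_smoking_alter = conditioning.any(axis=1)
        if not has_smoking_alter.any():
            return float("nan")
        return float(s[has_smoking_alter].mean(dtype=float))
    total = conditioning.sum()
    if total == 0:
        return float("nan")
    return float((conditioning & s[:, None]).sum() / total)


def bootstrap_ci(
    run_values,
    level: float = 0.95,
    reps: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of across-run values."""
    values = np.asarray(run_values, dtype=float)
    if values.size < 2:
        warnings.warn("bootstrap over a single run yields a degenerate interval")
        v = float(values[0]) if values.size else float("nan")
        return (v, v)
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.integers(0, values.size, size=(reps, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def bootstrap_bands(
    run_matrix: np.ndarray,
    levels: tuple[float, ...] = (0.95, 0.99),
    reps: int = 2000,
    rng: np.random.Generator | None = None,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Per-column percentile bootstrap bands for an (n_runs, n_steps) matrix.

    All levels share one set of resamples, so wider bands contain narrower
    ones by construction.  NaN cells (undefined metrics in some runs) are
    excluded via NaN-aware means.
    """
    rng = np.random.default_rng() if rng is None else rng
    run_matrix = np.asarray(run_matrix, dtype=float)
    n_runs = run_matrix.shape[0]
    idx = rng.integers(0, n_runs, size=(reps, n_runs))
    # resample means via a run-count weight matrix: avoids materialising
    # the (reps, n_runs, n_steps) cube
    weights = np.zeros((reps, n_runs))
    for r in range(reps):
        np.add.at(weights[r], idx[r], 1.0)
    valid = np.isfinite(run_matrix)
    filled = np.where(valid, run_matrix, 0.0)
    sums = weights @ filled
    counts = weights @ valid.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    bands = {}
    for level in levels:
        lo, hi = np.nanquantile(means, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
        bands[level] = (lo, hi)
    return bands
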