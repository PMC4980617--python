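"""Exogenous normative forcing of the disposition distribution.

Dispositions are collectively dragged toward a moving target density — the
parabolic family

    y(x; t) = a(t) * (b(t) - x)^2 + c(t),   x in [0, 1],

pinned down by three constraints: unit integral, y(0) = C1 and y(1) = C2(t).
With C2 = C1 the density is symmetric and bimodal (peaks at both ends, a
balanced split of low and high dispositions); lowering C2 towards C_f tilts
it into a quasi-unimodal shape favouring low dispositions.  A linear schedule
C2(t): C1 -> C_f over the forcing window emulates gradually shifting social
norms (health campaigns, changing public opinion).

Individual dispositions follow a Markov process: each forcing step adds
sign-directed log-normal noise, weighted linearly by the local deviation of
the empirical CDF from the target CDF, iterating until a one-sample
Kolmogorov–Smirnov test accepts the sample at significance level
``1 - ks_alpha`` (90% by default).  The population-level distribution is thus
externally controlled while each agent's disposition drifts smoothly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

_PPF_GRID = 4097


def parabolic_density_params(c1: float, c2: float) -> tuple[float, float, float]:
    """Solve (a, b, c) of ``y(x) = a(b - x)^2 + c`` from the unit-integral and
    endpoint constraints ``y(0) = c1``, ``y(1) = c2``.

    The constraint system reduces to ``a(2b - 1) = c1 - c2`` and
    ``a(b - 1/3) = c1 - 1``, which is solved in closed form.  Raises
    :class:`ConfigurationError` if the resulting density dips below zero.
    """
    if c1 < 0 or c2 < 0:
        raise ConfigurationError(f"endpoint densities must be nonnegative (C1={c1}, C2={c2})")
    if math.isclose(c1, c2):
        b = 0.5
        a = 6.0 * (c1 - 1.0)
        c = (3.0 - c1) / 2.0
    elif math.isclose(c1, 1.0):
        b = 1.0 / 3.0
        a = 3.0 * (c2 - c1)
        c = c1 - a * b * b
    else:
        r = (c1 - c2) / (c1 - 1.0)
        if math.isclose(r, 2.0):
            raise ConfigurationError(
                f"no parabolic density satisfies C1={c1}, C2={c2} (degenerate system)"
            )
        b = (1.0 - r / 3.0) / (2.0 - r)
        a = (c1 - 1.0) / (b - 1.0 / 3.0)
        c = c1 - a * b * b
    interior_min = c if (a > 0 and 0.0 <= b <= 1.0) else min(c1, c2)
    if interior_min < -1e-12:
        raise ConfigurationError(
            f"parabolic density is negative on [0, 1] for C1={c1}, C2={c2}"
        )
    return a, b, c


@dataclass(frozen=True)
class ParabolicDensity:
    """Target density ``y(x) = a(b - x)^2 + c`` on [0, 1]."""

    a: float
    b: float
    c: float

    @classmethod
    def from_endpoint_values(cls, c1: float, c2: float) -> "ParabolicDensity":
        return cls(*parabolic_density_params(c1, c2))

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * (self.b - x) ** 2 + self.c

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        x = np.clip(x, 0.0, 1.0)
        return self.a * (self.b**3 - (self.b - x) ** 3) / 3.0 + self.c * x

    def ppf(self, u):
        """Inverse CDF by monotone grid interpolation (cubic CDF)."""
        grid = np.linspace(0.0, 1.0, _PPF_GRID)
        cdf = self.cdf(grid)
        cdf[0], cdf[-1] = 0.0, 1.0
        return np.interp(np.asarray(u, dtype=float), cdf, grid)


@dataclass(frozen=True)
class ForcingNoiseParams:
    """Noise model of the disposition Markov chain.

    ``step_scale`` is the median of the log-normal step magnitude before
    deviation weighting; ``log_sd`` its log-scale shape; ``ks_alpha`` the KS
    acceptance level (p >= ks_alpha stops the inner loop).
    """

    step_scale: float = 0.05
    log_sd: float = 0.5
    ks_alpha: float = 0.10
    max_inner_iterations: int = 500

    def __post_init__(self) -> None:
        if self.step_scale <= 0 or self.log_sd <= 0 or self.max_inner_iterations <= 0:
            raise ConfigurationError("noise parameters must be positive")
        if not 0.0 < self.ks_alpha < 1.0:
            raise ConfigurationError("ks_alpha must be in (0, 1)")


def linear_forcing_schedule(c1: float, c_final: float, steps: int) -> np.ndarray:
    """C2 values for forcing steps 1..steps, linear from C1 down to C_f."""
    if steps < 0:
        raise ConfigurationError("steps must be nonnegative")
    return np.linspace(c1, c_final, steps + 1)[1:]


def sample_initial_dispositions(
    n: int, density: ParabolicDensity, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sample of ``n`` dispositions from the target density."""
    return density.ppf(rng.random(n))


def _empirical_cdf_at(values: np.ndarray) -> np.ndarray:
    """Mid-rank empirical CDF evaluated at the sample's own points."""
    n = values.size
    out = np.empty(n)
    out[np.argsort(values, kind="stable")] = (np.arange(n) + 0.5) / n
    return out


def evolve_dispositions(
    previous: np.ndarray,
    density: ParabolicDensity,
    noise: ForcingNoiseParams = ForcingNoiseParams(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One forcing step: perturb dispositions until they are KS-consistent
    with the target density.

    Each inner round moves every disposition by ``sign * |dev| * eta`` where
    ``dev`` is the empirical-minus-target CDF deviation at the agent's own
    value (its sign points toward the nearest density deficit) and ``eta`` is
    log-normal with median ``step_scale``.  Values are clipped to [0, 1].

    The transformation is applied at every call — at least one noise round
    happens even when the sample already passes the KS test — so the
    dispositions keep drifting as a genuine Markov chain instead of freezing
    at the acceptance boundary; without this, a monotonically moving target
    leaves the sample pinned one full KS tolerance behind it.
    """
    rng = np.random.default_rng() if rng is None else rng
    gamma = np.asarray(previous, dtype=float).copy()
    if np.any((gamma < 0) | (gamma > 1)):
        raise ConfigurationError("dispositions must lie in [0, 1]")
    mu = math.log(noise.step_scale)
    for rounds in range(noise.max_inner_iterations):
        if rounds > 0 and stats.kstest(gamma, density.cdf).pvalue >= noise.ks_alpha:
            return gamma
        dev = _empirical_cdf_at(gamma) - density.cdf(gamma)
        eta = rng.lognormal(mu, noise.log_sd, gamma.size)
        gamma = np.clip(gamma + np.sign(dev) * np.abs(dev) * eta, 0.0, 1.0)
    logger.warning(
        "disposition forcing: KS criterion not met after %d iterations "
        "(p=%.3g); returning best effort",
        noise.max_inner_iterations,
        stats.kstest(gamma, density.cdf).pvalue,
    )
    return gamma
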