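"""Triangular distributions: the uncertainty model for every stochastic input.

Every uncertain model input is a three-parameter triangular distribution
``Tri(minimum, mode, maximum)`` — the standard way to encode an expert's
lower bound, best estimate and upper bound in decision-analytic models.
Sampling is by inverse-CDF transform of a single uniform stream, which
makes runs reproducible from one seed and makes rank-based sensitivity
binning well defined.

The degenerate case ``minimum == mode == maximum`` is a legal point mass,
so deterministic point-estimate runs and Monte Carlo runs share one code
path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["TriangularDist", "tri_mean", "tri_var", "tri_ppf", "tri_cdf", "tri_sample"]


@dataclass(frozen=True)
class TriangularDist:
    """Triangular distribution on ``[minimum, maximum]`` with peak ``mode``.

    Parameters are dimensionless proportions in the models of this
    package, but the mathematics places no such restriction.
    """

    minimum: float
    mode: float
    maximum: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mode <= self.maximum):
            raise ValueError(
                f"triangular parameters must satisfy minimum <= mode <= maximum, "
                f"got ({self.minimum}, {self.mode}, {self.maximum})"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.minimum == self.maximum

    @property
    def mean(self) -> float:
        return (self.minimum + self.mode + self.maximum) / 3.0

    @property
    def var(self) -> float:
        a, b, c = self.minimum, self.mode, self.maximum
        return (a * a + b * b + c * c - a * b - a * c - b * c) / 18.0

    def ppf(self, u):
        """Quantile function (inverse CDF), vectorised over ``u``.

        ``u`` must lie in [0, 1].  A point mass returns its location for
        every ``u``.
        """
        u = np.asarray(u, dtype=float)
        if np.any((u < 0.0) | (u > 1.0)):
            raise ValueError("quantile argument u must lie in [0, 1]")
        a, b, c = self.minimum, self.mode, self.maximum
        if self.is_degenerate:
            return np.broadcast_to(np.float64(a), u.shape).copy() if u.shape else np.float64(a)
        span = c - a
        # CDF mass to the left of the mode; 0 when mode == minimum
        f_mode = (b - a) / span
        left = a + np.sqrt(u * span * (b - a))
        right = c - np.sqrt((1.0 - u) * span * (c - b))
        x = np.where(u <= f_mode, left, right)
        return x if x.shape else np.float64(x)

    def cdf(self, x):
        """Distribution function, vectorised over ``x``."""
        x = np.asarray(x, dtype=float)
        a, b, c = self.minimum, self.mode, self.maximum
        if self.is_degenerate:
            out = np.where(x < a, 0.0, 1.0)
            return out if out.shape else np.float64(out)
        span = c - a
        with np.errstate(divide="ignore", invalid="ignore"):
            left = np.where(b > a, (x - a) ** 2 / (span * (b - a)), 0.0)
            right = np.where(c > b, 1.0 - (c - x) ** 2 / (span * (c - b)), 1.0)
        out = np.where(x <= b, left, right)
        out = np.clip(out, 0.0, 1.0)
        out = np.where(x <= a, 0.0, np.where(x >= c, 1.0, out))
        return out if out.shape else np.float64(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values by applying the ppf to ``rng``'s uniforms."""
        if n < 1:
            raise ValueError(f"sample size must be >= 1, got {n}")
        u = rng.random(n)
        return np.asarray(self.ppf(u), dtype=float)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.minimum, self.mode, self.maximum)

    @classmethod
    def point(cls, value: float) -> "TriangularDist":
        """A degenerate triangular: point mass at ``value``."""
        return cls(value, value, value)


def tri_mean(dist: TriangularDist) -> float:
    """Mean of a triangular distribution, ``(min + mode + max) / 3``."""
    return dist.mean


def tri_var(dist: TriangularDist) -> float:
    """Variance, ``(a² + b² + c² − ab − ac − bc) / 18``."""
    return dist.var


def tri_ppf(u, dist: TriangularDist):
    """Quantile function of ``dist`` evaluated at ``u`` in [0, 1]."""
    return dist.ppf(u)


def tri_cdf(x, dist: TriangularDist):
    return dist.cdf(x)


def tri_sample(dist: TriangularDist, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` independent draws from ``dist`` using ``rng``'s uniform stream."""
    return dist.sample(n, rng)
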