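"""Cohort model of cigar users prevented by deterred initiation and continuation.

For one cohort of 18-year-olds the chain is:

    base = cohort size x current-cigar-use prevalence
                       x fraction who initiated with a flavored product

    initiates prevented  = base x d          (d = initiation reduction)
    continuing prevented = base x (1 - d) x c (c = continuing-use reduction)
    total prevented      = base x [d + (1 - d) c]

The initiation reduction ``d`` is the fraction of would-be flavored-cigar
initiates who never try cigars once flavored products are unavailable.
The continuing-use reduction ``c`` comes from the adjusted prevalence
ratio (PR) of current regular use between flavored and non-flavored
initiates: removing flavors moves flavored initiates to the non-flavored
continuation rate, a relative reduction of ``1 - 1/PR`` (35.9% at the
published PR of 1.56).

Full precision is carried through the chain; rounding (persons to the
nearest 1,000, percentages to one decimal) happens only in reports.  The
headline 37.1% prevalence reduction is reproduced by the unrounded chain
(0.37103) but not by rounded intermediates (112,000 / 302,400 = 0.3704).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import TriangularDist
from .errors import ScenarioValidationError

__all__ = [
    "InitiationScenario",
    "continuing_reduction_from_ratio",
    "flavored_initiate_base",
    "users_prevented",
    "prevalence_reduction",
    "US_INITIATION",
]

#: Tolerance for the load-time consistency check between the configured
#: continuing-reduction mode and 1 - 1/prevalence_ratio (three decimals).
_MODE_RATIO_TOL = 5e-4


def continuing_reduction_from_ratio(prevalence_ratio: float) -> float:
    """Relative reduction in continuing use implied by a prevalence ratio.

    ``1 - 1/PR``: the drop in current regular use when flavored-product
    initiates instead continue at the non-flavored initiates' rate.
    """
    if prevalence_ratio <= 0:
        raise ValueError(f"prevalence ratio must be > 0, got {prevalence_ratio}")
    return 1.0 - 1.0 / prevalence_ratio


def flavored_initiate_base(cohort_size, prevalence, flavored_fraction):
    """Current cigar users in the cohort who initiated with a flavored product.

    Triple product, unrounded (4,200,000 x 0.072 x 0.654 = 197,769.6).
    """
    n = np.asarray(cohort_size, dtype=float)
    p = np.asarray(prevalence, dtype=float)
    f = np.asarray(flavored_fraction, dtype=float)
    if np.any(n < 0) or np.any(p < 0) or np.any(f < 0):
        raise ValueError("all inputs to flavored_initiate_base must be non-negative")
    if np.any(p > 1) or np.any(f > 1):
        raise ValueError("proportions passed to flavored_initiate_base must be <= 1")
    out = n * p * f
    return out if out.shape else float(out)


def users_prevented(base, initiation_reduction, continuing_reduction):
    """(initiates prevented, continuing users prevented, total), unrounded.

    The two deterrence routes partition the flavored-initiate base: a
    fraction ``d`` never starts; of the remaining ``1 - d``, a fraction
    ``c`` does not progress to continuing use.  Vectorised over draws.
    """
    b = np.asarray(base, dtype=float)
    d = np.asarray(initiation_reduction, dtype=float)
    c = np.asarray(continuing_reduction, dtype=float)
    if np.any((d < 0) | (d > 1)) or np.any((c < 0) | (c > 1)):
        raise ValueError("reduction proportions must lie in [0, 1]")
    initiates = b * d
    continuing = b * (1.0 - d) * c
    total = initiates + continuing
    if total.shape:
        return initiates, continuing, total
    return float(initiates), float(continuing), float(total)


def prevalence_reduction(total_prevented, current_users):
    """Relative reduction in current cigar-use prevalence in the cohort."""
    if np.any(np.asarray(current_users) <= 0):
        raise ValueError("current_users must be > 0")
    out = np.asarray(total_prevented, dtype=float) / np.asarray(current_users, dtype=float)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class InitiationScenario:
    """Inputs for the cohort initiation/continuation chain.

    The default prevalence is the 7.2% every-day/some-day measure; the
    13.1% past-30-day measure is a supported alternate scenario (it
    makes the defaults conservative), not the default.

    The continuing-use reduction is stored as a distribution in its own
    right — mode 1 - 1/PR, min and max from the PR confidence bounds
    (1.29, 1.87) — and is validated, not silently re-derived: loading
    fails if its mode disagrees with 1 - 1/prevalence_ratio beyond the
    third decimal.
    """

    cohort_size: float = 4_200_000.0
    current_use_prevalence: float = 0.072
    flavored_initiation_fraction: float = 0.654
    initiation_reduction: TriangularDist = field(
        default_factory=lambda: TriangularDist(0.0, 0.325, 0.65))
    continuing_prevalence_ratio: float = 1.56
    continuing_reduction: TriangularDist = field(
        default_factory=lambda: TriangularDist(0.225, 0.359, 0.465))

    model_kind = "initiation"
    primary_output = "total_prevented"

    def __post_init__(self) -> None:
        problems = []
        if not self.cohort_size > 0:
            problems.append(f"cohort_size must be > 0, got {self.cohort_size}")
        for name in ("current_use_prevalence", "flavored_initiation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        if not self.continuing_prevalence_ratio > 0:
            problems.append(
                f"continuing_prevalence_ratio must be > 0, got {self.continuing_prevalence_ratio}")
        for name in ("initiation_reduction", "continuing_reduction"):
            d = getattr(self, name)
            if not (0.0 <= d.minimum and d.maximum <= 1.0):
                problems.append(f"{name} support must lie in [0, 1], got {d.as_tuple()}")
        if self.continuing_prevalence_ratio > 0:
            implied = continuing_reduction_from_ratio(self.continuing_prevalence_ratio)
            if abs(self.continuing_reduction.mode - implied) > _MODE_RATIO_TOL:
                problems.append(
                    f"continuing_reduction mode {self.continuing_reduction.mode} is "
                    f"inconsistent with 1 - 1/{self.continuing_prevalence_ratio} = "
                    f"{implied:.4f} (must agree to three decimals)")
        if problems:
            raise ScenarioValidationError(problems)

    @property
    def current_users(self) -> float:
        """Total current cigar users in the cohort (flavored or not)."""
        return self.cohort_size * self.current_use_prevalence

    @property
    def base(self) -> float:
        """Flavored-initiate base of the chain, unrounded."""
        return flavored_initiate_base(
            self.cohort_size, self.current_use_prevalence,
            self.flavored_initiation_fraction)

    def distributions(self) -> dict[str, TriangularDist]:
        """Stochastic inputs in sampling order."""
        return {
            "initiation_reduction": self.initiation_reduction,
            "continuing_reduction": self.continuing_reduction,
        }

    def evaluate(self, draws: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        initiates, continuing, total = users_prevented(
            self.base, draws["initiation_reduction"], draws["continuing_reduction"])
        return {
            "initiates_prevented": initiates,
            "continuing_prevented": continuing,
            "total_prevented": total,
        }

    def point_estimate(self) -> dict[str, float]:
        """Deterministic chain at modes, plus the prevalence reduction."""
        modes = {k: np.float64(d.mode) for k, d in self.distributions().items()}
        out = {k: float(v) for k, v in self.evaluate(modes).items()}
        out["prevalence_reduction"] = prevalence_reduction(
            out["total_prevented"], self.current_users)
        return out

    def analytic_mean(self) -> float:
        """E[total prevented] under independent triangular inputs.

        Uses E[d + (1-d)c] = E[d] + (1 - E[d]) E[c], valid because the
        two reductions are sampled independently.
        """
        ed = self.initiation_reduction.mean
        ec = self.continuing_reduction.mean
        return self.base * (ed + (1.0 - ed) * ec)


#: The published nationwide US cohort scenario (all defaults).
US_INITIATION = InitiationScenario()
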