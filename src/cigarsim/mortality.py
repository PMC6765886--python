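"""Mortality benefit from increased cessation among existing cigar smokers.

The model is a three-factor product chain:

    deaths avoided / year
        = attributable deaths among exclusive regular cigar smokers
        x reduction in total cigar consumption under the flavor ban
        x fraction of that reduction that is complete cessation

Only exclusive cigar smokers' attributable deaths (5200/year in the
default US scenario) enter the model: dual users of cigars and
cigarettes may switch rather than quit, so no benefit is credited to
them.  No mortality benefit is credited to smokers who cut back without
quitting.  The model is static: prevalence, and hence attributable
mortality absent the policy, is assumed constant, so the output reads as
deaths avoided per year at steady state.

The two behavioural factors are uncertain and carried as triangular
distributions; evaluating the chain at their modes gives the
deterministic main estimate (5200 x 30% x 50% = 780).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import TriangularDist
from .errors import ScenarioValidationError

__all__ = [
    "MortalityScenario",
    "deaths_avoided",
    "flavored_market_share_bound",
    "US_MORTALITY",
]


def deaths_avoided(attributable_deaths, consumption_reduction, cessation_fraction):
    """Premature deaths avoided per year: the triple product, unrounded.

    Accepts scalars or arrays (vectorised over Monte Carlo draws).
    Raises on negative inputs or proportions above 1.
    """
    a = np.asarray(attributable_deaths, dtype=float)
    x = np.asarray(consumption_reduction, dtype=float)
    y = np.asarray(cessation_fraction, dtype=float)
    if np.any(a < 0) or np.any(x < 0) or np.any(y < 0):
        raise ValueError("all inputs to deaths_avoided must be non-negative")
    if np.any(x > 1) or np.any(y > 1):
        raise ValueError("proportions passed to deaths_avoided must be <= 1")
    out = a * x * y
    return out if out.shape else float(out)


def flavored_market_share_bound(machine_made_share: float, flavored_retail_share: float) -> float:
    """Estimated flavored share of all US cigar sales.

    The product of the machine-made share of cigars sold (hand-made
    cigars are generally not flavored) and the flavored share of
    machine-made retail sales.  This product motivates the upper bound
    of the consumption-reduction distribution; the configured bound
    itself remains the headline 45% rather than this product.
    """
    for name, v in (("machine_made_share", machine_made_share),
                    ("flavored_retail_share", flavored_retail_share)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return machine_made_share * flavored_retail_share


@dataclass(frozen=True)
class MortalityScenario:
    """Inputs for the cessation-mortality chain.

    attributable_deaths
        Annual premature deaths among exclusive regular cigar smokers
        (regular = 15+ of the past 30 days).
    consumption_reduction
        Proportional reduction in total cigar consumption caused by the
        flavor ban, as a triangular distribution.
    cessation_fraction
        Proportion of the consumption reduction that is complete
        cessation (vs. cutting back), as a triangular distribution.
    machine_made_share, flavored_retail_share
        Market-structure constants behind the consumption-reduction
        upper bound; informative only, they do not enter the chain.
    """

    attributable_deaths: float = 5200.0
    consumption_reduction: TriangularDist = field(
        default_factory=lambda: TriangularDist(0.15, 0.30, 0.45))
    cessation_fraction: TriangularDist = field(
        default_factory=lambda: TriangularDist(0.25, 0.50, 0.75))
    machine_made_share: float = 0.92
    flavored_retail_share: float = 0.521

    model_kind = "mortality"
    primary_output = "deaths_avoided"

    def __post_init__(self) -> None:
        problems = []
        if not self.attributable_deaths > 0:
            problems.append(
                f"attributable_deaths must be > 0, got {self.attributable_deaths}")
        for name in ("machine_made_share", "flavored_retail_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        for name in ("consumption_reduction", "cessation_fraction"):
            d = getattr(self, name)
            if not (0.0 <= d.minimum and d.maximum <= 1.0):
                problems.append(f"{name} support must lie in [0, 1], got {d.as_tuple()}")
        if problems:
            raise ScenarioValidationError(problems)

    def distributions(self) -> dict[str, TriangularDist]:
        """Stochastic inputs in sampling order."""
        return {
            "consumption_reduction": self.consumption_reduction,
            "cessation_fraction": self.cessation_fraction,
        }

    def evaluate(self, draws: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Model outputs for one vector of draws per stochastic input."""
        return {
            "deaths_avoided": deaths_avoided(
                self.attributable_deaths,
                draws["consumption_reduction"],
                draws["cessation_fraction"],
            )
        }

    def point_estimate(self) -> dict[str, float]:
        """Deterministic chain with every uncertain input at its mode."""
        modes = {k: np.float64(d.mode) for k, d in self.distributions().items()}
        return {k: float(v) for k, v in self.evaluate(modes).items()}

    def analytic_mean(self) -> float:
        """E[deaths avoided] under independent triangular inputs."""
        return (self.attributable_deaths
                * self.consumption_reduction.mean
                * self.cessation_fraction.mean)


#: The published nationwide US scenario (all defaults).
US_MORTALITY = MortalityScenario()
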