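"""Random, structurally valid scenarios with analytically known means.

Each generated scenario is paired with the closed-form expectation of
its primary output under independent triangular inputs:

* mortality:   deaths x E[X] x E[Y]
* initiation:  base x (E[D] + (1 - E[D]) E[C])

The initiation form uses E[D + (1-D)C] = E[D] + (1 - E[D]) E[C], valid
because the two reductions are sampled independently; a correlated
extension would have to revisit it.  The pairs drive the engine-vs-
analytic property tests: the Monte Carlo mean of every generated
scenario must recover its paired expectation to CLT tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import TriangularDist
from .initiation import InitiationScenario, continuing_reduction_from_ratio
from .mortality import MortalityScenario

__all__ = ["SyntheticSpec", "generate_scenarios"]

#: ((min_lo, min_hi), (mode_lo, mode_hi), (max_lo, max_hi)) for one triangular
TriRange = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

_FULL: TriRange = ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Ranges from which random scenarios are drawn.

    Defaults bracket the published US inputs by roughly an order of
    magnitude either side so the generated family exercises the models
    well away from the single published configuration.  Collapsing every
    range to a point reproduces that configuration exactly.

    ``tri_ranges`` optionally pins the sampling window of each
    triangular parameter, keyed by input name; absent inputs draw three
    sorted uniforms on [0, 1].  ``degenerate_rate`` is the probability
    that an unpinned triangular collapses to a point mass, exercising
    the shared deterministic code path.
    """

    seed: int = 0
    n_scenarios: int = 50
    kind: str = "mortality"  # or "initiation"
    deaths_range: tuple[float, float] = (500.0, 50_000.0)
    cohort_range: tuple[float, float] = (100_000.0, 10_000_000.0)
    prevalence_range: tuple[float, float] = (0.01, 0.30)
    flavored_fraction_range: tuple[float, float] = (0.2, 0.9)
    prevalence_ratio_range: tuple[float, float] = (1.05, 2.5)
    tri_ranges: dict[str, TriRange] = field(default_factory=dict)
    degenerate_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("mortality", "initiation"):
            raise ValueError(f"kind must be mortality or initiation, got {self.kind!r}")
        if self.n_scenarios < 1:
            raise ValueError("n_scenarios must be >= 1")
        if not 0.0 <= self.degenerate_rate <= 1.0:
            raise ValueError("degenerate_rate must be in [0, 1]")


def _random_tri(rng: np.random.Generator, spec: SyntheticSpec, name: str) -> TriangularDist:
    """A random valid triangular for the named input."""
    ranges = spec.tri_ranges.get(name)
    if ranges is None:
        if rng.random() < spec.degenerate_rate:
            return TriangularDist.point(float(rng.uniform(0.0, 1.0)))
        ranges = _FULL
    a, b, c = sorted(float(rng.uniform(lo, hi)) for lo, hi in ranges)
    return TriangularDist(a, b, c)


def _mortality(rng: np.random.Generator, spec: SyntheticSpec):
    s = MortalityScenario(
        attributable_deaths=float(rng.uniform(*spec.deaths_range)),
        consumption_reduction=_random_tri(rng, spec, "consumption_reduction"),
        cessation_fraction=_random_tri(rng, spec, "cessation_fraction"),
        machine_made_share=float(rng.uniform(0.0, 1.0)),
        flavored_retail_share=float(rng.uniform(0.0, 1.0)),
    )
    return s, s.analytic_mean()


def _initiation(rng: np.random.Generator, spec: SyntheticSpec):
    ratio = float(rng.uniform(*spec.prevalence_ratio_range))
    mode = continuing_reduction_from_ratio(ratio)
    # min/max bracket the ratio-implied mode inside [0, 1), mirroring the
    # confidence-bound construction of the published scenario
    lo = float(rng.uniform(max(0.0, mode - 0.2), mode))
    hi = float(rng.uniform(mode, min(0.99, mode + 0.2)))
    s = InitiationScenario(
        cohort_size=float(rng.uniform(*spec.cohort_range)),
        current_use_prevalence=float(rng.uniform(*spec.prevalence_range)),
        flavored_initiation_fraction=float(rng.uniform(*spec.flavored_fraction_range)),
        initiation_reduction=_random_tri(rng, spec, "initiation_reduction"),
        continuing_prevalence_ratio=ratio,
        continuing_reduction=TriangularDist(lo, mode, hi),
    )
    return s, s.analytic_mean()


def generate_scenarios(spec: SyntheticSpec) -> list[tuple[object, float]]:
    """``n_scenarios`` random valid scenarios, each with its analytic mean."""
    rng = np.random.default_rng(spec.seed)
    make = _mortality if spec.kind == "mortality" else _initiation
    return [make(rng, spec) for _ in range(spec.n_scenarios)]
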