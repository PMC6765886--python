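# Methods

## The models

`cigarsim` quantifies the projected population-health benefit of a
nationwide US prohibition of characterizing flavors (fruit, candy, etc.,
other than tobacco) in cigars. Two static decision-analytic chains are
modelled; both are products of a small number of aggregate constants and
uncertain behavioural proportions.

**Cessation mortality.** Annual premature deaths avoided among existing
exclusive cigar smokers:

    deaths_avoided = A · X · Y

where `A` is the attributable-mortality burden (default 5200 premature
deaths/year among exclusive regular cigar smokers, regular = 15+ of the
past 30 days), `X` is the proportional reduction in total cigar
consumption caused by the ban, and `Y` the fraction of that reduction
that is complete cessation rather than cutting back. Modelling
assumptions: only exclusive cigar smokers receive credit (dual users may
switch products instead of quitting); no mortality benefit accrues to
smokers who cut back without quitting; and prevalence — hence `A` — is
assumed constant absent the policy, so the output is a steady-state
annual rate, not a multi-year projection.

**Cohort initiation.** Current cigar users prevented in one cohort of
18-year-olds:

    base  = N · p · f                      (flavored-initiate base)
    total = base · [d + (1 − d) · c]

with `N` the cohort size (4.2 million), `p` current cigar-use prevalence
at 18 (7.2%, the every-day/some-day measure), `f` the fraction of
current users who initiated with a flavored product (65.4%), `d` the
fraction of would-be flavored initiates deterred from ever trying cigars,
and `c` the reduction in continuing use among non-deterred initiates.
`c` derives from the adjusted prevalence ratio `PR` of current regular
use between flavored and non-flavored initiates: removing flavors moves
flavored initiates to the non-flavored continuation rate, a relative
reduction of `1 − 1/PR` (35.9% at PR = 1.56). The two deterrence routes
partition the base, so `total ≤ base` always. Dividing `total` by the
cohort's current users `N · p` gives the relative prevalence reduction
(37.1% at the main estimates).

The alternate past-30-day prevalence measure (13.1%) is a supported
scenario variant; it rescales the chain but leaves the relative
prevalence reduction unchanged.

## Uncertainty model

Every uncertain proportion is a triangular distribution
`Tri(min, mode, max)` encoding a lower bound, best estimate and upper
bound:

| input | distribution | provenance of bounds |
|---|---|---|
| consumption reduction `X` | Tri(0.15, 0.30, 0.45) | observed sales drops after local flavor bans (15% New York City with partial compliance, ~31% Providence); 45% ≈ flavored share of all cigar sales |
| cessation fraction `Y` | Tri(0.25, 0.50, 0.75) | tax-increase studies: about half of sales reductions come from quitting |
| initiation reduction `d` | Tri(0, 0.325, 0.65) | midpoint of 35% (current non-flavored initiation share) and 100% (complete substitution), i.e. 67.5% still initiate → 32.5% deterred; bounds symmetric about it |
| continuing reduction `c` | Tri(0.225, 0.359, 0.465) | `1 − 1/PR` at PR = 1.56 and its 95% CI (1.29, 1.87) |

The flavored-share construction multiplies the machine-made share of US
cigar sales (92%) by the flavored share of machine-made retail sales
(52.1%); the product is 0.479, conventionally rounded down to the 45%
upper bound, and the package keeps both: `flavored_market_share_bound`
returns the exact product while the configured bound stays 0.45.

The continuing-reduction distribution is stored explicitly rather than
re-derived: loading fails if its mode disagrees with `1 − 1/PR` beyond
the third decimal, so a scenario file cannot silently drift from its
prevalence ratio.

## Monte Carlo engine

Inputs are sampled independently across inputs and iterations — no
correlation structure is asserted — by inverse-CDF transform of a single
seeded uniform stream (numpy `default_rng`). The inverse CDF of the
triangular is the piecewise square-root inversion; degenerate point-mass
distributions are legal, so deterministic and stochastic runs share one
code path. Sampling through one stream makes every run bit-reproducible
from its seed and makes rank-based sensitivity binning well defined.

Summaries are the arithmetic mean and a central quantile-based
prediction interval (default mass 0.90: the empirical 5th and 95th
percentiles, linear-interpolation estimator). At 1000+ iterations the
quantile-estimator choice moves the bounds by less than Monte Carlo
noise. Default `n_iterations` is 1000, matching the published analysis;
internal convergence checks use 10^5–10^6 iterations and a brute-force
oracle of 2×10^6 direct product draws through numpy's own triangular
sampler, a route fully independent of the package's ppf.

Per-iteration input draws are retained on the result object so
sensitivity analysis conditions on input bins without re-running.

## Sensitivity analysis

The published one-way ranges cannot come from substituting an input's
extremes into the chain (that gives 390–1170 for either mortality
input). They are closely matched by **conditional outer-bin means**:
rank iterations by one input, cut into ten equal-count bins, and average
the output in the lowest and highest bins. Under independence this
factorizes, e.g. for the mortality model

    E[A·X·Y | X in outer decile] = A · E[Y] · E[X | outer decile],

and the closed-form outer-decile conditional means of Tri(0.15, 0.30,
0.45) give ≈506 and ≈1054 — within a few percent of the published
522–1057 and 509–1055. This reconstruction (decile-conditional means,
`n_bins = 10`, configurable) is therefore the default method; the exact
algorithm inside the original commercial risk-analysis software is not
public, so agreement is expected only within Monte Carlo tolerance.
Because widening the bin count makes the outer bins more extreme, the
reported range grows with `n_bins`. The deterministic one-at-a-time
method (input at min/max, others at modes) is always reported alongside
so the reconstruction's assumptions stay visible.

## Numerical conventions

- Proportions are fractions in [0, 1] everywhere; percent formatting is
  a reporting concern.
- Full precision is carried through every chain; publication rounding
  (persons to the nearest 1,000, deaths to the nearest integer,
  percentages to one decimal) happens only in the report layer. This is
  load-bearing: the 37.1% prevalence reduction is reproduced by the
  unrounded chain (0.37103) but not by rounded intermediates
  (112,000 / 302,400 = 0.3704).
- Validation gathers *all* invariant violations before raising, so a
  bad scenario file reports every offending key at once.
- Degenerate inputs: a point-mass triangular collapses simulation,
  sensitivity and point estimate to the same number.

## Synthetic scenarios

`cigarsim.synthetic` generates random, structurally valid scenarios
paired with closed-form expected outputs — mortality `A·E[X]·E[Y]`,
initiation `base·(E[d] + (1 − E[d])·E[c])`, the latter valid only
because `d` and `c` are independent (a correlated extension must revisit
it). Default parameter ranges bracket the published US inputs by
roughly an order of magnitude either side (deaths 500–50,000, cohorts
0.1–10 million, prevalence 1–30%, prevalence ratio 1.05–2.5), chosen so
the property tests exercise the models well away from the single
published configuration; collapsing every range to a point reproduces
that configuration exactly. About 10% of unpinned triangulars collapse
to point masses to keep the degenerate path covered. The generator
emulates only the aggregate-constant structure of the analysis; it does
not simulate survey microdata, so passing tests demonstrate correctness
of the propagation machinery, not of the survey-derived input values
themselves.

## Known limitations and open reconciliations

- The published initiation-simulation mean (108,846 at 1000 iterations)
  sits ~2% below the analytic expectation of the stated inputs
  (197,769.6 × [0.325 + 0.675 × 0.34967] ≈ 110,950); whether that
  reflects the original run's particular seed at n = 1000 or an
  undocumented input variant is unknowable from the published numbers.
  This package's large-n results converge to the analytic value, and the
  same ~2–5% offset appears in the lower prediction-interval bound
  (converged ≈79,800 vs published 75,914).
- Single cohort, single year: no multi-cohort accumulation, no
  life-years, no morbidity, no product substitution.
- Problem sizes: validation simulations use 10^5 iterations (10^6 for
  sampler-moment checks, 2×10^6 for the brute-force oracle), sizes at
  which Monte Carlo noise is well below every tolerance of interest
  while runs stay interactive.
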