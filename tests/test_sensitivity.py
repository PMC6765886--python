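"""One-way sensitivity: conditional-decile means and one-at-a-time ranges."""

import numpy as np
import pytest
from scipy import integrate, stats

from cigarsim import (
    MortalityScenario,
    SimulationSettings,
    TriangularDist,
    conditional_mean_range,
    one_at_a_time,
    run_simulation,
    tornado,
)


def triangular_conditional_mean(d: TriangularDist, q0: float, q1: float) -> float:
    """Closed-form E[X | q0 < F(X) <= q1] by numeric integration of x·f(x),
    built on scipy's triangular distribution — independent of the package."""
    scale = d.maximum - d.minimum
    ref = stats.triang((d.mode - d.minimum) / scale, loc=d.minimum, scale=scale)
    lo, hi = ref.ppf(q0), ref.ppf(q1)
    val, _ = integrate.quad(lambda x: x * ref.pdf(x), lo, hi)
    return val / (q1 - q0)


@pytest.mark.parametrize(
    "input_name, expected",
    [
        ("consumption_reduction", (390.0, 1170.0)),  # 5200 x {0.15, 0.45} x 0.50
        ("cessation_fraction", (390.0, 1170.0)),     # 5200 x 0.30 x {0.25, 0.75}
    ],
)
def test_one_at_a_time_mortality(us_mortality, input_name, expected):
    assert one_at_a_time(us_mortality, input_name) == pytest.approx(expected)


def test_one_at_a_time_degenerate_input_collapses():
    s = MortalityScenario(cessation_fraction=TriangularDist.point(0.5))
    assert one_at_a_time(s, "cessation_fraction") == (pytest.approx(780.0),
                                                      pytest.approx(780.0))


def test_one_at_a_time_unknown_input(us_mortality):
    with pytest.raises(KeyError):
        one_at_a_time(us_mortality, "no_such_input")


def test_conditional_mean_matches_independence_factorization(us_mortality):
    """Low/high decile means equal 5200 · E[Y] · E[X | outer decile] to 3 SE."""
    n = 200_000
    r = run_simulation(us_mortality, SimulationSettings(n_iterations=n, seed=17))
    entry = conditional_mean_range(r, "consumption_reduction", n_bins=10)
    X = us_mortality.consumption_reduction
    ey = us_mortality.cessation_fraction.mean
    for observed, (q0, q1) in [(entry.low_conditional_mean, (0.0, 0.1)),
                               (entry.high_conditional_mean, (0.9, 1.0))]:
        expected = 5200 * ey * triangular_conditional_mean(X, q0, q1)
        idx = np.argsort(r.inputs["consumption_reduction"])
        bin_idx = idx[: n // 10] if q0 == 0.0 else idx[-n // 10:]
        se = r.values[bin_idx].std() / np.sqrt(n // 10)
        assert observed == pytest.approx(expected, abs=3 * se)


def test_zero_effect_input_gives_flat_range():
    """Conditioning on an input the model ignores leaves low ≈ high."""
    s = MortalityScenario(consumption_reduction=TriangularDist.point(0.30))
    r = run_simulation(s, SimulationSettings(n_iterations=50_000, seed=23))
    entry = conditional_mean_range(r, "consumption_reduction", n_bins=10)
    # the conditioned input is constant, so the bins are arbitrary subsets
    assert entry.low_conditional_mean == pytest.approx(entry.high_conditional_mean, rel=0.02)


def test_more_bins_widen_the_range(us_mortality):
    r = run_simulation(us_mortality, SimulationSettings(n_iterations=100_000, seed=29))
    spreads = [conditional_mean_range(r, "consumption_reduction", n_bins=k).spread
               for k in (4, 10, 25)]
    assert spreads[0] < spreads[1] < spreads[2]


def test_bin_count_and_name_guards(us_mortality):
    r = run_simulation(us_mortality, SimulationSettings(n_iterations=100, seed=1))
    with pytest.raises(KeyError):
        conditional_mean_range(r, "nope")
    with pytest.raises(ValueError):
        conditional_mean_range(r, "consumption_reduction", n_bins=1)
    with pytest.raises(ValueError):
        conditional_mean_range(r, "consumption_reduction", n_bins=20)  # < 10 per bin


def test_tornado_reports_both_methods_for_every_input(us_initiation):
    r = run_simulation(us_initiation, SimulationSettings(n_iterations=5000, seed=31))
    records = tornado(r, us_initiation, n_bins=10)
    assert len(records) == 4
    methods = {(rec["input_name"], rec["method"]) for rec in records}
    assert methods == {
        ("initiation_reduction", "conditional_decile_mean"),
        ("initiation_reduction", "one_at_a_time"),
        ("continuing_reduction", "conditional_decile_mean"),
        ("continuing_reduction", "one_at_a_time"),
    }
    for rec in records:
        assert rec["low"] <= rec["high"]
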