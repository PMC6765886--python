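"""Triangular distribution mathematics and the seeded sampler."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cigarsim import TriangularDist, tri_mean, tri_ppf, tri_sample, tri_var

# proportions on a 6-decimal grid: keeps degenerate triples reachable while
# avoiding sub-precision support widths that underflow any CDF arithmetic
finite = st.floats(min_value=0.0, max_value=1.0, allow_nan=False).map(
    lambda v: round(v, 6))


def sorted_triple():
    return st.tuples(finite, finite, finite).map(sorted)


def scipy_equiv(d: TriangularDist) -> stats.rv_continuous:
    """Independent reference distribution for non-degenerate triangulars."""
    scale = d.maximum - d.minimum
    return stats.triang((d.mode - d.minimum) / scale, loc=d.minimum, scale=scale)


@pytest.mark.parametrize(
    "triple, expected_mean",
    [
        ((0.15, 0.30, 0.45), 0.30),        # symmetric: mean = mode
        ((0.225, 0.359, 0.465), 0.349667),  # (a+b+c)/3
        ((0.5, 0.5, 0.5), 0.5),            # point mass
    ],
)
def test_mean_closed_form(triple, expected_mean):
    assert tri_mean(TriangularDist(*triple)) == pytest.approx(expected_mean, abs=5e-7)


@pytest.mark.parametrize(
    "u, triple, expected",
    [
        (0.0, (0.15, 0.30, 0.45), 0.15),      # infimum of support
        (0.5, (0.15, 0.30, 0.45), 0.30),      # median of symmetric = mode
        (0.1, (0.25, 0.50, 0.75), 0.36180339887498947),  # solve (x-a)^2/((c-a)(b-a)) = u
        (1.0, (0.25, 0.50, 0.75), 0.75),
    ],
)
def test_ppf_examples(u, triple, expected):
    assert tri_ppf(u, TriangularDist(*triple)) == pytest.approx(expected, abs=1e-12)


def test_ppf_rejects_u_outside_unit_interval():
    d = TriangularDist(0.1, 0.2, 0.3)
    with pytest.raises(ValueError):
        tri_ppf(-0.01, d)
    with pytest.raises(ValueError):
        tri_ppf(1.01, d)


def test_invalid_ordering_rejected():
    with pytest.raises(ValueError):
        TriangularDist(0.5, 0.3, 0.6)
    with pytest.raises(ValueError):
        TriangularDist(0.1, 0.4, 0.2)


@given(triple=sorted_triple(), u=st.floats(min_value=0.0, max_value=1.0))
@settings(deadline=None, max_examples=200)
def test_ppf_matches_reference_implementation(triple, u):
    """Our piecewise inverse CDF agrees with scipy's for every valid shape."""
    a, b, c = triple
    d = TriangularDist(a, b, c)
    if d.is_degenerate:
        assert tri_ppf(u, d) == a
    else:
        assert tri_ppf(u, d) == pytest.approx(scipy_equiv(d).ppf(u), abs=1e-9)


@given(triple=sorted_triple())
@settings(deadline=None, max_examples=100)
def test_ppf_nondecreasing_and_cdf_roundtrip(triple):
    d = TriangularDist(*triple)
    u = np.linspace(0.0, 1.0, 101)
    x = d.ppf(u)
    assert np.all(np.diff(x) >= -1e-12)
    if not d.is_degenerate:
        # F(ppf(u)) = u on the open support
        inner = u[1:-1]
        assert d.cdf(d.ppf(inner)) == pytest.approx(inner, abs=1e-9)


def test_sampler_moments_converge(rng):
    """Empirical mean and variance match the closed forms to CLT tolerance."""
    d = TriangularDist(0.15, 0.30, 0.45)
    n = 1_000_000
    x = tri_sample(d, n, rng)
    se_mean = np.sqrt(tri_var(d) / n)
    assert x.mean() == pytest.approx(tri_mean(d), abs=3 * se_mean)
    assert x.var() == pytest.approx(tri_var(d), rel=0.02)
    assert x.min() >= d.minimum and x.max() <= d.maximum


def test_sampler_is_deterministic_given_seed():
    d = TriangularDist(0.2, 0.4, 0.9)
    a = tri_sample(d, 1000, np.random.default_rng(7))
    b = tri_sample(d, 1000, np.random.default_rng(7))
    assert np.array_equal(a, b)


def test_point_mass_sampling(rng):
    d = TriangularDist(0.3, 0.3, 0.3)
    assert np.array_equal(tri_sample(d, 5, rng), np.full(5, 0.3))


def test_sample_size_must_be_positive(rng):
    with pytest.raises(ValueError):
        tri_sample(TriangularDist(0, 0.5, 1), 0, rng)


@pytest.mark.parametrize("triple", [(0.0, 0.0, 1.0), (0.0, 1.0, 1.0)])
def test_edge_modes_sample_within_support(triple, rng):
    """mode == min and mode == max are valid shapes with finite draws."""
    d = TriangularDist(*triple)
    x = tri_sample(d, 10_000, rng)
    assert np.isfinite(x).all()
    assert x.min() >= d.minimum and x.max() <= d.maximum
    assert x.mean() == pytest.approx(tri_mean(d), abs=0.02)
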