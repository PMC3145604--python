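"""Spline basis tests against independent brute-force transcriptions of the
truncated-power formulas, plus the structural identities the cure
restriction relies on."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexcure.splines import (KnotSet, RestrictedCubicSpline, basis_backward,
                              basis_derivative, basis_standard, orthogonalize,
                              resolve_knots, SENSITIVITY_KNOT_RULES)
from flexcure.splines import InvalidKnotsError


# -- independent oracles: literal transcriptions of the truncated-power
#    formulas, deliberately scalar and loop-based ---------------------------

def _plus3(u):
    return u ** 3 if u > 0 else 0.0


def oracle_standard(x, knots):
    K = len(knots)
    k1, kK = knots[0], knots[-1]
    out = [x]
    for j in range(2, K):
        kj = knots[j - 1]
        lam = (kK - kj) / (kK - k1)
        out.append(_plus3(x - kj) - lam * _plus3(x - k1) - (1 - lam) * _plus3(x - kK))
    return out


def oracle_backward(x, knots):
    K = len(knots)
    k1, kK = knots[0], knots[-1]
    out = [x]
    for j in range(2, K):
        kj = knots[K - j]  # knots in reversed order
        mu = (kj - k1) / (kK - k1)
        out.append(_plus3(kj - x) - mu * _plus3(kK - x) - (1 - mu) * _plus3(k1 - x))
    return out


@pytest.mark.parametrize("fn,oracle", [(basis_standard, oracle_standard),
                                       (basis_backward, oracle_backward)])
def test_basis_matches_bruteforce(fn, oracle, rng):
    knots = np.sort(rng.uniform(-2, 3, size=6))
    ks = KnotSet(knots)
    xs = rng.uniform(-4, 5, size=200)
    got = fn(xs, ks)
    want = np.array([oracle(x, knots) for x in xs])
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_fixed_point_values():
    # standard basis, knots {0, 0.5, 1} at x = 0.75: hand-checkable case
    ks = KnotSet([0.0, 0.5, 1.0])
    got = basis_standard(0.75, ks)[0]
    lam = (1.0 - 0.5) / 1.0
    want2 = 0.25 ** 3 - lam * 0.75 ** 3  # (x-kK)_+ term vanishes
    assert got[0] == 0.75
    assert got[1] == pytest.approx(want2, abs=1e-15)
    # backward basis, knots {0, 0.4, 1.2} at x = 0.2
    ks = KnotSet([0.0, 0.4, 1.2])
    got = basis_backward(0.2, ks)[0]
    mu = (0.4 - 0.0) / 1.2
    want2 = (0.4 - 0.2) ** 3 - mu * (1.2 - 0.2) ** 3
    assert got[1] == pytest.approx(want2, rel=1e-12)


def test_standard_basis_zero_at_and_below_first_knot():
    ks = KnotSet([-1.0, 0.0, 0.7, 2.0])
    b = basis_standard([-1.0, -3.5], ks)
    assert b[0, 0] == -1.0
    assert np.all(b[:, 1:] == 0.0)


def test_two_knots_is_pure_linear():
    ks = KnotSet([0.0, 1.0])
    b = basis_standard([0.3, 2.2], ks)
    assert b.shape == (2, 1)
    np.testing.assert_array_equal(b[:, 0], [0.3, 2.2])


def test_backward_basis_zero_at_and_beyond_last_knot():
    ks = KnotSet([-0.5, 0.3, 1.0, 1.8])
    b = basis_backward([1.8, 2.8, 50.0], ks)
    assert np.all(b[:, 1:] == 0.0)


def test_backward_restriction_gives_constant_beyond_last_knot(rng):
    # zero linear coefficient => s(x) constant on [kK, inf)
    knots = np.sort(rng.uniform(-1, 2, size=5))
    ks = KnotSet(knots)
    gam = np.concatenate([[0.0], rng.normal(size=3)])
    xs = np.array([knots[-1], knots[-1] + 0.5, knots[-1] + 40.0])
    s = basis_backward(xs, ks) @ gam
    assert s[0] == s[1] == s[2]


@pytest.mark.parametrize("direction", ["standard", "backward"])
def test_derivative_matches_finite_differences(direction, rng):
    knots = np.sort(rng.uniform(-2, 2, size=5))
    ks = KnotSet(knots)
    xs = rng.uniform(-3, 3, size=100)
    h = 1e-6
    fn = basis_standard if direction == "standard" else basis_backward
    fd = (fn(xs + h, ks) - fn(xs - h, ks)) / (2 * h)
    an = basis_derivative(xs, ks, direction)
    np.testing.assert_allclose(an, fd, atol=1e-6)
    assert np.all(an[:, 0] == 1.0)


def test_backward_derivative_zero_beyond_last_knot():
    ks = KnotSet([0.0, 0.5, 1.0])
    d = basis_derivative([1.0, 3.0], ks, "backward")
    assert np.all(d[:, 1:] == 0.0)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10 ** 6))
def test_continuity_at_knots_for_random_coefficients(seed):
    """s, s' and s'' are continuous at every knot; s'' = 0 outside [k1,kK]."""
    r = np.random.default_rng(seed)
    knots = np.sort(r.uniform(-2, 2, size=5))
    if np.min(np.diff(knots)) < 1e-3:
        return
    ks = KnotSet(knots)
    gam = r.normal(size=4)
    direction = "backward" if seed % 2 else "standard"
    fn = basis_standard if direction == "standard" else basis_backward
    h = 1e-5
    for k in knots:
        left, right = k - h, k + h
        s = fn(np.array([left, right]), ks) @ gam
        d = basis_derivative(np.array([left, right]), ks, direction) @ gam
        assert abs(s[1] - s[0]) < 1e-3  # ~ |s'| * 2h
        assert abs(d[1] - d[0]) < 1e-3
        # second derivative continuity via FD of the analytic first derivative
        dd = (basis_derivative(np.array([left + h, right + h]), ks, direction)
              - basis_derivative(np.array([left - h, right - h]), ks, direction)
              ) / (2 * h) @ gam
        assert abs(dd[1] - dd[0]) < 1e-2
    # linearity outside the boundary knots: second derivative ~ 0
    for x in (knots[0] - 1.0, knots[-1] + 1.0):
        dd = ((basis_derivative(np.array([x + h]), ks, direction)
               - basis_derivative(np.array([x - h]), ks, direction)) / (2 * h) @ gam)
        assert abs(dd[0]) < 1e-8


def test_invalid_knots_raise():
    with pytest.raises(InvalidKnotsError):
        KnotSet([1.0, 0.5])
    with pytest.raises(InvalidKnotsError):
        KnotSet([1.0, 1.0, 2.0])
    with pytest.raises(InvalidKnotsError):
        KnotSet([1.0])
    with pytest.raises(InvalidKnotsError):
        KnotSet([0.0, np.inf])


def test_orthogonalize_roundtrip(rng):
    x = rng.uniform(-1, 2, size=300)
    raw = basis_standard(x, KnotSet([-0.5, 0.2, 0.9, 1.5]))
    T, R = orthogonalize(raw)
    # columns orthogonal to each other and to the constant
    G = np.column_stack([np.ones(len(x)), T])
    gram = G.T @ G
    np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
    # invert the recorded transform: [1|raw] = Q_full @ R with Q_full[:,0] const
    q0 = np.full(len(x), 1.0 / R[0, 0])
    rec = np.column_stack([q0, T]) @ R
    np.testing.assert_allclose(rec[:, 1:], raw, atol=1e-10)


def test_orthogonalize_rank_deficient_raises(rng):
    x = rng.uniform(0, 1, size=50)
    bad = np.column_stack([x, 2.0 * x])
    with pytest.raises(np.linalg.LinAlgError, match="column"):
        orthogonalize(bad)


def test_centered_orthogonalised_backward_basis_is_zero_at_last_knot(rng):
    knots = np.sort(rng.uniform(-1, 2, size=5))
    sp = RestrictedCubicSpline(knots=knots, direction="backward",
                               include_linear=False, orthogonalize=True,
                               center_last_knot=True)
    sp.fit(rng.uniform(-1, 2, size=500))
    at_kK = sp.transform([knots[-1]])
    np.testing.assert_array_equal(at_kK, np.zeros_like(at_kK))
    beyond = sp.transform([knots[-1] + 3.0])
    np.testing.assert_array_equal(beyond, np.zeros_like(beyond))


def test_transformer_replay_on_new_points(rng):
    x_train = rng.uniform(-1, 2, size=400)
    sp = RestrictedCubicSpline(knots=[-0.5, 0.5, 1.5], orthogonalize=True,
                               center_last_knot=True).fit(x_train)
    sub = sp.transform(x_train[:50])
    np.testing.assert_allclose(sub, sp.transform(x_train)[:50], atol=1e-12)


def test_resolve_knots_rules():
    deaths = np.exp(np.linspace(np.log(0.05), np.log(9.0), 101))
    k = resolve_knots("centiles 0 50 100", deaths)
    np.testing.assert_allclose(k, np.log([0.05, np.sqrt(0.05 * 9.0), 9.0]), rtol=1e-9)
    k = resolve_knots("centiles 0 100 + fixed 12", deaths)
    assert k[-1] == pytest.approx(np.log(12.0))
    k = resolve_knots("years first 3 last", deaths)
    np.testing.assert_allclose(k, np.log([0.05, 3.0, 9.0]), rtol=1e-9)
    with pytest.raises(ValueError):
        resolve_knots("bogus 1 2 3")
    with pytest.raises(ValueError):
        resolve_knots("centiles 0 50 100")  # no death times
    assert len(SENSITIVITY_KNOT_RULES) == 6
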