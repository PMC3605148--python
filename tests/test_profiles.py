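"""Rate-profile construction, normalization and discretization."""

import numpy as np
import pytest
from scipy.integrate import simpson

from recombpast.profiles import (PRESETS, constant_low_high, discretize,
                                 evaluate_rate, make_profile, preset_profile)

RBAR = 3.75e-8
T = 1.0e4


def _numeric_mean(profile, npts=20001):
    t = np.linspace(0.0, profile.window_T, npts)
    r = np.array([profile.rate(x) for x in t])
    return simpson(r, x=t) / profile.window_T


@pytest.mark.parametrize("name", [p for p in PRESETS
                                  if not p.startswith("constant-")])
def test_equal_total_recombination(name):
    """Every shape/direction integrates to the same mean rate over the window."""
    p = preset_profile(name)
    assert _numeric_mean(p) == pytest.approx(RBAR, rel=1e-8)


def test_constant_profile_is_flat():
    p = make_profile("constant")
    for t in [0.0, 123.4, T, 1e6]:
        assert evaluate_rate(p, t) == pytest.approx(RBAR)


def test_linear_endpoints():
    dec = make_profile("linear", "decreasing_toward_present")
    assert evaluate_rate(dec, 0.0) == 0.0
    assert evaluate_rate(dec, T) == pytest.approx(2 * RBAR)
    inc = make_profile("linear", "increasing_toward_present")
    assert evaluate_rate(inc, 0.0) == pytest.approx(2 * RBAR)
    assert evaluate_rate(inc, T) == 0.0


def test_rate_held_constant_beyond_window():
    for name in PRESETS:
        p = preset_profile(name)
        assert evaluate_rate(p, 5 * T) == pytest.approx(evaluate_rate(p, T))


def test_exponential_ratio_follows_lambda():
    p = make_profile("exponential", "decreasing_toward_present")
    lam = p.lambda_exp
    for t, dt in [(1000.0, 500.0), (2000.0, 3000.0)]:
        assert (evaluate_rate(p, t) / evaluate_rate(p, t + dt)
                == pytest.approx(np.exp(-lam * dt)))


@pytest.mark.parametrize("name,increasing_in_t", [
    ("linear-dec", True), ("linear-inc", False),
    ("exp-dec", True), ("exp-inc", False),
    ("logistic-dec", True), ("logistic-inc", False),
])
def test_monotonicity_over_window(name, increasing_in_t):
    p = preset_profile(name)
    t = np.linspace(0, T, 500)
    r = np.array([p.rate(x) for x in t])
    diffs = np.diff(r)
    assert np.all(diffs >= -1e-20) if increasing_in_t else np.all(diffs <= 1e-20)


def test_logistic_limits():
    # steep growth approaches a step; slow growth approaches constant
    steep = make_profile("logistic", "decreasing_toward_present", logistic_g=0.05)
    assert steep.rate(0.0) < 0.02 * steep.rate(T)
    flat = make_profile("logistic", "decreasing_toward_present", logistic_g=1e-7)
    assert flat.rate(0.0) == pytest.approx(flat.rate(T), rel=1e-2)


def test_nonnegative_rates():
    for name in PRESETS:
        p = preset_profile(name)
        assert min(p.rate(t) for t in np.linspace(0, 2 * T, 200)) >= 0.0


def test_discretize_conserves_total_recombination():
    for name in PRESETS:
        p = preset_profile(name)
        epochs = discretize(p, step=20.0)
        total = sum((t1 - t0) * r for t0, t1, r in epochs if np.isfinite(t1))
        assert total == pytest.approx(p.mean_rate * T, rel=1e-3)
        assert np.isinf(epochs[-1][1])
        assert epochs[-1][2] == pytest.approx(p.rate(T))


def test_discretize_constant_and_single_step():
    const = discretize(make_profile("constant"), step=20.0)
    assert all(r == pytest.approx(RBAR) for _, _, r in const)
    lin = make_profile("linear", "decreasing_toward_present")
    one = discretize(lin, step=T)
    assert one[0][2] == pytest.approx(RBAR)  # midpoint of the line = mean


def test_constant_low_high():
    lin = make_profile("linear", "decreasing_toward_present")
    low, high = constant_low_high(lin)
    assert low == pytest.approx(0.15 * 7.5e-8)
    assert high == pytest.approx(0.85 * 7.5e-8)
    assert low / high == pytest.approx(15 / 85)
    with pytest.raises(ValueError):
        constant_low_high(make_profile("constant"))


def test_invalid_inputs():
    with pytest.raises(ValueError):
        make_profile("spline", "n/a")
    with pytest.raises(ValueError):
        make_profile("linear", "sideways")
    with pytest.raises(ValueError):
        make_profile("constant", window_T=-1.0)
    with pytest.raises(ValueError):
        make_profile("exponential", "increasing_toward_present", lambda_exp=-1.0)
    p = make_profile("constant")
    with pytest.raises(ValueError):
        evaluate_rate(p, -5.0)
    with pytest.raises(ValueError):
        discretize(p, step=0.0)
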