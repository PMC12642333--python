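"""Hazard models: pointwise values, clamping, integration, survivorship."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agesim.hazards import (
    DAParams,
    GMMParams,
    GompertzParams,
    HDAParams,
    HazardOverflowError,
    HazardSpec,
    HeligmanParams,
    SilerParams,
    cumulative_hazard,
    da_hazard,
    gamma_benefit,
    gmm_hazard,
    gompertz_hazard,
    hda_hazard,
    heligman_hazard,
    lambda_benefit,
    siler_hazard,
    survivorship,
)


@pytest.mark.parametrize(
    "t, a, b, expected",
    [
        (0.0, 0.5, 0.1, 0.5),
        (10.0, 1.0, 0.0, 1.0),
        (10.0, 0.01, 0.085, 0.01 * np.exp(0.85)),
    ],
)
def test_gompertz_pointwise(t, a, b, expected):
    assert gompertz_hazard(t, GompertzParams(a, b)) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "t, d, beta, expected",
    [
        (20.0, 35.0, 0.2, 0.01 * np.exp(2.0)),  # below onset: pure Gompertz
        (40.0, 35.0, 0.2, 0.8 * 0.01 * np.exp(4.0)),  # benefit applies
        (35.0, 35.0, 0.2, 0.8 * 0.01 * np.exp(3.5)),  # boundary inclusive
        (40.0, 35.0, 0.0, 0.01 * np.exp(4.0)),  # no-benefit control
    ],
)
def test_da_step_benefit(t, d, beta, expected):
    p = DAParams(GompertzParams(0.01, 0.1), beta=beta, d=d)
    assert da_hazard(t, p) == pytest.approx(expected, rel=1e-12)


def test_gamma_benefit_values():
    assert gamma_benefit(0.0, 0.05, 2.0) == 0.0
    # asymptote towards gamma_max
    assert gamma_benefit(1000.0, 0.05, 2.0) == pytest.approx(
        0.05 * (1 - 1 / 1000001), rel=1e-12
    )


@given(h=st.floats(0.05, 10.0), gamma_max=st.floats(1e-6, 1.0))
def test_gamma_halfway_is_age_one_for_any_steepness(h, gamma_max):
    assert gamma_benefit(1.0, gamma_max, h) == pytest.approx(gamma_max / 2, rel=1e-12)


@given(n=st.floats(0.01, 5.0), k=st.floats(0.0, 100.0), lmax=st.floats(1e-6, 1.0))
def test_lambda_halfway_at_k(n, k, lmax):
    assert lambda_benefit(k, lmax, n, k) == pytest.approx(lmax / 2, rel=1e-12)


def test_lambda_benefit_values():
    assert lambda_benefit(0.0, 0.1, 0.3, 30.0) == pytest.approx(
        0.1 * (1 - 1 / (1 + np.exp(-9.0))), rel=1e-10
    )
    assert lambda_benefit(500.0, 0.0, 0.3, 30.0) == 0.0
    # saturation guard: huge n*(t-k) must not overflow
    assert lambda_benefit(1e6, 0.1, 5.0, 30.0) == pytest.approx(0.1)


@given(
    gamma_max=st.floats(0.0, 0.5),
    h=st.floats(0.1, 10.0),
    t1=st.floats(0.0, 200.0),
    dt=st.floats(0.0, 50.0),
)
def test_benefits_monotone_and_bounded(gamma_max, h, t1, dt):
    g1, g2 = gamma_benefit(t1, gamma_max, h), gamma_benefit(t1 + dt, gamma_max, h)
    assert 0.0 <= g1 <= g2 <= gamma_max
    l1, l2 = lambda_benefit(t1, 0.3, 0.2, 40.0), lambda_benefit(t1 + dt, 0.3, 0.2, 40.0)
    assert 0.0 <= l1 <= l2 <= 0.3


def test_hda_reduces_to_gmm_without_benefits():
    t = np.linspace(0, 110, 400)
    hda = HDAParams(c=0.01, a=1e-4, b=0.09, gamma_max=0.0, lambda_max=0.0)
    gmm = GMMParams(c=0.01, a=1e-4, b=0.09)
    np.testing.assert_allclose(hda_hazard(t, hda), gmm_hazard(t, gmm), atol=1e-12)


def test_hda_clamps_at_zero():
    p = HDAParams(c=0.0, a=0.001, b=0.05, gamma_max=0.5, h_gamma=2.0, lambda_max=0.0)
    assert hda_hazard(5.0, p) == 0.0


def test_hda_pointwise_sum_of_terms():
    p = HDAParams(c=0.01, a=0.001, b=0.1, gamma_max=0.02, h_gamma=2.0,
                  lambda_max=0.1, n=0.3, k=30.0)
    expected = 0.01 + 0.001 - 0.0 - 0.1 * (1 - 1 / (1 + np.exp(-9.0)))
    assert hda_hazard(0.0, p) == pytest.approx(expected, rel=1e-6)


def test_siler_special_cases():
    const = SilerParams(a1=0.0, b1=1.0, a2=0.01, a3=0.0, b3=0.0)
    assert siler_hazard(17.0, const) == pytest.approx(0.01)
    nested = SilerParams(a1=0.0, b1=1.0, a2=0.001, a3=1e-4, b3=0.09)
    t = np.linspace(0, 100, 50)
    np.testing.assert_allclose(
        siler_hazard(t, nested), gmm_hazard(t, GMMParams(0.001, 1e-4, 0.09)), rtol=1e-12
    )


def test_heligman_senescent_term_and_age_zero_midpoint():
    p = HeligmanParams(A=0.0, B=0.1, C=0.1, D=0.0, E=10.0, F=20.0, G=1e-4, H=1.1)
    assert heligman_hazard(10.0, p) == pytest.approx(1e-4 * 1.1**10, rel=1e-12)
    # age 0 evaluated at the 0.5-year midpoint
    assert heligman_hazard(0.0, p) == pytest.approx(1e-4 * 1.1**0.5, rel=1e-12)


def test_overflow_raises():
    with pytest.raises(HazardOverflowError):
        gompertz_hazard(1000.0, GompertzParams(0.01, 1.0))


@pytest.mark.parametrize(
    "spec, t, closed_form",
    [
        (HazardSpec("gompertz", GompertzParams(0.01, 0.085)), 50.0,
         0.01 / 0.085 * (np.exp(0.085 * 50) - 1)),
        (HazardSpec("gmm", GMMParams(0.02, 0.0, 0.0)), 10.0, 0.2),
        (HazardSpec("gmm", GMMParams(0.005, 1e-4, 0.1)), 70.0,
         0.005 * 70 + 1e-4 / 0.1 * (np.exp(7.0) - 1)),
    ],
)
def test_cumulative_hazard_matches_closed_forms(spec, t, closed_form):
    assert cumulative_hazard(spec, t) == pytest.approx(closed_form, rel=1e-6)


def test_cumulative_hazard_zero_at_birth_and_monotone():
    spec = HazardSpec("hda", HDAParams(c=0.03, a=1e-4, b=0.09, gamma_max=0.029))
    ts = np.linspace(0, 110, 223)
    H = cumulative_hazard(spec, ts)
    assert H[0] == 0.0
    assert np.all(np.diff(H) >= 0)


def test_survivorship_values():
    const = HazardSpec("gmm", GMMParams(0.02, 0.0, 0.0))
    assert survivorship(const, 0.0) == 1.0
    assert survivorship(const, 10.0) == pytest.approx(np.exp(-0.2), rel=1e-9)
    gomp = HazardSpec("gompertz", GompertzParams(0.01, 0.085))
    expected = np.exp(-0.01 / 0.085 * (np.exp(0.085 * 70) - 1))
    assert survivorship(gomp, 70.0) == pytest.approx(expected, rel=1e-6)


@given(
    c=st.floats(0.0, 0.05),
    a=st.floats(1e-6, 1e-3),
    b=st.floats(0.0, 0.3),
    gamma_max=st.floats(0.0, 0.06),
    lambda_max=st.floats(0.0, 0.01),
)
def test_survivorship_is_probability_and_non_increasing(c, a, b, gamma_max, lambda_max):
    spec = HazardSpec(
        "hda", HDAParams(c=c, a=a, b=b, gamma_max=gamma_max, lambda_max=lambda_max)
    )
    x = np.linspace(0, 110, 56)
    lx = survivorship(spec, x)
    # l(x) > 0 mathematically; float underflow to 0 possible at extreme ages
    assert np.all(lx >= 0) and np.all(lx <= 1.0)
    assert lx[0] == 1.0
    assert np.all(np.diff(lx) <= 1e-15)


def test_spec_roundtrip_from_dict():
    cfg = {"model": "hda", "params": {"c": 0.01, "a": 1e-4, "b": 0.09,
                                      "gamma_max": 0.005, "h_gamma": 2.0,
                                      "lambda_max": 0.001, "n": 0.3, "k": 30.0}}
    spec = HazardSpec.from_dict(cfg)
    assert spec.to_dict() == cfg
    da = HazardSpec.from_dict({"model": "da", "params": {"a": 0.01, "b": 0.1, "beta": 0.2, "d": 35.0}})
    assert da.params.d == 35.0
    with pytest.raises(ValueError):
        HazardSpec.from_dict({"model": "nope", "params": {}})
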