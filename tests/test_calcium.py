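"""Minimal calcium model: indicator link, balance ODE and least-squares fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ionrep.calcium import (CalciumParams, ca_to_fluorescence, calcium_currents,
                            fit_calcium_model, fluorescence_to_ca,
                            simulate_calcium)
from ionrep.waveform import Waveform

P = CalciumParams(kd=1050.0, f_min=0.0, f_max=4520.0, gamma_l=0.6,
                  gamma_t=6e-4, lam=0.00063, ca_init=60.7)


def _wf(times, values, unit):
    return Waveform(np.asarray(times, float), np.asarray(values, float), unit)


def test_indicator_link_identities():
    t = np.array([0.0, 1.0, 2.0])
    # f = f_min -> zero calcium
    ca = fluorescence_to_ca(_wf(t, np.full(3, P.f_min), "dimensionless"), P)
    np.testing.assert_allclose(ca.values, 0.0)
    # midpoint -> K_d
    mid = 0.5 * (P.f_min + P.f_max)
    ca = fluorescence_to_ca(_wf(t, np.full(3, mid), "dimensionless"), P)
    np.testing.assert_allclose(ca.values, P.kd)
    # saturation rejected
    with pytest.raises(ValueError, match="saturated"):
        fluorescence_to_ca(_wf(t, np.full(3, P.f_max), "dimensionless"), P)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.lists(st.floats(0.0, 4000.0), min_size=2, max_size=8))
def test_indicator_round_trip_and_monotonicity(vals):
    t = np.arange(len(vals), dtype=float)
    f = _wf(t, vals, "dimensionless")
    ca = fluorescence_to_ca(f, P)
    back = ca_to_fluorescence(ca, P)
    np.testing.assert_allclose(back.values, f.values, atol=1e-10)
    order = np.argsort(f.values)
    assert np.all(np.diff(ca.values[order]) >= -1e-12)


def test_decay_to_zero_without_influx():
    """Clamped far below threshold with zero channel densities: pure
    exponential decay at rate lambda."""
    t = np.arange(0.0, 4000.0, 10.0)
    v = _wf(t, np.full_like(t, -80.0), "mV")
    ca = simulate_calcium(v, P, kappa_l=0.0, kappa_t=0.0)
    expected = P.ca_init * np.exp(-P.lam * t)
    np.testing.assert_allclose(ca.values, expected, rtol=1e-5, atol=1e-3)


def test_linear_growth_without_clearance():
    t = np.arange(0.0, 1000.0, 5.0)
    v = _wf(t, np.full_like(t, -80.0), "mV")
    p0 = CalciumParams(kd=P.kd, f_max=P.f_max, gamma_l=1.0, gamma_t=0.0,
                       lam=0.0, ca_init=50.0)
    psi = (_wf(t, np.full_like(t, -2.0), "pA"), _wf(t, np.zeros_like(t), "pA"))
    ca = simulate_calcium(v, p0, kappa_l=1.0, kappa_t=0.0, psi_pair=psi)
    np.testing.assert_allclose(ca.values, 50.0 + 2.0 * t, rtol=1e-6)


def test_matches_fixed_step_integrator():
    """Cross-check the adaptive solve against an independent RK4 at a fine
    fixed step on an AP-like voltage waveform."""
    t = np.arange(0.0, 3000.0, 1.0)
    v_vals = -50.0 + 45.0 * np.exp(-((t - 800.0) / 180.0) ** 2) \
        + 40.0 * np.exp(-((t - 1800.0) / 150.0) ** 2)
    v = _wf(t, v_vals, "mV")
    kl, kt = 10.5, 19.8
    psi = calcium_currents(v, ca0=P.ca_init)
    ca = simulate_calcium(v, P, kl, kt, psi_pair=psi)
    influx = P.gamma_l * kl * (-psi[0].values) + P.gamma_t * kt * (-psi[1].values)

    def f(tq, y):
        return np.interp(tq, t, influx) - P.lam * y

    dt = 0.05
    y = P.ca_init
    grid = np.arange(0.0, t[-1] + dt, dt)
    out = np.empty_like(grid)
    for i, tq in enumerate(grid):
        out[i] = y
        k1 = f(tq, y)
        k2 = f(tq + dt / 2, y + dt / 2 * k1)
        k3 = f(tq + dt / 2, y + dt / 2 * k2)
        k4 = f(tq + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    oracle = np.interp(t, grid, out)
    rel = np.abs(ca.values - oracle).max() / oracle.max()
    assert rel < 1e-3


def _synthetic_pair(p, seed=0, noise=0.0, duration=6000.0):
    """V/f pair generated under the fitter's conventions (driving currents
    evaluated at the reference calcium), with transients reaching ~K_d so
    the indicator nonlinearity pins the concentration scale."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0)
    # hyperpolarised baseline de-inactivates the T-type channel so gamma_T is
    # identifiable; large depolarisations push the transient toward indicator
    # saturation, pinning the concentration scale (K_d)
    v_vals = -80.0 + 70.0 * np.exp(-(((t % 1500.0) - 700.0) / 140.0) ** 2)
    v = _wf(t, v_vals, "mV")
    psi = calcium_currents(v, ca0=100.0)
    ca = simulate_calcium(v, p, kappa_l=10.5, kappa_t=19.8, psi_pair=psi)
    assert ca.values.max() > 0.5 * p.kd  # identifiable regime
    f = ca_to_fluorescence(ca, p)
    t_f = np.arange(0.0, duration, 1000.0 / 30.0)
    f_vals = f(t_f)
    if noise > 0:
        f_vals = f_vals * (1.0 + noise * rng.standard_normal(t_f.size))
    return v, _wf(t_f, np.clip(f_vals, 0.0, None), "dimensionless")


def test_noiseless_self_fit_recovers_parameters():
    true = CalciumParams(kd=1050.0, f_min=0.0, f_max=4520.0, gamma_l=4.0,
                         gamma_t=0.3, lam=8e-4, ca_init=70.0)
    v, f = _synthetic_pair(true)
    est = fit_calcium_model(v, f, n_starts=1, x0=true)
    for attr in ("kd", "f_max", "gamma_l", "gamma_t", "lam", "ca_init"):
        assert getattr(est, attr) == pytest.approx(getattr(true, attr), rel=1e-2)


def test_noisy_fit_recovers_parameters():
    """1% multiplicative fluorescence noise: all parameters within 10%
    (gamma_T within 25%; it is weakly identified)."""
    true = CalciumParams(kd=1050.0, f_min=0.0, f_max=4520.0, gamma_l=4.0,
                         gamma_t=0.3, lam=8e-4, ca_init=70.0)
    v, f = _synthetic_pair(true, seed=11, noise=0.01)
    est = fit_calcium_model(v, f, n_starts=8, seed=4)
    for attr, tol in (("kd", 0.1), ("f_max", 0.1), ("gamma_l", 0.1),
                      ("lam", 0.1), ("ca_init", 0.1), ("gamma_t", 0.25)):
        assert getattr(est, attr) == pytest.approx(getattr(true, attr), rel=tol), attr


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        CalciumParams(kd=-1.0)
    with pytest.raises(ValueError):
        CalciumParams(f_max=0.0, f_min=1.0)
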