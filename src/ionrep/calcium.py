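"""Minimal intracellular calcium dynamics.

Cytosolic calcium is linked to the indicator fluorescence by the
single-site binding relation

    [Ca2+]_i = K_d (f - f_min) / (f_max - f)

and evolves according to a one-variable balance: influx through the two
voltage-gated calcium channels (L-type and T-type) against a first-order
recovery term,

    d[Ca2+]_i/dt = gamma_L J_L + gamma_T J_T - lambda [Ca2+]_i

with J = -I the inward current magnitude (currents are outward-positive
internally).  Internal units: Ca in nM, t in ms, current density in pA/pF;
gamma_* are nM/ms per pA/pF, lambda in 1/ms.  Sarcoplasmic-reticulum
release and buffering are deliberately not modelled.

Fitting works in fluorescence space: for candidate parameters the calcium
transient is forward-simulated from the voltage trace, mapped through the
inverse indicator relation and compared with the recorded f/f0 signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .environment import IonEnvironment, DEFAULT_ENVIRONMENT
from .gating import with_defaults
from .species import ConductanceSpec, species_list
from .waveform import Waveform, common_span

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalciumParams:
    kd: float = 1050.0          # nM, indicator affinity
    f_min: float = 0.0
    f_max: float = 4520.0
    gamma_l: float = 2.251      # nM/ms per pA/pF
    gamma_t: float = 0.00138    # nM/ms per pA/pF
    lam: float = 0.00063        # 1/ms
    ca_init: float = 60.7       # nM

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("K_d must be positive")
        if not self.f_max > self.f_min >= 0:
            raise ValueError("need f_max > f_min >= 0")
        if self.lam < 0 or self.ca_init <= 0:
            raise ValueError("lambda must be >= 0 and Ca_init > 0")


def fluorescence_to_ca(f: Waveform, p: CalciumParams) -> Waveform:
    """Indicator fluorescence to [Ca2+]_i (nM); errors at saturation."""
    vals = f.values
    if np.any(vals >= p.f_max):
        raise ValueError("fluorescence at or above f_max: indicator saturated")
    if np.any(vals < p.f_min):
        raise ValueError("fluorescence below f_min")
    ca = p.kd * (vals - p.f_min) / (p.f_max - vals)
    return Waveform(f.times, ca, "nM")


def ca_to_fluorescence(ca: Waveform, p: CalciumParams) -> Waveform:
    """Inverse of :func:`fluorescence_to_ca`."""
    x = ca.values / p.kd
    f = (p.f_min + p.f_max * x) / (1.0 + x)
    return Waveform(ca.times, f, "dimensionless")


def _ca_channel_specs() -> tuple[ConductanceSpec, ConductanceSpec]:
    cal, cat = species_list(["CaL", "CaT"])
    return cal, cat


def calcium_currents(v: Waveform, ca0: float = 100.0,
                     env: IonEnvironment = DEFAULT_ENVIRONMENT,
                     specs: tuple | None = None):
    """Voltage-driven L- and T-type unit currents ignoring Ca feedback on
    gating (the clamp module handles the fully coupled case).

    Returns callables psi_l(t), psi_t(t) in pA per channel evaluated on the
    waveform grid by interpolation.
    """
    cal, cat = specs if specs is not None else _ca_channel_specs()
    u = with_defaults({"ca": ca0})
    times = v.times

    def gate_traj(spec):
        y0 = spec.gating.steady_state(float(v(times[0])), u)

        def rhs(t, y):
            return spec.gating.derivative(y, float(v(t)), u)

        sol = solve_ivp(rhs, (times[0], times[-1]), y0, method="LSODA",
                        t_eval=times, rtol=1e-6, atol=1e-9)
        return sol.y.T

    e_ca = env.with_ca_i(ca0).nernst("Ca")
    psi = []
    for spec, states in ((cal, gate_traj(cal)), (cat, gate_traj(cat))):
        vals = np.array([
            spec.unit_current(states[k], float(v(t)), env, u, e_rev=e_ca)
            for k, t in enumerate(times)])
        psi.append(Waveform(times, vals, "pA"))
    return psi[0], psi[1]


def simulate_calcium(v: Waveform, p: CalciumParams,
                     kappa_l: float, kappa_t: float,
                     env: IonEnvironment = DEFAULT_ENVIRONMENT,
                     psi_pair: tuple[Waveform, Waveform] | None = None) -> Waveform:
    """Integrate the calcium balance under the recorded voltage."""
    if kappa_l < 0 or kappa_t < 0:
        raise ValueError("channel densities must be non-negative")
    if psi_pair is None:
        psi_pair = calcium_currents(v, ca0=p.ca_init, env=env)
    psi_l, psi_t = psi_pair
    influx = (p.gamma_l * kappa_l * (-psi_l.values)
              + p.gamma_t * kappa_t * (-psi_t.values))
    influx_wf = Waveform(v.times, influx, "nM")

    def rhs(t, y):
        return [float(influx_wf(t)) - p.lam * y[0]]

    sol = solve_ivp(rhs, (v.t0, v.t1), [p.ca_init], method="LSODA",
                    t_eval=v.times, rtol=1e-8, atol=1e-6)
    return Waveform(v.times, np.clip(sol.y[0], 0.0, None), "nM")


def fit_calcium_model(v: Waveform, f: Waveform,
                      kappa_l: float = 10.5, kappa_t: float = 19.8,
                      env: IonEnvironment = DEFAULT_ENVIRONMENT,
                      n_starts: int = 20, seed: int = 0,
                      kd: float = 1050.0, fit_kd: bool = False,
                      x0: CalciumParams | None = None) -> CalciumParams:
    """Least-squares estimation of the calcium-model parameters.

    Free parameters: f_max, gamma_L, gamma_T, lambda, Ca_init (f_min is
    fixed at 0 for Fluo-4).  The fluorescence signal depends on calcium only
    through the ratio [Ca2+]/K_d and the balance equation is linear in
    calcium, so the indicator affinity K_d is structurally non-identifiable
    from an f/f0 trace alone: by default it is held at the dye's calibrated
    affinity (``kd``); with ``fit_kd=True`` a profile over a K_d grid is
    run and the flattest-valley minimiser is returned (see docs/methods.md).

    The residual is computed in fluorescence space.  Starts combine a
    variable-projection grid (the transient is linear in Ca_init, gamma_L,
    gamma_T at fixed lambda) with random log-uniform draws; the accepted
    run's objective decreases monotonically by construction of the
    trust-region solver.
    """
    t0, t1 = common_span(v, f)
    v = v.restricted(t0, t1)
    f = f.restricted(t0, t1)
    f_on_grid = f(v.times)       # for the coarse start-selection stage
    f_times, f_vals = f.times, f.values
    psi_pair = calcium_currents(v, env=env)

    if fit_kd:
        best_p, best_cost = None, np.inf
        for kd0 in np.geomspace(300.0, 3000.0, 5):
            p = fit_calcium_model(v, f, kappa_l, kappa_t, env,
                                  max(4, n_starts // 4), seed, kd=kd0,
                                  fit_kd=False, x0=x0)
            ca = simulate_calcium(v, p, kappa_l, kappa_t, env,
                                  psi_pair=psi_pair)
            cost = float(np.sum((ca_to_fluorescence(ca, p)(f_times)
                                 - f_vals) ** 2))
            if cost < best_cost:
                best_p, best_cost = p, cost
        return best_p

    # theta = log([f_max, gamma_L, gamma_T, lambda, Ca_init])
    def predict(theta):
        fmax, gl, gt, lam, ca0 = np.exp(theta)
        p = CalciumParams(kd=kd, f_min=0.0, f_max=fmax, gamma_l=gl,
                          gamma_t=gt, lam=lam, ca_init=ca0)
        ca = simulate_calcium(v, p, kappa_l, kappa_t, env, psi_pair=psi_pair)
        return ca_to_fluorescence(ca, p)(v.times)

    def resid(theta):
        # residual at the fluorescence sample times (the data grid)
        try:
            return np.interp(f_times, v.times, predict(theta)) - f_vals
        except (ValueError, RuntimeError):
            return np.full(f_times.size, 1e3)

    rng = np.random.default_rng(seed)
    f_scale = max(np.max(f_on_grid), 1.0)
    lo = np.log([1.02 * f_scale, 1e-3, 1e-7, 1e-5, 5.0])
    hi = np.log([50.0 * f_scale, 100.0, 10.0, 1e-2, 1000.0])

    # variable projection: at fixed lambda the transient is linear in
    # (Ca_init, gamma_L, gamma_T); at fixed f_max the fluorescence inverts
    t_rel = v.times - v.times[0]
    jl = np.clip(-psi_pair[0].values * kappa_l, 0.0, None)
    jt = np.clip(-psi_pair[1].values * kappa_t, 0.0, None)
    dt = np.diff(v.times)
    scored = []
    for lam0 in np.geomspace(1e-4, 5e-3, 6):
        decay = np.exp(-lam0 * t_rel)
        hl = np.zeros_like(t_rel)
        ht = np.zeros_like(t_rel)
        for k in range(t_rel.size - 1):
            e = np.exp(-lam0 * dt[k])
            hl[k + 1] = hl[k] * e + 0.5 * dt[k] * (jl[k] * e + jl[k + 1])
            ht[k + 1] = ht[k] * e + 0.5 * dt[k] * (jt[k] * e + jt[k + 1])
        basis = np.column_stack([decay, hl, ht])
        for fmax0 in np.array([1.1, 1.5, 2.5, 5.0]) * f_scale:
            ca_obs = kd * f_on_grid / np.maximum(fmax0 - f_on_grid,
                                                 1e-3 * fmax0)
            coef, *_ = np.linalg.lstsq(basis, ca_obs, rcond=None)
            coef = np.clip(coef, [5.0, 1e-3, 1e-7], None)
            pred = basis @ coef
            fp = fmax0 * pred / (kd + np.maximum(pred, 0.0))
            sse = float(np.sum((fp - f_on_grid) ** 2))
            scored.append((sse, np.log([fmax0, coef[1], coef[2], lam0,
                                        coef[0]])))
    scored.sort(key=lambda s: s[0])
    starts = [th for _, th in scored[:3]]
    if x0 is not None:
        starts.insert(0, np.log([x0.f_max, x0.gamma_l, x0.gamma_t, x0.lam,
                                 x0.ca_init]))
    for _ in range(max(0, n_starts - len(starts))):
        starts.append(lo + rng.random(5) * (hi - lo))
    starts = [np.clip(th, lo, hi) for th in starts[:max(3, n_starts)]]

    best, best_cost = None, np.inf
    for theta0 in starts:
        try:
            res = least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                                diff_step=1e-4, xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
            log.info("calcium fit: improved cost %.6g", best_cost)
    if best is None:
        raise RuntimeError("calcium fit failed for all starts")
    fmax, gl, gt, lam, ca0 = np.exp(best.x)
    return CalciumParams(kd=kd, f_min=0.0, f_max=fmax, gamma_l=gl,
                         gamma_t=gt, lam=lam, ca_init=ca0)
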