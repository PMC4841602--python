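"""Data-driven engine: gating forced by observed V(t) and Ca(t).

The recorded voltage and calcium waveforms are used as forcing functions
for every species' gating kinetics (an initial-value problem started from
the steady state at the first sample).  The resulting per-species unit
currents are integrated to cumulative charge, assembling the linear system

    Y = W kappa,   Y_h = V(t_h) - V(0) - V0(t_h),   W_hi = -q_i(t_h)

which is linear in the density vector kappa.  Unit currents are
outward-positive; the negated charge integrals make the identity hold as
written.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .environment import IonEnvironment, DEFAULT_ENVIRONMENT
from .gating import with_defaults
from .species import ConductanceSpec
from .waveform import Waveform, common_span

#: default integration tolerances (per state), configurable in all entry points
RTOL = 1e-6
ATOL = 1e-9

#: rows beyond this are decimated uniformly to keep W conditioning manageable
M_MAX = 20_000


@dataclass
class LinearSystem:
    """Charge-integral design matrix and voltage-response vector."""

    W: np.ndarray             # (m, n) mV per unit density
    Y: np.ndarray             # (m,) mV
    species: list[str]
    times: np.ndarray         # (m,) ms
    v0: np.ndarray            # (m,) mV, voltage term due to injected current

    def __post_init__(self):
        m, n = self.W.shape
        if self.Y.shape != (m,) or self.times.shape != (m,):
            raise ValueError("inconsistent linear-system shapes")
        if len(self.species) != n:
            raise ValueError("species labels do not match W columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.W.shape

    def residual(self, kappa: np.ndarray) -> np.ndarray:
        return self.Y - self.W @ np.asarray(kappa, float)

    def residual_rms(self, kappa: np.ndarray) -> float:
        r = self.residual(kappa)
        return float(np.sqrt(np.mean(r * r)))


def _input_functions(ca: Waveform, extra: dict | None):
    """Time-dependent gating inputs; calcium must be in nM."""
    if ca.unit not in ("nM", "uM"):
        raise ValueError("calcium waveform must be in nM or uM")
    scale = 1.0 if ca.unit == "nM" else 1e3
    fns = {"ca": lambda t: scale * ca(t)}
    for key, wf in (extra or {}).items():
        if isinstance(wf, Waveform):
            fns[key] = wf
        elif callable(wf):
            fns[key] = wf
        else:
            fns[key] = (lambda val: lambda t: val)(float(wf))
    return fns


def _inputs_at(fns: dict, t: float) -> dict:
    return with_defaults({k: float(f(t)) for k, f in fns.items()})


def drive_gating(specs: list[ConductanceSpec], v: Waveform, ca: Waveform,
                 extra_inputs: dict | None = None,
                 env: IonEnvironment = DEFAULT_ENVIRONMENT,
                 rtol: float = RTOL, atol: float = ATOL,
                 times: np.ndarray | None = None,
                 return_states: bool = False):
    """Force every species with the observed waveforms.

    Returns ``(times, psi)`` with ``psi[k, i]`` the unit current of species
    ``i`` at observation time ``k`` (pA per channel; pA/pF for
    density-factor species).  With ``return_states`` the per-species gating
    trajectories are returned as a third element.
    """
    t0, t1 = common_span(v, ca)
    if times is None:
        times = v.times[(v.times >= t0) & (v.times <= t1)]
    times = np.asarray(times, float)
    fns = _input_functions(ca, extra_inputs)
    u0 = _inputs_at(fns, times[0])
    v0 = float(v(times[0]))

    psi = np.zeros((times.size, len(specs)))
    trajectories: dict[str, np.ndarray] = {}
    for j, spec in enumerate(specs):
        gating = spec.gating
        if gating.n_states == 0:
            states = np.zeros((times.size, 0))
        else:
            y0 = gating.steady_state(v0, u0)

            def rhs(t, y, _g=gating):
                return _g.derivative(y, float(v(t)), _inputs_at(fns, t))

            sol = solve_ivp(rhs, (times[0], times[-1]), y0, method="LSODA",
                            t_eval=times, rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(f"gating integration failed for {spec.name}: "
                                   f"{sol.message}")
            states = sol.y.T
            if gating.is_markov:
                states = np.clip(states, 0.0, 1.0)
                states /= states.sum(axis=1, keepdims=True)
        trajectories[spec.name] = states

        tracks_ca = spec.reversal is not None and spec.reversal.tracks_calcium
        e_fixed = None
        if not spec.density_factor and spec.reversal is not None and not tracks_ca:
            e_fixed = spec.reversal.potential(env)
        for k, t in enumerate(times):
            u = _inputs_at(fns, t)
            psi[k, j] = spec.unit_current(states[k], float(v(t)), env, u,
                                          e_rev=e_fixed)
    if return_states:
        return times, psi, trajectories
    return times, psi


def accumulate_charge(psi: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal charge integrals q(t_k) = int_{t_0}^{t_k} psi dt."""
    psi = np.asarray(psi, float)
    times = np.asarray(times, float)
    if psi.shape[0] != times.size:
        raise ValueError("psi must be sampled at the given times")
    return cumulative_trapezoid(psi, times, axis=0, initial=0.0)


def build_linear_system(specs: list[ConductanceSpec], v: Waveform, ca: Waveform,
                        injected: Waveform | None = None,
                        extra_inputs: dict | None = None,
                        env: IonEnvironment = DEFAULT_ENVIRONMENT,
                        rtol: float = RTOL, atol: float = ATOL,
                        m_max: int = M_MAX) -> LinearSystem:
    """Assemble Y = W kappa from the recorded waveforms.

    ``injected`` is the injected-current density (pA/pF); it defaults to
    zero.  If the system has fewer sample times than species an ill-posed
    warning is emitted but the system is still returned.
    """
    times, psi = drive_gating(specs, v, ca, extra_inputs, env, rtol, atol)
    q = accumulate_charge(psi, times)
    w = -q
    v0 = np.zeros(times.size)
    if injected is not None:
        v0 = cumulative_trapezoid(injected(times), times, initial=0.0)
    y = v(times) - float(v(times[0])) - v0
    if times.size > m_max:
        keep = np.unique(np.linspace(0, times.size - 1, m_max).astype(int))
        times, w, y, v0 = times[keep], w[keep], y[keep], v0[keep]
    if times.size < len(specs):
        import warnings
        warnings.warn("fewer sample times than species: system is ill-posed",
                      stacklevel=2)
    return LinearSystem(W=w, Y=y, species=[s.name for s in specs],
                        times=times, v0=v0)
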