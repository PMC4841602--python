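"""Free-running whole-cell simulator and voltage-clamp protocols.

The closed-loop model couples the membrane equation (in per-capacitance
form, so 1 pA/pF = 1 mV/ms)

    dV/dt = i_inj(t) - sum_i kappa_i psi_i(t)

to the minimal calcium balance and to every species' gating kinetics.
Forcing programs cover the three hypothesis experiments: an extracellular
ATP step driving P2RX4, a PIP2 depletion switch swapping the hERG and
Kir7.1 parameterisations, and a stochastic calcium-spark train driving a
subpopulation of calcium-activated chloride channels.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .calcium import CalciumParams
from .clamp import drive_gating
from .environment import IonEnvironment, DEFAULT_ENVIRONMENT
from .estimate import DensityVector, RedundancyMap
from .gating import with_defaults
from .species import (ConductanceSpec, FREERUN_SPECIES, build_species,
                      load_catalogue, species_list)
from .waveform import Waveform

log = logging.getLogger(__name__)

#: default absolute capacitance used only to convert per-cell channel counts
#: to channels/pF (densities themselves are per pF throughout)
CELL_CAPACITANCE_PF = 50.0

#: free-running calcium parameters (calibrated to this channel library so the
#: closed loop rests near -50 mV with ~10^2 nM calcium; see docs/methods.md)
FREERUN_CALCIUM = CalciumParams(kd=1050.0, f_min=0.0, f_max=4520.0,
                                gamma_l=0.313, gamma_t=0.000192,
                                lam=0.00063, ca_init=60.7)


@dataclass(frozen=True)
class ClampProtocol:
    """Holding potential, voltage steps, optional tail, sample interval."""

    holding_mv: float = -60.0
    steps: tuple = ((40.0, 1000.0),)   # (potential mV, duration ms)
    tail_mv: float | None = None
    tail_ms: float = 500.0
    pre_ms: float = 500.0
    dt_ms: float = 0.5

    def __post_init__(self):
        if any(d <= 0 for _, d in self.steps):
            raise ValueError("step durations must be positive")

    def waveform(self) -> Waveform:
        times = [0.0]
        values = [self.holding_mv]
        t = self.pre_ms
        eps = 1e-9
        for v_step, dur in self.steps:
            times += [t - eps if t > 0 else t, t + eps]
            values += [values[-1], v_step]
            t += dur
        if self.tail_mv is not None:
            times += [t - eps, t + eps]
            values += [values[-1], self.tail_mv]
            t += self.tail_ms
        times.append(t)
        values.append(values[-1])
        grid = np.arange(0.0, t + self.dt_ms, self.dt_ms)
        base = Waveform(np.array(times), np.array(values), "mV")
        return Waveform(grid, base(grid), "mV")


@dataclass
class SparkTrainParams:
    """Stochastic local-calcium spark train (log-normal times/amplitudes)."""

    duration_ms: float = 30_000.0
    median_interval_ms: float = 1000.0
    sigma_log_interval: float = 0.3
    median_amplitude_um: float = 30.0
    sigma_log_amplitude: float = 0.4
    amplitude_range_um: tuple = (10.0, 80.0)
    duration_range_ms: tuple = (200.0, 500.0)
    median_duration_ms: float = 300.0
    sigma_log_duration: float = 0.15
    dt_ms: float = 2.0


@dataclass
class ForcingProgram:
    """External drives for a free-running simulation."""

    atp_amplitude_um: float = 0.0
    atp_onset_ms: float = 5000.0
    atp_duration_ms: float = 10_000.0
    pip2_off_onset_ms: float | None = None
    pip2_off_duration_ms: float = 30_000.0
    spark_params: SparkTrainParams | None = None
    spark_trace: Waveform | None = None        # local Ca, uM
    spark_fraction: float = 0.05
    injected: Waveform | None = None           # pA/pF

    def __post_init__(self):
        if self.atp_amplitude_um < 0:
            raise ValueError("ATP amplitude must be non-negative")

    def atp(self, t: float) -> float:
        if (self.atp_amplitude_um > 0
                and self.atp_onset_ms <= t < self.atp_onset_ms + self.atp_duration_ms):
            return self.atp_amplitude_um
        return 0.0

    def pip2(self, t: float) -> float:
        if (self.pip2_off_onset_ms is not None
                and self.pip2_off_onset_ms <= t
                < self.pip2_off_onset_ms + self.pip2_off_duration_ms):
            return 0.0
        return 1.0


@dataclass
class FreerunResult:
    times: np.ndarray
    voltage: Waveform
    calcium: Waveform
    states: dict                    # species -> (m, n_states)
    current_densities: dict         # species -> (m,) pA/pF
    kappa: DensityVector
    success: bool = True
    message: str = ""

    def current(self, name: str) -> np.ndarray:
        return self.current_densities[name]


# --------------------------------------------------------------------------
# assembly


class _Assembly:
    """Flattened state bookkeeping for the closed-loop system."""

    def __init__(self, kappa: DensityVector, env: IonEnvironment,
                 forcing: ForcingProgram, calcium: CalciumParams,
                 overrides: dict | None = None,
                 spark_trace: Waveform | None = None,
                 pip2_sensitive: bool = False):
        cat = load_catalogue(overrides)
        names = list(kappa.species)
        dens = list(kappa.values)
        if spark_trace is not None and "CaCC" in names and forcing.spark_fraction > 0:
            i = names.index("CaCC")
            total = dens[i]
            dens[i] = total * (1.0 - forcing.spark_fraction)
            names.append("CaCC_spark")
            dens.append(total * forcing.spark_fraction)
            cat = dict(cat)
            cat["CaCC_spark"] = cat["CaCC"]
        if pip2_sensitive and "hERG" in names:
            # PIP2 experiments use the PIP2-dependent hERG parameterisation
            cat = dict(cat)
            cat["hERG"] = dict(cat["hERG_PIP2"])
        self.specs = [build_species(n, cat[n]) for n in names]
        self.kappa = np.array(dens)
        self.names = names
        self.env = env
        self.forcing = forcing
        self.calcium = calcium
        self.spark_trace = spark_trace
        self.offsets = []
        off = 2
        for s in self.specs:
            self.offsets.append((off, off + s.n_states))
            off += s.n_states
        self.n_state = off
        self.e_fixed = []
        for s in self.specs:
            if s.density_factor or s.reversal is None:
                self.e_fixed.append(None)
            elif s.reversal.tracks_calcium or s.reversal.kind == "junctional":
                self.e_fixed.append(None)
            else:
                self.e_fixed.append(s.reversal.potential(env))
        self.i_l = self.names.index("CaL") if "CaL" in self.names else None
        self.i_t = self.names.index("CaT") if "CaT" in self.names else None
        self.n_states_per = [s.n_states for s in self.specs]
        self._current_fns = [self._make_current_fn(j) for j in range(len(self.specs))]

    def _make_current_fn(self, j: int):
        """Per-species unit-current closure (pA or pA/pF), bypassing the
        generic dispatch on the simulator hot path."""
        spec = self.specs[j]
        env = self.env
        if spec.density_factor:
            fn = spec.current_density_fn
            return lambda seg, v, u: fn(v, env, u)
        g = spec.conductance
        cf = spec.gating.conducting_fraction
        if spec.reversal is not None and spec.reversal.kind == "junctional":
            return lambda seg, v, u: g * cf(seg) * u["vj"] * 1e-3
        if spec.reversal is not None and spec.reversal.tracks_calcium:
            from .constants import thermal_voltage
            half_vt = 0.5 * thermal_voltage(env.temperature)
            ca_o = env.ca_o
            camod = spec.ca_modulation

            def fn_ca(seg, v, u):
                e = half_vt * math.log(ca_o / (u["ca"] * 1e-6))
                frac = cf(seg)
                if camod is not None:
                    frac *= camod(u["ca"])
                return g * frac * (v - e) * 1e-3

            return fn_ca
        e_fixed = self.e_fixed[j]
        # Kir7.1 carries a [K+]o conductance factor; fold it into g
        if spec.name.startswith("Kir7.1"):
            g = g * (env.k_o / spec.params["ko_ref"]) ** spec.params["ko_exponent"]
        return lambda seg, v, u: g * cf(seg) * (v - e_fixed) * 1e-3

    def inputs_at(self, t: float, ca: float) -> dict:
        u = {"ca": max(ca, 1e-3), "atp": self.forcing.atp(t),
             "pip2": self.forcing.pip2(t), "vj": 0.0, "ca_local": 0.0,
             "_full": True}
        return u

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        v, ca = y[0], y[1]
        u = self.inputs_at(t, ca)
        if self.spark_trace is not None:
            local = float(self.spark_trace(t)) * 1e3  # uM -> nM
        else:
            local = 0.0
        dy = np.zeros_like(y)
        total = 0.0
        il = it = 0.0
        for j, spec in enumerate(self.specs):
            a, b = self.offsets[j]
            seg = y[a:b]
            uj = u
            if local > 0.0 and spec.name == "CaCC_spark":
                uj = dict(u)
                uj["ca_local"] = local
            if self.n_states_per[j]:
                dy[a:b] = spec.gating.derivative(seg, v, uj)
            i_dens = self.kappa[j] * self._current_fns[j](seg, v, uj)
            total += i_dens
            if j == self.i_l:
                il = i_dens
            elif j == self.i_t:
                it = i_dens
        i_inj = float(self.forcing.injected(t)) if self.forcing.injected is not None else 0.0
        dy[0] = i_inj - total
        p = self.calcium
        dy[1] = p.gamma_l * (-il) + p.gamma_t * (-it) - p.lam * ca
        return dy

    def initial_state(self, v0: float, ca0: float) -> np.ndarray:
        y = np.zeros(self.n_state)
        y[0], y[1] = v0, ca0
        u = self.inputs_at(0.0, ca0)
        for j, spec in enumerate(self.specs):
            a, b = self.offsets[j]
            if spec.n_states:
                y[a:b] = spec.gating.steady_state(v0, u)
        return y

    def normalise(self, y: np.ndarray) -> np.ndarray:
        out = y.copy()
        for j, spec in enumerate(self.specs):
            if spec.gating.is_markov:
                a, b = self.offsets[j]
                seg = np.clip(out[a:b], 0.0, 1.0)
                s = seg.sum()
                if s > 0:
                    out[a:b] = seg / s
        return out


def find_equilibrium(kappa: DensityVector,
                     env: IonEnvironment = DEFAULT_ENVIRONMENT,
                     calcium: CalciumParams = FREERUN_CALCIUM,
                     overrides: dict | None = None,
                     settle_ms: float = 1e5,
                     v_guess: float = -50.0, ca_guess: float = 100.0,
                     polish: bool = True) -> np.ndarray:
    """Whole-system equilibrium without input current.

    Damped integration toward the rest state followed by a root polish
    (direct root finding from arbitrary guesses is unreliable for the stiff
    Markov schemes).
    """
    asm = _Assembly(kappa, env, ForcingProgram(), calcium, overrides)
    y0 = asm.initial_state(v_guess, ca_guess)
    sol = solve_ivp(asm.rhs, (0.0, settle_ms), y0, method="LSODA",
                    rtol=1e-7, atol=1e-9)
    y = asm.normalise(sol.y[:, -1])
    if polish:
        try:
            res = root(lambda z: asm.rhs(0.0, z), y, method="hybr",
                       options={"xtol": 1e-10})
            if res.success and abs(res.x[0] - y[0]) < 5.0:
                y = asm.normalise(res.x)
        except Exception:  # fall back to the integrated state
            pass
    return y


def freerun(kappa: DensityVector, forcing: ForcingProgram | None = None,
            duration_ms: float = 30_000.0, seed: int | None = None,
            env: IonEnvironment = DEFAULT_ENVIRONMENT,
            calcium: CalciumParams = FREERUN_CALCIUM,
            overrides: dict | None = None,
            dt_out_ms: float = 1.0,
            y0: np.ndarray | None = None,
            rtol: float = 1e-6, atol: float = 1e-8) -> FreerunResult:
    """Free-running whole-cell simulation.

    The initial condition is the whole-system equilibrium without input;
    ``seed`` only feeds the stochastic spark generator.  On integrator
    failure a diagnostic result with the last accepted state is returned.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if np.any(kappa.values < 0):
        raise ValueError("densities must be non-negative")
    forcing = forcing or ForcingProgram()
    spark = forcing.spark_trace
    if spark is None and forcing.spark_params is not None:
        from .synthetic import spark_train
        p = replace(forcing.spark_params, duration_ms=duration_ms)
        spark = spark_train(p, seed=0 if seed is None else seed)
    pip2_sensitive = forcing.pip2_off_onset_ms is not None
    asm = _Assembly(kappa, env, forcing, calcium, overrides,
                    spark_trace=spark, pip2_sensitive=pip2_sensitive)
    if y0 is None:
        eq_kappa = kappa  # equilibrium of the unforced system
        base = find_equilibrium(eq_kappa, env, calcium, overrides)
        y0 = asm.initial_state(base[0], base[1])
        # re-use equilibrium gating for shared species (CaCC split changes layout)
        y0[0], y0[1] = base[0], base[1]
        u = asm.inputs_at(0.0, base[1])
        for j, spec in enumerate(asm.specs):
            a, b = asm.offsets[j]
            if spec.n_states:
                y0[a:b] = spec.gating.steady_state(base[0], u)
    times = np.arange(0.0, duration_ms + dt_out_ms, dt_out_ms)
    sol = solve_ivp(asm.rhs, (0.0, duration_ms), y0, method="LSODA",
                    t_eval=times, rtol=rtol, atol=atol, max_step=20.0)
    ok = sol.success
    tt = sol.t
    ys = sol.y
    states, currents = {}, {}
    v_arr, ca_arr = ys[0], ys[1]
    for j, spec in enumerate(asm.specs):
        a, b = asm.offsets[j]
        states[spec.name] = ys[a:b].T
        vals = np.empty(tt.size)
        for k in range(tt.size):
            uj = asm.inputs_at(tt[k], ca_arr[k])
            if spec.name == "CaCC_spark" and spark is not None:
                uj["ca_local"] = float(spark(tt[k])) * 1e3
            vals[k] = asm.kappa[j] * spec.unit_current(
                ys[a:b, k], v_arr[k], env, uj, e_rev=asm.e_fixed[j])
        currents[spec.name] = vals
    if tt.size < 2:
        raise RuntimeError(f"integration produced no output: {sol.message}")
    return FreerunResult(
        times=tt, voltage=Waveform(tt, v_arr, "mV"),
        calcium=Waveform(tt, ca_arr, "nM"), states=states,
        current_densities=currents, kappa=kappa, success=ok,
        message=sol.message if not ok else "")


# --------------------------------------------------------------------------
# voltage clamp


def voltage_clamp(kappa: DensityVector, protocol: ClampProtocol,
                  env: IonEnvironment = DEFAULT_ENVIRONMENT,
                  ca_nM: float = 100.0,
                  overrides: dict | None = None) -> dict:
    """Voltage-clamp simulation returning per-species current densities.

    Returns a dict with ``times`` (ms), ``v`` (mV), ``currents`` (species ->
    pA/pF), ``total`` and the step onset time ``t_step``.
    """
    specs = species_list(kappa.species, overrides)
    v = protocol.waveform()
    ca = Waveform(np.array([v.t0, v.t1]), np.array([ca_nM, ca_nM]), "nM")
    times, psi = drive_gating(specs, v, ca, env=env)
    currents = {s.name: kappa.values[j] * psi[:, j]
                for j, s in enumerate(specs)}
    total = np.sum(kappa.values[None, :] * psi, axis=1)
    return {"times": times, "v": v(times), "currents": currents,
            "total": total, "t_step": protocol.pre_ms}


def clamp_statistics(result: dict, at_ms_post_step: float = 450.0) -> dict:
    """Peak and fixed-time statistics of a clamp simulation (pA/pF)."""
    t = result["times"]
    step_mask = t >= result["t_step"]
    total = result["total"]
    i_peak = float(total[step_mask][np.argmax(np.abs(total[step_mask]))])
    t_q = result["t_step"] + at_ms_post_step
    i_at = float(np.interp(t_q, t, total))
    return {"peak": i_peak, "at_time": i_at, "query_ms": t_q}


# --------------------------------------------------------------------------
# compensation experiments and AP detection


def apply_compensation(kappa: DensityVector, rmap: RedundancyMap,
                       leading: str, delta: float) -> DensityVector:
    """kappa' = kappa + delta * (redundancy-map row); clipped at zero."""
    row = rmap.row_for(leading)
    vals = kappa.values + delta * row
    if np.any(vals < 0):
        warnings.warn("compensated densities clipped at zero "
                      "(outside the physiological operating range)",
                      stacklevel=2)
        vals = np.clip(vals, 0.0, None)
    return DensityVector(kappa.species, vals)


def minimum_cacc_count(seed: int = 0, n_seeds: int = 6,
                       duration_ms: float = 20_000.0,
                       lo: float = 200.0, hi: float = 6400.0,
                       rel_tol: float = 0.1,
                       spark_params: SparkTrainParams | None = None,
                       spark_fraction: float = 0.05,
                       threshold_mv: float = -20.0,
                       capacitance_pf: float = CELL_CAPACITANCE_PF,
                       kappa: DensityVector | None = None,
                       verbose: bool = False) -> dict:
    """Minimal calcium-activated chloride channel count per cell required
    for spark-driven excitation.

    Bisects over the total CaCC count N (per cell), running ``n_seeds``
    seeded free-running simulations per level with ``spark_fraction`` of the
    population driven by the stochastic spark train; a level is excitable
    when the majority of seeds reach the action-potential threshold.  The
    rest of the repertoire is the reference density vector.

    Returns a dict with the bracketing counts and the midpoint estimate.
    """
    from .synthetic import table2_repertoire
    base = kappa or table2_repertoire(include_p2rx4=True)
    params = spark_params or SparkTrainParams()

    def excitable(n_per_cell: float) -> bool:
        kap = base.with_value("CaCC", n_per_cell / capacitance_pf)
        hits = 0
        need = n_seeds // 2 + 1
        for k in range(n_seeds):
            f = ForcingProgram(spark_params=params,
                               spark_fraction=spark_fraction)
            res = freerun(kap, f, duration_ms=duration_ms,
                          seed=seed * 1009 + k)
            if res.voltage.values.max() >= threshold_mv:
                hits += 1
            if hits >= need or hits + (n_seeds - k - 1) < need:
                break
        if verbose:
            log.info("N=%.0f: %d/%d excitable", n_per_cell, hits, n_seeds)
        return hits >= need

    while not excitable(hi):
        lo, hi = hi, hi * 2.0
        if hi > 1e5:
            raise RuntimeError("no excitable CaCC count found below 1e5")
    if excitable(lo):
        while lo > 25.0 and excitable(lo / 2.0):
            lo /= 2.0
        lo /= 2.0
    while (hi - lo) / hi > rel_tol:
        mid = np.sqrt(lo * hi)
        if excitable(mid):
            hi = mid
        else:
            lo = mid
    return {"lo": lo, "hi": hi, "estimate": float(np.sqrt(lo * hi)),
            "n_seeds": n_seeds, "duration_ms": duration_ms}


@dataclass
class APEvent:
    time_ms: float
    amplitude_mv: float
    duration_ms: float


def detect_action_potentials(v: Waveform, threshold_mv: float = -20.0,
                             refractory_ms: float = 200.0,
                             baseline_ms: float = 50.0) -> list[APEvent]:
    """Upward threshold crossings with refractory separation.

    Amplitude is the post-crossing peak minus the pre-event baseline;
    duration is the time spent above threshold.
    """
    if v.duration < 1000.0:
        raise ValueError("need at least 1 s of voltage data")
    t, x = v.times, v.values
    above = x >= threshold_mv
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    events: list[APEvent] = []
    last = -np.inf
    for idx in crossings:
        t0 = t[idx]
        if t0 - last < refractory_ms:
            continue
        last = t0
        end = idx
        while end < x.size and x[end] >= threshold_mv:
            end += 1
        peak = float(np.max(x[idx:max(end, idx + 1)]))
        pre = x[(t >= t0 - baseline_ms) & (t < t0)]
        baseline = float(np.mean(pre)) if pre.size else float(x[max(idx - 1, 0)])
        dur = float(t[min(end, t.size - 1)] - t0)
        events.append(APEvent(time_ms=float(t0), amplitude_mv=peak - baseline,
                              duration_ms=dur))
    return events
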