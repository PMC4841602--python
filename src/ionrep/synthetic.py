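"""Synthetic-data generation: model-generated recordings, spark trains and
toy linear systems.

The generator stands in for a paired current-clamp voltage / calcium
recording of a spontaneously active uterine myocyte: the free-running model
itself produces an AP-train-like voltage waveform with simultaneous calcium
transients from a known density vector, optionally degraded with additive
Gaussian noise and resampled at realistic acquisition rates (1 kHz voltage,
30 Hz calcium).  All stochastic generators are reproducible from a single
integer seed; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .clamp import LinearSystem
from .estimate import DensityVector
from .simulate import ForcingProgram, FreerunResult, SparkTrainParams, freerun
from .waveform import Waveform

__all__ = ["SparkTrainParams", "NoiseConfig", "spark_train",
           "generate_waveforms", "toy_linear_system", "table2_repertoire"]

#: logistic-pulse shape factor: FWHM = 2 * 2*arccosh(sqrt(2)) * w
_FWHM_PER_W = 4.0 * np.arccosh(np.sqrt(2.0))


@dataclass(frozen=True)
class NoiseConfig:
    v_mv: float = 0.0          # additive Gaussian noise on voltage
    ca_nm: float = 0.0         # additive Gaussian noise on calcium
    v_rate_hz: float = 1000.0  # acquisition rates
    ca_rate_hz: float = 30.0


def _truncated_lognormal(rng, median, sigma_log, lo, hi, size):
    """Log-normal draws resampled into [lo, hi] (guarantees the invariant)."""
    out = np.empty(size)
    mu = np.log(median)
    for i in range(size):
        for _ in range(1000):
            x = float(np.exp(rng.normal(mu, sigma_log)))
            if lo <= x <= hi:
                out[i] = x
                break
        else:
            out[i] = np.clip(np.exp(mu), lo, hi)
    return out


def spark_train(p: SparkTrainParams, seed: int = 0) -> Waveform:
    """Local-calcium spark train (uM): sum of logistic pulses.

    Each spark is A * sech^2((t - T)/(2 w)) — the peak equals the drawn
    amplitude A and the full width at half maximum is ~3.525 w, solved from
    the target duration.  Event times are a renewal process with log-normal
    inter-event intervals; amplitudes and durations are independent
    log-normal variates constrained to the configured ranges.
    """
    rng = np.random.default_rng(seed)
    t_end = p.duration_ms
    intervals = []
    total = 0.0
    while total < t_end + 2000.0:
        iv = float(np.exp(rng.normal(np.log(p.median_interval_ms),
                                     p.sigma_log_interval)))
        intervals.append(iv)
        total += iv
    times = np.cumsum(intervals)
    times = times[times < t_end]
    n = times.size
    amps = _truncated_lognormal(rng, p.median_amplitude_um,
                                p.sigma_log_amplitude,
                                *p.amplitude_range_um, size=n)
    fwhms = _truncated_lognormal(rng, p.median_duration_ms,
                                 p.sigma_log_duration,
                                 *p.duration_range_ms, size=n)
    widths = fwhms / _FWHM_PER_W
    grid = np.arange(0.0, t_end + p.dt_ms, p.dt_ms)
    trace = np.zeros_like(grid)
    for t0, a, w in zip(times, amps, widths):
        x = (grid - t0) / w
        e = np.exp(-np.abs(x))  # symmetric, overflow-safe form of 4e^x/(1+e^x)^2
        trace += 4.0 * a * e / (1.0 + e) ** 2
    return Waveform(grid, trace, "uM")


def generate_waveforms(kappa_true: DensityVector,
                       forcing: ForcingProgram | None = None,
                       duration_ms: float = 20_000.0,
                       noise: NoiseConfig = NoiseConfig(),
                       seed: int = 0,
                       return_result: bool = False,
                       **freerun_kwargs):
    """Model-generated (V, Ca) waveform pair from a known density vector.

    Returns ``(v, ca, kappa_true)`` (plus the full free-run result when
    ``return_result``).  The voltage is sampled at ``noise.v_rate_hz`` and
    the calcium trace at ``noise.ca_rate_hz``; zero noise reproduces the
    free-run output exactly on those grids.
    """
    if np.any(kappa_true.values < 0):
        raise ValueError("kappa_true must be non-negative")
    dt_v = 1000.0 / noise.v_rate_hz
    res = freerun(kappa_true, forcing, duration_ms=duration_ms, seed=seed,
                  dt_out_ms=dt_v, **freerun_kwargs)
    rng = np.random.default_rng(seed + 1)
    v_times = res.times
    v_vals = res.voltage.values.copy()
    if noise.v_mv > 0:
        v_vals = v_vals + rng.normal(0.0, noise.v_mv, v_vals.shape)
    dt_ca = 1000.0 / noise.ca_rate_hz
    ca_times = np.arange(v_times[0], v_times[-1], dt_ca)
    if ca_times.size < 2:
        ca_times = v_times
    ca_vals = res.calcium(ca_times)
    if noise.ca_nm > 0:
        ca_vals = ca_vals + rng.normal(0.0, noise.ca_nm, ca_vals.shape)
        ca_vals = np.clip(ca_vals, 0.1, None)
    v = Waveform(v_times, v_vals, "mV")
    ca = Waveform(ca_times, ca_vals, "nM")
    if return_result:
        return v, ca, kappa_true, res
    return v, ca, kappa_true


def toy_linear_system(n: int, m: int, rank: int, seed: int = 0,
                      kappa_scale: float = 2.0):
    """Random linear system of exactly the requested rank with a known
    non-negative solution.

    Returns ``(system, kappa_true, null_basis)`` where ``null_basis`` is an
    orthonormal basis of the planted null space of W.
    """
    if rank > min(m, n):
        raise ValueError("rank cannot exceed min(m, n)")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((m, rank))
    b = rng.standard_normal((rank, n))
    w = a @ b if rank else np.zeros((m, n))
    kappa = rng.uniform(0.0, kappa_scale, n)
    kappa[rng.random(n) < 0.3] = 0.0
    y = w @ kappa
    species = [f"s{i}" for i in range(n)]
    sys = LinearSystem(W=w, Y=y, species=species,
                       times=np.arange(m, dtype=float), v0=np.zeros(m))
    # planted null space: null(b)
    _, s, vt = np.linalg.svd(b) if rank else (None, np.zeros(0), np.eye(n))
    null = vt[rank:].T if rank else np.eye(n)
    return sys, DensityVector(species, kappa), null


def table2_repertoire(include_p2rx4: bool = False,
                      kappa_p2rx4: float = 90.0) -> DensityVector:
    """The reference minimal-total-density repertoire (channels/pF)."""
    values = {
        "Kv2.1": 15.7, "Kv9.3": 6.0, "Kv6.1": 0.74,
        "BK": 0.064, "BKb1": 0.3, "BKb3": 0.037, "BKb4": 0.0,
        "SK2": 0.0, "SK3": 0.78, "SK4": 0.015,
        "hERG": 2.4, "CaL": 10.5, "CaT": 19.8, "CaCC": 0.45,
        "Kv4.1": 0.0, "Kv4.3": 0.0, "Kv4.3_KCNE3": 1.3,
        "Kv4.3_KChIP2b": 2.7, "Kv4.3_KChIP2d": 0.3,
        "Kv4.3_KChIP2b_KCNE3": 0.0, "Kv3.4": 5.2,
        "Kv7.1": 0.0, "Kv7.4": 0.84, "Kir7.1": 0.0,
        "bgK": 0.5, "bgCl": 0.46, "Gap1": 0.0, "Gap2": 0.0,
        "NCX": 0.03, "PMCA": 3.9, "NaK": 1.1,
    }
    if include_p2rx4:
        values["P2RX4"] = kappa_p2rx4
    return DensityVector(list(values), np.array(list(values.values())))
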