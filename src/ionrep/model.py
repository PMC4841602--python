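"""Model/Results front end for conductance-repertoire estimation.

`ConductanceRepertoireModel` is built from a paired voltage/calcium
recording plus a species list; ``fit()`` assembles the charge-integral
linear system and returns a :class:`RepertoireFitResults` carrying the
pseudo-inverse, non-negative and l1-minimal density estimates, the kernel
(functional-redundancy) basis, residual diagnostics and a summary table.
Simulation helpers (free-running prediction, compensation experiments)
hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clamp import LinearSystem, build_linear_system, RTOL, ATOL, M_MAX
from .environment import IonEnvironment, DEFAULT_ENVIRONMENT
from .estimate import (DensityBounds, DensityVector, KernelBasis, RANK_TOL,
                       RedundancyMap, kernel_basis, l1_minimal_solution,
                       nonneg_particular_solution, pseudo_inverse_solution,
                       redundancy_map)
from .species import DEFAULT_SPECIES, species_list
from .waveform import Waveform, read_recording


class ConductanceRepertoireModel:
    """Linear density-estimation model for one V/Ca recording.

    Parameters
    ----------
    voltage, calcium
        Observed membrane potential (mV) and intracellular calcium (nM)
        waveforms driving the gating kinetics.
    species
        Species names (defaults to the full estimation repertoire).
    injected
        Injected current density (pA/pF), if any.
    overrides
        Catalogue parameter overrides merged by species name.
    """

    def __init__(self, voltage: Waveform, calcium: Waveform,
                 species: list[str] | None = None,
                 injected: Waveform | None = None,
                 env: IonEnvironment = DEFAULT_ENVIRONMENT,
                 overrides: dict | None = None):
        self.voltage = voltage
        self.calcium = calcium
        self.species_names = list(species) if species else list(DEFAULT_SPECIES)
        self.specs = species_list(self.species_names, overrides)
        self.injected = injected
        self.env = env
        self._system: LinearSystem | None = None

    @classmethod
    def from_recording(cls, path, time_col=0, voltage_col=1, calcium_col=2,
                       time_unit="ms", calcium_unit="nM", **kwargs):
        """Build from a delimited recording file (time, V, Ca columns)."""
        v, ca = read_recording(path, time_col, voltage_col, calcium_col,
                               time_unit, calcium_unit)
        if ca.unit == "dimensionless":
            from .calcium import CalciumParams, fluorescence_to_ca
            ca = fluorescence_to_ca(ca, kwargs.pop("calcium_params",
                                                   CalciumParams()))
        return cls(v, ca, **kwargs)

    @property
    def system(self) -> LinearSystem:
        if self._system is None:
            self._system = build_linear_system(
                self.specs, self.voltage, self.calcium, self.injected,
                env=self.env, rtol=self._rtol, atol=self._atol,
                m_max=self._m_max)
        return self._system

    _rtol, _atol, _m_max = RTOL, ATOL, M_MAX

    def fit(self, rank_tol: float = RANK_TOL, rtol: float = RTOL,
            atol: float = ATOL, m_max: int = M_MAX) -> "RepertoireFitResults":
        """Assemble the linear system and estimate the density vector."""
        self._rtol, self._atol, self._m_max = rtol, atol, m_max
        sys = self.system
        kplus = pseudo_inverse_solution(sys, rank_tol)
        basis = kernel_basis(sys, rank_tol)
        kp = nonneg_particular_solution(sys)
        khat = l1_minimal_solution(sys, basis, kp)
        return RepertoireFitResults(model=self, system=sys, rank_tol=rank_tol,
                                    kappa_pinv=kplus, kappa_nonneg=kp,
                                    kappa_l1=khat, kernel=basis)


@dataclass
class RepertoireFitResults:
    """Estimates, uncertainty structure (the kernel) and diagnostics."""

    model: ConductanceRepertoireModel
    system: LinearSystem
    rank_tol: float
    kappa_pinv: DensityVector
    kappa_nonneg: DensityVector
    kappa_l1: DensityVector
    kernel: KernelBasis
    _cache: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------ diagnostics

    @property
    def rank(self) -> int:
        return self.kernel.rank

    @property
    def kernel_dimension(self) -> int:
        return self.kernel.dimension

    @property
    def singular_values(self) -> np.ndarray:
        return self.kernel.singular_values

    def residual_rms(self, which: str = "l1") -> float:
        kappa = {"pinv": self.kappa_pinv, "nonneg": self.kappa_nonneg,
                 "l1": self.kappa_l1}[which]
        return self.system.residual_rms(kappa.values)

    def redundancy_map(self, leading: str | list[str],
                       bounds: DensityBounds | None = None) -> RedundancyMap:
        return redundancy_map(self.kernel, leading, bounds)

    # --------------------------------------------------------------- summary

    def summary(self, sig_figs: int = 3) -> str:
        df = self.to_frame()

        def fmt(x):
            if x == 0:
                return "0"
            return f"{x:.{sig_figs}g}"

        lines = ["Conductance repertoire estimation",
                 "=" * 49,
                 f"samples m = {self.system.shape[0]}, "
                 f"species n = {self.system.shape[1]}",
                 f"rank r = {self.rank}, kernel dimension = {self.kernel_dimension}",
                 f"residual RMS (l1 solution) = {self.residual_rms():.4g} mV",
                 "-" * 49,
                 f"{'species':<22}{'pinv':>9}{'nonneg':>9}{'l1':>9}"]
        for name, row in df.iterrows():
            lines.append(f"{name:<22}{fmt(row['pinv']):>9}"
                         f"{fmt(row['nonneg']):>9}{fmt(row['l1']):>9}")
        lines.append("-" * 49)
        lines.append(f"{'total':<22}{fmt(df['pinv'].sum()):>9}"
                     f"{fmt(df['nonneg'].sum()):>9}{fmt(df['l1'].sum()):>9}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pinv": self.kappa_pinv.values,
            "nonneg": self.kappa_nonneg.values,
            "l1": self.kappa_l1.values,
        }, index=self.system.species)

    # ------------------------------------------------------------ simulation

    def predicted_voltage(self, kappa: DensityVector | None = None) -> Waveform:
        """Data-driven predicted voltage V(0) + V0(t) - (W kappa shifted)."""
        kappa = kappa or self.kappa_l1
        sys = self.system
        v0 = float(self.model.voltage(sys.times[0]))
        pred = v0 + sys.v0 + sys.W @ kappa.values
        return Waveform(sys.times, pred, "mV")

    def plot_fit(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        t = self.system.times / 1000.0
        ax.plot(t, self.model.voltage(self.system.times), "k-", lw=0.8,
                label="observed")
        ax.plot(t, self.predicted_voltage().values, "r--", lw=0.8,
                label="predicted (l1)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("V (mV)")
        ax.legend(frameon=False)
        return ax

    def plot_redundancy_map(self, leading, reference: DensityVector | None = None,
                            ax=None, delta: float = 1.0):
        """log10 fold-change heat map of the echelon redundancy rows."""
        import matplotlib.pyplot as plt
        rmap = self.redundancy_map(leading)
        ref = reference or self.kappa_l1
        img = rmap.log10_fold_change(ref, delta)
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 0.5 + 0.4 * len(rmap.leading)))
        masked = np.ma.masked_invalid(img)
        pc = ax.imshow(masked, aspect="auto", cmap="RdBu_r",
                       vmin=-np.nanmax(np.abs(img)) if np.isfinite(img).any() else -1,
                       vmax=np.nanmax(np.abs(img)) if np.isfinite(img).any() else 1)
        ax.set_xticks(range(len(rmap.species)))
        ax.set_xticklabels(rmap.species, rotation=90, fontsize=7)
        ax.set_yticks(range(len(rmap.leading)))
        ax.set_yticklabels(rmap.leading, fontsize=7)
        plt.colorbar(pc, ax=ax, label="log10 fold change")
        return ax
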