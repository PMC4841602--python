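"""Density estimation and redundancy analysis.

Given the linear system Y = W kappa assembled by :mod:`ionrep.clamp`, this
module computes

* the minimum-norm least-squares solution (SVD pseudo-inverse),
* an orthonormal basis of the null space of W (the functional redundancy),
* a non-negative particular solution (NNLS),
* the l1-minimal non-negative solution on the feasible affine slice
  (linear programming over the kernel coefficients),
* echelon-form redundancy (compensation) maps, and
* physiological upper bounds on densities from steady-state I-V curves.

All solutions achieve the same fit residual up to kernel moves, which are
fit-neutral by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import svd
from scipy.optimize import linprog, nnls

from .clamp import LinearSystem
from .environment import IonEnvironment, DEFAULT_ENVIRONMENT
from .gating import with_defaults
from .species import ConductanceSpec

log = logging.getLogger(__name__)

RANK_TOL = 1e-8


@dataclass
class DensityVector:
    """Per-species scaled surface densities (channels/pF; dimensionless
    factors for PMCA, NaK, NCX)."""

    species: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species),):
            raise ValueError("values must match species labels")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.species.index(name)])

    def with_value(self, name: str, value: float) -> "DensityVector":
        v = self.values.copy()
        v[self.species.index(name)] = value
        return DensityVector(self.species, v)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def to_text(self, path) -> None:
        lines = ["# species\tdensity\tunit"]
        for s, v in zip(self.species, self.values):
            unit = "1" if s in ("NCX", "PMCA", "NaK") else "channels/pF"
            lines.append(f"{s}\t{float(v)!r}\t{unit}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path) -> "DensityVector":
        species, values = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            species.append(parts[0])
            values.append(float(parts[1]))
        return cls(species, np.array(values))


@dataclass
class KernelBasis:
    """Orthonormal basis of the null space of W."""

    basis: np.ndarray           # (n, n - r)
    rank: int
    singular_values: np.ndarray
    species: list[str]

    @property
    def dimension(self) -> int:
        return self.basis.shape[1]

    def project(self, vec: np.ndarray) -> np.ndarray:
        """Orthogonal projection of ``vec`` onto the kernel."""
        return self.basis @ (self.basis.T @ np.asarray(vec, float))


@dataclass
class RedundancyMap:
    """Echelon form of the kernel with chosen leading species.

    Each row is a kernel vector normalised to +1 in its leading coordinate:
    a unit increase of the leading density is compensated, to first order,
    by the trailing shifts.
    """

    species: list[str]
    leading: list[str]          # leading species per row
    rows: np.ndarray            # (k, n)
    pinned: list[str] = field(default_factory=list)
    implausible: dict = field(default_factory=dict)

    def row_for(self, name: str) -> np.ndarray:
        return self.rows[self.leading.index(name)]

    def log10_fold_change(self, reference: DensityVector, delta: float = 1.0):
        """log10 of the per-species fold change produced by applying each row
        with step ``delta`` to ``reference`` (NaN where the reference is 0)."""
        ref = reference.values
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = (ref[None, :] + delta * self.rows) / ref[None, :]
            out = np.where(fold > 0, np.log10(np.abs(fold)), np.nan)
        return out

    def to_text(self, path) -> None:
        lines = ["# leading\t" + "\t".join(self.species)]
        for lead, row in zip(self.leading, self.rows):
            lines.append(lead + "\t" + "\t".join(repr(float(x)) for x in row))
        if self.pinned:
            lines.append("# pinned: " + ", ".join(self.pinned))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class DensityBounds:
    """Physiological per-species upper bounds (channels/pF); lower bounds 0."""

    species: list[str]
    upper: np.ndarray           # NaN where undefined

    def __getitem__(self, name: str) -> float:
        return float(self.upper[self.species.index(name)])

    def to_text(self, path) -> None:
        lines = ["# species\tupper_bound"]
        for s, v in zip(self.species, self.upper):
            lines.append(f"{s}\t{float(v)!r}")
        Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# solutions of the linear system


def pseudo_inverse_solution(sys: LinearSystem,
                            rank_tol: float = RANK_TOL) -> DensityVector:
    """Minimum-norm least-squares solution kappa+ (may be negative)."""
    u, s, vt = svd(sys.W, full_matrices=False)
    r = int(np.sum(s > rank_tol * s[0])) if s.size else 0
    inv = np.zeros_like(s)
    inv[:r] = 1.0 / s[:r]
    kappa = vt.T @ (inv * (u.T @ sys.Y))
    return DensityVector(sys.species, kappa)


def kernel_basis(sys: LinearSystem, rank_tol: float = RANK_TOL) -> KernelBasis:
    """Orthonormal null-space basis of W via the SVD."""
    _, s, vt = svd(sys.W, full_matrices=True)
    n = sys.W.shape[1]
    r = int(np.sum(s > rank_tol * s[0])) if s.size else 0
    return KernelBasis(basis=vt[r:].T.copy(), rank=r, singular_values=s,
                       species=list(sys.species))


def nonneg_particular_solution(sys: LinearSystem) -> DensityVector:
    """kappa >= 0 minimising ||Y - W kappa||_2 (NNLS)."""
    kappa, _ = nnls(sys.W, sys.Y)
    return DensityVector(sys.species, kappa)


def l1_minimal_solution(sys: LinearSystem, basis: KernelBasis,
                        kappa_p: DensityVector) -> DensityVector:
    """Least-total-density solution on the feasible affine slice.

    Minimises sum(kappa_p + B gamma) subject to kappa_p + B gamma >= 0 over
    the kernel coefficients gamma; the fit residual is unchanged because
    kernel moves are fit-neutral.
    """
    kp = kappa_p.values
    if np.any(kp < -1e-12):
        raise ValueError("kappa_p must be non-negative (feasible)")
    b = basis.basis
    if b.shape[1] == 0:
        return DensityVector(sys.species, kp.copy())
    c = b.sum(axis=0)
    res = linprog(c, A_ub=-b, b_ub=np.clip(kp, 0.0, None), bounds=(None, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"l1 linear program failed: {res.message}")
    gamma = res.x
    kappa = np.clip(kp + b @ gamma, 0.0, None)
    log.info("l1 solution: kernel dim %d, total density %.6g -> %.6g",
             b.shape[1], kp.sum(), kappa.sum())
    return DensityVector(sys.species, kappa)


# --------------------------------------------------------------------------
# redundancy maps


def redundancy_map(basis: KernelBasis, leading: str | list[str],
                   bounds: DensityBounds | None = None,
                   tol: float = 1e-10) -> RedundancyMap:
    """Echelon form of the kernel with the requested leading species.

    The kernel basis is row-reduced with pivots chosen first on the
    requested species, then greedily on the remaining largest columns; each
    pivot row is rescaled to +1 in its leading coordinate.  A leading
    species with no kernel component is reported as pinned
    (non-compensatable) rather than an error.
    """
    names = list(basis.species)
    lead_names = [leading] if isinstance(leading, str) else list(leading)
    for nm in lead_names:
        if nm not in names:
            raise ValueError(f"unknown species {nm!r}")
    mat = basis.basis.T.copy()          # (k, n) rows span the kernel
    k, n = mat.shape
    scale = np.abs(mat).max() if k else 0.0
    pinned, rows, leads = [], [], []
    used_rows: list[int] = []
    order = [names.index(nm) for nm in lead_names]
    order += [j for j in range(n) if j not in order]
    for col in order:
        if len(used_rows) == k:
            break
        candidates = [i for i in range(k) if i not in used_rows]
        i_best = max(candidates, key=lambda i: abs(mat[i, col]))
        if abs(mat[i_best, col]) <= tol * max(scale, 1.0):
            if names[col] in lead_names:
                pinned.append(names[col])
            continue
        pivot = mat[i_best] / mat[i_best, col]
        for i in range(k):
            if i != i_best:
                mat[i] = mat[i] - mat[i, col] * pivot
        mat[i_best] = pivot
        used_rows.append(i_best)
        rows.append(pivot)
        leads.append(names[col])
    rows_arr = np.array(rows) if rows else np.zeros((0, n))
    implausible = {}
    if bounds is not None and rows:
        for lead, row in zip(leads, rows_arr):
            bad = {}
            for j, x in enumerate(row):
                ub = bounds.upper[j] if j < len(bounds.upper) else np.nan
                if np.isfinite(ub) and abs(x) > ub:
                    bad[names[j]] = float(x)
            if bad:
                implausible[lead] = bad
    return RedundancyMap(species=names, leading=leads, rows=rows_arr,
                         pinned=pinned, implausible=implausible)


# --------------------------------------------------------------------------
# physiological upper bounds


def density_upper_bounds(iv_curve: np.ndarray, specs: list[ConductanceSpec],
                         env: IonEnvironment = DEFAULT_ENVIRONMENT,
                         ca_nM: float = 100.0,
                         guard_mv: float = 1.0,
                         guard_g: float = 1e-12) -> DensityBounds:
    """Upper density bounds from a steady-state whole-cell I-V curve.

    ``iv_curve`` is an (n_points, 2) array of (V mV, current density pA/pF).
    For each species the bound is the maximum over sampled voltages of
    |I(V)| / |g_i(x_ss(V)) (V - E_i)|, the density the species would need to
    carry the whole observed current alone; points within ``guard_mv`` of
    the reversal potential or with conducting fraction below ``guard_g``
    are skipped.  A species with no valid point gets NaN (undefined bound).
    """
    iv = np.asarray(iv_curve, float)
    if iv.ndim != 2 or iv.shape[1] != 2:
        raise ValueError("iv_curve must be (n, 2): voltage, current density")
    u = with_defaults({"ca": ca_nM})
    upper = np.full(len(specs), np.nan)
    for j, spec in enumerate(specs):
        if spec.density_factor:
            continue  # dimensionless factors: no conductance-based bound
        best = np.nan
        for v_mv, i_obs in iv:
            e = spec.reversal_potential(env, ca_nM=ca_nM)
            if spec.reversal is not None and spec.reversal.kind == "junctional":
                continue
            if abs(v_mv - e) < guard_mv:
                continue
            ss = spec.gating.steady_state(v_mv, u)
            frac = spec.gating.conducting_fraction(ss)
            if spec.ca_modulation is not None:
                frac *= spec.ca_modulation(ca_nM)
            unit = spec.conductance * frac * (v_mv - e) * 1e-3  # pA/channel
            if abs(unit) <= guard_g:
                continue
            bound = abs(i_obs) / abs(unit)
            if not np.isfinite(best) or bound > best:
                best = bound
        upper[j] = best
    return DensityBounds([s.name for s in specs], upper)
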