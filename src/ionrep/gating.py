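"""Gating-model primitives: Hodgkin–Huxley gates and Markov schemes.

Every electrogenic species owns a :class:`GatingModel` mapping
(state, V, inputs) to a state derivative, a steady state, and a conducting
fraction in [0, 1].  ``inputs`` is a plain dict of auxiliary drives:

``ca``    intracellular calcium seen by the species, nM
``atp``   extracellular ATP, uM
``pip2``  1.0 when PIP2 is present (default), 0.0 when depleted
``vj``    transjunctional voltage for gap junctions, mV

Markov occupancies are probabilities: they stay in [0, 1], sum to one, and
the redundant occupancy is *not* eliminated — conservation is asserted
instead (the scheme's rate matrix has zero column sums by construction).
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

Inputs = dict

DEFAULT_INPUTS: Inputs = {"ca": 100.0, "atp": 0.0, "pip2": 1.0, "vj": 0.0}


def with_defaults(inputs: Inputs | None) -> Inputs:
    if not inputs:
        return dict(DEFAULT_INPUTS)
    if "_full" in inputs:  # already complete (hot path in the simulator)
        return inputs
    merged = dict(DEFAULT_INPUTS)
    merged.update(inputs)
    return merged


# --------------------------------------------------------------------------
# functional building blocks


def boltzmann(v: float, vhalf: float, k: float) -> float:
    """1 / (1 + exp(-(v - vhalf)/k)); negative k yields an inactivation curve."""
    x = -(v - vhalf) / k
    if x > 500.0:
        return 0.0
    if x < -500.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


def hill(c: float, ec50: float, n: float) -> float:
    """Hill activation for non-negative concentration c."""
    if c <= 0.0:
        return 0.0
    r = (ec50 / c) ** n
    return 1.0 / (1.0 + r)


def bell_tau(v: float, base: float, amp: float, vpeak: float, width: float) -> float:
    """Gaussian-bell time constant profile (ms)."""
    z = (v - vpeak) / width
    return base + amp * math.exp(-z * z)


# --------------------------------------------------------------------------
# gating models


class GatingModel(ABC):
    """Abstract gating dynamics of one species."""

    state_labels: tuple[str, ...]

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @abstractmethod
    def derivative(self, state: np.ndarray, v: float, inputs: Inputs) -> np.ndarray:
        ...

    @abstractmethod
    def steady_state(self, v: float, inputs: Inputs) -> np.ndarray:
        ...

    @abstractmethod
    def conducting_fraction(self, state: np.ndarray) -> float:
        ...

    @property
    def is_markov(self) -> bool:
        return False


@dataclass
class Gate:
    name: str
    xinf: Callable[[float, Inputs], float]
    tau: Callable[[float, Inputs], float]


class HHGating(GatingModel):
    """Independent first-order gates relaxing toward their steady states."""

    def __init__(self, gates: Sequence[Gate],
                 conducting: Callable[[np.ndarray], float] | None = None):
        self.gates = list(gates)
        self.state_labels = tuple(g.name for g in self.gates)
        self._conducting = conducting

    def derivative(self, state, v, inputs):
        out = np.empty(len(self.gates))
        for i, g in enumerate(self.gates):
            out[i] = (g.xinf(v, inputs) - state[i]) / g.tau(v, inputs)
        return out

    def steady_state(self, v, inputs):
        return np.array([g.xinf(v, inputs) for g in self.gates])

    def conducting_fraction(self, state):
        if self._conducting is not None:
            return float(self._conducting(state))
        out = 1.0
        for x in state:
            out *= x
        return float(out)


class ConstantGating(GatingModel):
    """Stateless (ohmic / algebraically gated) species."""

    state_labels: tuple[str, ...] = ()

    def __init__(self, conducting: Callable[[np.ndarray], float] | None = None):
        self._conducting = conducting

    def derivative(self, state, v, inputs):
        return np.empty(0)

    def steady_state(self, v, inputs):
        return np.empty(0)

    def conducting_fraction(self, state):
        return 1.0 if self._conducting is None else float(self._conducting(state))


@dataclass
class Transition:
    src: str
    dst: str
    rate: Callable[[float, Inputs], float]


class MarkovGating(GatingModel):
    """Continuous-time Markov scheme over channel conformations.

    dp/dt = Q(V, u) p with zero column sums, so total occupancy is
    conserved exactly by the dynamics.

    Schemes may supply ``rates_fn(v, u) -> array`` evaluating every
    transition rate at once (in ``transitions`` order); the derivative then
    uses a vectorised flux accumulation, which matters in the free-running
    simulator.  Per-transition closures and the vectorised evaluator are
    required to agree; audits use the closures.
    """

    def __init__(self, labels: Sequence[str], transitions: Sequence[Transition],
                 conducting_states: Sequence[str] | None = None,
                 conducting: Callable[[np.ndarray], float] | None = None,
                 rates_fn: Callable[[float, Inputs], np.ndarray] | None = None):
        self.state_labels = tuple(labels)
        self.transitions = list(transitions)
        self._index = {s: i for i, s in enumerate(self.state_labels)}
        for tr in self.transitions:
            if tr.src not in self._index or tr.dst not in self._index:
                raise ValueError(f"transition {tr.src}->{tr.dst} references unknown state")
        self._conducting_idx = (
            np.array([self._index[s] for s in conducting_states], dtype=int)
            if conducting_states else None)
        self._conducting = conducting
        if self._conducting_idx is None and self._conducting is None:
            raise ValueError("a Markov scheme needs conducting states or a rule")
        self._rates_fn = rates_fn
        self._src = np.array([self._index[t.src] for t in self.transitions])
        self._dst = np.array([self._index[t.dst] for t in self.transitions])

    @property
    def is_markov(self) -> bool:
        return True

    def transition_rates(self, v: float, inputs: Inputs) -> np.ndarray:
        if self._rates_fn is not None:
            return np.asarray(self._rates_fn(v, inputs), float)
        return np.array([t.rate(v, inputs) for t in self.transitions])

    def rate_matrix(self, v: float, inputs: Inputs) -> np.ndarray:
        n = self.n_states
        q = np.zeros((n, n))
        r = self.transition_rates(v, inputs)
        for k in range(r.size):
            i, j = self._src[k], self._dst[k]
            q[j, i] += r[k]
            q[i, i] -= r[k]
        return q

    def derivative(self, state, v, inputs):
        flux = self.transition_rates(v, inputs) * np.take(state, self._src)
        n = self.n_states
        return (np.bincount(self._dst, weights=flux, minlength=n)
                - np.bincount(self._src, weights=flux, minlength=n))

    def steady_state(self, v, inputs):
        """Stationary distribution: null vector of Q normalised to sum 1."""
        q = self.rate_matrix(v, inputs)
        n = self.n_states
        a = np.vstack([q, np.ones((1, n))])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        p, *_ = np.linalg.lstsq(a, b, rcond=None)
        p = np.clip(p, 0.0, None)
        return p / p.sum()

    def conducting_fraction(self, state):
        if self._conducting is not None:
            return float(self._conducting(state))
        return float(np.take(state, self._conducting_idx).sum())

    # ------------------------------------------------------------- audits

    def cycles(self) -> list[list[str]]:
        """Independent cycles of the transition graph (spanning-tree basis)."""
        edges = {frozenset((tr.src, tr.dst)) for tr in self.transitions}
        adj: dict[str, set[str]] = {s: set() for s in self.state_labels}
        for e in edges:
            a, b = tuple(e)
            adj[a].add(b)
            adj[b].add(a)
        parent: dict[str, str | None] = {}
        order = []
        for root in self.state_labels:
            if root in parent:
                continue
            parent[root] = None
            stack = [root]
            while stack:
                u = stack.pop()
                order.append(u)
                for w in adj[u]:
                    if w not in parent:
                        parent[w] = u
                        stack.append(w)
        tree = {frozenset((u, p)) for u, p in parent.items() if p is not None}
        cycles = []
        for e in edges - tree:
            a, b = tuple(e)
            pa, pb = _path_to_root(a, parent), _path_to_root(b, parent)
            common = set(pa) & set(pb)
            ia = next(i for i, s in enumerate(pa) if s in common)
            ib = next(i for i, s in enumerate(pb) if s in common)
            if pa[ia] != pb[ib]:  # pick the shared ancestor consistently
                anc = (set(pa) & set(pb))
                ia = min(i for i, s in enumerate(pa) if s in anc)
                ib = min(i for i, s in enumerate(pb) if s in anc)
            cycle = pa[:ia + 1] + list(reversed(pb[:ib]))
            cycles.append(cycle)
        return cycles

    def detailed_balance_residuals(self, v: float, inputs: Inputs) -> dict[tuple[str, ...], float]:
        """|forward/backward rate product - 1| for each independent cycle."""
        rates: dict[tuple[str, str], float] = {}
        for tr in self.transitions:
            rates[(tr.src, tr.dst)] = rates.get((tr.src, tr.dst), 0.0) + tr.rate(v, inputs)
        out = {}
        for cycle in self.cycles():
            fwd, bwd = 1.0, 1.0
            ok = True
            for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                if (a, b) not in rates or (b, a) not in rates:
                    ok = False
                    break
                fwd *= rates[(a, b)]
                bwd *= rates[(b, a)]
            if ok and bwd > 0:
                out[tuple(cycle)] = abs(fwd / bwd - 1.0)
        return out


def _path_to_root(node: str, parent: dict) -> list[str]:
    path = [node]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path
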