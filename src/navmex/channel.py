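"""Markov model of NaV1.5 with explicit DIII voltage-sensor regimes.

The drug-free channel has 16 states arranged in three DIII-VSD regimes:

* ``R``  (DIII down, rested): 4 closed states RC1..RC4
* ``A1`` (DIII first activation): 4 closed states A1C1..A1C4
* ``A2`` (DIII fully up): an 8-state gating core C3-C2-C1-O with
  fast-inactivated IF, closed-inactivated IC3/IC2 and slow-inactivated IS.

Opening and inactivation are only possible in the A2 regime, so the DIII
sensor both gates the conducting pathway and "guards" the local-anesthetic
receptor: mexiletine binds only from A2 states, into a mirrored row of eight
non-conducting drug-bound states.  Bound gating is the free A2 gating scaled
by shared kinetic modifiers; inactivated bound states are stabilized by the
factor ``phi`` (modulated-receptor behaviour), which by detailed balance
makes their unbinding rate ``kon * Kd / phi``.

Rates fixed by microscopic reversibility (one per independent cycle) are
monomials of the elementary rate laws, so every cycle product closes exactly
at every voltage and concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .rates import InvalidParameterError, RateLaw

STATE_NAMES: Tuple[str, ...] = (
    "RC1", "RC2", "RC3", "RC4",
    "A1C1", "A1C2", "A1C3", "A1C4",
    "C3", "C2", "C1", "O", "IF", "IC3", "IC2", "IS",
    "BC3", "BC2", "BC1", "BO", "BIF", "BIC3", "BIC2", "BIS",
)
N_STATES = len(STATE_NAMES)
N_FREE = 16
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

R_STATES = tuple(range(0, 4))
A1_STATES = tuple(range(4, 8))
A2_STATES = tuple(range(8, 16))
BOUND_STATES = tuple(range(16, 24))
OPEN = IDX["O"]
A2_CLOSED = (IDX["C3"], IDX["C2"], IDX["C1"])
A2_INACT = (IDX["IF"], IDX["IC3"], IDX["IC2"], IDX["IS"])

# Reversibility-derived monomials (one per independent cycle family):
#  - acg: the pre-open activation step in the R/A1 rows, fixed by the
#    A1C3-A1C4-O-C1 square because the A1C4<->O step (a3/b3) may differ
#    from the generic A1<->A2 step (ay/by).
#  - ifo: IF->O recovery, fixed by the C1-O-IF triangle.
_ACG = {"ay": 1, "act3": 1, "b3": 1, "a3": -1, "by": -1}
_IFO = {"act3": 1, "oif": 1, "del": 1, "gam": -1, "dea3": -1}
_BIFO = {"act3": 1, "oif": 1, "del": 1, "gam": -1, "dea3": -1, "m_oif": 1, "phi": -1}

Monomial = Mapping[str, float]


@dataclass(frozen=True)
class Edge:
    src: int
    dst: int
    fwd: Monomial
    bwd: Monomial
    binding: bool = False  # forward rate additionally multiplied by [drug]


def _core_edges(prefix: str, mod: Dict[str, int] | None = None) -> List[Edge]:
    """The 10 edges of one 8-state gating core (free or drug-bound)."""
    m = dict(mod or {})
    p = prefix

    def mono(d: Dict[str, int]) -> Dict[str, int]:
        out = dict(d)
        for k, v in m.items():
            out[k] = out.get(k, 0) + v
        return out

    def s(name: str) -> int:
        return IDX[p + name]

    edges = [
        Edge(s("C3"), s("C2"), mono({"act1": 1}), mono({"dea1": 1})),
        Edge(s("C2"), s("C1"), mono({"act2": 1}), mono({"dea2": 1})),
        Edge(s("C1"), s("O"), mono({"act3": 1}), mono({"dea3": 1})),
        Edge(s("IC3"), s("IC2"), mono({"act1": 1}), mono({"dea1": 1})),
        Edge(s("IC2"), s("IF"), mono({"act2": 1}), mono({"dea2": 1})),
    ]
    return edges


def _build_edges() -> List[Edge]:
    edges: List[Edge] = []
    # R and A1 rows: three activation steps mirroring C3-C2-C1-O; the last
    # step is reversibility-derived (acg).
    for row in ("RC", "A1C"):
        base = [IDX[row + str(j)] for j in (1, 2, 3, 4)]
        edges.append(Edge(base[0], base[1], {"act1": 1}, {"dea1": 1}))
        edges.append(Edge(base[1], base[2], {"act2": 1}, {"dea2": 1}))
        edges.append(Edge(base[2], base[3], dict(_ACG), {"dea3": 1}))
    # A2 free core.
    edges += _core_edges("")
    edges.append(Edge(IDX["C3"], IDX["IC3"], {"gam": 1}, {"del": 1}))
    edges.append(Edge(IDX["C2"], IDX["IC2"], {"gam": 1}, {"del": 1}))
    edges.append(Edge(IDX["C1"], IDX["IF"], {"gam": 1}, {"del": 1}))
    edges.append(Edge(IDX["O"], IDX["IF"], {"oif": 1}, dict(_IFO)))
    edges.append(Edge(IDX["IF"], IDX["IS"], {"ise": 1}, {"isx": 1}))
    # DIII-VSD steps: R<->A1 (ax/bx, column independent), A1<->A2 (ay/by for
    # the closed columns, a3/b3 for the open-aligned column).
    for j in range(4):
        edges.append(Edge(R_STATES[j], A1_STATES[j], {"ax": 1}, {"bx": 1}))
    for a1, a2 in zip((IDX["A1C1"], IDX["A1C2"], IDX["A1C3"]), (IDX["C3"], IDX["C2"], IDX["C1"])):
        edges.append(Edge(a1, a2, {"ay": 1}, {"by": 1}))
    edges.append(Edge(IDX["A1C4"], IDX["O"], {"a3": 1}, {"b3": 1}))
    # Drug-bound core: free rates scaled by shared kinetic modifiers; the
    # closed->inactivated equilibrium additionally gains the factor phi.
    edges += _core_edges("B", {"m_act": 1})
    for c, i in (("BC3", "BIC3"), ("BC2", "BIC2"), ("BC1", "BIF")):
        edges.append(Edge(IDX[c], IDX[i], {"gam": 1, "m_rec": 1, "phi": 1},
                          {"del": 1, "m_rec": 1}))
    edges.append(Edge(IDX["BO"], IDX["BIF"], {"oif": 1, "m_oif": 1}, dict(_BIFO)))
    edges.append(Edge(IDX["BIF"], IDX["BIS"], {"ise": 1, "m_is": 1}, {"isx": 1, "m_is": 1}))
    # Binding edges (A2 -> bound mirror).  Unbinding is kon*Kd for the
    # accessible (closed/open) states and kon*Kd/phi for inactivated states,
    # as required by detailed balance.
    for c, b in ((IDX["C3"], IDX["BC3"]), (IDX["C2"], IDX["BC2"]), (IDX["C1"], IDX["BC1"])):
        edges.append(Edge(c, b, {"kon_c": 1}, {"kon_c": 1, "kd": 1}, binding=True))
    edges.append(Edge(IDX["O"], IDX["BO"], {"kon_o": 1}, {"kon_o": 1, "kd": 1}, binding=True))
    for i, b in ((IDX["IF"], IDX["BIF"]), (IDX["IC3"], IDX["BIC3"]),
                 (IDX["IC2"], IDX["BIC2"]), (IDX["IS"], IDX["BIS"])):
        edges.append(Edge(i, b, {"kon_i": 1}, {"kon_i": 1, "kd": 1, "phi": -1}, binding=True))
    return edges


EDGES: Tuple[Edge, ...] = tuple(_build_edges())


class DegenerateModelError(RuntimeError):
    """The generator has a multi-dimensional null space (disconnected graph)."""


@dataclass
class OccupancyState:
    """Probability vector over all states at one instant."""

    p: np.ndarray
    t: float = 0.0
    v: float = float("nan")
    drug: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_STATES,):
            raise ValueError(f"occupancy must have {N_STATES} entries")
        if np.any(self.p < -1e-9) or np.any(self.p > 1.0 + 1e-9):
            raise ValueError("occupancy entries outside [0, 1]")
        if abs(self.p.sum() - 1.0) > 1e-6:
            raise ValueError(f"occupancy sums to {self.p.sum()}, not 1")


@dataclass
class Trajectory:
    """Sampled occupancy under a piecewise-constant voltage protocol."""

    t: np.ndarray
    p: np.ndarray  # (n_samples, N_STATES)
    v: np.ndarray
    drug: np.ndarray


def _eval_monomial(values: Mapping[str, float], mono: Monomial) -> float:
    out = 1.0
    for name, exp in mono.items():
        base = values[name]
        if base == 0.0:
            return 0.0
        out *= base ** exp
    return out


class ChannelModel:
    """State list, labelled edges and generator-matrix builder."""

    def __init__(self) -> None:
        self.states = STATE_NAMES
        self.edges = EDGES

    # -- rate evaluation ------------------------------------------------
    @staticmethod
    def _values_at(params: "ConstructParameters", v: float) -> Dict[str, float]:
        vals = {name: law(v) for name, law in params.effective_laws().items()}
        vals.update(params.scalars())
        return vals

    def build_generator(self, params: "ConstructParameters", v: float,
                        drug: float = 0.0, validate: bool = False) -> np.ndarray:
        """Probability-conserving rate matrix Q with columns summing to zero."""
        if not math.isfinite(v):
            raise InvalidParameterError(f"voltage {v} is not finite")
        if drug < 0:
            raise InvalidParameterError(f"drug concentration {drug} < 0")
        vals = self._values_at(params, v)
        g = np.zeros((N_STATES, N_STATES))
        for e in self.edges:
            kf = _eval_monomial(vals, e.fwd)
            kb = _eval_monomial(vals, e.bwd)
            if e.binding:
                kf *= drug
            if validate:
                for k, mono in ((kf, e.fwd), (kb, e.bwd)):
                    if not math.isfinite(k) or k < 0.0:
                        raise InvalidParameterError(
                            f"rate {dict(mono)} -> {k} at V={v} mV is invalid")
            g[e.dst, e.src] += kf
            g[e.src, e.dst] += kb
        # diagonal set from the assembled columns; a second correction pass
        # removes the summation-order residue so conservation holds to
        # better than 1e-12 even with near-cap rates
        np.fill_diagonal(g, 0.0)
        np.fill_diagonal(g, -g.sum(axis=0))
        np.fill_diagonal(g, np.diag(g) - g.sum(axis=0))
        return g

    # -- steady state ----------------------------------------------------
    def steady_state(self, params: "ConstructParameters", v: float,
                     drug: float = 0.0) -> OccupancyState:
        g = self.build_generator(params, v, drug)
        p = generator_steady_state(g, drug_reachable=drug > 0.0)
        return OccupancyState(p=p, t=0.0, v=v, drug=drug)

    # -- propagation ------------------------------------------------------
    def propagate(self, params: "ConstructParameters",
                  segments: Sequence[Tuple[float, float, float]],
                  p0: OccupancyState | np.ndarray,
                  sample_dt: float | None = None) -> Trajectory:
        """Master-equation propagation through (duration, V, drug) segments.

        Piecewise-constant segments are stepped with the matrix exponential,
        which is exact to machine precision; ``sample_dt`` controls the
        sampling density inside each segment (None: segment endpoints only).
        """
        p = np.array(p0.p if isinstance(p0, OccupancyState) else p0, dtype=float)
        ts: List[float] = [0.0]
        ps: List[np.ndarray] = [p.copy()]
        vs: List[float] = [segments[0][1] if segments else float("nan")]
        ds: List[float] = [segments[0][2] if segments else 0.0]
        t = 0.0
        for si, (dur, v, drug) in enumerate(segments):
            if dur < 0:
                raise ValueError(f"segment {si}: negative duration {dur}")
            if dur == 0:
                continue
            g = self.build_generator(params, v, drug)
            if sample_dt is None or sample_dt >= dur:
                steps: List[Tuple[float, np.ndarray]] = [(dur, expm(g * dur))]
            else:
                n = int(dur / sample_dt)
                e_dt = expm(g * sample_dt)
                steps = [(sample_dt, e_dt)] * n
                rem = dur - n * sample_dt
                if rem > 1e-12:
                    steps.append((rem, expm(g * rem)))
            for dt, e_step in steps:
                p = e_step @ p
                np.clip(p, 0.0, None, out=p)
                s = p.sum()
                if abs(s - 1.0) > 1e-9:
                    p /= s
                t += dt
                ts.append(t)
                ps.append(p.copy())
                vs.append(v)
                ds.append(drug)
        return Trajectory(t=np.array(ts), p=np.array(ps), v=np.array(vs),
                          drug=np.array(ds))

    # -- observables -----------------------------------------------------
    @staticmethod
    def sodium_current(traj: Trajectory, params: "ConstructParameters",
                       ena: float = 65.0) -> np.ndarray:
        """I_Na = gNa * p_O * (V - ENa); only the free open state conducts."""
        return params.gna * traj.p[:, OPEN] * (traj.v - ena)

    @staticmethod
    def fluorescence_signal(traj_or_p, params: "ConstructParameters") -> np.ndarray:
        """DIII-VSD activation: (w1*sum A1 + w2*(sum A2 + bound)) / total."""
        p = traj_or_p.p if isinstance(traj_or_p, (Trajectory, OccupancyState)) else traj_or_p
        p = np.atleast_2d(np.asarray(p, dtype=float))
        a1 = p[:, list(A1_STATES)].sum(axis=1)
        a2 = p[:, list(A2_STATES) + list(BOUND_STATES)].sum(axis=1)
        tot = p.sum(axis=1)
        f = (params.w1 * a1 + params.w2 * a2) / tot
        return f if f.size > 1 else f[0]

    # -- diagnostics ------------------------------------------------------
    def check_reversibility(self, params: "ConstructParameters",
                            v_grid: Sequence[float] = (-140.0, -80.0, 0.0),
                            drug_grid: Sequence[float] = (0.0, 100.0)) -> List[float]:
        """|log cycle-product| for every independent cycle on the grids.

        Binding edges only participate when drug > 0 and the corresponding
        kon is non-zero (absent edges cannot violate reversibility).
        """
        import networkx as nx

        residuals: List[float] = []
        for drug in drug_grid:
            lookup: Dict[Tuple[int, int], Tuple[float, float]] = {}
            graph = nx.Graph()
            graph.add_nodes_from(range(N_STATES))
            for v in v_grid:
                vals = self._values_at(params, v)
                graph.clear_edges()
                lookup.clear()
                for e in self.edges:
                    kf = _eval_monomial(vals, e.fwd)
                    kb = _eval_monomial(vals, e.bwd)
                    if e.binding:
                        kf *= drug
                    if kf <= 0.0 or kb <= 0.0:
                        continue
                    lookup[(e.src, e.dst)] = (kf, kb)
                    graph.add_edge(e.src, e.dst)
                for cyc in nx.cycle_basis(graph):
                    logprod = 0.0
                    for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                        if (a, b) in lookup:
                            kf, kb = lookup[(a, b)]
                            logprod += math.log(kf / kb)
                        else:
                            kf, kb = lookup[(b, a)]
                            logprod -= math.log(kf / kb)
                    residuals.append(abs(logprod))
        return residuals

    def mean_open_time(self, params: "ConstructParameters", v: float = 0.0) -> float:
        """Open-state mean dwell time 1 / (sum of exit rates), ms."""
        g = self.build_generator(params, v, 0.0)
        return -1.0 / g[OPEN, OPEN]


def generator_steady_state(g: np.ndarray, drug_reachable: bool = True) -> np.ndarray:
    """Normalized null-space vector of a probability-conserving generator.

    With no drug the bound mirror states are unreachable and excluded before
    solving, so the null space of the reachable block must be 1-dimensional;
    a higher-dimensional null space raises :class:`DegenerateModelError`.
    """
    n = g.shape[0]
    idx = np.arange(n)
    if not drug_reachable and n == N_STATES:
        idx = np.arange(N_FREE)
    sub = g[np.ix_(idx, idx)]
    sv = np.linalg.svd(sub, compute_uv=False)
    tol = max(sub.shape) * np.finfo(float).eps * (sv[0] if sv[0] > 0 else 1.0)
    null_dim = int(np.sum(sv < max(tol, 1e-12)))
    if null_dim != 1:
        raise DegenerateModelError(
            f"generator null space has dimension {null_dim}; model graph disconnected?")
    a = np.vstack([sub, np.ones(len(idx))])
    b = np.zeros(len(idx) + 1)
    b[-1] = 1.0
    p_sub, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.any(p_sub < -1e-9):
        raise DegenerateModelError("steady state has significantly negative entries")
    p_sub = np.clip(p_sub, 0.0, None)
    p_sub /= p_sub.sum()
    p = np.zeros(n)
    p[idx] = p_sub
    return p


#: module-level singleton; the topology is fixed, parameters vary.
MODEL = ChannelModel()
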