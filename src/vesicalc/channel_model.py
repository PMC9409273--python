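"""Seven-state Markov model of the alpha3beta4 nicotinic receptor channel.

The module provides three layers:

* a data-driven rate graph (:class:`RateGraph`) whose edges are either
  constant rates or rates proportional to the agonist (ACh) concentration;
* deterministic propagation of a state-occupancy distribution under the
  master equation (:func:`propagate_distribution`), which doubles as the
  independent oracle for the stochastic sampler;
* stochastic gating of a channel ensemble (:func:`sample_ensemble`) and the
  conversion of the open-channel count into a calcium influx rate
  (:func:`calcium_influx_rate`).

The default topology is a linear two-site binding chain ``C0 = C1 = C2``
followed by the open state ``O``, a desensitized branch ``O = D = D2`` and an
agonist-dependent slow-inactivated state ``B``.  The graph is serialisable to
JSON so an alternative topology can be substituted without code changes; all
numerical routines only consume the generator matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "ChannelParams",
    "RateEdge",
    "RateGraph",
    "StateDistribution",
    "EnsembleTrace",
    "build_rate_graph",
    "propagate_distribution",
    "stationary_distribution",
    "sample_ensemble",
    "sample_paths",
    "calcium_influx_rate",
]

#: charge of a divalent calcium ion, in coulomb
_CA_CHARGE = 2.0 * 1.602176634e-19


@dataclass(frozen=True)
class ChannelParams:
    """Kinetic and current parameters of the receptor channel.

    Rates are in s^-1, except the agonist-dependent on-rates ``k_plus`` and
    ``k_pb`` which are in uM^-1 s^-1.  ``i_unit_pA`` is the whole
    single-channel current amplitude; it is a configurable order-of-magnitude
    default, not a measured value.
    """

    k_plus: float = 227.0          # uM^-1 s^-1, agonist binding
    k_minus: float = 38_541.0      # s^-1, agonist unbinding
    alpha: float = 2_024.0         # s^-1, channel closing
    beta: float = 50_600.0         # s^-1, channel opening
    k_pg: float = 49.0             # s^-1, desensitization forward
    k_mg: float = 512.0            # s^-1, desensitization backward
    # Slow-inactivation on-rate. NOTE: interpreted on the mM scale
    # (241.5 mM^-1 s^-1 = 0.2415 uM^-1 s^-1).  Taken per-uM at 100 uM agonist
    # the whole ensemble would inactivate within ~1 ms and the macroscopic
    # current would carry essentially no calcium, which is inconsistent with
    # a current that decays visibly over a 1 s pulse while sustaining
    # near-membrane calcium entry.  Override if a different reading is wanted.
    k_pb: float = 0.2415           # uM^-1 s^-1, slow inactivation forward
    k_mb: float = 0.3              # s^-1, slow inactivation backward
    ach_conc: float = 100.0        # uM
    f_ca: float = 0.025            # fractional calcium current
    i_unit_pA: float = 2.0         # pA, single-channel current (configurable)

    def __post_init__(self) -> None:
        for name in ("k_plus", "k_minus", "alpha", "beta", "k_pg", "k_mg",
                     "k_pb", "k_mb", "ach_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate parameter {name!r} must be >= 0")
        if not 0.0 <= self.f_ca <= 1.0:
            raise ValueError("f_ca must lie in [0, 1]")


@dataclass(frozen=True)
class RateEdge:
    """Directed transition with a constant or agonist-proportional rate."""

    src: str
    dst: str
    value: float
    kind: str = "const"  # "const" (s^-1) or "per_uM_ACh" (uM^-1 s^-1)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"edge {self.src}->{self.dst}: negative rate")
        if self.kind not in ("const", "per_uM_ACh"):
            raise ValueError(f"unknown edge kind {self.kind!r}")

    def rate(self, ach_conc: float) -> float:
        return self.value if self.kind == "const" else self.value * ach_conc


@dataclass(frozen=True)
class RateGraph:
    """Continuous-time Markov rate graph for one channel."""

    states: tuple[str, ...]
    edges: tuple[RateEdge, ...]
    open_state: str
    ground_state: str
    ach_conc: float

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state names")
        if self.open_state not in self.states:
            raise ValueError("open_state not among states")
        if self.ground_state not in self.states:
            raise ValueError("ground_state not among states")
        index = {s: i for i, s in enumerate(self.states)}
        adj = {s: set() for s in self.states}
        for e in self.edges:
            if e.src not in index or e.dst not in index:
                raise ValueError(f"edge {e.src}->{e.dst} uses unknown state")
            adj[e.src].add(e.dst)
            adj[e.dst].add(e.src)
        # connectivity (as an undirected graph)
        seen = {self.states[0]}
        stack = [self.states[0]]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if len(seen) != len(self.states):
            raise ValueError("rate graph is not connected")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def open_index(self) -> int:
        return self.states.index(self.open_state)

    @property
    def ground_index(self) -> int:
        return self.states.index(self.ground_state)

    def generator(self) -> np.ndarray:
        """Generator matrix Q with Q[i, j] = rate i->j, rows summing to 0."""
        n = self.n_states
        index = {s: i for i, s in enumerate(self.states)}
        q = np.zeros((n, n))
        for e in self.edges:
            q[index[e.src], index[e.dst]] += e.rate(self.ach_conc)
        q[np.diag_indices(n)] -= q.sum(axis=1)
        return q

    def with_ach(self, ach_conc: float) -> "RateGraph":
        if ach_conc < 0:
            raise ValueError("ach_conc must be >= 0")
        return replace(self, ach_conc=ach_conc)

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "states": list(self.states),
                "open_state": self.open_state,
                "ground_state": self.ground_state,
                "ach_conc": self.ach_conc,
                "edges": [
                    {"src": e.src, "dst": e.dst, "value": e.value, "kind": e.kind}
                    for e in self.edges
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RateGraph":
        d = json.loads(text)
        return cls(
            states=tuple(d["states"]),
            edges=tuple(RateEdge(**e) for e in d["edges"]),
            open_state=d["open_state"],
            ground_state=d["ground_state"],
            ach_conc=float(d["ach_conc"]),
        )


@dataclass
class StateDistribution:
    """Occupancy probability per state, summing to one."""

    graph: RateGraph
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.graph.n_states,):
            raise ValueError("probability vector has wrong length")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")

    @classmethod
    def point_mass(cls, graph: RateGraph, state: str) -> "StateDistribution":
        p = np.zeros(graph.n_states)
        p[graph.states.index(state)] = 1.0
        return cls(graph, p)

    @property
    def open_probability(self) -> float:
        return float(self.probs[self.graph.open_index])


@dataclass
class EnsembleTrace:
    """Per-state integer channel counts on a fixed time grid."""

    graph: RateGraph
    times: np.ndarray                 # (T,), seconds
    counts: np.ndarray                # (T, n_states) integers
    seed: int | None = None
    paths: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.times.size, self.graph.n_states):
            raise ValueError("counts shape does not match time grid")
        if np.any(self.counts < 0):
            raise ValueError("negative channel counts")
        totals = self.counts.sum(axis=1)
        if totals.size and np.any(totals != totals[0]):
            raise ValueError("channel count is not conserved")

    @property
    def n_channels(self) -> int:
        return int(self.counts[0].sum()) if self.counts.size else 0

    @property
    def open_count(self) -> np.ndarray:
        return self.counts[:, self.graph.open_index]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=[f"n_{s}" for s in self.graph.states])
        df.insert(0, "time_s", self.times)
        df["open_count"] = self.open_count
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_DEFAULT_STATES = ("C0", "C1", "C2", "O", "D", "B", "D2")


def build_rate_graph(params: ChannelParams) -> RateGraph:
    """Build the default 7-state topology from kinetic parameters.

    Binding chain carries statistical factors for two equivalent agonist
    sites (2*k_plus forward from C0, 2*k_minus backward from C2).  The deep
    desensitized state D2 reuses the k_pg/k_mg pair.
    """
    p = params
    edges = (
        RateEdge("C0", "C1", 2.0 * p.k_plus, "per_uM_ACh"),
        RateEdge("C1", "C0", p.k_minus),
        RateEdge("C1", "C2", p.k_plus, "per_uM_ACh"),
        RateEdge("C2", "C1", 2.0 * p.k_minus),
        RateEdge("C2", "O", p.beta),
        RateEdge("O", "C2", p.alpha),
        RateEdge("O", "D", p.k_pg),
        RateEdge("D", "O", p.k_mg),
        RateEdge("O", "B", p.k_pb, "per_uM_ACh"),
        RateEdge("B", "O", p.k_mb),
        RateEdge("D", "D2", p.k_pg),
        RateEdge("D2", "D", p.k_mg),
    )
    return RateGraph(
        states=_DEFAULT_STATES,
        edges=edges,
        open_state="O",
        ground_state="C0",
        ach_conc=p.ach_conc,
    )


def propagate_distribution(
    dist: StateDistribution, graph: RateGraph, dt: float
) -> StateDistribution:
    """Advance an occupancy distribution by ``dt`` under the master equation.

    Uses the exact matrix exponential of the generator; normalisation is
    preserved by construction and re-imposed to guard round-off.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return StateDistribution(graph, dist.probs.copy())
    p = expm(graph.generator().T * dt) @ dist.probs
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return StateDistribution(graph, p)


def stationary_distribution(graph: RateGraph) -> StateDistribution:
    """Stationary distribution from the null space of the generator."""
    ns = null_space(graph.generator().T)
    if ns.shape[1] != 1:
        # pick the non-negative extreme ray; with ach 0 the chain is reducible
        raise ValueError("generator null space is not one-dimensional")
    p = ns[:, 0]
    p = np.abs(p)
    p /= p.sum()
    return StateDistribution(graph, p)


def _max_exit_rate(q: np.ndarray) -> float:
    return float(np.max(-np.diag(q))) if q.size else 0.0


def sample_ensemble(
    n_channels: int,
    graph: RateGraph,
    duration: float,
    dt: float,
    seed: int | None = None,
    init: Sequence[int] | str | None = None,
    method: str = "substep",
    max_substeps: int = 100_000,
) -> EnsembleTrace:
    """Sample stochastic gating of ``n_channels`` independent channels.

    Parameters
    ----------
    init:
        Initial per-state counts, a state name, or None for all channels in
        the unliganded ground state.
    method:
        ``"substep"`` — fixed-step jump sampling on state counts with
        automatic sub-stepping so the total exit probability per sub-step is
        at most 0.1.  ``"gillespie"`` — exact event-driven sampling per
        channel; stores per-channel paths on the returned trace.
    """
    if n_channels < 0:
        raise ValueError("n_channels must be >= 0")
    if duration < 0 or dt <= 0:
        raise ValueError("need duration >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    q = graph.generator()
    n = graph.n_states
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt

    counts0 = np.zeros(n, dtype=np.int64)
    if init is None:
        counts0[graph.ground_index] = n_channels
    elif isinstance(init, str):
        counts0[graph.states.index(init)] = n_channels
    else:
        counts0[:] = np.asarray(init, dtype=np.int64)
        if counts0.sum() != n_channels or np.any(counts0 < 0):
            raise ValueError("init counts must be non-negative and sum to n_channels")

    if n_channels == 0 or n_steps == 0:
        counts = np.tile(counts0, (n_steps + 1, 1))
        return EnsembleTrace(graph, times, counts, seed=seed)

    if method == "gillespie":
        paths = sample_paths(graph, n_channels, duration, rng=rng, init=counts0)
        counts = _paths_to_counts(paths, times, n)
        return EnsembleTrace(graph, times, counts, seed=seed, paths=paths)
    if method != "substep":
        raise ValueError(f"unknown method {method!r}")

    rmax = _max_exit_rate(q)
    n_sub = max(1, int(math.ceil(rmax * dt / 0.1)))
    if n_sub > max_substeps:
        raise ValueError(
            f"dt={dt} requires {n_sub} sub-steps (> {max_substeps}); reduce dt"
        )
    dts = dt / n_sub
    # per-state jump probabilities per sub-step: [stay, to_state_0, ...]
    jump_p = np.zeros((n, n + 1))
    for i in range(n):
        out = q[i].copy()
        out[i] = 0.0
        jump_p[i, 1:] = out * dts
        jump_p[i, 0] = 1.0 - jump_p[i, 1:].sum()

    counts = np.empty((n_steps + 1, n), dtype=np.int64)
    counts[0] = counts0
    cur = counts0.copy()
    for step in range(n_steps):
        for _ in range(n_sub):
            nxt = np.zeros(n, dtype=np.int64)
            for i in range(n):
                c = cur[i]
                if c == 0:
                    continue
                moved = rng.multinomial(c, jump_p[i])
                nxt[i] += moved[0]
                nxt += moved[1:]
            cur = nxt
        counts[step + 1] = cur
    return EnsembleTrace(graph, times, counts, seed=seed)


def sample_paths(
    graph: RateGraph,
    n_channels: int,
    duration: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    init: Sequence[int] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Exact (Gillespie) per-channel trajectories.

    Returns one ``(jump_times, states)`` pair per channel where ``states[k]``
    is occupied on ``[jump_times[k], jump_times[k+1])``; ``jump_times[0]`` is
    always 0.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    q = graph.generator()
    n = graph.n_states
    exit_rate = -np.diag(q)
    jump = q.copy()
    np.fill_diagonal(jump, 0.0)
    with np.errstate(invalid="ignore"):
        cum = np.cumsum(jump, axis=1)
        cum /= np.where(cum[:, -1:] > 0, cum[:, -1:], 1.0)

    if init is None:
        start_states = np.full(n_channels, graph.ground_index)
    else:
        start_states = np.repeat(np.arange(n), np.asarray(init, dtype=int))
    paths = []
    for ch in range(n_channels):
        s = int(start_states[ch])
        t = 0.0
        ts, ss = [0.0], [s]
        while True:
            r = exit_rate[s]
            if r <= 0.0:
                break
            t += rng.exponential(1.0 / r)
            if t >= duration:
                break
            s = int(np.searchsorted(cum[s], rng.random()))
            ts.append(t)
            ss.append(s)
        paths.append((np.array(ts), np.array(ss, dtype=np.int64)))
    return paths


def _paths_to_counts(paths, times: np.ndarray, n_states: int) -> np.ndarray:
    counts = np.zeros((times.size, n_states), dtype=np.int64)
    for ts, ss in paths:
        idx = np.searchsorted(ts, times, side="right") - 1
        states_at = ss[idx]
        counts[np.arange(times.size), states_at] += 1
    return counts


def open_series_from_paths(paths, times: np.ndarray, open_index: int) -> np.ndarray:
    """Boolean (n_channels, T) matrix: channel open at each grid time."""
    out = np.zeros((len(paths), times.size), dtype=bool)
    for i, (ts, ss) in enumerate(paths):
        idx = np.searchsorted(ts, times, side="right") - 1
        out[i] = ss[idx] == open_index
    return out


def dwell_times(paths, state_index: int, duration: float) -> np.ndarray:
    """Completed sojourn durations in one state, pooled over channels.

    Sojourns truncated by the end of the observation window are discarded so
    the sample mean estimates the exponential dwell mean without censoring
    bias.
    """
    out = []
    for ts, ss in paths:
        bounds = np.append(ts, duration)
        for k in range(len(ss)):
            if ss[k] == state_index and k + 1 < len(bounds) - 0:
                end = bounds[k + 1]
                if end < duration:  # completed sojourn only
                    out.append(end - bounds[k])
    return np.asarray(out)


def calcium_influx_rate(open_count: int, params: ChannelParams) -> float:
    """Calcium ion influx (ions/s) carried by ``open_count`` open channels.

    The calcium component is ``f_ca`` of the unit current; each ion carries
    two elementary charges.
    """
    if open_count < 0:
        raise ValueError("open_count must be >= 0")
    i_ca = open_count * params.f_ca * params.i_unit_pA * 1e-12  # ampere
    return i_ca / _CA_CHARGE
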