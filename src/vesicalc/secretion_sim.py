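"""Particle-based Monte Carlo simulation of calcium buffered diffusion and
vesicle fusion in a conical sub-membrane domain.

The domain is an orthogonal 3D lattice clipped to a cone whose base (slice 0)
represents the plasma membrane.  Receptor channels inject calcium ions at
slice-0 voxels; ions perform a lattice random walk with reflecting walls,
bind reversibly to an immobile buffer, and load the three binding sites of
secretory vesicles, which fuse irreversibly once fully loaded.

Two channel/vesicle geometries are supported: ``random`` (both placed
uniformly on slice 0) and ``colocalized`` (channels placed randomly, then
vesicles placed on the nearest available slice-0 voxels).

`diffusion_step`, `reaction_step` and `vesicle_step` are reference numpy
implementations of the three stochastic update rules, used directly in unit
and acceptance tests; `run_pulse` drives the same rules through a fused
numba kernel for speed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.constants import N_A

from . import channel_model as cm
from ._kernels import core_pulse

__all__ = [
    "ConeDomain",
    "box_domain",
    "discretize_cone",
    "BufferField",
    "Vesicle",
    "SimConfig",
    "SimResult",
    "place_channels",
    "place_vesicles",
    "diffusion_step",
    "reaction_step",
    "vesicle_step",
    "run_pulse",
]

_MAX_EVENT_P = 0.1  # per-event probability bound before sub-stepping


def _molar_per_molecule_uM(dx_um: float) -> float:
    """Concentration (µM) contributed by one molecule in a dx^3 voxel."""
    return 1e21 / (N_A * dx_um**3)


# ---------------------------------------------------------------------------
# domain
# ---------------------------------------------------------------------------


class ConeDomain:
    """Orthogonal 3D lattice clipped to a cone (or any voxel predicate).

    Voxel centers sit on the lattice ``(i*dx, j*dx, k*dx)``; slice ``k`` is
    the set of voxels at depth ``k*dx`` from the membrane (slice 0 = base).
    ``neighbors[v, d]`` holds the voxel index one lattice step away along
    +x, -x, +y, -y, +z, -z, or -1 where the step leaves the domain.
    """

    def __init__(self, coords: np.ndarray, dx: float, base_radius: float,
                 height: float):
        self.coords = np.asarray(coords, dtype=np.int64)  # (N, 3) i, j, k
        self.dx = float(dx)
        self.base_radius = float(base_radius)
        self.height = float(height)
        self._index = {tuple(c): n for n, c in enumerate(map(tuple, self.coords))}
        self.neighbors = self._build_neighbors()
        self.slice_index = self.coords[:, 2].copy()

    def _build_neighbors(self) -> np.ndarray:
        steps = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=np.int64,
        )
        nb = np.full((len(self.coords), 6), -1, dtype=np.int32)
        for n, c in enumerate(self.coords):
            for d, s in enumerate(steps):
                nb[n, d] = self._index.get(tuple(c + s), -1)
        return nb

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx**3

    @property
    def molar_per_molecule_uM(self) -> float:
        return _molar_per_molecule_uM(self.dx)

    @property
    def slice0(self) -> np.ndarray:
        """Indices of the membrane (slice 0) voxels."""
        return np.flatnonzero(self.slice_index == 0)

    def positions_um(self, idx) -> np.ndarray:
        return self.coords[idx] * self.dx

    def contains_point(self, i: int, j: int, k: int) -> bool:
        return (i, j, k) in self._index


def discretize_cone(base_radius: float = 1.0, height: float = 5.0,
                    dx: float = 0.07) -> ConeDomain:
    """Clip the regular lattice to the cone r(z) <= R*(1 - z/h).

    Grid points (not cell corners) are kept when their center satisfies the
    cone inequality; slice 0 therefore tiles the base disk of radius R.
    """
    if dx <= 0 or base_radius <= 0 or height <= 0:
        raise ValueError("geometry parameters must be positive")
    if dx >= base_radius:
        raise ValueError("dx must be smaller than the base radius")
    m = int(math.floor(base_radius / dx))
    kmax = int(math.floor(height / dx))
    coords = []
    eps = 1e-12
    for k in range(kmax + 1):
        r_k = base_radius * (1.0 - k * dx / height)
        if r_k < -eps:
            break
        r2 = (r_k / dx) ** 2 + eps
        for i in range(-m, m + 1):
            for j in range(-m, m + 1):
                if i * i + j * j <= r2:
                    coords.append((i, j, k))
    return ConeDomain(np.array(coords), dx, base_radius, height)


class _BoxIndex:
    """Arithmetic (i, j, k) -> voxel index map for rectangular lattices."""

    def __init__(self, nx: int, ny: int, nz: int):
        self.shape = (nx, ny, nz)

    def _flat(self, key):
        i, j, k = key
        nx, ny, nz = self.shape
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
            return (i * ny + j) * nz + k
        return None

    def __contains__(self, key) -> bool:
        return self._flat(key) is not None

    def __getitem__(self, key) -> int:
        out = self._flat(key)
        if out is None:
            raise KeyError(key)
        return out

    def get(self, key, default=-1):
        out = self._flat(key)
        return default if out is None else out


def box_domain(nx: int, ny: int, nz: int, dx: float = 0.07) -> ConeDomain:
    """Rectangular lattice domain with reflecting walls (testing helper)."""
    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    coords = np.column_stack([i.ravel(), j.ravel(), k.ravel()])
    dom = ConeDomain.__new__(ConeDomain)
    dom.coords = coords.astype(np.int64)
    dom.dx = float(dx)
    dom.base_radius = nx * dx
    dom.height = nz * dx
    dom._index = _BoxIndex(nx, ny, nz)
    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    nb = np.full((nx * ny * nz, 6), -1, dtype=np.int32)
    nb[idx[:-1].ravel(), 0] = idx[1:].ravel()       # +x
    nb[idx[1:].ravel(), 1] = idx[:-1].ravel()       # -x
    nb[idx[:, :-1].reshape(-1), 2] = idx[:, 1:].reshape(-1)   # +y
    nb[idx[:, 1:].reshape(-1), 3] = idx[:, :-1].reshape(-1)   # -y
    nb[idx[:, :, :-1].reshape(-1), 4] = idx[:, :, 1:].reshape(-1)  # +z
    nb[idx[:, :, 1:].reshape(-1), 5] = idx[:, :, :-1].reshape(-1)  # -z
    dom.neighbors = nb
    dom.slice_index = dom.coords[:, 2].copy()
    return dom


# ---------------------------------------------------------------------------
# particles
# ---------------------------------------------------------------------------


@dataclass
class BufferField:
    """Immobile buffer: per-voxel totals and bound counts.

    ``k_on`` is in M^-1 s^-1 and ``kd_uM`` in µM; the off rate is
    ``k_on * Kd``.  Totals never change (the buffer does not diffuse).
    """

    domain: ConeDomain
    total: np.ndarray          # (N,) int64 molecules per voxel
    bound: np.ndarray          # (N,) int64
    k_on: float = 5e8          # M^-1 s^-1
    kd_uM: float = 10.0

    @classmethod
    def from_concentration(cls, domain: ConeDomain, conc_uM: float = 500.0,
                          k_on: float = 5e8, kd_uM: float = 10.0) -> "BufferField":
        per_voxel = int(round(conc_uM / domain.molar_per_molecule_uM))
        total = np.full(domain.n_voxels, per_voxel, dtype=np.int64)
        return cls(domain, total, np.zeros(domain.n_voxels, dtype=np.int64),
                   k_on, kd_uM)

    @property
    def k_off(self) -> float:
        return self.k_on * self.kd_uM * 1e-6

    def validate(self) -> None:
        if np.any(self.bound < 0) or np.any(self.bound > self.total):
            raise ValueError("bound buffer outside [0, total]")


@dataclass
class Vesicle:
    """Secretory vesicle on a slice-0 voxel with 3 calcium binding sites."""

    voxel: int
    sites_total: int = 3
    sites_bound: int = 0
    fused: bool = False
    fusion_time: float | None = None
    k_on: float = 8e6            # M^-1 s^-1, per site
    kd_uM: float = 13.0
    gamma_fuse: float = 1000.0   # s^-1 once fully loaded

    @property
    def k_off(self) -> float:
        return self.k_on * self.kd_uM * 1e-6

    def validate(self) -> None:
        if not 0 <= self.sites_bound <= self.sites_total:
            raise ValueError("sites_bound outside [0, sites_total]")


@dataclass
class SimConfig:
    """Full configuration of a pulse simulation (defaults per the study)."""

    n_channels: int = 7
    n_vesicles: int = 10
    mode: str = "random"             # "random" | "colocalized"
    pulse_s: float = 1.0
    ach_uM: float = 100.0
    d_ca: float = 220.0              # µm^2 s^-1
    ca_basal_uM: float = 0.1
    buffer_uM: float = 500.0
    buffer_k_on: float = 5e8         # M^-1 s^-1
    buffer_kd_uM: float = 10.0
    ves_k_on: float = 8e6            # M^-1 s^-1
    ves_kd_uM: float = 13.0
    ves_sites: int = 3
    gamma_fuse: float = 1000.0       # s^-1
    base_radius: float = 1.0         # µm
    height: float = 5.0              # µm
    dx: float = 0.07                 # µm
    seed: int = 0
    n_replicates: int = 5
    equil_s: float = 0.01
    record_dt_s: float = 1e-3
    dt_scale: float = 1.0            # master dt = dt_scale * dx^2/(6 D)
    channel: cm.ChannelParams = field(default_factory=cm.ChannelParams)

    def __post_init__(self) -> None:
        if self.mode not in ("random", "colocalized"):
            raise ValueError("mode must be 'random' or 'colocalized'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.dt_scale <= 1.0:
            raise ValueError("dt_scale must lie in (0, 1]")
        if isinstance(self.channel, dict):
            self.channel = cm.ChannelParams(**self.channel)
        object.__setattr__(self, "channel",
                           replace(self.channel, ach_conc=self.ach_uM))

    @property
    def dt(self) -> float:
        return self.dt_scale * self.dx**2 / (6.0 * self.d_ca)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def place_channels(domain: ConeDomain, n_channels: int, seed=None) -> np.ndarray:
    """Distinct slice-0 voxels drawn uniformly without replacement."""
    s0 = domain.slice0
    if n_channels > s0.size:
        raise ValueError(f"cannot place {n_channels} channels on "
                         f"{s0.size} membrane voxels")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(s0, size=n_channels, replace=False))


def place_vesicles(domain: ConeDomain, channels: np.ndarray, mode: str,
                   n_vesicles: int, seed=None) -> list[Vesicle]:
    """Place vesicles on slice-0 voxels not occupied by channels.

    ``random``: uniform without replacement over the available voxels.
    ``colocalized``: the available voxels closest (XY Euclidean) to any
    channel, ties broken in seed-reproducible random order.
    """
    s0 = domain.slice0
    avail = np.setdiff1d(s0, channels)
    if n_vesicles > avail.size:
        raise ValueError("not enough free membrane voxels for the vesicles")
    rng = np.random.default_rng(seed)
    if n_vesicles == 0:
        chosen = np.empty(0, dtype=np.int64)
    elif mode == "random":
        chosen = rng.choice(avail, size=n_vesicles, replace=False)
    elif mode == "colocalized":
        if channels.size == 0:
            raise ValueError("colocalized mode needs at least one channel")
        pa = domain.positions_um(avail)[:, :2]
        pc = domain.positions_um(channels)[:, :2]
        d = np.sqrt(((pa[:, None, :] - pc[None, :, :]) ** 2).sum(-1)).min(1)
        perm = rng.permutation(avail.size)
        order = perm[np.argsort(d[perm], kind="stable")]
        chosen = avail[order[:n_vesicles]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [Vesicle(voxel=int(v)) for v in chosen]


# ---------------------------------------------------------------------------
# reference update rules (numpy)
# ---------------------------------------------------------------------------


def diffusion_step(ion_voxels: np.ndarray, domain: ConeDomain, d_coef: float,
                   dt: float, rng: np.random.Generator) -> np.ndarray:
    """One lattice diffusion step; moves crossing a wall are bounced.

    Each ion moves to a given neighbour with probability ``D*dt/dx^2``
    (requires ``dt <= dx^2 / (6 D)``); ion count is conserved.
    """
    if d_coef < 0 or dt < 0:
        raise ValueError("need D >= 0 and dt >= 0")
    p = d_coef * dt / domain.dx**2
    if 6.0 * p > 1.0 + 1e-12:
        raise ValueError("dt too large: require dt <= dx^2/(6 D)")
    ion_voxels = np.asarray(ion_voxels, dtype=np.int64)
    n = ion_voxels.size
    if n == 0 or p == 0.0:
        return ion_voxels.copy()
    u = rng.random(n)
    moving = u < 6.0 * p
    out = ion_voxels.copy()
    if moving.any():
        dirs = np.minimum((u[moving] / p).astype(np.int64), 5)
        tgt = domain.neighbors[ion_voxels[moving], dirs]
        ok = tgt >= 0
        idx = np.flatnonzero(moving)[ok]
        out[idx] = tgt[ok]
    return out


def _substeps(max_rate: float, dt: float) -> int:
    return max(1, int(math.ceil(max_rate * dt / _MAX_EVENT_P)))


def reaction_step(ion_voxels: np.ndarray, buffer: BufferField, dt: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, BufferField]:
    """Calcium <-> immobile buffer exchange over one step of length ``dt``.

    Per free ion: binding probability ``1 - exp(-k_on [B_free] dt)`` with the
    free-buffer concentration of its voxel; per bound molecule: release
    probability ``1 - exp(-k_off dt)``.  Sub-stepped internally so every
    per-event probability is at most 0.1.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    ions = np.asarray(ion_voxels, dtype=np.int64).copy()
    bound = buffer.bound.copy()
    if dt == 0:
        return ions, replace(buffer, bound=bound)
    c1 = buffer.domain.molar_per_molecule_uM
    kon_uM = buffer.k_on * 1e-6
    max_rate = max(kon_uM * c1 * float(buffer.total.max(initial=0)),
                   buffer.k_off)
    n_sub = _substeps(max_rate, dt)
    dts = dt / n_sub
    p_off = 1.0 - math.exp(-buffer.k_off * dts)
    for _ in range(n_sub):
        if ions.size:
            bfree = buffer.total[ions] - bound[ions]
            p = 1.0 - np.exp(-kon_uM * c1 * bfree * dts)
            hit = rng.random(ions.size) < p
            if hit.any():
                hv = ions[hit]
                binds = np.bincount(hv, minlength=bound.size)
                over = np.flatnonzero(binds > buffer.total - bound)
                if over.size:  # rare: more hits than free buffer in a voxel
                    hit_idx = np.flatnonzero(hit)
                    for v in over:
                        excess = binds[v] - (buffer.total[v] - bound[v])
                        drop = hit_idx[ions[hit_idx] == v][-excess:]
                        hit[drop] = False
                    hv = ions[hit]
                    binds = np.bincount(hv, minlength=bound.size)
                bound += binds
                ions = ions[~hit]
        occ = np.flatnonzero(bound)
        if occ.size:
            rel = rng.binomial(bound[occ], p_off)
            bound[occ] -= rel
            if rel.sum():
                ions = np.concatenate([ions, np.repeat(occ, rel)])
    out = BufferField(buffer.domain, buffer.total, bound, buffer.k_on,
                      buffer.kd_uM)
    out.validate()
    return ions, out


def vesicle_step(vesicles: list[Vesicle], ion_voxels: np.ndarray,
                 domain: ConeDomain, dt: float, rng: np.random.Generator,
                 t_now: float = 0.0) -> tuple[list[Vesicle], np.ndarray, int]:
    """Vesicle site kinetics and fusion over one step.

    Order per vesicle: fusion (state at step start), unbinding, binding.
    Returns updated vesicles, the updated free-ion array, and the number of
    ions retired by fusions during the step ("vesicle-consumed").
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    ions = np.asarray(ion_voxels, dtype=np.int64).copy()
    consumed = 0
    c1 = domain.molar_per_molecule_uM
    out = []
    for ves in vesicles:
        ves = replace(ves)
        if ves.fused:
            out.append(ves)
            continue
        n_sub = _substeps(
            max(ves.gamma_fuse, ves.k_off,
                ves.k_on * 1e-6 * c1 * max(1, np.count_nonzero(ions == ves.voxel))),
            dt,
        )
        dts = dt / n_sub
        p_fuse = 1.0 - math.exp(-ves.gamma_fuse * dts)
        p_off = 1.0 - math.exp(-ves.k_off * dts)
        for s in range(n_sub):
            if ves.sites_bound == ves.sites_total and rng.random() < p_fuse:
                ves.fused = True
                ves.fusion_time = t_now + (s + 1) * dts
                consumed += ves.sites_bound
                break
            if ves.sites_bound:
                k = rng.binomial(ves.sites_bound, p_off)
                if k:
                    ves.sites_bound -= k
                    ions = np.concatenate([ions, np.full(k, ves.voxel)])
            free_here = np.count_nonzero(ions == ves.voxel)
            n_free_sites = ves.sites_total - ves.sites_bound
            if free_here and n_free_sites:
                p_on = 1.0 - math.exp(-ves.k_on * 1e-6 * c1 * free_here * dts)
                k = min(int(rng.binomial(n_free_sites, p_on)), free_here)
                if k:
                    ves.sites_bound += k
                    where = np.flatnonzero(ions == ves.voxel)[:k]
                    ions = np.delete(ions, where)
        ves.validate()
        out.append(ves)
    return out, ions, consumed


# ---------------------------------------------------------------------------
# full pulse simulation
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Recorded time series for every replicate plus replicate averages."""

    config: SimConfig
    times: np.ndarray                       # (T,) seconds
    current_pA: np.ndarray                  # (R, T) calcium current
    ca_slice0_uM: np.ndarray                # (R, T) mean free [Ca] in slice 0
    fused_pct: np.ndarray                   # (R, T) cumulative fused %
    ledger: dict[str, np.ndarray]           # each (R, T): free/bound/...
    seeds: list[int]
    channel_voxels: list[np.ndarray]
    vesicle_voxels: list[np.ndarray]

    @property
    def avg_current_pA(self) -> np.ndarray:
        return self.current_pA.mean(axis=0)

    @property
    def avg_ca_slice0_uM(self) -> np.ndarray:
        return self.ca_slice0_uM.mean(axis=0)

    @property
    def avg_fused_pct(self) -> np.ndarray:
        return self.fused_pct.mean(axis=0)

    def ledger_balanced(self) -> bool:
        lg = self.ledger
        lhs = lg["initial"] + lg["injected"]
        rhs = lg["free"] + lg["buffer_bound"] + lg["vesicle_bound"] + lg["consumed"]
        return bool(np.all(lhs == rhs))

    def to_frame(self):
        import pandas as pd

        rows = {}
        rows["time_s"] = self.times
        for r in range(self.current_pA.shape[0]):
            rows[f"current_pA_rep{r}"] = self.current_pA[r]
            rows[f"ca_slice0_uM_rep{r}"] = self.ca_slice0_uM[r]
            rows[f"fused_pct_rep{r}"] = self.fused_pct[r]
        rows["current_pA_mean"] = self.avg_current_pA
        rows["ca_slice0_uM_mean"] = self.avg_ca_slice0_uM
        rows["fused_pct_mean"] = self.avg_fused_pct
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "timeseries.csv", index=False)
        summary = {
            "config": asdict(self.config),
            "seeds": self.seeds,
            "ledger_balanced": self.ledger_balanced(),
            "final_fused_pct_mean": float(self.avg_fused_pct[-1]),
            "channel_voxels": [v.tolist() for v in self.channel_voxels],
            "vesicle_voxels": [v.tolist() for v in self.vesicle_voxels],
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


_DOMAIN_CACHE: dict[tuple, ConeDomain] = {}


def get_domain(config: SimConfig) -> ConeDomain:
    key = (config.base_radius, config.height, config.dx)
    if key not in _DOMAIN_CACHE:
        _DOMAIN_CACHE[key] = discretize_cone(*key)
    return _DOMAIN_CACHE[key]


def _gating_open_matrix(config: SimConfig, n_steps: int, dt: float,
                        seed: int) -> np.ndarray:
    """(n_channels, n_steps) open/closed matrix from exact gating paths."""
    graph = cm.build_rate_graph(config.channel)
    paths = cm.sample_paths(graph, config.n_channels, n_steps * dt, seed=seed)
    times = (np.arange(n_steps) + 0.5) * dt
    return cm.open_series_from_paths(paths, times, graph.open_index).astype(np.uint8)


def run_pulse(config: SimConfig) -> SimResult:
    """Simulate ``n_replicates`` pulses and collect averaged time series."""
    domain = get_domain(config)
    dt = config.dt
    n_steps = int(round(config.pulse_s / dt))
    n_equil = int(round(config.equil_s / dt))
    stride = max(1, int(round(config.record_dt_s / dt)))

    c1 = domain.molar_per_molecule_uM
    btotal = int(round(config.buffer_uM / c1))
    kon_uM = config.buffer_k_on * 1e-6
    k_off = config.buffer_k_on * config.buffer_kd_uM * 1e-6
    p_bind_table = 1.0 - np.exp(-kon_uM * c1 * np.arange(btotal + 1) * dt)
    rel_every = max(1, int(math.floor(_MAX_EVENT_P / (k_off * dt))))
    p_rel = 1.0 - math.exp(-k_off * rel_every * dt)
    p_dir = config.d_ca * dt / config.dx**2
    lam_open = cm.calcium_influx_rate(1, config.channel) * dt
    ves_on_per_ion = config.ves_k_on * 1e-6 * c1
    p_ves_off = 1.0 - math.exp(-config.ves_k_on * config.ves_kd_uM * 1e-6 * dt)
    p_fuse = 1.0 - math.exp(-config.gamma_fuse * dt)
    is_slice0 = (domain.slice_index == 0).astype(np.uint8)
    n_slice0 = int(is_slice0.sum())

    reps = {k: [] for k in ("current", "ca", "fused", "free", "bound",
                            "vbound", "consumed", "injected", "initial")}
    seeds, ch_list, ves_list = [], [], []
    times = None

    for r in range(config.n_replicates):
        ss = np.random.SeedSequence([config.seed, r])
        s_place, s_ves, s_gate, s_basal, s_equil, s_core = [
            int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(6)
        ]
        channels = place_channels(domain, config.n_channels, s_place)
        vesicles = place_vesicles(domain, channels, config.mode,
                                  config.n_vesicles, s_ves)
        open_mat = _gating_open_matrix(config, n_steps, dt, s_gate)

        # basal calcium + empty buffer, then pre-equilibration
        rng = np.random.default_rng(s_basal)
        n_basal = rng.poisson(config.ca_basal_uM / c1 * domain.n_voxels)
        exp_inj = lam_open * open_mat.sum()
        cap = int(n_basal + exp_inj + 10 * math.sqrt(exp_inj + 1) + 10_000)
        ion_vox = np.zeros(cap, dtype=np.int64)
        ion_vox[:n_basal] = rng.integers(0, domain.n_voxels, n_basal)
        bound = np.zeros(domain.n_voxels, dtype=np.int64)

        ves_vox = np.array([v.voxel for v in vesicles], dtype=np.int64)
        ves_sites = np.zeros(len(vesicles), dtype=np.int64)
        ves_fused = np.zeros(len(vesicles), dtype=np.uint8)
        ves_fuse_step = np.full(len(vesicles), -1, dtype=np.int64)

        cons0 = 0
        if n_equil:
            rec0 = np.zeros((3, len(_REC)), dtype=np.float64)
            n_free, _, cons0, _ = core_pulse(
                s_equil, n_equil, n_equil, domain.neighbors, is_slice0,
                ion_vox, n_basal, bound, btotal, p_bind_table,
                p_rel, rel_every, p_dir,
                np.zeros((config.n_channels, n_equil), dtype=np.uint8),
                channels.astype(np.int64),
                0.0, ves_vox, ves_sites, ves_fused, ves_fuse_step,
                config.ves_sites, ves_on_per_ion, p_ves_off, p_fuse, dt,
                rec0, 0, 0)
        else:
            n_free = n_basal

        active = ves_fused == 0
        initial_total = (n_free + int(bound.sum())
                         + int(ves_sites[active].sum()) + cons0)
        n_rec = n_steps // stride + 2
        rec = np.zeros((n_rec, len(_REC)), dtype=np.float64)
        n_free, injected, consumed, used = core_pulse(
            s_core, n_steps, stride, domain.neighbors, is_slice0,
            ion_vox, n_free, bound, btotal, p_bind_table,
            p_rel, rel_every, p_dir, open_mat, channels.astype(np.int64),
            lam_open, ves_vox, ves_sites, ves_fused, ves_fuse_step,
            config.ves_sites, ves_on_per_ion, p_ves_off, p_fuse, dt,
            rec, 0, cons0)
        rec = rec[:used]
        if times is None:
            times = rec[:, 0] * dt
        i_ca_pA = config.channel.f_ca * config.channel.i_unit_pA
        reps["current"].append(rec[:, 1] * i_ca_pA)
        reps["ca"].append(rec[:, 7] / n_slice0 * c1)
        nv = max(1, config.n_vesicles)
        reps["fused"].append(rec[:, 6] / nv * 100.0)
        reps["free"].append(rec[:, 2].astype(np.int64))
        reps["bound"].append(rec[:, 3].astype(np.int64))
        reps["vbound"].append(rec[:, 4].astype(np.int64))
        reps["consumed"].append(rec[:, 5].astype(np.int64))
        reps["injected"].append(rec[:, 8].astype(np.int64))
        reps["initial"].append(np.full(used, initial_total, dtype=np.int64))
        seeds.append(r)
        ch_list.append(channels)
        ves_list.append(ves_vox)

    ledger = {
        "free": np.vstack(reps["free"]),
        "buffer_bound": np.vstack(reps["bound"]),
        "vesicle_bound": np.vstack(reps["vbound"]),
        "consumed": np.vstack(reps["consumed"]),
        "injected": np.vstack(reps["injected"]),
        "initial": np.vstack(reps["initial"]),
    }
    return SimResult(
        config=config,
        times=times,
        current_pA=np.vstack(reps["current"]),
        ca_slice0_uM=np.vstack(reps["ca"]),
        fused_pct=np.vstack(reps["fused"]),
        ledger=ledger,
        seeds=seeds,
        channel_voxels=ch_list,
        vesicle_voxels=ves_list,
    )


_REC = ("step", "open_count", "free", "bound", "ves_bound", "consumed",
        "fused", "slice0_free", "injected")
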