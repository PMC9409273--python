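import dataclasses
import math

import numpy as np
import pytest

from vesicalc import secretion_sim as sim
from vesicalc.secretion_sim import (
    BufferField,
    SimConfig,
    Vesicle,
    box_domain,
    diffusion_step,
    discretize_cone,
    place_channels,
    place_vesicles,
    reaction_step,
    run_pulse,
    vesicle_step,
)


# ---------------------------------------------------------------------------
# domain
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("bad", [
    dict(dx=1.0, base_radius=1.0),       # dx == radius
    dict(dx=2.0, base_radius=1.0),       # dx > radius
    dict(dx=-0.1, base_radius=1.0),
    dict(base_radius=0.0),
])
def test_degenerate_geometry_rejected(bad):
    with pytest.raises(ValueError):
        discretize_cone(**bad)


def test_voxels_satisfy_cone_inequality(cone):
    xyz = cone.coords * cone.dx
    r = np.hypot(xyz[:, 0], xyz[:, 1])
    allowed = cone.base_radius * (1.0 - xyz[:, 2] / cone.height)
    assert np.all(r <= allowed + 1e-9)


def test_slice0_matches_brute_force_enumeration(cone):
    """[DERIVED] independent enumeration of grid points in the base disk."""
    dx, r = cone.dx, cone.base_radius
    m = int(math.floor(r / dx))
    count = sum(
        1
        for i in range(-m, m + 1)
        for j in range(-m, m + 1)
        if math.hypot(i * dx, j * dx) <= r + 1e-12
    )
    assert cone.slice0.size == count


def test_neighbors_are_symmetric(small_cone):
    nb = small_cone.neighbors
    for v in range(small_cone.n_voxels):
        for d in range(6):
            w = nb[v, d]
            if w >= 0:
                back = d + 1 if d % 2 == 0 else d - 1
                assert nb[w, back] == v


def test_voxel_molarity_constant(cone):
    # one molecule in a (70 nm)^3 voxel is ~4.84 µM
    assert cone.molar_per_molecule_uM == pytest.approx(4.84, rel=2e-3)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def test_place_channels_distinct_slice0(cone):
    ch = place_channels(cone, 7, seed=1)
    assert len(set(ch.tolist())) == 7
    assert np.all(cone.slice_index[ch] == 0)


def test_place_channels_deterministic(cone):
    assert np.array_equal(place_channels(cone, 7, 5), place_channels(cone, 7, 5))


def test_place_channels_exhaustive(small_cone):
    n = small_cone.slice0.size
    ch = place_channels(small_cone, n, seed=0)
    assert np.array_equal(np.sort(ch), small_cone.slice0)
    with pytest.raises(ValueError):
        place_channels(small_cone, n + 1, seed=0)


def test_place_vesicles_empty(cone):
    assert place_vesicles(cone, place_channels(cone, 3, 0), "random", 0, 1) == []


def test_vesicles_avoid_channel_voxels(cone):
    ch = place_channels(cone, 7, seed=2)
    for mode in ("random", "colocalized"):
        ves = place_vesicles(cone, ch, mode, 25, seed=3)
        vset = {v.voxel for v in ves}
        assert len(vset) == 25
        assert vset.isdisjoint(ch.tolist())
        assert np.all(cone.slice_index[list(vset)] == 0)


def test_colocalized_single_pair_nearest_available(cone):
    ch = place_channels(cone, 1, seed=4)
    ves = place_vesicles(cone, ch, "colocalized", 1, seed=4)
    pv = cone.positions_um([ves[0].voxel])[0, :2]
    pc = cone.positions_um(ch)[0, :2]
    # nearest available distinct voxel: one lattice step away
    assert np.hypot(*(pv - pc)) == pytest.approx(cone.dx)


def test_colocalized_closer_than_random_on_average(cone):
    """[DERIVED] mean vesicle-to-nearest-channel distance, 20 seed pairs."""
    def mean_dist(mode, seed):
        ch = place_channels(cone, 7, seed)
        ves = place_vesicles(cone, ch, mode, 10, seed + 1000)
        pv = cone.positions_um([v.voxel for v in ves])[:, :2]
        pc = cone.positions_um(ch)[:, :2]
        d = np.sqrt(((pv[:, None] - pc[None]) ** 2).sum(-1)).min(1)
        return d.mean()

    rnd = np.mean([mean_dist("random", s) for s in range(20)])
    col = np.mean([mean_dist("colocalized", s) for s in range(20)])
    assert col < rnd


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


def test_diffusion_zero_d_noop(cone, rng):
    ions = rng.integers(0, cone.n_voxels, 50)
    out = diffusion_step(ions, cone, 0.0, 1e-6, rng)
    assert np.array_equal(out, ions)


def test_diffusion_conserves_count(cone, rng):
    ions = rng.integers(0, cone.n_voxels, 500)
    dt = cone.dx**2 / (6 * 220.0)
    out = diffusion_step(ions, cone, 220.0, dt, rng)
    assert out.size == ions.size
    assert np.all((out >= 0) & (out < cone.n_voxels))


def test_diffusion_dt_too_large(cone, rng):
    with pytest.raises(ValueError):
        diffusion_step(np.array([0]), cone, 220.0, 1.0, rng)


def test_diffusion_msd_matches_theory(rng):
    """[DERIVED] interior MSD = 6 D k dt over 200 steps (3 SE)."""
    dom = box_domain(81, 81, 81, dx=0.07)
    d_coef, k = 220.0, 200
    dt = dom.dx**2 / (6 * d_coef)
    n = 4000
    center = dom._index[(40, 40, 40)]
    ions = np.full(n, center)
    for _ in range(k):
        ions = diffusion_step(ions, dom, d_coef, dt, rng)
    disp = (dom.coords[ions] - dom.coords[center]) * dom.dx
    r2 = (disp**2).sum(axis=1)
    expect = 6 * d_coef * k * dt
    se = r2.std(ddof=1) / np.sqrt(n)
    assert abs(r2.mean() - expect) <= 3 * se
    # nobody reached a wall
    assert np.abs(dom.coords[ions] - 40).max() < 40


def test_reflecting_wall_bounces(rng):
    dom = box_domain(1, 1, 2, dx=0.07)  # two voxels stacked in z
    ions = np.zeros(2000, dtype=np.int64)
    dt = dom.dx**2 / (6 * 220.0)
    out = diffusion_step(ions, dom, 220.0, dt, rng)
    assert set(np.unique(out)) <= {0, 1}  # never leaves the domain


# ---------------------------------------------------------------------------
# buffer reactions
# ---------------------------------------------------------------------------


def test_reaction_dt_zero_noop(small_cone, rng):
    buf = BufferField.from_concentration(small_cone)
    ions = rng.integers(0, small_cone.n_voxels, 40)
    out_ions, out_buf = reaction_step(ions, buf, 0.0, rng)
    assert np.array_equal(np.sort(out_ions), np.sort(ions))
    assert out_buf.bound.sum() == 0


def test_no_free_buffer_no_binding(small_cone, rng):
    buf = BufferField.from_concentration(small_cone)
    buf = dataclasses.replace(buf, bound=buf.total.copy())  # saturated
    ions = rng.integers(0, small_cone.n_voxels, 30)
    out_ions, out_buf = reaction_step(ions, buf, 1e-9, rng)
    # binding impossible; a release may free buffer, so only check no growth
    assert out_buf.bound.sum() <= buf.total.sum()
    assert out_ions.size + out_buf.bound.sum() == ions.size + buf.bound.sum()


def test_reaction_conserves_calcium(small_cone, rng):
    buf = BufferField.from_concentration(small_cone)
    ions = rng.integers(0, small_cone.n_voxels, 200)
    total = ions.size
    for _ in range(50):
        ions, buf = reaction_step(ions, buf, 2e-6, rng)
        assert ions.size + buf.bound.sum() == total
        buf.validate()


def test_closed_box_equilibrium(rng):
    """[DERIVED] bound fraction = [B]/([B]+Kd) in a well-mixed closed box.

    A single large voxel (0.7 µm) holds ~1e5 buffer molecules, so depletion
    by the 150 test ions is negligible.
    """
    dom = box_domain(1, 1, 1, dx=0.7)
    buf = BufferField.from_concentration(dom, 500.0)
    b_uM = buf.total[0] * dom.molar_per_molecule_uM
    expect = b_uM / (b_uM + buf.kd_uM)
    n = 150
    ions = np.zeros(n, dtype=np.int64)
    dt = 1e-6
    samples = []
    for step in range(3000):
        ions, buf = reaction_step(ions, buf, dt, rng)
        if step >= 500 and step % 25 == 0:
            samples.append(buf.bound[0] / n)
    samples = np.asarray(samples)
    se = math.sqrt(expect * (1 - expect) / n) / math.sqrt(len(samples))
    assert abs(samples.mean() - expect) <= 3 * se


# ---------------------------------------------------------------------------
# vesicles
# ---------------------------------------------------------------------------


def test_vesicle_noop_without_calcium(small_cone, rng):
    ves = [Vesicle(voxel=int(small_cone.slice0[0]))]
    out, ions, consumed = vesicle_step(ves, np.array([], dtype=int),
                                       small_cone, 1e-5, rng)
    assert out[0].sites_bound == 0 and not out[0].fused
    assert ions.size == 0 and consumed == 0


def test_vesicle_fusion_hazard(small_cone):
    """[DERIVED] fully loaded vesicles fuse at rate gamma (3 SE)."""
    rng = np.random.default_rng(2)
    dt = 1e-5
    n = 8000
    ves = [Vesicle(voxel=0, sites_bound=3) for _ in range(n)]
    out, _, consumed = vesicle_step(ves, np.array([], dtype=int),
                                    small_cone, dt, rng)
    frac = np.mean([v.fused for v in out])
    p = 1.0 - math.exp(-1000.0 * dt)
    se = math.sqrt(p * (1 - p) / n)
    assert abs(frac - p) <= 3 * se
    assert consumed == 3 * sum(v.fused for v in out)


def test_vesicle_first_binding_hazard_scales_with_free_sites(small_cone):
    """[DERIVED] 3 free sites -> first-binding hazard 3x the single-site one."""
    rng = np.random.default_rng(7)
    dt = 1e-4
    v0 = int(small_cone.slice0[0])
    ions_in_voxel = 5
    counts = {3: 0, 1: 0}
    n = 6000
    for sites in (3, 1):
        for _ in range(n):
            ves = [Vesicle(voxel=v0, sites_total=sites)]
            ions = np.full(ions_in_voxel, v0)
            out, _, _ = vesicle_step(ves, ions, small_cone, dt, rng)
            counts[sites] += out[0].sites_bound > 0
    rate1 = small_cone.molar_per_molecule_uM * ions_in_voxel * 8e6 * 1e-6
    for sites in (3, 1):
        p = 1.0 - math.exp(-sites * rate1 * dt)
        frac = counts[sites] / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 3 * se


def test_vesicle_conservation_and_absorbing_fusion(small_cone, rng):
    v0 = int(small_cone.slice0[0])
    ves = [Vesicle(voxel=v0, sites_bound=3)]
    ions = np.full(50, v0)
    total = 50 + 3
    consumed_total = 0
    fused_at = None
    for step in range(400):
        ves, ions, consumed = vesicle_step(ves, ions, small_cone, 1e-4, rng,
                                           t_now=step * 1e-4)
        consumed_total += consumed
        assert ions.size + ves[0].sites_bound * (not ves[0].fused) \
            + consumed_total == total
        if ves[0].fused and fused_at is None:
            fused_at = ves[0].fusion_time
    assert ves[0].fused and fused_at is not None
    assert ves[0].fusion_time == fused_at  # absorbing


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(mode="clustered")
    with pytest.raises(ValueError):
        SimConfig(n_replicates=0)


def test_config_yaml_round_trip(tmp_path):
    cfg = SimConfig(mode="colocalized", n_vesicles=4, seed=9)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert SimConfig.from_yaml(path) == cfg


def test_master_dt_stability_bound():
    cfg = SimConfig()
    assert cfg.dt <= cfg.dx**2 / (6 * cfg.d_ca) + 1e-18
    assert cfg.dt == pytest.approx(3.712e-6, rel=1e-3)


# ---------------------------------------------------------------------------
# full pulse
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def short_pulse_result():
    cfg = SimConfig(pulse_s=0.03, n_replicates=2, mode="colocalized", seed=5)
    return cfg, run_pulse(cfg)


def test_pulse_ledger_balances(short_pulse_result):
    _, res = short_pulse_result
    assert res.ledger_balanced()


def test_pulse_fused_pct_monotone_bounded(short_pulse_result):
    _, res = short_pulse_result
    assert np.all(np.diff(res.fused_pct, axis=1) >= 0)
    assert np.all((res.fused_pct >= 0) & (res.fused_pct <= 100))


def test_pulse_slice0_calcium_above_basal(short_pulse_result):
    cfg, res = short_pulse_result
    assert res.ca_slice0_uM.mean(axis=0).max() > cfg.ca_basal_uM


def test_pulse_reproducible(short_pulse_result):
    cfg, res = short_pulse_result
    res2 = run_pulse(cfg)
    assert np.array_equal(res.fused_pct, res2.fused_pct)
    assert np.array_equal(res.ledger["injected"], res2.ledger["injected"])


def test_pulse_zero_agonist_inert():
    cfg = SimConfig(pulse_s=0.02, n_replicates=1, ach_uM=0.0, seed=1)
    res = run_pulse(cfg)
    assert res.ledger["injected"].sum() == 0
    assert res.fused_pct.max() == 0.0
    assert res.current_pA.max() == 0.0
    assert res.ledger_balanced()


def test_pulse_dt_convergence():
    """Halving dt changes mean cumulative release by < the replicate SE."""
    base = SimConfig(pulse_s=0.12, n_replicates=4, mode="colocalized",
                     n_vesicles=20, seed=21)
    fine = dataclasses.replace(base, dt_scale=0.5)
    r1, r2 = run_pulse(base), run_pulse(fine)
    end1 = r1.fused_pct[:, -1]
    end2 = r2.fused_pct[:, -1]
    se = math.hypot(end1.std(ddof=1) / 2, end2.std(ddof=1) / 2)
    assert abs(end1.mean() - end2.mean()) <= max(se, 1e-9) + 1e-9


def test_result_frame_and_save(tmp_path, short_pulse_result):
    _, res = short_pulse_result
    df = res.to_frame()
    assert "time_s" in df.columns and "fused_pct_mean" in df.columns
    res.save(tmp_path / "out")
    assert (tmp_path / "out" / "timeseries.csv").exists()
    assert (tmp_path / "out" / "summary.json").exists()
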