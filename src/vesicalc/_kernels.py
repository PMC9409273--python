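"""Numba kernel for the particle-based pulse simulation.

Implements, in one fused loop, exactly the probabilistic rules of the
reference operations in :mod:`vesicalc.secretion_sim`:

* lattice diffusion with reflecting ("bounce back") walls;
* calcium->buffer binding with the exact exponential probability
  ``1 - exp(-k_on [B_free] dt)`` per free ion (the closed-form compound of
  sub-steps whose individual probabilities are <= 0.1);
* buffer release drawn per bound molecule every ``rel_every`` master steps
  with the matching exponential probability (<= 0.1); voxels are assigned a
  fixed release phase (``voxel % rel_every``) so the batches are staggered
  and recorded snapshots are cycle-averaged.  The per-voxel release count is
  an exact Binomial(bound, p) sampled by CDF inversion from one uniform;
* vesicle site binding/unbinding and fusion (fusion is evaluated on the
  state at the start of the step, then unbinding, then binding);
* Poisson ion injection at open-channel voxels.

All particle counts are integers, so the conservation ledger is exact.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# record columns
REC_FIELDS = (
    "step",
    "open_count",
    "free",
    "bound",
    "ves_bound",
    "consumed",
    "fused",
    "slice0_free",
    "injected",
)


@njit(cache=True)
def core_pulse(
    seed,
    n_steps,
    stride,
    neighbors,        # (N, 6) int32, -1 = wall
    is_slice0,        # (N,) uint8
    ion_vox,          # (cap,) int64, first n_free entries valid
    n_free,
    bound,            # (N,) int64
    btotal,           # scalar int: buffer molecules per voxel
    p_bind_table,     # (btotal + 1,) binding prob per step by free-buffer count
    p_rel,            # per-molecule release prob per rel_every master steps
    rel_every,
    p_dir,            # per-direction move probability (D*dt/dx^2)
    open_ch,          # (n_ch, n_steps) uint8
    ch_vox,           # (n_ch,) int64
    lam_open,         # mean injected ions per step per open channel
    ves_vox,          # (V,) int64
    ves_sites,        # (V,) int64 bound sites
    ves_fused,        # (V,) uint8
    ves_fuse_step,    # (V,) int64
    n_sites,
    ves_on_per_ion,   # per-site binding rate per free ion in the voxel (s^-1)
    p_ves_off,        # per bound site unbinding prob per master step
    p_fuse,           # fusion prob per master step
    dt,
    rec,              # (n_rec, 9) float64 output
    injected0,
    consumed0,
):
    np.random.seed(seed)
    n_vox = bound.shape[0]
    cap = ion_vox.shape[0]
    six_p = 6.0 * p_dir

    # survival table for release: (1 - p_rel)^b
    surv = np.empty(btotal + 1)
    surv[0] = 1.0
    for b in range(1, btotal + 1):
        surv[b] = surv[b - 1] * (1.0 - p_rel)
    p_ratio = p_rel / (1.0 - p_rel)

    # per-voxel free-ion counts
    free_cnt = np.zeros(n_vox, dtype=np.int64)
    s0_free = 0
    for i in range(n_free):
        v = ion_vox[i]
        free_cnt[v] += 1
        if is_slice0[v]:
            s0_free += 1

    # occupied-buffer-voxel lists, bucketed by release phase (voxel % rel_every)
    occ = np.empty((rel_every, n_vox), dtype=np.int64)
    occ_cnt = np.zeros(rel_every, dtype=np.int64)
    occ_pos = np.full(n_vox, -1, dtype=np.int64)
    bound_sum = 0
    for v in range(n_vox):
        if bound[v] > 0:
            ph = v % rel_every
            occ[ph, occ_cnt[ph]] = v
            occ_pos[v] = occ_cnt[ph]
            occ_cnt[ph] += 1
            bound_sum += bound[v]

    ves_bound = 0
    fused_count = 0
    for m in range(ves_vox.shape[0]):
        if ves_fused[m]:
            fused_count += 1
        else:
            ves_bound += ves_sites[m]
    injected = injected0
    consumed = consumed0

    n_ch = ch_vox.shape[0]
    rec_row = 0

    for step in range(n_steps + 1):
        # ---- record (state at the top of step `step`) ----
        if step % stride == 0 or step == n_steps:
            oc = 0
            if step < n_steps:
                for c in range(n_ch):
                    oc += open_ch[c, step]
            elif n_steps > 0:
                for c in range(n_ch):
                    oc += open_ch[c, n_steps - 1]
            rec[rec_row, 0] = step
            rec[rec_row, 1] = oc
            rec[rec_row, 2] = n_free
            rec[rec_row, 3] = bound_sum
            rec[rec_row, 4] = ves_bound
            rec[rec_row, 5] = consumed
            rec[rec_row, 6] = fused_count
            rec[rec_row, 7] = s0_free
            rec[rec_row, 8] = injected
            rec_row += 1
        if step == n_steps:
            break

        # ---- injection at open channel voxels ----
        for c in range(n_ch):
            if open_ch[c, step]:
                k = np.random.poisson(lam_open)
                v = ch_vox[c]
                for _ in range(k):
                    if n_free >= cap:
                        raise RuntimeError("ion capacity exceeded")
                    ion_vox[n_free] = v
                    n_free += 1
                free_cnt[v] += k
                if is_slice0[v]:
                    s0_free += k
                injected += k

        # ---- diffusion (reflecting walls) ----
        for i in range(n_free):
            u = np.random.random()
            if u < six_p:
                d = int(u / p_dir)
                if d > 5:
                    d = 5
                v = ion_vox[i]
                w = neighbors[v, d]
                if w >= 0:
                    ion_vox[i] = w
                    free_cnt[v] -= 1
                    free_cnt[w] += 1
                    if is_slice0[v]:
                        s0_free -= 1
                    if is_slice0[w]:
                        s0_free += 1

        # ---- buffer binding ----
        i = 0
        while i < n_free:
            v = ion_vox[i]
            bf = btotal - bound[v]
            if bf > 0 and np.random.random() < p_bind_table[bf]:
                if bound[v] == 0:
                    ph = v % rel_every
                    occ[ph, occ_cnt[ph]] = v
                    occ_pos[v] = occ_cnt[ph]
                    occ_cnt[ph] += 1
                bound[v] += 1
                bound_sum += 1
                free_cnt[v] -= 1
                if is_slice0[v]:
                    s0_free -= 1
                n_free -= 1
                ion_vox[i] = ion_vox[n_free]
                continue
            i += 1

        # ---- buffer release: Binomial(bound, p_rel) by CDF inversion ----
        ph = step % rel_every
        j = 0
        while j < occ_cnt[ph]:
            v = occ[ph, j]
            b = bound[v]
            u = np.random.random()
            pmf = surv[b]           # P(K = 0)
            if u < pmf:
                j += 1
                continue
            cum = pmf
            k = 0
            while cum <= u and k < b:
                pmf *= (b - k) / (k + 1.0) * p_ratio
                k += 1
                cum += pmf
            bound[v] -= k
            bound_sum -= k
            for _ in range(k):
                if n_free >= cap:
                    raise RuntimeError("ion capacity exceeded")
                ion_vox[n_free] = v
                n_free += 1
            free_cnt[v] += k
            if is_slice0[v]:
                s0_free += k
            if bound[v] == 0:
                occ_cnt[ph] -= 1
                occ[ph, j] = occ[ph, occ_cnt[ph]]
                occ_pos[occ[ph, j]] = j
                occ_pos[v] = -1
                continue
            j += 1

        # ---- vesicles: fusion, unbinding, binding ----
        for m in range(ves_vox.shape[0]):
            if ves_fused[m]:
                continue
            if ves_sites[m] == n_sites and np.random.random() < p_fuse:
                ves_fused[m] = 1
                ves_fuse_step[m] = step
                consumed += ves_sites[m]
                ves_bound -= ves_sites[m]
                fused_count += 1
                continue
            v = ves_vox[m]
            if ves_sites[m] > 0:
                k = np.random.binomial(ves_sites[m], p_ves_off)
                if k > 0:
                    ves_sites[m] -= k
                    ves_bound -= k
                    for _ in range(k):
                        if n_free >= cap:
                            raise RuntimeError("ion capacity exceeded")
                        ion_vox[n_free] = v
                        n_free += 1
                    free_cnt[v] += k
                    if is_slice0[v]:
                        s0_free += k
            nfs = n_sites - ves_sites[m]
            nfv = free_cnt[v]
            if nfs > 0 and nfv > 0:
                p = 1.0 - np.exp(-ves_on_per_ion * nfv * dt)
                k = np.random.binomial(nfs, p)
                if k > nfv:
                    k = nfv
                if k > 0:
                    ves_sites[m] += k
                    ves_bound += k
                    removed = 0
                    i = 0
                    while i < n_free and removed < k:
                        if ion_vox[i] == v:
                            n_free -= 1
                            ion_vox[i] = ion_vox[n_free]
                            removed += 1
                            continue
                        i += 1
                    free_cnt[v] -= k
                    if is_slice0[v]:
                        s0_free -= k

    return n_free, injected, consumed, rec_row
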