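"""Numba kernels: pair forces, BAOAB Langevin integration, contact statistics,
and the lattice pivot sampler.

These are internal; public wrappers live in :mod:`sbsfold.dynamics`,
:mod:`sbsfold.observables` and :mod:`sbsfold.synthetic`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT2 = 2.0 ** (1.0 / 3.0)  # (2^{1/6})^2

# status codes returned by run_chunk
OK = 0
ERR_OVERSTRETCH = 1
ERR_NAN = 2
ERR_CAPACITY = 3
ERR_SINGULAR = 4


@njit(cache=True, inline="always")
def _min_image(d, L):
    return d - L * np.round(d / L)


@njit(cache=True, inline="always")
def _mi1(d, L, halfL):
    # single-branch minimum image; valid for wrapped coordinates (|d| < L)
    if d > halfL:
        return d - L
    if d < -halfL:
        return d + L
    return d


@njit(cache=True)
def _wrap(pos, w, L):
    n = pos.shape[0]
    for i in range(n):
        for d in range(3):
            w[i, d] = pos[i, d] - L * np.floor(pos[i, d] / L)


@njit(cache=True)
def build_pairs(w, L, r_list, pairs):
    """All-pairs neighbor search on wrapped coordinates (minimum image).
    Returns pair count or -1 on capacity overflow."""
    n = w.shape[0]
    cap = pairs.shape[0]
    r2max = r_list * r_list
    halfL = 0.5 * L
    cnt = 0
    for i in range(n - 1):
        xi, yi, zi = w[i, 0], w[i, 1], w[i, 2]
        for j in range(i + 1, n):
            dx = _mi1(xi - w[j, 0], L, halfL)
            dy = _mi1(yi - w[j, 1], L, halfL)
            dz = _mi1(zi - w[j, 2], L, halfL)
            if dx * dx + dy * dy + dz * dz < r2max:
                if cnt >= cap:
                    return -1
                pairs[cnt, 0] = i
                pairs[cnt, 1] = j
                cnt += 1
    return cnt


@njit(cache=True)
def compute_forces(
    w, forces, pairs, npairs, n_beads, bcolors, attr, L,
    eps_rep, r_cut_attr, fene_k, fene_r0, attach_shifts,
):
    """Pair forces under minimum image.  Returns (potential energy, status).

    Nonbonded: WCA for bead-bead, binder-binder, and non-cognate bead-binder;
    truncated-shifted LJ of depth attr[i, color] for cognate bead-binder.
    Bonded (i, i+1): FENE on top of WCA.  ``attach_shifts`` caches the LJ
    value at the attraction cutoff per (bead, color).  ``w`` must hold
    wrapped coordinates (in [0, L)).
    """
    n = w.shape[0]
    halfL = 0.5 * L
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    u = 0.0
    rca2 = r_cut_attr * r_cut_attr
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = _mi1(w[i, 0] - w[j, 0], L, halfL)
        dy = _mi1(w[i, 1] - w[j, 1], L, halfL)
        dz = _mi1(w[i, 2] - w[j, 2], L, halfL)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            return u, ERR_SINGULAR
        depth = 0.0
        if i < n_beads and j >= n_beads:
            depth = attr[i, bcolors[j - n_beads]]
        elif j < n_beads and i >= n_beads:
            depth = attr[j, bcolors[i - n_beads]]
        if depth > 0.0:
            if r2 < rca2:
                inv2 = 1.0 / r2
                sr6 = inv2 * inv2 * inv2
                sr12 = sr6 * sr6
                if i < n_beads:
                    shift = attach_shifts[i, bcolors[j - n_beads]]
                else:
                    shift = attach_shifts[j, bcolors[i - n_beads]]
                u += 4.0 * depth * (sr12 - sr6) - shift
                fmag = 24.0 * depth * (2.0 * sr12 - sr6) * inv2
                forces[i, 0] += fmag * dx
                forces[i, 1] += fmag * dy
                forces[i, 2] += fmag * dz
                forces[j, 0] -= fmag * dx
                forces[j, 1] -= fmag * dy
                forces[j, 2] -= fmag * dz
        else:
            if r2 < WCA_CUT2:
                inv2 = 1.0 / r2
                sr6 = inv2 * inv2 * inv2
                sr12 = sr6 * sr6
                u += 4.0 * eps_rep * (sr12 - sr6) + eps_rep
                fmag = 24.0 * eps_rep * (2.0 * sr12 - sr6) * inv2
                forces[i, 0] += fmag * dx
                forces[i, 1] += fmag * dy
                forces[i, 2] += fmag * dz
                forces[j, 0] -= fmag * dx
                forces[j, 1] -= fmag * dy
                forces[j, 2] -= fmag * dz
    # FENE bonds on the linear chain topology
    r02 = fene_r0 * fene_r0
    for i in range(n_beads - 1):
        dx = _mi1(w[i, 0] - w[i + 1, 0], L, halfL)
        dy = _mi1(w[i, 1] - w[i + 1, 1], L, halfL)
        dz = _mi1(w[i, 2] - w[i + 1, 2], L, halfL)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return u, ERR_OVERSTRETCH
        frac = r2 / r02
        u += -0.5 * fene_k * r02 * np.log(1.0 - frac)
        fmag = -fene_k / (1.0 - frac)
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[i + 1, 0] -= fmag * dx
        forces[i + 1, 1] -= fmag * dy
        forces[i + 1, 2] -= fmag * dz
    return u, OK


@njit(cache=True)
def _bonds_ok(pos, n_beads, L, fene_r0):
    # unwrapped coordinates: bonded neighbours are spatially adjacent, so
    # direct distances are correct (never near a box length)
    lim = (0.995 * fene_r0) ** 2
    for i in range(n_beads - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        if dx * dx + dy * dy + dz * dz >= lim:
            return False
    return True


@njit(cache=True)
def run_chunk(
    pos, vel, forces, pairs, ref_pos,
    n_steps, n_beads, bcolors, attr, L,
    eps_rep, r_cut_attr, fene_k, fene_r0,
    dt, gamma, kT, skin, noise,
    attach_shifts,
):
    """Advance ``n_steps`` BAOAB Langevin steps in place.

    ``noise`` has shape (n_steps, n, 3) of unit normals (pre-drawn for
    determinism).  Returns (status, n_halved_steps).  On an overstretched
    bond the step is retried with halved dt (same noise), up to 14 times.
    """
    n = pos.shape[0]
    r_list = max(np.sqrt(WCA_CUT2), r_cut_attr) + skin
    w = np.empty((n, 3))
    _wrap(pos, w, L)
    npairs = build_pairs(w, L, r_list, pairs)
    if npairs < 0:
        return ERR_CAPACITY, 0
    for i in range(n):
        ref_pos[i, 0] = pos[i, 0]
        ref_pos[i, 1] = pos[i, 1]
        ref_pos[i, 2] = pos[i, 2]
    _, status = compute_forces(
        w, forces, pairs, npairs, n_beads, bcolors, attr, L,
        eps_rep, r_cut_attr, fene_k, fene_r0, attach_shifts,
    )
    if status != OK:
        return status, 0
    x0 = np.empty((n, 3))
    v0 = np.empty((n, 3))
    n_halved = 0
    for step in range(n_steps):
        for i in range(n):
            x0[i, 0] = pos[i, 0]
            x0[i, 1] = pos[i, 1]
            x0[i, 2] = pos[i, 2]
            v0[i, 0] = vel[i, 0]
            v0[i, 1] = vel[i, 1]
            v0[i, 2] = vel[i, 2]
        h = dt
        for attempt in range(15):
            if attempt > 0:
                for i in range(n):
                    pos[i, 0] = x0[i, 0]
                    pos[i, 1] = x0[i, 1]
                    pos[i, 2] = x0[i, 2]
                    vel[i, 0] = v0[i, 0]
                    vel[i, 1] = v0[i, 1]
                    vel[i, 2] = v0[i, 2]
                h = h * 0.5
                n_halved += 1
            c1 = np.exp(-gamma * h)
            c2 = np.sqrt((1.0 - c1 * c1) * kT) if gamma > 0.0 else 0.0
            half = 0.5 * h
            for i in range(n):
                for d in range(3):
                    vel[i, d] += half * forces[i, d]
                    pos[i, d] += half * vel[i, d]
                    vel[i, d] = c1 * vel[i, d] + c2 * noise[step, i, d]
                    pos[i, d] += half * vel[i, d]
            if _bonds_ok(pos, n_beads, L, fene_r0):
                break
        else:
            return ERR_OVERSTRETCH, n_halved
        # rebuild neighbor list when any particle moved more than skin/2
        lim = (0.5 * skin) ** 2
        rebuild = False
        for i in range(n):
            dx = pos[i, 0] - ref_pos[i, 0]
            dy = pos[i, 1] - ref_pos[i, 1]
            dz = pos[i, 2] - ref_pos[i, 2]
            if dx * dx + dy * dy + dz * dz > lim:
                rebuild = True
                break
        _wrap(pos, w, L)
        if rebuild:
            npairs = build_pairs(w, L, r_list, pairs)
            if npairs < 0:
                return ERR_CAPACITY, n_halved
            for i in range(n):
                ref_pos[i, 0] = pos[i, 0]
                ref_pos[i, 1] = pos[i, 1]
                ref_pos[i, 2] = pos[i, 2]
        _, status = compute_forces(
            w, forces, pairs, npairs, n_beads, bcolors, attr, L,
            eps_rep, r_cut_attr, fene_k, fene_r0, attach_shifts,
        )
        if status != OK:
            return status, n_halved
        half = 0.5 * h
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * forces[i, d]
        if not np.isfinite(pos[0, 0]):
            return ERR_NAN, n_halved
    return OK, n_halved


@njit(cache=True)
def contact_counts(traj, L, threshold):
    """Sum over snapshots of the pairwise contact indicator (minimum image).

    ``traj``: (T, N, 3). Returns an (N, N) float64 count matrix with the
    diagonal set to T (a bead is always in contact with itself)."""
    T, N = traj.shape[0], traj.shape[1]
    out = np.zeros((N, N))
    thr2 = threshold * threshold
    for t in range(T):
        for i in range(N - 1):
            xi = traj[t, i, 0]
            yi = traj[t, i, 1]
            zi = traj[t, i, 2]
            for j in range(i + 1, N):
                dx = xi - traj[t, j, 0]
                dy = yi - traj[t, j, 1]
                dz = zi - traj[t, j, 2]
                if L > 0.0:
                    dx -= L * np.round(dx / L)
                    dy -= L * np.round(dy / L)
                    dz -= L * np.round(dz / L)
                if dx * dx + dy * dy + dz * dz <= thr2:
                    out[i, j] += 1.0
                    out[j, i] += 1.0
    for i in range(N):
        out[i, i] = T
    return out


@njit(cache=True)
def r2_by_separation(traj):
    """Mean square spatial distance per contour separation (unwrapped).

    Returns (sum_r2[s], n_pairs[s]) for s = 0..N-1."""
    T, N = traj.shape[0], traj.shape[1]
    sums = np.zeros(N)
    counts = np.zeros(N, dtype=np.int64)
    for t in range(T):
        for i in range(N - 1):
            xi = traj[t, i, 0]
            yi = traj[t, i, 1]
            zi = traj[t, i, 2]
            for j in range(i + 1, N):
                dx = xi - traj[t, j, 0]
                dy = yi - traj[t, j, 1]
                dz = zi - traj[t, j, 2]
                sums[j - i] += dx * dx + dy * dy + dz * dz
                counts[j - i] += 1
    return sums, counts


@njit(cache=True)
def many_body_component_counts(traj, L, threshold, s_min):
    """Mean-per-snapshot counts of contact-graph connected components.

    Edges join bead pairs within ``threshold`` and contour separation
    >= ``s_min``.  Returns counts[n] = total number (over snapshots) of
    components of size exactly n, for n = 0..N."""
    T, N = traj.shape[0], traj.shape[1]
    counts = np.zeros(N + 1)
    parent = np.empty(N, dtype=np.int64)
    size = np.empty(N, dtype=np.int64)
    thr2 = threshold * threshold
    for t in range(T):
        for i in range(N):
            parent[i] = i
            size[i] = 1
        for i in range(N - 1):
            xi = traj[t, i, 0]
            yi = traj[t, i, 1]
            zi = traj[t, i, 2]
            for j in range(i + s_min, N):
                dx = xi - traj[t, j, 0]
                dy = yi - traj[t, j, 1]
                dz = zi - traj[t, j, 2]
                if L > 0.0:
                    dx -= L * np.round(dx / L)
                    dy -= L * np.round(dy / L)
                    dz -= L * np.round(dz / L)
                if dx * dx + dy * dy + dz * dz <= thr2:
                    ri = i
                    while parent[ri] != ri:
                        parent[ri] = parent[parent[ri]]
                        ri = parent[ri]
                    rj = j
                    while parent[rj] != rj:
                        parent[rj] = parent[parent[rj]]
                        rj = parent[rj]
                    if ri != rj:
                        if size[ri] < size[rj]:
                            ri, rj = rj, ri
                        parent[rj] = ri
                        size[ri] += size[rj]
        for i in range(N):
            if parent[i] == i:
                counts[size[i]] += 1.0
    return counts


@njit(cache=True)
def triplet_contact_grid(traj, L, threshold, max_s):
    """P_c(s1, s2) for bead triplets (i, i+s1, i+s1+s2), s1,s2 in 1..max_s.

    Returns (hits, totals) grids of shape (max_s+1, max_s+1)."""
    T, N = traj.shape[0], traj.shape[1]
    hits = np.zeros((max_s + 1, max_s + 1))
    totals = np.zeros((max_s + 1, max_s + 1))
    thr2 = threshold * threshold
    cmat = np.zeros((N, N), dtype=np.uint8)
    for t in range(T):
        for i in range(N):
            for j in range(N):
                cmat[i, j] = 0
        for i in range(N - 1):
            xi = traj[t, i, 0]
            yi = traj[t, i, 1]
            zi = traj[t, i, 2]
            jmax = min(N, i + 2 * max_s + 1)
            for j in range(i + 1, jmax):
                dx = xi - traj[t, j, 0]
                dy = yi - traj[t, j, 1]
                dz = zi - traj[t, j, 2]
                if L > 0.0:
                    dx -= L * np.round(dx / L)
                    dy -= L * np.round(dy / L)
                    dz -= L * np.round(dz / L)
                if dx * dx + dy * dy + dz * dz <= thr2:
                    cmat[i, j] = 1
                    cmat[j, i] = 1
        for s1 in range(1, max_s + 1):
            for s2 in range(1, max_s + 1):
                for i in range(N - s1 - s2):
                    j = i + s1
                    k = j + s2
                    totals[s1, s2] += 1.0
                    if cmat[i, j] and cmat[j, k] and cmat[i, k]:
                        hits[s1, s2] += 1.0
    return hits, totals


# ---------------------------------------------------------------------------
# Lattice pivot sampler for self-avoiding walks
# ---------------------------------------------------------------------------


def _octahedral_ops() -> np.ndarray:
    """The 48 signed-permutation matrices of the cubic point group."""
    ops = []
    for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    m = np.zeros((3, 3), dtype=np.int64)
                    for row, (col, s) in enumerate(zip(perm, (sx, sy, sz))):
                        m[row, col] = s
                    ops.append(m)
    return np.stack(ops)


OCTA_OPS = _octahedral_ops()


@njit(cache=True)
def _hash_key(x, y, z):
    off = 1 << 20
    return (x + off) + ((y + off) << 21) + ((z + off) << 42)


@njit(cache=True)
def pivot_saw_ensemble(n, n_samples, stride, warmup, seed, ops):
    """Pivot Monte Carlo on the cubic lattice with site exclusion.

    Starts from a rod, attempts ``warmup`` pivots, then records a
    conformation every ``stride`` attempts.  Returns (samples, n_accepted)
    with samples of shape (n_samples, n, 3) in lattice units (int16)."""
    np.random.seed(seed)
    pos = np.zeros((n, 3), dtype=np.int64)
    for i in range(n):
        pos[i, 0] = i
    hsize = 1
    while hsize < 4 * n:
        hsize <<= 1
    mask = hsize - 1
    table = np.full(hsize, -1, dtype=np.int64)
    used = np.empty(n, dtype=np.int64)
    newpos = np.empty((n, 3), dtype=np.int64)
    samples = np.empty((n_samples, n, 3), dtype=np.int16)
    total_attempts = warmup + n_samples * stride
    n_acc = 0
    n_rec = 0
    for attempt in range(total_attempts):
        p = 1 + np.random.randint(n - 2)  # pivot bead
        op = 1 + np.random.randint(47)    # non-identity symmetry
        # move the shorter arm
        if p < n - p:
            mstart, mend = 0, p       # moving beads [0, p)
            fstart, fend = p, n       # fixed beads [p, n)
        else:
            mstart, mend = p + 1, n
            fstart, fend = 0, p + 1
        nused = 0
        for i in range(fstart, fend):
            key = _hash_key(pos[i, 0], pos[i, 1], pos[i, 2])
            slot = (key * 2654435761) & mask
            while table[slot] != -1:
                slot = (slot + 1) & mask
            table[slot] = key
            used[nused] = slot
            nused += 1
        px, py, pz = pos[p, 0], pos[p, 1], pos[p, 2]
        ok = True
        for i in range(mstart, mend):
            dx = pos[i, 0] - px
            dy = pos[i, 1] - py
            dz = pos[i, 2] - pz
            nx = px + ops[op, 0, 0] * dx + ops[op, 0, 1] * dy + ops[op, 0, 2] * dz
            ny = py + ops[op, 1, 0] * dx + ops[op, 1, 1] * dy + ops[op, 1, 2] * dz
            nz = pz + ops[op, 2, 0] * dx + ops[op, 2, 1] * dy + ops[op, 2, 2] * dz
            key = _hash_key(nx, ny, nz)
            slot = (key * 2654435761) & mask
            while table[slot] != -1:
                if table[slot] == key:
                    ok = False
                    break
                slot = (slot + 1) & mask
            if not ok:
                break
            newpos[i, 0] = nx
            newpos[i, 1] = ny
            newpos[i, 2] = nz
        for u in range(nused):
            table[used[u]] = -1
        if ok:
            for i in range(mstart, mend):
                pos[i, 0] = newpos[i, 0]
                pos[i, 1] = newpos[i, 1]
                pos[i, 2] = newpos[i, 2]
            n_acc += 1
        if (attempt + 1) % (4 * n) == 0:
            # keep absolute coordinates near the origin (hash-key range)
            ox, oy, oz = pos[0, 0], pos[0, 1], pos[0, 2]
            for i in range(n):
                pos[i, 0] -= ox
                pos[i, 1] -= oy
                pos[i, 2] -= oz
        if attempt >= warmup and (attempt - warmup + 1) % stride == 0:
            for i in range(n):
                samples[n_rec, i, 0] = np.int16(pos[i, 0] - pos[0, 0])
                samples[n_rec, i, 1] = np.int16(pos[i, 1] - pos[0, 1])
                samples[n_rec, i, 2] = np.int16(pos[i, 2] - pos[0, 2])
            n_rec += 1
            if n_rec == n_samples:
                break
    return samples, n_acc
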