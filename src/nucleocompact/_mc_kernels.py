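"""Numba kernels for the confined discrete worm-like-chain Monte Carlo.

The chain is a bead-rod polymer: N beads, fixed bond length b, bending energy
E/kT = kappa * sum_i theta_i^2 with kappa = P/(2b).  Three trial moves are
used:

* crankshaft -- rotate a short interior run of beads about the chord through
  its end beads; bond lengths and interior angles are preserved exactly and
  only the two joint angles change;
* pivot -- rotate the shorter chain side about a random axis through a bead;
  one joint angle changes;
* reptation (slithering snake) -- delete a bead from one end and append a
  bead at the other, with the new joint angle drawn from its Boltzmann
  density sin(t) exp(-kappa t^2) (via a precomputed inverse CDF) and uniform
  azimuth; the proposal density then cancels the bending weight exactly, so
  the move is accepted whenever the new bead satisfies the wall and
  excluded-volume constraints.  Reptation is what decorrelates the global
  extension of a channel-confined chain at acceptable cost.

Because reptation renumbers the chain, beads live in a circular buffer:
``head`` is the storage slot of chain bead 0 and chain bead k sits in slot
(head + k) mod N.

Hard channel walls act on bead centers in x and y; optional excluded volume
is a hard-core diameter between beads at least two bonds apart, enforced
through a spatial hash grid updated incrementally on accepted moves.
"""

import numpy as np
from numba import njit

__all__ = ["run_chain", "bend_angles"]


@njit(cache=True, inline="always")
def _hash_cell(ix, iy, iz, M):
    h = (ix * 73856093) ^ (iy * 19349663) ^ (iz * 83492791)
    h %= M
    if h < 0:
        h += M
    return h


@njit(cache=True)
def _build_grid(pos, cell, M, head_arr, nxt, cellid):
    head_arr[:] = -1
    n = pos.shape[0]
    for s in range(n):
        ix = np.int64(np.floor(pos[s, 0] / cell))
        iy = np.int64(np.floor(pos[s, 1] / cell))
        iz = np.int64(np.floor(pos[s, 2] / cell))
        h = _hash_cell(ix, iy, iz, M)
        cellid[s] = h
        nxt[s] = head_arr[h]
        head_arr[h] = s


@njit(cache=True, inline="always")
def _grid_remove(s, head_arr, nxt, cellid):
    h = cellid[s]
    cur = head_arr[h]
    if cur == s:
        head_arr[h] = nxt[s]
        return
    while nxt[cur] != s:
        cur = nxt[cur]
    nxt[cur] = nxt[s]


@njit(cache=True, inline="always")
def _grid_insert(s, x, y, z, cell, M, head_arr, nxt, cellid):
    ix = np.int64(np.floor(x / cell))
    iy = np.int64(np.floor(y / cell))
    iz = np.int64(np.floor(z / cell))
    h = _hash_cell(ix, iy, iz, M)
    cellid[s] = h
    nxt[s] = head_arr[h]
    head_arr[h] = s


@njit(cache=True)
def _overlap(ci, x, y, z, pos, cell, M, head_arr, nxt, d2, lo, hi, head, n, skip):
    """True if a bead with chain index ``ci`` placed at (x,y,z) overlaps any
    bead whose chain index is outside [lo, hi], differs from ci by >= 2, and
    is not ``skip`` (the slot of a bead being removed; -1 for none)."""
    ix = np.int64(np.floor(x / cell))
    iy = np.int64(np.floor(y / cell))
    iz = np.int64(np.floor(z / cell))
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                h = _hash_cell(ix + dx, iy + dy, iz + dz, M)
                s = head_arr[h]
                while s != -1:
                    if s != skip:
                        c = s - head
                        if c < 0:
                            c += n
                        if (c < lo or c > hi) and (c < ci - 1 or c > ci + 1):
                            rx = pos[s, 0] - x
                            ry = pos[s, 1] - y
                            rz = pos[s, 2] - z
                            if rx * rx + ry * ry + rz * rz < d2:
                                return True
                    s = nxt[s]
    return False


@njit(cache=True, inline="always")
def _angle_energy(ax, ay, az, bx, by, bz, b2, kappa):
    c = (ax * bx + ay * by + az * bz) / b2
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    th = np.arccos(c)
    return kappa * th * th


@njit(cache=True, inline="always")
def _rotate(px, py, pz, ox, oy, oz, ux, uy, uz, ca, sa):
    """Rodrigues rotation of point p about axis u through origin o."""
    vx = px - ox
    vy = py - oy
    vz = pz - oz
    dot = ux * vx + uy * vy + uz * vz
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    rx = vx * ca + cx * sa + ux * dot * (1.0 - ca)
    ry = vy * ca + cy * sa + uy * dot * (1.0 - ca)
    rz = vz * ca + cz * sa + uz * dot * (1.0 - ca)
    return ox + rx, oy + ry, oz + rz


@njit(cache=True)
def run_chain(
    pos,
    head,
    segment,
    kappa,
    half_w,
    half_h,
    confined,
    ev_diam,
    n_sweeps,
    tune_until,
    crank_amp0,
    pivot_amp0,
    pivots_per_sweep,
    reptations_per_sweep,
    max_span,
    theta_cdf,
    seed,
):
    """Metropolis sampling; returns per-sweep z-span and move statistics.

    ``theta_cdf``: inverse CDF of the joint-angle Boltzmann density on a
    uniform [0, 1] grid, used to propose reptation angles.  ``tune_until``:
    crankshaft/pivot amplitudes adapt toward ~40% acceptance every 100 sweeps
    during the first ``tune_until`` sweeps only, so production sweeps satisfy
    detailed balance with fixed amplitudes.  Returns (extension trajectory
    with columns [z-span, sqrt(12 var z)], crank rate, pivot rate, reptation
    rate, crank amp, pivot amp, head).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    b2 = segment * segment
    use_ev = ev_diam > 0.0
    cell = ev_diam if use_ev else 1.0
    M = 4 * n + 7
    grid_head = np.full(M, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cellid = np.zeros(n, dtype=np.int64)
    if use_ev:
        _build_grid(pos, cell, M, grid_head, nxt, cellid)
    d2 = ev_diam * ev_diam
    ncdf = theta_cdf.shape[0]

    newp = np.empty((n, 3))
    ext = np.empty((n_sweeps, 2))
    crank_amp = crank_amp0
    pivot_amp = pivot_amp0
    acc_c = 0
    try_c = 0
    acc_p = 0
    try_p = 0
    acc_r = 0
    try_r = 0
    acc_c_tot = 0
    try_c_tot = 0
    acc_p_tot = 0
    try_p_tot = 0

    for sweep in range(n_sweeps):
        # --- reptation ---
        for _ in range(reptations_per_sweep):
            try_r += 1
            forward = np.random.random() < 0.5
            if forward:
                # remove chain bead 0, append after bead n-1
                s_rm = head
                s_a = head + n - 2
                if s_a >= n:
                    s_a -= n
                s_b = head + n - 1
                if s_b >= n:
                    s_b -= n
                ci_new = n  # one past the current tail: excludes only the attach bead
            else:
                s_rm = head + n - 1
                if s_rm >= n:
                    s_rm -= n
                s_a = head + 1
                if s_a >= n:
                    s_a -= n
                s_b = head
                ci_new = -1
            # tangent of the boundary bond
            tx = (pos[s_b, 0] - pos[s_a, 0]) / segment
            ty = (pos[s_b, 1] - pos[s_a, 1]) / segment
            tz = (pos[s_b, 2] - pos[s_a, 2]) / segment
            # orthonormal frame: e1 = t x a with a chosen away from t
            if abs(tz) > 0.9:
                e1x, e1y, e1z = 0.0, tz, -ty  # a = x-hat
            else:
                e1x, e1y, e1z = ty, -tx, 0.0  # a = z-hat
            nrm = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            e1x /= nrm
            e1y /= nrm
            e1z /= nrm
            e2x = ty * e1z - tz * e1y
            e2y = tz * e1x - tx * e1z
            e2z = tx * e1y - ty * e1x
            # Boltzmann-proposed joint angle via inverse CDF
            u = np.random.random() * (ncdf - 1)
            iu = int(u)
            if iu >= ncdf - 1:
                iu = ncdf - 2
            th = theta_cdf[iu] + (u - iu) * (theta_cdf[iu + 1] - theta_cdf[iu])
            ph = np.random.random() * 2.0 * np.pi
            st = np.sin(th)
            ctn = np.cos(th)
            dxn = ctn * tx + st * (np.cos(ph) * e1x + np.sin(ph) * e2x)
            dyn = ctn * ty + st * (np.cos(ph) * e1y + np.sin(ph) * e2y)
            dzn = ctn * tz + st * (np.cos(ph) * e1z + np.sin(ph) * e2z)
            x = pos[s_b, 0] + segment * dxn
            y = pos[s_b, 1] + segment * dyn
            z = pos[s_b, 2] + segment * dzn
            if confined and (abs(x) > half_w or abs(y) > half_h):
                continue
            if use_ev and _overlap(
                ci_new, x, y, z, pos, cell, M, grid_head, nxt, d2, -2, -2, head, n, s_rm
            ):
                continue
            # accept: proposal density cancels the bending Boltzmann factor
            if use_ev:
                _grid_remove(s_rm, grid_head, nxt, cellid)
            pos[s_rm, 0] = x
            pos[s_rm, 1] = y
            pos[s_rm, 2] = z
            if use_ev:
                _grid_insert(s_rm, x, y, z, cell, M, grid_head, nxt, cellid)
            if forward:
                head += 1
                if head >= n:
                    head -= n
            else:
                head -= 1
                if head < 0:
                    head += n
            acc_r += 1

        # --- crankshaft ---
        for _ in range(n):
            try_c += 1
            i = np.random.randint(0, n - 2)
            span = 2 + np.random.randint(max_span)
            j = i + span
            if j > n - 1:
                j = n - 1
            si = head + i
            if si >= n:
                si -= n
            sj = head + j
            if sj >= n:
                sj -= n
            ax = pos[sj, 0] - pos[si, 0]
            ay = pos[sj, 1] - pos[si, 1]
            az = pos[sj, 2] - pos[si, 2]
            norm = np.sqrt(ax * ax + ay * ay + az * az)
            if norm < 1e-12:
                continue
            ax /= norm
            ay /= norm
            az /= norm
            ang = (2.0 * np.random.random() - 1.0) * crank_amp
            ca = np.cos(ang)
            sa = np.sin(ang)
            ok = True
            for k in range(i + 1, j):
                sk = head + k
                if sk >= n:
                    sk -= n
                x, y, z = _rotate(
                    pos[sk, 0], pos[sk, 1], pos[sk, 2],
                    pos[si, 0], pos[si, 1], pos[si, 2],
                    ax, ay, az, ca, sa,
                )
                if confined and (abs(x) > half_w or abs(y) > half_h):
                    ok = False
                    break
                if use_ev and _overlap(
                    k, x, y, z, pos, cell, M, grid_head, nxt, d2, i + 1, j - 1, head, n, -1
                ):
                    ok = False
                    break
                newp[k, 0] = x
                newp[k, 1] = y
                newp[k, 2] = z
            if not ok:
                continue
            dE = 0.0
            if i >= 1:
                sm = head + i - 1
                if sm >= n:
                    sm -= n
                e_old = _angle_energy(
                    pos[si, 0] - pos[sm, 0],
                    pos[si, 1] - pos[sm, 1],
                    pos[si, 2] - pos[sm, 2],
                    pos[_slot(head, i + 1, n), 0] - pos[si, 0],
                    pos[_slot(head, i + 1, n), 1] - pos[si, 1],
                    pos[_slot(head, i + 1, n), 2] - pos[si, 2],
                    b2,
                    kappa,
                )
                e_new = _angle_energy(
                    pos[si, 0] - pos[sm, 0],
                    pos[si, 1] - pos[sm, 1],
                    pos[si, 2] - pos[sm, 2],
                    newp[i + 1, 0] - pos[si, 0],
                    newp[i + 1, 1] - pos[si, 1],
                    newp[i + 1, 2] - pos[si, 2],
                    b2,
                    kappa,
                )
                dE += e_new - e_old
            if j <= n - 2:
                sp = head + j + 1
                if sp >= n:
                    sp -= n
                e_old = _angle_energy(
                    pos[sj, 0] - pos[_slot(head, j - 1, n), 0],
                    pos[sj, 1] - pos[_slot(head, j - 1, n), 1],
                    pos[sj, 2] - pos[_slot(head, j - 1, n), 2],
                    pos[sp, 0] - pos[sj, 0],
                    pos[sp, 1] - pos[sj, 1],
                    pos[sp, 2] - pos[sj, 2],
                    b2,
                    kappa,
                )
                e_new = _angle_energy(
                    pos[sj, 0] - newp[j - 1, 0],
                    pos[sj, 1] - newp[j - 1, 1],
                    pos[sj, 2] - newp[j - 1, 2],
                    pos[sp, 0] - pos[sj, 0],
                    pos[sp, 1] - pos[sj, 1],
                    pos[sp, 2] - pos[sj, 2],
                    b2,
                    kappa,
                )
                dE += e_new - e_old
            if dE <= 0.0 or np.random.random() < np.exp(-dE):
                for k in range(i + 1, j):
                    sk = head + k
                    if sk >= n:
                        sk -= n
                    if use_ev:
                        _grid_remove(sk, grid_head, nxt, cellid)
                    pos[sk, 0] = newp[k, 0]
                    pos[sk, 1] = newp[k, 1]
                    pos[sk, 2] = newp[k, 2]
                    if use_ev:
                        _grid_insert(
                            sk, pos[sk, 0], pos[sk, 1], pos[sk, 2], cell, M,
                            grid_head, nxt, cellid,
                        )
                acc_c += 1

        # --- pivot ---
        for _ in range(pivots_per_sweep):
            try_p += 1
            i = 1 + np.random.randint(n - 2)
            if i <= n - 1 - i:
                lo, hi = 0, i - 1
            else:
                lo, hi = i + 1, n - 1
            ux = np.random.normal()
            uy = np.random.normal()
            uz = np.random.normal()
            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
            if norm < 1e-12:
                continue
            ux /= norm
            uy /= norm
            uz /= norm
            ang = (2.0 * np.random.random() - 1.0) * pivot_amp
            ca = np.cos(ang)
            sa = np.sin(ang)
            si = head + i
            if si >= n:
                si -= n
            ok = True
            for k in range(lo, hi + 1):
                sk = head + k
                if sk >= n:
                    sk -= n
                x, y, z = _rotate(
                    pos[sk, 0], pos[sk, 1], pos[sk, 2],
                    pos[si, 0], pos[si, 1], pos[si, 2],
                    ux, uy, uz, ca, sa,
                )
                if confined and (abs(x) > half_w or abs(y) > half_h):
                    ok = False
                    break
                if use_ev and _overlap(
                    k, x, y, z, pos, cell, M, grid_head, nxt, d2, lo, hi, head, n, -1
                ):
                    ok = False
                    break
                newp[k, 0] = x
                newp[k, 1] = y
                newp[k, 2] = z
            if not ok:
                continue
            sm = head + i - 1
            if sm >= n:
                sm -= n
            sp = head + i + 1
            if sp >= n:
                sp -= n
            e_old = _angle_energy(
                pos[si, 0] - pos[sm, 0],
                pos[si, 1] - pos[sm, 1],
                pos[si, 2] - pos[sm, 2],
                pos[sp, 0] - pos[si, 0],
                pos[sp, 1] - pos[si, 1],
                pos[sp, 2] - pos[si, 2],
                b2,
                kappa,
            )
            if hi < i:  # head side rotated: bond i-1 changed
                e_new = _angle_energy(
                    pos[si, 0] - newp[i - 1, 0],
                    pos[si, 1] - newp[i - 1, 1],
                    pos[si, 2] - newp[i - 1, 2],
                    pos[sp, 0] - pos[si, 0],
                    pos[sp, 1] - pos[si, 1],
                    pos[sp, 2] - pos[si, 2],
                    b2,
                    kappa,
                )
            else:  # tail side rotated: bond i changed
                e_new = _angle_energy(
                    pos[si, 0] - pos[sm, 0],
                    pos[si, 1] - pos[sm, 1],
                    pos[si, 2] - pos[sm, 2],
                    newp[i + 1, 0] - pos[si, 0],
                    newp[i + 1, 1] - pos[si, 1],
                    newp[i + 1, 2] - pos[si, 2],
                    b2,
                    kappa,
                )
            dE = e_new - e_old
            if dE <= 0.0 or np.random.random() < np.exp(-dE):
                for k in range(lo, hi + 1):
                    sk = head + k
                    if sk >= n:
                        sk -= n
                    if use_ev:
                        _grid_remove(sk, grid_head, nxt, cellid)
                    pos[sk, 0] = newp[k, 0]
                    pos[sk, 1] = newp[k, 1]
                    pos[sk, 2] = newp[k, 2]
                    if use_ev:
                        _grid_insert(
                            sk, pos[sk, 0], pos[sk, 1], pos[sk, 2], cell, M,
                            grid_head, nxt, cellid,
                        )
                acc_p += 1

        zmin = pos[0, 2]
        zmax = pos[0, 2]
        zs = 0.0
        zs2 = 0.0
        for s in range(n):
            z = pos[s, 2]
            if z < zmin:
                zmin = z
            elif z > zmax:
                zmax = z
            zs += z
            zs2 += z * z
        ext[sweep, 0] = zmax - zmin
        var = zs2 / n - (zs / n) ** 2
        if var < 0.0:
            var = 0.0
        # uniform-rod identity: the axial length of a homogeneous segment
        # with this second moment
        ext[sweep, 1] = np.sqrt(12.0 * var)

        if sweep < tune_until and (sweep + 1) % 100 == 0:
            if try_c > 0:
                rate = acc_c / try_c
                if rate < 0.3:
                    crank_amp *= 0.8
                elif rate > 0.5:
                    crank_amp *= 1.25
                if crank_amp > np.pi:
                    crank_amp = np.pi
                elif crank_amp < 1e-4:
                    crank_amp = 1e-4
            if try_p > 0:
                rate = acc_p / try_p
                if rate < 0.3:
                    pivot_amp *= 0.8
                elif rate > 0.5:
                    pivot_amp *= 1.25
                if pivot_amp > np.pi:
                    pivot_amp = np.pi
                elif pivot_amp < 1e-5:
                    pivot_amp = 1e-5
            acc_c_tot += acc_c
            try_c_tot += try_c
            acc_p_tot += acc_p
            try_p_tot += try_p
            acc_c = 0
            try_c = 0
            acc_p = 0
            try_p = 0

    acc_c_tot += acc_c
    try_c_tot += try_c
    acc_p_tot += acc_p
    try_p_tot += try_p
    rate_c = acc_c_tot / try_c_tot if try_c_tot > 0 else 0.0
    rate_p = acc_p_tot / try_p_tot if try_p_tot > 0 else 0.0
    rate_r = acc_r / try_r if try_r > 0 else 0.0
    return ext, rate_c, rate_p, rate_r, crank_amp, pivot_amp, head


@njit(cache=True, inline="always")
def _slot(head, k, n):
    s = head + k
    if s >= n:
        s -= n
    return s


@njit(cache=True)
def reorder(pos, head):
    """Return bead positions in chain order (chain bead 0 first)."""
    n = pos.shape[0]
    out = np.empty_like(pos)
    for k in range(n):
        s = head + k
        if s >= n:
            s -= n
        out[k] = pos[s]
    return out


@njit(cache=True)
def bend_angles(pos, segment):
    """Interior bend angles theta_i of a chain-ordered bead array."""
    n = pos.shape[0]
    out = np.empty(n - 2)
    b2 = segment * segment
    for v in range(1, n - 1):
        ax = pos[v, 0] - pos[v - 1, 0]
        ay = pos[v, 1] - pos[v - 1, 1]
        az = pos[v, 2] - pos[v - 1, 2]
        bx = pos[v + 1, 0] - pos[v, 0]
        by = pos[v + 1, 1] - pos[v, 1]
        bz = pos[v + 1, 2] - pos[v, 2]
        c = (ax * bx + ay * by + az * bz) / b2
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        out[v - 1] = np.arccos(c)
    return out
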