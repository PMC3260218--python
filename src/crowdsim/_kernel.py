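"""Compiled event-loop core.

The simulator is asynchronous: each particle keeps the position and
time at which it was last sampled, and only event participants are ever
moved.  Every live particle owns one pending event — either the
earliest diffusion-limit-sphere contact against any other particle
(computed from the analytic pair collision time) or, when nothing can
happen within the staleness horizon, a refresh that simply resamples
it.  Popped events whose participants changed since scheduling are
discarded via per-particle generation counters; dimers additionally
carry a birth epoch so that dissociation events survive position
resampling but not the dimer's death.

Because every pending event fires (or is superseded) within
``refresh_ns`` of its owner's last sample, no particle's position is
ever staler than the horizon.  That bound makes neighbour search with a
uniform cell grid exact: scanning outward in Chebyshev shells can stop
as soon as the nearest unscanned cell is farther than any
maximally-stale particle's diffusion limit sphere could reach within
the current best contact delay.

Everything here operates on flat preallocated arrays so numba can
compile the whole loop; the friendly wrappers live in ``engine`` and
``chemistry``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .collision import contact_delay

# species codes (match params.MONOMER/DIMER/INERT)
MONOMER, DIMER, INERT = 0, 1, 2

# event kinds
EV_PAIR = 0  # b >= 0: pair contact; b == -1: refresh
EV_DISS = 1
EV_REC = 2

# reaction outcome codes (shared with chemistry wrappers)
OUT_NO_CONTACT = 0
OUT_BOUND = 1
OUT_REJECTED = 2
OUT_PLACEMENT_FAILED = 3

# stats slots
S_EVENTS = 0
S_PAIR = 1
S_CONTACTS = 2
S_BOUND = 3
S_REJECTED = 4
S_DISS_OK = 5
S_DISS_POSTPONED = 6
S_SAMPLE_FALLBACK = 7
S_DIMER_PLACE_FAIL = 8
S_REFRESH = 9
N_STATS = 10

MAX_SAMPLE_TRIES = 100
MAX_SEPARATE_TRIES = 20
MAX_DIMER_TRIES = 20
MAX_DISS_TRIES = 100

#: minimum rescheduling delay (ns) between two freshly sampled particles;
#: prevents zero-measure same-timestamp event loops when a pair is left
#: in contact after failed placements.  Diffusion over this interval is
#: ~1e-4 nm, far below any geometric scale of the model.
MIN_FRESH_DELAY = 1e-6

#: minimum contact-event spacing (ns) for pairs with no chemistry
#: (anything but monomer-monomer).  Their events only refresh positions
#: against the hard-sphere constraint, so sub-resolution pinging near
#: contact is pure overhead; diffusion over this floor is ~0.04 nm.
NONREACTIVE_MIN_DELAY = 0.01

#: rescheduling floor (ns) for the two monomers after a failed dimer
#: placement: re-attempting the same blocked binding at the contact
#: granularity would busy-loop until the local cage rearranges, so the
#: pair waits roughly a cage-relaxation time instead.
PLACEMENT_FAIL_BACKOFF = 0.02


@njit(cache=True, inline="always")
def _cell_index(x, y, z, inv_ex, inv_ey, inv_ez, nx, ny, nz):
    cx = int(x * inv_ex)
    cy = int(y * inv_ey)
    cz = int(z * inv_ez)
    if cx < 0:
        cx = 0
    elif cx >= nx:
        cx = nx - 1
    if cy < 0:
        cy = 0
    elif cy >= ny:
        cy = ny - 1
    if cz < 0:
        cz = 0
    elif cz >= nz:
        cz = nz - 1
    return (cx * ny + cy) * nz + cz


@njit(cache=True, inline="always")
def _grid_remove(i, head, nxt, prv, cellid):
    c = cellid[i]
    if c < 0:
        return
    p = prv[i]
    n = nxt[i]
    if p >= 0:
        nxt[p] = n
    else:
        head[c] = n
    if n >= 0:
        prv[n] = p
    cellid[i] = -1


@njit(cache=True, inline="always")
def _grid_insert(i, c, head, nxt, prv, cellid):
    cellid[i] = c
    prv[i] = -1
    nxt[i] = head[c]
    if head[c] >= 0:
        prv[head[c]] = i
    head[c] = i


@njit(cache=True, fastmath=True)
def _fits(x, y, z, r, skip_a, skip_b, pos, rad, alive, box, grid):
    """Centre inside the box and no hard-sphere overlap with any live
    particle (at its last-sampled position), excluding two slots.

    The cell edge is at least one maximal interaction diameter, so the
    3x3x3 block around the candidate cell covers every possible overlap.
    """
    if x < 0.0 or x > box[0] or y < 0.0 or y > box[1] or z < 0.0 or z > box[2]:
        return False
    head, nxt, prv, cellid, dims, inv = grid
    nx, ny, nz = dims[0], dims[1], dims[2]
    cx = min(max(int(x * inv[0]), 0), nx - 1)
    cy = min(max(int(y * inv[1]), 0), ny - 1)
    cz = min(max(int(z * inv[2]), 0), nz - 1)
    for ax in range(max(cx - 1, 0), min(cx + 2, nx)):
        for ay in range(max(cy - 1, 0), min(cy + 2, ny)):
            for az in range(max(cz - 1, 0), min(cz + 2, nz)):
                j = head[(ax * ny + ay) * nz + az]
                while j >= 0:
                    if j != skip_a and j != skip_b:
                        dx = x - pos[j, 0]
                        dy = y - pos[j, 1]
                        dz = z - pos[j, 2]
                        rr = r + rad[j]
                        if dx * dx + dy * dy + dz * dz < rr * rr:
                            return False
                    j = nxt[j]
    return True


@njit(cache=True)
def _random_unit():
    while True:
        x = np.random.standard_normal()
        y = np.random.standard_normal()
        z = np.random.standard_normal()
        n = math.sqrt(x * x + y * y + z * z)
        if n > 1e-12:
            return x / n, y / n, z / n


@njit(cache=True, inline="always")
def _move_to(i, x, y, z, pos, grid):
    head, nxt, prv, cellid, dims, inv = grid
    pos[i, 0] = x
    pos[i, 1] = y
    pos[i, 2] = z
    c = _cell_index(x, y, z, inv[0], inv[1], inv[2], dims[0], dims[1], dims[2])
    if c != cellid[i]:
        _grid_remove(i, head, nxt, prv, cellid)
        _grid_insert(i, c, head, nxt, prv, cellid)


@njit(cache=True, fastmath=True)
def _sample_position(i, t, pos, rad, dif, tl, gen, alive, box, grid, skip):
    """Move particle ``i`` to time ``t``.

    Draws an isotropic Gaussian displacement (per-coordinate sigma
    ``sqrt(2*D*dt)``), rejected until it lies inside the 3-sigma
    diffusion limit sphere; mirrors across violated box faces (redrawn
    if the mirrored centre is still outside, which can happen in thin
    boxes); redraws on hard-sphere overlap with any other particle's
    last-sampled position.  ``skip >= 0`` exempts one particle from the
    overlap check (used when a sampled overlap with the collision
    partner counts as the collision itself and is resolved by the
    reaction step).  On retry exhaustion the particle keeps its
    position and only advances its clock, which guarantees progress in
    extreme crowding.  Returns 1 on that fallback, else 0.
    """
    dt = t - tl[i]
    if dt <= 0.0:
        return 0
    sig = math.sqrt(2.0 * dif[i] * dt)
    rmax2 = 9.0 * sig * sig
    for _ in range(MAX_SAMPLE_TRIES):
        dx = sig * np.random.standard_normal()
        dy = sig * np.random.standard_normal()
        dz = sig * np.random.standard_normal()
        if dx * dx + dy * dy + dz * dz > rmax2:
            continue
        x = pos[i, 0] + dx
        y = pos[i, 1] + dy
        z = pos[i, 2] + dz
        if x < 0.0:
            x = -x
        elif x > box[0]:
            x = 2.0 * box[0] - x
        if y < 0.0:
            y = -y
        elif y > box[1]:
            y = 2.0 * box[1] - y
        if z < 0.0:
            z = -z
        elif z > box[2]:
            z = 2.0 * box[2] - z
        if _fits(x, y, z, rad[i], i, skip, pos, rad, alive, box, grid):
            _move_to(i, x, y, z, pos, grid)
            tl[i] = t
            gen[i] += 1
            return 0
    tl[i] = t
    gen[i] += 1
    return 1


@njit(cache=True, fastmath=True)
def _separate_pair(a, b, t, pos, rad, tl, gen, alive, box, d_th, grid):
    """Re-place a collided-but-unbound pair just outside interaction range.

    Both particles end at separation exactly ``r_a + r_b + d_th``
    (contact is strict inequality) about their centre of mass, first
    along their current axis and then along random axes.  Returns 1 on
    success, 0 if no placement fits (the pair is left at its sampled
    in-contact positions and will simply collide again)."""
    target = rad[a] + rad[b] + d_th
    cx = 0.5 * (pos[a, 0] + pos[b, 0])
    cy = 0.5 * (pos[a, 1] + pos[b, 1])
    cz = 0.5 * (pos[a, 2] + pos[b, 2])
    ddx = pos[a, 0] - pos[b, 0]
    ddy = pos[a, 1] - pos[b, 1]
    ddz = pos[a, 2] - pos[b, 2]
    d = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
    for k in range(MAX_SEPARATE_TRIES):
        if k == 0 and d > 1e-12:
            ux, uy, uz = ddx / d, ddy / d, ddz / d
        else:
            ux, uy, uz = _random_unit()
        h = 0.5 * target
        ax, ay, az = cx + ux * h, cy + uy * h, cz + uz * h
        bx, by, bz = cx - ux * h, cy - uy * h, cz - uz * h
        if _fits(ax, ay, az, rad[a], a, b, pos, rad, alive, box, grid) and _fits(
            bx, by, bz, rad[b], a, b, pos, rad, alive, box, grid
        ):
            _move_to(a, ax, ay, az, pos, grid)
            _move_to(b, bx, by, bz, pos, grid)
            tl[a] = t
            tl[b] = t
            gen[a] += 1
            gen[b] += 1
            return 1
    return 0


@njit(cache=True, fastmath=True)
def _resample_apart(
    a, b, t, pax, pay, paz, pbx, pby, pbz, tla, tlb,
    pos, rad, dif, tl, gen, alive, box, d_th, grid,
):
    """Re-place a collided-but-unbound pair by redrawing its move.

    Both particles' diffusion displacements for this event are redrawn
    from their pre-event positions until the sampled configuration puts
    them outside interaction range (separation > r_a + r_b + d_th).
    Falls back to the deterministic minimal push-apart when conditioning
    cannot be satisfied (e.g. the pre-event configuration was already
    within range because a third-party event moved one of them there).
    Returns 1 on success, 0 on fallback."""
    target = rad[a] + rad[b] + d_th
    for _ in range(MAX_SEPARATE_TRIES):
        # restore the pre-event state and redraw the move
        _move_to(a, pax, pay, paz, pos, grid)
        _move_to(b, pbx, pby, pbz, pos, grid)
        tl[a] = tla
        tl[b] = tlb
        _sample_position(a, t, pos, rad, dif, tl, gen, alive, box, grid, b)
        _sample_position(b, t, pos, rad, dif, tl, gen, alive, box, grid, a)
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        if dx * dx + dy * dy + dz * dz > target * target:
            return 1
    sep = _separate_pair(a, b, t, pos, rad, tl, gen, alive, box, d_th, grid)
    if sep == 0:
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        if dx * dx + dy * dy + dz * dz < (rad[a] + rad[b]) ** 2:
            # unresolved hard-core overlap: undo the move entirely
            _move_to(a, pax, pay, paz, pos, grid)
            _move_to(b, pbx, pby, pbz, pos, grid)
    return 0


@njit(cache=True, fastmath=True)
def _place_dimer(a, b, pos, rad, alive, box, r_dimer, grid):
    """Find a centre for the dimer replacing monomers a and b.

    Tries the pair's centre of mass first, then isotropically jittered
    candidates.  Returns (ok, x, y, z)."""
    cx = 0.5 * (pos[a, 0] + pos[b, 0])
    cy = 0.5 * (pos[a, 1] + pos[b, 1])
    cz = 0.5 * (pos[a, 2] + pos[b, 2])
    jitter = 0.5  # nm
    for k in range(MAX_DIMER_TRIES):
        if k == 0:
            x, y, z = cx, cy, cz
        else:
            x = cx + jitter * np.random.standard_normal()
            y = cy + jitter * np.random.standard_normal()
            z = cz + jitter * np.random.standard_normal()
        if _fits(x, y, z, r_dimer, a, b, pos, rad, alive, box, grid):
            return True, x, y, z
    return False, 0.0, 0.0, 0.0


@njit(cache=True, fastmath=True)
def _place_dissociated(i, pos, rad, alive, box, r_mono, diss_gap, grid):
    """Positions for the two monomers released by dimer ``i``.

    Placed symmetrically about the dimer centre along a uniformly
    random axis at separation exactly ``2*r_mono + d_th`` (just beyond
    interaction range, honouring the post-reaction separation rule).
    Returns (ok, ax, ay, az, bx, by, bz)."""
    h = r_mono + 0.5 * diss_gap
    cx, cy, cz = pos[i, 0], pos[i, 1], pos[i, 2]
    for _ in range(MAX_DISS_TRIES):
        ux, uy, uz = _random_unit()
        ax, ay, az = cx + ux * h, cy + uy * h, cz + uz * h
        bx, by, bz = cx - ux * h, cy - uy * h, cz - uz * h
        if _fits(ax, ay, az, r_mono, i, -1, pos, rad, alive, box, grid) and _fits(
            bx, by, bz, r_mono, i, -1, pos, rad, alive, box, grid
        ):
            return True, ax, ay, az, bx, by, bz
    return False, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0


@njit(cache=True)
def _heap_swap(ht, hseq, hk, ha, hb, hga, hgb, i, j):
    ht[i], ht[j] = ht[j], ht[i]
    hseq[i], hseq[j] = hseq[j], hseq[i]
    hk[i], hk[j] = hk[j], hk[i]
    ha[i], ha[j] = ha[j], ha[i]
    hb[i], hb[j] = hb[j], hb[i]
    hga[i], hga[j] = hga[j], hga[i]
    hgb[i], hgb[j] = hgb[j], hgb[i]


@njit(cache=True)
def _heap_push(ht, hseq, hk, ha, hb, hga, hgb, hn, t, sq, k, a, b, ga, gb):
    i = hn
    ht[i] = t
    hseq[i] = sq
    hk[i] = k
    ha[i] = a
    hb[i] = b
    hga[i] = ga
    hgb[i] = gb
    while i > 0:
        p = (i - 1) >> 1
        if (ht[p] > ht[i]) or (ht[p] == ht[i] and hseq[p] > hseq[i]):
            _heap_swap(ht, hseq, hk, ha, hb, hga, hgb, i, p)
            i = p
        else:
            break
    return hn + 1


@njit(cache=True)
def _heap_pop(ht, hseq, hk, ha, hb, hga, hgb, hn):
    n = hn - 1
    _heap_swap(ht, hseq, hk, ha, hb, hga, hgb, 0, n)
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        m = i
        if l < n and ((ht[l] < ht[m]) or (ht[l] == ht[m] and hseq[l] < hseq[m])):
            m = l
        if r < n and ((ht[r] < ht[m]) or (ht[r] == ht[m] and hseq[r] < hseq[m])):
            m = r
        if m == i:
            break
        _heap_swap(ht, hseq, hk, ha, hb, hga, hgb, i, m)
        i = m
    return n


@njit(cache=True)
def _heapify(ht, hseq, hk, ha, hb, hga, hgb, m):
    for start in range((m - 2) >> 1, -1, -1):
        i = start
        while True:
            l = 2 * i + 1
            r = l + 1
            mm = i
            if l < m and ((ht[l] < ht[mm]) or (ht[l] == ht[mm] and hseq[l] < hseq[mm])):
                mm = l
            if r < m and ((ht[r] < ht[mm]) or (ht[r] == ht[mm] and hseq[r] < hseq[mm])):
                mm = r
            if mm == i:
                break
            _heap_swap(ht, hseq, hk, ha, hb, hga, hgb, i, mm)
            i = mm


@njit(cache=True)
def _heap_compact(ht, hseq, hk, ha, hb, hga, hgb, hn, gen, epoch, alive):
    """Drop entries whose owner is stale and re-heapify."""
    m = 0
    for i in range(hn):
        k = hk[i]
        a = ha[i]
        keep = True
        if k == EV_PAIR:
            if (not alive[a]) or gen[a] != hga[i]:
                keep = False
        elif k == EV_DISS:
            if (not alive[a]) or epoch[a] != hga[i]:
                keep = False
        if keep:
            ht[m] = ht[i]
            hseq[m] = hseq[i]
            hk[m] = hk[i]
            ha[m] = a
            hb[m] = hb[i]
            hga[m] = hga[i]
            hgb[m] = hgb[i]
            m += 1
    _heapify(ht, hseq, hk, ha, hb, hga, hgb, m)
    return m


@njit(cache=True, fastmath=True)
def _schedule_next(
    i, now, pos, rad, acoef, tl, gen, alive, refresh_ns, r_max, a_max,
    ht, hseq, hk, ha, hb, hga, hgb, hn, seq, grid, box, sp, pair_dth, min_u,
):
    """Push particle ``i``'s next event: its earliest sphere-contact time
    against any other live particle, or a refresh at the horizon.

    Scans the cell grid outward shell by shell; stops once no particle
    beyond the scanned shells — even one at maximal staleness — could
    make contact sooner than the best delay found."""
    head, nxt, prv, cellid, dims, inv = grid
    nx, ny, nz = dims[0], dims[1], dims[2]
    s_i = now - tl[i]
    a_i = acoef[i]
    best_u = refresh_ns
    best_j = -1
    px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
    cx = min(max(int(px * inv[0]), 0), nx - 1)
    cy = min(max(int(py * inv[1]), 0), ny - 1)
    cz = min(max(int(pz * inv[2]), 0), nz - 1)
    # smallest cell edge among axes that actually have multiple cells
    min_edge = 1e300
    if nx > 1 and 1.0 / inv[0] < min_edge:
        min_edge = 1.0 / inv[0]
    if ny > 1 and 1.0 / inv[1] < min_edge:
        min_edge = 1.0 / inv[1]
    if nz > 1 and 1.0 / inv[2] < min_edge:
        min_edge = 1.0 / inv[2]
    k_cap = nx
    if ny > k_cap:
        k_cap = ny
    if nz > k_cap:
        k_cap = nz
    for shell in range(k_cap):
        lo_x = max(cx - shell, 0)
        hi_x = min(cx + shell, nx - 1)
        lo_y = max(cy - shell, 0)
        hi_y = min(cy + shell, ny - 1)
        lo_z = max(cz - shell, 0)
        hi_z = min(cz + shell, nz - 1)
        for ax in range(lo_x, hi_x + 1):
            on_x = ax == cx - shell or ax == cx + shell
            for ay in range(lo_y, hi_y + 1):
                on_y = ay == cy - shell or ay == cy + shell
                for az in range(lo_z, hi_z + 1):
                    if shell > 0 and not (on_x or on_y or az == cz - shell or az == cz + shell):
                        continue
                    j = head[(ax * ny + ay) * nz + az]
                    while j >= 0:
                        if j != i:
                            dx = px - pos[j, 0]
                            dy = py - pos[j, 1]
                            dz = pz - pos[j, 2]
                            c = math.sqrt(dx * dx + dy * dy + dz * dz) - rad[i] - rad[j]
                            reactive_pair = sp[i] == MONOMER and sp[j] == MONOMER
                            if reactive_pair:
                                c -= pair_dth
                            s_j = now - tl[j]
                            if s_i <= s_j:
                                a1, a2, ds, smin = a_i, acoef[j], s_j - s_i, s_i
                            else:
                                a1, a2, ds, smin = acoef[j], a_i, s_i - s_j, s_j
                            g = c - a2 * math.sqrt(ds)
                            skip = False
                            if g > 0.0:
                                lb = g / (a1 + a2)
                                if lb * lb - smin >= best_u:
                                    skip = True
                            if not skip:
                                u = contact_delay(c, a1, a2, ds) - smin
                                if u < 0.0:
                                    u = 0.0
                                if u < MIN_FRESH_DELAY and s_i == 0.0 and s_j == 0.0:
                                    u = MIN_FRESH_DELAY
                                if not reactive_pair and u < NONREACTIVE_MIN_DELAY:
                                    # non-reactive contacts only enforce the
                                    # hard core, which position sampling
                                    # already guarantees; firing them at
                                    # vanishing intervals near contact adds
                                    # nothing but cost
                                    u = NONREACTIVE_MIN_DELAY
                                if u < min_u:
                                    u = min_u
                                if u < best_u:
                                    best_u = u
                                    best_j = j
                        j = nxt[j]
        # can any unscanned particle beat best_u?
        reach = (
            rad[i]
            + r_max
            + a_i * math.sqrt(s_i + best_u)
            + a_max * math.sqrt(refresh_ns + best_u)
        )
        if shell * min_edge >= reach:
            break
    if best_j >= 0:
        hn = _heap_push(
            ht, hseq, hk, ha, hb, hga, hgb, hn,
            now + best_u, seq, EV_PAIR, i, best_j, gen[i], gen[best_j],
        )
    else:
        hn = _heap_push(
            ht, hseq, hk, ha, hb, hga, hgb, hn,
            now + refresh_ns, seq, EV_PAIR, i, -1, gen[i], 0,
        )
    return hn, seq + 1


@njit(cache=True)
def run_kernel(
    pos, rad, dif, acoef, tl, sp, gen, epoch, alive,
    box, b_prob, m_ns, d_th, r_mono, d_mono, r_dimer, d_dimer,
    t_end, rec_interval, refresh_ns, seed, overlap_contact, diss_gap, pair_dth,
    rec_t, rec_nm, rec_nd,
):
    """Advance the event queue to ``t_end`` (ns).

    Mutates the state arrays in place, fills the record arrays at every
    multiple of ``rec_interval`` (including t = 0), and returns
    ``(n_records, stats)``.
    """
    np.random.seed(seed)
    cap = alive.shape[0]
    stats = np.zeros(N_STATS, dtype=np.int64)
    eps = 1e-9

    # cell grid: edge large enough that (a) overlap checks never look
    # past the adjacent shell and (b) a single shell covers the farthest
    # any maximally-stale diffusion limit sphere can reach within one
    # horizon, so the scheduling scan almost always stops at shell 1
    r_max = r_dimer if r_dimer > r_mono else r_mono
    a_max = acoef[0]
    for i in range(cap):
        if alive[i]:
            if rad[i] > r_max:
                r_max = rad[i]
            if acoef[i] > a_max:
                a_max = acoef[i]
    a_dimer = 3.0 * math.sqrt(2.0 * d_dimer)
    a_mono = 3.0 * math.sqrt(2.0 * d_mono)
    if a_dimer > a_max:
        a_max = a_dimer
    if a_mono > a_max:
        a_max = a_mono
    h_min = 2.0 * r_max + d_th + 2.0 * a_max * math.sqrt(2.0 * refresh_ns)
    dims = np.empty(3, dtype=np.int64)
    inv = np.empty(3, dtype=np.float64)
    for ax in range(3):
        n_ax = int(box[ax] / h_min)
        if n_ax < 1:
            n_ax = 1
        dims[ax] = n_ax
        inv[ax] = n_ax / box[ax]
    ncells = dims[0] * dims[1] * dims[2]
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(cap, -1, dtype=np.int64)
    prv = np.full(cap, -1, dtype=np.int64)
    cellid = np.full(cap, -1, dtype=np.int64)
    grid = (head, nxt, prv, cellid, dims, inv)
    for i in range(cap):
        if alive[i]:
            c = _cell_index(
                pos[i, 0], pos[i, 1], pos[i, 2],
                inv[0], inv[1], inv[2], dims[0], dims[1], dims[2],
            )
            _grid_insert(i, c, head, nxt, prv, cellid)

    n_mono = 0
    n_dimer = 0
    for i in range(cap):
        if alive[i]:
            if sp[i] == MONOMER:
                n_mono += 1
            elif sp[i] == DIMER:
                n_dimer += 1

    free = np.empty(cap, dtype=np.int64)
    n_free = 0
    for i in range(cap - 1, -1, -1):
        if not alive[i]:
            free[n_free] = i
            n_free += 1

    hcap = 64 * cap + 1024
    ht = np.empty(hcap, dtype=np.float64)
    hseq = np.empty(hcap, dtype=np.int64)
    hk = np.empty(hcap, dtype=np.int8)
    ha = np.empty(hcap, dtype=np.int64)
    hb = np.empty(hcap, dtype=np.int64)
    hga = np.empty(hcap, dtype=np.int64)
    hgb = np.empty(hcap, dtype=np.int64)
    hn = 0
    seq = 0

    hn = _heap_push(ht, hseq, hk, ha, hb, hga, hgb, hn, 0.0, seq, EV_REC, -1, -1, 0, 0)
    seq += 1
    for i in range(cap):
        if alive[i]:
            hn, seq = _schedule_next(
                i, 0.0, pos, rad, acoef, tl, gen, alive, refresh_ns, r_max, a_max,
                ht, hseq, hk, ha, hb, hga, hgb, hn, seq, grid, box, sp, pair_dth, 0.0,
            )

    n_rec = 0

    while hn > 0:
        if hn + 8 >= hcap:
            hn = _heap_compact(ht, hseq, hk, ha, hb, hga, hgb, hn, gen, epoch, alive)
            if hn + 8 >= hcap:
                raise RuntimeError("event heap overflow")
        t = ht[0]
        k = hk[0]
        a = ha[0]
        b = hb[0]
        ga = hga[0]
        gb = hgb[0]
        hn = _heap_pop(ht, hseq, hk, ha, hb, hga, hgb, hn)
        if t > t_end + eps:
            break
        stats[S_EVENTS] += 1

        if k == EV_REC:
            rec_t[n_rec] = t
            rec_nm[n_rec] = n_mono
            rec_nd[n_rec] = n_dimer
            n_rec += 1
            nxt_t = t + rec_interval
            if nxt_t <= t_end + eps and n_rec < rec_t.shape[0]:
                hn = _heap_push(
                    ht, hseq, hk, ha, hb, hga, hgb, hn, nxt_t, seq, EV_REC, -1, -1, 0, 0
                )
                seq += 1
            continue

        if k == EV_DISS:
            if (not alive[a]) or epoch[a] != ga or sp[a] != DIMER:
                continue
            stats[S_SAMPLE_FALLBACK] += _sample_position(
                a, t, pos, rad, dif, tl, gen, alive, box, grid, -1
            )
            ok, ax_, ay_, az_, bx_, by_, bz_ = _place_dissociated(
                a, pos, rad, alive, box, r_mono, diss_gap, grid
            )
            if ok:
                alive[a] = False
                gen[a] += 1
                _grid_remove(a, head, nxt, prv, cellid)
                free[n_free] = a
                n_free += 1
                n_dimer -= 1
                for child in range(2):
                    n_free -= 1
                    slot = free[n_free]
                    alive[slot] = True
                    sp[slot] = MONOMER
                    rad[slot] = r_mono
                    dif[slot] = d_mono
                    acoef[slot] = a_mono
                    if child == 0:
                        x_, y_, z_ = ax_, ay_, az_
                    else:
                        x_, y_, z_ = bx_, by_, bz_
                    pos[slot, 0], pos[slot, 1], pos[slot, 2] = x_, y_, z_
                    c = _cell_index(
                        x_, y_, z_, inv[0], inv[1], inv[2], dims[0], dims[1], dims[2]
                    )
                    _grid_insert(slot, c, head, nxt, prv, cellid)
                    tl[slot] = t
                    gen[slot] += 1
                    epoch[slot] += 1
                    n_mono += 1
                    hn, seq = _schedule_next(
                        slot, t, pos, rad, acoef, tl, gen, alive, refresh_ns, r_max,
                        a_max, ht, hseq, hk, ha, hb, hga, hgb, hn, seq, grid, box,
                        sp, pair_dth, 0.0,
                    )
                stats[S_DISS_OK] += 1
            else:
                stats[S_DISS_POSTPONED] += 1
                hn = _heap_push(
                    ht, hseq, hk, ha, hb, hga, hgb, hn,
                    t + np.random.exponential(m_ns), seq, EV_DISS, a, -1, epoch[a], 0,
                )
                seq += 1
                hn, seq = _schedule_next(
                    a, t, pos, rad, acoef, tl, gen, alive, refresh_ns, r_max, a_max,
                    ht, hseq, hk, ha, hb, hga, hgb, hn, seq, grid, box, sp, pair_dth, 0.0,
                )
            continue

        # EV_PAIR (b >= 0) or refresh (b == -1)
        if (not alive[a]) or gen[a] != ga:
            continue
        if b == -1 or (not alive[b]) or gen[b] != gb:
            # horizon refresh, or the partner changed since scheduling:
            # resample the owner (keeping staleness bounded) and recompute
            stats[S_REFRESH] += 1
            stats[S_SAMPLE_FALLBACK] += _sample_position(
                a, t, pos, rad, dif, tl, gen, alive, box, grid, -1
            )
            hn, seq = _schedule_next(
                a, t, pos, rad, acoef, tl, gen, alive, refresh_ns, r_max, a_max,
                ht, hseq, hk, ha, hb, hga, hgb, hn, seq, grid, box, sp, pair_dth, 0.0,
            )
            continue

        stats[S_PAIR] += 1
        backoff = 0.0
        reactive = sp[a] == MONOMER and sp[b] == MONOMER
        skip_ab = overlap_contact != 0 and reactive
        pax, pay, paz = pos[a, 0], pos[a, 1], pos[a, 2]
        pbx, pby, pbz = pos[b, 0], pos[b, 1], pos[b, 2]
        tla, tlb = tl[a], tl[b]
        stats[S_SAMPLE_FALLBACK] += _sample_position(
            a, t, pos, rad, dif, tl, gen, alive, box, grid, b if skip_ab else -1
        )
        stats[S_SAMPLE_FALLBACK] += _sample_position(
            b, t, pos, rad, dif, tl, gen, alive, box, grid, a if skip_ab else -1
        )

        if reactive:
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dz = pos[a, 2] - pos[b, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < rad[a] + rad[b] + d_th:
                stats[S_CONTACTS] += 1
                if np.random.random() < b_prob:
                    ok, x, y, z = _place_dimer(a, b, pos, rad, alive, box, r_dimer, grid)
                    if ok:
                        alive[a] = False
                        alive[b] = False
                        gen[a] += 1
                        gen[b] += 1
                        _grid_remove(a, head, nxt, prv, cellid)
                        _grid_remove(b, head, nxt, prv, cellid)
                        free[n_free] = a
                        n_free += 1
                        free[n_free] = b
                        n_free += 1
                        n_mono -= 2
                        n_free -= 1
                        slot = free[n_free]
                        alive[slot] = True
                        sp[slot] = DIMER
                        rad[slot] = r_dimer
                        dif[slot] = d_dimer
                        acoef[slot] = a_dimer
                        pos[slot, 0], pos[slot, 1], pos[slot, 2] = x, y, z
                        c = _cell_index(
                            x, y, z, inv[0], inv[1], inv[2], dims[0], dims[1], dims[2]
                        )
                        _grid_insert(slot, c, head, nxt, prv, cellid)
                        tl[slot] = t
                        gen[slot] += 1
                        epoch[slot] += 1
                        n_dimer += 1
                        stats[S_BOUND] += 1
                        hn = _heap_push(
                            ht, hseq, hk, ha, hb, hga, hgb, hn,
                            t + np.random.exponential(m_ns), seq, EV_DISS,
                            slot, -1, epoch[slot], 0,
                        )
                        seq += 1
                        hn, seq = _schedule_next(
                            slot, t, pos, rad, acoef, tl, gen, alive, refresh_ns,
                            r_max, a_max, ht, hseq, hk, ha, hb, hga, hgb, hn, seq,
                            grid, box, sp, pair_dth, 0.0,
                        )
                        continue
                    stats[S_DIMER_PLACE_FAIL] += 1
                    stats[S_REJECTED] += 1
                    backoff = PLACEMENT_FAIL_BACKOFF
                    if overlap_contact == 3:
                        _resample_apart(
                            a, b, t, pax, pay, paz, pbx, pby, pbz, tla, tlb,
                            pos, rad, dif, tl, gen, alive, box, d_th, grid,
                        )
                    else:
                        sep_ok = _separate_pair(
                            a, b, t, pos, rad, tl, gen, alive, box, d_th, grid
                        )
                        if sep_ok == 0 and skip_ab and d < rad[a] + rad[b]:
                            _move_to(a, pax, pay, paz, pos, grid)
                            _move_to(b, pbx, pby, pbz, pos, grid)
                else:
                    stats[S_REJECTED] += 1
                    if overlap_contact == 3:
                        _resample_apart(
                            a, b, t, pax, pay, paz, pbx, pby, pbz, tla, tlb,
                            pos, rad, dif, tl, gen, alive, box, d_th, grid,
                        )
                    elif overlap_contact == 2:
                        # sticky rule: the pair keeps its sampled positions
                        # (still within interaction range); only a hard-core
                        # overlap is pushed out, to exact touching
                        if d < rad[a] + rad[b]:
                            if _separate_pair(
                                a, b, t, pos, rad, tl, gen, alive, box, 0.0, grid
                            ) == 0:
                                _move_to(a, pax, pay, paz, pos, grid)
                                _move_to(b, pbx, pby, pbz, pos, grid)
                    else:
                        sep_ok = _separate_pair(
                            a, b, t, pos, rad, tl, gen, alive, box, d_th, grid
                        )
                        if sep_ok == 0 and skip_ab and d < rad[a] + rad[b]:
                            # unresolved hard-core overlap: undo the move,
                            # treating the collision as not yet resolved
                            _move_to(a, pax, pay, paz, pos, grid)
                            _move_to(b, pbx, pby, pbz, pos, grid)

        hn, seq = _schedule_next(
            a, t, pos, rad, acoef, tl, gen, alive, refresh_ns, r_max, a_max,
            ht, hseq, hk, ha, hb, hga, hgb, hn, seq, grid, box, sp, pair_dth, backoff,
        )
        hn, seq = _schedule_next(
            b, t, pos, rad, acoef, tl, gen, alive, refresh_ns, r_max, a_max,
            ht, hseq, hk, ha, hb, hga, hgb, hn, seq, grid, box, sp, pair_dth, backoff,
        )

    return n_rec, stats


@njit(cache=True)
def seed_rng(seed):
    """Seed the kernel's RNG stream (used by wrappers and tests)."""
    np.random.seed(seed)
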