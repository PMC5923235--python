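"""Numba core of the 2D diffusion--dimerisation simulator.

The elementary dynamics are: per-axis Gaussian displacements with
sd = sqrt(2*D*dT) on a periodic square box, Bernoulli(p) dimerisation
trials for every monomer--monomer pair at contact (separation <= the
collision diameter) on every elementary step of overlap, and first-order
dimer dissociation with per-step probability 1 - exp(-k_off*dT).

To make second-scale trajectories affordable at sub-microsecond elementary
steps, the kernel merges elementary steps adaptively: when the smallest
pair gap is g, up to k elementary steps are taken as one Gaussian jump with
variance 2*D*k*dT, with k chosen so that no pair can plausibly cover its
gap within the jump (safety factor `n_sigma` on the relative-displacement
sd).  Gaussian increments compose exactly for free diffusion, so this is
exact away from contact; whenever any pair is near contact, or any
reaction fired, the kernel falls back to k = 1, so encounter and
dissociation statistics are always resolved at the elementary step.

Pair search uses a linked-cell grid (cell size >= collision diameter,
minimum-image convention); boxes smaller than four collision diameters
fall back to an all-pairs scan.
"""

import numpy as np
from numba import njit

__all__ = ["run_core"]


@njit(cache=True)
def _scan(x, y, typ, n, L, d_coll, G, cell, head, nxt, used_cells, n_used_prev,
          p_i, p_j, p_d2):
    """Build the cell grid, return (n_pairs, n_used, gmin).

    Fills p_i/p_j/p_d2 with monomer-monomer pairs at contact
    (d2 <= d_coll**2).  gmin is a lower bound on the minimum
    monomer-monomer separation (exact if attained by a candidate pair,
    otherwise the cell size).  Only monomer pairs can react, so only they
    constrain the temporal coarse-graining; dissociation products are
    handled by forcing elementary resolution after every reaction event.
    """
    dc2 = d_coll * d_coll
    n_pairs = 0
    cap = p_i.shape[0]
    if G < 4:
        # all-pairs fallback for tiny boxes
        d2min = L * L
        for i in range(n):
            for j in range(i + 1, n):
                if typ[i] != 0 or typ[j] != 0:
                    continue
                dx = x[i] - x[j]
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                dy = y[i] - y[j]
                if dy > 0.5 * L:
                    dy -= L
                elif dy < -0.5 * L:
                    dy += L
                d2 = dx * dx + dy * dy
                if d2 < d2min:
                    d2min = d2
                if d2 <= dc2 and n_pairs < cap:
                    p_i[n_pairs] = i
                    p_j[n_pairs] = j
                    p_d2[n_pairs] = d2
                    n_pairs += 1
        return n_pairs, 0, np.sqrt(d2min)

    # reset cells touched by the previous scan
    for u in range(n_used_prev):
        head[used_cells[u]] = -1
    # insert monomers only (dimers take no part in pair logic)
    n_used = 0
    for i in range(n):
        if typ[i] != 0:
            continue
        cx = int(x[i] / cell)
        if cx >= G:
            cx = G - 1
        cy = int(y[i] / cell)
        if cy >= G:
            cy = G - 1
        c = cy * G + cx
        if head[c] == -1:
            used_cells[n_used] = c
            n_used += 1
        nxt[i] = head[c]
        head[c] = i
    d2min = cell * cell
    # half stencil: same cell + E, NE, N, NW neighbours (periodic wrap)
    for u in range(n_used):
        c = used_cells[u]
        cy = c // G
        cx = c - cy * G
        i = head[c]
        while i != -1:
            if typ[i] != 0:
                i = nxt[i]
                continue
            j = nxt[i]
            while j != -1:
                if typ[j] != 0:
                    j = nxt[j]
                    continue
                dx = x[i] - x[j]
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                dy = y[i] - y[j]
                if dy > 0.5 * L:
                    dy -= L
                elif dy < -0.5 * L:
                    dy += L
                d2 = dx * dx + dy * dy
                if d2 < d2min:
                    d2min = d2
                if d2 <= dc2 and n_pairs < cap:
                    p_i[n_pairs] = i
                    p_j[n_pairs] = j
                    p_d2[n_pairs] = d2
                    n_pairs += 1
                j = nxt[j]
            i = nxt[i]
        for s in range(4):
            if s == 0:
                ox, oy = 1, 0
            elif s == 1:
                ox, oy = 1, 1
            elif s == 2:
                ox, oy = 0, 1
            else:
                ox, oy = -1, 1
            ncx = cx + ox
            if ncx == G:
                ncx = 0
            elif ncx == -1:
                ncx = G - 1
            ncy = cy + oy
            if ncy == G:
                ncy = 0
            c2 = ncy * G + ncx
            i = head[c]
            while i != -1:
                if typ[i] != 0:
                    i = nxt[i]
                    continue
                j = head[c2]
                while j != -1:
                    if typ[j] != 0:
                        j = nxt[j]
                        continue
                    dx = x[i] - x[j]
                    if dx > 0.5 * L:
                        dx -= L
                    elif dx < -0.5 * L:
                        dx += L
                    dy = y[i] - y[j]
                    if dy > 0.5 * L:
                        dy -= L
                    elif dy < -0.5 * L:
                        dy += L
                    d2 = dx * dx + dy * dy
                    if d2 < d2min:
                        d2min = d2
                    if d2 <= dc2 and n_pairs < cap:
                        p_i[n_pairs] = i
                        p_j[n_pairs] = j
                        p_d2[n_pairs] = d2
                        n_pairs += 1
                    j = nxt[j]
                i = nxt[i]
    return n_pairs, n_used, np.sqrt(d2min)


@njit(cache=True)
def run_core(seed, L, d_coll, p_coll, k_off, D_mon, D_dim, dt, n_steps,
             rec_every, k_max, n_sigma, pos_tol,
             x, y, typ, pa, pb, n0,
             rec_mono, rec_dim, rec_events, rec_trials,
             ev_time, ev_pa, ev_pb,
             snap_every, snap_x, snap_y, snap_typ, snap_pa, snap_pb, snap_n):
    """Run n_steps elementary steps in place; returns (n_final, n_events, n_ev_logged).

    Recording arrays are indexed by step // rec_every (index 0 = initial
    state).  If snap_every > 0, full particle snapshots are written every
    snap_every elementary steps.  ev_* log dimer-formation events
    (time, protomer ids) up to their capacity.
    """
    np.random.seed(seed)
    n = n0
    n_cap = x.shape[0]
    G = int(L / d_coll)
    if G > 48:
        G = 48
    if G < 4:
        G = 1
        cell = L
    else:
        cell = L / G
    head = np.full(G * G, -1, np.int64)
    nxt = np.empty(n_cap, np.int64)
    used_cells = np.empty(n_cap, np.int64)
    pair_cap = 4 * n_cap + 16
    p_i = np.empty(pair_cap, np.int64)
    p_j = np.empty(pair_cap, np.int64)
    p_d2 = np.empty(pair_cap, np.float64)
    order = np.empty(pair_cap, np.int64)
    dead = np.zeros(n_cap, np.uint8)
    # dimers do not react, so their Brownian updates are deferred (Gaussian
    # increments compose exactly); last_move[i] is the step of the last
    # actual displacement of particle i
    last_move = np.zeros(n_cap, np.int64)

    n_events = 0
    n_trials = 0
    ev_n = 0
    ev_cap = ev_time.shape[0]

    n_dim = 0
    for i in range(n):
        if typ[i] == 1:
            n_dim += 1

    n_used = 0
    n_pairs, n_used, gmin = _scan(x, y, typ, n, L, d_coll, G, cell, head, nxt,
                                  used_cells, 0, p_i, p_j, p_d2)
    n_trials += n_pairs

    rec_mono[0] = n - n_dim
    rec_dim[0] = n_dim
    rec_events[0] = 0
    rec_trials[0] = 0
    snap_i = 0
    if snap_every > 0:
        for i in range(n):
            snap_x[0, i] = x[i]
            snap_y[0, i] = y[i]
            snap_typ[0, i] = typ[i]
            snap_pa[0, i] = pa[i]
            snap_pb[0, i] = pb[i]
        snap_n[0] = n
        snap_i = 1

    sig1 = 2.0 * np.sqrt(max(D_mon, D_dim) * dt)  # per-axis relative-displacement sd, 1 step
    n_mono_gap = 64  # refine the monomer gap exactly when few monomers
    step = 0
    while step < n_steps:
        # --- choose the temporal coarse-graining factor k ---
        if n_pairs == 0 and gmin >= cell and n - n_dim <= n_mono_gap and G > 1:
            # cell-size bound attained: compute the true monomer-monomer
            # minimum-image gap directly (cheap, few monomers)
            d2m = L * L
            for i in range(n):
                if typ[i] != 0:
                    continue
                for j in range(i + 1, n):
                    if typ[j] != 0:
                        continue
                    dx = x[i] - x[j]
                    if dx > 0.5 * L:
                        dx -= L
                    elif dx < -0.5 * L:
                        dx += L
                    dy = y[i] - y[j]
                    if dy > 0.5 * L:
                        dy -= L
                    elif dy < -0.5 * L:
                        dy += L
                    d2 = dx * dx + dy * dy
                    if d2 < d2m:
                        d2m = d2
            gmin = np.sqrt(d2m)
        gap = gmin - d_coll
        if gap <= 0.0:
            k = 1
        else:
            kf = gap / (n_sigma * sig1)
            k = int(kf * kf)
            if k < 1:
                k = 1
            elif k > k_max:
                k = k_max
            if k_off > 0.0 and k > 1 and n_dim > 0:
                # keep expected dissociations per jump small so products
                # appear close to their true event times
                k_ev = int(0.2 / (n_dim * k_off * dt))
                if k_ev < 1:
                    k_ev = 1
                if k > k_ev:
                    k = k_ev
        r = rec_every - step % rec_every
        if k > r:
            k = r
        if snap_every > 0:
            r = snap_every - step % snap_every
            if k > r:
                k = r
        if k > n_steps - step:
            k = n_steps - step

        # --- displace monomers (dimers deferred) ---
        sig_m = np.sqrt(2.0 * D_mon * k * dt)
        for i in range(n):
            if typ[i] == 0:
                x[i] = (x[i] + np.random.normal() * sig_m) % L
                y[i] = (y[i] + np.random.normal() * sig_m) % L
                last_move[i] = last_move[i] + k  # == step + k for monomers
        step += k
        t_now = step * dt

        # --- pair scan ---
        n_pairs, n_used, gmin = _scan(x, y, typ, n, L, d_coll, G, cell, head,
                                      nxt, used_cells, n_used, p_i, p_j, p_d2)
        n_trials += n_pairs
        any_event = False

        # --- dissociation of pre-existing dimers ---
        if k_off > 0.0 and n_dim > 0:
            q = 1.0 - np.exp(-k_off * k * dt)
            n_before = n
            for i in range(n_before):
                if typ[i] == 1 and np.random.random() < q:
                    lag = step - last_move[i]
                    if lag > 0:
                        s = np.sqrt(2.0 * D_dim * lag * dt)
                        x[i] = (x[i] + np.random.normal() * s) % L
                        y[i] = (y[i] + np.random.normal() * s) % L
                    theta = np.random.random() * 2.0 * np.pi
                    h = 0.5 * d_coll * (1.0 + pos_tol)
                    cx_ = x[i]
                    cy_ = y[i]
                    dxu = h * np.cos(theta)
                    dyu = h * np.sin(theta)
                    x[i] = (cx_ + dxu) % L
                    y[i] = (cy_ + dyu) % L
                    typ[i] = 0
                    last_move[i] = step
                    b = pb[i]
                    pb[i] = -1
                    x[n] = (cx_ - dxu) % L
                    y[n] = (cy_ - dyu) % L
                    typ[n] = 0
                    pa[n] = b
                    pb[n] = -1
                    dead[n] = 0
                    last_move[n] = step
                    n += 1
                    n_dim -= 1
                    any_event = True

        # --- dimerisation trials, closest pair first ---
        if n_pairs > 0 and p_coll > 0.0:
            for m in range(n_pairs):
                order[m] = m
            # insertion sort by d2
            for m in range(1, n_pairs):
                om = order[m]
                dm = p_d2[om]
                w = m - 1
                while w >= 0 and p_d2[order[w]] > dm:
                    order[w + 1] = order[w]
                    w -= 1
                order[w + 1] = om
            for m in range(n_pairs):
                om = order[m]
                i = p_i[om]
                j = p_j[om]
                if typ[i] != 0 or typ[j] != 0 or dead[i] == 1 or dead[j] == 1:
                    continue
                if np.random.random() < p_coll:
                    # place the dimer at the minimum-image midpoint
                    dx = x[j] - x[i]
                    if dx > 0.5 * L:
                        dx -= L
                    elif dx < -0.5 * L:
                        dx += L
                    dy = y[j] - y[i]
                    if dy > 0.5 * L:
                        dy -= L
                    elif dy < -0.5 * L:
                        dy += L
                    x[i] = (x[i] + 0.5 * dx) % L
                    y[i] = (y[i] + 0.5 * dy) % L
                    typ[i] = 1
                    last_move[i] = step
                    pb[i] = pa[j]
                    dead[j] = 1
                    n_events += 1
                    n_dim += 1
                    any_event = True
                    if ev_n < ev_cap:
                        ev_time[ev_n] = t_now
                        ev_pa[ev_n] = pa[i]
                        ev_pb[ev_n] = pb[i]
                        ev_n += 1

        # --- compact dead slots ---
        if any_event:
            i = 0
            while i < n:
                if dead[i] == 1:
                    n -= 1
                    if i != n:
                        x[i] = x[n]
                        y[i] = y[n]
                        typ[i] = typ[n]
                        pa[i] = pa[n]
                        pb[i] = pb[n]
                        last_move[i] = last_move[n]
                        dead[i] = dead[n]
                        dead[n] = 0
                    else:
                        dead[i] = 0
                else:
                    i += 1
            gmin = 0.0  # force elementary resolution after any reaction

        # --- record ---
        if step % rec_every == 0:
            ridx = step // rec_every
            rec_mono[ridx] = n - n_dim
            rec_dim[ridx] = n_dim
            rec_events[ridx] = n_events
            rec_trials[ridx] = n_trials
        if snap_every > 0 and step % snap_every == 0:
            for i in range(n):
                lag = step - last_move[i]
                if lag > 0:  # sync deferred dimer positions
                    s = np.sqrt(2.0 * D_dim * lag * dt)
                    x[i] = (x[i] + np.random.normal() * s) % L
                    y[i] = (y[i] + np.random.normal() * s) % L
                    last_move[i] = step
                snap_x[snap_i, i] = x[i]
                snap_y[snap_i, i] = y[i]
                snap_typ[snap_i, i] = typ[i]
                snap_pa[snap_i, i] = pa[i]
                snap_pb[snap_i, i] = pb[i]
            snap_n[snap_i] = n
            snap_i += 1

    # sync any remaining deferred dimer positions to the final time
    for i in range(n):
        lag = n_steps - last_move[i]
        if lag > 0:
            s = np.sqrt(2.0 * D_dim * lag * dt)
            x[i] = (x[i] + np.random.normal() * s) % L
            y[i] = (y[i] + np.random.normal() * s) % L
            last_move[i] = n_steps
    return n, n_events, ev_n
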