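"""Numba event loop for the discrete-dynamics engine.

Free flight between events, analytic crossing-time prediction, collision
resolution by the conservation laws, Poisson-scheduled Andersen kicks.
The event queue is a binary heap with lazy invalidation: every scheduled
event carries the collision counters of its two beads and is discarded on
pop if either counter has advanced.

All arrays are packed by :meth:`dmdrex.potentials.InteractionModel.packed`;
``+inf`` energy levels arrive encoded as 1e30.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1e30
GRAZE_EPS = 1e-12

# event-kind codes shared with engine.py
K_CROSS_OUT = 1
K_CROSS_IN = 2
K_REFLECT_OUT = 3
K_REFLECT_IN = 4
K_KICK = 5

ERR_OK = 0
ERR_HEAP_FULL = 1


@njit(cache=True, inline="always")
def _predict(p, pos, vel, pi, pj, offsets, nthr, thr, shells):
    """Earliest boundary crossing for pair p measured from now.

    Returns (dt, direction); direction 0 = no event, +1 outward crossing,
    -1 inward crossing.  Grazing inward approaches (discriminant < 1e-12)
    count as no crossing.
    """
    i = pi[p]
    j = pj[p]
    rx = pos[i, 0] - pos[j, 0]
    ry = pos[i, 1] - pos[j, 1]
    rz = pos[i, 2] - pos[j, 2]
    vx = vel[i, 0] - vel[j, 0]
    vy = vel[i, 1] - vel[j, 1]
    vz = vel[i, 2] - vel[j, 2]
    a = vx * vx + vy * vy + vz * vz
    if a <= 0.0:
        return np.inf, 0
    b = rx * vx + ry * vy + rz * vz
    c = rx * rx + ry * ry + rz * rz
    s = shells[p]
    K = nthr[p]
    off = offsets[p]
    best_t = np.inf
    best_dir = 0
    if s < K:  # outer boundary exists
        d = thr[off + s]
        q = c - d * d
        if q > 0.0:
            # rounding put us marginally outside the shell we believe we
            # are in; treat as sitting on the boundary
            q = 0.0
        disc = b * b - a * q
        t_out = (-b + np.sqrt(disc)) / a
        if t_out >= 0.0:
            best_t = t_out
            best_dir = 1
    if s > 0 and b < 0.0:  # inner boundary, approaching
        d = thr[off + s - 1]
        q = c - d * d
        if q < 0.0:
            q = 0.0
        disc = b * b - a * q
        if disc > GRAZE_EPS:
            t_in = (-b - np.sqrt(disc)) / a
            if 0.0 <= t_in < best_t:
                best_t = t_in
                best_dir = -1
    return best_t, best_dir


@njit(cache=True, inline="always")
def _heap_push(h_t, h_p, h_dir, h_ci, h_cj, size, t, p, d, ci, cj):
    k = size
    h_t[k] = t
    h_p[k] = p
    h_dir[k] = d
    h_ci[k] = ci
    h_cj[k] = cj
    while k > 0:
        parent = (k - 1) // 2
        if h_t[parent] <= h_t[k]:
            break
        h_t[parent], h_t[k] = h_t[k], h_t[parent]
        h_p[parent], h_p[k] = h_p[k], h_p[parent]
        h_dir[parent], h_dir[k] = h_dir[k], h_dir[parent]
        h_ci[parent], h_ci[k] = h_ci[k], h_ci[parent]
        h_cj[parent], h_cj[k] = h_cj[k], h_cj[parent]
        k = parent
    return size + 1


@njit(cache=True, inline="always")
def _heap_pop(h_t, h_p, h_dir, h_ci, h_cj, size):
    last = size - 1
    h_t[0], h_t[last] = h_t[last], h_t[0]
    h_p[0], h_p[last] = h_p[last], h_p[0]
    h_dir[0], h_dir[last] = h_dir[last], h_dir[0]
    h_ci[0], h_ci[last] = h_ci[last], h_ci[0]
    h_cj[0], h_cj[last] = h_cj[last], h_cj[0]
    size = last
    k = 0
    while True:
        left = 2 * k + 1
        if left >= size:
            break
        child = left
        right = left + 1
        if right < size and h_t[right] < h_t[left]:
            child = right
        if h_t[k] <= h_t[child]:
            break
        h_t[k], h_t[child] = h_t[child], h_t[k]
        h_p[k], h_p[child] = h_p[child], h_p[k]
        h_dir[k], h_dir[child] = h_dir[child], h_dir[k]
        h_ci[k], h_ci[child] = h_ci[child], h_ci[k]
        h_cj[k], h_cj[child] = h_cj[child], h_cj[k]
        k = child
    return size


@njit(cache=True)
def _heap_compact(h_t, h_p, h_dir, h_ci, h_cj, size, cnt, pi, pj):
    """Drop stale entries and re-heapify; returns the new size."""
    m = 0
    for k in range(size):
        p = h_p[k]
        if h_ci[k] == cnt[pi[p]] and h_cj[k] == cnt[pj[p]]:
            h_t[m] = h_t[k]
            h_p[m] = h_p[k]
            h_dir[m] = h_dir[k]
            h_ci[m] = h_ci[k]
            h_cj[m] = h_cj[k]
            m += 1
    # bottom-up heapify
    for start in range(m // 2 - 1, -1, -1):
        k = start
        while True:
            left = 2 * k + 1
            if left >= m:
                break
            child = left
            right = left + 1
            if right < m and h_t[right] < h_t[left]:
                child = right
            if h_t[k] <= h_t[child]:
                break
            h_t[k], h_t[child] = h_t[child], h_t[k]
            h_p[k], h_p[child] = h_p[child], h_p[k]
            h_dir[k], h_dir[child] = h_dir[child], h_dir[k]
            h_ci[k], h_ci[child] = h_ci[child], h_ci[k]
            h_cj[k], h_cj[child] = h_cj[child], h_cj[k]
            k = child
    return m


@njit(cache=True)
def _rebuild(
    pos, vel, pi, pj, offsets, nthr, thr, shells,
    t, win_end, cnt, h_t, h_p, h_dir, h_ci, h_cj,
    act_pairs, act_cnt, window,
):
    """Rebuild the active-pair lists and the event heap from scratch.

    A pair is *dormant* when it sits outside its outermost threshold by
    more than the largest distance the pair can close before the next
    rebuild (2 × speed cap × window).  Dormant pairs are skipped entirely;
    the speed cap is enforced by the caller, which triggers an early
    rebuild whenever any bead exceeds it.  Returns (heap size, speed cap²).
    """
    n = pos.shape[0]
    P = pi.shape[0]
    vmax2 = 0.0
    for b in range(n):
        sp2 = vel[b, 0] ** 2 + vel[b, 1] ** 2 + vel[b, 2] ** 2
        if sp2 > vmax2:
            vmax2 = sp2
    vcap = 1.4 * np.sqrt(vmax2)
    margin = 2.0 * vcap * window
    for b in range(n):
        act_cnt[b] = 0
    size = 0
    for p in range(P):
        i = pi[p]
        j = pj[p]
        s = shells[p]
        K = nthr[p]
        if s == K:
            reach = thr[offsets[p] + K - 1] + margin
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            if rx * rx + ry * ry + rz * rz > reach * reach:
                continue
        act_pairs[i, act_cnt[i]] = p
        act_cnt[i] += 1
        act_pairs[j, act_cnt[j]] = p
        act_cnt[j] += 1
        dt, d = _predict(p, pos, vel, pi, pj, offsets, nthr, thr, shells)
        if d != 0 and t + dt <= win_end:
            size = _heap_push(
                h_t, h_p, h_dir, h_ci, h_cj, size, t + dt, p, d,
                cnt[i], cnt[j],
            )
    return size, vcap * vcap


@njit(cache=True)
def run_kernel(
    pos,
    vel,
    mass,
    pi,
    pj,
    bead_pairs,
    offsets,
    nthr,
    confin,
    thr,
    en,
    shells,
    pe0,
    t_end,
    frame_interval,
    temperature,
    kick_rate,
    seed,
    ev_cap,
    window,
):
    """Advance the system event-by-event to ``t_end``.

    Only events due within the current look-ahead ``window`` are kept on
    the heap; at every window boundary all pair predictions are rebuilt
    from scratch (which also clears stale entries).  Returns frame arrays,
    the processed-event count, an error code, the optional event log and
    the final (pe, ke).  ``pos``, ``vel`` and ``shells`` are updated in
    place.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    P = pi.shape[0]
    cnt = np.zeros(n, dtype=np.int64)

    cap = 16 * P
    if cap < 8192:
        cap = 8192
    h_t = np.empty(cap, dtype=np.float64)
    h_p = np.empty(cap, dtype=np.int64)
    h_dir = np.empty(cap, dtype=np.int8)
    h_ci = np.empty(cap, dtype=np.int64)
    h_cj = np.empty(cap, dtype=np.int64)
    size = 0

    t = 0.0
    pe = pe0
    ke = 0.0
    for k in range(n):
        ke += 0.5 * mass[k] * (
            vel[k, 0] ** 2 + vel[k, 1] ** 2 + vel[k, 2] ** 2
        )

    if window <= 0.0:
        window = t_end
    win_end = window if window < t_end else t_end

    nframes = int(np.floor(t_end / frame_interval + 1e-9)) + 1
    f_t = np.empty(nframes, dtype=np.float64)
    f_pos = np.empty((nframes, n, 3), dtype=np.float64)
    f_pe = np.empty(nframes, dtype=np.float64)
    f_ke = np.empty(nframes, dtype=np.float64)

    ev_t = np.empty(ev_cap, dtype=np.float64)
    ev_kind = np.empty(ev_cap, dtype=np.int8)
    ev_i = np.empty(ev_cap, dtype=np.int64)
    ev_j = np.empty(ev_cap, dtype=np.int64)
    ev_n = 0

    err = ERR_OK
    n_events = 0

    act_pairs = np.empty((n, n - 1), dtype=np.int64)
    act_cnt = np.zeros(n, dtype=np.int64)

    # initial predictions
    size, vcap2 = _rebuild(
        pos, vel, pi, pj, offsets, nthr, thr, shells,
        t, win_end, cnt, h_t, h_p, h_dir, h_ci, h_cj,
        act_pairs, act_cnt, window,
    )

    # frame 0
    f_t[0] = 0.0
    f_pos[0] = pos
    f_pe[0] = pe
    f_ke[0] = ke
    next_frame = 1

    if kick_rate > 0.0:
        next_kick = np.random.exponential(1.0 / (kick_rate * n))
    else:
        next_kick = np.inf

    while err == ERR_OK:
        # discard stale heap tops
        while size > 0:
            p = h_p[0]
            if h_ci[0] == cnt[pi[p]] and h_cj[0] == cnt[pj[p]]:
                break
            size = _heap_pop(h_t, h_p, h_dir, h_ci, h_cj, size)
        t_ev = h_t[0] if size > 0 else np.inf
        t_next = t_ev if t_ev < next_kick else next_kick
        at_boundary = t_next > win_end
        if at_boundary:
            t_next = win_end

        # emit frames that precede the next event
        while next_frame < nframes and next_frame * frame_interval <= t_next:
            ft = next_frame * frame_interval
            if ft > t_end + 1e-9:
                break
            dt = ft - t
            for k in range(n):
                pos[k, 0] += vel[k, 0] * dt
                pos[k, 1] += vel[k, 1] * dt
                pos[k, 2] += vel[k, 2] * dt
            t = ft
            f_t[next_frame] = ft
            f_pos[next_frame] = pos
            f_pe[next_frame] = pe
            f_ke[next_frame] = ke
            next_frame += 1

        if at_boundary:
            # window boundary: advance, rebuild every prediction
            dt = win_end - t
            for k in range(n):
                pos[k, 0] += vel[k, 0] * dt
                pos[k, 1] += vel[k, 1] * dt
                pos[k, 2] += vel[k, 2] * dt
            t = win_end
            if win_end >= t_end:
                break
            win_end = t + window
            if win_end > t_end:
                win_end = t_end
            size, vcap2 = _rebuild(
                pos, vel, pi, pj, offsets, nthr, thr, shells,
                t, win_end, cnt, h_t, h_p, h_dir, h_ci, h_cj,
                act_pairs, act_cnt, window,
            )
            continue

        # advance everyone to the event instant
        dt = t_next - t
        for k in range(n):
            pos[k, 0] += vel[k, 0] * dt
            pos[k, 1] += vel[k, 1] * dt
            pos[k, 2] += vel[k, 2] * dt
        t = t_next

        if next_kick <= t_ev:
            # Andersen kick: full velocity redraw for one random bead
            b = int(np.random.random() * n)
            if b >= n:
                b = n - 1
            sig = np.sqrt(temperature / mass[b])
            old = (
                vel[b, 0] ** 2 + vel[b, 1] ** 2 + vel[b, 2] ** 2
            )
            vel[b, 0] = sig * np.random.normal()
            vel[b, 1] = sig * np.random.normal()
            vel[b, 2] = sig * np.random.normal()
            new = (
                vel[b, 0] ** 2 + vel[b, 1] ** 2 + vel[b, 2] ** 2
            )
            ke += 0.5 * mass[b] * (new - old)
            cnt[b] += 1
            if ev_n < ev_cap:
                ev_t[ev_n] = t
                ev_kind[ev_n] = K_KICK
                ev_i[ev_n] = b
                ev_j[ev_n] = -1
                ev_n += 1
            next_kick = t + np.random.exponential(1.0 / (kick_rate * n))
            if new > vcap2:
                # kicked bead outruns the screening bound: force a rebuild
                win_end = t
                continue
            # reschedule the kicked bead's pairs
            for kk in range(act_cnt[b]):
                q = act_pairs[b, kk]
                dtq, dq = _predict(q, pos, vel, pi, pj, offsets, nthr, thr, shells)
                if dq != 0 and t + dtq <= win_end:
                    if size >= cap:
                        size = _heap_compact(
                            h_t, h_p, h_dir, h_ci, h_cj, size, cnt, pi, pj
                        )
                        if size >= cap:
                            err = ERR_HEAP_FULL
                            break
                    size = _heap_push(
                        h_t, h_p, h_dir, h_ci, h_cj, size, t + dtq, q, dq,
                        cnt[pi[q]], cnt[pj[q]],
                    )
            continue

        # pair event
        p = h_p[0]
        direction = h_dir[0]
        size = _heap_pop(h_t, h_p, h_dir, h_ci, h_cj, size)
        i = pi[p]
        j = pj[p]
        s = shells[p]
        off = offsets[p]
        enoff = off + p
        kb = s if direction == 1 else s - 1

        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        rnorm = np.sqrt(rx * rx + ry * ry + rz * rz)
        ux = rx / rnorm
        uy = ry / rnorm
        uz = rz / rnorm
        vrx = vel[i, 0] - vel[j, 0]
        vry = vel[i, 1] - vel[j, 1]
        vrz = vel[i, 2] - vel[j, 2]
        vr = vrx * ux + vry * uy + vrz * uz

        mi = mass[i]
        mj = mass[j]
        mu = mi * mj / (mi + mj)

        s_new = s + direction
        u_new = en[enoff + s_new]
        u_cur = en[enoff + s]
        crossed = False
        if u_new >= BIG:
            vr_new = -vr  # hard core / confining bond wall: reflect
        else:
            dU = u_new - u_cur
            if dU > 0.0 and 0.5 * mu * vr * vr <= dU:
                vr_new = -vr  # insufficient radial energy: bounce off the step
            else:
                arg = vr * vr - 2.0 * dU / mu
                root = np.sqrt(arg)
                vr_new = root if vr >= 0.0 else -root
                pe += dU
                shells[p] = s_new
                crossed = True

        dv = vr_new - vr
        vel[i, 0] += (mu / mi) * dv * ux
        vel[i, 1] += (mu / mi) * dv * uy
        vel[i, 2] += (mu / mi) * dv * uz
        vel[j, 0] -= (mu / mj) * dv * ux
        vel[j, 1] -= (mu / mj) * dv * uy
        vel[j, 2] -= (mu / mj) * dv * uz
        ke += 0.5 * mu * (vr_new * vr_new - vr * vr)
        cnt[i] += 1
        cnt[j] += 1
        n_events += 1

        if ev_n < ev_cap:
            ev_t[ev_n] = t
            if crossed:
                ev_kind[ev_n] = K_CROSS_OUT if direction == 1 else K_CROSS_IN
            else:
                ev_kind[ev_n] = K_REFLECT_OUT if direction == 1 else K_REFLECT_IN
            ev_i[ev_n] = i
            ev_j[ev_n] = j
            ev_n += 1

        spi = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
        spj = vel[j, 0] ** 2 + vel[j, 1] ** 2 + vel[j, 2] ** 2
        if spi > vcap2 or spj > vcap2:
            # a collision partner outruns the screening bound
            win_end = t
            continue

        # reschedule every active pair touching i or j
        for kk in range(act_cnt[i]):
            q = act_pairs[i, kk]
            dtq, dq = _predict(q, pos, vel, pi, pj, offsets, nthr, thr, shells)
            if dq != 0 and t + dtq <= win_end:
                if size >= cap:
                    size = _heap_compact(
                        h_t, h_p, h_dir, h_ci, h_cj, size, cnt, pi, pj
                    )
                    if size >= cap:
                        err = ERR_HEAP_FULL
                        break
                size = _heap_push(
                    h_t, h_p, h_dir, h_ci, h_cj, size, t + dtq, q, dq,
                    cnt[pi[q]], cnt[pj[q]],
                )
        if err != ERR_OK:
            break
        for kk in range(act_cnt[j]):
            q = act_pairs[j, kk]
            if pi[q] == i or pj[q] == i:
                continue  # already rescheduled from i's list
            dtq, dq = _predict(q, pos, vel, pi, pj, offsets, nthr, thr, shells)
            if dq != 0 and t + dtq <= win_end:
                if size >= cap:
                    size = _heap_compact(
                        h_t, h_p, h_dir, h_ci, h_cj, size, cnt, pi, pj
                    )
                    if size >= cap:
                        err = ERR_HEAP_FULL
                        break
                size = _heap_push(
                    h_t, h_p, h_dir, h_ci, h_cj, size, t + dtq, q, dq,
                    cnt[pi[q]], cnt[pj[q]],
                )

    # emit any frames left between the last event and the horizon
    while next_frame < nframes:
        ft = next_frame * frame_interval
        if ft > t_end + 1e-9:
            break
        dt = ft - t
        for k in range(n):
            pos[k, 0] += vel[k, 0] * dt
            pos[k, 1] += vel[k, 1] * dt
            pos[k, 2] += vel[k, 2] * dt
        t = ft
        f_t[next_frame] = ft
        f_pos[next_frame] = pos
        f_pe[next_frame] = pe
        f_ke[next_frame] = ke
        next_frame += 1

    return (
        f_t[:next_frame],
        f_pos[:next_frame],
        f_pe[:next_frame],
        f_ke[:next_frame],
        n_events,
        err,
        ev_t[:ev_n],
        ev_kind[:ev_n],
        ev_i[:ev_n],
        ev_j[:ev_n],
        pe,
        ke,
    )
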