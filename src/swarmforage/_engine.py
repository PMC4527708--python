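"""Numba kernel advancing the foraging world.

One jitted routine implements the whole control step pipeline — rule
scan, item actions, motion with obstacle avoidance, item sliding and
source replenishment — and is shared by :func:`swarmforage.sim.step`
(``n_steps=1``) and :func:`swarmforage.sim.run_episode` (batched), so
stepping a world one tick at a time or in a single call produces
bitwise-identical trajectories and event logs.

All randomness is drawn from a 64-bit xorshift* stream whose state
lives in the world (mirrored bit-exactly by
:class:`swarmforage.world.XorShift64Star`).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# motion / interaction constants (see docs/methods.md for rationale)
PICKUP_RADIUS = 0.15
BODY_RADIUS = 0.085
AVOID_RADIUS = 0.35  # robot-robot repulsion range (center-to-center)
WALL_MARGIN = 0.2  # wall repulsion range beyond the body radius
AVOID_GAIN = 2.0
AVOID_ROT = 0.4  # rad; repulsion rotated so blocked robots slide sideways
MAX_TURN_RATE = 1.5  # rad/s
RW_DWELL_MIN = 2.0
RW_DWELL_MAX = 10.0
#: items are physical cylinders; their centers keep this distance from walls
ITEM_WALL_MARGIN = 0.1

_COS_ROT = math.cos(AVOID_ROT)
_SIN_ROT = math.sin(AVOID_ROT)

STATUS_OK = 0
STATUS_NAN = 1
STATUS_CAPACITY = 2

EV_PICKUP, EV_DROP, EV_SLIDE_STOP, EV_DELIVER = 0, 1, 2, 3


@njit(cache=True)
def _rngf(rng):
    x = rng[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    rng[0] = x
    return np.float64((x * np.uint64(2685821657736338717)) >> np.uint64(11)) * (
        1.0 / 9007199254740992.0
    )


@njit(cache=True)
def _floor_insert(i, fnext, fprev, meta):
    head = meta[2]
    fprev[i] = -1
    fnext[i] = head
    if head >= 0:
        fprev[head] = i
    meta[2] = i


@njit(cache=True)
def _floor_remove(i, fnext, fprev, meta):
    p = fprev[i]
    nx = fnext[i]
    if p >= 0:
        fnext[p] = nx
    else:
        meta[2] = nx
    if nx >= 0:
        fprev[nx] = p
    fnext[i] = -1
    fprev[i] = -1


@njit(cache=True)
def _record(meta, record_events, ev_t, ev_item, ev_code, ev_robot, ev_x, ev_y, t, item, code, robot, x, y):
    if not record_events:
        return
    n = meta[5]
    if n < ev_t.shape[0]:
        ev_t[n] = t
        ev_item[n] = item
        ev_code[n] = code
        ev_robot[n] = robot
        ev_x[n] = x
        ev_y[n] = y
        meta[5] = n + 1
    else:
        meta[6] = 1


@njit(cache=True)
def advance(
    n_steps,
    dt,
    start_step,
    # arena
    L,
    W,
    e0,
    e1,
    e2,
    sloped,
    v_flat,
    v_up,
    v_down,
    v_slide,
    rw_dwell_min,
    rw_dwell_max,
    # robots
    rx,
    ry,
    rhead,
    rbeh,
    rcarry,
    rstate,
    rw_head,
    rw_timer,
    # compiled rules
    rule_lo,
    rule_hi,
    pre,
    bmask,
    act_off,
    act_type,
    act_arg,
    act_prob,
    # items
    ix,
    iy,
    istat,
    icarr,
    fnext,
    fprev,
    slide_ids,
    # scalars
    meta,
    tarr,
    rng,
    # recording
    record_events,
    ev_t,
    ev_item,
    ev_code,
    ev_robot,
    ev_x,
    ev_y,
    record_snaps,
    stride,
    snap_t,
    snap_x,
    snap_y,
    snap_head,
    snap_beh,
    snap_carry,
    snap_cache,
):
    n_robots = rx.shape[0]
    cap = ix.shape[0]
    pv = np.empty(8, dtype=np.int8)
    queue = np.empty(8, dtype=np.int8)
    two_r2 = (2.0 * BODY_RADIUS) * (2.0 * BODY_RADIUS)
    pick_r2 = PICKUP_RADIUS * PICKUP_RADIUS
    wall_lim = BODY_RADIUS + WALL_MARGIN

    for step_i in range(n_steps):
        t = tarr[0]
        for r in range(n_robots):
            x = rx[r]
            y = ry[r]
            # --- percepts -------------------------------------------------
            if x < e0:
                z = 0
            elif x < e1:
                z = 1
            elif x < e2:
                z = 2
            else:
                z = 3
            for v in range(4):
                pv[v] = 1 if v == z else 0
            pv[4] = 1 if rcarry[r] >= 0 else 0
            pv[5] = 1 if rstate[r, 0] > 0 else 0
            pv[6] = 1 if rstate[r, 1] > 0 else 0
            pv[7] = 1 if rstate[r, 2] > 0 else 0

            # --- ordered rule scan ---------------------------------------
            qn = 0
            for ri in range(rule_lo[r], rule_hi[r]):
                if (bmask[ri] >> np.uint8(rbeh[r])) & np.uint8(1) == 0:
                    continue
                ok = True
                for v in range(8):
                    p = pre[ri, v]
                    if p >= 0 and pv[v] != p:
                        ok = False
                        break
                if not ok:
                    continue
                for a in range(act_off[ri], act_off[ri + 1]):
                    pr = act_prob[a]
                    if pr < 1.0 and _rngf(rng) >= pr:
                        continue
                    ty = act_type[a]
                    if ty == 0:
                        rbeh[r] = act_arg[a]
                    elif ty == 3:
                        var = act_arg[a] // 4
                        op = act_arg[a] % 4
                        cur = rstate[r, var]
                        hi = 1 if var == 0 else 3
                        if op == 0:
                            nv = 0
                        elif op == 1:
                            nv = 1
                        elif op == 2:
                            nv = cur + 1 if cur < hi else hi
                        else:
                            nv = cur - 1 if cur > 0 else 0
                        rstate[r, var] = nv
                        pv[5 + var] = 1 if nv > 0 else 0
                    else:
                        if qn < 8:
                            queue[qn] = ty
                            qn += 1

            # --- attempt queued item actions ------------------------------
            for q in range(qn):
                if queue[q] == 1:  # pickup
                    if rcarry[r] >= 0:
                        continue
                    # sliding items move at 1 m/s, far beyond grasping
                    # speed, and are not eligible for pickup
                    best = -1
                    bd = pick_r2
                    j = meta[2]
                    while j >= 0:
                        if istat[j] != 2:
                            dxi = ix[j] - x
                            dyi = iy[j] - y
                            d2 = dxi * dxi + dyi * dyi
                            if d2 < bd:
                                bd = d2
                                best = j
                        j = fnext[j]
                    if best < 0:
                        continue
                    was_source = istat[best] == 0
                    if istat[best] == 3:
                        meta[4] -= 1
                    _floor_remove(best, fnext, fprev, meta)
                    istat[best] = 1
                    icarr[best] = r
                    rcarry[r] = best
                    _record(
                        meta, record_events, ev_t, ev_item, ev_code, ev_robot, ev_x, ev_y,
                        t, best, EV_PICKUP, r, ix[best], iy[best],
                    )
                    if was_source:
                        k = meta[0]
                        if k >= cap:
                            return STATUS_CAPACITY
                        ix[k] = e2 + _rngf(rng) * (L - ITEM_WALL_MARGIN - e2)
                        iy[k] = ITEM_WALL_MARGIN + _rngf(rng) * (W - 2.0 * ITEM_WALL_MARGIN)
                        istat[k] = 0
                        icarr[k] = -1
                        _floor_insert(k, fnext, fprev, meta)
                        meta[0] = k + 1
                else:  # drop
                    it = rcarry[r]
                    if it < 0:
                        continue
                    ix[it] = x
                    iy[it] = y
                    icarr[it] = -1
                    rcarry[r] = -1
                    pv[4] = 0  # spec: carrying percept is fixed per scan,
                    # but queued actions run after the scan, so this only
                    # affects subsequent queued pickups this step
                    if x < e0:
                        istat[it] = 5
                        meta[1] += 1
                        _record(
                            meta, record_events, ev_t, ev_item, ev_code, ev_robot, ev_x, ev_y,
                            t, it, EV_DELIVER, r, x, y,
                        )
                    elif sloped and e1 <= x < e2:
                        istat[it] = 2
                        slide_ids[meta[3]] = it
                        meta[3] += 1
                        _floor_insert(it, fnext, fprev, meta)
                        _record(
                            meta, record_events, ev_t, ev_item, ev_code, ev_robot, ev_x, ev_y,
                            t, it, EV_DROP, r, x, y,
                        )
                    else:
                        istat[it] = 4
                        _floor_insert(it, fnext, fprev, meta)
                        _record(
                            meta, record_events, ev_t, ev_item, ev_code, ev_robot, ev_x, ev_y,
                            t, it, EV_DROP, r, x, y,
                        )

            # --- desired direction from the active behavior ---------------
            b = rbeh[r]
            if b == 0:  # PHOTOTAXIS: light is effectively at +x infinity
                dxd = 1.0
                dyd = 0.0
            elif b == 1:  # ANTI_PHOTOTAXIS
                dxd = -1.0
                dyd = 0.0
            else:  # RANDOM_WALK
                rw_timer[r] -= dt
                if rw_timer[r] <= 0.0:
                    rw_head[r] = 2.0 * math.pi * _rngf(rng)
                    rw_timer[r] = rw_dwell_min + (rw_dwell_max - rw_dwell_min) * _rngf(rng)
                dxd = math.cos(rw_head[r])
                dyd = math.sin(rw_head[r])

            # --- obstacle avoidance (always on) ---------------------------
            ax = 0.0
            ay = 0.0
            for o in range(n_robots):
                if o == r:
                    continue
                ddx = x - rx[o]
                ddy = y - ry[o]
                d2 = ddx * ddx + ddy * ddy
                if d2 < AVOID_RADIUS * AVOID_RADIUS:
                    if d2 > 1e-12:
                        d = math.sqrt(d2)
                        w = (AVOID_RADIUS - d) / AVOID_RADIUS
                        ux = ddx / d
                        uy = ddy / d
                        ax += w * (ux * _COS_ROT - uy * _SIN_ROT)
                        ay += w * (ux * _SIN_ROT + uy * _COS_ROT)
                    else:
                        # coincident centers: deterministic split by id
                        ay += 1.0 if r < o else -1.0
            if x < wall_lim:
                w = (wall_lim - x) / WALL_MARGIN
                ax += w * _COS_ROT
                ay += w * _SIN_ROT
            if x > L - wall_lim:
                w = (x - (L - wall_lim)) / WALL_MARGIN
                ax -= w * _COS_ROT
                ay -= w * _SIN_ROT
            if y < wall_lim:
                w = (wall_lim - y) / WALL_MARGIN
                ax += -w * _SIN_ROT
                ay += w * _COS_ROT
            if y > W - wall_lim:
                w = (y - (W - wall_lim)) / WALL_MARGIN
                ax += w * _SIN_ROT
                ay += -w * _COS_ROT

            tx = dxd + AVOID_GAIN * ax
            ty = dyd + AVOID_GAIN * ay

            # --- rate-limited steering, speed scaled by alignment ---------
            h = rhead[r]
            if tx * tx + ty * ty > 1e-12:
                th = math.atan2(ty, tx)
                dh = th - h
                while dh > math.pi:
                    dh -= 2.0 * math.pi
                while dh < -math.pi:
                    dh += 2.0 * math.pi
                lim = MAX_TURN_RATE * dt
                if dh > lim:
                    dh = lim
                elif dh < -lim:
                    dh = -lim
                h = h + dh
                if h > math.pi:
                    h -= 2.0 * math.pi
                elif h < -math.pi:
                    h += 2.0 * math.pi
                rhead[r] = h
                err = th - h
                while err > math.pi:
                    err -= 2.0 * math.pi
                while err < -math.pi:
                    err += 2.0 * math.pi
                align = math.cos(err)
                if align < 0.0:
                    align = 0.0
            else:
                align = 0.0

            ch = math.cos(h)
            sh = math.sin(h)
            if sloped and z == 2:
                if ch > 1e-9:
                    cap_v = v_up
                elif ch < -1e-9:
                    cap_v = v_down
                else:
                    cap_v = v_flat
            else:
                cap_v = v_flat
            v = cap_v * align

            nx_ = x + v * ch * dt
            ny_ = y + v * sh * dt
            # resolve body contacts by sliding off the neighbor, then
            # re-clip to the walls; revert only if contact persists
            for _ in range(2):
                for o in range(n_robots):
                    if o == r:
                        continue
                    ddx = nx_ - rx[o]
                    ddy = ny_ - ry[o]
                    d2 = ddx * ddx + ddy * ddy
                    if d2 < two_r2:
                        if d2 > 1e-12:
                            d = math.sqrt(d2)
                            push = (2.0 * BODY_RADIUS - d) + 1e-9
                            nx_ += ddx / d * push
                            ny_ += ddy / d * push
                        else:
                            ny_ += (2.0 * BODY_RADIUS) * (1.0 if r < o else -1.0)
                if nx_ < BODY_RADIUS:
                    nx_ = BODY_RADIUS
                elif nx_ > L - BODY_RADIUS:
                    nx_ = L - BODY_RADIUS
                if ny_ < BODY_RADIUS:
                    ny_ = BODY_RADIUS
                elif ny_ > W - BODY_RADIUS:
                    ny_ = W - BODY_RADIUS
            blocked = False
            for o in range(n_robots):
                if o == r:
                    continue
                ddx = nx_ - rx[o]
                ddy = ny_ - ry[o]
                if ddx * ddx + ddy * ddy < two_r2 - 1e-9:
                    blocked = True
                    break
            if not blocked:
                rx[r] = nx_
                ry[r] = ny_
            if not (math.isfinite(rx[r]) and math.isfinite(ry[r]) and math.isfinite(rhead[r])):
                return STATUS_NAN

        # --- item sliding (gravity transport) -----------------------------
        if sloped:
            s = 0
            while s < meta[3]:
                i = slide_ids[s]
                ix[i] -= v_slide * dt
                if ix[i] < e1:
                    u1 = _rngf(rng)
                    u2 = _rngf(rng)
                    # stopped by friction / pile just downhill of the slope foot
                    ix[i] = e1 - 0.05 - 0.15 * u1
                    yy = iy[i] + (u2 - 0.5) * 0.2
                    if yy < ITEM_WALL_MARGIN:
                        yy = ITEM_WALL_MARGIN
                    elif yy > W - ITEM_WALL_MARGIN:
                        yy = W - ITEM_WALL_MARGIN
                    iy[i] = yy
                    istat[i] = 3
                    meta[4] += 1
                    _record(
                        meta, record_events, ev_t, ev_item, ev_code, ev_robot, ev_x, ev_y,
                        t, i, EV_SLIDE_STOP, -1, ix[i], iy[i],
                    )
                    meta[3] -= 1
                    slide_ids[s] = slide_ids[meta[3]]
                else:
                    s += 1

        tarr[0] = t + dt

        if record_snaps and (start_step + step_i + 1) % stride == 0:
            sn = meta[7]
            if sn < snap_t.shape[0]:
                snap_t[sn] = tarr[0]
                for r in range(n_robots):
                    snap_x[sn, r] = rx[r]
                    snap_y[sn, r] = ry[r]
                    snap_head[sn, r] = rhead[r]
                    snap_beh[sn, r] = rbeh[r]
                    snap_carry[sn, r] = rcarry[r]
                snap_cache[sn] = meta[4]
                meta[7] = sn + 1

    return STATUS_OK
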