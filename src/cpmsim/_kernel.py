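"""Inner Monte Carlo sweep, written in scalar style so the same function body
runs either jitted through numba (fast path) or as plain Python (fallback).

The sweep consumes pre-drawn random arrays (target index, kernel offset index,
uniform acceptance draw — one triple per attempt), so trajectories are
bit-identical whether or not numba is available.
"""

from __future__ import annotations

import numpy as np


def _gm_impl(identity, activity, offs, torus_x, torus_y, x, y):
    h, w = identity.shape
    cid = identity[y, x]
    if cid == 0:
        return 0.0
    prod = float(activity[y, x])
    count = 1
    if prod == 0.0:
        zero = True
    else:
        zero = False
    for k in range(offs.shape[0]):
        nx = x + offs[k, 0]
        ny = y + offs[k, 1]
        if torus_x:
            nx %= w
        elif nx < 0 or nx >= w:
            continue
        if torus_y:
            ny %= h
        elif ny < 0 or ny >= h:
            continue
        if identity[ny, nx] == cid:
            av = float(activity[ny, nx])
            if av == 0.0:
                zero = True
            prod *= av
            count += 1
    if zero:
        return 0.0
    return prod ** (1.0 / count)


def _sweep_impl(
    identity,
    activity,
    kind_of,
    volume,
    perimeter,
    target_volume,
    immutable,
    J,
    lam_v,
    tgt_v,
    lam_p,
    tgt_p,
    lam_act,
    max_act,
    offs,
    torus_x,
    torus_y,
    temperature,
    tidx,
    oidx,
    unif,
):
    h, w = identity.shape
    K = offs.shape[0]
    cid_buf = np.empty(K + 2, np.int64)
    dp_buf = np.empty(K + 2, np.int64)
    n_accepted = 0
    for i in range(tidx.shape[0]):
        t = tidx[i]
        ty = t // w
        tx = t - ty * w
        sx = tx + offs[oidx[i], 0]
        sy = ty + offs[oidx[i], 1]
        if torus_x:
            sx %= w
        elif sx < 0 or sx >= w:
            continue
        if torus_y:
            sy %= h
        elif sy < 0 or sy >= h:
            continue
        a = identity[ty, tx]
        b = identity[sy, sx]
        if a == b:
            continue
        ka = kind_of[a]
        kb = kind_of[b]
        if immutable[ka] or immutable[kb]:
            continue

        dH = 0.0
        cid_buf[0] = a
        dp_buf[0] = 0
        cid_buf[1] = b
        dp_buf[1] = 0
        nc = 2
        for k in range(K):
            nx = tx + offs[k, 0]
            ny = ty + offs[k, 1]
            if torus_x:
                nx %= w
            elif nx < 0 or nx >= w:
                continue
            if torus_y:
                ny %= h
            elif ny < 0 or ny >= h:
                continue
            nid = identity[ny, nx]
            kn = kind_of[nid]
            if nid != a:
                dH -= J[ka, kn]
                dp_buf[0] -= 1
            if nid != b:
                dH += J[kb, kn]
                dp_buf[1] += 1
            d = 0
            if nid != b:
                d += 1
            if nid != a:
                d -= 1
            if d != 0:
                found = False
                for j in range(nc):
                    if cid_buf[j] == nid:
                        dp_buf[j] += d
                        found = True
                        break
                if not found:
                    cid_buf[nc] = nid
                    dp_buf[nc] = d
                    nc += 1

        if a != 0 and lam_v[ka] > 0.0:
            tv = target_volume[a]
            if tv < 0.0:
                tv = tgt_v[ka]
            v = float(volume[a])
            dH += lam_v[ka] * ((v - 1.0 - tv) ** 2 - (v - tv) ** 2)
        if b != 0 and lam_v[kb] > 0.0:
            tv = target_volume[b]
            if tv < 0.0:
                tv = tgt_v[kb]
            v = float(volume[b])
            dH += lam_v[kb] * ((v + 1.0 - tv) ** 2 - (v - tv) ** 2)

        for j in range(nc):
            c = cid_buf[j]
            if c == 0 or dp_buf[j] == 0:
                continue
            lp = lam_p[kind_of[c]]
            if lp > 0.0:
                p = float(perimeter[c])
                tp = tgt_p[kind_of[c]]
                dH += lp * ((p + dp_buf[j] - tp) ** 2 - (p - tp) ** 2)

        la = lam_act[kb]
        ma = max_act[kb]
        if la <= 0.0 or ma == 0:
            la = lam_act[ka]
            ma = max_act[ka]
        if la > 0.0 and ma > 0:
            gm_s = _gm_impl(identity, activity, offs, torus_x, torus_y, sx, sy)
            gm_t = _gm_impl(identity, activity, offs, torus_x, torus_y, tx, ty)
            dH += -(la / ma) * (gm_s - gm_t)

        if dH <= 0.0 or unif[i] < np.exp(-dH / temperature):
            volume[a] -= 1
            volume[b] += 1
            for j in range(nc):
                perimeter[cid_buf[j]] += dp_buf[j]
            identity[ty, tx] = b
            if b != 0:
                activity[ty, tx] = max_act[kb]
            else:
                activity[ty, tx] = 0
            n_accepted += 1

    # per-MCS activity decay (floor 0)
    for y in range(h):
        for x in range(w):
            if activity[y, x] > 0:
                activity[y, x] -= 1
    return n_accepted


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _gm_impl = njit(cache=True)(_gm_impl)
    sweep = njit(cache=True)(_sweep_impl)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    sweep = _sweep_impl
    HAVE_NUMBA = False
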