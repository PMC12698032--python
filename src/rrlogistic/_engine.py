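"""Jitted core of the event-driven simulator.

The functions here operate on flat preallocated arrays and a NumPy
``Generator`` (numba's implementation draws the identical stream, which the
test-suite exploits to compare this engine against the pure-NumPy reference
path event by event).

Layout: organisms occupy slots ``0..N-1`` of the capacity arrays; a death
swap-removes by moving the last slot down.  Death rates are recomputed from
scratch after every movement update (all organisms move), while in sessile
mode they are maintained incrementally -- positions never change, so the
increments added at a neighbour's birth cancel bitwise at its death.

Kernel convention: the Gaussian competition kernel is truncated on the
minimum-image distance; when the truncation radius reaches L/2 the kernel is
summed over ``m_img`` periodic images per axis (separable 1-D sums).
"""

import math

import numpy as np
from numba import njit

# status codes returned by run_events
OK = 0
EXTINCT = 1
CAPACITY = 2


@njit(cache=True, inline="always")
def _min_image(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True, inline="always")
def _kval(dx, dy, L, s2, norm, rcut2, m_img):
    """Truncated (image-summed) Gaussian kernel at min-image displacement."""
    r2 = dx * dx + dy * dy
    if r2 > rcut2:
        return 0.0
    if m_img == 0:
        return norm * math.exp(-r2 / (2.0 * s2))
    sx = 0.0
    sy = 0.0
    for k in range(-m_img, m_img + 1):
        ax = dx + k * L
        sx += math.exp(-ax * ax / (2.0 * s2))
        ay = dy + k * L
        sy += math.exp(-ay * ay / (2.0 * s2))
    return norm * sx * sy


@njit(cache=True)
def _rates_bruteforce(px, py, N, L, d0, gamma, s2, norm, rcut2, m_img, out):
    for i in range(N):
        out[i] = d0
    for i in range(N):
        xi = px[i]
        yi = py[i]
        for j in range(i + 1, N):
            dx = _min_image(px[j] - xi, L)
            dy = _min_image(py[j] - yi, L)
            k = _kval(dx, dy, L, s2, norm, rcut2, m_img)
            if k != 0.0:
                out[i] += gamma * k
                out[j] += gamma * k


@njit(cache=True)
def _rates_cells(
    px, py, N, L, ncell, d0, gamma, s2, norm, rcut2, wx, wy, cellix, celliy, start, cur, order, out
):
    """Cell-list death-rate recompute; cell size >= truncation radius."""
    nc2 = ncell * ncell
    for c in range(nc2 + 1):
        start[c] = 0
    for i in range(N):
        x = px[i] - L * math.floor(px[i] / L)
        y = py[i] - L * math.floor(py[i] / L)
        if x >= L:
            x = 0.0
        if y >= L:
            y = 0.0
        wx[i] = x
        wy[i] = y
        ix = int(x * ncell / L)
        iy = int(y * ncell / L)
        if ix >= ncell:
            ix = ncell - 1
        if iy >= ncell:
            iy = ncell - 1
        cellix[i] = ix
        celliy[i] = iy
        start[iy * ncell + ix + 1] += 1
    for c in range(nc2):
        start[c + 1] += start[c]
        cur[c] = 0
    for i in range(N):
        c = celliy[i] * ncell + cellix[i]
        order[start[c] + cur[c]] = i
        cur[c] += 1
    for i in range(N):
        s = 0.0
        xi = wx[i]
        yi = wy[i]
        for oy in range(-1, 2):
            jy = celliy[i] + oy
            if jy < 0:
                jy += ncell
            elif jy >= ncell:
                jy -= ncell
            for ox in range(-1, 2):
                jx = cellix[i] + ox
                if jx < 0:
                    jx += ncell
                elif jx >= ncell:
                    jx -= ncell
                c = jy * ncell + jx
                for idx in range(start[c], start[c + 1]):
                    j = order[idx]
                    if j == i:
                        continue
                    dx = _min_image(wx[j] - xi, L)
                    dy = _min_image(wy[j] - yi, L)
                    s += _kval(dx, dy, L, s2, norm, rcut2, 0)
        out[i] = d0 + gamma * s


@njit(cache=True)
def run_events(
    cx,
    cy,
    px,
    py,
    ids,
    drate,
    n_init,
    t_init,
    next_id_init,
    rates_valid,
    L,
    b,
    d0,
    gamma,
    s2,
    norm,
    rcut2,
    m_img,
    ncell,
    mode,  # 0 OU, 1 BM, 2 sessile
    tau,
    sigma_r2,
    D,
    disp_family,  # 0 gaussian, 1 gamma-distance
    sigma_d,
    gshape,
    gscale,
    n_events,
    e_start,
    t_rec,
    n_rec,
    ev_rec,
    wx,
    wy,
    cellix,
    celliy,
    start,
    cur,
    order,
    rng,
):
    """Advance the population by Gillespie events; returns (e, N, t, next_id, status).

    Per-event protocol: rates from pre-move positions -> exponential waiting
    time -> propagate every organism -> select birth/death with the pre-move
    rates -> execute -> record.  The RNG draw order is part of the contract
    (mirrored by the reference implementation).
    """
    N = n_init
    t = t_init
    next_id = next_id_init
    cap = px.shape[0]
    use_cells = (m_img == 0) and (ncell >= 3)
    two_pi = 2.0 * math.pi

    if mode == 2 and not rates_valid:
        _rates_bruteforce(px, py, N, L, d0, gamma, s2, norm, rcut2, m_img, drate)

    e = e_start
    while e < n_events:
        if N + 1 > cap:
            return e, N, t, next_id, CAPACITY
        if mode != 2:
            if use_cells:
                _rates_cells(
                    px, py, N, L, ncell, d0, gamma, s2, norm, rcut2,
                    wx, wy, cellix, celliy, start, cur, order, drate,
                )
            else:
                _rates_bruteforce(px, py, N, L, d0, gamma, s2, norm, rcut2, m_img, drate)
        B = b * N
        Dtot = 0.0
        for i in range(N):
            Dtot += drate[i]
        total = B + Dtot
        dt = rng.standard_exponential() / total

        if mode == 0:
            a = math.exp(-dt / tau)
            sd = math.sqrt(sigma_r2 * -math.expm1(-2.0 * dt / tau))
            for i in range(N):
                px[i] = cx[i] + (px[i] - cx[i]) * a + sd * rng.standard_normal()
                py[i] = cy[i] + (py[i] - cy[i]) * a + sd * rng.standard_normal()
        elif mode == 1:
            sd = math.sqrt(2.0 * D * dt)
            for i in range(N):
                px[i] += sd * rng.standard_normal()
                py[i] += sd * rng.standard_normal()

        t += dt
        u = rng.random()
        if u * total < B:
            parent = int(rng.random() * N)
            if disp_family == 0:
                ux = sigma_d * rng.standard_normal()
                uy = sigma_d * rng.standard_normal()
            else:
                r = gscale * rng.standard_gamma(gshape)
                th = two_pi * rng.random()
                ux = r * math.cos(th)
                uy = r * math.sin(th)
            ncx = cx[parent] + ux
            ncy = cy[parent] + uy
            ncx = ncx - L * math.floor(ncx / L)
            ncy = ncy - L * math.floor(ncy / L)
            if ncx >= L:
                ncx = 0.0
            if ncy >= L:
                ncy = 0.0
            if mode == 0:
                sr = math.sqrt(sigma_r2)
                npx = ncx + sr * rng.standard_normal()
                npy = ncy + sr * rng.standard_normal()
            elif mode == 1:
                npx = L * rng.random()
                npy = L * rng.random()
            else:
                npx = ncx
                npy = ncy
            cx[N] = ncx
            cy[N] = ncy
            px[N] = npx
            py[N] = npy
            ids[N] = next_id
            next_id += 1
            if mode == 2:
                s = 0.0
                for j in range(N):
                    dx = _min_image(px[j] - npx, L)
                    dy = _min_image(py[j] - npy, L)
                    k = _kval(dx, dy, L, s2, norm, rcut2, m_img)
                    if k != 0.0:
                        drate[j] += gamma * k
                        s += k
                drate[N] = d0 + gamma * s
            N += 1
            ev = 1
        else:
            v = rng.random() * Dtot
            acc = 0.0
            victim = N - 1
            for i in range(N):
                acc += drate[i]
                if v < acc:
                    victim = i
                    break
            if mode == 2:
                xv = px[victim]
                yv = py[victim]
                for j in range(N):
                    if j == victim:
                        continue
                    dx = _min_image(px[j] - xv, L)
                    dy = _min_image(py[j] - yv, L)
                    k = _kval(dx, dy, L, s2, norm, rcut2, m_img)
                    if k != 0.0:
                        drate[j] -= gamma * k
            last = N - 1
            cx[victim] = cx[last]
            cy[victim] = cy[last]
            px[victim] = px[last]
            py[victim] = py[last]
            ids[victim] = ids[last]
            drate[victim] = drate[last]
            N = last
            ev = -1

        t_rec[e] = t
        n_rec[e] = N
        ev_rec[e] = ev
        e += 1
        if N == 0:
            return e, N, t, next_id, EXTINCT
    return e, N, t, next_id, OK
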