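"""Numba-compiled inner loops.

Everything here is a plain function of arrays — no objects, no I/O — so the
kernels can be unit-tested directly and the higher-level modules stay
readable.  All sweeps are Jacobi (simultaneous) updates: results are
independent of site traversal order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

AIR = 0
AGAR = 1
CELL = 2


@njit(cache=True)
def diffuse_substrate(phi, out, site, D, air_value, fac, kmax):
    """One explicit seven-point-stencil sweep for a single substrate.

    ``fac = dtau / lam**2``.  Air sites act as clamped sources: flux from an
    air site into agar/cells is admitted only when directed into the site
    (one-way faces), so aqueous substrates cannot escape into the air.
    Domain walls are no-flux; Dirichlet values are re-imposed by the caller.
    """
    nx, ny, nz = site.shape
    if kmax > nz:
        kmax = nz
    for i in range(nx):
        for j in range(ny):
            for k in range(kmax):
                st = site[i, j, k]
                if st == AIR:
                    out[i, j, k] = air_value
                    continue
                p = phi[i, j, k]
                d = D[i, j, k]
                acc = 0.0
                # -x / +x / -y / +y / -z / +z faces
                for di, dj, dk in ((-1, 0, 0), (1, 0, 0), (0, -1, 0),
                                   (0, 1, 0), (0, 0, -1), (0, 0, 1)):
                    ii = i + di
                    jj = j + dj
                    kk = k + dk
                    if ii < 0 or ii >= nx or jj < 0 or jj >= ny \
                            or kk < 0 or kk >= nz:
                        continue
                    dn = 0.5 * (d + D[ii, jj, kk])
                    if site[ii, jj, kk] == AIR:
                        flux = dn * (air_value - p)
                        if flux > 0.0:
                            acc += flux
                    else:
                        acc += dn * (phi[ii, jj, kk] - p)
                out[i, j, k] = p + fac * acc


@njit(cache=True)
def mm_uptake(ext, intra, rho_tot, site, vmax_vol, km, dtau, kmax):
    """Michaelis-Menten active import: move ext -> intra at the local rate
    rho * vmax_vol * phi/(km + phi), capping the transfer at the available
    extracellular pool so it never goes negative.  Returns the number of
    capped sites."""
    nx, ny, nz = site.shape
    if kmax > nz:
        kmax = nz
    capped = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(kmax):
                if site[i, j, k] != CELL:
                    continue
                r = rho_tot[i, j, k]
                if r <= 0.0:
                    continue
                p = ext[i, j, k]
                if p <= 0.0:
                    continue
                move = r * vmax_vol * p / (km + p) * dtau
                if move > p:
                    move = p
                    capped += 1
                ext[i, j, k] = p - move
                intra[i, j, k] += move
    return capped


@njit(cache=True, inline="always")
def _locate(ax, x):
    """Index of the grid interval containing x and the fractional position
    within it; x is assumed clamped to [ax[0], ax[-1]]."""
    n = ax.shape[0]
    if n == 1:
        return 0, 0.0
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ax[mid] <= x:
            lo = mid
        else:
            hi = mid
    w = ax[lo + 1] - ax[lo]
    f = (x - ax[lo]) / w if w > 0.0 else 0.0
    if f < 0.0:
        f = 0.0
    elif f > 1.0:
        f = 1.0
    return lo, f


@njit(cache=True, inline="always")
def _trilinear(tab, i0, i1, i2, f0, f1, f2):
    n0, n1, n2 = tab.shape
    j0 = i0 + 1 if i0 + 1 < n0 else i0
    j1 = i1 + 1 if i1 + 1 < n1 else i1
    j2 = i2 + 1 if i2 + 1 < n2 else i2
    c00 = tab[i0, i1, i2] * (1 - f0) + tab[j0, i1, i2] * f0
    c10 = tab[i0, j1, i2] * (1 - f0) + tab[j0, j1, i2] * f0
    c01 = tab[i0, i1, j2] * (1 - f0) + tab[j0, i1, j2] * f0
    c11 = tab[i0, j1, j2] * (1 - f0) + tab[j0, j1, j2] * f0
    c0 = c00 * (1 - f1) + c10 * f1
    c1 = c01 * (1 - f1) + c11 * f1
    return c0 * (1 - f2) + c1 * f2


@njit(cache=True)
def fba_apply(site, rho, ext, intra, growth, vex,
              gtab, vtab, ax0, ax1, ax2, caps,
              tr_sub, tr_act, avail_fac, conc_fac, kmax):
    """Per-site FBA step via lookup-table interpolation.

    For every cell site: build the availability constraint vector (tracked
    substrates; intracellular pool over total rho for active transport,
    extracellular concentration for passive, then the kinetic cap), query
    each state's table by trilinear interpolation, clamp interpolated uptakes
    to the queried constraint, record growth rates and exchange fluxes, and
    apply the concentration updates.  Returns the number of pool-negativity
    violations beyond -1e-15 M (0 on a consistent table).
    """
    nx, ny, nz = site.shape
    if kmax > nz:
        kmax = nz
    ns = rho.shape[0]
    bad = 0
    c = np.empty(3)
    for i in range(nx):
        for j in range(ny):
            for k in range(kmax):
                if site[i, j, k] != CELL:
                    continue
                rtot = 0.0
                for s in range(ns):
                    rtot += rho[s, i, j, k]
                if rtot <= 0.0:
                    continue
                for t in range(3):
                    if tr_act[t] >= 0:
                        avail = intra[tr_act[t], i, j, k] / rtot * avail_fac
                    else:
                        avail = ext[tr_sub[t], i, j, k] * avail_fac
                    if avail < 0.0:
                        avail = 0.0
                    if avail > caps[t]:
                        avail = caps[t]
                    c[t] = avail
                i0, f0 = _locate(ax0, c[0])
                i1, f1 = _locate(ax1, c[1])
                i2, f2 = _locate(ax2, c[2])
                for s in range(ns):
                    rs = rho[s, i, j, k]
                    g = _trilinear(gtab[s], i0, i1, i2, f0, f1, f2)
                    growth[s, i, j, k] = g
                    for t in range(3):
                        v = _trilinear(vtab[s, t], i0, i1, i2, f0, f1, f2)
                        if v > c[t]:
                            v = c[t]
                        vex[s, t, i, j, k] = v
                        dphi = v * conc_fac * rs
                        if dphi > 0.0:       # uptake
                            if tr_act[t] >= 0:
                                intra[tr_act[t], i, j, k] -= dphi
                            else:
                                ext[tr_sub[t], i, j, k] -= dphi
                        elif dphi < 0.0:     # secretion goes to the shared field
                            ext[tr_sub[t], i, j, k] -= dphi
                # floor rounding noise, flag real violations
                for t in range(3):
                    if tr_act[t] >= 0:
                        p = intra[tr_act[t], i, j, k]
                        if p < 0.0:
                            if p < -1e-15:
                                bad += 1
                            intra[tr_act[t], i, j, k] = 0.0
                    else:
                        p = ext[tr_sub[t], i, j, k]
                        if p < 0.0:
                            if p < -1e-15:
                                bad += 1
                            ext[tr_sub[t], i, j, k] = 0.0
    return bad


@njit(cache=True)
def relax_expansion_sweeps(site, rho, intra, rho_max, delta_rho,
                           max_sweeps, kmax):
    """Iterative Jacobi redistribution of over-filled cell volume.

    Each sweep moves (1/12) * [max(0, rho_i - rho_max) - max(0, rho_j -
    rho_max)] of total volume fraction through every face between non-agar
    sites (the 1/12 = 1/2 * 1/6 contains the convergence damping), splits it
    among states by the donor's relative fractions, and carries the donor's
    intracellular pools along in proportion.  Air sites receiving volume
    become cell sites.  Stops when the largest over-filling is within
    delta_rho.

    Returns (sweeps_used, sites_converted, total_volume_moved,
    residual_history).
    """
    nx, ny, nz = site.shape
    if kmax > nz:
        kmax = nz
    ns = rho.shape[0]
    na = intra.shape[0]
    over = np.zeros((nx, ny, nz))
    drho = np.zeros((ns, nx, ny, nz))
    dintra = np.zeros((na, nx, ny, nz))
    residuals = np.empty(max_sweeps + 1)
    total_moved = 0.0
    converted = 0
    sweeps = 0
    while True:
        maxof = 0.0
        for i in range(nx):
            for j in range(ny):
                for k in range(kmax):
                    rtot = 0.0
                    for s in range(ns):
                        rtot += rho[s, i, j, k]
                    o = rtot - rho_max
                    if o < 0.0:
                        o = 0.0
                    over[i, j, k] = o
                    if o > maxof:
                        maxof = o
        residuals[sweeps] = maxof
        if maxof <= delta_rho or sweeps >= max_sweeps:
            break
        drho[:] = 0.0
        dintra[:] = 0.0
        for i in range(nx):
            for j in range(ny):
                for k in range(kmax):
                    o = over[i, j, k]
                    if o <= 0.0:
                        continue
                    rtot = 0.0
                    for s in range(ns):
                        rtot += rho[s, i, j, k]
                    for di, dj, dk in ((-1, 0, 0), (1, 0, 0), (0, -1, 0),
                                       (0, 1, 0), (0, 0, -1), (0, 0, 1)):
                        ii = i + di
                        jj = j + dj
                        kk = k + dk
                        if ii < 0 or ii >= nx or jj < 0 or jj >= ny \
                                or kk < 0 or kk >= nz:
                            continue
                        if site[ii, jj, kk] == AGAR:
                            continue
                        t = (o - over[ii, jj, kk]) / 12.0
                        if t <= 0.0:
                            continue
                        total_moved += t
                        frac = t / rtot
                        for s in range(ns):
                            ds = rho[s, i, j, k] * frac
                            drho[s, i, j, k] -= ds
                            drho[s, ii, jj, kk] += ds
                        for a in range(na):
                            da = intra[a, i, j, k] * frac
                            dintra[a, i, j, k] -= da
                            dintra[a, ii, jj, kk] += da
        for s in range(ns):
            for i in range(nx):
                for j in range(ny):
                    for k in range(kmax):
                        rho[s, i, j, k] += drho[s, i, j, k]
        for a in range(na):
            for i in range(nx):
                for j in range(ny):
                    for k in range(kmax):
                        intra[a, i, j, k] += dintra[a, i, j, k]
        for i in range(nx):
            for j in range(ny):
                for k in range(kmax):
                    if site[i, j, k] == AIR:
                        rtot = 0.0
                        for s in range(ns):
                            rtot += rho[s, i, j, k]
                        if rtot > 0.0:
                            site[i, j, k] = CELL
                            converted += 1
        sweeps += 1
    return sweeps, converted, total_moved, residuals[:sweeps + 1]
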