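"""Numba-compiled inner loops: force evaluation, SHAKE/RATTLE, BAOAB Langevin.

Everything here works on plain float64/int64 arrays packed from a CGTopology
by :mod:`nrrgo.engine`.  Units: kcal/mol, A, ps, amu; forces kcal/mol/A;
the single unit conversion KCAL_TO_MD = 418.4 turns kcal/mol into
amu*A^2/ps^2 inside the integrator.
"""

import math

import numpy as np
from numba import njit

KCAL_TO_MD = 418.4

# status codes returned by run_md
OK = 0
UNSTABLE = 1            # per-step displacement beyond guard
SHAKE_FAIL = 2
SPRING_RUNAWAY = 3
NONFINITE = 4


@njit(cache=True)
def energy_forces(x, f,
                  ai, aj, ak, at0, akk,
                  di, dj, dk, dl, damp, ddel,
                  ci, cj, cr0, ceps, cshift,
                  ri, rj, rsig, rep_eps, rshift,
                  hi, hj, hr0, hk,
                  cutoff2):
    """Fill ``f`` with -grad(E); return the five energy components
    (angle, dihedral, contact, repulsion, restraint)."""
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0

    e_ang = 0.0
    for m in range(ai.shape[0]):
        i, j, k = ai[m], aj[m], ak[m]
        ux = x[i, 0] - x[j, 0]; uy = x[i, 1] - x[j, 1]; uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]; vy = x[k, 1] - x[j, 1]; vz = x[k, 2] - x[j, 2]
        ru = math.sqrt(ux * ux + uy * uy + uz * uz)
        rv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = math.acos(c)
        s = math.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        diff = th - at0[m]
        e_ang += akk[m] * diff * diff
        dvdt = 2.0 * akk[m] * diff
        coef = dvdt / s
        # F_i = coef * (v/(ru*rv) - c*u/ru^2); F_k symmetric; F_j = -F_i - F_k
        fix = coef * (vx / (ru * rv) - c * ux / (ru * ru))
        fiy = coef * (vy / (ru * rv) - c * uy / (ru * ru))
        fiz = coef * (vz / (ru * rv) - c * uz / (ru * ru))
        fkx = coef * (ux / (ru * rv) - c * vx / (rv * rv))
        fky = coef * (uy / (ru * rv) - c * vy / (rv * rv))
        fkz = coef * (uz / (ru * rv) - c * vz / (rv * rv))
        f[i, 0] += fix; f[i, 1] += fiy; f[i, 2] += fiz
        f[k, 0] += fkx; f[k, 1] += fky; f[k, 2] += fkz
        f[j, 0] -= fix + fkx; f[j, 1] -= fiy + fky; f[j, 2] -= fiz + fkz

    e_dih = 0.0
    for m in range(di.shape[0]):
        i, j, k, l = di[m], dj[m], dk[m], dl[m]
        b1x = x[j, 0] - x[i, 0]; b1y = x[j, 1] - x[i, 1]; b1z = x[j, 2] - x[i, 2]
        b2x = x[k, 0] - x[j, 0]; b2y = x[k, 1] - x[j, 1]; b2z = x[k, 2] - x[j, 2]
        b3x = x[l, 0] - x[k, 0]; b3y = x[l, 1] - x[k, 1]; b3z = x[l, 2] - x[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2n = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-12 or n2sq < 1e-12 or b2n < 1e-8:
            continue
        # phi = atan2((n1 x n2).b2hat, n1.n2)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        sinp = (cxx * b2x + cxy * b2y + cxz * b2z) / b2n
        cosp = n1x * n2x + n1y * n2y + n1z * n2z
        phi = math.atan2(sinp, cosp)
        dvdphi = 0.0
        for t in range(4):
            arg = (t + 1) * phi - ddel[m, t]
            e_dih += damp[m, t] * (1.0 + math.cos(arg))
            dvdphi -= damp[m, t] * (t + 1) * math.sin(arg)
        # dphi/dr
        gix = -(b2n / n1sq) * n1x
        giy = -(b2n / n1sq) * n1y
        giz = -(b2n / n1sq) * n1z
        glx = (b2n / n2sq) * n2x
        gly = (b2n / n2sq) * n2y
        glz = (b2n / n2sq) * n2z
        s1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        s2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        gjx = -(1.0 + s1) * gix + s2 * glx
        gjy = -(1.0 + s1) * giy + s2 * gly
        gjz = -(1.0 + s1) * giz + s2 * glz
        gkx = s1 * gix - (1.0 + s2) * glx
        gky = s1 * giy - (1.0 + s2) * gly
        gkz = s1 * giz - (1.0 + s2) * glz
        f[i, 0] -= dvdphi * gix; f[i, 1] -= dvdphi * giy; f[i, 2] -= dvdphi * giz
        f[j, 0] -= dvdphi * gjx; f[j, 1] -= dvdphi * gjy; f[j, 2] -= dvdphi * gjz
        f[k, 0] -= dvdphi * gkx; f[k, 1] -= dvdphi * gky; f[k, 2] -= dvdphi * gkz
        f[l, 0] -= dvdphi * glx; f[l, 1] -= dvdphi * gly; f[l, 2] -= dvdphi * glz

    e_con = 0.0
    for m in range(ci.shape[0]):
        i, j = ci[m], cj[m]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff2:
            continue
        r = math.sqrt(r2)
        xr = cr0[m] / r
        x6 = xr ** 6
        x10 = x6 * xr ** 4
        x12 = x6 * x6
        e_con += ceps[m] * (13.0 * x12 - 18.0 * x10 + 4.0 * x6) - cshift[m]
        dvdr = -(ceps[m] / r) * (156.0 * x12 - 180.0 * x10 + 24.0 * x6)
        cfac = -dvdr / r
        f[i, 0] += cfac * dx; f[i, 1] += cfac * dy; f[i, 2] += cfac * dz
        f[j, 0] -= cfac * dx; f[j, 1] -= cfac * dy; f[j, 2] -= cfac * dz

    e_rep = 0.0
    for m in range(ri.shape[0]):
        i, j = ri[m], rj[m]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff2:
            continue
        r = math.sqrt(r2)
        sr12 = (rsig[m] / r) ** 12
        e_rep += rep_eps * sr12 - rshift[m]
        dvdr = -12.0 * rep_eps * sr12 / r
        cfac = -dvdr / r
        f[i, 0] += cfac * dx; f[i, 1] += cfac * dy; f[i, 2] += cfac * dz
        f[j, 0] -= cfac * dx; f[j, 1] -= cfac * dy; f[j, 2] -= cfac * dz

    e_res = 0.0
    for m in range(hi.shape[0]):
        i, j = hi[m], hj[m]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        diff = r - hr0[m]
        e_res += hk[m] * diff * diff
        dvdr = 2.0 * hk[m] * diff
        cfac = -dvdr / r
        f[i, 0] += cfac * dx; f[i, 1] += cfac * dy; f[i, 2] += cfac * dz
        f[j, 0] -= cfac * dx; f[j, 1] -= cfac * dy; f[j, 2] -= cfac * dz

    return e_ang, e_dih, e_con, e_rep, e_res


@njit(cache=True)
def max_bond_residual(x, bi, bj, br0):
    worst = 0.0
    for m in range(bi.shape[0]):
        i, j = bi[m], bj[m]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        d = abs(r - br0[m])
        if d > worst:
            worst = d
    return worst


@njit(cache=True)
def shake(xnew, xref, bi, bj, br0, invm, tol, maxiter):
    """Iterative SHAKE (Gauss-Seidel sweeps).  Returns sweeps used, or -1
    on non-convergence.  ``tol`` is an absolute bond-length residual in A."""
    nb = bi.shape[0]
    if nb == 0:
        return 0
    for it in range(maxiter):
        for m in range(nb):
            i, j = bi[m], bj[m]
            dx = xnew[i, 0] - xnew[j, 0]
            dy = xnew[i, 1] - xnew[j, 1]
            dz = xnew[i, 2] - xnew[j, 2]
            diff = dx * dx + dy * dy + dz * dz - br0[m] * br0[m]
            if abs(diff) < 1e-14:
                continue
            rx = xref[i, 0] - xref[j, 0]
            ry = xref[i, 1] - xref[j, 1]
            rz = xref[i, 2] - xref[j, 2]
            denom = 2.0 * (invm[i] + invm[j]) * (rx * dx + ry * dy + rz * dz)
            if abs(denom) < 1e-12:
                denom = 1e-12 if denom >= 0 else -1e-12
            g = diff / denom
            xnew[i, 0] -= g * invm[i] * rx
            xnew[i, 1] -= g * invm[i] * ry
            xnew[i, 2] -= g * invm[i] * rz
            xnew[j, 0] += g * invm[j] * rx
            xnew[j, 1] += g * invm[j] * ry
            xnew[j, 2] += g * invm[j] * rz
        if max_bond_residual(xnew, bi, bj, br0) < tol:
            return it + 1
    return -1


@njit(cache=True)
def rattle(v, x, bi, bj, br0, invm, tol, maxiter):
    """Project velocities onto the constraint manifold (relative velocity
    along each fixed bond -> 0).  ``tol`` in A/ps."""
    nb = bi.shape[0]
    if nb == 0:
        return 0
    for it in range(maxiter):
        worst = 0.0
        for m in range(nb):
            i, j = bi[m], bj[m]
            dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            rv = ((v[i, 0] - v[j, 0]) * dx + (v[i, 1] - v[j, 1]) * dy
                  + (v[i, 2] - v[j, 2]) * dz)
            kfac = rv / ((invm[i] + invm[j]) * r2)
            v[i, 0] -= kfac * invm[i] * dx
            v[i, 1] -= kfac * invm[i] * dy
            v[i, 2] -= kfac * invm[i] * dz
            v[j, 0] += kfac * invm[j] * dx
            v[j, 1] += kfac * invm[j] * dy
            v[j, 2] += kfac * invm[j] * dz
            a = abs(rv) / math.sqrt(r2)
            if a > worst:
                worst = a
        if worst < tol:
            return it + 1
    return -1


@njit(cache=True)
def run_md(x, v, invm, masses,
           dt, gamma, kT_md, n_steps, save_every, seed,
           bi, bj, br0,
           ai, aj, ak, at0, akk,
           di, dj, dk, dl, damp, ddel,
           ci, cj, cr0, ceps, cshift,
           ri, rj, rsig, rep_eps, rshift,
           hi, hj, hr0, hk,
           cutoff2,
           shake_tol, shake_maxiter, guard,
           pull_on, pull_i, pull_j, pull_k, pull_speed, pull_s0,
           pull_max_ext, spring_runaway,
           frames, vel_frames, save_vel, times, exts, pull_forces, e_series):
    """BAOAB Langevin dynamics with SHAKE-constrained virtual bonds and an
    optional pair of moving pulling springs on beads (pull_i, pull_j).

    Saves a frame every ``save_every`` steps (frame 0 = initial state).
    Returns (status, frames_written, bad_index, steps_done).
    gamma == 0 gives velocity Verlet (no RNG is consumed).
    """
    np.random.seed(seed)
    n = x.shape[0]
    f = np.zeros((n, 3))
    xref = np.zeros((n, 3))
    xstart = np.zeros((n, 3))
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    half = 0.5 * dt

    e5 = energy_forces(x, f, ai, aj, ak, at0, akk, di, dj, dk, dl, damp, ddel,
                       ci, cj, cr0, ceps, cshift, ri, rj, rsig, rep_eps, rshift,
                       hi, hj, hr0, hk, cutoff2)
    ea, ed, ec, er, eh = e5
    facc = 0.0
    ext = 0.0
    if pull_on == 1:
        dx = x[pull_j, 0] - x[pull_i, 0]
        dy = x[pull_j, 1] - x[pull_i, 1]
        dz = x[pull_j, 2] - x[pull_i, 2]
        ext = math.sqrt(dx * dx + dy * dy + dz * dz)
        s = pull_s0
        ux, uy, uz = dx / ext, dy / ext, dz / ext
        gap = 0.5 * (s - ext)
        f[pull_j, 0] += pull_k * gap * ux
        f[pull_j, 1] += pull_k * gap * uy
        f[pull_j, 2] += pull_k * gap * uz
        f[pull_i, 0] -= pull_k * gap * ux
        f[pull_i, 1] -= pull_k * gap * uy
        f[pull_i, 2] -= pull_k * gap * uz

    nframe = 0
    # frame 0: initial state
    for i in range(n):
        frames[nframe, i, 0] = x[i, 0]
        frames[nframe, i, 1] = x[i, 1]
        frames[nframe, i, 2] = x[i, 2]
        if save_vel == 1:
            vel_frames[nframe, i, 0] = v[i, 0]
            vel_frames[nframe, i, 1] = v[i, 1]
            vel_frames[nframe, i, 2] = v[i, 2]
    times[nframe] = 0.0
    exts[nframe] = ext
    pull_forces[nframe] = 0.0
    e_series[nframe, 0] = ea
    e_series[nframe, 1] = ed
    e_series[nframe, 2] = ec
    e_series[nframe, 3] = er
    e_series[nframe, 4] = eh
    ke = 0.0
    for i in range(n):
        ke += 0.5 * masses[i] * (v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2)
    e_series[nframe, 5] = ke / KCAL_TO_MD
    nframe += 1

    fcount = 0
    for step in range(1, n_steps + 1):
        for i in range(n):
            xstart[i, 0] = x[i, 0]
            xstart[i, 1] = x[i, 1]
            xstart[i, 2] = x[i, 2]
        # B: half kick
        for i in range(n):
            a = KCAL_TO_MD * invm[i] * half
            v[i, 0] += a * f[i, 0]
            v[i, 1] += a * f[i, 1]
            v[i, 2] += a * f[i, 2]
        if rattle(v, x, bi, bj, br0, invm, 1e-10, shake_maxiter) < 0:
            return SHAKE_FAIL, nframe, -1, step
        # A: half drift + SHAKE
        for i in range(n):
            xref[i, 0] = x[i, 0]
            xref[i, 1] = x[i, 1]
            xref[i, 2] = x[i, 2]
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        if shake(x, xref, bi, bj, br0, invm, shake_tol, shake_maxiter) < 0:
            return SHAKE_FAIL, nframe, -1, step
        for i in range(n):
            v[i, 0] = (x[i, 0] - xref[i, 0]) / half
            v[i, 1] = (x[i, 1] - xref[i, 1]) / half
            v[i, 2] = (x[i, 2] - xref[i, 2]) / half
        # O: Ornstein-Uhlenbeck
        if gamma > 0.0:
            for i in range(n):
                sig = c2 * math.sqrt(kT_md * invm[i])
                v[i, 0] = c1 * v[i, 0] + sig * np.random.standard_normal()
                v[i, 1] = c1 * v[i, 1] + sig * np.random.standard_normal()
                v[i, 2] = c1 * v[i, 2] + sig * np.random.standard_normal()
            if rattle(v, x, bi, bj, br0, invm, 1e-10, shake_maxiter) < 0:
                return SHAKE_FAIL, nframe, -1, step
        # A: second half drift + SHAKE
        for i in range(n):
            xref[i, 0] = x[i, 0]
            xref[i, 1] = x[i, 1]
            xref[i, 2] = x[i, 2]
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        if shake(x, xref, bi, bj, br0, invm, shake_tol, shake_maxiter) < 0:
            return SHAKE_FAIL, nframe, -1, step
        for i in range(n):
            v[i, 0] = (x[i, 0] - xref[i, 0]) / half
            v[i, 1] = (x[i, 1] - xref[i, 1]) / half
            v[i, 2] = (x[i, 2] - xref[i, 2]) / half
        # forces at new positions
        e5 = energy_forces(x, f, ai, aj, ak, at0, akk, di, dj, dk, dl, damp,
                           ddel, ci, cj, cr0, ceps, cshift, ri, rj, rsig,
                           rep_eps, rshift, hi, hj, hr0, hk, cutoff2)
        ea, ed, ec, er, eh = e5
        if not (math.isfinite(ea + ed + ec + er + eh)):
            return NONFINITE, nframe, -1, step
        faxial = 0.0
        if pull_on == 1:
            dx = x[pull_j, 0] - x[pull_i, 0]
            dy = x[pull_j, 1] - x[pull_i, 1]
            dz = x[pull_j, 2] - x[pull_i, 2]
            ext = math.sqrt(dx * dx + dy * dy + dz * dz)
            s = pull_s0 + pull_speed * (step * dt)
            ux, uy, uz = dx / ext, dy / ext, dz / ext
            gap = 0.5 * (s - ext)
            if abs(gap) > spring_runaway:
                return SPRING_RUNAWAY, nframe, -1, step
            f[pull_j, 0] += pull_k * gap * ux
            f[pull_j, 1] += pull_k * gap * uy
            f[pull_j, 2] += pull_k * gap * uz
            f[pull_i, 0] -= pull_k * gap * ux
            f[pull_i, 1] -= pull_k * gap * uy
            f[pull_i, 2] -= pull_k * gap * uz
            faxial = pull_k * gap
            facc += faxial
            fcount += 1
        # B: half kick
        for i in range(n):
            a = KCAL_TO_MD * invm[i] * half
            v[i, 0] += a * f[i, 0]
            v[i, 1] += a * f[i, 1]
            v[i, 2] += a * f[i, 2]
        if rattle(v, x, bi, bj, br0, invm, 1e-10, shake_maxiter) < 0:
            return SHAKE_FAIL, nframe, -1, step
        # instability guard
        for i in range(n):
            ddx = x[i, 0] - xstart[i, 0]
            ddy = x[i, 1] - xstart[i, 1]
            ddz = x[i, 2] - xstart[i, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > guard * guard:
                return UNSTABLE, nframe, i, step
        # save
        if step % save_every == 0:
            for i in range(n):
                frames[nframe, i, 0] = x[i, 0]
                frames[nframe, i, 1] = x[i, 1]
                frames[nframe, i, 2] = x[i, 2]
                if save_vel == 1:
                    vel_frames[nframe, i, 0] = v[i, 0]
                    vel_frames[nframe, i, 1] = v[i, 1]
                    vel_frames[nframe, i, 2] = v[i, 2]
            times[nframe] = step * dt
            exts[nframe] = ext
            if fcount > 0:
                pull_forces[nframe] = facc / fcount
            else:
                pull_forces[nframe] = 0.0
            facc = 0.0
            fcount = 0
            e_series[nframe, 0] = ea
            e_series[nframe, 1] = ed
            e_series[nframe, 2] = ec
            e_series[nframe, 3] = er
            e_series[nframe, 4] = eh
            ke = 0.0
            for i in range(n):
                ke += 0.5 * masses[i] * (v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2)
            e_series[nframe, 5] = ke / KCAL_TO_MD
            nframe += 1
            if pull_on == 1 and ext >= pull_max_ext:
                return OK, nframe, -1, step
    return OK, nframe, -1, n_steps
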