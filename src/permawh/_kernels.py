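"""Jitted inner loops: Langevin (BAOAB) stepping, Gibbs reference-point moves
and sample accumulation.

Everything here operates on plain arrays; the typed surface lives in
:mod:`permawh.dynamics` and :mod:`permawh.awh`.  The landscape is passed as
flat parameter arrays (Gaussian feature centers/heights/widths, trap and
soft-core parameters) so the kernels stay compilable and cacheable.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def land_eval(z, th, featc, feath, featw, theta_b, trapc, trapw, trapd, trapph,
              theta_k, solvent_level):
    """Barrier part P, well part A and their z/theta derivatives at (z, th)."""
    P = 0.0
    A = solvent_level
    dPdz = 0.0
    dAdz = 0.0
    dPdt = 0.0
    dAdt = 0.0
    for i in range(featc.shape[0]):
        g = feath[i] * math.exp(-((z - featc[i]) ** 2) / (2.0 * featw[i] * featw[i]))
        dg = -g * (z - featc[i]) / (featw[i] * featw[i])
        if feath[i] > 0.0:
            P += g
            dPdz += dg
        else:
            A += g
            dAdz += dg
    if theta_b > 0.0:
        s = math.sin(th)
        P += theta_b * s * s
        dPdt += theta_b * 2.0 * s * math.cos(th)
    for i in range(trapc.shape[0]):
        env = math.exp(-((z - trapc[i]) ** 2) / (2.0 * trapw[i] * trapw[i]))
        denv = -env * (z - trapc[i]) / (trapw[i] * trapw[i])
        c = math.cos(th - trapph[i])
        A += -env * trapd[i] * 0.5 * (1.0 + c)
        dAdz += -denv * trapd[i] * 0.5 * (1.0 + c)
        dAdt += env * trapd[i] * 0.5 * math.sin(th - trapph[i])
    if theta_k > 0.0:
        A += 0.5 * theta_k * th * th
        dAdt += theta_k * th
    return P, A, dPdz, dAdz, dPdt, dAdt


@njit(cache=True)
def potential_and_forces(z, th, lam, alpha, eps_sc,
                         featc, feath, featw, theta_b, trapc, trapw, trapd, trapph,
                         theta_k, solvent_level):
    """U(z, th, lam) and (-dU/dz, -dU/dth) with soft-core coupled barriers."""
    P, A, dPdz, dAdz, dPdt, dAdt = land_eval(
        z, th, featc, feath, featw, theta_b, trapc, trapw, trapd, trapph,
        theta_k, solvent_level)
    cpl = 1.0 - lam
    q = 1.0 + alpha * lam * math.sqrt(P / eps_sc) if P > 0.0 else 1.0
    u = cpl * P / (q * q) + cpl * A
    dSdP = cpl / (q * q * q)
    fz = -(dSdP * dPdz + cpl * dAdz)
    ft = -(dSdP * dPdt + cpl * dAdt)
    return u, fz, ft


@njit(cache=True)
def potential_lambda_sweep(z, th, lam_values, alpha, eps_sc,
                           featc, feath, featw, theta_b, trapc, trapw, trapd, trapph,
                           theta_k, solvent_level, out):
    """U(z, th, lam) for every lambda state; P/A evaluated once."""
    P, A, _, _, _, _ = land_eval(
        z, th, featc, feath, featw, theta_b, trapc, trapw, trapd, trapph,
        theta_k, solvent_level)
    sp = math.sqrt(P / eps_sc) if P > 0.0 else 0.0
    for il in range(lam_values.shape[0]):
        lam = lam_values[il]
        q = 1.0 + alpha * lam * sp
        out[il] = (1.0 - lam) * (P / (q * q) + A)


@njit(cache=True, inline="always")
def _reflect(z, v, L, reflect):
    if reflect:
        while z < 0.0 or z > L:
            if z < 0.0:
                z = -z
                v = -v
            else:
                z = 2.0 * L - z
                v = -v
    else:
        z = z % L
    return z, v


@njit(cache=True, inline="always")
def _wrap_theta(th):
    while th > math.pi:
        th -= TWO_PI
    while th < -math.pi:
        th += TWO_PI
    return th


@njit(cache=True)
def langevin_run(n_steps, stride,
                 z0, vz0, th0, vth0, lam,
                 featc, feath, featw, theta_b, trapc, trapw, trapd, trapph,
                 theta_k, solvent_level, alpha, eps_sc,
                 L, reflect, dt, gamma, mass, kT,
                 normals, z_out, vz_out, th_out):
    """Unbiased BAOAB run of one particle; records every ``stride`` steps.

    Returns the final (z, vz, th, vth).
    """
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT / mass * (1.0 - c1 * c1))
    z, vz, th, vth = z0, vz0, th0, vth0
    _, fz, ft = potential_and_forces(z, th, lam, alpha, eps_sc,
                                     featc, feath, featw, theta_b, trapc, trapw,
                                     trapd, trapph, theta_k, solvent_level)
    k_out = 0
    for s in range(n_steps):
        vz += 0.5 * dt * fz / mass
        vth += 0.5 * dt * ft / mass
        z += 0.5 * dt * vz
        th += 0.5 * dt * vth
        z, vz = _reflect(z, vz, L, reflect)
        th = _wrap_theta(th)
        vz = c1 * vz + c2 * normals[s, 0]
        vth = c1 * vth + c2 * normals[s, 1]
        z += 0.5 * dt * vz
        th += 0.5 * dt * vth
        z, vz = _reflect(z, vz, L, reflect)
        th = _wrap_theta(th)
        _, fz, ft = potential_and_forces(z, th, lam, alpha, eps_sc,
                                         featc, feath, featw, theta_b, trapc, trapw,
                                         trapd, trapph, theta_k, solvent_level)
        vz += 0.5 * dt * fz / mass
        vth += 0.5 * dt * ft / mass
        if (s + 1) % stride == 0:
            z_out[k_out] = z
            vz_out[k_out] = vz
            th_out[k_out] = th
            k_out += 1
    return z, vz, th, vth


@njit(cache=True)
def awh_rounds(n_rounds, mc_interval,
               z, vz, th, vth, lam_idx, ref_iz, fcz, fct,
               featc, feath, featw, theta_b, trapc, trapw, trapd, trapph,
               theta_k, solvent_level, alpha, eps_sc,
               lam_values, z_centers, L, reflect,
               dt, gamma, mass, kT, k_umb, win_bins,
               f, logtarget, dW, visited, wmin, wmax,
               normals, u_mc,
               force_out, bin_out, lam_out, z_out,
               fr_S, fr_T, fr_Q, rounds_per_block, round_offset, lam_cond):
    """Run ``n_rounds`` of (mc_interval BAOAB steps + one Gibbs move) per walker.

    Mutates walker state, the sample-weight accumulator ``dW``, per-walker
    visit flags and spatial extents, and fills the per-round force series.
    Additionally accumulates the blocked, Gibbs-weight-conditioned pull-force
    sums used by the friction metric: per (block, walker, z-bin),
    fr_S += omega * F * dt, fr_T += omega * dt and fr_Q += omega^2 * dt,
    where omega is the sample's normalized weight share at that bin
    (restricted to the ``lam_cond`` lambda state, or summed over lambda if
    lam_cond < 0).  The squared-weight sum is the correct normalization of
    the blocked variance for soft (Gaussian-kernel) assignment; it reduces
    to the occupancy time for hard 0/1 assignment.
    Returns (status, walker): status 0 on success, 1 on force overflow.
    """
    n_w = z.shape[0]
    n_z = z_centers.shape[0]
    n_l = lam_values.shape[0]
    beta = 1.0 / kT
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT / mass * (1.0 - c1 * c1))
    dz_grid = z_centers[1] - z_centers[0] if n_z > 1 else 1.0
    u_l = np.empty(n_l)
    logw = np.empty((2 * win_bins + 1, n_l))

    for r in range(n_rounds):
        for s in range(mc_interval):
            irow = r * mc_interval + s
            for w in range(n_w):
                zref = z_centers[ref_iz[w]]
                fz_tot = fcz[w] - k_umb * (z[w] - zref)
                vz[w] += 0.5 * dt * fz_tot / mass
                vth[w] += 0.5 * dt * fct[w] / mass
                z[w] += 0.5 * dt * vz[w]
                th[w] += 0.5 * dt * vth[w]
                z[w], vz[w] = _reflect(z[w], vz[w], L, reflect)
                th[w] = _wrap_theta(th[w])
                vz[w] = c1 * vz[w] + c2 * normals[irow, w, 0]
                vth[w] = c1 * vth[w] + c2 * normals[irow, w, 1]
                z[w] += 0.5 * dt * vz[w]
                th[w] += 0.5 * dt * vth[w]
                z[w], vz[w] = _reflect(z[w], vz[w], L, reflect)
                th[w] = _wrap_theta(th[w])
                _, fz, ft = potential_and_forces(
                    z[w], th[w], lam_values[lam_idx[w]], alpha, eps_sc,
                    featc, feath, featw, theta_b, trapc, trapw, trapd, trapph,
                    theta_k, solvent_level)
                fcz[w] = fz
                fct[w] = ft
                if abs(fz) > 1e12 or abs(ft) > 1e12:
                    return 1, w
                fz_tot = fz - k_umb * (z[w] - z_centers[ref_iz[w]])
                vz[w] += 0.5 * dt * fz_tot / mass
                vth[w] += 0.5 * dt * fct[w] / mass

        for w in range(n_w):
            # record the pull force governing this sampling interval
            force_out[r, w] = -k_umb * (z[w] - z_centers[ref_iz[w]])
            bin_out[r, w] = ref_iz[w]
            lam_out[r, w] = lam_idx[w]
            z_out[r, w] = z[w]

            # Gibbs move over (z_ref, lambda) within the umbrella window
            potential_lambda_sweep(z[w], th[w], lam_values, alpha, eps_sc,
                                   featc, feath, featw, theta_b, trapc, trapw,
                                   trapd, trapph, theta_k, solvent_level, u_l)
            iz_near = int(round((z[w] - z_centers[0]) / dz_grid)) if n_z > 1 else 0
            if iz_near < 0:
                iz_near = 0
            if iz_near > n_z - 1:
                iz_near = n_z - 1
            lo = iz_near - win_bins
            if lo < 0:
                lo = 0
            hi = iz_near + win_bins
            if hi > n_z - 1:
                hi = n_z - 1
            nwin = hi - lo + 1
            mx = -1e300
            for j in range(nwin):
                iz = lo + j
                du = 0.5 * k_umb * (z[w] - z_centers[iz]) ** 2
                for il in range(n_l):
                    lw = logtarget[iz, il] + beta * f[iz, il] - beta * (du + u_l[il])
                    logw[j, il] = lw
                    if lw > mx:
                        mx = lw
            tot = 0.0
            for j in range(nwin):
                for il in range(n_l):
                    wv = math.exp(logw[j, il] - mx)
                    logw[j, il] = wv
                    tot += wv
            if not (tot > 0.0) or not math.isfinite(tot):
                return 2, w
            # categorical draw
            target_u = u_mc[r, w] * tot
            acc = 0.0
            sel_iz = hi
            sel_il = n_l - 1
            done = False
            for j in range(nwin):
                if done:
                    break
                for il in range(n_l):
                    acc += logw[j, il]
                    if acc >= target_u:
                        sel_iz = lo + j
                        sel_il = il
                        done = True
                        break
            # accumulate the normalized weight vector (Rao-Blackwellised)
            for j in range(nwin):
                for il in range(n_l):
                    dW[lo + j, il] += logw[j, il] / tot
            # blocked friction sums, conditioned smoothly on the point weight
            blk = (round_offset + r) // rounds_per_block
            if blk > fr_S.shape[0] - 1:
                blk = fr_S.shape[0] - 1
            dts = mc_interval * dt
            for j in range(nwin):
                if lam_cond >= 0:
                    om = logw[j, lam_cond] / tot
                else:
                    om = 0.0
                    for il in range(n_l):
                        om += logw[j, il]
                    om /= tot
                if om > 0.0:
                    fpull = -k_umb * (z[w] - z_centers[lo + j])
                    fr_S[blk, w, lo + j] += om * fpull * dts
                    fr_T[blk, w, lo + j] += om * dts
                    fr_Q[blk, w, lo + j] += om * om * dts
            lam_changed = sel_il != lam_idx[w]
            ref_iz[w] = sel_iz
            lam_idx[w] = sel_il
            visited[w, sel_iz, sel_il] = True
            zr = z_centers[sel_iz]
            if zr < wmin[w]:
                wmin[w] = zr
            if zr > wmax[w]:
                wmax[w] = zr
            if lam_changed:
                _, fz, ft = potential_and_forces(
                    z[w], th[w], lam_values[sel_il], alpha, eps_sc,
                    featc, feath, featw, theta_b, trapc, trapw, trapd, trapph,
                    theta_k, solvent_level)
                fcz[w] = fz
                fct[w] = ft
    return 0, -1
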