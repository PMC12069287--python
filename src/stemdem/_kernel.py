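"""Compiled inner loop of the bonded-sphere DEM.

The kernel advances the explicit Newton–Euler integration over a chunk of
steps with a frozen contact-candidate pair list; the Python driver in
:mod:`stemdem.simulation` rebuilds neighbour lists between chunks and owns
recording, rupture logging and the quasi-staticity guard.

Everything here mirrors the reference semantics in :mod:`stemdem.core`:
Hertz–Mindlin contact with restitution-consistent damping and regularised
Coulomb friction, the incremental bond force/torque law, magnitude-based
stress rupture, and Cundall local damping for quasi-static settling.

Wall (rigid tool) encoding, per wall ``w``:

=====  ==========================  ==========================================
kind   geometry                    parameters used
=====  ==========================  ==========================================
0      infinite plane              point ``wp``, outward normal ``wn``
1      slotted plane               plane plus slot direction ``ws`` and
                                   half-gap ``wg`` (inactive strip)
2      solid cylinder              axis point ``wp``, axis ``wn``, radius
                                   ``wr`` (contact on the outer surface)
=====  ==========================  ==========================================
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_UNSTABLE = 1

#: hard abort threshold on particle speed, m/s
V_ABORT = 100.0


@njit(cache=True, fastmath=True)
def _wall_overlap(kind, wp, wn, ws, wr, wg, x, r):
    """Overlap and contact normal (wall -> particle) for one wall.

    Returns (overlap, nx, ny, nz, arm); ``arm`` is the lever-arm length from
    the particle centre towards the contact point (along -normal).
    """
    if kind == 0 or kind == 1:
        dx = x[0] - wp[0]
        dy = x[1] - wp[1]
        dz = x[2] - wp[2]
        d = dx * wn[0] + dy * wn[1] + dz * wn[2]
        if kind == 1:
            s = dx * ws[0] + dy * ws[1] + dz * ws[2]
            if abs(s) < wg:
                return -1.0, 0.0, 0.0, 0.0, 0.0
        ov = r - d
        return ov, wn[0], wn[1], wn[2], d
    # solid cylinder
    dx = x[0] - wp[0]
    dy = x[1] - wp[1]
    dz = x[2] - wp[2]
    t = dx * wn[0] + dy * wn[1] + dz * wn[2]
    ux = dx - t * wn[0]
    uy = dy - t * wn[1]
    uz = dz - t * wn[2]
    dist = math.sqrt(ux * ux + uy * uy + uz * uz)
    if dist < 1e-12:
        return -1.0, 0.0, 0.0, 0.0, 0.0
    ov = (r + wr) - dist
    return ov, ux / dist, uy / dist, uz / dist, dist - wr


@njit(cache=True, fastmath=True)
def step_chunk(
    # particle state
    pos, vel, omg, drv,
    m, inertia, r,
    # bonds
    bp, b_fn, b_ft, b_mn, b_ms, b_ok,
    K_n, K_s, A_b, J, R_ab, sig_max, tau_max,
    # contact candidate pairs (particle-particle)
    cp,
    # contact coefficients: (E*, beta, mu_s, mu_r) for pp and pw
    estar_pp, beta_pp, mu_pp, mur_pp,
    estar_pw, beta_pw, mu_pw, mur_pw,
    # walls
    wk, wp, wn, ws, wr, wg, wv,
    # integration
    dt, damping, gravity, v_reg,
    n_steps, rec_every, rec_wall,
    # outputs (n_rec rows)
    rec_force, rec_ke, rec_se_bond, rec_se_contact, rec_broken,
    # scratch (N,3)
    force, torque,
):
    """Advance ``n_steps`` steps; record averaged tool reaction force and
    instantaneous energies every ``rec_every`` steps.

    ``rec_wall >= 0`` records the force particles exert on that wall;
    ``rec_wall == -1`` records the net force acting on velocity-driven
    particles with ``drv == 1`` (grip reaction; ``drv == 2`` marks kinematic
    particles excluded from recording, e.g. the static clamp).  Returns
    STATUS_OK or STATUS_UNSTABLE.
    """
    n = pos.shape[0]
    n_bonds = bp.shape[0]
    n_cp = cp.shape[0]
    n_walls = wk.shape[0]

    acc_fx = 0.0
    acc_fy = 0.0
    acc_fz = 0.0
    rec_i = 0

    r_star_pp = 0.5 * r
    m_star_pp = 0.5 * m
    k_hz_pp = (4.0 / 3.0) * estar_pp * math.sqrt(r_star_pp)
    k_hz_pw = (4.0 / 3.0) * estar_pw * math.sqrt(r)
    dcoef = 2.0 * math.sqrt(5.0 / 6.0)

    for step in range(n_steps):
        for i in range(n):
            force[i, 0] = 0.0
            force[i, 1] = 0.0
            force[i, 2] = m * gravity
            torque[i, 0] = 0.0
            torque[i, 1] = 0.0
            torque[i, 2] = 0.0

        step_fx = 0.0
        step_fy = 0.0
        step_fz = 0.0

        # ---- bonds ----
        for b in range(n_bonds):
            if b_ok[b] == 0:
                continue
            ia = bp[b, 0]
            ib = bp[b, 1]
            nx = pos[ib, 0] - pos[ia, 0]
            ny = pos[ib, 1] - pos[ia, 1]
            nz = pos[ib, 2] - pos[ia, 2]
            d = math.sqrt(nx * nx + ny * ny + nz * nz)
            if d < 1e-12:
                continue
            nx /= d
            ny /= d
            nz /= d
            half = 0.5 * d
            # relative velocity of b w.r.t. a at the bond midpoint
            # arm a -> mid = +half*n ; arm b -> mid = -half*n
            vx = (
                vel[ib, 0]
                + (omg[ib, 1] * (-half * nz) - omg[ib, 2] * (-half * ny))
                - vel[ia, 0]
                - (omg[ia, 1] * (half * nz) - omg[ia, 2] * (half * ny))
            )
            vy = (
                vel[ib, 1]
                + (omg[ib, 2] * (-half * nx) - omg[ib, 0] * (-half * nz))
                - vel[ia, 1]
                - (omg[ia, 2] * (half * nx) - omg[ia, 0] * (half * nz))
            )
            vz = (
                vel[ib, 2]
                + (omg[ib, 0] * (-half * ny) - omg[ib, 1] * (-half * nx))
                - vel[ia, 2]
                - (omg[ia, 0] * (half * ny) - omg[ia, 1] * (half * nx))
            )
            v_n = vx * nx + vy * ny + vz * nz
            vtx = vx - v_n * nx
            vty = vy - v_n * ny
            vtz = vz - v_n * nz
            wxr = omg[ib, 0] - omg[ia, 0]
            wyr = omg[ib, 1] - omg[ia, 1]
            wzr = omg[ib, 2] - omg[ia, 2]
            w_n = wxr * nx + wyr * ny + wzr * nz
            wtx = wxr - w_n * nx
            wty = wyr - w_n * ny
            wtz = wzr - w_n * nz

            b_fn[b] -= v_n * K_n * A_b * dt
            b_ft[b, 0] -= vtx * K_s * A_b * dt
            b_ft[b, 1] -= vty * K_s * A_b * dt
            b_ft[b, 2] -= vtz * K_s * A_b * dt
            b_mn[b] -= w_n * K_s * J * dt
            b_ms[b, 0] -= 0.5 * wtx * K_n * J * dt
            b_ms[b, 1] -= 0.5 * wty * K_n * J * dt
            b_ms[b, 2] -= 0.5 * wtz * K_n * J * dt

            # keep tangential state in the (rotating) contact plane
            ftn = b_ft[b, 0] * nx + b_ft[b, 1] * ny + b_ft[b, 2] * nz
            b_ft[b, 0] -= ftn * nx
            b_ft[b, 1] -= ftn * ny
            b_ft[b, 2] -= ftn * nz
            msn = b_ms[b, 0] * nx + b_ms[b, 1] * ny + b_ms[b, 2] * nz
            b_ms[b, 0] -= msn * nx
            b_ms[b, 1] -= msn * ny
            b_ms[b, 2] -= msn * nz

            ft_mag = math.sqrt(
                b_ft[b, 0] ** 2 + b_ft[b, 1] ** 2 + b_ft[b, 2] ** 2
            )
            ms_mag = math.sqrt(
                b_ms[b, 0] ** 2 + b_ms[b, 1] ** 2 + b_ms[b, 2] ** 2
            )
            sigma = -b_fn[b] / A_b + 2.0 * ms_mag * R_ab / J
            tau = ft_mag / A_b + abs(b_mn[b]) * R_ab / J
            if sigma > sig_max or tau > tau_max:
                b_ok[b] = 0
                b_fn[b] = 0.0
                b_ft[b, 0] = 0.0
                b_ft[b, 1] = 0.0
                b_ft[b, 2] = 0.0
                b_mn[b] = 0.0
                b_ms[b, 0] = 0.0
                b_ms[b, 1] = 0.0
                b_ms[b, 2] = 0.0
                continue

            fbx = b_fn[b] * nx + b_ft[b, 0]
            fby = b_fn[b] * ny + b_ft[b, 1]
            fbz = b_fn[b] * nz + b_ft[b, 2]
            force[ib, 0] += fbx
            force[ib, 1] += fby
            force[ib, 2] += fbz
            force[ia, 0] -= fbx
            force[ia, 1] -= fby
            force[ia, 2] -= fbz
            # torque from the tangential force acting at the midpoint:
            # both particles receive -(half) n x F_t
            tfx = -half * (ny * b_ft[b, 2] - nz * b_ft[b, 1])
            tfy = -half * (nz * b_ft[b, 0] - nx * b_ft[b, 2])
            tfz = -half * (nx * b_ft[b, 1] - ny * b_ft[b, 0])
            mx = b_mn[b] * nx + b_ms[b, 0]
            my = b_mn[b] * ny + b_ms[b, 1]
            mz = b_mn[b] * nz + b_ms[b, 2]
            torque[ib, 0] += tfx + mx
            torque[ib, 1] += tfy + my
            torque[ib, 2] += tfz + mz
            torque[ia, 0] += tfx - mx
            torque[ia, 1] += tfy - my
            torque[ia, 2] += tfz - mz

        # ---- particle-particle contacts ----
        for c in range(n_cp):
            ia = cp[c, 0]
            ib = cp[c, 1]
            nx = pos[ib, 0] - pos[ia, 0]
            ny = pos[ib, 1] - pos[ia, 1]
            nz = pos[ib, 2] - pos[ia, 2]
            d = math.sqrt(nx * nx + ny * ny + nz * nz)
            ov = 2.0 * r - d
            if ov <= 0.0 or d < 1e-12:
                continue
            nx /= d
            ny /= d
            nz /= d
            arm = 0.5 * d
            vx = (
                vel[ib, 0]
                + (omg[ib, 1] * (-arm * nz) - omg[ib, 2] * (-arm * ny))
                - vel[ia, 0]
                - (omg[ia, 1] * (arm * nz) - omg[ia, 2] * (arm * ny))
            )
            vy = (
                vel[ib, 1]
                + (omg[ib, 2] * (-arm * nx) - omg[ib, 0] * (-arm * nz))
                - vel[ia, 1]
                - (omg[ia, 2] * (arm * nx) - omg[ia, 0] * (arm * nz))
            )
            vz = (
                vel[ib, 2]
                + (omg[ib, 0] * (-arm * ny) - omg[ib, 1] * (-arm * nx))
                - vel[ia, 2]
                - (omg[ia, 0] * (arm * ny) - omg[ia, 1] * (arm * nx))
            )
            v_n = vx * nx + vy * ny + vz * nz
            f_el = k_hz_pp * ov * math.sqrt(ov)
            s_n = 2.0 * estar_pp * math.sqrt(r_star_pp * ov)
            f_dmp = -dcoef * beta_pp * math.sqrt(s_n * m_star_pp) * v_n
            f_n = f_el + f_dmp
            if f_n < 0.0:
                f_n = 0.0
            # repulsion on b acts along +n (a -> b)
            vtx = vx - v_n * nx
            vty = vy - v_n * ny
            vtz = vz - v_n * nz
            vt = math.sqrt(vtx * vtx + vty * vty + vtz * vtz)
            ftx = 0.0
            fty = 0.0
            ftz = 0.0
            if vt > 1e-15:
                # regularised Coulomb, additionally capped at the viscous
                # stability bound of the explicit step
                f_mag = mu_pp * f_n * math.tanh(vt / v_reg)
                f_cap = 0.1 * m_star_pp * vt / dt
                if f_mag > f_cap:
                    f_mag = f_cap
                f_t = -f_mag / vt
                ftx = f_t * vtx
                fty = f_t * vty
                ftz = f_t * vtz
            fbx = f_n * nx + ftx
            fby = f_n * ny + fty
            fbz = f_n * nz + ftz
            force[ib, 0] += fbx
            force[ib, 1] += fby
            force[ib, 2] += fbz
            force[ia, 0] -= fbx
            force[ia, 1] -= fby
            force[ia, 2] -= fbz
            tfx = -arm * (ny * ftz - nz * fty)
            tfy = -arm * (nz * ftx - nx * ftz)
            tfz = -arm * (nx * fty - ny * ftx)
            torque[ib, 0] += tfx
            torque[ib, 1] += tfy
            torque[ib, 2] += tfz
            torque[ia, 0] += tfx
            torque[ia, 1] += tfy
            torque[ia, 2] += tfz
            # rolling resistance opposing relative spin
            wxr = omg[ib, 0] - omg[ia, 0]
            wyr = omg[ib, 1] - omg[ia, 1]
            wzr = omg[ib, 2] - omg[ia, 2]
            wmag = math.sqrt(wxr * wxr + wyr * wyr + wzr * wzr)
            if wmag > 1e-12:
                t_mag = mur_pp * f_n * r_star_pp
                t_cap = 0.1 * inertia * wmag / dt
                if t_mag > t_cap:
                    t_mag = t_cap
                tr = -t_mag / wmag
                torque[ib, 0] += tr * wxr
                torque[ib, 1] += tr * wyr
                torque[ib, 2] += tr * wzr
                torque[ia, 0] -= tr * wxr
                torque[ia, 1] -= tr * wyr
                torque[ia, 2] -= tr * wzr

        # ---- walls ----
        for w in range(n_walls):
            for i in range(n):
                ov, nxw, nyw, nzw, arm = _wall_overlap(
                    wk[w], wp[w], wn[w], ws[w], wr[w], wg[w], pos[i], r
                )
                if ov <= 0.0:
                    continue
                # relative velocity particle - wall at contact point
                vx = (
                    vel[i, 0]
                    + (omg[i, 1] * (-arm * nzw) - omg[i, 2] * (-arm * nyw))
                    - wv[w, 0]
                )
                vy = (
                    vel[i, 1]
                    + (omg[i, 2] * (-arm * nxw) - omg[i, 0] * (-arm * nzw))
                    - wv[w, 1]
                )
                vz = (
                    vel[i, 2]
                    + (omg[i, 0] * (-arm * nyw) - omg[i, 1] * (-arm * nxw))
                    - wv[w, 2]
                )
                v_n = vx * nxw + vy * nyw + vz * nzw
                f_el = k_hz_pw * ov * math.sqrt(ov)
                s_n = 2.0 * estar_pw * math.sqrt(r * ov)
                f_dmp = -dcoef * beta_pw * math.sqrt(s_n * m) * v_n
                f_n = f_el + f_dmp
                if f_n < 0.0:
                    f_n = 0.0
                vtx = vx - v_n * nxw
                vty = vy - v_n * nyw
                vtz = vz - v_n * nzw
                vt = math.sqrt(vtx * vtx + vty * vty + vtz * vtz)
                ftx = 0.0
                fty = 0.0
                ftz = 0.0
                if vt > 1e-15:
                    f_mag = mu_pw * f_n * math.tanh(vt / v_reg)
                    f_cap = 0.1 * m * vt / dt
                    if f_mag > f_cap:
                        f_mag = f_cap
                    f_t = -f_mag / vt
                    ftx = f_t * vtx
                    fty = f_t * vty
                    ftz = f_t * vtz
                fx = f_n * nxw + ftx
                fy = f_n * nyw + fty
                fz = f_n * nzw + ftz
                force[i, 0] += fx
                force[i, 1] += fy
                force[i, 2] += fz
                tfx = -arm * (nyw * ftz - nzw * fty)
                tfy = -arm * (nzw * ftx - nxw * ftz)
                tfz = -arm * (nxw * fty - nyw * ftx)
                wmag = math.sqrt(
                    omg[i, 0] ** 2 + omg[i, 1] ** 2 + omg[i, 2] ** 2
                )
                if wmag > 1e-12:
                    t_mag = mur_pw * f_n * r
                    t_cap = 0.1 * inertia * wmag / dt
                    if t_mag > t_cap:
                        t_mag = t_cap
                    tr = -t_mag / wmag
                    tfx += tr * omg[i, 0]
                    tfy += tr * omg[i, 1]
                    tfz += tr * omg[i, 2]
                torque[i, 0] += tfx
                torque[i, 1] += tfy
                torque[i, 2] += tfz
                if w == rec_wall:
                    step_fx -= fx
                    step_fy -= fy
                    step_fz -= fz

        if rec_wall == -1:
            for i in range(n):
                if drv[i] == 1:
                    step_fx += force[i, 0]
                    step_fy += force[i, 1]
                    step_fz += force[i, 2]

        acc_fx += step_fx
        acc_fy += step_fy
        acc_fz += step_fz

        # ---- integrate (semi-implicit Euler, Cundall local damping) ----
        for i in range(n):
            if drv[i] != 0:
                pos[i, 0] += vel[i, 0] * dt
                pos[i, 1] += vel[i, 1] * dt
                pos[i, 2] += vel[i, 2] * dt
                continue
            for k in range(3):
                f = force[i, k]
                if damping > 0.0:
                    if vel[i, k] > 0.0:
                        f -= damping * abs(f)
                    elif vel[i, k] < 0.0:
                        f += damping * abs(f)
                vel[i, k] += f / m * dt
                t = torque[i, k]
                if damping > 0.0:
                    if omg[i, k] > 0.0:
                        t -= damping * abs(t)
                    elif omg[i, k] < 0.0:
                        t += damping * abs(t)
                omg[i, k] += t / inertia * dt
                pos[i, k] += vel[i, k] * dt

        for w in range(n_walls):
            wp[w, 0] += wv[w, 0] * dt
            wp[w, 1] += wv[w, 1] * dt
            wp[w, 2] += wv[w, 2] * dt

        # ---- record ----
        if (step + 1) % rec_every == 0:
            inv = 1.0 / rec_every
            rec_force[rec_i, 0] = acc_fx * inv
            rec_force[rec_i, 1] = acc_fy * inv
            rec_force[rec_i, 2] = acc_fz * inv
            acc_fx = 0.0
            acc_fy = 0.0
            acc_fz = 0.0
            ke = 0.0
            vmax2 = 0.0
            for i in range(n):
                v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                w2 = omg[i, 0] ** 2 + omg[i, 1] ** 2 + omg[i, 2] ** 2
                if drv[i] == 0:
                    ke += 0.5 * m * v2 + 0.5 * inertia * w2
                if v2 > vmax2:
                    vmax2 = v2
            se = 0.0
            nbroken = 0
            for b in range(n_bonds):
                if b_ok[b] == 0:
                    nbroken += 1
                    continue
                ft2 = b_ft[b, 0] ** 2 + b_ft[b, 1] ** 2 + b_ft[b, 2] ** 2
                ms2 = b_ms[b, 0] ** 2 + b_ms[b, 1] ** 2 + b_ms[b, 2] ** 2
                se += (
                    b_fn[b] ** 2 / (2.0 * K_n * A_b)
                    + ft2 / (2.0 * K_s * A_b)
                    + b_mn[b] ** 2 / (2.0 * K_s * J)
                    + ms2 / (K_n * J)
                )
            sec = 0.0
            for c in range(n_cp):
                ia = cp[c, 0]
                ib = cp[c, 1]
                dx = pos[ib, 0] - pos[ia, 0]
                dy = pos[ib, 1] - pos[ia, 1]
                dz = pos[ib, 2] - pos[ia, 2]
                ov = 2.0 * r - math.sqrt(dx * dx + dy * dy + dz * dz)
                if ov > 0.0:
                    sec += 0.4 * k_hz_pp * ov * ov * math.sqrt(ov)
            rec_ke[rec_i] = ke
            rec_se_bond[rec_i] = se
            rec_se_contact[rec_i] = sec
            rec_broken[rec_i] = nbroken
            rec_i += 1
            if not math.isfinite(ke) or vmax2 > V_ABORT * V_ABORT:
                return STATUS_UNSTABLE
    return STATUS_OK
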