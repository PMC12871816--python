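"""Numba-compiled force evaluation and BAOAB Langevin integration.

Everything here works on plain float64/int64 arrays; the object-level API
lives in :mod:`tailgate.dynamics`.  Excluded-volume interactions go through
a Verlet neighbour list over a precomputed candidate-pair array (pairs with
at least one mobile atom, minus bonded/contact exclusions); the list is
rebuilt whenever any mobile atom has moved more than half the skin since
the last build.
"""

import numpy as np
from numba import njit

FORM_12_6 = 0
FORM_12_10 = 1


@njit(cache=True, fastmath=False)
def forces_energy(coords, f_out,
                  bond_i, bond_j, bond_r0, k_bond,
                  ang_i, ang_j, ang_k, ang_t0, k_angle,
                  dih_i, dih_j, dih_k, dih_l, dih_p0, k_dih,
                  con_i, con_j, con_r0, con_eps, form,
                  ev_i, ev_j, ev_sig, n_ev, eps_ev,
                  res_idx, res_x0, res_k):
    """Accumulate forces into f_out (zeroed here); return potential energy.

    Only the first ``n_ev`` entries of the ev pair arrays are used, so the
    caller can pass a partially filled neighbour list.
    """
    n = coords.shape[0]
    for a in range(n):
        f_out[a, 0] = 0.0
        f_out[a, 1] = 0.0
        f_out[a, 2] = 0.0
    energy = 0.0

    # bonds
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        energy += 0.5 * k_bond * dr * dr
        fmag = -k_bond * dr / r
        f_out[i, 0] += fmag * dx
        f_out[i, 1] += fmag * dy
        f_out[i, 2] += fmag * dz
        f_out[j, 0] -= fmag * dx
        f_out[j, 1] -= fmag * dy
        f_out[j, 2] -= fmag * dz

    # angles: V = 1/2 k (theta - theta0)^2
    for a in range(ang_i.shape[0]):
        i = ang_i[a]
        j = ang_j[a]
        k = ang_k[a]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - ang_t0[a]
        energy += 0.5 * k_angle * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = k_angle * dth / s     # = dV/dtheta / sin(theta)
        # F_i = coef * dc/dr_i  (since dtheta/dr = -dc/dr / sin)
        fix = coef * (vx / (nu * nv) - c * ux / (nu * nu))
        fiy = coef * (vy / (nu * nv) - c * uy / (nu * nu))
        fiz = coef * (vz / (nu * nv) - c * uz / (nu * nu))
        fkx = coef * (ux / (nu * nv) - c * vx / (nv * nv))
        fky = coef * (uy / (nu * nv) - c * vy / (nv * nv))
        fkz = coef * (uz / (nu * nv) - c * vz / (nv * nv))
        f_out[i, 0] += fix
        f_out[i, 1] += fiy
        f_out[i, 2] += fiz
        f_out[k, 0] += fkx
        f_out[k, 1] += fky
        f_out[k, 2] += fkz
        f_out[j, 0] -= fix + fkx
        f_out[j, 1] -= fiy + fky
        f_out[j, 2] -= fiz + fkz

    # dihedrals: V = k[1 - cos(dphi)] + k/2 [1 - cos(3 dphi)]
    for d in range(dih_i.shape[0]):
        i = dih_i[d]
        j = dih_j[d]
        k = dih_k[d]
        l = dih_l[d]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-18 or n2sq < 1e-18:
            continue
        # phi via atan2((n1 x b2hat).n2, n1.n2), matching the builder
        m1x = n1y * b2z - n1z * b2y
        m1y = n1z * b2x - n1x * b2z
        m1z = n1x * b2y - n1y * b2x
        sinp = (m1x * n2x + m1y * n2y + m1z * n2z) / nb2
        cosp = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sinp, cosp)
        dphi = phi - dih_p0[d]
        energy += k_dih * (1.0 - np.cos(dphi)) \
            + 0.5 * k_dih * (1.0 - np.cos(3.0 * dphi))
        dv = k_dih * np.sin(dphi) + 1.5 * k_dih * np.sin(3.0 * dphi)
        # dphi/dr_i = |b2|/|n1|^2 n1 ; dphi/dr_l = -|b2|/|n2|^2 n2
        # (sign fixed by the atan2 convention above)
        gix = nb2 / n1sq * n1x
        giy = nb2 / n1sq * n1y
        giz = nb2 / n1sq * n1z
        glx = -nb2 / n2sq * n2x
        gly = -nb2 / n2sq * n2y
        glz = -nb2 / n2sq * n2z
        d12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        d32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        gjx = -(1.0 + d12) * gix + d32 * glx
        gjy = -(1.0 + d12) * giy + d32 * gly
        gjz = -(1.0 + d12) * giz + d32 * glz
        gkx = d12 * gix - (1.0 + d32) * glx
        gky = d12 * giy - (1.0 + d32) * gly
        gkz = d12 * giz - (1.0 + d32) * glz
        f_out[i, 0] -= dv * gix
        f_out[i, 1] -= dv * giy
        f_out[i, 2] -= dv * giz
        f_out[j, 0] -= dv * gjx
        f_out[j, 1] -= dv * gjy
        f_out[j, 2] -= dv * gjz
        f_out[k, 0] -= dv * gkx
        f_out[k, 1] -= dv * gky
        f_out[k, 2] -= dv * gkz
        f_out[l, 0] -= dv * glx
        f_out[l, 1] -= dv * gly
        f_out[l, 2] -= dv * glz

    # native contacts
    for cpair in range(con_i.shape[0]):
        i = con_i[cpair]
        j = con_j[cpair]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        sr = con_r0[cpair] / r
        sr2 = sr * sr
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        eps = con_eps[cpair]
        if form == FORM_12_6:
            energy += eps * (sr12 - 2.0 * sr6)
            dv = -12.0 * eps * (sr12 - sr6) / r
        else:  # 12-10
            sr10 = sr12 / sr2
            energy += eps * (5.0 * sr12 - 6.0 * sr10)
            dv = -60.0 * eps * (sr12 - sr10) / r
        fmag = -dv / r
        f_out[i, 0] += fmag * dx
        f_out[i, 1] += fmag * dy
        f_out[i, 2] += fmag * dz
        f_out[j, 0] -= fmag * dx
        f_out[j, 1] -= fmag * dy
        f_out[j, 2] -= fmag * dz

    # excluded volume, truncated at r = sigma_ij (zero energy/force there)
    for p in range(n_ev):
        i = ev_i[p]
        j = ev_j[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s = ev_sig[p]
        if r2 >= s * s:
            continue
        r = np.sqrt(r2)
        sr = s / r
        sr2 = sr * sr
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        energy += eps_ev * (sr12 - 2.0 * sr6 + 1.0)
        dv = -12.0 * eps_ev * (sr12 - sr6) / r
        fmag = -dv / r
        f_out[i, 0] += fmag * dx
        f_out[i, 1] += fmag * dy
        f_out[i, 2] += fmag * dz
        f_out[j, 0] -= fmag * dx
        f_out[j, 1] -= fmag * dy
        f_out[j, 2] -= fmag * dz

    # positional restraints
    for rr in range(res_idx.shape[0]):
        i = res_idx[rr]
        kk = res_k[rr]
        dx = coords[i, 0] - res_x0[rr, 0]
        dy = coords[i, 1] - res_x0[rr, 1]
        dz = coords[i, 2] - res_x0[rr, 2]
        energy += 0.5 * kk * (dx * dx + dy * dy + dz * dz)
        f_out[i, 0] -= kk * dx
        f_out[i, 1] -= kk * dy
        f_out[i, 2] -= kk * dz

    return energy


@njit(cache=True)
def build_neighbor_list(coords, cand_i, cand_j, cand_sig, skin,
                        act_i, act_j, act_sig):
    """Fill the active-pair buffers with candidates within sigma+skin.

    Returns the number of active pairs.
    """
    n_act = 0
    for p in range(cand_i.shape[0]):
        i = cand_i[p]
        j = cand_j[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        cut = cand_sig[p] + skin
        if r2 < cut * cut:
            act_i[n_act] = i
            act_j[n_act] = j
            act_sig[n_act] = cand_sig[p]
            n_act += 1
    return n_act


@njit(cache=True)
def integrate_chunk(coords, vels, forces, mobile_idx,
                    dt, c1, c2, noise,
                    bond_i, bond_j, bond_r0, k_bond,
                    ang_i, ang_j, ang_k, ang_t0, k_angle,
                    dih_i, dih_j, dih_k, dih_l, dih_p0, k_dih,
                    con_i, con_j, con_r0, con_eps, form,
                    cand_i, cand_j, cand_sig, skin, eps_ev,
                    act_i, act_j, act_sig, n_act, ref_coords,
                    res_idx, res_x0, res_k,
                    frames_out, ke_out, stride, step_offset, frame_count):
    """Advance ``noise.shape[0]`` BAOAB steps in place.

    ``forces`` must hold the forces at the entry coordinates.  Frames are
    written whenever the global step index (step_offset + local step + 1)
    is a multiple of ``stride``.  Returns (status, local_step, n_act,
    frame_count): status 0 on success, 1 on divergence at local_step.
    """
    n_steps = noise.shape[0]
    n_mob = mobile_idx.shape[0]
    half = 0.5 * dt
    for step in range(n_steps):
        # B + A
        for m in range(n_mob):
            a = mobile_idx[m]
            vels[a, 0] += half * forces[a, 0]
            vels[a, 1] += half * forces[a, 1]
            vels[a, 2] += half * forces[a, 2]
            coords[a, 0] += half * vels[a, 0]
            coords[a, 1] += half * vels[a, 1]
            coords[a, 2] += half * vels[a, 2]
        # O
        for m in range(n_mob):
            a = mobile_idx[m]
            vels[a, 0] = c1 * vels[a, 0] + c2 * noise[step, m, 0]
            vels[a, 1] = c1 * vels[a, 1] + c2 * noise[step, m, 1]
            vels[a, 2] = c1 * vels[a, 2] + c2 * noise[step, m, 2]
        # A
        for m in range(n_mob):
            a = mobile_idx[m]
            coords[a, 0] += half * vels[a, 0]
            coords[a, 1] += half * vels[a, 1]
            coords[a, 2] += half * vels[a, 2]
        # neighbour-list maintenance
        max_d2 = 0.0
        for m in range(n_mob):
            a = mobile_idx[m]
            dx = coords[a, 0] - ref_coords[a, 0]
            dy = coords[a, 1] - ref_coords[a, 1]
            dz = coords[a, 2] - ref_coords[a, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > max_d2:
                max_d2 = d2
        if max_d2 > 0.25 * skin * skin:
            n_act = build_neighbor_list(coords, cand_i, cand_j, cand_sig,
                                        skin, act_i, act_j, act_sig)
            for a in range(coords.shape[0]):
                ref_coords[a, 0] = coords[a, 0]
                ref_coords[a, 1] = coords[a, 1]
                ref_coords[a, 2] = coords[a, 2]
        # force update + final B
        forces_energy(coords, forces,
                      bond_i, bond_j, bond_r0, k_bond,
                      ang_i, ang_j, ang_k, ang_t0, k_angle,
                      dih_i, dih_j, dih_k, dih_l, dih_p0, k_dih,
                      con_i, con_j, con_r0, con_eps, form,
                      act_i, act_j, act_sig, n_act, eps_ev,
                      res_idx, res_x0, res_k)
        ok = True
        for m in range(n_mob):
            a = mobile_idx[m]
            vels[a, 0] += half * forces[a, 0]
            vels[a, 1] += half * forces[a, 1]
            vels[a, 2] += half * forces[a, 2]
            if not (np.isfinite(coords[a, 0]) and np.isfinite(coords[a, 1])
                    and np.isfinite(coords[a, 2])):
                ok = False
        if not ok:
            return 1, step, n_act, frame_count
        if (step_offset + step + 1) % stride == 0:
            for a in range(coords.shape[0]):
                frames_out[frame_count, a, 0] = coords[a, 0]
                frames_out[frame_count, a, 1] = coords[a, 1]
                frames_out[frame_count, a, 2] = coords[a, 2]
            ke = 0.0
            for m in range(n_mob):
                a = mobile_idx[m]
                ke += 0.5 * (vels[a, 0] * vels[a, 0]
                             + vels[a, 1] * vels[a, 1]
                             + vels[a, 2] * vels[a, 2])
            ke_out[frame_count] = ke
            frame_count += 1
    return 0, n_steps, n_act, frame_count
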