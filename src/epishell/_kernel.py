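"""Jit-compiled energy/gradient kernel for the shell vertex model.

Single hot routine evaluating, in one pass over the centroid-fan
triangulation, the total energy (surface tensions + harmonic volume
constraints + junctional line tensions), the analytic gradient with
respect to every apical and basal vertex, per-cell volumes, the lumen
volume and the junction edge lengths.

The same formulas exist in plain numpy in :mod:`epishell.mesh`
(areas/volumes) and :mod:`epishell.energetics` (energies); the test suite
cross-checks the two paths and also checks the gradient against central
finite differences of the energy.
"""

import numba as nb
import numpy as np

__all__ = ["energy_and_gradient"]

# relaxed float ordering for speed, but keep NaN/Inf semantics so the
# non-finite-energy abort check in the stepping loop stays meaningful
_FASTMATH = {"contract", "reassoc", "nsz", "arcp"}


@nb.njit(cache=True, inline="always", fastmath=_FASTMATH)
def _cross(ax, ay, az, bx, by, bz):
    return ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx


@nb.njit(cache=True, fastmath=_FASTMATH)
def energy_and_gradient(apical, basal,
                        cells_flat, cells_off,
                        edges_u, edges_v, edge_cl, edge_cr,
                        gamma, cell_vtarget,
                        alpha, beta, k_cell, k_lumen, vlumen_target):
    """Returns (grad_a, grad_b, w_surface, w_constraint, w_line,
    cell_volumes, lumen_volume, l_apical, l_basal)."""
    nv = apical.shape[0]
    nc = cells_off.shape[0] - 1
    ne = edges_u.shape[0]

    ca = np.zeros((nc, 3))
    cb = np.zeros((nc, 3))
    for c in range(nc):
        s, e = cells_off[c], cells_off[c + 1]
        k = e - s
        for idx in range(s, e):
            v = cells_flat[idx]
            for d in range(3):
                ca[c, d] += apical[v, d]
                cb[c, d] += basal[v, d]
        for d in range(3):
            ca[c, d] /= k
            cb[c, d] /= k

    qc = np.empty((ne, 3))
    for j in range(ne):
        u, v = edges_u[j], edges_v[j]
        for d in range(3):
            qc[j, d] = 0.25 * (apical[u, d] + apical[v, d]
                               + basal[u, d] + basal[v, d])

    # ---- pass 1: volumes ------------------------------------------------
    vols = np.zeros(nc)
    vlum = 0.0
    for c in range(nc):
        s, e = cells_off[c], cells_off[c + 1]
        for idx in range(s, e):
            u = cells_flat[idx]
            v = cells_flat[s] if idx == e - 1 else cells_flat[idx + 1]
            cx, cy, cz = _cross(apical[u, 0], apical[u, 1], apical[u, 2],
                                apical[v, 0], apical[v, 1], apical[v, 2])
            ta = (ca[c, 0] * cx + ca[c, 1] * cy + ca[c, 2] * cz) / 6.0
            cx, cy, cz = _cross(basal[u, 0], basal[u, 1], basal[u, 2],
                                basal[v, 0], basal[v, 1], basal[v, 2])
            tb = (cb[c, 0] * cx + cb[c, 1] * cy + cb[c, 2] * cz) / 6.0
            vlum += ta
            vols[c] += tb - ta
    # lateral quads: (a_u, a_v, b_v, b_u) is oriented outward from the
    # cell holding the directed edge u -> v (edge_cl)
    corner = np.empty((4, 3))
    for j in range(ne):
        u, v = edges_u[j], edges_v[j]
        for d in range(3):
            corner[0, d] = apical[u, d]
            corner[1, d] = apical[v, d]
            corner[2, d] = basal[v, d]
            corner[3, d] = basal[u, d]
        qv = 0.0
        for k in range(4):
            k2 = (k + 1) % 4
            cx, cy, cz = _cross(corner[k, 0], corner[k, 1], corner[k, 2],
                                corner[k2, 0], corner[k2, 1], corner[k2, 2])
            qv += (qc[j, 0] * cx + qc[j, 1] * cy + qc[j, 2] * cz) / 6.0
        vols[edge_cl[j]] += qv
        vols[edge_cr[j]] -= qv

    # ---- pass 2: energy + gradient --------------------------------------
    ga = np.zeros((nv, 3))
    gb = np.zeros((nv, 3))
    gca = np.zeros((nc, 3))
    gcb = np.zeros((nc, 3))
    gqc = np.zeros((ne, 3))

    area_a_tot = 0.0
    area_b_tot = 0.0
    area_l_tot = 0.0

    for c in range(nc):
        s, e = cells_off[c], cells_off[c + 1]
        wv_cell = k_cell * (vols[c] - cell_vtarget[c])
        for idx in range(s, e):
            u = cells_flat[idx]
            v = cells_flat[s] if idx == e - 1 else cells_flat[idx + 1]
            for surf in range(2):
                if surf == 0:
                    pos = apical
                    cen = ca
                    gpos = ga
                    gcen = gca
                    coef = alpha
                    wv = -wv_cell + k_lumen * (vlum - vlumen_target)
                else:
                    pos = basal
                    cen = cb
                    gpos = gb
                    gcen = gcb
                    coef = beta
                    wv = wv_cell
                p0x, p0y, p0z = cen[c, 0], cen[c, 1], cen[c, 2]
                p1x, p1y, p1z = pos[u, 0], pos[u, 1], pos[u, 2]
                p2x, p2y, p2z = pos[v, 0], pos[v, 1], pos[v, 2]
                # area of (p0, p1, p2)
                nx, ny, nz = _cross(p1x - p0x, p1y - p0y, p1z - p0z,
                                    p2x - p0x, p2y - p0y, p2z - p0z)
                nn = np.sqrt(nx * nx + ny * ny + nz * nz)
                area = 0.5 * nn
                if surf == 0:
                    area_a_tot += area
                else:
                    area_b_tot += area
                if nn > 1e-14:
                    hx, hy, hz = nx / nn, ny / nn, nz / nn
                    f = 0.5 * coef
                    # dA/dp0 = 0.5 n_hat x (p2 - p1), etc.
                    cx, cy, cz = _cross(hx, hy, hz, p2x - p1x, p2y - p1y, p2z - p1z)
                    gcen[c, 0] += f * cx
                    gcen[c, 1] += f * cy
                    gcen[c, 2] += f * cz
                    cx, cy, cz = _cross(hx, hy, hz, p0x - p2x, p0y - p2y, p0z - p2z)
                    gpos[u, 0] += f * cx
                    gpos[u, 1] += f * cy
                    gpos[u, 2] += f * cz
                    cx, cy, cz = _cross(hx, hy, hz, p1x - p0x, p1y - p0y, p1z - p0z)
                    gpos[v, 0] += f * cx
                    gpos[v, 1] += f * cy
                    gpos[v, 2] += f * cz
                # volume gradient of tet (origin, p0, p1, p2), weight wv
                # sign: apical tets enter lumen with +, cell with -;
                # basal tets enter cell with +; wv already carries this.
                f = wv / 6.0
                cx, cy, cz = _cross(p1x, p1y, p1z, p2x, p2y, p2z)
                gcen[c, 0] += f * cx
                gcen[c, 1] += f * cy
                gcen[c, 2] += f * cz
                cx, cy, cz = _cross(p2x, p2y, p2z, p0x, p0y, p0z)
                gpos[u, 0] += f * cx
                gpos[u, 1] += f * cy
                gpos[u, 2] += f * cz
                cx, cy, cz = _cross(p0x, p0y, p0z, p1x, p1y, p1z)
                gpos[v, 0] += f * cx
                gpos[v, 1] += f * cy
                gpos[v, 2] += f * cz

    la = np.empty(ne)
    lb = np.empty(ne)
    w_line = 0.0
    cidx = np.empty(4, dtype=np.int64)
    for j in range(ne):
        u, v = edges_u[j], edges_v[j]
        wvq = (k_cell * (vols[edge_cl[j]] - cell_vtarget[edge_cl[j]])
               - k_cell * (vols[edge_cr[j]] - cell_vtarget[edge_cr[j]]))
        for d in range(3):
            corner[0, d] = apical[u, d]
            corner[1, d] = apical[v, d]
            corner[2, d] = basal[v, d]
            corner[3, d] = basal[u, d]
        cidx[0] = u
        cidx[1] = v
        cidx[2] = v
        cidx[3] = u
        p0x, p0y, p0z = qc[j, 0], qc[j, 1], qc[j, 2]
        for k in range(4):
            k2 = (k + 1) % 4
            p1x, p1y, p1z = corner[k, 0], corner[k, 1], corner[k, 2]
            p2x, p2y, p2z = corner[k2, 0], corner[k2, 1], corner[k2, 2]
            nx, ny, nz = _cross(p1x - p0x, p1y - p0y, p1z - p0z,
                                p2x - p0x, p2y - p0y, p2z - p0z)
            nn = np.sqrt(nx * nx + ny * ny + nz * nz)
            area_l_tot += 0.5 * nn
            # lateral tension coefficient is 1 (its own unit)
            if nn > 1e-14:
                hx, hy, hz = nx / nn, ny / nn, nz / nn
                cx, cy, cz = _cross(hx, hy, hz, p2x - p1x, p2y - p1y, p2z - p1z)
                gqc[j, 0] += 0.5 * cx
                gqc[j, 1] += 0.5 * cy
                gqc[j, 2] += 0.5 * cz
                g1 = ga if k < 2 else gb
                g2 = ga if k2 < 2 else gb
                cx, cy, cz = _cross(hx, hy, hz, p0x - p2x, p0y - p2y, p0z - p2z)
                g1[cidx[k], 0] += 0.5 * cx
                g1[cidx[k], 1] += 0.5 * cy
                g1[cidx[k], 2] += 0.5 * cz
                cx, cy, cz = _cross(hx, hy, hz, p1x - p0x, p1y - p0y, p1z - p0z)
                g2[cidx[k2], 0] += 0.5 * cx
                g2[cidx[k2], 1] += 0.5 * cy
                g2[cidx[k2], 2] += 0.5 * cz
            f = wvq / 6.0
            cx, cy, cz = _cross(p1x, p1y, p1z, p2x, p2y, p2z)
            gqc[j, 0] += f * cx
            gqc[j, 1] += f * cy
            gqc[j, 2] += f * cz
            g1 = ga if k < 2 else gb
            g2 = ga if k2 < 2 else gb
            cx, cy, cz = _cross(p2x, p2y, p2z, p0x, p0y, p0z)
            g1[cidx[k], 0] += f * cx
            g1[cidx[k], 1] += f * cy
            g1[cidx[k], 2] += f * cz
            cx, cy, cz = _cross(p0x, p0y, p0z, p1x, p1y, p1z)
            g2[cidx[k2], 0] += f * cx
            g2[cidx[k2], 1] += f * cy
            g2[cidx[k2], 2] += f * cz
        # line tension on the apical and basal edge of the junction
        dax = apical[u, 0] - apical[v, 0]
        day = apical[u, 1] - apical[v, 1]
        daz = apical[u, 2] - apical[v, 2]
        la[j] = np.sqrt(dax * dax + day * day + daz * daz)
        dbx = basal[u, 0] - basal[v, 0]
        dby = basal[u, 1] - basal[v, 1]
        dbz = basal[u, 2] - basal[v, 2]
        lb[j] = np.sqrt(dbx * dbx + dby * dby + dbz * dbz)
        g = gamma[j]
        if g != 0.0:
            w_line += g * (la[j] + lb[j])
            if la[j] > 1e-14:
                f = g / la[j]
                ga[u, 0] += f * dax
                ga[u, 1] += f * day
                ga[u, 2] += f * daz
                ga[v, 0] -= f * dax
                ga[v, 1] -= f * day
                ga[v, 2] -= f * daz
            if lb[j] > 1e-14:
                f = g / lb[j]
                gb[u, 0] += f * dbx
                gb[u, 1] += f * dby
                gb[u, 2] += f * dbz
                gb[v, 0] -= f * dbx
                gb[v, 1] -= f * dby
                gb[v, 2] -= f * dbz
        else:
            w_line += 0.0

    # ---- fold centroid gradients back onto vertices ----------------------
    for c in range(nc):
        s, e = cells_off[c], cells_off[c + 1]
        k = e - s
        for idx in range(s, e):
            v = cells_flat[idx]
            for d in range(3):
                ga[v, d] += gca[c, d] / k
                gb[v, d] += gcb[c, d] / k
    for j in range(ne):
        u, v = edges_u[j], edges_v[j]
        for d in range(3):
            ga[u, d] += 0.25 * gqc[j, d]
            ga[v, d] += 0.25 * gqc[j, d]
            gb[u, d] += 0.25 * gqc[j, d]
            gb[v, d] += 0.25 * gqc[j, d]

    w_surface = alpha * area_a_tot + beta * area_b_tot + area_l_tot
    w_constraint = 0.0
    for c in range(nc):
        dv = vols[c] - cell_vtarget[c]
        w_constraint += 0.5 * k_cell * dv * dv
    dvl = vlum - vlumen_target
    w_constraint += 0.5 * k_lumen * dvl * dvl

    return ga, gb, w_surface, w_constraint, w_line, vols, vlum, la, lb


@nb.njit(cache=True, fastmath=_FASTMATH)
def run_steps(apical, basal,
              cells_flat, cells_off,
              edges_u, edges_v, edge_cl, edge_cr,
              gamma, vtargets,
              alpha, beta, k_cell, k_lumen, vlumen_arr,
              dt, n_steps, threshold, mask,
              pair_u, pair_v,
              ou_enabled, ou_decay, ou_amp, noise,
              growth_enabled, growth_inc):
    """Advance up to ``n_steps`` overdamped Euler steps.

    Stops early when a T1 trigger fires (an unmasked junction's projected
    mid-length drops below ``threshold``; the triggering step is NOT
    executed), when the energy turns non-finite, or when a growing cell's
    target volume crosses 2 (division due).  ``mask`` marks junctions that
    are refractory or dwell-blocked; bits are cleared in place once a
    junction's mid-length exceeds the threshold.  OU line-tension noise and
    linear growth of cell/lumen targets are applied per executed step.

    Returns (steps_done, trigger_junction, status) with status
    0 = ran to completion, 1 = trigger, 2 = non-finite, 3 = division due.
    """
    ne = edges_u.shape[0]
    nd = pair_u.shape[0]
    for s in range(n_steps):
        ga, gb, ws, wc, wl, vols, vlum, la, lb = energy_and_gradient(
            apical, basal, cells_flat, cells_off,
            edges_u, edges_v, edge_cl, edge_cr,
            gamma, vtargets, alpha, beta, k_cell, k_lumen, vlumen_arr[s])
        trig = -1
        for j in range(ne):
            mid = 0.5 * (la[j] + lb[j])
            if mask[j]:
                if mid > threshold:
                    mask[j] = 0
            elif mid < threshold:
                trig = j
                break
        if trig >= 0:
            return s, trig, 1
        if not (np.isfinite(ws) and np.isfinite(wc) and np.isfinite(wl)):
            return s, -1, 2
        nv = apical.shape[0]
        for v in range(nv):
            for d in range(3):
                apical[v, d] -= dt * ga[v, d]
                basal[v, d] -= dt * gb[v, d]
        for p in range(nd):
            u, v = pair_u[p], pair_v[p]
            for d in range(3):
                m = 0.5 * (apical[u, d] + apical[v, d])
                apical[u, d] = m
                apical[v, d] = m
                m = 0.5 * (basal[u, d] + basal[v, d])
                basal[u, d] = m
                basal[v, d] = m
        if ou_enabled:
            amp = ou_amp[s]
            for j in range(ne):
                gamma[j] = gamma[j] * (1.0 - ou_decay) + amp * noise[s, j]
        if growth_enabled:
            crossed = False
            nc = vtargets.shape[0]
            for c in range(nc):
                if growth_inc[c] != 0.0:
                    vtargets[c] += growth_inc[c]
                    if vtargets[c] >= 2.0:
                        crossed = True
            if crossed:
                return s + 1, -1, 3
    return n_steps, -1, 0
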