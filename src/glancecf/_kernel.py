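"""Compiled trial loop.

Numerically mirrors the reference loop in :mod:`glancecf.environment`
(same equations, same random-draw order per step: own-acceleration noise
block, leader-acceleration noise block, three percept noises, resampling
offset), fused into a single jitted function so large virtual datasets
are affordable on one CPU.
"""

import math

import numpy as np
from numba import njit

RAD2DEG = 180.0 / math.pi


@njit(cache=True)
def run_trial_kernel(rng, n_steps, dt, n_particles,
                     v0, gap0, r0,
                     switch_times, targets, ramp,
                     sigma_F, sigma_phi, sigma_vphi, u_w, d_front,
                     v_floor, lam_a, sigma_aL,
                     v_max, T, a_max, b_max, delta, s0, s1,
                     sigma_star, n_glance,
                     d_lo, d_hi, r_lo, r_hi, leader_speed_prior):
    n = n_particles
    pv = np.full(n, v0)
    pd = rng.uniform(d_lo, d_hi, n)
    pr = rng.uniform(r_lo, r_hi, n)
    if leader_speed_prior:
        for k in range(n):
            pr[k] -= v0
    w = np.full(n, 1.0 / n)
    logw = np.empty(n)
    acc = np.empty(n)
    npv = np.empty(n)
    npd = np.empty(n)
    npr = np.empty(n)

    t_a = np.zeros(n_steps + 1)
    v_a = np.zeros(n_steps + 1)
    vL_a = np.zeros(n_steps + 1)
    d_a = np.zeros(n_steps + 1)
    r_a = np.zeros(n_steps + 1)
    a_a = np.zeros(n_steps + 1)
    s_a = np.zeros(n_steps + 1)
    occ_a = np.zeros(n_steps + 1, dtype=np.int8)
    lift_a = np.zeros(n_steps + 1, dtype=np.int8)

    v = v0
    vL = v0 + r0
    d = gap0
    r = r0
    a_prev = 0.0
    glance_start = -(2 ** 30)
    seg = 0
    nseg = switch_times.size
    n_rec = 0
    collided = False
    sq_ab = math.sqrt(a_max * b_max)

    for j in range(n_steps):
        t = j * dt
        while seg + 1 < nseg and switch_times[seg + 1] <= t + 1e-9:
            seg += 1

        # (1) belief prediction with the previous actuated acceleration
        eps_a = rng.standard_normal(n)
        eps_L = rng.standard_normal(n)
        sd_a = lam_a * abs(a_prev)
        for k in range(n):
            pd[k] += pr[k] * dt
            vL_k = pv[k] + pr[k]
            vnew = pv[k] + (a_prev + sd_a * eps_a[k]) * dt
            pv[k] = vnew if vnew > 0.0 else 0.0
            vLnew = vL_k + sigma_aL * eps_L[k] * dt
            if vLnew < 0.0:
                vLnew = 0.0
            pr[k] = vLnew - pv[k]

        # (2) percept sampling from the true scene
        eF = rng.standard_normal()
        ephi = rng.standard_normal()
        evphi = rng.standard_normal()
        vc = v if v > v_floor else v_floor
        zF = math.log(vc) + sigma_F * eF
        ddw = d + d_front
        zphi = 2.0 * math.atan(u_w / (2.0 * ddw)) * RAD2DEG + sigma_phi * ephi
        zvphi = (-4.0 * u_w * r / (4.0 * ddw * ddw + u_w * u_w) * RAD2DEG
                 + sigma_vphi * evphi)
        visible = (j > glance_start) and (j - glance_start < n_glance)

        # (3) Bayes reweighting (log space) and systematic resampling
        m = -np.inf
        for k in range(n):
            if pv[k] < 0.0 or pd[k] + d_front <= 0.0:
                lw = -np.inf
            else:
                pvc = pv[k] if pv[k] > v_floor else v_floor
                zf = (zF - math.log(pvc)) / sigma_F
                lw = -0.5 * zf * zf
                if visible:
                    pdd = pd[k] + d_front
                    ph = 2.0 * math.atan(u_w / (2.0 * pdd)) * RAD2DEG
                    z1 = (zphi - ph) / sigma_phi
                    vp = (-4.0 * u_w * pr[k]
                          / (4.0 * pdd * pdd + u_w * u_w) * RAD2DEG)
                    z2 = (zvphi - vp) / sigma_vphi
                    lw += -0.5 * (z1 * z1 + z2 * z2)
            logw[k] = lw
            if lw > m:
                m = lw
        if m == -np.inf:
            return (1, j, n_rec, collided, t_a, v_a, vL_a, d_a, r_a,
                    a_a, s_a, occ_a, lift_a)
        wsum = 0.0
        for k in range(n):
            w[k] = math.exp(logw[k] - m)
            wsum += w[k]
        for k in range(n):
            w[k] /= wsum

        u_off = rng.random()
        cum = w[0]
        src = 0
        for k in range(n):
            pos = (k + u_off) / n
            while cum < pos and src < n - 1:
                src += 1
                cum += w[src]
            npv[k] = pv[src]
            npd[k] = pd[src]
            npr[k] = pr[src]
        for k in range(n):
            pv[k] = npv[k]
            pd[k] = npd[k]
            pr[k] = npr[k]
            w[k] = 1.0 / n

        # (4) acceleration distribution via the IDM
        m1 = 0.0
        m2 = 0.0
        for k in range(n):
            if pd[k] <= 0.0:
                a_k = -b_max
            else:
                dv = -pr[k]
                vk = pv[k] if pv[k] > 0.0 else 0.0
                s_dyn = (s1 * math.sqrt(vk / v_max) + pv[k] * T
                         + pv[k] * dv / (2.0 * sq_ab))
                if s_dyn < 0.0:
                    s_dyn = 0.0
                s_st = s0 + s_dyn
                a_k = a_max * (1.0 - (pv[k] / v_max) ** delta
                               - (s_st / pd[k]) ** 2)
            acc[k] = a_k
            m1 += w[k] * a_k
            m2 += w[k] * a_k * a_k
        a_bar = m1
        var = m2 - m1 * m1
        sig = math.sqrt(var) if var > 0.0 else 0.0

        # (5) attention decision
        occluded_now = (j - glance_start) >= n_glance
        lift = occluded_now and (sig > sigma_star)
        if lift:
            glance_start = j
        occ = 0 if (j - glance_start) < n_glance else 1

        t_a[j] = t
        v_a[j] = v
        vL_a[j] = vL
        d_a[j] = d
        r_a[j] = r
        a_a[j] = a_bar
        s_a[j] = sig
        occ_a[j] = occ
        lift_a[j] = 1 if lift else 0
        n_rec = j + 1
        if not (math.isfinite(a_bar) and math.isfinite(sig)
                and math.isfinite(d)):
            return (2, j, n_rec, collided, t_a, v_a, vL_a, d_a, r_a,
                    a_a, s_a, occ_a, lift_a)

        # (6) actuate and advance the scene and leader
        tgt = targets[seg]
        dvl = tgt - vL
        step = ramp * dt
        if abs(dvl) <= step:
            vL_new = tgt
        else:
            vL_new = vL + (step if dvl > 0.0 else -step)
        if vL_new < 0.0:
            vL_new = 0.0
        v_new = v + a_bar * dt
        if v_new < 0.0:
            v_new = 0.0
        d = d + r * dt
        r = vL_new - v_new
        v = v_new
        vL = vL_new
        a_prev = a_bar
        if d <= 0.0:
            collided = True
            jj = j + 1
            t_a[jj] = jj * dt
            v_a[jj] = v
            vL_a[jj] = vL
            d_a[jj] = d
            r_a[jj] = r
            a_a[jj] = a_bar
            s_a[jj] = sig
            occ_a[jj] = 0 if (jj - glance_start) < n_glance else 1
            n_rec = jj + 1
            break
    return (0, -1, n_rec, collided, t_a, v_a, vL_a, d_a, r_a, a_a, s_a,
            occ_a, lift_a)
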