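"""Compiled transport kernels.

Everything in this module is numba-njit compiled and operates on the flat
array representation produced by :mod:`cemamc.transport`.  The particle loop
is a single stack-driven history processor; all randomness is drawn from a
per-history xoroshiro128+ stream seeded from ``(run seed, history id)``
(plus a variant index for phase-space replay), which makes runs bit
reproducible, restartable in chunks, and independent of whether passive
tallies are attached.

Layout conventions
------------------
* Region 0 is the vacuum world, region 1 the phantom, regions 2.. the
  cylinder bodies (later bodies take precedence in overlaps).
* ``geom`` tuple: ``(cyl, cylreg, half, matidx, bfac, ecut, iscav)``.
* ``mats`` tuple: photon/electron tables on log-uniform energy grids, see
  :func:`cemamc.transport.CompiledModel`.
* ``tal`` tuple: accumulators / squared sums / per-history buffers for dose,
  track ends and (species, bin) fluence, plus interaction-site counters.
* ``aud`` array: run-level energy bookkeeping (see AUD_* indices).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# audit slots
# ---------------------------------------------------------------------------
AUD_EMITTED = 0
AUD_DEPOSITED = 1
AUD_ESCAPED = 2
AUD_RR_KILLED = 3
AUD_RR_BOOST = 4
AUD_MASS_SINK = 5
AUD_MASS_SOURCE = 6
AUD_SUBPCUT = 7
AUD_MAX_IMBALANCE = 8
AUD_PRIMARY_UNCOLLIDED = 9
AUD_SIZE = 10

MEC2 = 0.51099895
TWO_MEC2 = 2.0 * MEC2
EPS_B = 1e-9  # boundary push-past [cm]

MAX_STACK = 40000

# kinds
PHOTON = 0
ELECTRON = 1
POSITRON = 2

_U64 = np.uint64
_C1 = _U64(0x9E3779B97F4A7C15)
_C2 = _U64(0xBF58476D1CE4E5B9)
_C3 = _U64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _splitmix(z):
    z = z + _C1
    z = (z ^ (z >> _U64(30))) * _C2
    z = (z ^ (z >> _U64(27))) * _C3
    return z ^ (z >> _U64(31))


@njit(cache=True)
def seed_stream(seed, hist_id, variant):
    """Initialize a 2-word xoroshiro128+ state for one history stream."""
    st = np.empty(2, dtype=np.uint64)
    z = (
        _U64(seed) * _U64(0xD1342543DE82EF95)
        ^ _U64(hist_id) * _U64(0xAF251AF3B0F025B5)
        ^ _U64(variant) * _U64(0x9E3779B97F4A7C15)
    )
    s0 = _splitmix(z)
    s1 = _splitmix(s0 ^ z)
    if s0 == _U64(0) and s1 == _U64(0):
        s0 = _U64(1)
    st[0] = s0
    st[1] = s1
    return st


@njit(cache=True, inline="always")
def _rotl(x, k):
    return (x << _U64(k)) | (x >> _U64(64 - k))


@njit(cache=True, inline="always")
def rnd(st):
    """Uniform double in [0, 1) from a xoroshiro128+ state (updated in place)."""
    s0 = st[0]
    s1 = st[1]
    result = s0 + s1
    s1 = s1 ^ s0
    st[0] = _rotl(s0, 55) ^ s1 ^ (s1 << _U64(14))
    st[1] = _rotl(s1, 36)
    return float(result >> _U64(11)) * _INV53


# ---------------------------------------------------------------------------
# table interpolation (log-uniform energy grids)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _grid_pos(lne, ln0, dln, n):
    x = (lne - ln0) / dln
    if x <= 0.0:
        return 0, 0.0
    if x >= n - 1:
        return n - 2, 1.0
    i = int(x)
    return i, x - i


@njit(cache=True, inline="always")
def interp_lin(table, mat, e, ln0, dln):
    """Linear-in-lnE interpolation of a linear-valued table row."""
    i, f = _grid_pos(math.log(e), ln0, dln, table.shape[1])
    return table[mat, i] * (1.0 - f) + table[mat, i + 1] * f


@njit(cache=True, inline="always")
def interp_loglog(table_ln, mat, e, ln0, dln):
    """Log-log interpolation of a table stored as ln(values)."""
    i, f = _grid_pos(math.log(e), ln0, dln, table_ln.shape[1])
    return math.exp(table_ln[mat, i] * (1.0 - f) + table_ln[mat, i + 1] * f)


@njit(cache=True, inline="always")
def range_of(lnrange, mat, e, ln0, dln):
    return interp_loglog(lnrange, mat, e, ln0, dln)


@njit(cache=True)
def energy_of_range(lnrange, lne_grid, mat, r, ln0, dln):
    """Inverse of :func:`range_of` (binary search + the same piecewise
    log-log relation, hence an exact segment-wise inverse)."""
    n = lnrange.shape[1]
    lnr = math.log(r) if r > 0.0 else -1e30
    lo = 0
    hi = n - 1
    if lnr <= lnrange[mat, 0]:
        # below the table: linear r ~ E
        return math.exp(lne_grid[0]) * r / math.exp(lnrange[mat, 0])
    if lnr >= lnrange[mat, n - 1]:
        return math.exp(lne_grid[n - 1])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if lnrange[mat, mid] <= lnr:
            lo = mid
        else:
            hi = mid
    f = (lnr - lnrange[mat, lo]) / (lnrange[mat, hi] - lnrange[mat, lo])
    return math.exp(lne_grid[lo] * (1.0 - f) + lne_grid[hi] * f)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@njit(cache=True)
def locate(cyl, cylreg, half, x, y, z):
    for i in range(cyl.shape[0] - 1, -1, -1):
        dz = z - cyl[i, 2]
        if dz <= cyl[i, 4] and dz >= -cyl[i, 4]:
            dx = x - cyl[i, 0]
            dy = y - cyl[i, 1]
            if dx * dx + dy * dy <= cyl[i, 3] * cyl[i, 3]:
                return cylreg[i]
    if abs(x) <= half[0] and abs(y) <= half[1] and abs(z) <= half[2]:
        return 1
    return 0


@njit(cache=True)
def nearest_surface(cyl, half, x, y, z, u, v, w):
    """Distance to the nearest surface crossing (phantom faces or any
    cylinder surface); inf if none ahead."""
    best = 1e300
    # phantom box faces
    for axis in range(3):
        d = u if axis == 0 else (v if axis == 1 else w)
        if d != 0.0:
            p = x if axis == 0 else (y if axis == 1 else z)
            for sgn in range(2):
                plane = half[axis] if sgn == 0 else -half[axis]
                t = (plane - p) / d
                if EPS_B < t < best:
                    ok = True
                    for o in range(3):
                        if o == axis:
                            continue
                        po = x if o == 0 else (y if o == 1 else z)
                        do = u if o == 0 else (v if o == 1 else w)
                        if abs(po + t * do) > half[o] + 1e-7:
                            ok = False
                            break
                    if ok:
                        best = t
    # cylinders
    for i in range(cyl.shape[0]):
        cx = cyl[i, 0]
        cy = cyl[i, 1]
        cz = cyl[i, 2]
        rad = cyl[i, 3]
        hh = cyl[i, 4]
        px = x - cx
        py = y - cy
        pz = z - cz
        a = u * u + v * v
        if a > 0.0:
            bq = px * u + py * v
            c = px * px + py * py - rad * rad
            disc = bq * bq - a * c
            if disc > 0.0:
                sq = math.sqrt(disc)
                t1 = (-bq - sq) / a
                t2 = (-bq + sq) / a
                if EPS_B < t1 < best and abs(pz + t1 * w) <= hh:
                    best = t1
                if EPS_B < t2 < best and abs(pz + t2 * w) <= hh:
                    best = t2
        if w != 0.0:
            for sgn in range(2):
                plane = hh if sgn == 0 else -hh
                t = (plane - pz) / w
                if EPS_B < t < best:
                    xx = px + t * u
                    yy = py + t * v
                    if xx * xx + yy * yy <= rad * rad:
                        best = t
    return best


@njit(cache=True, inline="always")
def box_entry(lo0, lo1, lo2, hi0, hi1, hi2, x, y, z, u, v, w):
    """Slab-method entry/exit distances of a ray into an AABB; returns
    (t_in, t_out), with t_in > t_out meaning no intersection."""
    tmin = -1e300
    tmax = 1e300
    for axis in range(3):
        p = x if axis == 0 else (y if axis == 1 else z)
        d = u if axis == 0 else (v if axis == 1 else w)
        lo = lo0 if axis == 0 else (lo1 if axis == 1 else lo2)
        hi = hi0 if axis == 0 else (hi1 if axis == 1 else hi2)
        if d == 0.0:
            if p < lo or p > hi:
                return 1.0, -1.0
        else:
            t1 = (lo - p) / d
            t2 = (hi - p) / d
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    return tmin, tmax


@njit(cache=True, inline="always")
def in_box(lo0, lo1, lo2, hi0, hi1, hi2, x, y, z):
    return lo0 <= x <= hi0 and lo1 <= y <= hi1 and lo2 <= z <= hi2


# ---------------------------------------------------------------------------
# direction rotation
# ---------------------------------------------------------------------------


@njit(cache=True)
def rotate(u, v, w, cos_t, phi):
    """Rotate unit vector (u, v, w) by polar angle theta (cos_t) about itself
    with azimuth phi."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(w) > 0.99999999:
        sign = 1.0 if w > 0.0 else -1.0
        return sin_t * cp, sin_t * sp, sign * cos_t
    st2 = u * u + v * v
    rho = math.sqrt(st2)
    nu = u * cos_t + sin_t * (u * w * cp - v * sp) / rho
    nv = v * cos_t + sin_t * (v * w * cp + u * sp) / rho
    nw = w * cos_t - rho * sin_t * cp
    norm = math.sqrt(nu * nu + nv * nv + nw * nw)
    return nu / norm, nv / norm, nw / norm

# ---------------------------------------------------------------------------
# physics sampling
# ---------------------------------------------------------------------------


@njit(cache=True)
def sample_spectrum(st, disc, cdf, evals, edges):
    u = rnd(st)
    n = cdf.shape[0]
    lo = 0
    hi = n - 1
    if u <= cdf[0]:
        i = 0
    else:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if cdf[mid] < u:
                lo = mid
            else:
                hi = mid
        i = hi
    if disc == 1:
        return evals[i]
    return edges[i] + rnd(st) * (edges[i + 1] - edges[i])


@njit(cache=True)
def sample_compton_k(st, e):
    """Klein-Nishina sampling (free electron at rest); returns
    (E_scattered, cos_theta_photon, T_electron, cos_theta_electron)."""
    k = e / MEC2
    eps_min = 1.0 / (1.0 + 2.0 * k)
    a1 = -math.log(eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        if rnd(st) * (a1 + a2) < a1:
            eps = eps_min * math.exp(a1 * rnd(st))
        else:
            eps = math.sqrt(eps_min * eps_min + (1.0 - eps_min * eps_min) * rnd(st))
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if rnd(st) <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            break
    cos_th = 1.0 - t
    e_sc = eps * e
    t_el = e - e_sc
    if t_el > 0.0:
        p_el = math.sqrt(t_el * (t_el + TWO_MEC2))
        cos_el = (e - e_sc * cos_th) / p_el
        if cos_el > 1.0:
            cos_el = 1.0
        elif cos_el < -1.0:
            cos_el = -1.0
    else:
        cos_el = 1.0
    return e_sc, cos_th, t_el, cos_el


@njit(cache=True)
def sample_moller_eps(st, e, delta):
    """Fractional transfer eps in [delta/E, 1/2] from the Moller spectrum
    (rejection against the 1/eps^2 envelope)."""
    eps0 = delta / e
    tau = e / MEC2
    g2 = (tau / (tau + 1.0)) ** 2
    c = (2.0 * tau + 1.0) / ((tau + 1.0) * (tau + 1.0))
    bmax = 2.0 + 0.25 * g2
    span = 1.0 - 2.0 * eps0
    while True:
        eps = eps0 / (1.0 - rnd(st) * span)
        one_m = 1.0 - eps
        g = 1.0 + eps * eps / (one_m * one_m) + g2 * eps * eps - c * eps / one_m
        if rnd(st) * bmax <= g:
            return eps


@njit(cache=True)
def highland_deflect(st, u, v, w, e, s, x0):
    """Single Gaussian multiple-scattering deflection (Highland) over a
    condensed step of length s [cm] at kinetic energy e."""
    if s <= 0.0:
        return u, v, w
    beta_pc = e * (e + TWO_MEC2) / (e + MEC2)
    xr = s / x0
    if xr < 1e-12:
        return u, v, w
    corr = 1.0 + 0.038 * math.log(xr)
    if corr < 0.25:
        corr = 0.25
    theta0 = 13.6 / beta_pc * math.sqrt(xr) * corr
    # Box-Muller
    r = math.sqrt(-2.0 * math.log(1.0 - rnd(st)))
    theta = abs(theta0 * r * math.cos(2.0 * math.pi * rnd(st)))
    if theta > 1.5:
        theta = 1.5
    return rotate(u, v, w, math.cos(theta), 2.0 * math.pi * rnd(st))


# ---------------------------------------------------------------------------
# scoring helpers
# ---------------------------------------------------------------------------


@njit(cache=True)
def score_fluence_step(tal, mats, opt, mat, species, e_hi, e_lo, s, wt):
    """Apportion the track length s of a slowing-down step [e_lo, e_hi] onto
    the energy bins, each bin weighted by its share of the CSDA path."""
    (dose_buf, te_buf, flu_buf, touched, ntouched, sites,
     fsum_buf, csum_buf, cema_w) = tal
    el_ln0 = mats[6]
    el_dln = mats[7]
    ln_range = mats[10]
    delta = opt[0]
    dw = opt[7]
    nbins = opt[8]
    if e_hi <= delta:
        return
    if e_lo < delta:
        e_lo = delta
    i_lo = int((e_lo - delta) / dw)
    i_hi = int((e_hi - delta) / dw)
    if i_hi >= nbins:
        i_hi = nbins - 1
    if i_lo >= nbins:
        return
    if i_lo == i_hi:
        _flu_add(tal, species, i_lo, wt * s)
        return
    r_hi = range_of(ln_range, mat, e_hi, el_ln0, el_dln)
    r_lo = range_of(ln_range, mat, e_lo, el_ln0, el_dln)
    denom = r_hi - r_lo
    if denom <= 0.0:
        _flu_add(tal, species, i_hi, wt * s)
        return
    r_prev = r_lo
    for i in range(i_lo, i_hi + 1):
        eb = delta + (i + 1) * dw
        if eb > e_hi or i == i_hi:
            r_next = r_hi
        else:
            r_next = range_of(ln_range, mat, eb, el_ln0, el_dln)
        frac = (r_next - r_prev) / denom
        if frac > 0.0:
            _flu_add(tal, species, i, wt * s * frac)
        r_prev = r_next


@njit(cache=True, inline="always")
def _flu_add(tal, species, i, val):
    (dose_buf, te_buf, flu_buf, touched, ntouched, sites,
     fsum_buf, csum_buf, cema_w) = tal
    if flu_buf[species, i] == 0.0:
        touched[ntouched[0]] = species * flu_buf.shape[1] + i
        ntouched[0] += 1
    flu_buf[species, i] += val
    # per-history scalar tallies: total track length and the cema integral
    # (bin-centre stopping-power weights), per species and combined, so the
    # history-by-history estimator sees the full within-history correlation
    fsum_buf[species] += val
    fsum_buf[2] += val
    c = val * cema_w[i]
    csum_buf[species] += c
    csum_buf[2] += c


@njit(cache=True, inline="always")
def push(stack, sp, kind, e, x, y, z, u, v, w, wt, flag):
    (skind, sE, sx, sy, sz, su, sv, sw, swt, sflag) = stack
    if sp >= skind.shape[0]:
        return -1
    skind[sp] = kind
    sE[sp] = e
    sx[sp] = x
    sy[sp] = y
    sz[sp] = z
    su[sp] = u
    sv[sp] = v
    sw[sp] = w
    swt[sp] = wt
    sflag[sp] = flag
    return sp + 1


@njit(cache=True, inline="always")
def _record(ipss, hist, kind, e, x, y, z, u, v, w, wt):
    (mode, lo, hi, rkind, re_, rx, ry, rz, ru, rv, rw, rwt, rhist, rcount, errflag) = ipss
    n = rcount[0]
    if n >= rkind.shape[0]:
        errflag[0] = 2
        return
    rkind[n] = kind
    re_[n] = e
    rx[n] = x
    ry[n] = y
    rz[n] = z
    ru[n] = u
    rv[n] = v
    rw[n] = w
    rwt[n] = wt
    rhist[n] = hist
    rcount[0] = n + 1


# ---------------------------------------------------------------------------
# electron / positron transport
# ---------------------------------------------------------------------------


@njit(cache=True)
def transport_electron(st, kind, e, x, y, z, u, v, w, wt, reg,
                       geom, mats, opt, tal, audh, stack, sp, ipss, hist):
    (cyl, cylreg, half, matidx, bfac, ecut, iscav) = geom
    (ph_ln0, ph_dln, mu_tot, mu_c, mu_p, mu_pp,
     el_ln0, el_dln, lne_grid, ln_scont, ln_range, sig_hard, x0cm) = mats
    (dose_buf, te_buf, flu_buf, touched, ntouched, sites,
     fsum_buf, csum_buf, cema_w) = tal
    delta = opt[0]
    estepe = opt[2]
    msc_on = opt[5]
    score_flu = opt[6]
    ipss_mode = ipss[0]
    lo = ipss[1]
    hi = ipss[2]
    species = 0 if kind == ELECTRON else 1
    while True:
        if reg == 0:
            # vacuum: charged particles cannot return (convex phantom)
            audh[AUD_ESCAPED] += e * wt
            if kind == POSITRON:
                audh[AUD_ESCAPED] += TWO_MEC2 * wt
                audh[AUD_MASS_SOURCE] += TWO_MEC2 * wt
            return sp
        ec = ecut[reg]
        if e <= ec:
            # terminal deposition: dose plus track-end tally
            dose_buf[reg] += e * wt
            te_buf[reg] += e * wt
            audh[AUD_DEPOSITED] += e * wt
            if kind == POSITRON:
                # annihilation at rest: two opposed 511 keV photons
                audh[AUD_MASS_SOURCE] += TWO_MEC2 * wt
                cz = 2.0 * rnd(st) - 1.0
                phi = 2.0 * math.pi * rnd(st)
                sn = math.sqrt(max(0.0, 1.0 - cz * cz))
                au = sn * math.cos(phi)
                av = sn * math.sin(phi)
                sp = push(stack, sp, PHOTON, MEC2, x, y, z, au, av, cz, wt, 0)
                if sp < 0:
                    return -1
                sp = push(stack, sp, PHOTON, MEC2, x, y, z, -au, -av, -cz, wt, 0)
                if sp < 0:
                    return -1
            return sp
        mat = matidx[reg]
        r_now = range_of(ln_range, mat, e, el_ln0, el_dln)
        s_cut = r_now - range_of(ln_range, mat, ec, el_ln0, el_dln)
        e_es = e * (1.0 - estepe)
        if e_es > ec:
            s_es = r_now - range_of(ln_range, mat, e_es, el_ln0, el_dln)
        else:
            s_es = s_cut
        sh = interp_lin(sig_hard, mat, e, el_ln0, el_dln)
        if sh > 0.0 and e > 2.0 * delta:
            s_hard = -math.log(1.0 - rnd(st)) / sh
        else:
            s_hard = 1e300
        d_b = nearest_surface(cyl, half, x, y, z, u, v, w)
        s = s_cut
        ev = 0  # 0 cut, 1 estepe, 2 hard, 3 boundary
        if s_es < s:
            s = s_es
            ev = 1
        if s_hard < s:
            s = s_hard
            ev = 2
        if d_b < s:
            s = d_b
            ev = 3
        if ipss_mode == 1 and not in_box(lo[0], lo[1], lo[2], hi[0], hi[1], hi[2], x, y, z):
            t_in, t_out = box_entry(lo[0], lo[1], lo[2], hi[0], hi[1], hi[2], x, y, z, u, v, w)
            if t_out > t_in and 0.0 < t_in <= s:
                # partial step up to the box surface, then suspend & record
                e_in = energy_of_range(ln_range, lne_grid, mat, r_now - t_in, el_ln0, el_dln)
                dose_buf[reg] += (e - e_in) * wt
                audh[AUD_DEPOSITED] += (e - e_in) * wt
                xx = x + t_in * u
                yy = y + t_in * v
                zz = z + t_in * w
                _record(ipss, hist, kind, e_in, xx, yy, zz, u, v, w, wt)
                audh[AUD_ESCAPED] += e_in * wt
                if kind == POSITRON:
                    audh[AUD_ESCAPED] += TWO_MEC2 * wt
                    audh[AUD_MASS_SOURCE] += TWO_MEC2 * wt
                return sp
        if ev == 0:
            e_new = ec
        else:
            e_new = energy_of_range(ln_range, lne_grid, mat, r_now - s, el_ln0, el_dln)
            if e_new > e:
                e_new = e
        dep = (e - e_new) * wt
        dose_buf[reg] += dep
        audh[AUD_DEPOSITED] += dep
        if score_flu == 1 and iscav[reg] == 1:
            score_fluence_step(tal, mats, opt, mat, species, e, e_new, s, wt)
        x += s * u
        y += s * v
        z += s * w
        if ev == 3:
            x += EPS_B * u
            y += EPS_B * v
            z += EPS_B * w
            reg = locate(cyl, cylreg, half, x, y, z)
        elif ev == 2 and e_new > 2.0 * delta:
            eps = sample_moller_eps(st, e_new, delta)
            t_d = eps * e_new
            e_r = e_new - t_d
            # kinematics of the knock-on and the deflected primary
            cos_d = math.sqrt((t_d / e_new) * (e_new + TWO_MEC2) / (t_d + TWO_MEC2))
            cos_p = math.sqrt((e_r / e_new) * (e_new + TWO_MEC2) / (e_r + TWO_MEC2)) if e_r > 0.0 else 1.0
            phi = 2.0 * math.pi * rnd(st)
            du, dv, dw_ = rotate(u, v, w, cos_d, phi + math.pi)
            sp = push(stack, sp, ELECTRON, t_d, x, y, z, du, dv, dw_, wt, 0)
            if sp < 0:
                return -1
            u, v, w = rotate(u, v, w, cos_p, phi)
            e_new = e_r
        if msc_on == 1 and s > 0.0:
            u, v, w = highland_deflect(st, u, v, w, 0.5 * (e + e_new), s, x0cm[mat])
        e = e_new


# ---------------------------------------------------------------------------
# photon transport
# ---------------------------------------------------------------------------


@njit(cache=True)
def transport_photon(st, e, x, y, z, u, v, w, wt, reg,
                     geom, mats, opt, tal, audh, stack, sp, ipss, hist, is_primary):
    (cyl, cylreg, half, matidx, bfac, ecut, iscav) = geom
    (ph_ln0, ph_dln, mu_tot, mu_c, mu_p, mu_pp,
     el_ln0, el_dln, lne_grid, ln_scont, ln_range, sig_hard, x0cm) = mats
    (dose_buf, te_buf, flu_buf, touched, ntouched, sites,
     fsum_buf, csum_buf, cema_w) = tal
    pcut = opt[1]
    xcse_on = opt[3]
    rr_on = opt[4]
    ipss_mode = ipss[0]
    lo = ipss[1]
    hi = ipss[2]
    collided = 0
    while True:
        if e < pcut:
            dose_buf[reg] += e * wt
            audh[AUD_DEPOSITED] += e * wt
            audh[AUD_SUBPCUT] += e * wt
            return sp
        if reg == 0:
            t_in, t_out = box_entry(-half[0], -half[1], -half[2],
                                    half[0], half[1], half[2], x, y, z, u, v, w)
            if t_out <= t_in or t_out <= 0.0:
                audh[AUD_ESCAPED] += e * wt
                if is_primary == 1 and collided == 0:
                    audh[AUD_PRIMARY_UNCOLLIDED] += 1.0
                return sp
            t_adv = t_in if t_in > 0.0 else 0.0
            if ipss_mode == 1 and not in_box(lo[0], lo[1], lo[2], hi[0], hi[1], hi[2], x, y, z):
                b_in, b_out = box_entry(lo[0], lo[1], lo[2], hi[0], hi[1], hi[2], x, y, z, u, v, w)
                if b_out > b_in and 0.0 < b_in <= t_adv:
                    _record(ipss, hist, PHOTON, e, x + b_in * u, y + b_in * v, z + b_in * w, u, v, w, wt)
                    audh[AUD_ESCAPED] += e * wt
                    return sp
            x += (t_adv + EPS_B) * u
            y += (t_adv + EPS_B) * v
            z += (t_adv + EPS_B) * w
            reg = locate(cyl, cylreg, half, x, y, z)
            continue
        eta = -math.log(1.0 - rnd(st))
        # march through regions until eta mean-free-paths are consumed
        while True:
            mat = matidx[reg]
            mu = interp_lin(mu_tot, mat, e, ph_ln0, ph_dln)
            b = bfac[reg] if xcse_on == 1 else 1.0
            mueff = mu * b
            d_b = nearest_surface(cyl, half, x, y, z, u, v, w)
            s_int = eta / mueff if mueff > 0.0 else 1e300
            s_adv = s_int if s_int < d_b else d_b
            if ipss_mode == 1 and not in_box(lo[0], lo[1], lo[2], hi[0], hi[1], hi[2], x, y, z):
                b_in, b_out = box_entry(lo[0], lo[1], lo[2], hi[0], hi[1], hi[2], x, y, z, u, v, w)
                if b_out > b_in and 0.0 < b_in <= s_adv:
                    _record(ipss, hist, PHOTON, e, x + b_in * u, y + b_in * v, z + b_in * w, u, v, w, wt)
                    audh[AUD_ESCAPED] += e * wt
                    return sp
            if s_int < d_b:
                x += s_int * u
                y += s_int * v
                z += s_int * w
                break
            eta -= mueff * d_b
            x += (d_b + EPS_B) * u
            y += (d_b + EPS_B) * v
            z += (d_b + EPS_B) * w
            reg = locate(cyl, cylreg, half, x, y, z)
            if reg == 0:
                # re-enter the world handler (escape or box record)
                break
        if reg == 0:
            continue
        # --- interaction at (x, y, z) in region reg ---
        collided = 1
        sites[reg] += 1
        mat = matidx[reg]
        mc = interp_lin(mu_c, mat, e, ph_ln0, ph_dln)
        mp = interp_lin(mu_p, mat, e, ph_ln0, ph_dln)
        mpp = interp_lin(mu_pp, mat, e, ph_ln0, ph_dln) if e > TWO_MEC2 else 0.0
        xi = rnd(st) * (mc + mp + mpp)
        b = bfac[reg] if xcse_on == 1 else 1.0
        if b <= 1.0:
            # analog interaction
            if xi < mc:
                e_sc, cos_th, t_el, cos_el = sample_compton_k(st, e)
                phi = 2.0 * math.pi * rnd(st)
                eu, evv, ew = rotate(u, v, w, cos_el, phi + math.pi)
                sp = push(stack, sp, ELECTRON, t_el, x, y, z, eu, evv, ew, wt, 0)
                if sp < 0:
                    return -1
                u, v, w = rotate(u, v, w, cos_th, phi)
                e = e_sc
                continue
            elif xi < mc + mp:
                sp = push(stack, sp, ELECTRON, e, x, y, z, u, v, w, wt, 0)
                return sp
            else:
                kt = e - TWO_MEC2
                f = rnd(st)
                audh[AUD_MASS_SINK] += TWO_MEC2 * wt
                sp = push(stack, sp, ELECTRON, f * kt, x, y, z, u, v, w, wt, 0)
                if sp < 0:
                    return -1
                sp = push(stack, sp, POSITRON, (1.0 - f) * kt, x, y, z, u, v, w, wt, 0)
                return sp
        else:
            # XCSE split: an interacting copy of weight wt/b, the original
            # photon survives with weight wt*(1 - 1/b)
            wi = wt / b
            if xi < mc:
                e_sc, cos_th, t_el, cos_el = sample_compton_k(st, e)
                phi = 2.0 * math.pi * rnd(st)
                eu, evv, ew = rotate(u, v, w, cos_el, phi + math.pi)
                sp = push(stack, sp, ELECTRON, t_el, x, y, z, eu, evv, ew, wi, 0)
                if sp < 0:
                    return -1
                gu, gv, gw = rotate(u, v, w, cos_th, phi)
                if rr_on == 1:
                    # Russian roulette: survivors restored to analog weight
                    if rnd(st) < 1.0 / b:
                        audh[AUD_RR_BOOST] += (wt - wi) * e_sc
                        sp = push(stack, sp, PHOTON, e_sc, x, y, z, gu, gv, gw, wt, 0)
                        if sp < 0:
                            return -1
                    else:
                        audh[AUD_RR_KILLED] += wi * e_sc
                else:
                    sp = push(stack, sp, PHOTON, e_sc, x, y, z, gu, gv, gw, wi, 0)
                    if sp < 0:
                        return -1
            elif xi < mc + mp:
                sp = push(stack, sp, ELECTRON, e, x, y, z, u, v, w, wi, 0)
                if sp < 0:
                    return -1
            else:
                kt = e - TWO_MEC2
                f = rnd(st)
                audh[AUD_MASS_SINK] += TWO_MEC2 * wi
                sp = push(stack, sp, ELECTRON, f * kt, x, y, z, u, v, w, wi, 0)
                if sp < 0:
                    return -1
                sp = push(stack, sp, POSITRON, (1.0 - f) * kt, x, y, z, u, v, w, wi, 0)
                if sp < 0:
                    return -1
            wt = wt * (1.0 - 1.0 / b)
            continue


# ---------------------------------------------------------------------------
# history driver
# ---------------------------------------------------------------------------


@njit(cache=True)
def _process_stack(st, geom, mats, opt, tal, audh, stack, sp, ipss, hist):
    (skind, sE, sx, sy, sz, su, sv, sw, swt, sflag) = stack
    (cyl, cylreg, half, matidx, bfac, ecut, iscav) = geom
    while sp > 0:
        sp -= 1
        kind = skind[sp]
        e = sE[sp]
        x = sx[sp]
        y = sy[sp]
        z = sz[sp]
        u = su[sp]
        v = sv[sp]
        w = sw[sp]
        wt = swt[sp]
        flag = sflag[sp]
        reg = locate(cyl, cylreg, half, x, y, z)
        if ipss[0] == 1 and in_box(ipss[1][0], ipss[1][1], ipss[1][2],
                                   ipss[2][0], ipss[2][1], ipss[2][2], x, y, z):
            # born inside the phase-space box during recording: record at birth
            _record(ipss, hist, kind, e, x, y, z, u, v, w, wt)
            audh[AUD_ESCAPED] += e * wt
            if kind == POSITRON:
                audh[AUD_ESCAPED] += TWO_MEC2 * wt
                audh[AUD_MASS_SOURCE] += TWO_MEC2 * wt
            continue
        if kind == PHOTON:
            sp = transport_photon(st, e, x, y, z, u, v, w, wt, reg,
                                  geom, mats, opt, tal, audh, stack, sp, ipss, hist, flag)
        else:
            sp = transport_electron(st, kind, e, x, y, z, u, v, w, wt, reg,
                                    geom, mats, opt, tal, audh, stack, sp, ipss, hist)
        if sp < 0:
            return -1
    return 0


@njit(cache=True)
def _flush_history(tal, dose_acc, dose_sq, te_acc, te_sq, flu_acc, flu_sq,
                   fsum_acc, fsum_sq, csum_acc, csum_sq):
    (dose_buf, te_buf, flu_buf, touched, ntouched, sites,
     fsum_buf, csum_buf, cema_w) = tal
    nreg = dose_buf.shape[0]
    for r in range(nreg):
        if dose_buf[r] != 0.0:
            dose_acc[r] += dose_buf[r]
            dose_sq[r] += dose_buf[r] * dose_buf[r]
            dose_buf[r] = 0.0
        if te_buf[r] != 0.0:
            te_acc[r] += te_buf[r]
            te_sq[r] += te_buf[r] * te_buf[r]
            te_buf[r] = 0.0
    nbins = flu_buf.shape[1]
    for k in range(ntouched[0]):
        idx = touched[k]
        s = idx // nbins
        i = idx % nbins
        val = flu_buf[s, i]
        flu_acc[s, i] += val
        flu_sq[s, i] += val * val
        flu_buf[s, i] = 0.0
    ntouched[0] = 0
    for s in range(3):
        if fsum_buf[s] != 0.0:
            fsum_acc[s] += fsum_buf[s]
            fsum_sq[s] += fsum_buf[s] * fsum_buf[s]
            fsum_buf[s] = 0.0
        if csum_buf[s] != 0.0:
            csum_acc[s] += csum_buf[s]
            csum_sq[s] += csum_buf[s] * csum_buf[s]
            csum_buf[s] = 0.0


@njit(cache=True)
def _merge_audit(aud, audh):
    for i in range(AUD_SIZE):
        if i != AUD_MAX_IMBALANCE:
            aud[i] += audh[i]
    bal = (audh[AUD_EMITTED] + audh[AUD_MASS_SOURCE] + audh[AUD_RR_BOOST]
           - audh[AUD_DEPOSITED] - audh[AUD_ESCAPED] - audh[AUD_RR_KILLED]
           - audh[AUD_MASS_SINK])
    denom = audh[AUD_EMITTED]
    if denom > 0.0:
        rel = abs(bal) / denom
        if rel > aud[AUD_MAX_IMBALANCE]:
            aud[AUD_MAX_IMBALANCE] = rel
    for i in range(AUD_SIZE):
        audh[i] = 0.0


@njit(cache=True)
def sample_source_primary(st, src):
    """Returns (E, x, y, z, u, v, w) for one primary photon."""
    (kind, sx, sy, sz, half_field, dref, disc, cdf, evals, edges) = src
    e = sample_spectrum(st, disc, cdf, evals, edges)
    if kind == 1:
        # isotropic
        w = 2.0 * rnd(st) - 1.0
        phi = 2.0 * math.pi * rnd(st)
        s = math.sqrt(max(0.0, 1.0 - w * w))
        return e, sx, sy, sz, s * math.cos(phi), s * math.sin(phi), w
    # collimated: uniform per solid angle into the field pyramid
    while True:
        px = (2.0 * rnd(st) - 1.0) * half_field
        py = (2.0 * rnd(st) - 1.0) * half_field
        r2 = px * px + py * py + dref * dref
        cos3 = (dref * dref * dref) / (r2 * math.sqrt(r2))
        if rnd(st) <= cos3:
            break
    rn = math.sqrt(r2)
    return e, sx, sy, sz, px / rn, py / rn, dref / rn


@njit(cache=True)
def run_batch(n_hist, hist_offset, seed, variant, src, geom, mats, opt,
              dose_acc, dose_sq, dose_buf, te_acc, te_sq, te_buf,
              flu_acc, flu_sq, flu_buf, touched, ntouched, sites,
              fsum_acc, fsum_sq, fsum_buf, csum_acc, csum_sq, csum_buf,
              cema_w, aud, ipss):
    """Transport ``n_hist`` primary histories; returns 0, or a nonzero
    diagnostic code (1 = particle stack overflow, 2 = phase-space record
    buffer full)."""
    tal = (dose_buf, te_buf, flu_buf, touched, ntouched, sites,
           fsum_buf, csum_buf, cema_w)
    skind = np.empty(MAX_STACK, dtype=np.int64)
    sE = np.empty(MAX_STACK, dtype=np.float64)
    sx = np.empty(MAX_STACK, dtype=np.float64)
    sy = np.empty(MAX_STACK, dtype=np.float64)
    sz = np.empty(MAX_STACK, dtype=np.float64)
    su = np.empty(MAX_STACK, dtype=np.float64)
    sv = np.empty(MAX_STACK, dtype=np.float64)
    sw = np.empty(MAX_STACK, dtype=np.float64)
    swt = np.empty(MAX_STACK, dtype=np.float64)
    sflag = np.empty(MAX_STACK, dtype=np.int64)
    stack = (skind, sE, sx, sy, sz, su, sv, sw, swt, sflag)
    audh = np.zeros(AUD_SIZE, dtype=np.float64)
    for h in range(n_hist):
        hist = hist_offset + h
        st = seed_stream(seed, hist, variant)
        e, x, y, z, u, v, w = sample_source_primary(st, src)
        audh[AUD_EMITTED] += e
        sp = push(stack, 0, PHOTON, e, x, y, z, u, v, w, 1.0, 1)
        code = _process_stack(st, geom, mats, opt, tal, audh, stack, sp, ipss, hist)
        if code < 0:
            return 1
        if ipss[14][0] != 0:
            return int(ipss[14][0])
        _flush_history(tal, dose_acc, dose_sq, te_acc, te_sq, flu_acc, flu_sq,
                       fsum_acc, fsum_sq, csum_acc, csum_sq)
        _merge_audit(aud, audh)
    return 0


@njit(cache=True)
def replay_batch(nrec, rkind, re_, rx, ry, rz, ru, rv, rw, rwt, rhist,
                 seed, variant, geom, mats, opt,
                 dose_acc, dose_sq, dose_buf, te_acc, te_sq, te_buf,
                 flu_acc, flu_sq, flu_buf, touched, ntouched, sites,
                 fsum_acc, fsum_sq, fsum_buf, csum_acc, csum_sq, csum_buf,
                 cema_w, aud):
    """Re-run recorded phase-space particles against a detector variant.

    Records must be ordered by history id (they are, being written
    sequentially); each history gets a fresh stream seeded from
    (seed, history id, variant)."""
    tal = (dose_buf, te_buf, flu_buf, touched, ntouched, sites,
           fsum_buf, csum_buf, cema_w)
    skind = np.empty(MAX_STACK, dtype=np.int64)
    sE = np.empty(MAX_STACK, dtype=np.float64)
    sx = np.empty(MAX_STACK, dtype=np.float64)
    sy = np.empty(MAX_STACK, dtype=np.float64)
    sz = np.empty(MAX_STACK, dtype=np.float64)
    su = np.empty(MAX_STACK, dtype=np.float64)
    sv = np.empty(MAX_STACK, dtype=np.float64)
    sw = np.empty(MAX_STACK, dtype=np.float64)
    swt = np.empty(MAX_STACK, dtype=np.float64)
    sflag = np.empty(MAX_STACK, dtype=np.int64)
    stack = (skind, sE, sx, sy, sz, su, sv, sw, swt, sflag)
    audh = np.zeros(AUD_SIZE, dtype=np.float64)
    # inert phase-space config (recording off)
    lo = np.zeros(3, dtype=np.float64)
    hi = np.zeros(3, dtype=np.float64)
    dummy_i = np.zeros(1, dtype=np.int64)
    dummy_f = np.zeros(1, dtype=np.float64)
    errflag = np.zeros(1, dtype=np.int64)
    ipss = (0, lo, hi, dummy_i, dummy_f, dummy_f, dummy_f, dummy_f,
            dummy_f, dummy_f, dummy_f, dummy_f, dummy_i, dummy_i, errflag)
    prev_hist = np.int64(-1)
    st = seed_stream(seed, 0, variant)
    for k in range(nrec):
        hist = rhist[k]
        if hist != prev_hist:
            if prev_hist >= 0:
                _flush_history(tal, dose_acc, dose_sq, te_acc, te_sq, flu_acc, flu_sq,
                       fsum_acc, fsum_sq, csum_acc, csum_sq)
                _merge_audit(aud, audh)
            st = seed_stream(seed, hist, variant)
            prev_hist = hist
        e = re_[k]
        wt = rwt[k]
        audh[AUD_EMITTED] += e * wt
        if rkind[k] == POSITRON:
            audh[AUD_MASS_SINK] += TWO_MEC2 * wt
        sp = push(stack, 0, rkind[k], e, rx[k], ry[k], rz[k], ru[k], rv[k], rw[k], wt, 0)
        code = _process_stack(st, geom, mats, opt, tal, audh, stack, sp, ipss, hist)
        if code < 0:
            return 1
    if prev_hist >= 0:
        _flush_history(tal, dose_acc, dose_sq, te_acc, te_sq, flu_acc, flu_sq,
                       fsum_acc, fsum_sq, csum_acc, csum_sq)
        _merge_audit(aud, audh)
    return 0
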